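"""Simulation configuration shared by every synthetic-data generator.

A single :class:`SimulationConfig` fixes all physical parameters and the seed,
so that identical configurations produce bit-identical synthetic data. All
random draws flow through one ``numpy.random.Generator`` created from the seed;
no global RNG state is touched.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .exceptions import ParameterError

#: Default true exchange rates, fmol/cell/h, positive = secretion.
#: Magnitudes are typical of a glycolytic breast-cancer line in culture:
#: glucose uptake ~100-200 fmol/cell/h with lactate secretion near twice the
#: glucose uptake on a molar basis, glutamine the dominant amino-acid uptake.
DEFAULT_EXCHANGE_RATES: Mapping[str, float] = {
    "glucose": -150.0,
    "lactate": 250.0,
    "glutamine": -30.0,
    "glutamate": 4.0,
    "alanine": 8.0,
    "serine": -6.0,
    "glycine": 3.0,
    "proline": 2.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for all synthetic inputs.

    Parameters
    ----------
    seed:
        Seed for the single RNG used by every generator.
    pixel_size:
        µm per pixel for rendered images.
    frame_interval, duration:
        Time-lapse sampling for the diffusion movie, seconds. Defaults match
        a 2 s interval over 5 min.
    vessel_radius:
        Channel radius in µm (150 µm for a 300 µm needle-molded channel).
    true_permeability:
        Diffusive permeability of the vessel wall, µm/s.
    matrix_diffusivity:
        Free-dye diffusivity in the collagen matrix, µm²/s. Default 400
        approximates FITC at 37 °C with mild hindrance in dilute collagen.
    reservoir_volume_factor:
        Effective well-mixed vessel reservoir volume as a multiple of the
        channel volume; large values make the vessel concentration decay
        slowly, as in a device whose channel connects to media reservoirs.
    photon_budget:
        Expected total photons per FLIM decay histogram.
    flim_a1, flim_tau1, flim_tau2:
        Two-component decay ground truth: short-lifetime amplitude fraction
        and the two lifetimes in ns (tau1 < tau2; free vs bound NADH).
    growth_rate:
        Exponential cell growth rate, 1/h.
    true_exchange_rates:
        Metabolite -> fmol/cell/h, positive = secretion.
    noise_levels:
        Per-channel relative (multiplicative) noise SD, keys among
        {"diffusion", "metabolites", "image"}; missing keys mean noise-free.
    """

    seed: int = 0
    pixel_size: float = 1.66
    frame_interval: float = 2.0
    duration: float = 300.0
    vessel_radius: float = 150.0
    true_permeability: float = 1.0
    matrix_diffusivity: float = 400.0
    reservoir_volume_factor: float = 25.0
    photon_budget: float = 1e5
    flim_a1: float = 0.8
    flim_tau1: float = 0.4
    flim_tau2: float = 2.5
    growth_rate: float = 0.02
    true_exchange_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCHANGE_RATES)
    )
    noise_levels: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "duration": self.duration,
            "vessel_radius": self.vessel_radius,
            "matrix_diffusivity": self.matrix_diffusivity,
            "reservoir_volume_factor": self.reservoir_volume_factor,
            "photon_budget": self.photon_budget,
            "flim_tau1": self.flim_tau1,
            "flim_tau2": self.flim_tau2,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value!r}")
        if self.true_permeability < 0 or not np.isfinite(self.true_permeability):
            raise ParameterError(
                f"true_permeability must be non-negative, got {self.true_permeability!r}"
            )
        if not 0.0 <= self.flim_a1 <= 1.0:
            raise ParameterError(f"flim_a1 must lie in [0, 1], got {self.flim_a1!r}")
        if self.flim_tau1 >= self.flim_tau2:
            raise ParameterError("flim_tau1 must be smaller than flim_tau2")
        for key, level in self.noise_levels.items():
            if level < 0:
                raise ParameterError(f"noise level {key!r} must be >= 0, got {level!r}")

    def rng(self) -> np.random.Generator:
        """Fresh deterministic generator derived from the seed."""
        return np.random.default_rng(self.seed)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def noise(self, channel: str) -> float:
        return float(self.noise_levels.get(channel, 0.0))
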