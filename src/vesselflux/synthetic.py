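"""Synthetic-data generators with known ground truth for every pipeline stage.

All generators draw from a single seeded RNG held by the
:class:`~vesselflux.config.SimulationConfig`, so identical configurations give
bit-identical outputs. What each generator emulates:

* :func:`simulate_vessel_diffusion` — a tracer (FITC-like) diffusing from a
  cylindrical 300 µm channel into collagen, imaged every 2 s for 5 min. The
  forward model is a 1D radial finite-volume diffusion solve with a
  membrane-limited wall flux J = P (c_vessel - c_wall) and a well-mixed,
  reservoir-buffered vessel, advanced by Crank–Nicolson.
* :func:`simulate_invasion_field` — non-overlapping elliptical cells whose
  elongation grows stochastically with distance past the tumor-channel edge,
  with an optional displacement bias toward the endothelial channel.
* :func:`simulate_flim_decays` — two-component exponential photon decays,
  bin-integrated and Poisson-sampled (delta IRF by default, optional Gaussian
  IRF convolution).
* :func:`simulate_metabolite_timecourse` — medium concentrations at 0/24/48 h
  under exponential cell growth with paired cell-free blank series.
* :func:`toy_core_network` — re-exported packaged metabolic network.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csc_matrix, identity
from scipy.sparse.linalg import splu
from skimage import draw as skdraw

from .config import SimulationConfig
from .exceptions import GenerationError, ParameterError
from .flim import DecayHistogram
from .fluxomics import ExchangeRate, MetaboliteTimeSeries
from .morphometry import LabelMask
from .network import AMINO_ACIDS, toy_core_network  # re-export
from .permeability import IntensityTimeSeries

__all__ = [
    "simulate_vessel_diffusion",
    "simulate_invasion_field",
    "simulate_flim_decays",
    "simulate_metabolite_timecourse",
    "toy_core_network",
    "simulate_disk_field",
    "simulate_adhesion_image",
    "simulate_contraction_field",
    "simulate_tracks",
    "condition_exchange_rates",
    "condition_culture_parameters",
    "DEFAULT_INITIAL_CONCENTRATIONS",
    "CONDITION_RATES_MODEL_UNITS",
]

logger = logging.getLogger(__name__)

#: Arbitrary fluorescence gain (a.u. per unit concentration).
_INTENSITY_GAIN = 1000.0


# ---------------------------------------------------------------------------
# vessel diffusion
# ---------------------------------------------------------------------------

def simulate_vessel_diffusion(
    cfg: SimulationConfig,
    dr_um: float = 1.5,
    domain_width_um: float = 600.0,
    max_dt_s: float = 0.05,
) -> IntensityTimeSeries:
    """Forward-simulate the tracer time-lapse of a leaky cylindrical channel.

    The matrix occupies R <= r <= R + ``domain_width_um`` on a radial
    finite-volume grid (reflecting outer face, so total tracer is conserved);
    the wall passes flux P (c_vessel - c_wall) per unit area; the vessel is
    well-mixed with an effective volume ``reservoir_volume_factor`` times the
    channel volume, so its concentration decays slowly. Reported traces are
    I_vessel ∝ c_vessel and I_ECM ∝ (matrix tracer per unit length)/(π R²),
    i.e. integrated matrix density normalized by the channel cross-section.
    """
    P = cfg.true_permeability
    R = cfg.vessel_radius
    D = cfg.matrix_diffusivity
    if R <= 0:
        raise ParameterError("vessel radius must be positive")

    n = int(np.ceil(domain_width_um / dr_um))
    faces = R + dr_um * np.arange(n + 1)
    volumes = np.pi * (faces[1:] ** 2 - faces[:-1] ** 2)  # per unit length
    v_vessel = cfg.reservoir_volume_factor * np.pi * R**2

    # conductances (flux = g * concentration difference), per unit length
    g_membrane = P * 2.0 * np.pi * R
    g_face = D * 2.0 * np.pi * faces[1:-1] / dr_um  # between matrix cells

    # state x = [c_vessel, c_0 .. c_{n-1}]; dx/dt = diag(1/V) L x with L the
    # symmetric conductance Laplacian (zero column sums -> exact conservation)
    size = n + 1
    vols = np.concatenate([[v_vessel], volumes])
    rows, cols, vals = [], [], []

    def add_link(i, j, g):
        rows.extend([i, j, i, j])
        cols.extend([i, j, j, i])
        vals.extend([-g, -g, g, g])

    add_link(0, 1, g_membrane)
    for k in range(n - 1):
        add_link(1 + k, 2 + k, g_face[k])
    L = csc_matrix((vals, (rows, cols)), shape=(size, size))
    W = csc_matrix(np.diag(1.0 / vols)) @ L

    time = np.arange(0.0, cfg.duration + 1e-9, cfg.frame_interval)
    substeps = max(int(np.ceil(cfg.frame_interval / max_dt_s)), 1)
    dt = cfg.frame_interval / substeps

    I = identity(size, format="csc")
    lhs = splu((I - (dt / 2.0) * W).tocsc())
    rhs = (I + (dt / 2.0) * W).tocsc()

    x = np.zeros(size)
    x[0] = 1.0  # dimensionless initial vessel concentration
    c_vessel = [x[0]]
    matrix_total = [float(x[1:] @ volumes)]
    for _ in range(len(time) - 1):
        for _ in range(substeps):
            x = lhs.solve(rhs @ x)
        c_vessel.append(x[0])
        matrix_total.append(float(x[1:] @ volumes))

    area = np.pi * R**2
    i_vessel = _INTENSITY_GAIN * np.asarray(c_vessel)
    i_ecm = _INTENSITY_GAIN * np.asarray(matrix_total) / area
    sigma = cfg.noise("diffusion")
    if sigma > 0:
        rng = cfg.rng()
        i_vessel = i_vessel * (1.0 + sigma * rng.standard_normal(i_vessel.shape))
        i_ecm = i_ecm * (1.0 + sigma * rng.standard_normal(i_ecm.shape))
    i_vessel = np.maximum(i_vessel, 0.0)
    i_ecm = np.maximum(i_ecm, 0.0)
    return IntensityTimeSeries(
        time=time, I_vessel=i_vessel, I_ecm=i_ecm, r_vessel=R, roi_area=area
    )


# ---------------------------------------------------------------------------
# invasion fields
# ---------------------------------------------------------------------------

def simulate_invasion_field(
    cfg: SimulationConfig,
    n_cells: int,
    bias: float = 0.0,
    edge_x: float = 0.0,
    field_size_um: Tuple[float, float] = (700.0, 700.0),
    placement_sd_um: float = 100.0,
    mean_radius_um: float = 12.0,
    ar_gain_per_100um: float = 1.0,
    max_tries: int = 200,
) -> Tuple[LabelMask, pd.DataFrame]:
    """Render non-overlapping elliptical cells with known morphometry.

    Cell x positions are normal around ``edge_x + bias`` (SD
    ``placement_sd_um``); the field spans ``edge_x`` ± half the field width so
    an unbiased population has zero mean signed invasion distance. The
    ground-truth aspect ratio grows stochastically with distance past the
    edge: AR = 1 + gain * max(0, x - edge_x)/100 µm * lognormal noise.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if bias < 0:
        raise ParameterError("bias must be >= 0")
    rng = cfg.rng()
    px = cfg.pixel_size
    fx, fy = field_size_um
    width = int(round(fx / px))
    height = int(round(fy / px))
    labels = np.zeros((height, width), dtype=np.int32)
    x0 = edge_x - fx / 2.0  # µm position of column 0

    records = []
    for cell_id in range(1, n_cells + 1):
        placed = False
        for _ in range(max_tries):
            x_um = rng.normal(edge_x + bias, placement_sd_um)
            y_um = rng.uniform(0.08 * fy, 0.92 * fy)
            if not (x0 + 0.08 * fx < x_um < x0 + 0.92 * fx):
                continue
            ar_noise = float(np.exp(rng.normal(0.0, 0.15)))
            ar = 1.0 + ar_gain_per_100um * max(0.0, x_um - edge_x) / 100.0 * ar_noise
            radius = rng.normal(mean_radius_um, 1.5)
            area = np.pi * radius**2
            b_ax = np.sqrt(area / (np.pi * ar))  # semi-minor, µm
            a_ax = ar * b_ax                     # semi-major, µm
            theta = rng.uniform(0.0, np.pi)
            row_c = y_um / px
            col_c = (x_um - x0) / px
            rr, cc = skdraw.ellipse(
                row_c, col_c, (a_ax + px) / px, (b_ax + px) / px,
                shape=labels.shape, rotation=theta,
            )
            if len(rr) == 0 or np.any(labels[rr, cc] != 0):
                continue
            rr, cc = skdraw.ellipse(
                row_c, col_c, a_ax / px, b_ax / px,
                shape=labels.shape, rotation=theta,
            )
            if len(rr) == 0:
                continue
            labels[rr, cc] = cell_id
            # analytic truth: Ramanujan perimeter of the ideal ellipse
            h = ((a_ax - b_ax) / (a_ax + b_ax)) ** 2
            perim = np.pi * (a_ax + b_ax) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
            records.append(
                {
                    "cell_id": cell_id,
                    "centroid_x_um": x_um,
                    "centroid_y_um": y_um,
                    "invasion_distance_um": x_um - edge_x,
                    "area_um2": np.pi * a_ax * b_ax,
                    "aspect_ratio": ar,
                    "circularity": 4 * np.pi * (np.pi * a_ax * b_ax) / perim**2,
                    "orientation_rad": theta,
                }
            )
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place cell {cell_id}/{n_cells} without overlap after "
                f"{max_tries} tries; lower the density or enlarge the field"
            )
    return LabelMask(labels, px), pd.DataFrame(records)


# ---------------------------------------------------------------------------
# FLIM decays
# ---------------------------------------------------------------------------

def simulate_flim_decays(
    cfg: SimulationConfig,
    n_pixels: int,
    n_bins: int = 256,
    t_max_ns: Optional[float] = None,
    irf_sigma_ns: float = 0.0,
) -> Tuple[List[DecayHistogram], Dict[str, float]]:
    """Poisson-sampled two-component decays with recorded ground truth.

    Expected counts follow the bin-integrated model
    A [a1 e^{-t/tau1} + (1-a1) e^{-t/tau2}] normalized to ``photon_budget``
    expected photons per pixel. The bin range covers at least 5 tau2. With
    ``irf_sigma_ns`` > 0 the expected curve is convolved with a Gaussian
    instrument response of that width.
    """
    if n_pixels < 1:
        raise ParameterError("n_pixels must be >= 1")
    if cfg.photon_budget < 100:
        logger.warning(
            "photon budget %.0f < 100: decay fits will be unstable", cfg.photon_budget
        )
    rng = cfg.rng()
    a1, tau1, tau2 = cfg.flim_a1, cfg.flim_tau1, cfg.flim_tau2
    if t_max_ns is None:
        t_max_ns = max(12.5, 5.0 * tau2)
    elif t_max_ns < 4.0 * tau2:
        raise ParameterError("bin range must cover at least 4*tau2")
    edges = np.linspace(0.0, t_max_ns, n_bins + 1)

    def integrated(tau: float) -> np.ndarray:
        return tau * (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau))

    expected = a1 * integrated(tau1) + (1.0 - a1) * integrated(tau2)
    if irf_sigma_ns > 0:
        from scipy.ndimage import gaussian_filter1d

        bin_w = edges[1] - edges[0]
        expected = gaussian_filter1d(expected, irf_sigma_ns / bin_w, mode="constant")
    expected = expected / expected.sum() * cfg.photon_budget

    hists = [
        DecayHistogram(
            bin_edges=edges,
            counts=rng.poisson(expected),
            pixel_or_cell_id=i,
        )
        for i in range(n_pixels)
    ]
    truth = {
        "a1": a1,
        "tau1_ns": tau1,
        "tau2_ns": tau2,
        "mean_tau_ns": a1 * tau1 + (1 - a1) * tau2,
        "photon_budget": cfg.photon_budget,
    }
    return hists, truth


# ---------------------------------------------------------------------------
# metabolite time courses
# ---------------------------------------------------------------------------

#: Starting medium composition, mM (glucose-rich DMEM-like medium).
DEFAULT_INITIAL_CONCENTRATIONS: Mapping[str, float] = {
    "glucose": 25.0,
    "lactate": 1.0,
    "glutamine": 4.0,
    "glutamate": 0.4,
    "alanine": 0.4,
    "serine": 0.4,
    "glycine": 0.4,
    "proline": 0.3,
}
_FALLBACK_C0_MM = 0.4


def simulate_metabolite_timecourse(
    cfg: SimulationConfig,
    timepoints_h: Sequence[float] = (0.0, 24.0, 48.0),
    n0_cells: float = 5e4,
    volume_ml: float = 1.0,
    initial_concentrations: Optional[Mapping[str, float]] = None,
    blank_drift_mm_per_h: float = 0.0,
) -> Dict[str, MetaboliteTimeSeries]:
    """Medium concentrations under exponential growth, with blanks.

    C_m(t) = C_m(0) + drift·t + v_m ∫N(s)ds / V with N(t) = N0 e^{µ t};
    abiotic drift is applied to both the sample and the cell-free blank so
    blank correction recovers the drift-free trajectory. Consumption is
    clipped at zero concentration and flagged. Multiplicative Gaussian noise
    at the configured "metabolites" level is applied to sampled
    concentrations (never to the t = 0 anchor of the blank).
    """
    t = np.asarray(timepoints_h, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ParameterError("timepoints must be sorted and start at 0")
    if initial_concentrations is None:
        initial_concentrations = DEFAULT_INITIAL_CONCENTRATIONS
    rng = cfg.rng()
    mu = cfg.growth_rate
    if abs(mu) > 1e-12:
        integral = n0_cells * np.expm1(mu * t) / mu  # cell*h
    else:
        integral = n0_cells * t
    cell_count = n0_cells * np.exp(mu * t)
    sigma = cfg.noise("metabolites")

    out: Dict[str, MetaboliteTimeSeries] = {}
    for met, rate in cfg.true_exchange_rates.items():
        c0 = float(initial_concentrations.get(met, _FALLBACK_C0_MM))
        drift = blank_drift_mm_per_h * t
        clean = c0 + drift + rate * integral * 1e-9 / volume_ml  # mM
        clipped = bool(np.any(clean < 0))
        clean = np.maximum(clean, 0.0)
        if clipped:
            logger.warning("metabolite %s clipped at 0 mM (consumption exceeds pool)", met)
        noisy = clean * (1.0 + sigma * rng.standard_normal(clean.shape)) if sigma > 0 else clean
        noisy = np.maximum(noisy, 0.0)
        blank = c0 + drift
        out[met] = MetaboliteTimeSeries(
            metabolite=met,
            time=t,
            concentration=noisy,
            concentration_sd=np.maximum(sigma * clean, 1e-12),
            cell_count=cell_count,
            volume=volume_ml,
            blank_concentration=blank,
            clipped=clipped,
        )
    return out


# ---------------------------------------------------------------------------
# auxiliary image/track generators for morphometry ground truth
# ---------------------------------------------------------------------------

def simulate_disk_field(
    cfg: SimulationConfig,
    n_disks: int,
    radius_px: float = 10.0,
    snr: float = 10.0,
    shape: Tuple[int, int] = (512, 512),
    max_tries: int = 500,
) -> Tuple[np.ndarray, LabelMask]:
    """Bright disks on a noisy background; truth mask returned alongside."""
    rng = cfg.rng()
    truth = np.zeros(shape, dtype=np.int32)
    margin = int(radius_px) + 3
    for disk_id in range(1, n_disks + 1):
        for _ in range(max_tries):
            r = rng.uniform(margin, shape[0] - margin)
            c = rng.uniform(margin, shape[1] - margin)
            rr, cc = skdraw.disk((r, c), radius_px + 3, shape=shape)
            if np.any(truth[rr, cc] != 0):
                continue
            rr, cc = skdraw.disk((r, c), radius_px, shape=shape)
            truth[rr, cc] = disk_id
            break
        else:
            raise GenerationError(f"could not place disk {disk_id} without overlap")
    image = (truth > 0).astype(float) + rng.standard_normal(shape) / snr
    return np.maximum(image, 0.0), LabelMask(truth, cfg.pixel_size)


def simulate_adhesion_image(
    cfg: SimulationConfig,
    mask: LabelMask,
    puncta_per_cell: Mapping[int, int],
    puncta_radius_px: float = 1.8,
    snr: float = 10.0,
) -> np.ndarray:
    """Seed bright puncta inside each cell of ``mask`` (known counts)."""
    from skimage import morphology as _morph

    rng = cfg.rng()
    img = np.zeros(mask.labels.shape, dtype=float)
    pad = int(np.ceil(puncta_radius_px)) + 4
    for cell_id, k in puncta_per_cell.items():
        cell = mask.labels == cell_id
        if not cell.any():
            raise ParameterError(f"cell {cell_id} not present in mask")
        # keep puncta clear of the cell boundary so they remain intact in
        # boundary-insensitive analyses
        interior = _morph.erosion(cell, _morph.disk(pad))
        rows, cols = np.nonzero(interior if interior.any() else cell)
        placed = []
        tries = 0
        while len(placed) < k and tries < 1000:
            tries += 1
            i = int(rng.integers(len(rows)))
            r, c = rows[i], cols[i]
            if any((r - pr) ** 2 + (c - pc) ** 2 < (2 * puncta_radius_px + 1) ** 2
                   for pr, pc in placed):
                continue
            rr, cc = skdraw.disk((r, c), puncta_radius_px, shape=img.shape)
            img[rr, cc] = 1.0
            placed.append((r, c))
        if len(placed) < k:
            raise GenerationError(f"could not place {k} puncta in cell {cell_id}")
    img = img + 0.2 * (mask.labels > 0)  # diffuse cytoplasmic signal
    img += rng.standard_normal(img.shape) / snr
    return np.maximum(img, 0.0)


def simulate_contraction_field(
    cfg: SimulationConfig,
    mask: LabelMask,
    ring_width_um: float = 10.0,
    peripheral_contrast: float = 1.0,
    n_fibers: int = 400,
    snr: float = 20.0,
) -> np.ndarray:
    """Fibrillar reflectance image with a set peri-cellular contrast.

    Random line segments emulate collagen fibers; fiber intensity inside the
    ``ring_width_um`` ring around cells is multiplied by
    ``peripheral_contrast`` (1.0 = homogeneous matrix).
    """
    from skimage import morphology as _morph

    rng = cfg.rng()
    shape = mask.labels.shape
    fibers = np.zeros(shape, dtype=float)
    diag = int(np.hypot(*shape))
    for _ in range(n_fibers):
        r0 = int(rng.integers(shape[0]))
        c0 = int(rng.integers(shape[1]))
        theta = rng.uniform(0, np.pi)
        length = int(rng.uniform(0.1, 0.4) * diag)
        r1 = int(np.clip(r0 + length * np.sin(theta), 0, shape[0] - 1))
        c1 = int(np.clip(c0 + length * np.cos(theta), 0, shape[1] - 1))
        rr, cc = skdraw.line(r0, c0, r1, c1)
        fibers[rr, cc] = 1.0
    # a few pixels wide, comparable to real fiber bundles and to the default
    # ridge-filter scale
    fibers = _morph.dilation(fibers, _morph.disk(1))
    ring_px = max(int(round(ring_width_um / mask.pixel_size)), 1)
    cells = mask.labels > 0
    ring = _morph.dilation(cells, _morph.disk(ring_px)) & ~cells
    gain = np.ones(shape)
    gain[ring] = peripheral_contrast
    img = fibers * gain
    img[cells] = 0.0
    img += np.abs(rng.standard_normal(shape)) / snr
    return img


def simulate_tracks(
    cfg: SimulationConfig,
    n_tracks: int,
    n_steps: int = 72,
    dt_s: float = 1200.0,
    step_sd_um: float = 5.0,
    drift_um_per_step: Tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Isotropic 2D random-walk tracks (20-min default sampling)."""
    rng = cfg.rng()
    frames = []
    t = np.arange(n_steps + 1) * dt_s
    for tid in range(n_tracks):
        steps = rng.normal(0.0, step_sd_um, size=(n_steps, 2)) + np.asarray(
            drift_um_per_step
        )
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        frames.append(
            pd.DataFrame(
                {"track_id": tid, "t_s": t, "x_um": xy[:, 0], "y_um": xy[:, 1]}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# demo study conditions for the FBA stage
# ---------------------------------------------------------------------------

#: Measured-style exchange rates per condition, mmol/gDW/h (positive =
#: secretion). "huvec_cm" emulates tumor cells exposed to endothelial
#: conditioned medium: more glucose uptake and lactate secretion, less
#: glutamate and asparagine secretion, more proline secretion, higher O2
#: consumption — the qualitative pattern measured in co-culture experiments.
CONDITION_RATES_MODEL_UNITS: Mapping[str, Mapping[str, Tuple[float, float]]] = {
    "ctrl_cm": {
        "glucose": (-0.35, 0.05),
        "lactate": (0.60, 0.09),
        "glutamine": (-0.15, 0.02),
        "glutamate": (0.030, 0.005),
        "alanine": (0.040, 0.006),
        "serine": (-0.030, 0.005),
        "proline": (0.010, 0.002),
        "aspartate": (-0.010, 0.002),
        "asparagine": (0.010, 0.002),
        "arginine": (-0.050, 0.008),
        "cysteine": (-0.020, 0.003),
        "histidine": (-0.020, 0.003),
        "isoleucine": (-0.050, 0.008),
        "methionine": (-0.020, 0.003),
        # measured but left unconstrained by default (the omitted set)
        "glycine": (0.020, 0.003),
        "leucine": (-0.060, 0.009),
        "lysine": (-0.050, 0.008),
        "phenylalanine": (-0.030, 0.005),
        "threonine": (-0.040, 0.006),
        "tryptophan": (-0.010, 0.002),
        "tyrosine": (-0.030, 0.005),
        "valine": (-0.050, 0.008),
    },
    "huvec_cm": {
        "glucose": (-0.50, 0.07),
        "lactate": (0.85, 0.12),
        "glutamine": (-0.20, 0.03),
        "glutamate": (0.010, 0.003),
        "alanine": (0.040, 0.006),
        "serine": (-0.040, 0.006),
        "proline": (0.030, 0.005),
        "aspartate": (-0.010, 0.002),
        "asparagine": (0.004, 0.001),
        "arginine": (-0.050, 0.008),
        "cysteine": (-0.020, 0.003),
        "histidine": (-0.020, 0.003),
        "isoleucine": (-0.050, 0.008),
        "methionine": (-0.020, 0.003),
        "glycine": (0.010, 0.002),
        "leucine": (-0.060, 0.009),
        "lysine": (-0.050, 0.008),
        "phenylalanine": (-0.030, 0.005),
        "threonine": (-0.040, 0.006),
        "tryptophan": (-0.010, 0.002),
        "tyrosine": (-0.030, 0.005),
        "valine": (-0.050, 0.008),
    },
}

#: Growth rate (1/h, ± SD) and O2 exchange (mmol/gDW/h, ± SD) per condition.
_CONDITION_CULTURE = {
    "ctrl_cm": {"growth_rate": (0.015, 0.002), "o2": (-0.20, 0.03)},
    "huvec_cm": {"growth_rate": (0.018, 0.002), "o2": (-0.30, 0.045)},
}


def condition_exchange_rates(condition: str) -> Dict[str, ExchangeRate]:
    """Measured-style exchange rates (model units) for a demo condition."""
    if condition not in CONDITION_RATES_MODEL_UNITS:
        raise ParameterError(
            f"unknown condition {condition!r}; "
            f"choose from {sorted(CONDITION_RATES_MODEL_UNITS)}"
        )
    return {
        met: ExchangeRate(metabolite=met, rate=rate, rate_sd=sd)
        for met, (rate, sd) in CONDITION_RATES_MODEL_UNITS[condition].items()
    }


def condition_culture_parameters(condition: str) -> Dict[str, Tuple[float, float]]:
    """Growth-rate and O2-exchange measurements for a demo condition."""
    if condition not in _CONDITION_CULTURE:
        raise ParameterError(f"unknown condition {condition!r}")
    return dict(_CONDITION_CULTURE[condition])
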