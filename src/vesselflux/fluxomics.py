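"""Per-cell exchange fluxes from extracellular metabolite time courses.

Media sampled at 0/24/48 h is blank-corrected and normalized to the (growing)
cell number. The exchange rate of metabolite *m* follows from mass balance on
the medium:

    C_m(T) - C_m(0) = v_m * integral_0^T N(t) dt / V,

with N(t) interpolated exponentially between measured cell counts, so

    v_m = dC * V / integral N dt        [positive = secretion]

in fmol/cell/h for concentrations in mM, volume in mL and time in h. The
growth integral has the closed form N0 (e^{mu T} - 1)/mu, continuous at
mu -> 0 where it reduces to N0*T.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = [
    "MetaboliteTimeSeries",
    "ExchangeRate",
    "blank_correct",
    "exchange_rate",
    "log2_fold_change",
    "estimate_exchange_rates",
    "fmol_per_cell_h_to_mmol_per_gdw_h",
    "mmol_per_gdw_h_to_fmol_per_cell_h",
    "rates_to_frame",
    "write_rates_csv",
    "read_metabolite_csv",
    "write_metabolite_csv",
]

#: Conversion constants between mM * mL and fmol: 1 mM * 1 mL = 1e9 fmol.
_FMOL_PER_MM_ML = 1e9

#: Default dry mass per cell for model-unit conversion, gDW/cell (300 pg).
DEFAULT_GDW_PER_CELL = 3e-10

SIGN_CONVENTION = "positive = secretion into medium, negative = consumption"


@dataclass(frozen=True)
class MetaboliteTimeSeries:
    """Concentration trajectory of one metabolite with matched cell counts."""

    metabolite: str
    time: np.ndarray               # h, includes 0
    concentration: np.ndarray      # mM (replicate mean)
    cell_count: np.ndarray         # cells at matched times
    volume: float                  # mL
    concentration_sd: Optional[np.ndarray] = None  # mM
    blank_concentration: Optional[np.ndarray] = None  # mM, cell-free wells
    clipped: bool = False          # True when the generator clipped at 0

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.concentration, dtype=float)
        n = np.asarray(self.cell_count, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "cell_count", n)
        if self.concentration_sd is not None:
            object.__setattr__(
                self, "concentration_sd", np.asarray(self.concentration_sd, dtype=float)
            )
        if self.blank_concentration is not None:
            object.__setattr__(
                self,
                "blank_concentration",
                np.asarray(self.blank_concentration, dtype=float),
            )
        if len(t) < 2 or len(c) != len(t) or len(n) != len(t):
            raise ParameterError("time, concentration and cell_count must align (>= 2 points)")
        if t[0] != 0:
            raise ParameterError("time course must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ParameterError("time must be strictly increasing")
        if self.volume <= 0:
            raise ParameterError("volume must be > 0")
        if np.any(n <= 0):
            raise ParameterError("cell counts must be > 0")


@dataclass(frozen=True)
class ExchangeRate:
    """Net exchange rate of one metabolite; sign per :data:`SIGN_CONVENTION`."""

    metabolite: str
    rate: float                    # fmol/cell/h
    rate_sd: float                 # fmol/cell/h
    log2fc: Optional[float] = None  # vs t = 0; None if C(0) not quantified


def blank_correct(series: MetaboliteTimeSeries) -> MetaboliteTimeSeries:
    """Remove cell-free medium drift while preserving the t = 0 anchor.

    corrected(t) = sample(t) - (blank(t) - blank(0)). Without a blank the
    series passes through unchanged (warning-level condition left to caller
    logging; the returned object is identical).
    """
    if series.blank_concentration is None:
        return series
    blank = series.blank_concentration
    if len(blank) != len(series.time):
        raise ParameterError("blank series must align with sample times")
    corrected = series.concentration - (blank - blank[0])
    return MetaboliteTimeSeries(
        metabolite=series.metabolite,
        time=series.time,
        concentration=corrected,
        cell_count=series.cell_count,
        volume=series.volume,
        concentration_sd=series.concentration_sd,
        blank_concentration=None,
        clipped=series.clipped,
    )


def _growth_integral(n0: float, mu: float, T: float) -> float:
    """integral_0^T n0 e^{mu t} dt, cell*h; exact limit n0*T as mu -> 0."""
    if abs(mu) < 1e-12:
        # expm1 keeps the mu->0 limit continuous to machine precision anyway,
        # but guard the exact-zero division.
        return n0 * T
    return n0 * np.expm1(mu * T) / mu


def exchange_rate(
    series: MetaboliteTimeSeries,
    growth_rate: Optional[float] = None,
) -> ExchangeRate:
    """Endpoint exchange rate in fmol/cell/h with propagated uncertainty.

    Parameters
    ----------
    series:
        Blank-corrected time course.
    growth_rate:
        Exponential growth rate in 1/h. When omitted it is inferred from the
        first and last measured cell counts.
    """
    t = series.time
    T = float(t[-1])
    n0 = float(series.cell_count[0])
    if growth_rate is None:
        growth_rate = float(np.log(series.cell_count[-1] / n0) / T)
    integral = _growth_integral(n0, growth_rate, T)  # cell*h
    d_conc = float(series.concentration[-1] - series.concentration[0])  # mM
    rate = d_conc * series.volume * _FMOL_PER_MM_ML / integral
    if series.concentration_sd is not None:
        sd = series.concentration_sd
        d_sd = float(np.hypot(sd[-1], sd[0]))
    else:
        d_sd = 0.0
    rate_sd = d_sd * series.volume * _FMOL_PER_MM_ML / integral
    return ExchangeRate(
        metabolite=series.metabolite,
        rate=float(rate),
        rate_sd=float(rate_sd),
        log2fc=log2_fold_change(series),
    )


def log2_fold_change(series: MetaboliteTimeSeries) -> Optional[float]:
    """log2(C(T)/C(0)); None when C(0) is not quantifiable (<= 0)."""
    c0 = float(series.concentration[0])
    cT = float(series.concentration[-1])
    if c0 <= 0 or cT <= 0:
        return None
    return float(np.log2(cT / c0))


def estimate_exchange_rates(
    series_collection: Iterable[MetaboliteTimeSeries],
    growth_rate: Optional[float] = None,
) -> Dict[str, ExchangeRate]:
    """Blank-correct and estimate rates for a collection of metabolites."""
    out: Dict[str, ExchangeRate] = {}
    for series in series_collection:
        corrected = blank_correct(series)
        out[corrected.metabolite] = exchange_rate(corrected, growth_rate=growth_rate)
    return out


def fmol_per_cell_h_to_mmol_per_gdw_h(
    rate: float, gdw_per_cell: float = DEFAULT_GDW_PER_CELL
) -> float:
    """fmol/cell/h -> mmol/gDW/h (1 fmol = 1e-12 mmol)."""
    return rate * 1e-12 / gdw_per_cell


def mmol_per_gdw_h_to_fmol_per_cell_h(
    rate: float, gdw_per_cell: float = DEFAULT_GDW_PER_CELL
) -> float:
    return rate * gdw_per_cell / 1e-12


def rates_to_frame(rates: Mapping[str, ExchangeRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "rate_fmol_cell_h": r.rate,
                "rate_sd_fmol_cell_h": r.rate_sd,
                "log2fc": np.nan if r.log2fc is None else r.log2fc,
            }
            for r in rates.values()
        ]
    ).set_index("metabolite")


def write_rates_csv(rates: Mapping[str, ExchangeRate], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sign convention: {SIGN_CONVENTION}\n")
        rates_to_frame(rates).to_csv(fh)


def write_metabolite_csv(series_collection: Iterable[MetaboliteTimeSeries], path) -> None:
    rows = []
    for s in series_collection:
        sd = s.concentration_sd if s.concentration_sd is not None else np.zeros_like(s.time)
        for i, t in enumerate(s.time):
            rows.append(
                {
                    "metabolite": s.metabolite,
                    "time_h": t,
                    "conc_mM": s.concentration[i],
                    "conc_sd": sd[i],
                    "cell_count": s.cell_count[i],
                    "volume_mL": s.volume,
                    "is_blank": False,
                }
            )
            if s.blank_concentration is not None:
                rows.append(
                    {
                        "metabolite": s.metabolite,
                        "time_h": t,
                        "conc_mM": s.blank_concentration[i],
                        "conc_sd": 0.0,
                        "cell_count": s.cell_count[i],
                        "volume_mL": s.volume,
                        "is_blank": True,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metabolite_csv(path) -> Dict[str, MetaboliteTimeSeries]:
    df = pd.read_csv(path)
    out: Dict[str, MetaboliteTimeSeries] = {}
    for met, grp in df.groupby("metabolite"):
        sample = grp[~grp["is_blank"]].sort_values("time_h")
        blank = grp[grp["is_blank"]].sort_values("time_h")
        out[str(met)] = MetaboliteTimeSeries(
            metabolite=str(met),
            time=sample["time_h"].to_numpy(),
            concentration=sample["conc_mM"].to_numpy(),
            concentration_sd=sample["conc_sd"].to_numpy(),
            cell_count=sample["cell_count"].to_numpy(),
            volume=float(sample["volume_mL"].iloc[0]),
            blank_concentration=blank["conc_mM"].to_numpy() if len(blank) else None,
        )
    return out


def read_rates_csv(path) -> Dict[str, ExchangeRate]:
    """Read a rates CSV (metabolite, rate, sd[, log2fc]); '#' lines ignored.

    Accepts both the column names written by :func:`write_rates_csv` and the
    short schema (rate, sd).
    """
    df = pd.read_csv(path, comment="#")
    rate_col = "rate_fmol_cell_h" if "rate_fmol_cell_h" in df.columns else "rate"
    sd_col = "rate_sd_fmol_cell_h" if "rate_sd_fmol_cell_h" in df.columns else "sd"
    out: Dict[str, ExchangeRate] = {}
    for _, row in df.iterrows():
        fc = row.get("log2fc", np.nan)
        out[str(row["metabolite"])] = ExchangeRate(
            metabolite=str(row["metabolite"]),
            rate=float(row[rate_col]),
            rate_sd=float(row[sd_col]) if sd_col in df.columns else 0.0,
            log2fc=None if pd.isna(fc) else float(fc),
        )
    return out
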