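"""Diffusive permeability of a microvessel from fluorescence time-lapse traces.

The measurement follows Fick's first law for a cylindrical channel. With a
membrane-limited wall, the tracer flux per unit wall area is

    J = P_D * (c_vessel - c_ECM),

and, while the matrix concentration near the wall is small compared to the
vessel, the permeability follows from the initial vessel intensity and the
early-time slope of the matrix signal:

    P_D = (r_vessel / 2) * (dI_ECM/dt) / I_vessel(0),

where ``I_ECM`` is the integrated matrix fluorescence normalized by the
channel cross-sectional area (pi r^2), so intensity units cancel and P_D comes
out in µm/s when r is in µm and time in s.

The estimator is valid in the membrane-limited regime. When P_D approaches
the diffusive conductance of the matrix (P_D * sqrt(t_frame / D) no longer
small), tracer piles up at the wall between frames, the c_vessel >> c_ECM
assumption fails within the first frame interval, and the slope saturates;
see docs/methods.md for the quantitative breakdown.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import FitError, ParameterError

__all__ = [
    "IntensityTimeSeries",
    "SlopeFit",
    "PermeabilityResult",
    "fit_ecm_slope",
    "diffusive_permeability",
    "estimate_permeability",
    "compare_conditions",
    "read_traces_csv",
    "write_traces_csv",
]


@dataclass(frozen=True)
class IntensityTimeSeries:
    """Vessel and matrix ROI intensity traces with channel geometry.

    ``I_ecm`` is the integrated matrix fluorescence divided by the channel
    cross-sectional area ``roi_area`` (same arbitrary intensity units as
    ``I_vessel``), so the permeability formula is unit-free.
    """

    time: np.ndarray          # s, strictly increasing
    I_vessel: np.ndarray      # a.u.
    I_ecm: np.ndarray         # a.u.
    r_vessel: float           # µm
    roi_area: float = 0.0     # µm²; 0 -> pi r^2 implied

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        iv = np.asarray(self.I_vessel, dtype=float)
        ie = np.asarray(self.I_ecm, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "I_vessel", iv)
        object.__setattr__(self, "I_ecm", ie)
        if not (len(time) == len(iv) == len(ie)):
            raise ParameterError("time, I_vessel and I_ecm must have equal length")
        if len(time) < 3:
            raise ParameterError("need at least 3 frames")
        if np.any(np.diff(time) <= 0):
            raise ParameterError("time must be strictly increasing")
        if self.r_vessel <= 0:
            raise ParameterError(f"r_vessel must be > 0, got {self.r_vessel!r}")
        if self.roi_area == 0.0:
            object.__setattr__(self, "roi_area", float(np.pi * self.r_vessel**2))

    @property
    def n_frames(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class SlopeFit:
    slope: float            # a.u./s
    stderr: float           # a.u./s
    window: Tuple[float, float]  # (t_start, t_end), s
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class PermeabilityResult:
    p_d: float                       # µm/s
    slope: float                     # a.u./s
    slope_stderr: float              # a.u./s
    fit_window: Tuple[float, float]  # s
    I_vessel_0: float                # a.u.
    r_squared: float


def _ols_line(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Slope, slope-stderr and r² of an OLS line fit."""
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise FitError("zero time variance in fit window")
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if n > 2:
        sigma2 = ss_res / (n - 2)
        stderr = float(np.sqrt(sigma2 / sxx))
    else:
        stderr = float("nan")
    return float(slope), stderr, r2


def _quadratic_significant(t: np.ndarray, y: np.ndarray) -> bool:
    """True when a quadratic term is statistically detectable (|t-stat| > 2).

    Used to find the end of the linear portion of a trace: the window stops
    growing as soon as curvature is resolvable above the residual noise.
    """
    if len(t) < 5:
        return False
    ts = (t - t.mean()) / max(float(np.ptp(t)), 1e-300)
    X = np.column_stack([np.ones_like(ts), ts, ts**2])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(t) - 3
    if dof <= 0:
        return False
    fitted = X @ coef
    sigma2 = float(np.sum((y - fitted) ** 2)) / dof
    scale = float(np.max(np.abs(y))) + 1e-300
    if sigma2 <= (1e-9 * scale) ** 2 or abs(coef[2]) <= 1e-8 * scale:
        return False  # residuals / curvature at float-noise level: treat as linear
    cov = np.linalg.inv(X.T @ X) * sigma2
    tstat = coef[2] / np.sqrt(cov[2, 2])
    return abs(tstat) > 2.0


def _auto_window(time: np.ndarray, y: np.ndarray, min_frames: int = 5) -> int:
    """Number of leading frames forming the linear portion of ``y(t)``.

    Expands a prefix window from ``min_frames`` and stops just before the
    quadratic curvature term becomes significant. Exactly linear traces use
    all frames; smoothly concave noise-free traces stop at ``min_frames``,
    which carries the least-biased early-time slope.
    """
    n = len(time)
    k = min(min_frames, n)
    while k < n and not _quadratic_significant(time[: k + 1], y[: k + 1]):
        k += 1
    return k


def fit_ecm_slope(
    series: IntensityTimeSeries,
    window: Optional[Tuple[float, float]] = None,
    min_frames: int = 5,
) -> SlopeFit:
    """OLS slope of the matrix intensity trace on the linear portion.

    Parameters
    ----------
    series:
        Vessel/matrix traces.
    window:
        Optional explicit ``(t_start, t_end)`` in seconds. When omitted the
        linear portion is selected automatically (curvature-test window
        starting at frame 0, minimum ``min_frames`` frames).
    """
    t, y = series.time, series.I_ecm
    if window is not None:
        t0, t1 = window
        sel = (t >= t0) & (t <= t1)
        if sel.sum() < 3:
            raise FitError(f"fewer than 3 frames in window {window!r}")
        tw, yw = t[sel], y[sel]
    else:
        k = _auto_window(t, y, min_frames=min_frames)
        tw, yw = t[:k], y[:k]
    slope, stderr, r2 = _ols_line(tw, yw)
    return SlopeFit(
        slope=slope,
        stderr=stderr,
        window=(float(tw[0]), float(tw[-1])),
        r_squared=r2,
        n_points=len(tw),
    )


def diffusive_permeability(
    series: IntensityTimeSeries,
    slope_fit: SlopeFit,
    background: float = 0.0,
    n_baseline_frames: int = 3,
) -> PermeabilityResult:
    """Permeability from the matrix slope and the initial vessel intensity.

    ``I_vessel(0)`` is the mean background-subtracted vessel intensity over the
    first ``n_baseline_frames`` frames. Units cancel between the two traces;
    the result is µm/s for r in µm and time in s.
    """
    baseline = float(np.mean(series.I_vessel[:n_baseline_frames])) - background
    if baseline <= 0:
        raise ParameterError(
            f"background-subtracted baseline vessel intensity must be > 0, got {baseline!r}"
        )
    p_d = (series.r_vessel / 2.0) * slope_fit.slope / baseline
    return PermeabilityResult(
        p_d=float(p_d),
        slope=slope_fit.slope,
        slope_stderr=slope_fit.stderr,
        fit_window=slope_fit.window,
        I_vessel_0=baseline,
        r_squared=slope_fit.r_squared,
    )


def estimate_permeability(
    series: IntensityTimeSeries,
    window: Optional[Tuple[float, float]] = None,
    background: float = 0.0,
) -> PermeabilityResult:
    """Convenience chain: slope fit then permeability."""
    return diffusive_permeability(series, fit_ecm_slope(series, window=window),
                                  background=background)


def compare_conditions(
    groups: Mapping[str, Sequence[PermeabilityResult]],
) -> pd.DataFrame:
    """Per-condition mean ± SD of permeability with an ordering report.

    Returns a DataFrame indexed by condition with columns
    ``mean_um_s, sd_um_s, n, single_replicate, rank`` (rank 1 = lowest mean).
    """
    rows = {}
    for name, results in groups.items():
        values = [r.p_d for r in results]
        if len(values) == 0:
            raise ParameterError(f"condition {name!r} has no replicates")
        rows[name] = {
            "mean_um_s": float(np.mean(values)),
            "sd_um_s": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
            "n": len(values),
            "single_replicate": len(values) == 1,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["rank"] = table["mean_um_s"].rank(method="min").astype(int)
    return table.sort_values("rank")


def write_traces_csv(series: IntensityTimeSeries, path) -> None:
    df = pd.DataFrame(
        {"time_s": series.time, "I_vessel": series.I_vessel, "I_ECM": series.I_ecm}
    )
    with open(path, "w") as fh:
        fh.write(f"# r_vessel_um={series.r_vessel} roi_area_um2={series.roi_area}\n")
        df.to_csv(fh, index=False)


def read_traces_csv(path, r_vessel: Optional[float] = None) -> IntensityTimeSeries:
    """Read a trace CSV (columns time_s, I_vessel, I_ECM).

    A leading ``# r_vessel_um=...`` comment supplies the radius unless one is
    passed explicitly.
    """
    with open(path) as fh:
        first = fh.readline()
        meta: Dict[str, float] = {}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key] = float(value)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if r_vessel is None:
        if "r_vessel_um" not in meta:
            raise ParameterError("r_vessel not given and not present in CSV header")
        r_vessel = meta["r_vessel_um"]
    return IntensityTimeSeries(
        time=df["time_s"].to_numpy(),
        I_vessel=df["I_vessel"].to_numpy(),
        I_ecm=df["I_ECM"].to_numpy(),
        r_vessel=float(r_vessel),
        roi_area=float(meta.get("roi_area_um2", 0.0)),
    )
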