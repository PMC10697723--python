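"""Two-component NADH fluorescence-lifetime fitting (TCSPC histograms).

Each photon-arrival histogram is fit past its peak to

    I(t) = A * [a1 * exp(-t/tau1) + (1 - a1) * exp(-t/tau2)] + bg

by weighted nonlinear least squares with Poisson weights
(variance = max(counts, 1)). Fits are multi-started because bi-exponential
decays are initialization-sensitive, components are reported in canonical
order tau1 < tau2, and near-degenerate component pairs (tau2/tau1 < 1.5) are
collapsed to a mono-exponential fit. The summary statistic is the
amplitude-weighted mean lifetime tm = a1*tau1 + a2*tau2 — short-lifetime
photons come from free NADH (glycolytic), long-lifetime photons from
protein-bound NADH (oxidative).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitError, ParameterError

__all__ = [
    "DecayHistogram",
    "FlimFit",
    "fit_biexponential",
    "summarize_by_mask",
    "read_decays_csv",
    "write_decays_csv",
]

logger = logging.getLogger(__name__)

#: Multi-start initial (tau1, tau2) pairs in ns.
_TAU_STARTS: Tuple[Tuple[float, float], ...] = ((0.3, 2.0), (0.5, 3.0))

#: Below this tau2/tau1 ratio the two components are not identifiable.
_MIN_TAU_RATIO = 1.5


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per arrival-time bin for one pixel or cell."""

    bin_edges: np.ndarray   # ns, len = n_bins + 1, uniform widths
    counts: np.ndarray      # non-negative integers
    pixel_or_cell_id: object = None

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(edges) != len(counts) + 1:
            raise ParameterError("bin_edges must have len(counts) + 1 entries")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0], rtol=1e-6):
            raise ParameterError("bin widths must be uniform and positive")
        if np.any(counts < 0):
            raise ParameterError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FlimFit:
    a1: float
    a2: float
    tau1: float        # ns; tau1 <= tau2
    tau2: float        # ns
    mean_tau: float    # ns, amplitude-weighted a1*tau1 + a2*tau2
    intensity: int     # total photons in the histogram
    chi2_reduced: float
    converged: bool
    low_confidence: bool = False
    pixel_or_cell_id: object = None


def _model(t: np.ndarray, a1: float, tau1: float, tau2: float,
           amp: float, bg: float) -> np.ndarray:
    return amp * (a1 * np.exp(-t / tau1) + (1.0 - a1) * np.exp(-t / tau2)) + bg


def _fit_once(t, counts, weights, x0, bounds):
    def residual(p):
        a1, lt1, lt2, amp, bg = p
        return (_model(t, a1, np.exp(lt1), np.exp(lt2), amp, bg) - counts) * weights

    return least_squares(residual, x0, bounds=bounds, method="trf", max_nfev=4000)


def _fit_mono(t, counts, weights):
    """Mono-exponential fallback: a1 = 1 by convention."""
    amp0 = max(counts.max(), 1.0)
    tau0 = max((t[-1] - t[0]) / 4.0, 0.1)

    def residual(p):
        ltau, amp, bg = p
        return (amp * np.exp(-t / np.exp(ltau)) + bg - counts) * weights

    res = least_squares(
        residual,
        [np.log(tau0), amp0, 0.0],
        bounds=([np.log(1e-3), 0.0, 0.0], [np.log(100.0), np.inf, np.inf]),
        method="trf",
        max_nfev=2000,
    )
    tau = float(np.exp(res.x[0]))
    dof = max(len(t) - 3, 1)
    chi2 = float(np.sum(res.fun**2)) / dof
    return tau, float(res.x[1]), float(res.x[2]), chi2, res.success


def fit_biexponential(
    hist: DecayHistogram,
    init: Optional[Mapping[str, float]] = None,
) -> FlimFit:
    """Fit a two-component decay to one histogram.

    The fit starts at the histogram peak bin (no IRF deconvolution; suited to
    generators or instruments with a narrow IRF). Total counts < 100 flag the
    fit as low-confidence but do not prevent fitting.
    """
    intensity = hist.total_counts
    if intensity <= 0:
        raise FitError("cannot fit a histogram with zero total counts")
    low_confidence = intensity < 100
    if low_confidence:
        logger.warning(
            "histogram %r has only %d photons; fit will be unstable",
            hist.pixel_or_cell_id, intensity,
        )

    peak = int(np.argmax(hist.counts))
    t = hist.bin_centers[peak:] - hist.bin_centers[peak]
    counts = hist.counts[peak:].astype(float)
    if len(t) < 6:
        raise FitError("too few bins past the peak to fit")
    weights = 1.0 / np.sqrt(np.maximum(counts, 1.0))

    amp0 = max(counts.max(), 1.0)
    starts = []
    if init is not None:
        starts.append((init.get("a1", 0.7), init["tau1"], init["tau2"]))
    starts.extend((0.7, t1, t2) for t1, t2 in _TAU_STARTS)

    lo = [0.0, np.log(1e-3), np.log(1e-3), 0.0, 0.0]
    hi = [1.0, np.log(100.0), np.log(100.0), np.inf, np.inf]
    best = None
    for a1_0, tau1_0, tau2_0 in starts:
        x0 = [a1_0, np.log(tau1_0), np.log(tau2_0), amp0, 0.0]
        try:
            res = _fit_once(t, counts, weights, x0, (lo, hi))
        except Exception:  # pragma: no cover - solver-internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return FlimFit(
            a1=np.nan, a2=np.nan, tau1=np.nan, tau2=np.nan, mean_tau=np.nan,
            intensity=intensity, chi2_reduced=np.nan, converged=False,
            low_confidence=low_confidence, pixel_or_cell_id=hist.pixel_or_cell_id,
        )

    a1, lt1, lt2, amp, bg = best.x
    tau1, tau2 = float(np.exp(lt1)), float(np.exp(lt2))
    a1 = float(a1)
    # canonical ordering: tau1 is always the short component
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a1 = 1.0 - a1
    dof = max(len(t) - 5, 1)
    chi2 = float(np.sum(best.fun**2)) / dof

    if tau2 / max(tau1, 1e-12) < _MIN_TAU_RATIO:
        # components not identifiable -> collapse to mono-exponential
        tau, amp, bg, chi2, ok = _fit_mono(t, counts, weights)
        return FlimFit(
            a1=1.0, a2=0.0, tau1=tau, tau2=tau, mean_tau=tau,
            intensity=intensity, chi2_reduced=chi2, converged=bool(ok),
            low_confidence=low_confidence, pixel_or_cell_id=hist.pixel_or_cell_id,
        )

    mean_tau = a1 * tau1 + (1.0 - a1) * tau2
    return FlimFit(
        a1=a1, a2=1.0 - a1, tau1=tau1, tau2=tau2, mean_tau=float(mean_tau),
        intensity=intensity, chi2_reduced=chi2, converged=bool(best.success),
        low_confidence=low_confidence, pixel_or_cell_id=hist.pixel_or_cell_id,
    )


def summarize_by_mask(
    fits: Sequence[FlimFit],
    fit_coords: np.ndarray,
    mask: np.ndarray,
    invaded_edge_x: float,
    pixel_size: float = 1.0,
) -> pd.DataFrame:
    """Aggregate per-pixel fits into a per-cell table with invasion grouping.

    Parameters
    ----------
    fits:
        Per-pixel fits aligned with ``fit_coords``.
    fit_coords:
        (n, 2) integer array of (row, col) pixel positions of each fit.
    mask:
        Label image (0 = background) aligned to the fit grid.
    invaded_edge_x:
        X threshold in µm; a cell whose centroid x exceeds it is "invaded".
    pixel_size:
        µm per pixel, converts mask columns to x positions.

    Returns a DataFrame with one row per cell: photon-weighted mean of the
    pixel mean lifetimes, summed intensity, centroid x and the invaded flag.
    Cells without any converged pixel are excluded (logged).
    """
    coords = np.asarray(fit_coords, dtype=int)
    if coords.shape[0] != len(fits):
        raise ParameterError("fit_coords must align with fits")
    rows = []
    labels = np.unique(mask)
    labels = labels[labels != 0]
    label_at = {tuple(rc): i for i, rc in enumerate(coords)}
    for lab in labels:
        rr, cc = np.nonzero(mask == lab)
        cell_fits = [
            fits[label_at[(r, c)]]
            for r, c in zip(rr, cc)
            if (r, c) in label_at and fits[label_at[(r, c)]].converged
        ]
        if not cell_fits:
            logger.info("cell %s has no converged pixels; excluded", lab)
            continue
        intensities = np.array([f.intensity for f in cell_fits], dtype=float)
        taus = np.array([f.mean_tau for f in cell_fits])
        total_photons = float(intensities.sum())
        mean_tau = float(np.sum(taus * intensities) / total_photons)
        centroid_x = float(cc.mean()) * pixel_size
        rows.append(
            {
                "cell_id": int(lab),
                "mean_tau_ns": mean_tau,
                "intensity": int(total_photons),
                "n_pixels": len(cell_fits),
                "centroid_x_um": centroid_x,
                "invaded": centroid_x > invaded_edge_x,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "mean_tau_ns", "intensity", "n_pixels",
                 "centroid_x_um", "invaded"],
    )


def write_decays_csv(hists: Sequence[DecayHistogram], path) -> None:
    """Long-format decay table: id, bin_ns (left edge), counts."""
    rows = []
    for h in hists:
        for edge, count in zip(h.bin_edges[:-1], h.counts):
            rows.append({"id": h.pixel_or_cell_id, "bin_ns": edge, "counts": int(count)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decays_csv(path) -> List[DecayHistogram]:
    df = pd.read_csv(path)
    out = []
    for hid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("bin_ns")
        edges = grp["bin_ns"].to_numpy(dtype=float)
        width = edges[1] - edges[0]
        out.append(
            DecayHistogram(
                bin_edges=np.append(edges, edges[-1] + width),
                counts=grp["counts"].to_numpy(),
                pixel_or_cell_id=hid,
            )
        )
    return out
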