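"""End-to-end orchestration: simulate -> analyze -> compare, with manifests.

A pipeline run executes the requested stages in dependency order inside one
output directory. Every stage communicates with later stages only through its
declared files, every output directory carries exactly one ``manifest.json``
(config snapshot, seed, package version, SHA-256 of each output), and
re-running with the same config and seed reproduces all stochastic outputs
bit-for-bit (the manifest's ``created`` timestamp is the only field allowed
to differ).
"""
from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimulationConfig
from .exceptions import PipelineError
from .fba import build_constraints, compare_conditions, ensemble_fba, solve_fba
from .flim import fit_biexponential, write_decays_csv
from .fluxomics import estimate_exchange_rates, rates_to_frame, write_metabolite_csv, write_rates_csv
from .morphometry import COORDINATE_NOTE, invasion_distances, shape_descriptors
from .network import save_network_json, toy_core_network
from .permeability import estimate_permeability, write_traces_csv
from . import synthetic

logger = logging.getLogger(__name__)

STAGES = ("diffusion", "invasion", "flim", "metabolites", "fba")

_DEMO_DEFAULTS: Mapping[str, Mapping] = {
    "diffusion": {"true_permeability": 1.0},
    "invasion": {"n_cells": 40, "bias": 40.0},
    "flim": {"n_pixels": 16},
    "metabolites": {},
    "fba": {"n": 100, "conditions": ["huvec_cm", "ctrl_cm"]},
}


def demo_config(seed: int = 0, **overrides) -> Dict:
    """A small end-to-end demo configuration (all five stages)."""
    cfg: Dict = {"seed": seed, "stages": list(STAGES)}
    for stage, params in _DEMO_DEFAULTS.items():
        cfg[stage] = dict(params)
    for key, value in overrides.items():
        cfg[key] = value
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_diffusion(cfg: Dict, seed: int, out: Path) -> List[Path]:
    params = dict(cfg.get("diffusion", {}))
    sim_cfg = SimulationConfig(seed=seed, **params)
    series = synthetic.simulate_vessel_diffusion(sim_cfg)
    traces = out / "diffusion_traces.csv"
    write_traces_csv(series, traces)
    result = estimate_permeability(series)
    summary = out / "permeability.json"
    _write_json(summary, {
        "P_D_um_s": result.p_d,
        "true_permeability_um_s": sim_cfg.true_permeability,
        "slope_au_s": result.slope,
        "fit_window_s": list(result.fit_window),
        "r_squared": result.r_squared,
    })
    return [traces, summary]


def _stage_invasion(cfg: Dict, seed: int, out: Path) -> List[Path]:
    import tifffile

    params = dict(cfg.get("invasion", {}))
    n_cells = int(params.pop("n_cells", 40))
    bias = float(params.pop("bias", 0.0))
    edge_x = float(params.pop("edge_x", 0.0))
    sim_cfg = SimulationConfig(seed=seed + 1)
    mask, truth = synthetic.simulate_invasion_field(
        sim_cfg, n_cells=n_cells, bias=bias, edge_x=edge_x, **params
    )
    mask_path = out / "invasion_mask.tif"
    tifffile.imwrite(mask_path, mask.labels.astype(np.uint16))
    truth_path = out / "invasion_truth.csv"
    truth.to_csv(truth_path, index=False)
    records = shape_descriptors(mask)
    records_path = out / "morphometry.csv"
    with open(records_path, "w") as fh:
        fh.write(f"# coordinates: {COORDINATE_NOTE}\n")
        records.to_csv(fh, index=False)
    inv = invasion_distances(records["centroid_x_um"].to_numpy() - mask.labels.shape[1] *
                             mask.pixel_size / 2.0 + edge_x, edge_x)
    summary = out / "invasion_summary.json"
    _write_json(summary, {
        "n_cells": int(len(records)),
        "mean_invasion_um": inv.mean,
        "sem_invasion_um": inv.sem,
        "mean_positive_only_um": inv.mean_positive_only,
        "true_bias_um": bias,
    })
    return [mask_path, truth_path, records_path, summary]


def _stage_flim(cfg: Dict, seed: int, out: Path) -> List[Path]:
    params = dict(cfg.get("flim", {}))
    n_pixels = int(params.pop("n_pixels", 16))
    sim_cfg = SimulationConfig(seed=seed + 2, **params)
    hists, truth = synthetic.simulate_flim_decays(sim_cfg, n_pixels=n_pixels)
    decays_path = out / "flim_decays.csv"
    write_decays_csv(hists, decays_path)
    fits = [fit_biexponential(h) for h in hists]
    fits_path = out / "flim_fits.csv"
    pd.DataFrame(
        [
            {"id": f.pixel_or_cell_id, "a1": f.a1, "tau1_ns": f.tau1,
             "tau2_ns": f.tau2, "mean_tau_ns": f.mean_tau,
             "intensity": f.intensity, "chi2_reduced": f.chi2_reduced,
             "converged": f.converged}
            for f in fits
        ]
    ).to_csv(fits_path, index=False)
    converged = [f.mean_tau for f in fits if f.converged]
    summary = out / "flim_summary.json"
    _write_json(summary, {
        "n_pixels": n_pixels,
        "median_mean_tau_ns": float(np.median(converged)) if converged else None,
        "true_mean_tau_ns": truth["mean_tau_ns"],
        "n_converged": len(converged),
    })
    return [decays_path, fits_path, summary]


def _stage_metabolites(cfg: Dict, seed: int, out: Path) -> List[Path]:
    params = dict(cfg.get("metabolites", {}))
    sim_cfg = SimulationConfig(seed=seed + 3, **params)
    series = synthetic.simulate_metabolite_timecourse(sim_cfg)
    met_path = out / "metabolites.csv"
    write_metabolite_csv(series.values(), met_path)
    rates = estimate_exchange_rates(series.values())
    rates_path = out / "exchange_rates.csv"
    write_rates_csv(rates, rates_path)
    return [met_path, rates_path]


def _stage_fba(cfg: Dict, seed: int, out: Path) -> List[Path]:
    params = dict(cfg.get("fba", {}))
    n = int(params.pop("n", 100))
    conditions = list(params.pop("conditions", ["huvec_cm", "ctrl_cm"]))
    if len(conditions) != 2:
        raise PipelineError("fba stage expects exactly two conditions")
    net = toy_core_network()
    net_path = out / "core_network.json"
    save_network_json(net, net_path)
    ensembles = {}
    paths = [net_path]
    for i, cond in enumerate(conditions):
        rates = synthetic.condition_exchange_rates(cond)
        culture = synthetic.condition_culture_parameters(cond)
        cs = build_constraints(
            rates, net, rates_in_model_units=True,
            growth_rate=culture["growth_rate"][0],
            growth_rate_sd=culture["growth_rate"][1],
            o2_rate=culture["o2"][0], o2_rate_sd=culture["o2"][1],
        )
        ens = ensemble_fba(net, cs, n=n, seed=seed + 10 + i, condition=cond)
        ensembles[cond] = ens
        flux_path = out / f"fba_fluxes_{cond}.csv"
        ens.fluxes.to_csv(flux_path, index=False)
        paths.append(flux_path)
    table = compare_conditions(ensembles[conditions[0]], ensembles[conditions[1]], net)
    cmp_path = out / "fba_comparison.csv"
    table.to_csv(cmp_path)
    summary = out / "fba_summary.json"
    _write_json(summary, {
        "n_runs": n,
        "conditions": conditions,
        "infeasible": {c: ensembles[c].infeasible_count for c in conditions},
        "objective_means": {
            c: float(ensembles[c].fluxes["HAS"].mean()) for c in conditions
        },
    })
    return paths + [cmp_path, summary]


_STAGE_FUNCS = {
    "diffusion": _stage_diffusion,
    "invasion": _stage_invasion,
    "flim": _stage_flim,
    "metabolites": _stage_metabolites,
    "fba": _stage_fba,
}


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir, seed: Optional[int] = None) -> Path:
    """Execute the configured stages into ``out_dir`` and write a manifest.

    ``config`` is a mapping or a path to a YAML file with a ``stages`` list
    plus optional per-stage parameter sections. Unknown stage names fail
    before any stage executes. Partial failures keep completed-stage outputs
    and write ``error_report.json`` before raising :class:`PipelineError`.
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise PipelineError(f"unknown stage name(s): {unknown}; valid: {list(STAGES)}")
    if seed is None:
        seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    produced: Dict[str, List[str]] = {}
    errors: Dict[str, str] = {}
    for stage in stages:
        try:
            files = _STAGE_FUNCS[stage](config, seed, out)
            produced[stage] = [f.name for f in files]
            logger.info("stage %s complete: %s", stage, produced[stage])
        except Exception as exc:  # keep earlier outputs, report, then fail
            errors[stage] = f"{type(exc).__name__}: {exc}"
            logger.error("stage %s failed: %s", stage, errors[stage])
            break

    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "stages_completed": list(produced),
        "outputs": {
            name: _sha256(out / name)
            for names in produced.values()
            for name in names
        },
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    _write_json(out / "manifest.json", manifest)
    if errors:
        _write_json(out / "error_report.json", errors)
        raise PipelineError(f"pipeline stage(s) failed: {errors}")
    return out


def make_report(out_dir) -> Path:
    """Render a single-file Markdown summary of a pipeline output directory.

    Missing stage outputs are noted as gaps instead of failing. The report is
    idempotent: identical inputs give byte-identical report content.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest.json in {out}; not a pipeline output directory")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "# vesselflux run report",
        "",
        f"Seed: {manifest['seed']}  |  package version: {manifest['version']}",
        "",
    ]

    def section(title: str, path: str, render) -> None:
        lines.append(f"## {title}")
        lines.append("")
        full = out / path
        if not full.exists():
            lines.append(f"_Stage output `{path}` missing; stage not run or failed._")
        else:
            lines.extend(render(full))
        lines.append("")

    def perm(p):
        d = json.loads(p.read_text())
        return [
            f"- Estimated P_D = {d['P_D_um_s']:.3g} µm/s "
            f"(ground truth {d['true_permeability_um_s']:.3g} µm/s)",
            f"- Fit window {d['fit_window_s']} s, r² = {d['r_squared']:.3f}",
        ]

    def inv(p):
        d = json.loads(p.read_text())
        return [
            f"- {d['n_cells']} cells; mean signed invasion distance "
            f"{d['mean_invasion_um']:.1f} ± {d['sem_invasion_um']:.1f} µm (SEM)",
            f"- Generator bias: {d['true_bias_um']:.1f} µm",
        ]

    def flim_sec(p):
        d = json.loads(p.read_text())
        med = d["median_mean_tau_ns"]
        med_txt = "n/a" if med is None else f"{med:.3f} ns"
        return [
            f"- Median fitted mean lifetime {med_txt} "
            f"(truth {d['true_mean_tau_ns']:.3f} ns), "
            f"{d['n_converged']}/{d['n_pixels']} pixels converged",
        ]

    def rates(p):
        df = pd.read_csv(p, comment="#")
        body = ["| metabolite | rate (fmol/cell/h) | log2FC |", "|---|---|---|"]
        for _, row in df.iterrows():
            body.append(
                f"| {row['metabolite']} | {row['rate_fmol_cell_h']:.1f} | "
                f"{row['log2fc']:.3f} |"
            )
        return body

    def fba_sec(p):
        df = pd.read_csv(p)
        cols = list(df.columns)
        body = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
        for _, row in df.iterrows():
            body.append(
                "| " + " | ".join(
                    f"{v:.4g}" if isinstance(v, float) else str(v) for v in row
                ) + " |"
            )
        return body

    section("Vessel permeability", "permeability.json", perm)
    section("Invasion and morphology", "invasion_summary.json", inv)
    section("NADH FLIM", "flim_summary.json", flim_sec)
    section("Exchange fluxes", "exchange_rates.csv", rates)
    section("Flux balance analysis", "fba_comparison.csv", fba_sec)

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
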