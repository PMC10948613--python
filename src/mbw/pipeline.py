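"""Reproducible end-to-end runs: simulate -> fit -> network fractions -> Turing.

A run is described by a :class:`RunConfig` (deserializable from YAML),
executed stage by stage into an output directory with a manifest recording
the seed, the configuration hash and per-stage wall times.  The
``reproduce`` stage set regenerates the headline quantitative results of the
analysis from scratch: parameter-recovery reports on synthetic titration
suites, complex-fraction reports at the estimated dissociation constants,
ratio scans, and Turing-space summaries for complex orders 2, 4 and 6.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fitting, reaction_network, synthetic_data, turing
from .reaction_network import PAPER_ALPHA, PAPER_KDS

__all__ = ["RunConfig", "run_paper_reproduction", "DEFAULT_EXPECTATIONS"]

logger = logging.getLogger("mbw.pipeline")

STAGES = ("simulate", "fit", "network", "turing")

#: Reference values for the headline checks, with absolute tolerances in
#: percentage points where "about"-qualified rounding applies.
DEFAULT_EXPECTATIONS: dict[str, dict[str, float]] = {
    "n_species_no_inhibitor": {"value": 22, "tol": 0},
    "n_reactions_no_inhibitor": {"value": 92, "tol": 0},
    "n_reversible_no_inhibitor": {"value": 46, "tol": 0},
    "n_complexes_with_inhibitor": {"value": 26, "tol": 0},
    "pct_single_gl3_no_inhibitor": {"value": 50.0, "tol": 4.0},
    "pct_hexamer_no_inhibitor_max": {"value": 1.0, "tol": 0.0},
    "pct_try_in_single_gl3": {"value": 19.0, "tol": 3.0},
    "pct_try_in_dimer_gl3": {"value": 23.0, "tol": 4.0},
    "pct_trimer_equimolar": {"value": 5.0, "tol": 3.0},
}


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    stages: Sequence[str] = STAGES
    seed: int = 0
    out_dir: str = "mbw_run"
    kds: Mapping[str, float] = field(default_factory=lambda: dict(PAPER_KDS))
    alpha: float = PAPER_ALPHA
    noise: float = 0.03
    n_points_per_curve: int = 30
    competitor_ratios: Sequence[float] = (2.0, 1.0)
    turing_orders: Sequence[int] = (2, 4, 6)
    turing_resolution: int = 500
    weighting: str = "sigma"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        blob = json.dumps(
            {
                k: (list(v) if isinstance(v, (tuple, list)) else dict(v) if isinstance(v, Mapping) else v)
                for k, v in self.__dict__.items()
                if k != "out_dir"
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _titration_design(n_points: int) -> tuple[float, ...]:
    """n log-spaced ratios over 0.25-4 plus the saturation point."""
    return tuple(np.geomspace(0.25, 4.0, n_points - 1)) + (
        synthetic_data.SATURATION_RATIO,
    )


def _stage_simulate(config: RunConfig, out: Path) -> dict[str, Any]:
    datasets = {}
    design = _titration_design(config.n_points_per_curve)
    for prey, kd_key in (("TTG1", "GL3-TTG1"), ("GL1", "GL3-GL1")):
        cfg = synthetic_data.SyntheticConfig(
            model="single",
            params={"kd": config.kds[kd_key]},
            prey_ratios=design,
            noise=config.noise,
            seed=config.seed,
            experiment_id=f"single_{prey.lower()}",
            prey=prey,
        )
        ds = synthetic_data.generate(cfg)
        synthetic_data.write_dataset(ds, out / f"single_{prey.lower()}.csv")
        datasets[f"single_{prey}"] = ds
    suite = synthetic_data.generate_competition_suite(
        alpha=config.alpha,
        kds={
            "kd_prey": config.kds["GL3-TTG1"],
            "kd_comp": config.kds["GL3-GL1"],
        },
        competitor_ratios=config.competitor_ratios,
        config=synthetic_data.SyntheticConfig(
            model="cooperative",
            prey_ratios=design,
            noise=config.noise,
            seed=config.seed + 1,
            experiment_id="competition",
            prey="TTG1",
            competitor="GL1",
        ),
    )
    for i, ds in enumerate(suite):
        synthetic_data.write_dataset(ds, out / f"competition_{i + 1}.csv")
    datasets["competition_suite"] = suite
    return datasets


def _stage_fit(config: RunConfig, out: Path, datasets: dict) -> dict[str, Any]:
    report: dict[str, Any] = {"weighting": config.weighting}
    kd_cis = {}
    for prey, kd_key, name in (
        ("TTG1", "GL3-TTG1", "kd_prey"),
        ("GL1", "GL3-GL1", "kd_comp"),
    ):
        fit = fitting.fit_kd(
            datasets[f"single_{prey}"], weighting=config.weighting, seed=config.seed
        )
        lo, hi, _level = fit.ci["kd"]
        kd_cis[name] = (max(lo, 1e-3), min(hi, 1e3))
        report[f"kd_{prey}"] = {
            "true": config.kds[kd_key],
            "estimate": fit.estimates["kd"],
            "ci95": [lo, hi],
            "identifiable": fit.identifiable["kd"],
        }
    alpha_fit = fitting.fit_alpha(
        datasets["competition_suite"],
        kd_bounds=kd_cis,
        model="cooperative",
        weighting=config.weighting,
        seed=config.seed,
    )
    lo, hi, _level = alpha_fit.ci["alpha"]
    report["alpha"] = {
        "true": config.alpha,
        "estimate": alpha_fit.estimates["alpha"],
        "ci95": [lo, hi],
        "identifiable": alpha_fit.identifiable["alpha"],
        "recovered_within_ci": bool(lo <= config.alpha <= hi),
    }
    with open(out / "fit_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_network(config: RunConfig, out: Path) -> dict[str, Any]:
    report: dict[str, Any] = {}
    net = reaction_network.build_network(
        include_try=False, include_gl3_dimer=True, kds=config.kds, alpha=config.alpha
    )
    report["n_species_no_inhibitor"] = net.n_species
    report["n_reactions_no_inhibitor"] = net.n_reactions
    report["n_reversible_no_inhibitor"] = len(net.reversible_pairs)

    state = reaction_network.solve_equilibrium(
        net, {"GL3": 1.0, "GL1": 1.0, "TTG1": 1.0}
    )
    rep = reaction_network.fraction_report(state)
    report["pct_single_gl3_no_inhibitor"] = rep.groupings["single_gl3"]
    report["pct_hexamer_no_inhibitor"] = rep.groupings["hexamer"]
    report["fractions_no_inhibitor"] = rep.groupings
    report["alternatives_no_inhibitor"] = rep.alternatives

    net_try = reaction_network.build_network(
        include_try=True, include_gl3_dimer=True, kds=config.kds, alpha=config.alpha
    )
    report["n_complexes_with_inhibitor"] = len(
        reaction_network.enumerate_complexes(net_try)
    )
    state_try = reaction_network.solve_equilibrium(
        net_try, {"GL3": 1.0, "GL1": 1.0, "TTG1": 1.0, "TRY": 1.0}
    )
    rep_try = reaction_network.fraction_report(state_try)
    rep_try.table.to_csv(out / "fractions_equimolar.csv", index=False)
    report["pct_try_in_single_gl3"] = rep_try.groupings["try_in_single_gl3"]
    report["pct_try_in_dimer_gl3"] = rep_try.groupings["try_in_dimer_gl3"]
    report["pct_trimer_equimolar"] = rep_try.groupings["gl1_gl3_ttg1_trimer"]
    report["fractions_with_inhibitor"] = rep_try.groupings
    report["alternatives_with_inhibitor"] = rep_try.alternatives

    scan = reaction_network.ratio_scan(
        net_try, {"GL3": 1.0, "GL1": 1.0, "TTG1": 1.0, "TRY": 1.0}
    )
    scan.to_csv(out / "ratio_scan.csv", index=False)
    trimer = scan[scan.grouping == "gl1_gl3_ttg1_trimer"]
    high = trimer[(trimer.gl1_fold == 4.0) & (trimer.ttg1_fold == 4.0)]
    report["pct_trimer_gl1x4_ttg1x4"] = float(high[high.try_fold == 1.0].percent.iloc[0])
    inhibited = scan[scan.grouping == "try_containing"]
    low_gl1 = inhibited[(inhibited.gl1_fold == 0.25) & (inhibited.try_fold == 4.0)]
    report["pct_try_max_low_gl1_high_try"] = float(low_gl1.percent.max())
    with open(out / "network_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _stage_turing(config: RunConfig, out: Path) -> dict[str, Any]:
    summaries = []
    for n in config.turing_orders:
        grid = turing.turing_space(
            resolution=config.turing_resolution, n_order=int(n)
        )
        summaries.append(grid.summary())
        grid.to_frame().to_csv(out / f"turing_n{n}.csv", index=False)
    with open(out / "turing_summary.json", "w") as fh:
        json.dump(summaries, fh, indent=2)
    return {"summaries": summaries}


def _check_expectations(report: dict[str, Any]) -> list[dict[str, Any]]:
    checks = []
    mapping = {
        "n_species_no_inhibitor": report.get("n_species_no_inhibitor"),
        "n_reactions_no_inhibitor": report.get("n_reactions_no_inhibitor"),
        "n_reversible_no_inhibitor": report.get("n_reversible_no_inhibitor"),
        "n_complexes_with_inhibitor": report.get("n_complexes_with_inhibitor"),
        "pct_single_gl3_no_inhibitor": report.get("pct_single_gl3_no_inhibitor"),
        "pct_try_in_single_gl3": report.get("pct_try_in_single_gl3"),
        "pct_try_in_dimer_gl3": report.get("pct_try_in_dimer_gl3"),
        "pct_trimer_equimolar": report.get("pct_trimer_equimolar"),
    }
    for key, got in mapping.items():
        if got is None:
            continue
        exp = DEFAULT_EXPECTATIONS[key]
        checks.append(
            {
                "check": key,
                "value": got,
                "expected": exp["value"],
                "tolerance": exp["tol"],
                "passed": bool(abs(got - exp["value"]) <= exp["tol"]),
            }
        )
    hex_pct = report.get("pct_hexamer_no_inhibitor")
    if hex_pct is not None:
        checks.append(
            {
                "check": "pct_hexamer_no_inhibitor_max",
                "value": hex_pct,
                "expected": DEFAULT_EXPECTATIONS["pct_hexamer_no_inhibitor_max"]["value"],
                "tolerance": 0.0,
                "passed": bool(hex_pct < 1.0),
            }
        )
    return checks


def run_paper_reproduction(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write a manifest.

    Returns the full report bundle (also serialized to ``manifest.json`` in
    the output directory).  Stage failures abort with the stage name in the
    raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    datasets: dict[str, Any] = {}
    for stage in config.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        t0 = time.perf_counter()
        logger.info("stage %s: start (seed=%d)", stage, config.seed)
        try:
            if stage == "simulate":
                datasets = _stage_simulate(config, out)
                result: dict[str, Any] = {"datasets": sorted(datasets)}
            elif stage == "fit":
                if not datasets:
                    datasets = _stage_simulate(config, out)
                result = _stage_fit(config, out, datasets)
            elif stage == "network":
                result = _stage_network(config, out)
            else:
                result = _stage_turing(config, out)
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        wall = time.perf_counter() - t0
        logger.info("stage %s: done in %.2f s", stage, wall)
        bundle["stages"][stage] = {"wall_time_s": wall, "result": result}

    if "network" in bundle["stages"]:
        bundle["checks"] = _check_expectations(
            bundle["stages"]["network"]["result"]
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)
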