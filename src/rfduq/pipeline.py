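"""Configuration-driven pipeline with run provenance.

``run_pipeline`` executes requested stages (derive | tree | calibrate |
prob | simulate) in declared order, writes each stage's tables under the
run directory, and records a manifest (config hash, seeds, package version,
timestamps, output digests).  Config errors are reported with field paths
before any computation; results are write-once per run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import pandas as pd

from . import __version__, reference_values as ref
from .calibration import fit_loglog, inverse_predict, pod_from_threshold
from .prob_rfd import scenario_grid
from .rfd_core import (
    Classification,
    Metric,
    PointOfDeparture,
    derive_rfd,
    compose_uf,
)
from .sensitivity_tree import PodOption, enumerate_tree, tree_report
from .synthetic_data import (
    default_quartile_params,
    default_tsh_params,
    generate_quartile_summaries,
    generate_tsh_cohort,
)
from .group_stats import classify_noael_loael, welch_test_from_summaries

__all__ = ["ConfigError", "ComputationError", "RunManifest", "run_pipeline"]

STAGES = ("simulate", "derive", "tree", "calibrate", "prob")


class ConfigError(ValueError):
    """Invalid configuration; reported with the offending field path."""


class ComputationError(RuntimeError):
    """A stage failed during computation."""


@dataclasses.dataclass
class RunManifest:
    command: str
    config_sha256: str
    seed: int
    package_version: str
    started_utc: str
    finished_utc: str = ""
    outputs: Dict[str, str] = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _validate(config: Mapping[str, Any]) -> Dict[str, Any]:
    cfg = dict(config)
    stages = cfg.get("stages", [])
    if not isinstance(stages, (list, tuple)):
        raise ConfigError("stages: must be a list")
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"stages[{stages.index(s)}]: unknown stage {s!r}")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise ConfigError("seed: must be a non-negative integer")
    n_samples = cfg.get("n_samples", 100_000)
    if not isinstance(n_samples, int) or n_samples < 10_000:
        raise ConfigError("n_samples: must be an integer >= 10,000")
    return cfg


def _write_once(path: Path, writer) -> str:
    if path.exists():
        raise ComputationError(f"refusing to overwrite existing output {path}")
    writer(path)
    return _sha256_bytes(path.read_bytes())


def run_pipeline(config: Mapping[str, Any], out_dir: Path | str) -> RunManifest:
    """Execute the configured stages and write outputs plus a manifest."""
    cfg = _validate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.get("seed", 0)
    manifest = RunManifest(
        command=f"run_pipeline(stages={list(cfg.get('stages', []))})",
        config_sha256=_sha256_bytes(json.dumps(cfg, sort_keys=True, default=str).encode()),
        seed=seed,
        package_version=__version__,
        started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    )

    state: Dict[str, Any] = {}
    try:
        for stage in cfg.get("stages", []):
            runner = _STAGE_RUNNERS[stage]
            for name, df in runner(cfg, seed, state).items():
                path = out_dir / f"{name}.csv"
                manifest.outputs[f"{name}.csv"] = _write_once(
                    path, lambda p, df=df: df.to_csv(p, index=False)
                )
    except ConfigError:
        raise
    except Exception as exc:  # surface with stage context, keep traceback
        raise ComputationError(str(exc)) from exc

    manifest.finished_utc = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _stage_simulate(cfg, seed, state):
    pairs, truth = generate_tsh_cohort(default_tsh_params(seed=seed))
    summaries, _ = generate_quartile_summaries(default_quartile_params(seed=seed))
    state["pairs"] = pairs
    state["summaries"] = summaries
    qdf = pd.DataFrame(
        [
            {
                "label": s.label,
                "n": s.n,
                "mean": s.mean,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "dose_ppt": s.dose.value if s.dose else None,
            }
            for s in summaries
        ]
    )
    truth_df = pd.DataFrame([truth])
    return {"tsh_cohort": pairs.to_dataframe(), "tsh_cohort_truth": truth_df, "quartile_summaries": qdf}


def _stage_derive(cfg, seed, state):
    composite = compose_uf([ref.UF_L, ref.UF_H])
    pod = PointOfDeparture(ref.POD_INTAKE, Classification.LOAEL, "intake POD")
    rows = [
        {
            "scenario_id": "current",
            "pod_value": ref.POD_INTAKE.value,
            "pod_units": ref.POD_INTAKE.unit.value,
            "classification": "LOAEL",
            "metric": "TCDD",
            "composite_uf": composite,
            "rfd_exact_pg_kg_day": derive_rfd(pod, composite).value,
            "rfd_rounded": derive_rfd(pod, composite).rounded_value,
        },
        {
            "scenario_id": "noael_reading",
            "pod_value": ref.POD_INTAKE.value,
            "pod_units": ref.POD_INTAKE.unit.value,
            "classification": "NOAEL",
            "metric": "TCDD",
            "composite_uf": ref.UF_H.nominal,
            "rfd_exact_pg_kg_day": derive_rfd(pod, ref.UF_H.nominal).value,
            "rfd_rounded": derive_rfd(pod, ref.UF_H.nominal).rounded_value,
        },
    ]
    return {"rfd_derivation": pd.DataFrame(rows)}


def _stage_tree(cfg, seed, state):
    pod_options = [
        PodOption("serum_235_ppt", 235.0, "ppt", Metric.TCDD),
        PodOption("intake_0.020", 0.020, "ng/kg/day", Metric.TCDD),
    ]
    nodes = enumerate_tree(
        pod_options,
        [Classification.NOAEL, Classification.LOAEL],
        [("tcdd_only", None), ("teq", ref.TSH_TEQ)],
        {k: list(v) for k, v in ref.DEFAULT_UF_TABLE.items()},
        anchor=ref.ANCHOR,
    )
    table, _ = tree_report(nodes)
    return {"sensitivity_tree": table}


def _ensure_pairs(cfg, seed, state):
    if "pairs" not in state:
        state["pairs"], _ = generate_tsh_cohort(default_tsh_params(seed=seed))
    return state["pairs"]


def _stage_calibrate(cfg, seed, state):
    pairs = _ensure_pairs(cfg, seed, state)
    fit = fit_loglog(pairs)
    state["fit"] = fit
    rows = []
    for threshold in cfg.get("thresholds", [5.0, 10.0]):
        for method in ("approx_se", "fieller"):
            pred = inverse_predict(fit, threshold, method=method)
            rows.append(
                {
                    "threshold_tsh_uU_mL": threshold,
                    "method": method,
                    "point_ppt": pred.point,
                    "ci_low_ppt": pred.ci_low,
                    "ci_high_ppt": pred.ci_high,
                    "ci_kind": pred.kind.value,
                    "upper_display": pred.display_upper(),
                }
            )
    fit_df = pd.DataFrame(
        [
            {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "residual_se": fit.residual_se,
                "n": fit.n,
            }
        ]
    )
    return {"calibration_fit": fit_df, "inverse_predictions": pd.DataFrame(rows)}


def _stage_prob(cfg, seed, state):
    fits = state.get("fits")
    if fits is None:
        tcdd_pairs, _ = generate_tsh_cohort(default_tsh_params(seed=seed))
        teq_pairs, _ = generate_tsh_cohort(default_tsh_params(metric=Metric.TEQ, seed=seed + 1))
        fits = {Metric.TCDD: fit_loglog(tcdd_pairs), Metric.TEQ: fit_loglog(teq_pairs)}
    _, table = scenario_grid(
        fits,
        anchor=ref.ANCHOR,
        n_samples=cfg.get("n_samples", 100_000),
        seed=seed,
        reference_rfd=cfg.get("reference_rfd", ref.CURRENT_RFD),
    )
    return {"prob_rfd_scenarios": table}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "derive": _stage_derive,
    "tree": _stage_tree,
    "calibrate": _stage_calibrate,
    "prob": _stage_prob,
}
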