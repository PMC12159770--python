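"""End-to-end orchestration: simulate/load → fit baseline → score → compare.

The pipeline reproduces the benchmarking workflow on one configuration:

1. obtain a stay table (simulated, or loaded from CSV/Parquet together
   with unit/hospital attribute tables and a spectrum-score table);
2. validate it (schema, ``dp >= 1``, binary flags, agent coverage);
3. split into baseline and evaluation periods by the ``period`` tag;
4. fit the facility/unit-level NB model on baseline unit-months
   (backward-AIC over facility and unit terms) per outcome;
5. run the patient-level selection (prevalence/correlation prescreen,
   consensus LASSO over K subsets, backward-AIC offer of facility/unit
   terms) and fit the mixed ZINB model on baseline stays per outcome;
6. score the evaluation period (crude rates, O:E, P:E), build the
   benchmark table, the tau-b matrix and the intercept-correlation data.

Baseline fitting never touches evaluation-period rows: the split happens
once, up front, on the period tag, and all models are fitted on the
baseline frame only.  All randomness flows from one master seed expanded
per stage with ``numpy``'s SeedSequence.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import benchmark as bm
from . import compare as cmp
from . import selection as sel
from . import unit_model as um
from .patient_model import FitControl, ZinbMixedModel, fit_zinb_mixed
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("abxbench")

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]

FACILITY_TERMS = ["complexity_level", "icu_complexity", "surgical_complexity", "trainees_quintile"]
UNIT_TERMS = ["avg_los_quintile", "icu_floor", "surgical_floor"]
BASE_COUNT = ["age_c", "sex", "icu_stay", "surgical_specialty"]
BASE_ZERO = ["age_c", "sex", "icu_stay", "surgical_specialty", "log_dp"]


class PipelineConfig(BaseModel):
    """Single configuration object driving :func:`run_pipeline`."""

    outdir: str
    seed: int = 0
    outcomes: list[str] = Field(default_factory=lambda: ["dot", "dasc"])
    methods: list[str] = Field(default_factory=lambda: ["crude", "unit", "patient"])
    # data source: simulation settings, or file paths
    simulate: dict[str, Any] | None = None
    stays_path: str | None = None
    units_path: str | None = None
    hospitals_path: str | None = None
    spectrum_path: str | None = None
    # patient-level selection
    prescreen_floor: float = 0.005
    prescreen_alpha: float = 0.05
    k_subsets: int = 10
    n_lambda: int = 20
    do_selection: bool = True
    offer_facility_terms: bool = True
    # extras
    compute_variance_reduction: bool = False
    figures: bool = False


def _load_table(path: str) -> pd.DataFrame:
    p = Path(path)
    if p.suffix in (".parquet", ".pq"):
        return pd.read_parquet(p)
    return pd.read_csv(p)


def validate_inputs(
    stays: pd.DataFrame,
    units: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    agent_days: pd.DataFrame | None = None,
    spectrum_agents: set[str] | None = None,
) -> list[dict]:
    """Schema and invariant checks; returns a row-level violation list."""
    violations: list[dict] = []
    required = {"stay_id", "hospital_id", "unit_id", "month", "dp", "dot", "dasc"}
    for col in sorted(required - set(stays.columns)):
        violations.append({"rule": "missing_column", "detail": col})
    if violations:
        return violations
    bad_dp = stays.loc[stays["dp"] < 1, "stay_id"]
    violations += [{"rule": "dp_ge_1", "stay_id": s} for s in bad_dp]
    for col in [c for c in stays.columns if c.startswith(("com_", "proc_"))] + [
        c for c in ("icu_stay", "surgical_specialty", "sex") if c in stays.columns
    ]:
        bad = stays.loc[~stays[col].isin([0, 1]), "stay_id"]
        violations += [{"rule": "binary_flag", "column": col, "stay_id": s} for s in bad]
    for col in ("dot", "dasc"):
        bad = stays.loc[stays[col] < 0, "stay_id"]
        violations += [{"rule": "nonnegative_outcome", "column": col, "stay_id": s} for s in bad]
    if units is not None:
        unknown = set(stays["unit_id"]) - set(units["unit_id"])
        violations += [{"rule": "unknown_unit", "unit_id": u} for u in sorted(unknown)]
    if hospitals is not None:
        unknown = set(stays["hospital_id"]) - set(hospitals["hospital_id"])
        violations += [{"rule": "unknown_hospital", "hospital_id": h} for h in sorted(unknown)]
    if agent_days is not None and spectrum_agents is not None:
        missing = set(agent_days["agent_id"]) - spectrum_agents
        violations += [{"rule": "agent_without_score", "agent_id": a} for a in sorted(missing)]
    return violations


def _stage_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _fit_unit_models(baseline, units, hospitals, outcomes):
    records = um.aggregate_unit_month(baseline, units, hospitals)
    records, cutpoints = um.assign_los_quintiles(records)
    models = {}
    for oc in outcomes:
        def fit_fn(terms, _oc=oc):
            return um.fit_nb(records, _oc, terms).aic

        kept, trace = sel.backward_aic(fit_fn, [], FACILITY_TERMS + UNIT_TERMS)
        logger.info("unit model (%s): kept %s; eliminated %s", oc, kept, [t for t, _ in trace])
        model = um.fit_nb(records, oc, kept)
        model.los_cutpoints = cutpoints
        models[oc] = model
    return models


def _patient_terms(baseline, hospitals, cfg: PipelineConfig, seed: int, outcome: str):
    """Prescreen + consensus LASSO + facility-term AIC offer for one outcome."""
    flags = [c for c in baseline.columns if c.startswith(("com_", "proc_"))]
    candidates = sel.prescreen_union(
        baseline, flags, cfg.prescreen_floor, cfg.prescreen_alpha, outcomes=cfg.outcomes
    )
    logger.info("prescreen kept %d of %d flags", len(candidates), len(flags))
    cons = sel.consensus_select(
        baseline, K=cfg.k_subsets, seed=seed, outcome=outcome,
        candidates=candidates, n_lambda=cfg.n_lambda,
    )
    count_terms = BASE_COUNT + sorted(cons.consensus_count)
    zero_terms = BASE_ZERO + sorted(cons.consensus_zero)

    facility_kept: list[str] = []
    if cfg.offer_facility_terms and hospitals is not None:
        merged = baseline.merge(hospitals, on="hospital_id", how="left")
        records = merged  # patient-level frame with facility columns attached

        def fit_fn(terms):
            return um.fit_nb(records, outcome, terms).aic

        facility_kept, trace = sel.backward_aic(fit_fn, count_terms, FACILITY_TERMS)
        logger.info(
            "patient model (%s): facility terms kept %s", outcome, facility_kept
        )
    return count_terms, zero_terms, facility_kept, cons


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every configured stage; returns the artifact directory.

    Writes the benchmark table, tau matrix, intercept pairs, fitted-model
    JSON and a manifest with the config hash and stage seeds.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)

    # --- data -------------------------------------------------------------
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": seeds[0]})
        cohort = simulate_cohort(sim_cfg)
        stays, units, hospitals = cohort.stays, cohort.units, cohort.hospitals
    elif config.stays_path:
        stays = _load_table(config.stays_path)
        units = _load_table(config.units_path) if config.units_path else None
        hospitals = _load_table(config.hospitals_path) if config.hospitals_path else None
    else:
        raise ValueError("config must provide either 'simulate' settings or 'stays_path'")

    violations = validate_inputs(stays, units, hospitals)
    if violations:
        (outdir / "violations.json").write_text(json.dumps(violations, default=str))
        raise ValueError(f"input validation failed with {len(violations)} violations")

    baseline = stays[stays["period"] == "baseline"].reset_index(drop=True)
    evaluation = stays[stays["period"] == "evaluation"].reset_index(drop=True)
    if baseline.empty or evaluation.empty:
        raise ValueError("both baseline and evaluation periods must contain stays")
    logger.info("baseline %d stays, evaluation %d stays", len(baseline), len(evaluation))

    nb_models = zinb_models = None
    selections = {}

    # --- facility/unit-level model (aggregate NB) -------------------------
    if "unit" in config.methods:
        nb_models = _fit_unit_models(baseline, units, hospitals, config.outcomes)
        for oc, m in nb_models.items():
            (outdir / f"unit_model_{oc}.json").write_text(m.to_json())

    # --- patient-level mixed model ----------------------------------------
    if "patient" in config.methods:
        zinb_models = {}
        control = FitControl(compute_se=False)
        for oc in config.outcomes:
            if config.do_selection:
                count_terms, zero_terms, fac_kept, cons = _patient_terms(
                    baseline, hospitals, config, seeds[1], oc
                )
                selections[oc] = {
                    "count": sorted(cons.consensus_count),
                    "zero": sorted(cons.consensus_zero),
                    "facility_kept": fac_kept,
                }
            else:
                flags = [c for c in baseline.columns if c.startswith(("com_", "proc_"))]
                count_terms = BASE_COUNT + flags
                zero_terms = BASE_ZERO + flags
            model = fit_zinb_mixed(baseline, count_terms, zero_terms, outcome=oc, control=control)
            zinb_models[oc] = model
            (outdir / f"patient_model_{oc}.json").write_text(model.to_json())
            if config.compute_variance_reduction:
                null = fit_zinb_mixed(baseline, [], ["log_dp"], outcome=oc, control=control)
                from .patient_model import variance_reduction

                red = variance_reduction(null, model)
                selections.setdefault(oc, {})["variance_reduction"] = {
                    "count": red[0], "zero": red[1],
                }

    # --- scoring & comparison ----------------------------------------------
    bench = bm.build_benchmark(evaluation, units, hospitals, nb_models, zinb_models)
    bench.to_csv(outdir / "benchmark.csv", index=False)
    bm.benchmark_summary(bench).to_csv(outdir / "benchmark_summary.csv", index=False)

    ratio_cols = [c for c in bm.RATIO_COLUMNS if c in bench.columns]
    if len(ratio_cols) >= 2:
        tm = cmp.tau_matrix(bench, ratio_cols)
        tm.to_frame().to_csv(outdir / "tau_matrix.csv")

    if zinb_models:
        for oc, m in zinb_models.items():
            try:
                pairs, rho, p = cmp.intercept_correlation(m)
                pairs.to_csv(outdir / f"intercept_pairs_{oc}.csv", index=False)
            except ValueError as exc:
                warnings.warn(f"intercept correlation ({oc}): {exc}")

    if config.figures:
        _write_figures(outdir, bench, ratio_cols)

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "config": config.model_dump(),
        "selections": selections,
        "n_baseline": int(len(baseline)),
        "n_evaluation": int(len(evaluation)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _write_figures(outdir: Path, bench: pd.DataFrame, ratio_cols: list[str]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ratio_cols), figsize=(3 * len(ratio_cols), 4), sharey=False)
    if len(ratio_cols) == 1:
        axes = [axes]
    for ax, col in zip(np.atleast_1d(axes), ratio_cols):
        vals = bench[col].dropna().sort_values().to_numpy()
        ax.plot(np.arange(len(vals)), vals, "o", ms=3)
        ref = np.median(vals) if col.startswith("crude") else 1.0
        ax.axhline(ref, ls="--", c="grey")
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(outdir / "benchmark_dotplots.png", dpi=120)
    plt.close(fig)
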