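"""Facility benchmarking tables across metrics and adjustment levels.

For an evaluation period this module assembles, per hospital, up to six
benchmark columns — the crude DOT and DASC rates per 1000 DP, the O:E
ratios from the facility/unit-level NB model, and the P:E ratios from the
patient-level mixed model — together with each hospital's rank under each
column.  Ranks use average ranks for ties so that downstream Kendall
tau-b comparisons are tie-consistent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .patient_model import ZinbMixedModel, pe_ratios, reestimate_blups
from .unit_model import NbModel, aggregate_unit_month, assign_los_quintiles, oe_ratios

__all__ = ["build_benchmark", "benchmark_summary", "RATIO_COLUMNS"]

RATIO_COLUMNS = ["crude_dot", "crude_dasc", "oe_dot", "oe_dasc", "pe_dot", "pe_dasc"]


def build_benchmark(
    stays_eval: pd.DataFrame,
    units: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
    nb_models: dict[str, NbModel] | None = None,
    zinb_models: dict[str, ZinbMixedModel] | None = None,
) -> pd.DataFrame:
    """One row per hospital with every available benchmark column and rank.

    ``nb_models`` / ``zinb_models`` map outcome name (``dot``/``dasc``) to
    a model fitted on baseline data; pass ``None`` or omit outcomes to
    build a crude-only (or partial) table.  Hospitals missing from any
    requested column are flagged ``complete=False`` so rank correlations
    can drop them listwise.
    """
    crude = stays_eval.groupby("hospital_id").agg(
        dp=("dp", "sum"), dot=("dot", "sum"), dasc=("dasc", "sum")
    )
    bench = pd.DataFrame(index=crude.index)
    bench["crude_dot"] = 1000.0 * crude["dot"] / crude["dp"]
    bench["crude_dasc"] = 1000.0 * crude["dasc"] / crude["dp"]

    if nb_models:
        records = aggregate_unit_month(stays_eval, units, hospitals)
        for outcome, model in nb_models.items():
            scored, _ = assign_los_quintiles(records, model.los_cutpoints)
            oe = oe_ratios(model, scored).set_index("hospital_id")
            bench[f"oe_{outcome}"] = oe["oe"]

    if zinb_models:
        for outcome, model in zinb_models.items():
            blups = reestimate_blups(model, stays_eval)
            pe = pe_ratios(model, stays_eval, blups)
            s = pd.Series({r.hospital_id: r.pe_ratio for r in pe})
            bench[f"pe_{outcome}"] = s

    cols = [c for c in RATIO_COLUMNS if c in bench.columns]
    bench["complete"] = bench[cols].notna().all(axis=1)
    if not bench["complete"].all():
        warnings.warn(
            f"{(~bench['complete']).sum()} hospitals have incomplete benchmark rows"
        )
    for c in cols:
        bench[f"rank_{c}"] = bench[c].rank(method="average")
    return bench.reset_index()


def benchmark_summary(bench: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of each ratio column (median-unbiased quantiles)."""
    rows = []
    for c in [c for c in RATIO_COLUMNS if c in bench.columns]:
        v = bench[c].dropna().to_numpy()
        q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75], method="median_unbiased")
        rows.append({"column": c, "median": q50, "q25": q25, "q75": q75})
    return pd.DataFrame(rows)
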