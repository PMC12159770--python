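"""Facility/unit-level negative-binomial benchmarking model.

The aggregate-level adjustment approach: antibiotic use is summed to
unit × calendar-month records, and a single-level NB2 regression with a
``log(DP)`` offset relates the monthly count to facility attributes
(complexity level, ICU complexity, surgical complexity, trainee volume)
and unit attributes (ICU vs ward, surgical vs non-surgical specialty,
average-length-of-stay quintile).  No patient-level information enters.

The model is fitted on a baseline period and frozen; scoring an
evaluation period sums observed and model-expected use per facility and
reports the observed-to-expected (O:E) ratio.  The interval on O:E is an
exact Poisson-style interval on the observed total treating the expected
total as fixed — the convention used for standardised-ratio reporting.

Average-length-of-stay quintile cut points are computed on the baseline
records and reused verbatim for the evaluation period, so no
evaluation-period information leaks into the risk model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORICAL_LEVELS",
    "NbModel",
    "aggregate_unit_month",
    "assign_los_quintiles",
    "fit_nb",
    "oe_ratios",
]

# declared level order; the first level is the reference (rate ratio 1)
CATEGORICAL_LEVELS: dict[str, list] = {
    "complexity_level": ["1a", "1b", "1c", "2", "3"],
    "icu_complexity": ["5", "4", "3", "2", "1"],
    "surgical_complexity": ["4", "3", "2", "1", "0.5", "0"],
    "trainees_quintile": [1, 2, 3, 4, 5],
    "avg_los_quintile": [1, 2, 3, 4, 5],
}


@dataclass
class NbModel:
    """Fitted NB2 aggregate model: coefficients, dispersion and design spec."""

    outcome: str
    terms: list[str]
    columns: list[str]
    params: np.ndarray
    bse: np.ndarray
    theta: float
    categories: dict[str, list]  # term -> non-reference levels present at baseline
    los_cutpoints: list[float] | None = None
    loglik: float = np.nan
    aic: float = np.nan

    def rate_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """exp(coefficients) with Wald intervals, one row per design column."""
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "term": self.columns,
                "rate_ratio": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "outcome": self.outcome,
                "terms": self.terms,
                "columns": self.columns,
                "params": self.params.tolist(),
                "bse": self.bse.tolist(),
                "theta": self.theta,
                "categories": {k: list(v) for k, v in self.categories.items()},
                "los_cutpoints": self.los_cutpoints,
                "loglik": self.loglik,
                "aic": self.aic,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NbModel":
        d = json.loads(text)
        return cls(
            outcome=d["outcome"],
            terms=d["terms"],
            columns=d["columns"],
            params=np.asarray(d["params"]),
            bse=np.asarray(d["bse"]),
            theta=d["theta"],
            categories=d["categories"],
            los_cutpoints=d["los_cutpoints"],
            loglik=d["loglik"],
            aic=d["aic"],
        )


def aggregate_unit_month(
    stays: pd.DataFrame,
    units: pd.DataFrame | None = None,
    hospitals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sum stays to unit × month records, attaching unit/facility attributes.

    DOT, DASC and DP totals are conserved exactly (each stay belongs to one
    unit-month via its recorded month).  Also computes each unit's average
    length of stay (mean DP per stay) for downstream quintile assignment.
    """
    if units is not None:
        unknown = set(stays["unit_id"]) - set(units["unit_id"])
        if unknown:
            raise ValueError(f"stays reference unknown units: {sorted(unknown)[:5]}")
    grouped = (
        stays.groupby(["hospital_id", "unit_id", "month"], as_index=False)
        .agg(dp=("dp", "sum"), dot=("dot", "sum"), dasc=("dasc", "sum"), n_stays=("dp", "size"))
    )
    grouped["avg_los"] = grouped["dp"] / grouped["n_stays"]
    if units is not None:
        grouped = grouped.merge(
            units[["unit_id", "icu_floor", "surgical_floor"]], on="unit_id", how="left"
        )
    if hospitals is not None:
        grouped = grouped.merge(hospitals, on="hospital_id", how="left")
    return grouped


def assign_los_quintiles(
    records: pd.DataFrame, cutpoints: list[float] | None = None
) -> tuple[pd.DataFrame, list[float]]:
    """Attach ``avg_los_quintile`` (1–5); cut points frozen on first use.

    When ``cutpoints`` is None they are computed from these records
    (baseline); pass the stored cut points when scoring a later period.
    """
    records = records.copy()
    if cutpoints is None:
        cutpoints = list(np.quantile(records["avg_los"], [0.2, 0.4, 0.6, 0.8]))
    records["avg_los_quintile"] = 1 + np.searchsorted(
        np.asarray(cutpoints), records["avg_los"].to_numpy(), side="right"
    )
    return records, cutpoints


def _build_design(
    records: pd.DataFrame, terms: list[str], categories: dict[str, list] | None
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Design matrix with intercept; categoricals dummy-coded against their
    declared reference level.  When ``categories`` is given (scoring), a
    level unseen at baseline raises rather than silently re-referencing."""
    cols = [np.ones(len(records))]
    names = ["intercept"]
    cats_out: dict[str, list] = {}
    for t in terms:
        if t in CATEGORICAL_LEVELS:
            declared = CATEGORICAL_LEVELS[t]
            vals = records[t]
            bad = set(vals.unique()) - set(declared)
            if bad:
                raise ValueError(f"{t}: undeclared levels {sorted(map(str, bad))}")
            if categories is None:
                present = [lv for lv in declared[1:] if (vals == lv).any()]
            else:
                present = categories[t]
                unseen = set(vals.unique()) - set(present) - {declared[0]}
                if unseen:
                    raise ValueError(
                        f"{t}: levels {sorted(map(str, unseen))} were not present "
                        f"in the baseline fit"
                    )
            cats_out[t] = present
            for lv in present:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{t}[{lv}]")
        else:
            cols.append(records[t].to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names, cats_out


def fit_nb(
    records: pd.DataFrame, outcome: str, terms: list[str]
) -> NbModel:
    """Fit NB2 regression of a unit-month count on the given terms.

    ``log(dp)`` enters as the exposure offset.  Collinear design columns
    are dropped with a warning before fitting.  Non-integer outcomes
    (DASC) are rounded for the count likelihood.
    """
    import statsmodels.api as sm

    y = np.round(records[outcome].to_numpy(dtype=float))
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must take at least 2 distinct values")
    X, names, cats = _build_design(records, terms, None)

    # drop collinear columns (keep the first of each dependent group)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping collinear terms: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, exposure=records["dp"].to_numpy(dtype=float))
        res = model.fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(
            "negative binomial fit did not converge; "
            f"final gradient norm {np.abs(res.model.score(res.params)).max():.3g}"
        )
    alpha = float(res.params[-1])
    theta = 1.0 / max(alpha, 1e-8)
    return NbModel(
        outcome=outcome,
        terms=list(terms),
        columns=names,
        params=np.asarray(res.params[:-1]),
        bse=np.asarray(res.bse[:-1]),
        theta=theta,
        categories=cats,
        loglik=float(res.llf),
        aic=float(res.aic),
    )


def expected_counts(model: NbModel, records: pd.DataFrame) -> np.ndarray:
    """Model-expected outcome per record: exp(X beta + log dp)."""
    X, names, _ = _build_design(records, model.terms, model.categories)
    if names != model.columns:
        # collinear columns dropped at fit time are absent from the model
        idx = [names.index(c) for c in model.columns]
        X = X[:, idx]
    return np.exp(X @ model.params) * records["dp"].to_numpy(dtype=float)


def oe_ratios(model: NbModel, eval_records: pd.DataFrame) -> pd.DataFrame:
    """Facility observed-to-expected ratios for an evaluation period.

    O and E are sums of observed and fixed-effect-expected use over the
    facility's unit-months; the 95% interval is an exact Poisson interval
    on O with E treated as fixed.
    """
    e = expected_counts(model, eval_records)
    df = pd.DataFrame(
        {
            "hospital_id": eval_records["hospital_id"].to_numpy(),
            "observed": eval_records[model.outcome].to_numpy(dtype=float),
            "expected": e,
        }
    )
    agg = df.groupby("hospital_id", as_index=False).sum()
    o = agg["observed"].to_numpy()
    ex = agg["expected"].to_numpy()
    lo = np.where(o > 0, stats.chi2.ppf(0.025, 2 * o) / 2, 0.0) / ex
    hi = stats.chi2.ppf(0.975, 2 * (o + 1)) / 2 / ex
    agg["oe"] = o / ex
    agg["ci_low"] = lo
    agg["ci_high"] = hi
    return agg
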