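"""Agreement between benchmarking schemes.

Rank agreement between any two benchmark columns is summarised by the
Kendall tau-b coefficient (tie-corrected), classified as strong (>= 0.7),
moderate (0.5 to < 0.7) or weak (< 0.5).  tau-b is computed on the ratio
values themselves; because it depends only on pair orderings this equals
computing it on the ranks.

The module also reports the correlation between a fitted model's count-
and zero-component hospital intercepts — hospitals that start antibiotics
more freely also tending to treat longer/broader shows up as a positive
association between the two BLUP vectors.  Spearman correlation is used
because BLUP shrinkage is nonlinear in hospital size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .patient_model import ZinbMixedModel

__all__ = ["TauMatrix", "kendall_tau_b", "tau_matrix", "classify_tau", "intercept_correlation"]


def classify_tau(tau: float) -> str:
    if tau >= 0.7:
        return "strong"
    if tau >= 0.5:
        return "moderate"
    return "weak"


@dataclass
class TauMatrix:
    labels: list[str]
    tau: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.labels)
        assert self.tau.shape == (k, k)

    @property
    def classification(self) -> dict[tuple[str, str], str]:
        out = {}
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i < j:
                    out[(a, b)] = classify_tau(self.tau[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.labels, columns=self.labels)


def kendall_tau_b(x, y) -> float:
    """Kendall tau-b: (C - D) / sqrt((n0 - n1)(n0 - n2)), tie-corrected.

    Raises :class:`ValueError` if either vector is entirely tied (tau-b is
    undefined there, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau-b is undefined for an all-tied vector")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def tau_matrix(bench: pd.DataFrame, columns: list[str] | None = None) -> TauMatrix:
    """All pairwise tau-b values among benchmark ratio columns.

    Hospitals with a missing value in any requested column are dropped
    listwise.
    """
    from .benchmark import RATIO_COLUMNS

    if columns is None:
        columns = [c for c in RATIO_COLUMNS if c in bench.columns]
    sub = bench[columns].dropna()
    if len(sub) < 2:
        raise ValueError("need at least 2 complete hospitals")
    dropped = len(bench) - len(sub)
    if dropped:
        import warnings

        warnings.warn(f"dropped {dropped} incomplete hospitals from the tau matrix")
    k = len(columns)
    tau = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            tau[i, j] = tau[j, i] = kendall_tau_b(sub[columns[i]], sub[columns[j]])
    return TauMatrix(labels=list(columns), tau=tau)


def intercept_correlation(model: ZinbMixedModel) -> tuple[pd.DataFrame, float, float]:
    """Per-hospital (b_count, b_zero) BLUP pairs and their Spearman correlation.

    Returns the scatter data, rho, and the p-value.  Degenerate fits with
    (numerically) constant BLUPs raise, since the correlation is
    undefined there.
    """
    pairs = model.blups[["hospital_id", "b_count", "b_zero"]].copy()
    if len(pairs) < 3:
        raise ValueError("need at least 3 hospitals")
    if pairs["b_count"].nunique() < 2 or pairs["b_zero"].nunique() < 2:
        raise ValueError("degenerate fit: all BLUPs equal; correlation undefined")
    res = stats.spearmanr(pairs["b_count"], pairs["b_zero"])
    return pairs, float(res.statistic), float(res.pvalue)
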