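"""Variable screening and selection for the risk-adjustment models.

Three stages mirror how the patient-level model is assembled:

1. **Prescreen** — a comorbidity/procedure flag is a candidate only if at
   least a floor fraction of patients carry it (default 0.5%) *and* it has
   a significant univariate association with the per-DP outcome rate
   (Spearman rank correlation, two-sided, default alpha 0.05).  Flags
   passing for either DOT or DASC form a common candidate list.
2. **Consensus LASSO** — stays are split into K random subsets (a disjoint
   partition, stratified by hospital so every subset contains every
   hospital); an L1-penalised zero-inflated NB fit selects flags for the
   count and zero components within each subset; only flags selected in
   *all* K subsets survive.  The strict intersection controls overfitting
   on a large, heterogeneous cohort.
3. **Backward AIC** — facility- and unit-level variables are then offered
   to the model and removed one at a time (categorical variables move as a
   block) while any single removal lowers the AIC; the patient-level
   consensus variables are never dropped.

The penalised ZINB fit alternates between the two components in EM
fashion: given working parameters, each zero outcome gets a posterior
probability of being structural; the zero component is then a
fraction-response logistic LASSO and the count component a
posterior-weighted NB LASSO with ``log(dp)`` offset.  The penalty is
chosen by BIC along a log-spaced path, which is deterministic and cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, gammaln

__all__ = [
    "CandidateScreenResult",
    "ConsensusSelection",
    "prescreen_candidates",
    "prescreen_union",
    "lasso_select_zinb",
    "consensus_select",
    "backward_aic",
]


@dataclass
class CandidateScreenResult:
    variable_id: str
    prevalence: float
    screen_p_value: float
    passed: bool


@dataclass
class ConsensusSelection:
    per_subset_count: list[set[str]]
    per_subset_zero: list[set[str]]
    consensus_count: set[str] = field(init=False)
    consensus_zero: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.consensus_count = set.intersection(*self.per_subset_count)
        self.consensus_zero = set.intersection(*self.per_subset_zero)
        for name, sel in (("count", self.consensus_count), ("zero", self.consensus_zero)):
            if not sel:
                warnings.warn(f"empty consensus set for the {name} component")


# ---------------------------------------------------------------------------
# prescreen
# ---------------------------------------------------------------------------


def prescreen_candidates(
    stays: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "dot",
    floor: float = 0.005,
    alpha: float = 0.05,
) -> list[CandidateScreenResult]:
    """Prevalence + univariate-correlation screen against one outcome rate.

    The association statistic is the Spearman rank correlation between the
    binary flag and the stay-level ``outcome / dp`` rate.  Constant flags
    fail the screen (p-value NaN) without raising.
    """
    rate = stays[outcome].to_numpy(dtype=float) / stays["dp"].to_numpy(dtype=float)
    out = []
    for var in candidates:
        x = stays[var].to_numpy(dtype=float)
        prev = float(x.mean())
        if prev == 0.0 or prev == 1.0:
            out.append(CandidateScreenResult(var, prev, float("nan"), False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.spearmanr(x, rate)
        p = float(res.pvalue)
        out.append(CandidateScreenResult(var, prev, p, prev >= floor and p < alpha))
    return out


def prescreen_union(
    stays: pd.DataFrame,
    candidates: Sequence[str],
    floor: float = 0.005,
    alpha: float = 0.05,
    outcomes: Sequence[str] = ("dot", "dasc"),
) -> list[str]:
    """Flags passing the screen for *any* of the listed outcomes (common list)."""
    passed: set[str] = set()
    for oc in outcomes:
        for r in prescreen_candidates(stays, candidates, oc, floor, alpha):
            if r.passed:
                passed.add(r.variable_id)
    return [v for v in candidates if v in passed]


# ---------------------------------------------------------------------------
# penalised ZINB selection
# ---------------------------------------------------------------------------

_BASE_COUNT_TERMS = ["age_c", "sex", "icu_stay", "surgical_specialty"]
_BASE_ZERO_TERMS = ["age_c", "sex", "icu_stay", "surgical_specialty", "log_dp"]


def _design(stays, terms):
    cols = [np.ones(len(stays))]
    for t in terms:
        if t == "log_dp":
            cols.append(np.log(stays["dp"].to_numpy(dtype=float)))
        else:
            cols.append(stays[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _nb_logpmf(y, mu, theta):
    return (
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def _moment_theta(y, mu):
    """Method-of-moments NB2 dispersion given fitted means."""
    resid = (y - mu) ** 2 - mu
    denom = float((mu**2).sum())
    alpha = max(float(resid.sum()) / denom, 1e-3) if denom > 0 else 1.0
    return 1.0 / alpha


def _bic_path_fit(model_builder, X_pen_idx, n_eff, lambdas, loglik_fn):
    """Fit a warm-started penalty path; return the BIC-best support and coefs.

    The path walks from the strongest penalty down, reusing the previous
    solution as the start, and stops early once BIC has risen for several
    consecutive steps past the best point.
    """
    best = (np.inf, None, None)
    start = None
    rising = 0
    for lam in lambdas:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = model_builder(lam, start)
        except Exception:
            continue
        start = params
        support = np.abs(params[X_pen_idx]) > 1e-8
        df = 1 + int(support.sum())
        bic = -2.0 * loglik_fn(params) + df * np.log(n_eff)
        if bic < best[0]:
            best = (bic, params, support)
            rising = 0
        else:
            rising += 1
            if rising >= 4:
                break
    if best[1] is None:
        raise RuntimeError("no penalty on the path produced a converged fit")
    return best[2], best[1]


def penalized_zinb_supports(
    stays: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "dot",
    n_lambda: int = 25,
    max_cycles: int = 3,
    base_count_terms: Sequence[str] = tuple(_BASE_COUNT_TERMS),
    base_zero_terms: Sequence[str] = tuple(_BASE_ZERO_TERMS),
) -> tuple[set[str], set[str]]:
    """L1-penalised ZINB selection: returns (count support, zero support).

    Base demographic/unit terms and the intercept are never penalised;
    only the candidate flags carry the L1 penalty.  See the module
    docstring for the EM alternation.
    """
    import statsmodels.api as sm

    y = np.round(stays[outcome].to_numpy(dtype=float))
    if not (y == 0).any() or not (y > 0).any():
        raise ValueError("subset must contain both zero and positive outcomes")
    n = len(y)
    log_dp = np.log(stays["dp"].to_numpy(dtype=float))
    cand = list(candidates)

    Xc = _design(stays, list(base_count_terms) + cand)
    Xz = _design(stays, list(base_zero_terms) + cand)
    pen_c = np.arange(1 + len(base_count_terms), Xc.shape[1])
    pen_z = np.arange(1 + len(base_zero_terms), Xz.shape[1])

    zero_mask = y == 0

    # initial working fits: base-terms-only Poisson and logistic
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        po = sm.GLM(y, Xc[:, : 1 + len(base_count_terms)],
                    family=sm.families.Poisson(), offset=log_dp).fit()
        mu0 = po.fittedvalues
        lo = sm.GLM(zero_mask.astype(float), Xz[:, : 1 + len(base_zero_terms)],
                    family=sm.families.Binomial()).fit()
        pi0 = lo.fittedvalues
    theta = _moment_theta(y, mu0)
    mu, pi = mu0, pi0

    sel_c: set[str] = set()
    sel_z: set[str] = set()
    for _cycle in range(max_cycles):
        # E-step: posterior probability each observed zero is structural
        f0 = np.exp(theta * (np.log(theta) - np.log(theta + mu)))
        w = np.where(zero_mask, pi / np.clip(pi + (1 - pi) * f0, 1e-300, None), 0.0)

        # M-step, count component: posterior-weighted NB LASSO
        cw = np.clip(1.0 - w, 1e-6, 1.0)
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        score = np.abs(Xc[:, pen_c].T @ (cw * (y - mu)))
        lam_max = max(score.max() / n, 1e-4)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

        def fit_count(lam, start):
            avec = np.zeros(Xc.shape[1])
            avec[pen_c] = lam
            m = sm.GLM(y, Xc, family=fam, offset=log_dp, var_weights=cw)
            return m.fit_regularized(
                method="elastic_net", alpha=avec, L1_wt=1.0,
                start_params=start, cnvrg_tol=1e-5, maxiter=60,
            ).params

        def ll_count(params):
            mu_p = np.exp(Xc @ params + log_dp)
            return float((cw * _nb_logpmf(y, mu_p, theta)).sum())

        sup_c, par_c = _bic_path_fit(fit_count, pen_c, float(cw.sum()), lambdas, ll_count)
        mu = np.exp(Xc @ par_c + log_dp)
        theta = _moment_theta(y[~zero_mask], mu[~zero_mask])

        # M-step, zero component: fractional-response logistic LASSO
        score = np.abs(Xz[:, pen_z].T @ (w - pi))
        lam_max = max(score.max() / n, 1e-4)
        lambdas = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

        def fit_zero(lam, start):
            avec = np.zeros(Xz.shape[1])
            avec[pen_z] = lam
            m = sm.GLM(w, Xz, family=sm.families.Binomial())
            return m.fit_regularized(
                method="elastic_net", alpha=avec, L1_wt=1.0,
                start_params=start, cnvrg_tol=1e-5, maxiter=60,
            ).params

        def ll_zero(params):
            p = np.clip(expit(Xz @ params), 1e-12, 1 - 1e-12)
            return float((w * np.log(p) + (1 - w) * np.log(1 - p)).sum())

        sup_z, par_z = _bic_path_fit(fit_zero, pen_z, float(n), lambdas, ll_zero)
        pi = np.clip(expit(Xz @ par_z), 1e-10, 1 - 1e-10)

        new_c = {cand[i] for i in range(len(cand)) if sup_c[i]}
        new_z = {cand[i] for i in range(len(cand)) if sup_z[i]}
        if new_c == sel_c and new_z == sel_z:
            sel_c, sel_z = new_c, new_z
            break
        sel_c, sel_z = new_c, new_z
    return sel_c, sel_z


def lasso_select_zinb(
    subset_stays: pd.DataFrame,
    component: str,
    outcome: str = "dot",
    candidates: Sequence[str] | None = None,
    **kwargs,
) -> set[str]:
    """Selected candidate set for one ZINB component on one data subset."""
    if component not in ("count", "zero"):
        raise ValueError("component must be 'count' or 'zero'")
    if candidates is None:
        candidates = [c for c in subset_stays.columns if c.startswith(("com_", "proc_"))]
    sup_c, sup_z = penalized_zinb_supports(subset_stays, candidates, outcome, **kwargs)
    return sup_c if component == "count" else sup_z


def _partition_by_hospital(stays: pd.DataFrame, K: int, seed: int) -> list[np.ndarray]:
    """Disjoint random K-partition of stay row positions, stratified by hospital."""
    rng = np.random.default_rng(seed)
    buckets: list[list[int]] = [[] for _ in range(K)]
    for _, idx in stays.groupby("hospital_id").indices.items():
        idx = rng.permutation(idx)
        offset = rng.integers(K)
        for i, row in enumerate(idx):
            buckets[(i + offset) % K].append(row)
    return [np.sort(np.array(b)) for b in buckets]


def consensus_select(
    stays: pd.DataFrame,
    K: int = 10,
    seed: int = 0,
    outcome: str = "dot",
    candidates: Sequence[str] | None = None,
    **kwargs,
) -> ConsensusSelection:
    """Run the per-subset LASSO on a K-way random partition; keep the intersection."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if candidates is None:
        candidates = [c for c in stays.columns if c.startswith(("com_", "proc_"))]
    parts = _partition_by_hospital(stays.reset_index(drop=True), K, seed)
    per_c, per_z = [], []
    for k, rows in enumerate(parts):
        if len(rows) == 0:
            raise ValueError(f"subset {k} is empty; reduce K")
        sub = stays.reset_index(drop=True).iloc[rows]
        sup_c, sup_z = penalized_zinb_supports(sub, candidates, outcome, **kwargs)
        per_c.append(sup_c)
        per_z.append(sup_z)
    return ConsensusSelection(per_subset_count=per_c, per_subset_zero=per_z)


# ---------------------------------------------------------------------------
# backward elimination on AIC
# ---------------------------------------------------------------------------


def backward_aic(
    fit_fn: Callable[[list[str]], float],
    fixed_in: Sequence[str],
    candidates: Sequence[str],
) -> tuple[list[str], list[tuple[str, float]]]:
    """Backward elimination of ``candidates`` to minimise AIC.

    ``fit_fn(terms)`` fits the model with the given term list (categorical
    variables enter and leave as whole blocks inside the fit function) and
    returns its AIC.  ``fixed_in`` terms are always present and never
    dropped.  Returns the surviving candidate list and the elimination
    trace as (dropped term, AIC after dropping) pairs.  A candidate whose
    removal makes the fit fail is kept, with a warning.
    """
    remaining = list(candidates)
    trace: list[tuple[str, float]] = []
    current_aic = fit_fn(list(fixed_in) + remaining)
    while remaining:
        best = (current_aic, None)
        for c in remaining:
            terms = list(fixed_in) + [t for t in remaining if t != c]
            try:
                aic = fit_fn(terms)
            except Exception as exc:
                warnings.warn(f"fit without {c!r} failed ({exc}); keeping it")
                continue
            if aic < best[0]:
                best = (aic, c)
        if best[1] is None:
            break
        remaining.remove(best[1])
        trace.append((best[1], best[0]))
        current_aic = best[0]
    return remaining, trace
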