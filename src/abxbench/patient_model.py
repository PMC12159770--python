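"""Patient-level zero-inflated negative binomial model with hospital random intercepts.

This is the engine behind predicted-to-expected (P:E) benchmarking.  Each
stay's antibiotic use ``Y`` (DOT or DASC) follows a two-part mixture:

* a **zero-inflation component** — the probability ``pi`` that the stay
  receives no antibiotics at all, on the logit scale with patient
  covariates, ``log(dp)`` as a regular term, and a hospital intercept
  ``b_zero``;
* a **count component** — given any use, ``Y ~ NB2(mu, theta)`` with
  ``log mu = x'beta_count + log(dp) + b_count`` (days present as offset)
  and hospital intercept ``b_count``.

The two hospital intercepts are modelled as independent normals
``b_count ~ N(0, sigma2_count)``, ``b_zero ~ N(0, sigma2_zero)``; their
empirical correlation is examined after fitting rather than parameterised.
The marginal likelihood integrates the intercept pair out per hospital,
by default with a bivariate Laplace approximation at the posterior mode
(adaptive Gauss–Hermite quadrature with a configurable node count is
available as an accuracy cross-check).  BLUPs are the per-hospital
posterior modes.

Scoring a new period freezes the fixed effects, dispersion and variance
components and re-estimates only the intercepts from the new stays; the
facility P:E ratio is the facility total of mixture-mean predictions with
BLUPs over the same total with intercepts set to zero.  Because posterior
modes shrink toward zero when a hospital contributes little information,
P:E flags small hospitals less often than observed-to-expected ratios do.

DASC is non-integer after spectrum weighting; the model evaluates the NB2
likelihood at rounded outcomes by default (see :func:`fit_zinb_mixed`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.special import expit, gammaln, log_expit

__all__ = [
    "ZinbMixedModel",
    "FacilityPE",
    "FitControl",
    "zinb_loglik",
    "fit_zinb_mixed",
    "reestimate_blups",
    "pe_ratios",
    "variance_reduction",
]

_SIGMA2_FLOOR = 1e-8


@dataclass
class FitControl:
    """Optimiser settings for the marginal-likelihood fit."""

    method: str = "laplace"  # or "agq"
    agq_nodes: int = 7
    max_outer_iter: int = 400
    outer_gtol: float = 1e-6
    outer_ftol: float = 1e-11
    inner_gtol: float = 1e-9
    inner_max_iter: int = 60
    fd_eps: float = 1e-6
    round_outcome: bool = True  # round non-integer outcomes (DASC) for the NB pmf
    compute_se: bool = True


@dataclass
class ZinbMixedModel:
    """Fitted two-component mixed model: fixed effects, dispersion, variances, BLUPs."""

    count_terms: list[str]
    zero_terms: list[str]
    beta_count: np.ndarray
    beta_zero: np.ndarray
    theta: float
    sigma2_count: float
    sigma2_zero: float
    blups: pd.DataFrame  # hospital_id, b_count, b_zero
    loglik: float
    converged: bool
    outcome: str = "dot"
    se_count: np.ndarray | None = None
    se_zero: np.ndarray | None = None
    control: FitControl = field(default_factory=FitControl)
    n_stays: int = 0

    def ci_count(self, level: float = 0.95) -> np.ndarray:
        """Wald intervals for the count-component fixed effects (log scale)."""
        if self.se_count is None:
            raise ValueError("standard errors were not computed for this fit")
        z = special.ndtri(0.5 + level / 2)
        return np.column_stack(
            [self.beta_count - z * self.se_count, self.beta_count + z * self.se_count]
        )

    def ci_zero(self, level: float = 0.95) -> np.ndarray:
        if self.se_zero is None:
            raise ValueError("standard errors were not computed for this fit")
        z = special.ndtri(0.5 + level / 2)
        return np.column_stack(
            [self.beta_zero - z * self.se_zero, self.beta_zero + z * self.se_zero]
        )

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "count_terms": self.count_terms,
                "zero_terms": self.zero_terms,
                "beta_count": self.beta_count.tolist(),
                "beta_zero": self.beta_zero.tolist(),
                "theta": self.theta,
                "sigma2_count": self.sigma2_count,
                "sigma2_zero": self.sigma2_zero,
                "blups": self.blups.to_dict(orient="list"),
                "loglik": self.loglik,
                "converged": self.converged,
                "outcome": self.outcome,
                "round_outcome": self.control.round_outcome,
                "n_stays": self.n_stays,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ZinbMixedModel":
        import json

        d = json.loads(text)
        return cls(
            count_terms=d["count_terms"],
            zero_terms=d["zero_terms"],
            beta_count=np.asarray(d["beta_count"]),
            beta_zero=np.asarray(d["beta_zero"]),
            theta=d["theta"],
            sigma2_count=d["sigma2_count"],
            sigma2_zero=d["sigma2_zero"],
            blups=pd.DataFrame(d["blups"]),
            loglik=d["loglik"],
            converged=d["converged"],
            outcome=d["outcome"],
            control=FitControl(round_outcome=d["round_outcome"]),
            n_stays=d["n_stays"],
        )


@dataclass
class FacilityPE:
    """Facility totals of BLUP-based and fixed-effect-only expected use."""

    hospital_id: str
    predicted: float
    expected: float

    @property
    def pe_ratio(self) -> float:
        return self.predicted / self.expected


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 log pmf: variance mu + mu^2/theta."""
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu) - np.log(theta + mu))
    )


def _stay_loglik(y, eta_c, eta_z, theta, zero_mask):
    """Per-stay mixture log-likelihood, numerically stable at extreme logits."""
    mu = np.exp(eta_c)
    log_pi = log_expit(eta_z)
    log_1mpi = log_expit(-eta_z)
    log_f0 = theta * (np.log(theta) - np.log(theta + mu))
    ll = np.empty_like(eta_c)
    ll[zero_mask] = np.logaddexp(log_pi[zero_mask], log_1mpi[zero_mask] + log_f0[zero_mask])
    pos = ~zero_mask
    ll[pos] = log_1mpi[pos] + _nb_logpmf(y[pos], mu[pos], theta)
    return ll


def _stay_grad_hess(y, eta_c, eta_z, theta, zero_mask):
    """Per-stay first and second derivatives of the log-likelihood w.r.t.
    (b_count, b_zero) — i.e. w.r.t. shifts of eta_c and eta_z."""
    mu = np.exp(eta_c)
    pi = expit(eta_z)
    n = len(y)
    g_c = np.empty(n)
    g_z = np.empty(n)
    h_cc = np.empty(n)
    h_zz = np.empty(n)
    h_cz = np.zeros(n)

    pos = ~zero_mask
    if pos.any():
        mp, pp, yp = mu[pos], pi[pos], y[pos]
        g_z[pos] = -pp
        g_c[pos] = theta * (yp - mp) / (theta + mp)
        h_zz[pos] = -pp * (1 - pp)
        h_cc[pos] = -theta * mp * (theta + yp) / (theta + mp) ** 2

    if zero_mask.any():
        m0, p0 = mu[zero_mask], pi[zero_mask]
        v = np.exp(theta * (np.log(theta) - np.log(theta + m0)))  # NB(0)
        w = theta * m0 / (theta + m0)
        A = p0 + (1 - p0) * v
        A_z = p0 * (1 - p0) * (1 - v)
        vp = -v * w
        A_c = (1 - p0) * vp
        A_zz = (1 - v) * p0 * (1 - p0) * (1 - 2 * p0)
        vpp = v * theta**2 * m0 * (m0 - 1) / (theta + m0) ** 2
        A_cc = (1 - p0) * vpp
        A_cz = -p0 * (1 - p0) * vp
        g_z[zero_mask] = A_z / A
        g_c[zero_mask] = A_c / A
        h_zz[zero_mask] = A_zz / A - (A_z / A) ** 2
        h_cc[zero_mask] = A_cc / A - (A_c / A) ** 2
        h_cz[zero_mask] = A_cz / A - A_z * A_c / A**2
    return g_c, g_z, h_cc, h_zz, h_cz


def _design(stays: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(stays))]
    for t in terms:
        if t == "log_dp":
            cols.append(np.log(stays["dp"].to_numpy(dtype=float)))
        else:
            cols.append(stays[t].to_numpy(dtype=float))
    return np.column_stack(cols)


class _ZinbData:
    """Pre-extracted arrays for one stay table, grouped by hospital."""

    def __init__(self, stays, count_terms, zero_terms, round_outcome, outcome):
        y_raw = stays[outcome].to_numpy(dtype=float)
        if round_outcome:
            self.y = np.round(y_raw)
        else:
            self.y = y_raw
        if (self.y < 0).any():
            raise ValueError("outcome must be nonnegative")
        self.zero_mask = self.y == 0
        self.Xc = _design(stays, count_terms)
        self.Xz = _design(stays, zero_terms)
        self.log_dp = np.log(stays["dp"].to_numpy(dtype=float))
        hosp = stays["hospital_id"].to_numpy()
        self.hospital_ids, self.hidx = np.unique(hosp, return_inverse=True)
        self.n_hosp = len(self.hospital_ids)
        self.n = len(stays)
        if not self.zero_mask.any() or self.zero_mask.all():
            warnings.warn("outcome has no zeros (or only zeros); the mixture is weakly identified")


def _inner_modes(data, eta_c_fix, eta_z_fix, theta, s2c, s2z, b0, gtol, max_iter):
    """Posterior modes of all hospitals' intercept pairs, by damped Newton.

    Runs all hospitals simultaneously with vectorised per-stay derivative
    accumulation.  Returns modes, per-hospital joint log-density at the
    mode, and the 2x2 negative Hessians (as cc, zz, cz arrays).
    """
    H = data.n_hosp
    b_c = b0[:, 0].copy()
    b_z = b0[:, 1].copy()

    def joint_parts(bc, bz):
        eta_c = eta_c_fix + bc[data.hidx]
        eta_z = eta_z_fix + bz[data.hidx]
        ll = _stay_loglik(data.y, eta_c, eta_z, theta, data.zero_mask)
        per_h = np.bincount(data.hidx, weights=ll, minlength=H)
        prior = (
            -0.5 * bc**2 / s2c
            - 0.5 * bz**2 / s2z
            - 0.5 * np.log(2 * np.pi * s2c)
            - 0.5 * np.log(2 * np.pi * s2z)
        )
        return per_h + prior

    f = joint_parts(b_c, b_z)
    for _ in range(max_iter):
        eta_c = eta_c_fix + b_c[data.hidx]
        eta_z = eta_z_fix + b_z[data.hidx]
        g_c, g_z, h_cc, h_zz, h_cz = _stay_grad_hess(
            data.y, eta_c, eta_z, theta, data.zero_mask
        )
        G_c = np.bincount(data.hidx, weights=g_c, minlength=H) - b_c / s2c
        G_z = np.bincount(data.hidx, weights=g_z, minlength=H) - b_z / s2z
        H_cc = np.bincount(data.hidx, weights=h_cc, minlength=H) - 1.0 / s2c
        H_zz = np.bincount(data.hidx, weights=h_zz, minlength=H) - 1.0 / s2z
        H_cz = np.bincount(data.hidx, weights=h_cz, minlength=H)
        gnorm = np.sqrt(G_c**2 + G_z**2)
        if (gnorm < gtol).all():
            break
        # Newton step on -H (guard indefiniteness by ridging toward the prior)
        det = H_cc * H_zz - H_cz**2
        bad = (det <= 1e-12) | (H_cc >= 0) | (H_zz >= 0)
        H_cc = np.where(bad, np.minimum(H_cc, -1.0 / s2c), H_cc)
        H_zz = np.where(bad, np.minimum(H_zz, -1.0 / s2z), H_zz)
        H_cz = np.where(bad, 0.0, H_cz)
        det = H_cc * H_zz - H_cz**2
        step_c = -(H_zz * G_c - H_cz * G_z) / det
        step_z = -(H_cc * G_z - H_cz * G_c) / det
        # fall back to prior-preconditioned steepest ascent where the Newton
        # direction is not an ascent direction (or is numerically unusable)
        dd = G_c * step_c + G_z * step_z
        fallback = ~np.isfinite(dd) | (dd <= 0)
        step_c = np.where(fallback, G_c * s2c, step_c)
        step_z = np.where(fallback, G_z * s2z, step_z)
        # cap the step length; far-off warm starts can propose huge jumps
        norm = np.sqrt(step_c**2 + step_z**2)
        scale = np.where(norm > 4.0, 4.0 / norm, 1.0)
        step_c = step_c * scale
        step_z = step_z * scale
        # damped update: halve steps for hospitals whose joint density drops,
        # and freeze hospitals that fail to improve at any damping level
        lam = np.ones(H)
        slack = 1e-10 * (1.0 + np.abs(f))
        for _halve in range(25):
            f_new = joint_parts(b_c + lam * step_c, b_z + lam * step_z)
            worse = f_new < f - slack
            if not worse.any():
                break
            lam[worse] *= 0.5
        else:
            lam[worse] = 0.0
        b_c = b_c + lam * step_c
        b_z = b_z + lam * step_z
        f = joint_parts(b_c, b_z)

    # final curvature at the mode
    eta_c = eta_c_fix + b_c[data.hidx]
    eta_z = eta_z_fix + b_z[data.hidx]
    _, _, h_cc, h_zz, h_cz = _stay_grad_hess(data.y, eta_c, eta_z, theta, data.zero_mask)
    H_cc = np.bincount(data.hidx, weights=h_cc, minlength=H) - 1.0 / s2c
    H_zz = np.bincount(data.hidx, weights=h_zz, minlength=H) - 1.0 / s2z
    H_cz = np.bincount(data.hidx, weights=h_cz, minlength=H)
    modes = np.column_stack([b_c, b_z])
    return modes, joint_parts(b_c, b_z), (H_cc, H_zz, H_cz)


def _marginal_loglik(params, data, control, warm):
    """Marginal log-likelihood of the fixed parameters, intercepts integrated out."""
    pc = data.Xc.shape[1]
    pz = data.Xz.shape[1]
    beta_c = params[:pc]
    beta_z = params[pc : pc + pz]
    theta = np.exp(params[pc + pz])
    s2c = max(np.exp(params[pc + pz + 1]), _SIGMA2_FLOOR)
    s2z = max(np.exp(params[pc + pz + 2]), _SIGMA2_FLOOR)

    eta_c_fix = data.Xc @ beta_c + data.log_dp
    eta_z_fix = data.Xz @ beta_z

    modes, joint_at_mode, (H_cc, H_zz, H_cz) = _inner_modes(
        data, eta_c_fix, eta_z_fix, theta, s2c, s2z,
        warm["modes"], control.inner_gtol, control.inner_max_iter,
    )
    warm["modes"] = modes

    neg_det = H_cc * H_zz - H_cz**2  # det(-H) = det(H) for 2x2
    neg_det = np.maximum(neg_det, 1e-300)

    if control.method == "laplace" or control.agq_nodes <= 1:
        per_h = joint_at_mode + np.log(2 * np.pi) - 0.5 * np.log(neg_det)
        return float(per_h.sum()), modes

    # adaptive Gauss-Hermite on a tensor grid centred at the mode
    k = control.agq_nodes
    nodes, wts = np.polynomial.hermite.hermgauss(k)
    log_w = np.log(wts)
    per_h = np.empty(data.n_hosp)
    # Cholesky of covariance (-H)^{-1} per hospital
    for h in range(data.n_hosp):
        Hm = -np.array([[H_cc[h], H_cz[h]], [H_cz[h], H_zz[h]]])
        C = np.linalg.inv(Hm)
        L = np.linalg.cholesky(C)
        mask_h = data.hidx == h
        y_h = data.y[mask_h]
        zm_h = data.zero_mask[mask_h]
        ec_h = eta_c_fix[mask_h]
        ez_h = eta_z_fix[mask_h]
        vals = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                z = np.array([nodes[i], nodes[j]])
                b = modes[h] + np.sqrt(2.0) * (L @ z)
                ll = _stay_loglik(y_h, ec_h + b[0], ez_h + b[1], theta, zm_h).sum()
                prior = (
                    -0.5 * b[0] ** 2 / s2c
                    - 0.5 * b[1] ** 2 / s2z
                    - 0.5 * np.log(2 * np.pi * s2c)
                    - 0.5 * np.log(2 * np.pi * s2z)
                )
                vals[i, j] = ll + prior + z @ z + log_w[i] + log_w[j]
        per_h[h] = special.logsumexp(vals) + np.log(2.0) + np.log(L[0, 0] * L[1, 1])
    return float(per_h.sum()), modes


def zinb_loglik(
    stays: pd.DataFrame,
    count_terms: list[str],
    zero_terms: list[str],
    beta_count: np.ndarray,
    beta_zero: np.ndarray,
    theta: float,
    sigma2_count: float,
    sigma2_zero: float,
    outcome: str = "dot",
    method: str = "laplace",
    agq_nodes: int = 7,
    round_outcome: bool = True,
) -> float:
    """Marginal log-likelihood at given parameters (intercepts integrated out).

    ``method='laplace'`` uses the bivariate Laplace approximation;
    ``method='agq'`` refines it with an ``agq_nodes``-point adaptive
    Gauss–Hermite tensor grid per hospital.
    """
    control = FitControl(method=method, agq_nodes=agq_nodes, round_outcome=round_outcome)
    data = _ZinbData(stays, count_terms, zero_terms, round_outcome, outcome)
    params = np.concatenate(
        [
            np.asarray(beta_count, dtype=float),
            np.asarray(beta_zero, dtype=float),
            [np.log(theta), np.log(max(sigma2_count, _SIGMA2_FLOOR)),
             np.log(max(sigma2_zero, _SIGMA2_FLOOR))],
        ]
    )
    warm = {"modes": np.zeros((data.n_hosp, 2))}
    ll, _ = _marginal_loglik(params, data, control, warm)
    return ll


def _initial_params(data):
    """Warm start: Poisson GLM for the count part, logistic for the zero part."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            po = sm.GLM(
                data.y, data.Xc, family=sm.families.Poisson(), offset=data.log_dp
            ).fit()
            beta_c = po.params
        except Exception:
            beta_c = np.zeros(data.Xc.shape[1])
            beta_c[0] = np.log(max(data.y.mean(), 0.1)) - data.log_dp.mean()
        try:
            lo = sm.GLM(
                data.zero_mask.astype(float), data.Xz, family=sm.families.Binomial()
            ).fit()
            beta_z = lo.params
        except Exception:
            beta_z = np.zeros(data.Xz.shape[1])
    return np.concatenate([beta_c, beta_z, [np.log(1.0), np.log(0.1), np.log(0.1)]])


def fit_zinb_mixed(
    stays: pd.DataFrame,
    count_terms: list[str],
    zero_terms: list[str],
    outcome: str = "dot",
    control: FitControl | None = None,
) -> ZinbMixedModel:
    """Maximise the marginal likelihood over fixed effects, theta and variances.

    ``zero_terms`` should normally include ``"log_dp"`` so that days
    present enters the zero component as a regular covariate; the count
    component always uses ``log(dp)`` as an offset.

    A variance estimate hitting its lower bound is returned as a valid fit
    with ``sigma2`` reported at (numerically) zero.  Non-convergence of the
    outer optimiser raises with the optimiser's message.
    """
    control = control or FitControl()
    data = _ZinbData(stays, count_terms, zero_terms, control.round_outcome, outcome)
    if data.n_hosp < 2:
        raise ValueError("need stays from at least 2 hospitals")

    x0 = _initial_params(data)
    warm = {"modes": np.zeros((data.n_hosp, 2))}

    def nll(p):
        ll, _ = _marginal_loglik(p, data, control, warm)
        return -ll

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        options={
            "maxiter": control.max_outer_iter,
            "eps": control.fd_eps,
            "ftol": control.outer_ftol,
            "gtol": control.outer_gtol,
        },
    )
    if not res.success and "ROUNDING" not in str(res.message).upper():
        raise RuntimeError(f"marginal-likelihood optimisation failed: {res.message}")

    pc = data.Xc.shape[1]
    pz = data.Xz.shape[1]
    p = res.x
    ll, modes = _marginal_loglik(p, data, control, warm)

    se_c = se_z = None
    if control.compute_se:
        from statsmodels.tools.numdiff import approx_hess2

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Hm = approx_hess2(p, nll)
        try:
            cov = np.linalg.inv(Hm)
            dg = np.diag(cov).copy()
            dg[dg < 0] = np.nan
            se = np.sqrt(dg)
            se_c = se[:pc]
            se_z = se[pc : pc + pz]
        except np.linalg.LinAlgError:
            warnings.warn("information matrix singular; standard errors unavailable")

    blups = pd.DataFrame(
        {
            "hospital_id": data.hospital_ids,
            "b_count": modes[:, 0],
            "b_zero": modes[:, 1],
        }
    )
    return ZinbMixedModel(
        count_terms=list(count_terms),
        zero_terms=list(zero_terms),
        beta_count=p[:pc],
        beta_zero=p[pc : pc + pz],
        theta=float(np.exp(p[pc + pz])),
        sigma2_count=float(max(np.exp(p[pc + pz + 1]), _SIGMA2_FLOOR)),
        sigma2_zero=float(max(np.exp(p[pc + pz + 2]), _SIGMA2_FLOOR)),
        blups=blups,
        loglik=ll,
        converged=bool(res.success),
        outcome=outcome,
        se_count=se_c,
        se_zero=se_z,
        control=control,
        n_stays=data.n,
    )


def reestimate_blups(model: ZinbMixedModel, eval_stays: pd.DataFrame) -> pd.DataFrame:
    """Posterior-mode intercepts for a new period under frozen fixed effects.

    Fixed effects, dispersion and variance components come from the
    baseline fit and are NOT re-optimised; only the hospital intercept
    pairs are re-estimated from the evaluation stays.  Hospitals with no
    evaluation stays are omitted (with a warning).
    """
    data = _ZinbData(
        eval_stays, model.count_terms, model.zero_terms,
        model.control.round_outcome, model.outcome,
    )
    fitted = set(model.blups["hospital_id"])
    new = set(data.hospital_ids) - fitted
    if new:
        warnings.warn(f"hospitals absent from the baseline fit: {sorted(new)}")
    gone = fitted - set(data.hospital_ids)
    if gone:
        warnings.warn(f"hospitals with no evaluation stays omitted: {sorted(gone)}")

    eta_c_fix = data.Xc @ model.beta_count + data.log_dp
    eta_z_fix = data.Xz @ model.beta_zero
    modes, _, _ = _inner_modes(
        data, eta_c_fix, eta_z_fix, model.theta,
        max(model.sigma2_count, _SIGMA2_FLOOR), max(model.sigma2_zero, _SIGMA2_FLOOR),
        np.zeros((data.n_hosp, 2)), model.control.inner_gtol, model.control.inner_max_iter,
    )
    return pd.DataFrame(
        {"hospital_id": data.hospital_ids, "b_count": modes[:, 0], "b_zero": modes[:, 1]}
    )


def _mixture_mean(data, model, b_count, b_zero):
    eta_c = data.Xc @ model.beta_count + data.log_dp + b_count
    eta_z = data.Xz @ model.beta_zero + b_zero
    return (1.0 - expit(eta_z)) * np.exp(eta_c)


def pe_ratios(
    model: ZinbMixedModel, eval_stays: pd.DataFrame, blups: pd.DataFrame
) -> list[FacilityPE]:
    """Facility predicted-to-expected ratios for the evaluation period.

    Per stay, ``predicted`` is the mixture mean ``(1-pi)*mu`` with the
    hospital's BLUPs plugged in, ``expected`` is the same with both
    intercepts at zero (a hypothetical standardised hospital).  Both are
    summed per facility; P:E is their ratio.
    """
    data = _ZinbData(
        eval_stays, model.count_terms, model.zero_terms,
        model.control.round_outcome, model.outcome,
    )
    bmap = blups.set_index("hospital_id")
    missing = set(data.hospital_ids) - set(bmap.index)
    if missing:
        raise ValueError(f"no BLUPs for hospitals: {sorted(missing)}")
    b_c = bmap["b_count"].reindex(data.hospital_ids).to_numpy()[data.hidx]
    b_z = bmap["b_zero"].reindex(data.hospital_ids).to_numpy()[data.hidx]

    pred = _mixture_mean(data, model, b_c, b_z)
    expd = _mixture_mean(data, model, 0.0, 0.0)
    out = []
    for h, hid in enumerate(data.hospital_ids):
        mask = data.hidx == h
        e = float(expd[mask].sum())
        if e <= 0:
            raise ValueError(f"zero expected total for hospital {hid}")
        out.append(FacilityPE(hospital_id=hid, predicted=float(pred[mask].sum()), expected=e))
    return out


def variance_reduction(
    null_model: ZinbMixedModel, adjusted_model: ZinbMixedModel
) -> tuple[float | None, float | None]:
    """Fractional change in random-intercept variances from covariate adjustment.

    Returns ``1 - sigma2_adjusted / sigma2_null`` per component (count,
    zero).  Negative values mean adjustment *increased* the unexplained
    hospital-level variance.  ``None`` where the null variance is zero.
    """
    def red(null_v, adj_v):
        if null_v <= _SIGMA2_FLOOR * 10:
            return None
        return 1.0 - adj_v / null_v

    return (
        red(null_model.sigma2_count, adjusted_model.sigma2_count),
        red(null_model.sigma2_zero, adjusted_model.sigma2_zero),
    )
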