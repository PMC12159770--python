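"""Independent reference implementations used as test oracles.

Everything here is built only from scipy/numpy primitives, deliberately
avoiding the package's own likelihood and correlation code paths.
"""

import numpy as np
from scipy import stats
from scipy.special import expit


def zinb_logpmf_oracle(y, mu, pi, theta):
    """Zero-inflated NB2 mixture log pmf via scipy's nbinom."""
    p = theta / (theta + mu)
    nb = stats.nbinom.logpmf(y, theta, p)
    return np.where(
        y == 0,
        np.log(pi + (1 - pi) * np.exp(nb)),
        np.log1p(-pi) + nb,
    )


def design_oracle(stays, terms):
    cols = [np.ones(len(stays))]
    for t in terms:
        cols.append(np.log(stays["dp"]) if t == "log_dp" else stays[t].to_numpy(float))
    return np.column_stack(cols)


def grid_marginal_oracle(
    stays, count_terms, zero_terms, bc, bz, theta, s2c, s2z, half=6.0, n=201
):
    """Brute-force 2-D trapezoid integration of the per-hospital marginal
    likelihood over the random-intercept pair."""
    y = np.round(stays["dot"].to_numpy(float))
    Xc = design_oracle(stays, count_terms)
    Xz = design_oracle(stays, zero_terms)
    eta_c0 = Xc @ bc + np.log(stays["dp"].to_numpy(float))
    eta_z0 = Xz @ bz
    gc = np.linspace(-half * np.sqrt(s2c), half * np.sqrt(s2c), n)
    gz = np.linspace(-half * np.sqrt(s2z), half * np.sqrt(s2z), n)
    total = 0.0
    for hid, idx in stays.groupby("hospital_id").indices.items():
        mu = np.exp(eta_c0[idx][None, None, :] + gc[:, None, None])
        pi = expit(eta_z0[idx][None, None, :] + gz[None, :, None])
        ll = zinb_logpmf_oracle(y[idx][None, None, :], mu, pi, theta).sum(axis=2)
        prior = (
            stats.norm.logpdf(gc, scale=np.sqrt(s2c))[:, None]
            + stats.norm.logpdf(gz, scale=np.sqrt(s2z))[None, :]
        )
        lg = ll + prior
        m = lg.max()
        total += m + np.log(
            np.trapezoid(np.trapezoid(np.exp(lg - m), gz, axis=1), gc)
        )
    return total


def brute_force_tau_b(x, y):
    """O(n^2) pair-counting Kendall tau-b with tie corrections."""
    n = len(x)
    C = D = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sign(x[i] - x[j])
            b = np.sign(y[i] - y[j])
            if a != 0 and b != 0:
                if a == b:
                    C += 1
                else:
                    D += 1
    n0 = n * (n - 1) // 2

    def tied_pairs(v):
        _, counts = np.unique(v, return_counts=True)
        return int(sum(c * (c - 1) // 2 for c in counts))

    n1, n2 = tied_pairs(x), tied_pairs(y)
    return (C - D) / np.sqrt((n0 - n1) * (n0 - n2))
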