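"""Synthetic multi-hospital cohorts with known ground truth.

Real stay-level antibiotic-use data live in restricted clinical data
warehouses, so every stage of this package is exercised on simulated
cohorts whose generative model matches the assumptions of the
patient-level benchmarking model:

* hospitals carry a pair of random intercepts ``(b_zero, b_count)`` drawn
  from a bivariate normal — one shifts the log-odds that a stay receives
  no antibiotics at all, the other shifts the log of expected use given
  any use;
* each stay carries sparse binary comorbidity/procedure flags, ICU and
  surgical-specialty indicators, demographics, and an integer days-present
  (DP) exposure;
* the outcome is zero-inflated negative binomial:
  with probability ``pi = expit(x'beta_zero + gamma*log(dp) + b_zero)``
  the stay is a structural zero, otherwise
  ``Y ~ NB2(mean = exp(x'beta_count + log(dp) + b_count), dispersion theta)``.

DOT and its spectrum-weighted counterpart DASC are generated as two
independent draws from this family sharing covariates (the DASC draw has
its own hospital intercepts and a larger intercept, reflecting spectrum
weighting).  A ``coupled_agents`` mode instead derives both metrics from
simulated per-agent administration days and the synthetic spectrum table,
exercising the metrics layer end to end.

Case-mix confounding — hospitals differing in *patients* rather than in
prescribing behaviour — is injected by shifting each hospital's flag
prevalences on the logit scale (``casemix_sd``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import SpectrumScoreTable, toy_spectrum_table

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_cohort",
    "split_periods",
    "simulate_unit_months",
    "zinb_zero_probability",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults give a desk-scale but realistic cohort.

    The patient-level design vector is laid out as
    ``[intercept, age_c, sex, icu_stay, surgical_specialty, com_0.., proc_0..]``
    where ``age_c`` is (age - 70)/10.  ``beta_count`` / ``beta_zero`` follow
    that layout; ``None`` selects defaults with a handful of strong flag
    effects and the rest zero.
    """

    n_hospitals: int = 50
    units_per_hospital: int = 6
    mean_stays_per_hospital: float = 300.0
    stays_per_hospital: np.ndarray | None = None  # explicit sizes override the mean
    n_comorbidity_vars: int = 10
    n_procedure_vars: int = 10
    prevalence_floor: float = 0.005
    covariate_prevalences: np.ndarray | None = None
    beta_count: np.ndarray | None = None
    beta_zero: np.ndarray | None = None
    gamma_dp_zero: float = -0.6
    theta: float = 1.5
    sigma_count: float = 0.3
    sigma_zero: float = 0.4
    rho: float = 0.5
    dasc_scale: float = 6.5
    mean_dp: float = 5.2
    months: int = 36
    baseline_months: int = 24
    casemix_sd: float = 0.0
    complexity_tracks_casemix: bool = False
    complexity_casemix_noise_sd: float = 0.0
    planted_hospital: int | None = None
    planted_log_rr: float = 0.0
    coupled_agents: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hospitals < 2:
            raise ValueError("need at least 2 hospitals")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.sigma_count < 0 or self.sigma_zero < 0:
            raise ValueError("random-intercept standard deviations must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")
        if self.covariate_prevalences is not None:
            p = np.asarray(self.covariate_prevalences, dtype=float)
            if len(p) != self.n_flags:
                raise ValueError(
                    f"covariate_prevalences has length {len(p)}, expected {self.n_flags}"
                )
            if (p < self.prevalence_floor).any() or (p >= 1).any():
                raise ValueError(
                    f"prevalences must lie in [{self.prevalence_floor}, 1)"
                )
            self.covariate_prevalences = p
        for name in ("beta_count", "beta_zero"):
            b = getattr(self, name)
            if b is not None:
                b = np.asarray(b, dtype=float)
                if len(b) != self.n_patient_terms:
                    raise ValueError(
                        f"{name} has length {len(b)}, expected {self.n_patient_terms}"
                    )
                setattr(self, name, b)

    @property
    def n_flags(self) -> int:
        return self.n_comorbidity_vars + self.n_procedure_vars

    @property
    def n_patient_terms(self) -> int:
        return 5 + self.n_flags

    @property
    def flag_columns(self) -> list[str]:
        return [f"com_{j}" for j in range(self.n_comorbidity_vars)] + [
            f"proc_{j}" for j in range(self.n_procedure_vars)
        ]

    @property
    def patient_columns(self) -> list[str]:
        """Design columns after the intercept, in layout order."""
        return ["age_c", "sex", "icu_stay", "surgical_specialty"] + self.flag_columns


@dataclass
class SimulatedCohort:
    """Stay table plus the ground truth that produced it."""

    stays: pd.DataFrame
    hospitals: pd.DataFrame
    units: pd.DataFrame
    truth: dict
    agent_days: pd.DataFrame | None = None


def _default_betas(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    bc = np.zeros(cfg.n_patient_terms)
    bz = np.zeros(cfg.n_patient_terms)
    # [intercept, age_c, sex, icu, surgical, flags...]
    bc[:5] = [0.0, 0.10, -0.05, 0.35, 0.15]
    bz[:5] = [0.9, -0.10, 0.05, -0.50, -0.20]
    ncom = cfg.n_comorbidity_vars
    strong_com = min(3, ncom)
    bc[5 : 5 + strong_com] = [0.40, 0.30, 0.30][:strong_com]
    bz[5 : 5 + strong_com] = [-0.60, -0.50, -0.40][:strong_com]
    strong_proc = min(2, cfg.n_procedure_vars)
    bc[5 + ncom : 5 + ncom + strong_proc] = [0.35, 0.25][:strong_proc]
    bz[5 + ncom : 5 + ncom + strong_proc] = [-0.50, -0.40][:strong_proc]
    return bc, bz


def zinb_zero_probability(mu: np.ndarray, pi: np.ndarray, theta: float) -> np.ndarray:
    """P(Y = 0) under the zero-inflated NB2 model: pi + (1-pi)(theta/(theta+mu))^theta."""
    mu = np.asarray(mu, dtype=float)
    return pi + (1.0 - pi) * np.exp(theta * (np.log(theta) - np.log(theta + mu)))


def _draw_intercepts(
    rng: np.random.Generator, n: int, sigma_c: float, sigma_z: float, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    cov = np.array(
        [
            [sigma_c**2, rho * sigma_c * sigma_z],
            [rho * sigma_c * sigma_z, sigma_z**2],
        ]
    )
    draw = rng.multivariate_normal(np.zeros(2), cov, size=n)
    return draw[:, 0], draw[:, 1]


def _sample_zinb(
    rng: np.random.Generator, mu: np.ndarray, pi: np.ndarray, theta: float
) -> np.ndarray:
    n = len(mu)
    structural = rng.random(n) < pi
    # numpy's negative_binomial(n, p) has mean n(1-p)/p; NB2(mu, theta) maps to
    # n = theta, p = theta/(theta+mu)
    y = rng.negative_binomial(theta, theta / (theta + mu), size=n)
    y[structural] = 0
    return y


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full multi-hospital cohort from the configured ZINB model.

    Deterministic for a fixed config (including ``seed``).  Returns the
    stay table, hospital/unit attribute tables and the realised ground
    truth (coefficients and per-hospital intercepts for both outcomes).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    beta_count = cfg.beta_count
    beta_zero = cfg.beta_zero
    if beta_count is None or beta_zero is None:
        bc_d, bz_d = _default_betas(cfg)
        beta_count = bc_d if beta_count is None else beta_count
        beta_zero = bz_d if beta_zero is None else beta_zero

    prev = cfg.covariate_prevalences
    if prev is None:
        # sparse flags: log-uniform prevalence between 1% and 40%
        prev = np.exp(rng.uniform(np.log(0.01), np.log(0.40), size=cfg.n_flags))

    hosp_ids = [f"H{h:03d}" for h in range(cfg.n_hospitals)]

    # hospital attribute table (used by the facility/unit-level model)
    hospitals = pd.DataFrame(
        {
            "hospital_id": hosp_ids,
            "complexity_level": rng.choice(
                ["1a", "1b", "1c", "2", "3"], size=cfg.n_hospitals, p=[0.33, 0.24, 0.21, 0.10, 0.12]
            ),
            "icu_complexity": rng.choice(
                ["5", "4", "3", "2", "1"], size=cfg.n_hospitals, p=[0.45, 0.19, 0.23, 0.03, 0.10]
            ),
            "surgical_complexity": rng.choice(
                ["4", "3", "2", "1", "0.5", "0"],
                size=cfg.n_hospitals,
                p=[0.59, 0.23, 0.085, 0.026, 0.026, 0.043],
            ),
            "trainees_quintile": rng.integers(1, 6, size=cfg.n_hospitals),
        }
    )

    unit_rows = []
    for h in hosp_ids:
        for u in range(cfg.units_per_hospital):
            unit_rows.append(
                {
                    "hospital_id": h,
                    "unit_id": f"{h}-U{u}",
                    "icu_floor": int(u == 0),
                    "surgical_floor": int(u in (1, 2) and cfg.units_per_hospital >= 3),
                }
            )
    units = pd.DataFrame(unit_rows)

    b_count_dot, b_zero_dot = _draw_intercepts(
        rng, cfg.n_hospitals, cfg.sigma_count, cfg.sigma_zero, cfg.rho
    )
    b_count_dasc, b_zero_dasc = _draw_intercepts(
        rng, cfg.n_hospitals, cfg.sigma_count, cfg.sigma_zero, cfg.rho
    )
    if cfg.planted_hospital is not None:
        # the planted hospital's intercepts are set exactly: count-component
        # log rate ratio as configured, no excess zero inflation
        b_count_dot[cfg.planted_hospital] = cfg.planted_log_rr
        b_count_dasc[cfg.planted_hospital] = cfg.planted_log_rr
        b_zero_dot[cfg.planted_hospital] = 0.0
        b_zero_dasc[cfg.planted_hospital] = 0.0

    casemix_shift = (
        rng.normal(0.0, cfg.casemix_sd, size=cfg.n_hospitals)
        if cfg.casemix_sd > 0
        else np.zeros(cfg.n_hospitals)
    )
    if cfg.complexity_tracks_casemix and cfg.casemix_sd > 0:
        # facility complexity ordered by the hospital's case-mix severity, so
        # it predicts crude use but carries no information beyond the flags;
        # optional noise makes the designation an imperfect proxy (real
        # complexity levels track patient mix only loosely)
        proxy = casemix_shift
        if cfg.complexity_casemix_noise_sd > 0:
            proxy = proxy + rng.normal(
                0.0, cfg.complexity_casemix_noise_sd, size=cfg.n_hospitals
            )
        rank = np.argsort(np.argsort(proxy))
        bins = (rank * 5) // cfg.n_hospitals
        hospitals["complexity_level"] = np.array(["3", "2", "1c", "1b", "1a"])[bins]

    if cfg.stays_per_hospital is not None:
        n_stays = np.asarray(cfg.stays_per_hospital, dtype=int)
        if len(n_stays) != cfg.n_hospitals:
            raise ValueError("stays_per_hospital must have one entry per hospital")
    else:
        n_stays = rng.poisson(cfg.mean_stays_per_hospital, size=cfg.n_hospitals)
    n_stays = np.maximum(n_stays, 2)
    total = int(n_stays.sum())

    hidx = np.repeat(np.arange(cfg.n_hospitals), n_stays)
    stay_unit = np.empty(total, dtype=object)
    pos = 0
    for h, n_h in zip(range(cfg.n_hospitals), n_stays):
        u = rng.integers(0, cfg.units_per_hospital, size=n_h)
        stay_unit[pos : pos + n_h] = [f"{hosp_ids[h]}-U{ui}" for ui in u]
        pos += n_h

    unit_icu = units.set_index("unit_id")["icu_floor"]
    unit_surg = units.set_index("unit_id")["surgical_floor"]

    month = rng.integers(1, cfg.months + 1, size=total)
    age = np.clip(rng.normal(70, 10, size=total), 20, 100)
    sex = (rng.random(total) < 0.07).astype(int)  # mostly-male veteran-like mix
    dp = 1 + rng.poisson(cfg.mean_dp - 1.0, size=total)

    # flags: hospital-level logit shift creates case-mix confounding
    logit_prev = np.log(prev / (1 - prev))
    p_stay = 1.0 / (1.0 + np.exp(-(logit_prev[None, :] + casemix_shift[hidx, None])))
    flags = (rng.random((total, cfg.n_flags)) < p_stay).astype(int)

    icu_stay = np.array([unit_icu[u] for u in stay_unit], dtype=int)
    surgical = np.array([unit_surg[u] for u in stay_unit], dtype=int)

    X = np.column_stack(
        [
            np.ones(total),
            (age - 70.0) / 10.0,
            sex,
            icu_stay,
            surgical,
            flags,
        ]
    )

    def draw_outcome(bc, bz, b_c_h, b_z_h, intercept_shift):
        eta_c = X @ bc + intercept_shift + np.log(dp) + b_c_h[hidx]
        eta_z = X @ bz + cfg.gamma_dp_zero * np.log(dp) + b_z_h[hidx]
        mu = np.exp(eta_c)
        pi = 1.0 / (1.0 + np.exp(-eta_z))
        return _sample_zinb(rng, mu, pi, cfg.theta)

    dot = draw_outcome(beta_count, beta_zero, b_count_dot, b_zero_dot, 0.0)

    stays = pd.DataFrame(
        {
            "stay_id": [f"S{i:07d}" for i in range(total)],
            "hospital_id": [hosp_ids[h] for h in hidx],
            "unit_id": stay_unit,
            "month": month,
            "period": np.where(month <= cfg.baseline_months, "baseline", "evaluation"),
            "age": age,
            "age_c": (age - 70.0) / 10.0,
            "sex": sex,
            "icu_stay": icu_stay,
            "surgical_specialty": surgical,
            "dp": dp,
            "dot": dot,
        }
    )
    for j, col in enumerate(cfg.flag_columns):
        stays[col] = flags[:, j]

    agent_days = None
    if cfg.coupled_agents:
        # the realised agent-day allocation is authoritative: DOT is recomputed
        # from it (a draw exceeding the stay's agent-day capacity is capped)
        agent_days, dot_real, dasc = _agents_from_dot(rng, stays, toy_spectrum_table())
        stays["dot"] = dot_real
        stays["dasc"] = dasc
    else:
        stays["dasc"] = draw_outcome(
            beta_count, beta_zero, b_count_dasc, b_zero_dasc, np.log(cfg.dasc_scale)
        )

    truth = {
        "config": replace(cfg, beta_count=beta_count, beta_zero=beta_zero,
                          covariate_prevalences=prev),
        "beta_count": beta_count,
        "beta_zero": beta_zero,
        "prevalences": prev,
        "b_count_dot": b_count_dot,
        "b_zero_dot": b_zero_dot,
        "b_count_dasc": b_count_dasc,
        "b_zero_dasc": b_zero_dasc,
        "casemix_shift": casemix_shift,
        "hospital_ids": hosp_ids,
    }
    return SimulatedCohort(stays=stays, hospitals=hospitals, units=units,
                           truth=truth, agent_days=agent_days)


def _agents_from_dot(
    rng: np.random.Generator, stays: pd.DataFrame, scores: SpectrumScoreTable
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Distribute each stay's DOT over concrete agents; DASC follows from scores.

    Each agent contributes at most ``dp`` days (one administration-day count
    per agent), so a DOT draw above ``n_agents * dp`` is capped at capacity.
    """
    agents = scores.agents()
    score_vec = np.array([scores[a] for a in agents])
    rows = []
    dot_real = np.zeros(len(stays), dtype=int)
    dasc = np.zeros(len(stays))
    for i, (sid, dot_i, dp_i) in enumerate(
        zip(stays["stay_id"], stays["dot"], stays["dp"])
    ):
        remaining = min(int(dot_i), len(agents) * int(dp_i))
        if remaining == 0:
            continue
        order = rng.permutation(len(agents))
        total_sc = 0.0
        total_days = 0
        for k, ai in enumerate(order):
            if remaining == 0:
                break
            # remaining capacity of the agents not yet visited
            tail_cap = (len(order) - k - 1) * int(dp_i)
            lo = max(0, remaining - tail_cap)
            hi = int(min(remaining, dp_i))
            d = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            if d == 0:
                continue
            rows.append({"stay_id": sid, "agent_id": agents[ai], "n_days": d})
            total_sc += d * score_vec[ai]
            total_days += d
            remaining -= d
        dot_real[i] = total_days
        dasc[i] = total_sc
    frame = pd.DataFrame(rows, columns=["stay_id", "agent_id", "n_days"])
    return frame, dot_real, dasc


def split_periods(
    cohort: SimulatedCohort, fraction: float, seed: int = 0
) -> tuple[SimulatedCohort, SimulatedCohort]:
    """Randomly partition stays into baseline/evaluation sets per hospital.

    The split is stay-level disjoint; both halves keep every hospital and
    share the cohort's true intercepts (the hospitals do not change, only
    which stays are observed in each period).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    base_mask = np.zeros(len(cohort.stays), dtype=bool)
    for _, idx in cohort.stays.groupby("hospital_id").indices.items():
        n_h = len(idx)
        n_base = int(round(fraction * n_h))
        if n_base == 0 or n_base == n_h:
            raise ValueError(
                "a hospital would lose all stays in one period; "
                "use a less extreme fraction or more stays"
            )
        chosen = rng.choice(idx, size=n_base, replace=False)
        base_mask[chosen] = True

    def subset(mask, label):
        df = cohort.stays.loc[mask].copy()
        df["period"] = label
        return SimulatedCohort(
            stays=df.reset_index(drop=True),
            hospitals=cohort.hospitals,
            units=cohort.units,
            truth=cohort.truth,
            agent_days=cohort.agent_days,
        )

    return subset(base_mask, "baseline"), subset(~base_mask, "evaluation")


def simulate_unit_months(
    n_records: int,
    beta: np.ndarray,
    theta: float,
    seed: int = 0,
    mean_dp: float = 400.0,
) -> pd.DataFrame:
    """Directly simulate unit-month NB2 aggregates for the facility-level model.

    The design is ``[intercept, icu_floor, surgical_floor, x_cont]`` with
    ``x_cont ~ N(0,1)``; the outcome is NB2 with mean
    ``exp(X beta + log dp)``.  Used for parameter-recovery checks of the
    aggregate-level model without going through a patient cohort.
    """
    beta = np.asarray(beta, dtype=float)
    if len(beta) != 4:
        raise ValueError("beta must have length 4: intercept, icu, surgical, x_cont")
    rng = np.random.default_rng(seed)
    icu = (rng.random(n_records) < 0.2).astype(int)
    surg = (rng.random(n_records) < 0.3).astype(int)
    x = rng.normal(size=n_records)
    dp = np.maximum(rng.poisson(mean_dp, size=n_records), 30)
    X = np.column_stack([np.ones(n_records), icu, surg, x])
    mu = np.exp(X @ beta + np.log(dp))
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame(
        {
            "hospital_id": [f"H{i % 50:03d}" for i in range(n_records)],
            "unit_id": [f"U{i:05d}" for i in range(n_records)],
            "month": (np.arange(n_records) % 24) + 1,
            "dp": dp,
            "dot": y,
            "dasc": y,
            "icu_floor": icu,
            "surgical_floor": surg,
            "x_cont": x,
        }
    )
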