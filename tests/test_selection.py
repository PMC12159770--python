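"""Prescreen, penalised ZINB selection, consensus, and backward AIC."""

import numpy as np
import pandas as pd
import pytest

from abxbench import (
    SimulationConfig,
    backward_aic,
    consensus_select,
    lasso_select_zinb,
    prescreen_candidates,
    prescreen_union,
    simulate_cohort,
)
from abxbench.selection import (
    ConsensusSelection,
    _partition_by_hospital,
    penalized_zinb_supports,
)


def planted_config(**over):
    """4 comorbidity + 4 procedure flags; only com_0, com_1, proc_0 carry effects."""
    n_flags = 8
    bc = np.zeros(5 + n_flags)
    bc[:5] = [0.0, 0.1, -0.05, 0.35, 0.15]
    bz = np.zeros(5 + n_flags)
    bz[:5] = [0.9, -0.1, 0.05, -0.5, -0.2]
    # count effects on com_0, com_1, proc_0 (flag order: com_0..com_3, proc_0..proc_3)
    bc[5], bc[6], bc[9] = 0.5, 0.45, 0.4
    bz[5], bz[6], bz[9] = -1.0, -0.9, -0.8
    base = dict(
        n_hospitals=10, mean_stays_per_hospital=250,
        n_comorbidity_vars=4, n_procedure_vars=4,
        covariate_prevalences=np.full(n_flags, 0.3),
        beta_count=bc, beta_zero=bz, rho=0.0,
        sigma_count=0.15, sigma_zero=0.15, seed=31,
    )
    base.update(over)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def planted_cohort():
    return simulate_cohort(planted_config())


SIGNAL = {"com_0", "com_1", "proc_0"}
NOISE = {"com_2", "com_3", "proc_1", "proc_2", "proc_3"}


# ---------------------------------------------------------------------------
# prescreen
# ---------------------------------------------------------------------------


class TestPrescreen:
    def test_rare_flag_fails_prevalence_floor(self, planted_cohort):
        stays = planted_cohort.stays.copy()
        stays["com_rare"] = 0
        stays.loc[stays.index[:2], "com_rare"] = 1
        res = {r.variable_id: r for r in prescreen_candidates(stays, ["com_rare"])}
        assert res["com_rare"].prevalence < 0.005
        assert not res["com_rare"].passed

    def test_strong_driver_passes(self, planted_cohort):
        res = {r.variable_id: r for r in
               prescreen_candidates(planted_cohort.stays, ["com_0"])}
        assert res["com_0"].passed
        assert res["com_0"].screen_p_value < 1e-4

    def test_constant_flag_fails_without_raising(self, planted_cohort):
        stays = planted_cohort.stays.copy()
        stays["always"] = 1
        stays["never"] = 0
        res = {r.variable_id: r for r in
               prescreen_candidates(stays, ["always", "never"])}
        for v in ("always", "never"):
            assert not res[v].passed
            assert np.isnan(res[v].screen_p_value)

    def test_null_flags_pass_at_roughly_alpha_rate(self, rng):
        """Independent coin-flip flags against independent outcomes."""
        n = 2000
        stays = pd.DataFrame({"dp": rng.integers(2, 12, size=n),
                              "dot": rng.poisson(4.0, size=n)})
        flags = [f"f{i}" for i in range(40)]
        for f in flags:
            stays[f] = rng.integers(0, 2, size=n)
        res = prescreen_candidates(stays, flags, alpha=0.05)
        rate = np.mean([r.passed for r in res])
        assert rate < 0.2  # 40 Bernoulli(0.05) trials: P(rate >= 0.2) ~ 1e-3

    def test_permissive_thresholds_pass_everything_nonconstant(self, planted_cohort):
        flags = [c for c in planted_cohort.stays.columns
                 if c.startswith(("com_", "proc_"))]
        res = prescreen_candidates(planted_cohort.stays, flags, floor=0.0, alpha=1.01)
        assert all(r.passed for r in res)

    def test_union_includes_either_outcome(self, rng):
        """A flag driving only DASC still enters the common candidate list."""
        n = 3000
        stays = pd.DataFrame({"dp": rng.integers(2, 12, size=n)})
        stays["only_dasc"] = rng.integers(0, 2, size=n)
        stays["dot"] = rng.poisson(3.0, size=n)
        stays["dasc"] = stays["dot"] * (2.0 + 6.0 * stays["only_dasc"])
        got = prescreen_union(stays, ["only_dasc"])
        assert got == ["only_dasc"]
        # and not via the DOT screen alone
        res = prescreen_candidates(stays, ["only_dasc"], outcome="dot")
        assert not res[0].passed


# ---------------------------------------------------------------------------
# penalised ZINB selection
# ---------------------------------------------------------------------------


class TestLasso:
    def test_recovers_planted_count_signals(self, planted_cohort):
        sel = lasso_select_zinb(planted_cohort.stays, "count")
        assert SIGNAL <= sel
        assert len(sel & NOISE) <= 1

    def test_recovers_planted_zero_signals(self, planted_cohort):
        sel = lasso_select_zinb(planted_cohort.stays, "zero")
        assert SIGNAL <= sel
        assert len(sel & NOISE) <= 1

    def test_invalid_component_rejected(self, planted_cohort):
        with pytest.raises(ValueError, match="component"):
            lasso_select_zinb(planted_cohort.stays, "mixture")

    def test_degenerate_outcome_rejected(self, planted_cohort):
        allpos = planted_cohort.stays.copy()
        allpos["dot"] = allpos["dot"] + 1
        with pytest.raises(ValueError, match="zero and positive"):
            penalized_zinb_supports(allpos, ["com_0"])


# ---------------------------------------------------------------------------
# partition + consensus
# ---------------------------------------------------------------------------


class TestPartition:
    def test_disjoint_cover_stratified(self, planted_cohort):
        stays = planted_cohort.stays.reset_index(drop=True)
        parts = _partition_by_hospital(stays, 5, seed=3)
        flat = np.concatenate(parts)
        assert len(flat) == len(stays)
        assert len(np.unique(flat)) == len(stays)
        hosp = set(stays["hospital_id"])
        for rows in parts:
            assert set(stays.iloc[rows]["hospital_id"]) == hosp

    def test_deterministic_in_seed(self, planted_cohort):
        stays = planted_cohort.stays.reset_index(drop=True)
        a = _partition_by_hospital(stays, 4, seed=9)
        b = _partition_by_hospital(stays, 4, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestConsensus:
    def test_k1_equals_full_data_selection(self, planted_cohort):
        cs = consensus_select(planted_cohort.stays, K=1, seed=0)
        sup_c, sup_z = penalized_zinb_supports(
            planted_cohort.stays,
            [c for c in planted_cohort.stays.columns if c.startswith(("com_", "proc_"))],
        )
        assert cs.consensus_count == sup_c
        assert cs.consensus_zero == sup_z

    def test_strict_intersection(self):
        per = [{"a", "b"}] * 9 + [{"b"}]
        cs = ConsensusSelection(per_subset_count=per, per_subset_zero=[{"a"}] * 10)
        assert cs.consensus_count == {"b"}
        assert cs.consensus_zero == {"a"}

    def test_empty_consensus_warns(self):
        with pytest.warns(UserWarning, match="empty consensus"):
            ConsensusSelection(
                per_subset_count=[{"a"}, {"b"}], per_subset_zero=[{"c"}, {"c"}]
            )

    def test_oversized_k_rejected(self, planted_cohort):
        few = planted_cohort.stays.head(5)
        with pytest.raises(ValueError, match="empty"):
            consensus_select(few, K=50, seed=0)


# ---------------------------------------------------------------------------
# backward AIC
# ---------------------------------------------------------------------------


class TestBackwardAic:
    @staticmethod
    def synthetic_aic(terms):
        """2 per term, minus a large reward for each signal term present."""
        signal = {"s1", "s2"}
        return 2.0 * len(terms) - 10.0 * len(signal & set(terms))

    def test_drops_noise_keeps_signal(self):
        kept, trace = backward_aic(
            self.synthetic_aic, fixed_in=["base"],
            candidates=["s1", "n1", "s2", "n2", "n3"],
        )
        assert set(kept) == {"s1", "s2"}
        assert {t for t, _ in trace} == {"n1", "n2", "n3"}
        aics = [a for _, a in trace]
        assert aics == sorted(aics, reverse=True)  # monotone improvement

    def test_fixed_terms_never_dropped(self):
        seen = []

        def f(terms):
            seen.append(list(terms))
            return self.synthetic_aic(terms)

        kept, _ = backward_aic(f, fixed_in=["s1"], candidates=["n1"])
        assert kept == []
        assert all("s1" in t for t in seen)

    def test_empty_candidates(self):
        kept, trace = backward_aic(self.synthetic_aic, ["base"], [])
        assert kept == [] and trace == []

    def test_failing_removal_keeps_term(self):
        def f(terms):
            if "fragile" not in terms:
                raise RuntimeError("singular")
            return 2.0 * len(terms)

        with pytest.warns(UserWarning, match="keeping it"):
            kept, _ = backward_aic(f, [], ["fragile", "n1"])
        assert kept == ["fragile"]
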