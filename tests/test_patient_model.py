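"""Mixed ZINB model: marginal likelihood, BLUPs, P:E ratios, variance reduction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logsumexp

from abxbench import (
    FitControl,
    SimulationConfig,
    ZinbMixedModel,
    fit_zinb_mixed,
    pe_ratios,
    reestimate_blups,
    simulate_cohort,
    split_periods,
    variance_reduction,
    zinb_loglik,
)


from oracles import design_oracle, grid_marginal_oracle, zinb_logpmf_oracle


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_cohort():
    cfg = SimulationConfig(
        n_hospitals=6, mean_stays_per_hospital=30, rho=0.0,
        sigma_count=0.4, sigma_zero=0.4, n_comorbidity_vars=2,
        n_procedure_vars=1, seed=21,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="module")
def fit_cohort():
    cfg = SimulationConfig(
        n_hospitals=15, mean_stays_per_hospital=200, rho=0.0,
        sigma_count=0.35, sigma_zero=0.35, n_comorbidity_vars=2,
        n_procedure_vars=1, seed=22,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="module")
def fitted(fit_cohort):
    terms = ["age_c", "icu_stay", "com_0"]
    return fit_zinb_mixed(
        fit_cohort.stays, terms, terms + ["log_dp"],
        control=FitControl(compute_se=False),
    )


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------


class TestMarginalLoglik:
    TERMS_C = ["age_c", "icu_stay"]
    TERMS_Z = ["age_c", "icu_stay", "log_dp"]
    BC = np.array([0.1, 0.1, 0.3])
    BZ = np.array([0.5, -0.1, -0.4, -0.3])

    def test_laplace_matches_grid_oracle(self, tiny_cohort):
        stays = tiny_cohort.stays
        args = (self.BC, self.BZ, 1.8, 0.15, 0.2)
        ours = zinb_loglik(stays, self.TERMS_C, self.TERMS_Z, *args)
        oracle = grid_marginal_oracle(stays, self.TERMS_C, self.TERMS_Z, *args)
        assert ours == pytest.approx(oracle, rel=1e-3)

    def test_agq_refines_toward_grid_oracle(self, tiny_cohort):
        stays = tiny_cohort.stays
        args = (self.BC, self.BZ, 1.8, 0.15, 0.2)
        agq = zinb_loglik(stays, self.TERMS_C, self.TERMS_Z, *args, method="agq",
                          agq_nodes=9)
        oracle = grid_marginal_oracle(stays, self.TERMS_C, self.TERMS_Z, *args)
        assert agq == pytest.approx(oracle, rel=1e-5)

    def test_vanishing_variance_reduces_to_fixed_effect_loglik(self, tiny_cohort):
        stays = tiny_cohort.stays
        ours = zinb_loglik(
            stays, self.TERMS_C, self.TERMS_Z, self.BC, self.BZ, 1.8, 1e-12, 1e-12
        )
        # independent fixed-effect-only computation (intercepts pinned at 0)
        y = np.round(stays["dot"].to_numpy(float))
        mu = np.exp(
            design_oracle(stays, self.TERMS_C) @ self.BC + np.log(stays["dp"])
        )
        pi = expit(design_oracle(stays, self.TERMS_Z) @ self.BZ)
        direct = zinb_logpmf_oracle(y, mu, pi, 1.8).sum()
        assert ours == pytest.approx(direct, rel=1e-6)

    def test_pi_zero_reduces_to_nb_loglik_on_positive_data(self, rng):
        # all-positive outcomes with the zero gate slammed shut
        n = 200
        dp = rng.integers(2, 15, size=n)
        y = rng.poisson(0.8 * dp) + 1
        stays = pd.DataFrame(
            {"hospital_id": np.repeat(["a", "b"], n // 2), "dp": dp, "dot": y}
        )
        with pytest.warns(UserWarning, match="no zeros"):
            ours = zinb_loglik(
                stays, [], [], np.array([-0.2]), np.array([-40.0]),
                2.5, 1e-12, 1e-12,
            )
        direct = stats.nbinom.logpmf(y, 2.5, 2.5 / (2.5 + np.exp(-0.2) * dp)).sum()
        assert ours == pytest.approx(direct, rel=1e-6)

    def test_invariant_under_row_permutation(self, tiny_cohort, rng):
        stays = tiny_cohort.stays
        perm = stays.sample(frac=1.0, random_state=7)
        a = zinb_loglik(stays, self.TERMS_C, self.TERMS_Z, self.BC, self.BZ, 1.8, 0.2, 0.2)
        b = zinb_loglik(perm, self.TERMS_C, self.TERMS_Z, self.BC, self.BZ, 1.8, 0.2, 0.2)
        assert a == pytest.approx(b, rel=1e-9)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_parameters_in_plausible_range(self, fitted, fit_cohort):
        truth = fit_cohort.truth
        assert fitted.converged
        # intercept and icu effect within loose single-seed bands
        assert fitted.beta_count[0] == pytest.approx(truth["beta_count"][0], abs=0.25)
        assert fitted.beta_count[2] == pytest.approx(truth["beta_count"][3], abs=0.25)
        assert 0.5 < fitted.theta < 5.0
        assert 0.01 < fitted.sigma2_count < 1.0

    def test_fitted_loglik_beats_perturbed_parameters(self, fitted, fit_cohort):
        stays = fit_cohort.stays
        at_hat = zinb_loglik(
            stays, fitted.count_terms, fitted.zero_terms,
            fitted.beta_count, fitted.beta_zero, fitted.theta,
            fitted.sigma2_count, fitted.sigma2_zero,
        )
        assert at_hat == pytest.approx(fitted.loglik, rel=1e-6)
        for shift in (0.15, -0.15):
            worse = zinb_loglik(
                stays, fitted.count_terms, fitted.zero_terms,
                fitted.beta_count + shift, fitted.beta_zero, fitted.theta,
                fitted.sigma2_count, fitted.sigma2_zero,
            )
            assert worse < at_hat

    def test_single_hospital_rejected(self, fit_cohort):
        one = fit_cohort.stays[
            fit_cohort.stays["hospital_id"] == fit_cohort.stays["hospital_id"].iloc[0]
        ]
        with pytest.raises(ValueError, match="2 hospitals"):
            fit_zinb_mixed(one, [], ["log_dp"])

    def test_ci_requires_computed_se(self, fitted):
        with pytest.raises(ValueError, match="standard errors"):
            fitted.ci_count()

    def test_json_round_trip(self, fitted, fit_cohort):
        m2 = ZinbMixedModel.from_json(fitted.to_json())
        np.testing.assert_allclose(fitted.beta_count, m2.beta_count)
        np.testing.assert_allclose(fitted.beta_zero, m2.beta_zero)
        assert m2.theta == fitted.theta
        pd.testing.assert_frame_equal(
            fitted.blups.reset_index(drop=True), m2.blups.reset_index(drop=True)
        )
        # round-tripped model scores identically
        ev = fit_cohort.stays.head(200)
        p1 = pe_ratios(fitted, ev, fitted.blups)
        p2 = pe_ratios(m2, ev, m2.blups)
        for a, b in zip(p1, p2):
            assert a.pe_ratio == pytest.approx(b.pe_ratio, rel=1e-12)


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------


class TestBlups:
    def test_blups_track_true_intercepts(self, fitted, fit_cohort):
        truth = pd.Series(
            fit_cohort.truth["b_count_dot"], index=fit_cohort.truth["hospital_ids"]
        )
        b = fitted.blups.set_index("hospital_id")["b_count"]
        r = np.corrcoef(b, truth.loc[b.index])[0, 1]
        assert r > 0.7

    def test_blups_shrink_toward_zero(self, fitted, fit_cohort):
        """BLUP magnitudes are smaller on average than raw log rate offsets."""
        stays = fit_cohort.stays
        rates = stays.groupby("hospital_id").apply(
            lambda d: d["dot"].sum() / d["dp"].sum(), include_groups=False
        )
        raw_offset = np.log(rates) - np.log(stays["dot"].sum() / stays["dp"].sum())
        b = fitted.blups.set_index("hospital_id")["b_count"].loc[raw_offset.index]
        assert np.abs(b).mean() < np.abs(raw_offset).mean()

    def test_small_sample_shrinks_more(self, fitted, fit_cohort):
        """Re-estimating from a thin slice of data pulls BLUPs toward zero."""
        stays = fit_cohort.stays
        thin = stays.groupby("hospital_id", group_keys=False).head(5)
        bl_thin = reestimate_blups(fitted, thin).set_index("hospital_id")
        bl_full = reestimate_blups(fitted, stays).set_index("hospital_id")
        assert (
            np.abs(bl_thin["b_count"]).mean() < np.abs(bl_full["b_count"]).mean()
        )

    def test_missing_hospital_warns(self, fitted, fit_cohort):
        stays = fit_cohort.stays
        keep = stays["hospital_id"] != stays["hospital_id"].iloc[0]
        with pytest.warns(UserWarning, match="no evaluation stays"):
            bl = reestimate_blups(fitted, stays[keep])
        assert len(bl) == stays["hospital_id"].nunique() - 1

    def test_blups_are_posterior_modes(self, fitted, fit_cohort):
        """Nudging any hospital's intercept off the BLUP lowers its joint density."""
        stays = fit_cohort.stays
        bl = reestimate_blups(fitted, stays)

        def joint(hid, bc, bz):
            d = stays[stays["hospital_id"] == hid]
            y = np.round(d["dot"].to_numpy(float))
            mu = np.exp(
                design_oracle(d, fitted.count_terms) @ fitted.beta_count
                + np.log(d["dp"]) + bc
            )
            pi = expit(design_oracle(d, fitted.zero_terms) @ fitted.beta_zero + bz)
            return (
                zinb_logpmf_oracle(y, mu, pi, fitted.theta).sum()
                + stats.norm.logpdf(bc, scale=np.sqrt(fitted.sigma2_count))
                + stats.norm.logpdf(bz, scale=np.sqrt(fitted.sigma2_zero))
            )

        row = bl.iloc[0]
        at_mode = joint(row["hospital_id"], row["b_count"], row["b_zero"])
        for dc, dz in [(0.05, 0), (-0.05, 0), (0, 0.05), (0, -0.05)]:
            assert joint(row["hospital_id"], row["b_count"] + dc, row["b_zero"] + dz) < at_mode


# ---------------------------------------------------------------------------
# P:E ratios and variance reduction
# ---------------------------------------------------------------------------


class TestPERatios:
    def test_zero_blups_give_unit_ratio(self, fitted, fit_cohort):
        bl = fitted.blups.copy()
        bl["b_count"] = 0.0
        bl["b_zero"] = 0.0
        for fp in pe_ratios(fitted, fit_cohort.stays, bl):
            assert fp.pe_ratio == pytest.approx(1.0, rel=1e-12)

    def test_count_blup_scales_ratio_exponentially(self, fitted, fit_cohort):
        """With the zero-component intercept fixed, shifting b_count by d
        multiplies P:E by exp(d)."""
        bl = fitted.blups.copy()
        bl["b_zero"] = 0.0
        base = {f.hospital_id: f.pe_ratio for f in pe_ratios(fitted, fit_cohort.stays, bl)}
        bl2 = bl.copy()
        bl2["b_count"] = bl2["b_count"] + 0.3
        for fp in pe_ratios(fitted, fit_cohort.stays, bl2):
            assert fp.pe_ratio == pytest.approx(
                base[fp.hospital_id] * np.exp(0.3), rel=1e-10
            )

    def test_higher_zero_blup_lowers_ratio(self, fitted, fit_cohort):
        bl = fitted.blups.copy()
        bl["b_count"] = 0.0
        bl["b_zero"] = 0.0
        bl2 = bl.copy()
        bl2["b_zero"] = 1.0  # more structural zeros -> less predicted use
        lo = pe_ratios(fitted, fit_cohort.stays, bl2)
        for fp in lo:
            assert fp.pe_ratio < 1.0

    def test_missing_blup_raises(self, fitted, fit_cohort):
        bl = fitted.blups.iloc[1:]
        with pytest.raises(ValueError, match="no BLUPs"):
            pe_ratios(fitted, fit_cohort.stays, bl)


class TestVarianceReduction:
    def _model(self, s2c, s2z):
        return ZinbMixedModel(
            count_terms=[], zero_terms=[], beta_count=np.zeros(1),
            beta_zero=np.zeros(1), theta=1.0, sigma2_count=s2c, sigma2_zero=s2z,
            blups=pd.DataFrame({"hospital_id": [], "b_count": [], "b_zero": []}),
            loglik=0.0, converged=True,
        )

    def test_identical_models_give_zero_reduction(self):
        m = self._model(0.3, 0.2)
        assert variance_reduction(m, m) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_halved_variance_gives_half(self):
        rc, rz = variance_reduction(self._model(0.4, 0.2), self._model(0.2, 0.3))
        assert rc == pytest.approx(0.5)
        assert rz == pytest.approx(-0.5)  # zero-component variance grew

    def test_floor_null_variance_returns_none(self):
        rc, rz = variance_reduction(self._model(1e-9, 0.2), self._model(0.1, 0.1))
        assert rc is None
        assert rz == pytest.approx(0.5)
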