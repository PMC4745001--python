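"""Trial simulation: engines, operating characteristics, error-rate control."""

import numpy as np
import pytest

from flexselect import (
    EffectVector,
    NuisanceParams,
    SimulationConfig,
    TrialDesign,
    critical_value,
    fixture_table1,
    operating_characteristics,
    run_trial,
    simulate_interim,
    variant_moments,
)
from flexselect.simulator import TABLE1_MEANS
from conftest import nuis


def _cfg(design, rho, effects, rule, seed, **kw):
    kw.setdefault("c_variant", "tilde")
    kw.setdefault("n_reps", 100_000)
    return SimulationConfig(
        design=design,
        nuisance=nuis(rho),
        effects=effects,
        selection_rule=rule,
        seed=seed,
        **kw,
    )


class TestSimulateInterim:
    def test_perfect_correlation_locks_centred_pairs(self, base_design):
        rng = np.random.default_rng(0)
        nu = NuisanceParams(1.0, 1.0, 0.999999999)
        interim = simulate_interim(base_design, nu, EffectVector.null(3), rng)
        n1 = base_design.n1
        w1 = interim.w[:, :n1]
        resid = (w1 - w1.mean(axis=1, keepdims=True)) - (
            interim.y - interim.y.mean(axis=1, keepdims=True)
        )
        assert np.max(np.abs(resid)) < 1e-3

    def test_pair_correlation_near_truth(self, base_design):
        rng = np.random.default_rng(1)
        nu = NuisanceParams(1.0, 1.0, 0.8)
        cors = []
        for _ in range(300):
            interim = simulate_interim(base_design, nu, EffectVector.null(3), rng)
            cors.append(np.corrcoef(interim.w[1, : base_design.n1], interim.y[1])[0, 1])
        assert np.mean(cors) == pytest.approx(0.8, abs=0.02)

    def test_deterministic_given_seed(self, base_design):
        a = simulate_interim(base_design, nuis(0.5), EffectVector.null(3), np.random.default_rng(42))
        b = simulate_interim(base_design, nuis(0.5), EffectVector.null(3), np.random.default_rng(42))
        assert np.array_equal(a.w, b.w) and np.array_equal(a.y, b.y)


class TestRunTrial:
    def test_k1_reduces_to_fixed_sample_z_test(self):
        d = TrialDesign(k=1, n1=40, N1=100, n2=200)
        cfg = _cfg(d, 0.0, EffectVector.null(1), "breve", seed=2, n_reps=100_000)
        oc = operating_characteristics(cfg)
        assert oc.reject_rate == pytest.approx(0.025, abs=3 * oc.mc_se_reject + 1e-9)

    def test_extreme_effect_always_selected_and_rejected(self, base_design):
        eff = EffectVector(theta_long=(10.0, 0.0, 0.0))
        cfg = _cfg(base_design, 0.0, eff, "breve", seed=3, n_reps=10_000)
        oc = operating_characteristics(cfg)
        assert oc.select_and_reject_rate[0] >= 0.999

    def test_deterministic_trajectory(self, base_design):
        cfg = _cfg(base_design, 0.5, EffectVector.null(3), "tilde", seed=11, n_reps=10)
        r1 = run_trial(cfg)
        r2 = run_trial(cfg)
        assert r1 == r2


class TestErrorRateControl:
    @pytest.mark.parametrize("variant", ["breve", "hat", "tilde"])
    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_calibration_closure(self, base_design, variant, rho):
        """Selecting by the calibration variant attains alpha (within MC error)."""
        cfg = _cfg(
            base_design, rho, EffectVector.null(3), variant, seed=100, c_variant=variant
        )
        oc = operating_characteristics(cfg)
        assert oc.reject_any_true_null_rate == pytest.approx(
            0.025, abs=3 * oc.mc_se_fwer + 1e-9
        )

    def test_strong_control_with_one_false_null(self, base_design):
        """Worst-case selection restricted to true nulls stays below alpha.

        With theta = (0.5, 0, 0) the worst case for the familywise error is
        to select the best-looking of the two true-null arms; the flexible
        critical value must still hold the rejection rate of a true null.
        """
        rho = 0.9
        m = variant_moments(base_design, nuis(rho), "tilde")
        c = critical_value(base_design, nuis(rho), "tilde").c_standardised
        theta = np.array([0.5, 0.0, 0.0])
        mean = np.concatenate([theta, base_design.n2 * theta])
        rng = np.random.default_rng(123)
        n = 200_000
        draws = rng.multivariate_normal(mean, m.full_covariance(3), size=n, method="cholesky")
        sel_stats = draws[:, :3] / np.sqrt(m.V1)
        z = draws[:, 3:] / np.sqrt(m.V2)
        sel_null = 1 + np.argmax(sel_stats[:, 1:], axis=1)  # argmax over arms 2, 3
        rate = np.mean(z[np.arange(n), sel_null] >= c)
        se = np.sqrt(rate * (1 - rate) / n)
        assert rate <= 0.025 + 3 * se

    def test_conservatism_of_flexible_c_under_other_rules(self, base_design):
        """Any non-worst-case selection rule keeps the FWER below alpha."""
        rho = 0.9
        c = critical_value(base_design, nuis(rho), "tilde").c_standardised
        for rule in ("breve", "hat"):
            cfg = _cfg(base_design, rho, EffectVector.null(3), rule, seed=7, c_standardised=c)
            oc = operating_characteristics(cfg)
            assert oc.reject_any_true_null_rate <= 0.025 + 3 * oc.mc_se_fwer
        # random and fixed-arm selection, via the explicit joint law
        m = variant_moments(base_design, nuis(rho), "tilde")
        rng = np.random.default_rng(8)
        n = 100_000
        draws = rng.multivariate_normal(np.zeros(6), m.full_covariance(3), size=n, method="cholesky")
        z = draws[:, 3:] / np.sqrt(m.V2)
        sel_random = rng.integers(0, 3, size=n)
        for sel in (sel_random, np.zeros(n, dtype=int)):
            rate = np.mean(z[np.arange(n), sel] >= c)
            assert rate <= 0.025 + 3 * np.sqrt(rate * (1 - rate) / n)


class TestPublishedOperatingCharacteristics:
    def test_null_error_rate_rho0(self, base_design, null_effects):
        cfg = _cfg(base_design, 0.0, null_effects, "tilde", seed=21)
        oc = operating_characteristics(cfg)
        # published simulated value 0.0242 and the truth 0.025 share a 3-se band
        assert abs(oc.reject_any_true_null_rate - 0.025) <= 3 * oc.mc_se_fwer
        assert abs(oc.reject_any_true_null_rate - 0.0242) <= 6 * oc.mc_se_fwer

    @pytest.mark.parametrize("rho,published", [(0.0, 0.7827), (0.9, 0.8358)])
    def test_power_to_select_and_reject_arm1(self, base_design, rho, published):
        eff = EffectVector(theta_long=(1 / 3, 0.0, 0.0))
        cfg = _cfg(base_design, rho, eff, "hat", seed=22)
        oc = operating_characteristics(cfg)
        assert abs(oc.select_and_reject_rate[0] - published) <= 6 * oc.mc_se_reject

    def test_inflation_of_primary_only_c_under_worst_case(self, base_design, null_effects):
        from flexselect import error_rate_given_c

        c_b = critical_value(base_design, nuis(0.9), "breve").c_standardised
        cfg = _cfg(base_design, 0.9, null_effects, "tilde", seed=23, c_standardised=c_b)
        oc = operating_characteristics(cfg)
        analytic = error_rate_given_c(base_design, nuis(0.9), c_b, "tilde")
        assert oc.reject_any_true_null_rate > 0.025
        assert abs(oc.reject_any_true_null_rate - analytic) <= 3 * oc.mc_se_fwer


class TestEngines:
    def test_engines_agree_on_fwer(self, base_design, null_effects):
        cfg_s = _cfg(base_design, 0.5, null_effects, "tilde", seed=31)
        cfg_i = _cfg(base_design, 0.5, null_effects, "tilde", seed=32, engine="individual", n_reps=30_000)
        oc_s = operating_characteristics(cfg_s)
        oc_i = operating_characteristics(cfg_i)
        tol = 3 * np.hypot(oc_s.mc_se_fwer, oc_i.mc_se_fwer)
        assert abs(oc_s.reject_any_true_null_rate - oc_i.reject_any_true_null_rate) <= tol

    def test_engines_agree_on_power(self, base_design):
        eff = EffectVector(theta_long=(1 / 3, 0.0, 0.0))
        oc_s = operating_characteristics(_cfg(base_design, 0.9, eff, "hat", seed=33))
        oc_i = operating_characteristics(
            _cfg(base_design, 0.9, eff, "hat", seed=34, engine="individual", n_reps=30_000)
        )
        tol = 3 * np.hypot(
            np.sqrt(0.84 * 0.16 / oc_s.n_reps), np.sqrt(0.84 * 0.16 / oc_i.n_reps)
        )
        assert abs(oc_s.select_and_reject_rate[0] - oc_i.select_and_reject_rate[0]) <= tol

    def test_power_invariant_to_common_short_term_shift(self, base_design):
        """The adjusted-estimate rule cancels the true short-term effects."""
        eff_a = EffectVector(theta_long=(1 / 3, 0, 0), theta_short=(0.0, 0.0, 0.0))
        eff_b = EffectVector(theta_long=(1 / 3, 0, 0), theta_short=(5.0, 5.0, 5.0))
        oc_a = operating_characteristics(
            _cfg(base_design, 0.8, eff_a, "hat", seed=35, engine="individual", n_reps=5_000)
        )
        oc_b = operating_characteristics(
            _cfg(base_design, 0.8, eff_b, "hat", seed=35, engine="individual", n_reps=5_000)
        )
        assert oc_a.select_and_reject_rate[0] == oc_b.select_and_reject_rate[0]

    def test_estimated_nuisance_workflow_controls_error(self, base_design, null_effects):
        """Plugging interim nuisance estimates into selection and c keeps FWER near alpha."""
        cfg = _cfg(
            base_design, 0.9, null_effects, "tilde", seed=36,
            engine="individual", estimate_nuisance_params=True, n_reps=30_000,
        )
        oc = operating_characteristics(cfg)
        # published estimated-nuisance value at rho=0.9 is 0.0248
        assert oc.reject_any_true_null_rate == pytest.approx(0.025, abs=4 * oc.mc_se_fwer)


class TestFixture:
    def test_interim_means_match_printed_summaries(self):
        interim, _ = fixture_table1(seed=5)
        n1 = 40
        assert interim.y.mean(axis=1) == pytest.approx(TABLE1_MEANS["y_first"], abs=1e-10)
        assert interim.w[:, :n1].mean(axis=1) == pytest.approx(TABLE1_MEANS["w_first"], abs=1e-10)
        assert interim.w[:, n1:].mean(axis=1) == pytest.approx(TABLE1_MEANS["w_second"], abs=1e-10)
        # all-interim short-term means round to the printed column
        wN = interim.w.mean(axis=1)
        assert np.round(wN, 2) == pytest.approx([0.02, 1.11, 2.32, 1.25])

    def test_fixture_deterministic(self):
        a = fixture_table1(seed=9)
        b = fixture_table1(seed=9)
        assert np.array_equal(a[0].w, b[0].w)
        assert np.array_equal(a[1].y_selected, b[1].y_selected)

    def test_selection_frequencies_sum_to_one(self, base_design, null_effects):
        oc = operating_characteristics(
            _cfg(base_design, 0.5, null_effects, "hat", seed=37, n_reps=20_000)
        )
        assert oc.selection_frequencies.sum() == pytest.approx(1.0)
        assert np.all(oc.select_and_reject_rate <= oc.selection_frequencies + 1e-12)
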