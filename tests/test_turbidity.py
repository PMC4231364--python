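"""Rate extraction and adsorption-saturation fitting."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanokin import (
    DegenerateInputError,
    ErosionScenario,
    FitError,
    RateDataset,
    RatePoint,
    ValidationError,
    WindowPolicy,
    estimate_initial_rate,
    fit_saturation,
    fold_change,
    predict_rate,
    rates_from_curves,
    simulate_rate_dataset,
    simulate_turbidity_curves,
    sqrt_normalize,
)
from nanokin.turbidity import round_sig

from conftest import TRUTHS, make_curve


def two_point_saturation_solution(E1, R1, E2, R2):
    """Closed-form (k_tau, K_A) through two noise-free points.

    The model linearizes exactly: 1/R = 1/k_tau + 1/(k_tau K_A) * 1/E, so
    the line through (1/E1, 1/R1), (1/E2, 1/R2) gives both parameters.
    """
    x1, y1, x2, y2 = 1 / E1, 1 / R1, 1 / E2, 1 / R2
    slope = (y2 - y1) / (x2 - x1)
    intercept = y1 - slope * x1
    return 1 / intercept, intercept / slope


class TestSqrtNormalize:
    def test_constant_curve_normalizes_to_one(self):
        c = make_curve([0, 1, 2, 3], [0.4, 0.4, 0.4, 0.4])
        assert np.all(sqrt_normalize(c) == 1.0)

    def test_quadratic_decay_gives_exact_line(self):
        t = np.arange(0, 50.0)
        c = make_curve(t, 0.4 * (1 - 0.01 * t) ** 2)
        assert np.allclose(sqrt_normalize(c), 1 - 0.01 * t, atol=1e-14)

    def test_scale_invariance(self, rng):
        t = np.arange(0, 13.0)
        tau = np.abs(rng.normal(0.4, 0.05, t.size)) + 0.01
        a = sqrt_normalize(make_curve(t, tau))
        b = sqrt_normalize(make_curve(t, 7.3 * tau))
        assert np.allclose(a, b, atol=1e-14)

    def test_zero_initial_turbidity_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            make_curve([0, 1, 2, 3], [0.0, 0.1, 0.1, 0.1])


class TestInitialRate:
    def test_noise_free_simulated_curve_recovers_generating_rate(self):
        sc = ErosionScenario(
            k_tau=4.1e-3, K_A=44.4, enzyme_concs=(0.08,), noise_rel=0.0,
            n_replicates=1,
        )
        (curve,) = simulate_turbidity_curves(sc)
        est = estimate_initial_rate(curve)
        assert est.rate == pytest.approx(sc.rate(0.08), rel=1e-12)
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_constant_turbidity_gives_zero_rate(self):
        est = estimate_initial_rate(make_curve(np.arange(8.0), [0.4] * 8))
        assert est.rate == 0.0

    def test_monte_carlo_unbiasedness(self, rng):
        b = 3.0e-3  # true slope of y(t)
        t = np.arange(0, 61.0, 5.0)
        rates = []
        for _ in range(1000):
            y = 1 - b * t + rng.normal(0, 0.005, t.size)
            rates.append(estimate_initial_rate(make_curve(t, 0.4 * y**2)).rate)
        rates = np.array(rates)
        mc_se = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - b) < 2 * mc_se + 1e-5  # sqrt transform bias ~1e-6

    def test_fixed_window_respects_substrate_protocol(self):
        # PCL protocol: 15 min at 1-min steps
        sc = ErosionScenario(
            k_tau=122.2e-3, K_A=41.1, enzyme_concs=(0.01,), noise_rel=0.0,
            n_replicates=1, duration=15.0, dt=1.0, substrate="PCL",
        )
        (curve,) = simulate_turbidity_curves(sc)
        est = estimate_initial_rate(curve)
        assert est.window_used == (0.0, 15.0, 16)

    def test_auto_window_on_fully_linear_curve_uses_all_points(self):
        R = 0.005
        t = np.arange(0, 41.0)
        tau = 0.4 * (1 - R * t) ** 2
        est = estimate_initial_rate(make_curve(t, tau), WindowPolicy(mode="auto"))
        assert est.rate == pytest.approx(R, rel=1e-10)
        assert est.window_used == (0.0, 40.0, 41)

    def test_auto_window_shortens_at_depletion_kink(self):
        # sqrt-turbidity is linear to t=20 then clamped at 0; the R^2-based
        # prefix rule stops within a few samples of the kink, keeping the
        # estimate close to the generating slope
        R = 0.05
        t = np.arange(0, 41.0)
        tau = 0.4 * np.clip(1 - R * t, 0, None) ** 2
        est = estimate_initial_rate(make_curve(t, tau), WindowPolicy(mode="auto"))
        assert est.window_used[1] < 30.0
        assert 0.9 * R <= est.rate <= R

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match="window"):
            estimate_initial_rate(
                make_curve([0, 1, 2], [0.4, 0.39, 0.38]),
                WindowPolicy(mode="fixed", t_max=60.0),
            )


class TestPredictRate:
    def test_zero_and_half_saturation(self):
        assert predict_rate(4.1e-3, 44.4, 0.0) == 0.0
        assert predict_rate(4.1e-3, 44.4, 1 / 44.4) == pytest.approx(
            4.1e-3 / 2, abs=1e-12
        )

    def test_published_pet_hand_value(self):
        assert predict_rate(4.1e-3, 44.4, 0.08) == pytest.approx(3.1993e-3, rel=1e-4)

    @given(
        k_tau=st.floats(1e-4, 1.0),
        K_A=st.floats(1.0, 1e3),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, k_tau, K_A):
        E = np.linspace(0, 10 / K_A, 40)
        R = predict_rate(k_tau, K_A, E)
        assert np.all(np.diff(R) > 0)
        assert np.all(R < k_tau)
        assert predict_rate(k_tau, K_A, 1 / K_A) == pytest.approx(
            k_tau / 2, abs=1e-12 * k_tau
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            predict_rate(-1.0, 44.4, 0.1)
        with pytest.raises(ValidationError):
            predict_rate(4.1e-3, 44.4, -0.1)


def _dataset(E, R, substrate="PET", temperature=50.0):
    return RateDataset(
        points=[RatePoint(e, r) for e, r in zip(E, R)],
        substrate=substrate, temperature=temperature,
    )


class TestFitSaturation:
    def test_noise_free_recovery_at_published_pet_parameters(self):
        K_A, k_tau = TRUTHS[("Tcur1278", "PET", 50)]
        ds = simulate_rate_dataset(
            ErosionScenario(k_tau=k_tau, K_A=K_A, noise_rel=0.0, n_replicates=1)
        )
        fit = fit_saturation(ds)
        assert fit.converged
        assert fit.k_tau == pytest.approx(k_tau, rel=1e-6)
        assert fit.K_A == pytest.approx(K_A, rel=1e-6)

    def test_two_point_closed_form_oracle(self, rng):
        for _ in range(100):
            k_tau = 10 ** rng.uniform(-4, 0)
            K_A = 10 ** rng.uniform(0, 3)
            E1, E2 = 0.3 / K_A, 3.0 / K_A
            R1, R2 = predict_rate(k_tau, K_A, E1), predict_rate(k_tau, K_A, E2)
            # add a third point on-model so the fit precondition holds;
            # zero residuals mean the closed form through any two must match
            E3 = 1.0 / K_A
            ds = _dataset([E1, E2, E3], [R1, R2, predict_rate(k_tau, K_A, E3)])
            fit = fit_saturation(ds)
            k_cf, K_cf = two_point_saturation_solution(E1, R1, E2, R2)
            assert fit.k_tau == pytest.approx(k_cf, rel=1e-6)
            assert fit.K_A == pytest.approx(K_cf, rel=1e-6)

    @given(
        k_tau=st.floats(1e-4, 1.0),
        K_A=st.floats(1.0, 1e3),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_noise_free_recovery_sweep(self, k_tau, K_A):
        E = np.geomspace(0.1 / K_A, 10 / K_A, 8)
        ds = _dataset(E, predict_rate(k_tau, K_A, E))
        fit = fit_saturation(ds)
        assert fit.k_tau == pytest.approx(k_tau, rel=1e-6)
        assert fit.K_A == pytest.approx(K_A, rel=1e-6)

    def test_supramaximal_points_excluded_by_default(self):
        E = np.array([0.01, 0.02, 0.04, 0.08, 0.12, 0.16])
        R = predict_rate(4.1e-3, 44.4, E)
        R[4:] = R[3] * np.array([0.8, 0.6])  # crowding-like decline
        fit = fit_saturation(_dataset(E, R))
        assert [p.enzyme_conc for p in fit.excluded_points] == [0.12, 0.16]
        assert fit.n_points_used == 4
        assert fit.k_tau == pytest.approx(4.1e-3, rel=1e-6)
        # disabling exclusion biases the fit
        fit_all = fit_saturation(_dataset(E, R), exclude_supramaximal=False)
        assert fit_all.n_points_used == 6
        assert fit_all.k_tau != pytest.approx(4.1e-3, rel=1e-3)

    def test_point_order_invariance(self, rng):
        E = np.geomspace(0.005, 0.08, 8)
        R = predict_rate(4.1e-3, 44.4, E) * (1 + rng.normal(0, 0.03, E.size))
        fit_a = fit_saturation(_dataset(E, R))
        perm = rng.permutation(E.size)
        fit_b = fit_saturation(_dataset(E[perm], R[perm]))
        assert fit_b.k_tau == pytest.approx(fit_a.k_tau, rel=1e-7)
        assert fit_b.K_A == pytest.approx(fit_a.K_A, rel=1e-7)

    def test_duplicating_every_point_leaves_estimates_unchanged(self, rng):
        E = np.geomspace(0.005, 0.08, 8)
        R = predict_rate(4.1e-3, 44.4, E) * (1 + rng.normal(0, 0.03, E.size))
        fit_a = fit_saturation(_dataset(E, R))
        fit_b = fit_saturation(_dataset(np.r_[E, E], np.r_[R, R]))
        assert fit_b.k_tau == pytest.approx(fit_a.k_tau, rel=1e-7)
        assert fit_b.K_A == pytest.approx(fit_a.K_A, rel=1e-7)

    def test_stochastic_median_recovery_pcl(self):
        K_A, k_tau = TRUTHS[("Tcur1278", "PCL", 49)]
        grid = tuple(np.linspace(0.002, 0.03, 8))
        estimates = []
        for seed in range(1, 201):
            ds = simulate_rate_dataset(
                ErosionScenario(k_tau=k_tau, K_A=K_A, enzyme_concs=grid,
                                noise_rel=0.03, seed=seed, substrate="PCL",
                                temperature=49.0)
            )
            estimates.append(fit_saturation(ds).k_tau)
        assert np.median(estimates) == pytest.approx(k_tau, rel=0.02)

    def test_error_cases(self):
        with pytest.raises(FitError, match="distinct"):
            fit_saturation(_dataset([0.01, 0.02], [1e-3, 2e-3]))
        with pytest.raises(FitError, match="unidentifiable"):
            fit_saturation(_dataset([0.01, 0.02, 0.04], [0.0, 0.0, 0.0]))

    def test_se_shrinks_with_replicate_noise_reduction(self):
        # quadrupling replicates halves the point noise; fitted SEs track
        # within 20%
        K_A, k_tau = 44.4, 4.1e-3
        grid = tuple(np.geomspace(0.005, 0.08, 8))
        ses = {}
        for n_rep in (2, 8):
            vals = []
            for seed in range(60):
                ds = simulate_rate_dataset(
                    ErosionScenario(k_tau=k_tau, K_A=K_A, enzyme_concs=grid,
                                    noise_rel=0.04, n_replicates=n_rep, seed=seed)
                )
                vals.append(fit_saturation(ds).se_k_tau)
            ses[n_rep] = np.median(vals)
        assert ses[2] / ses[8] == pytest.approx(2.0, rel=0.2)


class TestFoldChange:
    def test_published_comparisons(self):
        def fit_like(K_A, k_tau):
            return fit_saturation(_dataset(
                np.geomspace(0.1 / K_A, 10 / K_A, 6), predict_rate(k_tau, K_A,
                np.geomspace(0.1 / K_A, 10 / K_A, 6))))

        pet_a = fit_like(*TRUTHS[("Tcur1278", "PET", 50)])
        pet_b = fit_like(*TRUTHS[("Tcur0390", "PET", 50)])
        fc_pet = fold_change(pet_a, pet_b)
        assert fc_pet.k_tau_ratio_2sf == 1.7
        assert fc_pet.K_A_ratio_2sf == 3.9

        pcl_a = fit_like(*TRUTHS[("Tcur1278", "PCL", 49)])
        pcl_b = fit_like(*TRUTHS[("Tcur0390", "PCL", 49)])
        assert fold_change(pcl_a, pcl_b).K_A_ratio_2sf == 2.3

    def test_identical_fits_give_unit_ratios(self, pet_scenario_noisefree):
        fit = fit_saturation(simulate_rate_dataset(pet_scenario_noisefree))
        fc = fold_change(fit, fit)
        assert fc.k_tau_ratio == 1.0 and fc.K_A_ratio == 1.0

    def test_round_sig(self):
        assert round_sig(7.0 / 4.1) == 1.7
        assert round_sig(172.7 / 44.4) == 3.9
        assert round_sig(96.0 / 41.1) == 2.3
        assert round_sig(0.0) == 0.0


class TestRatesFromCurves:
    def test_replicates_averaged_with_se(self):
        sc = ErosionScenario(noise_rel=0.02, n_replicates=4, seed=21)
        curves = simulate_turbidity_curves(sc)
        ds = rates_from_curves(curves)
        assert len(ds.points) == len(sc.enzyme_concs)
        assert all(p.n_replicates == 4 for p in ds.points)
        assert all(p.rate_se > 0 for p in ds.points)

    def test_mixed_conditions_rejected(self):
        a = make_curve(np.arange(8.0), 0.4 * (1 - 0.01 * np.arange(8.0)) ** 2,
                       substrate="PET")
        b = make_curve(np.arange(8.0), 0.4 * (1 - 0.01 * np.arange(8.0)) ** 2,
                       substrate="PCL")
        with pytest.raises(ValidationError, match="mixed"):
            rates_from_curves([a, b])
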