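import numpy as np
import pandas as pd
import pytest

import fovdesign as fd
from fovdesign.models import SaturationModel, _saturation


def _sse(y, yhat):
    return float(np.sum((np.asarray(y) - np.asarray(yhat)) ** 2))


class TestSaturationFit:
    def test_exact_data_recovers_parameters(self):
        r = np.arange(1, 21, dtype=float)
        y = 10 * (1 - np.exp(-r / 3.0))
        fit = SaturationModel(r, y).fit()
        assert fit.n_observable == pytest.approx(10.0, rel=1e-6)
        assert fit.tau == pytest.approx(3.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_two_tau_gives_86_percent(self):
        r = np.arange(1, 21, dtype=float)
        fit = SaturationModel(r, 10 * (1 - np.exp(-r / 3.0))).fit()
        frac = fit.predict(2 * fit.tau) / fit.n_observable
        assert frac == pytest.approx(1 - np.exp(-2), abs=1e-9)
        assert round(100 * frac) == 86

    def test_predict_closed_form_checkpoints(self):
        r = np.arange(1, 21, dtype=float)
        fit = SaturationModel(r, 8 * (1 - np.exp(-r / 5.0))).fit()
        assert fit.predict(0) == pytest.approx(0.0)
        assert fit.predict(fit.tau) == pytest.approx(
            fit.n_observable * (1 - np.exp(-1)), rel=1e-9
        )
        with pytest.raises(ValueError):
            fit.predict(-1)

    def test_noisy_fit_beats_grid_search_oracle(self):
        curve = fd.generate_curve_observations(10, 3.0, range(1, 16), reps=50, seed=12)
        fit = fd.fit_saturation(curve)
        r = curve.r_values.astype(float)
        y = curve.mean_recovered
        best = np.inf
        for n_o in np.linspace(5, 15, 101):
            for tau in np.linspace(1, 6, 101):
                best = min(best, _sse(y, _saturation(r, n_o, tau)))
        assert _sse(y, fit.predict(r)) <= best + 1e-9

    def test_insufficient_or_flat_data_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            SaturationModel([1, 2], [1.0, 2.0])
        with pytest.raises(ValueError, match="all equal"):
            SaturationModel([1, 2, 3], [5.0, 5.0, 5.0])

    def test_pathological_data_keeps_parameters_legal(self):
        # decreasing data cannot come from a saturation process; whatever
        # route the optimizer takes, reported parameters stay positive and
        # the diagnostic flags are coherent
        fit = SaturationModel([1, 2, 3, 4], [4.0, 3.0, 2.0, 1.0]).fit()
        assert fit.tau > 0 and fit.n_observable > 0
        assert isinstance(fit.converged, bool)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_parameter_recovery_over_seeds(self):
        # median fitted tau over 20 replicate noisy curves within 10% of truth
        taus = []
        for seed in range(20):
            curve = fd.generate_curve_observations(
                15, 4.0, range(1, 21), reps=50, seed=seed
            )
            taus.append(fd.fit_saturation(curve).tau)
        assert abs(np.median(taus) - 4.0) / 4.0 < 0.10


class TestPowerLawFit:
    def test_exact_inverse_square_law(self):
        w = np.array([200.0, 300.0, 400.0, 500.0])
        fit = fd.fit_tau_vs_width(1e6 / w**2, w)
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        assert fit.log10_coefficient == pytest.approx(6.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        w = np.array([200.0, 250.0, 320.0, 400.0, 480.0, 560.0])
        tau = 10**5.5 / w**1.3 * 10 ** rng.normal(0, 0.05, w.size)
        fit = fd.fit_tau_vs_width(tau, w)
        # closed-form simple linear regression on log10 scales
        lx, ly = np.log10(w), np.log10(tau)
        slope = np.sum((lx - lx.mean()) * (ly - ly.mean())) / np.sum(
            (lx - lx.mean()) ** 2
        )
        intercept = ly.mean() - slope * lx.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.log10_coefficient == pytest.approx(intercept, abs=1e-10)

    def test_prediction_inverts_the_law(self):
        w = np.array([100.0, 200.0, 400.0])
        fit = fd.fit_tau_vs_width(2e5 / w**1.5, w)
        assert fit.predict(300.0) == pytest.approx(2e5 / 300**1.5, rel=1e-9)

    def test_non_positive_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fd.fit_tau_vs_width([1.0, -2.0, 3.0], [100.0, 200.0, 300.0])


class TestTauVsAbundance:
    def test_exact_hpp_relation_beta_one(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        fit = fd.fit_tau_vs_abundance(5.0 / p, p)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficient == pytest.approx(5.0, rel=1e-9)

    def test_zero_proportion_excluded_with_warning(self):
        p = np.array([0.0, 0.2, 0.3, 0.5])
        with pytest.warns(UserWarning, match="zero abundance"):
            fit = fd.fit_tau_vs_abundance(np.array([9.9, 5.0 / 0.2, 5.0 / 0.3, 10.0]), p)
        assert fit.x.size == 3

    def test_transfer_ratio_arithmetic(self):
        p = np.array([0.1, 0.2, 0.4])
        fit = fd.fit_tau_vs_abundance(2.0 / p, p)
        # observed taus exactly half the predicted ones -> mean ratio 0.5
        assert fd.transfer_ratio(fit, 1.0 / p, p) == pytest.approx(0.5, rel=1e-9)

    def test_hpp_simulation_recovers_beta_near_one(self):
        # phenotypes at different densities: tau_i ~ 1/(lambda_i w^2) so
        # tau vs proportion follows a power law with exponent one
        ds = fd.generate_hpp_tissue(
            fd.HppSpec(
                densities={"A": 1.5e-6, "B": 3e-6, "C": 6e-6},
                extent=(0, 0, 6000, 6000), seed=29,
            )
        )
        probs = fd.per_phenotype_recovery(ds, range(1, 16), 350, T=0, reps=50, seed=8)
        taus = fd.fit_per_phenotype_tau(probs)
        p = ds.proportions().reindex(taus.index)
        fit = fd.fit_tau_vs_abundance(taus.to_numpy(), p.to_numpy())
        assert 0.7 < fit.exponent < 1.3


class TestKLDecayFit:
    def test_exact_data_recovers_parameters(self):
        r = np.arange(1, 13, dtype=float)
        kl = 1.0 * np.exp(-(r - 1) / 4.0) + 0.02
        fit = fd.fit_kl_model((r, kl))
        assert fit.kl_o == pytest.approx(1.0, abs=1e-6)
        assert fit.kl_b == pytest.approx(0.02, abs=1e-6)
        assert fit.theta == pytest.approx(4.0, abs=1e-6)

    def test_value_at_one_fov_is_klo_plus_klb(self):
        r = np.arange(1, 13, dtype=float)
        fit = fd.fit_kl_model((r, 0.8 * np.exp(-(r - 1) / 3.0) + 0.05))
        assert fit.predict(1) == pytest.approx(fit.kl_o + fit.kl_b, rel=1e-9)

    def test_noisy_fit_beats_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        r = np.arange(1, 16, dtype=float)
        kl = 0.9 * np.exp(-(r - 1) / 3.0) + 0.03 + rng.normal(0, 0.01, r.size)
        fit = fd.fit_kl_model((r, kl))
        best = np.inf
        for klo in np.linspace(0.5, 1.5, 41):
            for klb in np.linspace(0.0, 0.1, 41):
                for theta in np.linspace(1, 6, 51):
                    pred = klo * np.exp(-(r - 1) / theta) + klb
                    best = min(best, _sse(kl, pred))
        pred = fit.predict(r)
        assert _sse(kl, pred) <= best + 1e-9

    def test_needs_four_distinct_r(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fd.fit_kl_model(([1, 2, 3], [0.5, 0.3, 0.2]))


class TestShrinkageAlpha:
    @staticmethod
    def _power_law_dataset():
        # labels become visible at engineered window widths so that the
        # recovered count equals w^1.5 exactly at widths 4, 9, 16, 25
        xs, labels = [], []
        tiers = [(2.0, 8), (4.5, 19), (8.0, 37), (12.5, 61)]
        k = 0
        prev = 0.0
        for half, n_new in tiers:
            pos = prev + (half - prev) * (np.arange(n_new) + 0.5) / n_new
            for p in pos:
                xs.append(p if k % 2 == 0 else -p)
                labels.append(f"L{k}")
                k += 1
            prev = half
        x = np.array(xs)
        y = np.zeros_like(x)
        return fd.SpatialDataset(x, y, labels, bounds=(-50, -50, 50, 50))

    def test_exact_power_law_slope(self):
        ds = self._power_law_dataset()
        est = fd.estimate_alpha_by_shrinkage(
            ds, shrink_factors=(100 / 25, 100 / 16, 100 / 9, 100 / 4), T=0
        )
        assert sorted(est.recovered_counts.tolist()) == [8, 27, 64, 125]
        assert est.alpha == pytest.approx(1.5, abs=1e-9)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)
        assert est.passed_quality

    def test_low_quality_fit_flagged(self):
        rng = np.random.default_rng(2)
        # scattered single-point labels: counts vs width are far from a line
        n = 40
        ds = fd.SpatialDataset(
            np.concatenate([rng.uniform(-50, 50, n), np.zeros(3)]),
            np.concatenate([rng.uniform(-50, 50, n), [0.1, -0.1, 0.2]]),
            [f"L{i}" for i in range(n)] + ["core"] * 3,
            bounds=(-50, -50, 50, 50),
        )
        est = fd.estimate_alpha_by_shrinkage(ds, T=0)
        if not est.passed_quality:
            assert est.r_squared < 0.9

    def test_nothing_recovered_is_flagged(self):
        ds = fd.SpatialDataset([0.0], [0.0], ["A"], bounds=(-50, -50, 50, 50))
        with pytest.raises(ValueError, match="zero phenotypes"):
            fd.estimate_alpha_by_shrinkage(ds, T=5)


class TestMultinomialDeviance:
    def test_printed_examples(self):
        assert fd.multinomial_deviance([1, 1]) == pytest.approx(2 * np.log(2))
        n = 7
        assert fd.multinomial_deviance([n]) == pytest.approx(2 * n * np.log(n))

    def test_zeros_contribute_nothing(self):
        assert fd.multinomial_deviance([3, 0, 2]) == pytest.approx(
            fd.multinomial_deviance([3, 2])
        )

    def test_all_zero_vector_is_zero(self):
        assert fd.multinomial_deviance([0, 0, 0]) == 0.0

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            fd.multinomial_deviance([1.5, 2.0])
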