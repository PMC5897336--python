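"""Hill fitting, F-test confidence intervals, inversion, derived metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcstune import hill_inference as hi
from tcstune import synthetic_data as sd


def noiseless_data(truth=(100.0, 10000.0, 50.0, 1.5), seed=0):
    return sd.gen_dose_response(truth, sd.SyntheticConfig(seed=seed, noise_cv=0.0))


class TestFitHill:
    def test_exact_recovery_on_noiseless_data(self):
        data = noiseless_data()
        fit = hi.fit_hill(data, compute_ci=False)
        for name, true in data.metadata["truth"].items():
            assert getattr(fit, name) == pytest.approx(true, rel=1e-6)

    def test_dose_rescaling_shifts_only_k_half(self):
        """Units covariance: doses x10 means fitted K_1/2 x10."""
        data = noiseless_data()
        scaled = hi.DoseResponse(data.doses * 10, data.responses, data.replicates)
        f1 = hi.fit_hill(data, compute_ci=False)
        f2 = hi.fit_hill(scaled, compute_ci=False)
        assert f2.k_half == pytest.approx(10 * f1.k_half, rel=1e-6)
        assert f2.low == pytest.approx(f1.low, rel=1e-6, abs=1e-6)
        assert f2.high == pytest.approx(f1.high, rel=1e-6)
        assert f2.n == pytest.approx(f1.n, rel=1e-6)

    def test_record_order_invariance(self):
        """Pooled replicates fit identically regardless of row order."""
        data = sd.gen_dose_response(config=sd.SyntheticConfig(seed=3))
        perm = np.random.default_rng(0).permutation(len(data.doses))
        shuffled = hi.DoseResponse(data.doses[perm], data.responses[perm],
                                   data.replicates[perm])
        f1 = hi.fit_hill(data, compute_ci=False)
        f2 = hi.fit_hill(shuffled, compute_ci=False)
        for name in hi.PARAM_NAMES:
            assert getattr(f1, name) == pytest.approx(getattr(f2, name), rel=1e-9)

    def test_reported_rss_matches_brute_force_recomputation(self):
        data = sd.gen_dose_response(config=sd.SyntheticConfig(seed=5))
        fit = hi.fit_hill(data, compute_ci=False)
        assert fit.rss == pytest.approx(hi.weighted_rss(data, fit), rel=1e-12)

    def test_median_k_half_error_under_noise(self):
        """CV-10% Monte Carlo: median relative K_1/2 error well under 15%."""
        errs = []
        for s in range(60):
            d = sd.gen_dose_response(config=sd.SyntheticConfig(seed=200 + s))
            f = hi.fit_hill(d, compute_ci=False)
            errs.append(abs(f.k_half - 50.0) / 50.0)
        assert np.median(errs) < 0.15

    def test_degenerate_data_refused(self):
        flat = hi.DoseResponse([0, 1, 10, 100], [5.0] * 4, ["d1"] * 4)
        with pytest.raises(hi.FitError):
            hi.fit_hill(flat)
        few = hi.DoseResponse([0, 1, 1, 1], [1, 2, 3, 4], ["d1"] * 4)
        with pytest.raises(hi.FitError):
            hi.fit_hill(few)


class TestConfidenceIntervals:
    def test_noiseless_interval_collapses_to_estimate(self):
        fit = hi.fit_hill(noiseless_data(), compute_ci=True, ci_params=("k_half",))
        ci = fit.ci95["k_half"]
        assert ci.upper - ci.lower < 1e-6 * fit.k_half

    def test_interval_contains_estimate_and_nests(self):
        data = sd.gen_dose_response(config=sd.SyntheticConfig(seed=7))
        fit = hi.fit_hill(data, compute_ci=False)
        for name in hi.PARAM_NAMES:
            c68 = hi.ci_f_test(fit, data, name, level=0.68)
            c95 = hi.ci_f_test(fit, data, name, level=0.95)
            est = getattr(fit, name)
            assert c68.contains(est) and c95.contains(est)
            assert c95.lower <= c68.lower <= c68.upper <= c95.upper

    def test_doubling_noise_widens_interval(self):
        """Paired comparison: CV 20% data give a wider median K_1/2 CI."""
        widths = {cv: [] for cv in (0.1, 0.2)}
        for s in range(12):
            for cv in (0.1, 0.2):
                d = sd.gen_dose_response(
                    config=sd.SyntheticConfig(seed=500 + s, noise_cv=cv))
                f = hi.fit_hill(d, compute_ci=True, ci_params=("k_half",))
                ci = f.ci95["k_half"]
                widths[cv].append(ci.upper - ci.lower)
        assert np.median(widths[0.2]) > np.median(widths[0.1])

    def test_agrees_with_lmfit_conf_interval(self):
        """Independent cross-check against lmfit's own F-test profiler."""
        import lmfit

        data = sd.gen_dose_response(config=sd.SyntheticConfig(seed=9))
        fit = hi.fit_hill(data, compute_ci=True, ci_params=("k_half",))
        m = hi._dose_mean_weights(data, 1.0)
        params = hi._make_params(data)
        for k in hi.PARAM_NAMES:
            params[k].value = getattr(fit, k)
        mini = lmfit.Minimizer(hi._residual, params,
                               fcn_args=(data.doses, data.responses, m))
        res = mini.minimize(method="leastsq")
        ci = lmfit.conf_interval(mini, res, p_names=["k_half"], sigmas=[2])
        lo, hi_b = ci["k_half"][0][1], ci["k_half"][-1][1]
        ours = fit.ci95["k_half"]
        # 2-sigma (95.45%) vs 95% and different grids: agree to ~10%
        assert ours.lower == pytest.approx(lo, rel=0.1)
        assert ours.upper == pytest.approx(hi_b, rel=0.1)

    def test_unknown_parameter_rejected(self):
        data = sd.gen_dose_response(config=sd.SyntheticConfig(seed=1))
        fit = hi.fit_hill(data, compute_ci=False)
        with pytest.raises(ValueError):
            hi.ci_f_test(fit, data, "slope")


class TestInversion:
    def test_half_maximal_response_maps_to_k_half(self):
        fit = hi.HillFit(low=10, high=1000, k_half=25, n=2.0)
        assert hi.hill_invert(fit, 505.0) == pytest.approx(25.0, rel=1e-12)

    def test_round_trip_on_random_fits(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            fit = hi.HillFit(low=rng.uniform(0, 100),
                             high=rng.uniform(500, 50000),
                             k_half=10 ** rng.uniform(-1, 3),
                             n=rng.uniform(0.5, 4))
            x = fit.k_half * 10 ** rng.uniform(-1.5, 1.5)
            assert hi.hill_invert(fit, fit.eval(x)) == pytest.approx(x, rel=1e-10)

    def test_small_response_limit_approaches_zero_dose(self):
        fit = hi.HillFit(low=0.0, high=100.0, k_half=10.0, n=1.0)
        assert hi.hill_invert(fit, 1e-8) < 1e-8

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(low=st.floats(0, 100), span=st.floats(100, 50000),
           k_half=st.floats(0.1, 1000), n=st.floats(0.3, 6),
           log_rel=st.floats(-1.5, 1.5))
    def test_round_trip_property(self, low, span, k_half, n, log_rel):
        """hill_invert is the exact inverse of hill_eval on (low, high)."""
        fit = hi.HillFit(low=low, high=low + span, k_half=k_half, n=n)
        x = k_half * 10 ** log_rel
        assert hi.hill_invert(fit, fit.eval(x)) == pytest.approx(x, rel=1e-9)

    def test_out_of_range_response_rejected(self):
        fit = hi.HillFit(low=10, high=100, k_half=5, n=1)
        for y in (10.0, 100.0, 5.0, 200.0):
            with pytest.raises(ValueError):
                hi.hill_invert(fit, y)


class TestFoldChange:
    def test_lod_substitution_gives_lower_bound(self):
        # B. subtilis LOD (3 sigma of autofluorescence) = 36.4 MEFL
        r = hi.fold_change(24664.0, 5.0, 36.4)
        assert r.value == pytest.approx(24664.0 / 36.4, rel=1e-12)
        assert r.is_lower_bound

    def test_no_substitution_above_lod(self):
        r = hi.fold_change(1000.0, 100.0, 16.6)
        assert r.value == 10.0 and not r.is_lower_bound

    def test_both_below_lod_yields_unity(self):
        r = hi.fold_change(10.0, 10.0, 16.6)
        assert r.value == 1.0 and r.is_lower_bound

    def test_nonpositive_lod_rejected(self):
        with pytest.raises(ValueError):
            hi.fold_change(10.0, 5.0, 0.0)


class TestRangeMetrics:
    @pytest.mark.parametrize("low,high,amplitude", [
        (2508.0, 67910.0, 65402.0),    # NarX(C415R) nitrate sensor
        (34758.0, 66052.0, 31294.0),   # NarX(D558V) nitrate sensor
    ])
    def test_amplitude_range_from_published_plateaus(self, low, high, amplitude):
        r = hi.range_metrics(hi.HillFit(low=low, high=high, k_half=1.0, n=1.0))
        assert r.amplitude_range == amplitude
        assert r.dynamic_range == pytest.approx(high / low)

    def test_flat_fit_degenerates(self):
        r = hi.range_metrics(hi.HillFit(low=50.0, high=50.0, k_half=1.0, n=1.0))
        assert r.amplitude_range == 0.0 and r.dynamic_range == 1.0

    def test_zero_low_floored_at_lod(self):
        r = hi.range_metrics(hi.HillFit(low=0.0, high=100.0, k_half=1.0, n=1.0),
                             lod=16.6)
        assert r.floored and r.dynamic_range == pytest.approx(100 / 16.6)


class TestIsoSKDesign:
    def fits(self):
        d1, d2 = sd.gen_inducer_curves(config=sd.SyntheticConfig(seed=0, noise_cv=0.0))
        return (hi.fit_hill(d1, compute_ci=False),
                hi.fit_hill(d2, compute_ci=False))

    def test_degenerate_fraction_uses_zero_inducer(self):
        f1, f2 = self.fits()
        rows = hi.design_isosk_inductions(f1, f2, 775.0, [1.0])
        assert rows[0].inducer2 == 0.0
        assert rows[0].inducer1 == pytest.approx(hi.hill_invert(f1, 775.0))

    def test_forward_evaluation_reproduces_total(self):
        f1, f2 = self.fits()
        rows = hi.design_isosk_inductions(f1, f2, 775.0,
                                          np.round(np.arange(0, 1.01, 0.1), 10))
        for r in rows:
            total = f1.eval(r.inducer1) + f2.eval(r.inducer2)
            assert total == pytest.approx(775.0, rel=1e-6)

    def test_unreachable_target_reports_window(self):
        f1, f2 = self.fits()
        with pytest.raises(ValueError, match="achievable window"):
            hi.design_isosk_inductions(f1, f2, 10 * f1.high, [1.0])


class TestSoilReport:
    def test_half_maximal_fluorescence_reports_k_half(self):
        std = hi.HillFit(low=50, high=40000, k_half=100, n=1.5)
        rep = hi.report_soil_concentration(std, (50 + 40000) / 2)
        assert rep.reported == pytest.approx(100.0, rel=1e-12)
        assert rep.status == "ok"

    def test_out_of_window_statuses(self):
        std = hi.HillFit(low=50, high=40000, k_half=100, n=1.5)
        assert hi.report_soil_concentration(std, 10.0).status == "below_detection"
        assert hi.report_soil_concentration(std, 50000.0).status == "saturated"

    def test_round_trip_accuracy_under_noise(self):
        """CV-15% soil simulation: >= 90% of reports within twofold of the
        true spikes across the standard's responsive window."""
        ok = tot = 0
        for s in range(10):
            calib, samples = sd.gen_soil_experiment(
                config=sd.SyntheticConfig(seed=900 + s, noise_cv=0.15))
            std = hi.fit_hill(calib, compute_ci=False)
            for row in samples.itertuples():
                rep = hi.report_soil_concentration(
                    std, row.fluorescence_mefl, row.true_uM)
                tot += 1
                ok += rep.status == "ok" and rep.within_twofold
        assert ok / tot >= 0.90
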