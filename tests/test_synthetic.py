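import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smcortex import synthetic as syn


def _no_hazard_scheme():
    return syn.ImagingScheme(tau_int=0.02, delay=0.0, k_bleach=0.0, loc_error_sd=0.0)


class TestPopulationValidation:
    def test_fractions_must_sum_to_one(self):
        pops = [
            syn.KineticPopulation("a", 1.0, 0.1, 0.5),
            syn.KineticPopulation("b", 0.5, 0.1, 0.4),
        ]
        with pytest.raises(ValueError, match="sum to 1"):
            syn.validate_populations(pops)

    def test_negative_rate_names_field(self):
        with pytest.raises(ValueError, match="k_off"):
            syn.KineticPopulation("a", -1.0, 0.1, 1.0)

    def test_nonfinite_rate_rejected(self):
        with pytest.raises(ValueError, match="k_bleach"):
            syn.ImagingScheme(tau_int=0.02, k_bleach=float("nan"))

    def test_tau_tl_is_sum(self):
        scheme = syn.ImagingScheme(tau_int=0.02, delay=0.1)
        assert scheme.tau_tl == pytest.approx(0.12)


class TestSimulateBindingEvents:
    def test_no_hazards_all_events_survive(self, geometry):
        pops = [syn.KineticPopulation("p", 0.0, 0.1, 1.0)]
        events = syn.simulate_binding_events(pops, _no_hazard_scheme(), geometry, 50, seed=0)
        assert all(math.isinf(e.true_lifetime) for e in events)
        assert all(math.isinf(e.bleach_time) for e in events)

    def test_mean_lifetime_matches_rate(self, geometry):
        # single population at the wild-type fast rate: mean lifetime 1.1 s
        pops = [syn.KineticPopulation("p", 1.0 / 1.1, 0.1, 1.0)]
        events = syn.simulate_binding_events(pops, _no_hazard_scheme(), geometry, 10_000, seed=3)
        lifetimes = np.array([e.true_lifetime for e in events])
        se = lifetimes.std(ddof=1) / math.sqrt(lifetimes.size)
        assert abs(lifetimes.mean() - 1.1) < 3 * se

    def test_mixture_survival_matches_analytic(self, geometry):
        # KS distance < 0.01 against the closed-form two-exponential mixture
        k1, k2, w = 1.0, 0.2, 0.7
        pops = [
            syn.KineticPopulation("f", k1, 0.1, w),
            syn.KineticPopulation("s", k2, 0.1, 1 - w),
        ]
        events = syn.simulate_binding_events(pops, _no_hazard_scheme(), geometry, 50_000, seed=4)
        lifetimes = np.array([e.true_lifetime for e in events])

        def mixture_cdf(t):
            return 1.0 - (w * np.exp(-k1 * t) + (1 - w) * np.exp(-k2 * t))

        ks = stats.kstest(lifetimes, mixture_cdf)
        assert ks.statistic < 0.01
        assert ks.pvalue > 0.01

    def test_deterministic_under_seed(self, wt_populations, continuous_scheme, geometry):
        a = syn.simulate_binding_events(wt_populations, continuous_scheme, geometry, 100, seed=7)
        b = syn.simulate_binding_events(wt_populations, continuous_scheme, geometry, 100, seed=7)
        assert a == b

    def test_population_draw_by_fraction(self, wt_populations, continuous_scheme, geometry):
        events = syn.simulate_binding_events(
            wt_populations, continuous_scheme, geometry, 20_000, seed=5
        )
        frac = np.mean([e.population_label == "fast" for e in events])
        assert frac == pytest.approx(0.76, abs=3 * math.sqrt(0.76 * 0.24 / 20_000))

    def test_n_events_validated(self, wt_populations, continuous_scheme, geometry):
        with pytest.raises(ValueError, match="n_events"):
            syn.simulate_binding_events(wt_populations, continuous_scheme, geometry, 0, seed=0)


class TestObservedFrameCounts:
    def test_bleach_only_during_integration(self, geometry):
        # with a long dark delay the bleach hazard per frame is unchanged,
        # so frame counts follow the same geometric law at any tau_tl
        pops = [syn.KineticPopulation("p", 0.0, 0.0, 1.0)]
        counts = {}
        for delay in (0.0, 0.2):
            scheme = syn.ImagingScheme(tau_int=0.02, delay=delay, k_bleach=3.0)
            events = syn.simulate_binding_events(pops, scheme, geometry, 20_000, seed=11)
            counts[delay] = syn.observed_frame_counts(events, scheme)
        # per-frame survival exp(-k_bleach*tau_int) = exp(-0.06) either way
        p = math.exp(-3.0 * 0.02)
        for delay, n in counts.items():
            mean_expected = 1.0 / (1.0 - p)
            se = n.std(ddof=1) / math.sqrt(n.size)
            assert abs(n.mean() - mean_expected) < 3 * se

    def test_min_one_frame(self, wt_populations, continuous_scheme, geometry):
        events = syn.simulate_binding_events(
            wt_populations, continuous_scheme, geometry, 1000, seed=2
        )
        assert syn.observed_frame_counts(events, continuous_scheme).min() >= 1


class TestSimulateLocalizations:
    def test_frozen_molecule_identical_coordinates(self, geometry):
        pops = [syn.KineticPopulation("p", 1.0, 0.0, 1.0)]
        scheme = syn.ImagingScheme(tau_int=0.02, k_bleach=0.0, loc_error_sd=0.0)
        events = syn.simulate_binding_events(pops, scheme, geometry, 20, seed=6)
        table = syn.simulate_localizations(events, pops, scheme, geometry, seed=6)
        for _, grp in table.groupby("event_id"):
            assert grp["x_um"].nunique() == 1
            assert grp["y_um"].nunique() == 1

    def test_step_variance_matches_brownian(self, geometry):
        # mean squared per-frame step = 4 D tau_tl = 0.0248 um^2
        D, tau = 0.31, 0.02
        pops = [syn.KineticPopulation("p", 0.0, D, 1.0)]
        scheme = syn.ImagingScheme(tau_int=tau, k_bleach=0.0, loc_error_sd=0.0)
        events = syn.simulate_binding_events(pops, scheme, geometry, 5, seed=8, horizon_s=1.0)
        table = syn.simulate_localizations(events, pops, scheme, geometry, seed=8, max_frames=2001)
        sq = []
        for _, grp in table.groupby("event_id"):
            grp = grp.sort_values("frame")
            sq.extend(np.diff(grp["x_um"]) ** 2 + np.diff(grp["y_um"]) ** 2)
        sq = np.asarray(sq)[:10_000]
        se = sq.std(ddof=1) / math.sqrt(sq.size)
        assert abs(sq.mean() - 4 * D * tau) < 3 * se

    def test_step_variance_chi2(self, geometry):
        # per-axis step variance test against 2 D tau_tl at alpha = 0.01
        D, tau = 0.1, 0.02
        pops = [syn.KineticPopulation("p", 0.0, D, 1.0)]
        scheme = syn.ImagingScheme(tau_int=tau, k_bleach=0.0, loc_error_sd=0.0)
        events = syn.simulate_binding_events(pops, scheme, geometry, 3, seed=9, horizon_s=1.0)
        table = syn.simulate_localizations(events, pops, scheme, geometry, seed=9, max_frames=1500)
        steps = []
        for _, grp in table.groupby("event_id"):
            steps.extend(np.diff(grp.sort_values("frame")["x_um"]))
        steps = np.asarray(steps)
        n = steps.size
        statistic = n * steps.var() / (2 * D * tau)
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < statistic < hi

    def test_row_conservation_without_hazards(self, geometry):
        pops = [syn.KineticPopulation("p", 0.0, 0.1, 1.0)]
        scheme = _no_hazard_scheme()
        events = syn.simulate_binding_events(pops, scheme, geometry, 10, seed=10)
        n_frames = 37
        table = syn.simulate_localizations(events, pops, scheme, geometry, seed=10, max_frames=n_frames)
        assert (table.groupby("event_id").size() == n_frames).all()

    def test_deterministic_table(self, wt_populations, continuous_scheme, geometry):
        events = syn.simulate_binding_events(
            wt_populations, continuous_scheme, geometry, 200, seed=12
        )
        t1 = syn.simulate_localizations(events, wt_populations, continuous_scheme, geometry, seed=12)
        t2 = syn.simulate_localizations(events, wt_populations, continuous_scheme, geometry, seed=12)
        pd.testing.assert_frame_equal(t1, t2)


class TestGradientGenerator:
    def test_deterministic_limit(self):
        model = syn.GradientModel(
            amplitude_median=100.0, amplitude_gsd=1.0, decay_length_base=1.5,
            buffering_exponent=0.0, background=7.0,
        )
        profiles, truth = syn.simulate_gradient_profiles(model, 5, 4.0, 0.1, seed=0)
        for cid, grp in profiles.groupby("cell_id"):
            x = grp["x_um"].to_numpy()
            np.testing.assert_allclose(
                grp["intensity_au"].to_numpy(), 100.0 * np.exp(-x / 1.5) + 7.0
            )
        np.testing.assert_allclose(truth["decay_length_um"], 1.5)

    def test_buffering_exponent_sets_loglog_slope(self):
        model = syn.GradientModel(amplitude_gsd=2.0, buffering_exponent=0.5)
        _, truth = syn.simulate_gradient_profiles(model, 240, 5.0, 0.05, seed=1)
        la = np.log(truth["amplitude"])
        ll = np.log(truth["decay_length_um"])
        slope = np.polyfit(la, ll, 1)[0]
        r = np.corrcoef(la, ll)[0, 1]
        assert slope == pytest.approx(-0.5, abs=1e-9)
        assert r < -0.9

    def test_profile_count(self):
        model = syn.GradientModel(amplitude_gsd=1.5)
        profiles, truth = syn.simulate_gradient_profiles(model, 240, 5.0, 0.05, seed=2)
        assert profiles["cell_id"].nunique() == 240
        assert len(truth) == 240

    def test_negative_buffering_rejected(self):
        with pytest.raises(ValueError, match="buffering_exponent"):
            syn.GradientModel(buffering_exponent=-0.1)


class TestNodeGenerator:
    def test_never_on_stays_at_baseline(self):
        model = syn.NodeOccupancyModel(on_rate=0.0, off_rate=0.1, noise_sd=1.0, baseline=5.0)
        series, truth = syn.simulate_node_series(model, 20, 60.0, 1.0, seed=0)
        assert not truth["occupied"].any()
        assert abs(series["intensity_au"].mean() - 5.0) < 0.5

    def test_sample_count(self):
        model = syn.NodeOccupancyModel()
        series, _ = syn.simulate_node_series(model, 3, 60.0, 1.0, seed=1)
        assert (series.groupby("node_id").size() == 61).all()

    def test_telegraph_stationary_occupancy(self):
        model = syn.NodeOccupancyModel(on_rate=0.1, off_rate=0.1)
        _, truth = syn.simulate_node_series(model, 200, 120.0, 1.0, seed=2)
        per_node = truth.groupby("node_id")["occupied"].mean()
        se = per_node.std(ddof=1) / math.sqrt(len(per_node))
        assert abs(per_node.mean() - 0.5) < 3 * se

    def test_cell_length_effect_modulates_on_rate(self):
        model = syn.NodeOccupancyModel(
            on_rate=0.2, off_rate=0.2, noise_sd=0.0,
            cell_length_effect=lambda length: 4.0 if length < 8 else 0.25,
        )
        lengths = [7.0] * 50 + [13.0] * 50
        _, truth = syn.simulate_node_series(model, 100, 120.0, 1.0, seed=3, cell_lengths=lengths)
        occ = truth.groupby("node_id")["occupied"].mean()
        assert occ[:50].mean() > occ[50:].mean()

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            syn.simulate_node_series(syn.NodeOccupancyModel(), 1, 0.5, 1.0, seed=0)
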