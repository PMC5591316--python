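"""Step detection, selection filters, idealization, histogram fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribofret as rf
from ribofret import fret, selection


class TestDetectSteps:
    def test_noiseless_single_drop(self):
        x = np.concatenate([np.full(50, 400.0), np.full(50, 100.0)])
        steps = selection.detect_steps(x)
        assert len(steps) == 1
        assert steps[0].frame == 50
        assert steps[0].direction == "down"
        assert steps[0].magnitude == pytest.approx(300.0)

    def test_constant_series_has_no_steps(self):
        assert selection.detect_steps(np.full(100, 42.0)) == []

    def test_localization_under_noise(self):
        # 300-count step under sigma=20 Gaussian noise, many seeded trials
        rng = np.random.default_rng(0)
        hits = 0
        trials = 300
        for _ in range(trials):
            x = np.concatenate([np.full(150, 100.0), np.full(150, 400.0)])
            x += rng.normal(0, 20, 300)
            ups = [s for s in selection.detect_steps(x) if s.direction == "up"]
            if ups and abs(max(ups, key=lambda s: s.magnitude).frame - 150) <= 2:
                hits += 1
        assert hits / trials >= 0.95

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            selection.detect_steps(np.arange(5.0))


def _bleach_trace(scheme, seed, bleach=(0.02, 0.015, 0.025)):
    photo = rf.PhotophysicsParams(
        brightness=500,
        bleach_rates={"cy3": bleach[0], "cy5": bleach[1], "cy7": bleach[2]},
    )
    return rf.simulate_complex_trace(scheme, photo, 4000, seed=seed), photo


class TestStoichiometryFilter:
    def test_single_bleach_per_dye_passes(self, two_state_scheme):
        npass = 0
        for seed in range(8):
            (trace, gt), _ = _bleach_trace(two_state_scheme, seed)
            if any(v is None for v in gt.bleach_frames.values()):
                continue  # a dye survived the record; verdict legitimately fails
            npass += bool(selection.stoichiometry_filter(trace))
        assert npass >= 5

    def test_two_binders_fail_with_multiple_steps(self):
        # synthetic ch3 with two up-steps (two sequential binders)
        n = 400
        inten = np.tile([20.0, 20.0], n // 2).reshape(-1, 1) * np.ones(3)
        inten[100:, 0][::1] += 0.0
        g = np.arange(0, n, 2)
        inten[g[50:], 0] += 300.0  # first binder
        inten[g[120:], 0] += 300.0  # second binder
        inten[g[180:], 0] = 20.0  # both gone
        trace = rf.RawTrace(inten)
        v = selection.stoichiometry_filter(trace)
        assert not v.passed
        assert any("ch3: multiple steps" in r for r in v.reasons)

    def test_absent_dye_fails(self):
        rng = np.random.default_rng(3)
        inten = rng.poisson(20.0, (400, 3)).astype(float)
        g = np.arange(0, 400, 2)
        r = g + 1
        inten[g[:150], 0] += 400.0  # Cy3 binds then bleaches
        inten[r[:180], 1] += 400.0  # Cy5 present then bleaches
        # ch7 stays dark: Cy7 absent
        v = selection.stoichiometry_filter(trace := rf.RawTrace(inten))
        assert not v.passed
        assert any(r.startswith("ch7") for r in v.reasons)

    def test_permutation_invariance(self, two_state_scheme):
        traces = [_bleach_trace(two_state_scheme, s)[0][0] for s in range(4)]
        verdicts = [selection.stoichiometry_filter(t).passed for t in traces]
        shuffled = [
            selection.stoichiometry_filter(traces[i]).passed for i in (2, 0, 3, 1)
        ]
        assert [verdicts[i] for i in (2, 0, 3, 1)] == shuffled


class TestSiteSpecificFilter:
    @staticmethod
    def _binding_pair(e35, e37, seed=11):
        scheme = rf.KineticScheme(
            state_efficiencies={
                "docked": (0.61, e35, e37),
                "flipped": (0.27, e35, e37),
            },
            rates_pre={"dock_to_flip": 0.2, "flip_to_dock": 0.3},
            k_on=0.3,
            k_off=0.02,
        )
        photo = rf.PhotophysicsParams()
        pairs = rf.simulate_binding_experiment(
            scheme, photo, 1, 1200, seed=seed, max_events=1
        )
        trace = pairs[0][0]
        fs = fret.compute_fret_series(
            trace, fret.CorrectionParams.from_photophysics(photo)
        )
        return trace, fs

    def test_specific_binder_passes_fret_mode(self):
        trace, fs = self._binding_pair(0.3, 0.2)
        assert selection.site_specific_filter(trace, fs, "fret_s16").passed
        assert selection.site_specific_filter(trace, fs, "colocalize").passed

    def test_nonspecific_binder_fails_fret_passes_colocalize(self):
        trace, fs = self._binding_pair(0.0, 0.0)
        assert not selection.site_specific_filter(trace, fs, "fret_s16").passed
        assert selection.site_specific_filter(trace, fs, "colocalize").passed

    def test_dark_cy3_fails_both(self, two_state_scheme):
        photo = rf.PhotophysicsParams()
        scheme = rf.KineticScheme(
            state_efficiencies=two_state_scheme.state_efficiencies,
            rates_pre=two_state_scheme.rates_pre,
            k_on=1e-9,  # binding essentially never happens
            k_off=1.0,
        )
        pairs = rf.simulate_binding_experiment(scheme, photo, 1, 400, seed=1)
        trace = pairs[0][0]
        fs = fret.compute_fret_series(
            trace, fret.CorrectionParams.from_photophysics(photo)
        )
        assert not selection.site_specific_filter(trace, fs, "fret_s16").passed
        assert not selection.site_specific_filter(trace, fs, "colocalize").passed


class TestIdealize:
    def test_constant_high_is_single_docked_segment(self):
        path = selection.idealize(np.full(50, 0.6))
        assert path.segments == [("docked", 0, 50)]

    def test_clean_alternation_switches_at_exact_frames(self):
        e = np.tile(np.concatenate([np.full(20, 0.6), np.full(20, 0.1)]), 3)
        path = selection.idealize(e)
        starts = [s for _, s, _ in path.segments]
        assert starts == [0, 20, 40, 60, 80, 100]

    def test_short_blip_merged(self):
        e = np.full(40, 0.6)
        e[20] = 0.1  # single-frame excursion below threshold
        path = selection.idealize(e, min_dwell_frames=2)
        assert path.segments == [("docked", 0, 40)]

    def test_all_invalid_raises(self):
        with pytest.raises(ValueError):
            selection.idealize(np.full(10, np.nan))

    def test_fixture_occupancy_recovered(self):
        fx = rf.load_fixture("fig1_s4")
        occs, truths = [], []
        rng = np.random.default_rng(4)
        for _ in range(10):
            trace, gt = rf.simulate_complex_trace(fx.scheme, fx.photo, fx.n_frames, rng)
            fs = fret.compute_fret_series(
                trace, fret.CorrectionParams.from_photophysics(fx.photo)
            )
            e57, valid = fs.e57_pairs()
            # midpoint threshold separates the 0.33/0.61 states symmetrically
            path = selection.idealize(e57, threshold=0.47, valid=valid)
            occs.append(path.occupancy("flipped"))
            truths.append(gt.occupancy("flipped"))
        assert abs(np.mean(occs) - np.mean(truths)) < 0.02


class TestHistogramAndFit:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(300, 3000))
    def test_histogram_conserves_counts(self, seed, n):
        rng = np.random.default_rng(seed)
        values = rng.normal(0.5, 0.5, n)  # deliberately spills out of range
        hist = selection.fret_histogram(values)
        assert hist.total == n

    def test_mixture_parameters_recovered(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.normal(0.33, 0.06, 2000), rng.normal(0.61, 0.06, 3000)]
        )
        fit = selection.fit_double_gaussian(selection.fret_histogram(values))
        assert abs(fit.mu_low - 0.33) < 0.02
        assert abs(fit.mu_high - 0.61) < 0.02
        assert abs(fit.frac_low - 0.4) < 0.05
        assert fit.mu_low < fit.mu_high
        assert fit.frac_low + fit.frac_high == pytest.approx(1.0)

    def test_single_population_collapses_to_one_component(self):
        rng = np.random.default_rng(6)
        dominant = []
        for _ in range(5):
            values = rng.normal(0.6, 0.05, 5000)
            fit = selection.fit_double_gaussian(selection.fret_histogram(values))
            dominant.append(max(fit.frac_low, fit.frac_high))
        assert min(dominant) >= 0.95

    def test_frac_low_monotone_in_planted_occupancy(self):
        rng = np.random.default_rng(7)
        fracs = []
        for occ in (0.1, 0.3, 0.5, 0.7):
            n = 6000
            values = np.concatenate(
                [
                    rng.normal(0.33, 0.06, int(n * occ)),
                    rng.normal(0.61, 0.06, n - int(n * occ)),
                ]
            )
            fit = selection.fit_double_gaussian(selection.fret_histogram(values))
            fracs.append(fit.frac_low)
        assert all(a < b for a, b in zip(fracs, fracs[1:]))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            selection.fit_double_gaussian(
                selection.fret_histogram(np.random.default_rng(0).normal(0.5, 0.1, 100))
            )
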