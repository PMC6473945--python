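"""Per-frame broken-rod fits, model selection and time-course assembly."""

import numpy as np
import pytest

from clexsaxs.fitting import (
    FitConfig,
    TimeCourse,
    average_timecourses,
    fit_frame,
    fit_series,
    initial_guess,
    select_components,
    timecourse_table,
    weight_fractions,
)
from clexsaxs.formfactor import BrokenRodParams, kratky_model
from clexsaxs.saxs_io import KratkyProfile, subtract_buffer, to_kratky
from clexsaxs.synthetic import (
    ParameterTrajectory,
    default_q_grid,
    render_frames,
    scenario,
)
from conftest import render_subtracted_profile


def noiseless_profile(params, n=120, time=0.0):
    q = default_q_grid(n)
    return KratkyProfile(q=q, y=kratky_model(q, params), time=time)


class TestWeightFractions:
    @pytest.mark.parametrize(
        "k1, k2, expected",
        [(1.0, 1.0, (0.5, 0.5)), (0.0, 5.0, (0.0, 1.0)), (2.0, 8.0, (0.2, 0.8))],
    )
    def test_amplitude_normalisation(self, k1, k2, expected):
        assert weight_fractions(k1, k2) == pytest.approx(expected)

    def test_sums_to_one(self):
        w1, w2 = weight_fractions(0.37, 1.91)
        assert w1 + w2 == pytest.approx(1.0)

    def test_cross_section_mode_reweights(self):
        # equal amplitudes but the thick rod carries more mass per length
        w1, w2 = weight_fractions(1.0, 1.0, mode="cross_section",
                                  rc1=1.0, rc2=3.0)
        assert w2 == pytest.approx(9.0 / 10.0)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            weight_fractions(0.0, 0.0)


class TestInitialGuess:
    def test_junction_zone_radius_from_peak(self, full_gel_params):
        prof = noiseless_profile(full_gel_params)
        guess = initial_guess(prof)
        assert guess.n_components == 2
        assert guess.rc2 == pytest.approx(2.9, rel=0.15)

    def test_flat_profile_gives_tiny_amplitudes(self):
        q = default_q_grid()
        prof = KratkyProfile(q=q, y=np.full(q.size, 0.3))
        guess = initial_guess(prof)
        assert guess.k_total < 1e-3
        assert guess.const == pytest.approx(0.3, rel=1e-6)

    def test_linear_profile_single_component(self):
        q = default_q_grid()
        prof = KratkyProfile(q=q, y=0.25 * q)
        guess = initial_guess(prof)
        assert guess.n_components == 1

    def test_too_few_points_rejected(self):
        prof = KratkyProfile(q=np.linspace(0.1, 1, 5), y=np.zeros(5))
        with pytest.raises(ValueError):
            initial_guess(prof)


class TestFitFrame:
    def test_noiseless_round_trip_high_accuracy(self, full_gel_params):
        prof = noiseless_profile(full_gel_params)
        init = BrokenRodParams(
            rc1=full_gel_params.rc1 * 1.2,
            rc2=full_gel_params.rc2 * 1.2,
            k1=full_gel_params.k1 * 1.2,
            k2=full_gel_params.k2 * 1.2,
            const=full_gel_params.const * 1.2,
            n_components=2,
        )
        res = fit_frame(prof, init)
        assert res.converged
        for got, want in [
            (res.params.rc1, full_gel_params.rc1),
            (res.params.rc2, full_gel_params.rc2),
            (res.params.k1, full_gel_params.k1),
            (res.params.k2, full_gel_params.k2),
        ]:
            assert abs(got - want) / want < 1e-6

    def test_noiseless_single_component_round_trip(self, single_chain_params):
        prof = noiseless_profile(single_chain_params)
        init = BrokenRodParams(rc1=0.25, k1=1.3, const=0.02, n_components=1)
        res = fit_frame(prof, init)
        assert abs(res.params.rc1 - 0.2) / 0.2 < 1e-6

    def test_pure_constant_profile(self):
        q = default_q_grid()
        prof = KratkyProfile(q=q, y=np.full(q.size, 0.42))
        init = BrokenRodParams(rc1=0.5, k1=0.1, const=0.1, n_components=1)
        res = fit_frame(prof, init)
        assert res.params.k_total < 1e-8
        assert res.params.const == pytest.approx(0.42, rel=1e-6)

    def test_noisy_recovery_close_to_information_bound(self, full_gel_params):
        # At peak Kratky SNR ~30 the Cramer-Rao bound for rc1 is ~6%
        # relative (rc2, w2 ~2%); check the estimator sits near it.
        w2_truth = full_gel_params.k2 / full_gel_params.k_total
        errs = []
        for seed in range(12):
            prof = render_subtracted_profile(36000.0, seed=500 + seed)
            res = fit_frame(prof, full_gel_params)
            errs.append([
                res.params.rc1 / full_gel_params.rc1 - 1,
                res.params.rc2 / full_gel_params.rc2 - 1,
                res.weight_fractions[1] / w2_truth - 1,
            ])
        rmse = np.sqrt(np.mean(np.square(errs), axis=0))
        assert rmse[0] < 0.12
        assert rmse[1] < 0.05
        assert rmse[2] < 0.05

    def test_monotone_noise_response(self, full_gel_params):
        # estimator RMSE must shrink as the noise amplitude shrinks
        rmses = []
        for level in (0.03, 0.015, 0.003):
            errs = []
            for seed in range(25):
                prof = render_subtracted_profile(
                    36000.0, seed=100 + seed, noise_level=level
                )
                res = fit_frame(prof, full_gel_params)
                errs.append(res.params.rc2 / full_gel_params.rc2 - 1)
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_label_invariant_ordered_output(self, full_gel_params):
        # either labelling of the same two-component init converges to
        # the identical ordered result
        prof = render_subtracted_profile(36000.0, seed=11)
        init = BrokenRodParams.two_component(0.8, 0.25, 3.1, 0.75, const=0.01)
        swapped = BrokenRodParams.two_component(3.1, 0.75, 0.8, 0.25, const=0.01)
        res_a = fit_frame(prof, init)
        res_b = fit_frame(prof, swapped)
        assert res_a.params == res_b.params
        assert res_a.params.rc1 < res_a.params.rc2


class TestSelectComponents:
    def test_single_chain_frame_selects_one(self):
        prof = render_subtracted_profile(0.0, seed=3)
        res = select_components(prof)
        assert res.n_components == 1
        assert res.params.rc1 == pytest.approx(0.2, rel=0.25)

    def test_full_gel_frame_selects_two(self):
        prof = render_subtracted_profile(36000.0, seed=3)
        res = select_components(prof)
        assert res.n_components == 2

    def test_zero_signal_frame_degenerates_to_one_component(self):
        q = default_q_grid()
        rng = np.random.default_rng(0)
        sigma = np.full(q.size, 0.002)
        prof = KratkyProfile(q=q, y=rng.normal(0.0, 0.002, q.size),
                             sigma_y=sigma)
        res = select_components(prof)
        assert res.n_components == 1
        assert res.params.k_total * 0.25 < 5 * 0.002  # amplitude lost in noise


class TestFitSeries:
    def test_ramping_weight_fraction_recovered(self):
        # w2 ramps 0 -> 0.8; the fitted series must rise accordingly and
        # end within 5% of the plateau
        traj = scenario("pH7.0")
        times = np.append(np.arange(0.0, 150.0, 5.0), 36000.0)
        frames, buf = render_frames(traj, times, seed=21)
        tc = fit_series([subtract_buffer(f, buf) for f in frames])
        assert len(tc) == times.size
        assert tc.w2_series[-1] == pytest.approx(0.8, rel=0.05)
        # non-decreasing within noise
        assert np.all(np.diff(tc.w2_series) > -0.1)

    def test_constant_series_is_flat(self, full_gel_params):
        traj = ParameterTrajectory(
            rc1_anchors=((0.0, 0.9),),
            rc2_anchors=((0.0, 2.9),),
            w2_anchors=((0.0, 0.8),),
            switch_time=0.0,
        )
        frames, buf = render_frames(traj, np.arange(0.0, 100.0, 5.0), seed=5)
        tc = fit_series([subtract_buffer(f, buf) for f in frames])
        assert np.std(tc.rc2_series) / np.mean(tc.rc2_series) < 0.05
        assert np.std(tc.w2_series) < 0.05

    def test_single_frame_series(self):
        traj = scenario("pH7.0")
        frames, buf = render_frames(traj, [36000.0], seed=1)
        tc = fit_series([subtract_buffer(frames[0], buf)])
        assert len(tc) == 1

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fit_series([])

    def test_table_layout(self):
        traj = scenario("pH7.0")
        frames, buf = render_frames(traj, [0.0, 5.0], seed=1)
        tc = fit_series([subtract_buffer(f, buf) for f in frames])
        table = timecourse_table(tc)
        assert list(table.columns) == [
            "time_s", "n_comp", "rc1_nm", "rc2_nm", "w2",
            "cost", "bic", "converged",
        ]
        assert len(table) == 2


class TestAverageTimecourses:
    def _tc(self, times, rc1, rc2, w2, rep=""):
        times = np.asarray(times, dtype=float)
        return TimeCourse(
            times=times,
            rc1_series=np.asarray(rc1, dtype=float),
            rc2_series=np.asarray(rc2, dtype=float),
            w2_series=np.asarray(w2, dtype=float),
            n_comp=np.where(np.isnan(rc2), 1, 2),
            converged=np.ones(times.size, dtype=bool),
            replicate=rep,
        )

    def test_identical_replicates_identity(self):
        a = self._tc([0, 5, 10], [0.2, 0.5, 0.9], [np.nan, 2.7, 2.9],
                     [0, 0.3, 0.8], "a")
        out = average_timecourses(a, a)
        np.testing.assert_allclose(out.rc1_series, a.rc1_series)
        np.testing.assert_allclose(out.w2_series, a.w2_series)

    def test_symmetric_offsets_recover_truth(self):
        truth = np.array([0.5, 0.7, 0.9])
        a = self._tc([0, 5, 10], truth + 0.05, [2.9] * 3, [0.5] * 3, "a")
        b = self._tc([0, 5, 10], truth - 0.05, [2.9] * 3, [0.5] * 3, "b")
        out = average_timecourses(a, b)
        np.testing.assert_allclose(out.rc1_series, truth)

    def test_one_sided_rc2_contributes_alone(self):
        a = self._tc([0, 5], [0.2, 0.5], [np.nan, 2.8], [0.0, 0.4], "a")
        b = self._tc([0, 5], [0.2, 0.5], [2.6, 3.0], [0.2, 0.6], "b")
        out = average_timecourses(a, b)
        assert out.rc2_series[0] == pytest.approx(2.6)
        assert out.rc2_series[1] == pytest.approx(2.9)

    def test_different_lengths_average_overlap(self, caplog):
        a = self._tc([0, 5, 10, 15], [1] * 4, [2.9] * 4, [0.5] * 4, "a")
        b = self._tc([0, 5], [2] * 2, [2.9] * 2, [0.5] * 2, "b")
        with caplog.at_level("WARNING", logger="clexsaxs.fitting"):
            out = average_timecourses(a, b)
        assert any("overlap" in r.message for r in caplog.records)
        assert out.rc1_series[0] == pytest.approx(1.5)

    def test_disjoint_ranges_rejected(self):
        a = self._tc([0, 5], [1, 1], [2.9, 2.9], [0.5, 0.5], "a")
        b = self._tc([100, 105], [1, 1], [2.9, 2.9], [0.5, 0.5], "b")
        with pytest.raises(ValueError):
            average_timecourses(a, b)
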