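"""Cleaning-chain tests: each step's contract, zero-phase behaviour, nuisance
design construction, and group-PCA equivalence with direct eigendecomposition."""
import numpy as np
import pytest

from sonofc.core import ConfoundRecord, TimeSeriesRun
from sonofc.preprocess import (NuisanceDesign, build_nuisance_design,
                               demean_and_concatenate, despike_interpolate,
                               discard_initial_volumes, dynamic_bandstop,
                               group_pca_reduce, highpass_filter,
                               lowpass_filter, regress_confounds)

TR = 2.0


def _run(data: np.ndarray) -> TimeSeriesRun:
    return TimeSeriesRun(np.atleast_2d(data.T).T if data.ndim == 1 else data, TR)


def _white(rng, t=795, p=5) -> TimeSeriesRun:
    return TimeSeriesRun(rng.standard_normal((t, p)), TR)


class TestDiscard:
    def test_800_minus_5(self, rng):
        out = discard_initial_volumes(_white(rng, 800), 5)
        assert out.n_volumes == 795

    def test_zero_is_identity(self, rng):
        run = _white(rng, 20)
        np.testing.assert_array_equal(discard_initial_volumes(run, 0).data, run.data)

    def test_too_short_raises(self, rng):
        with pytest.raises(ValueError):
            discard_initial_volumes(_white(rng, 3), 5)


class TestDespike:
    def test_single_spike_replaced_by_neighbour_mean(self, rng):
        run = _white(rng, 100, 3)
        data = run.data.copy()
        data[50] += 30.0
        cleaned, idx = despike_interpolate(TimeSeriesRun(data, TR))
        assert idx.tolist() == [50]
        np.testing.assert_allclose(cleaned.data[50],
                                   (data[49] + data[51]) / 2, atol=1e-12)

    def test_adjacent_spikes_interpolated_from_flanks(self, rng):
        run = _white(rng, 100, 3)
        data = run.data.copy()
        data[40] += 25.0
        data[41] += 25.0
        cleaned, idx = despike_interpolate(TimeSeriesRun(data, TR))
        assert idx.tolist() == [40, 41]
        expected_40 = data[39] + (data[42] - data[39]) / 3
        np.testing.assert_allclose(cleaned.data[40], expected_40, atol=1e-12)

    def test_white_noise_false_positive_rate(self):
        """Volume-wise false-positive rate below 1e-3 on pure noise."""
        rng = np.random.default_rng(99)
        total, flagged = 0, 0
        for _ in range(20):
            _, idx = despike_interpolate(_white(rng, 795, 10))
            flagged += idx.size
            total += 795
        assert flagged / total < 1e-3

    def test_clean_data_unmodified(self, rng):
        run = _white(rng, 200, 4)
        cleaned, idx = despike_interpolate(run)
        if idx.size == 0:
            np.testing.assert_array_equal(cleaned.data, run.data)


class TestHighpass:
    def test_linear_trend_removed_fallback(self):
        t = np.arange(795) * TR
        run = _run(0.01 * t)
        out = highpass_filter(run)  # 2000 s cutoff > run length -> detrend
        assert np.abs(out.data).max() < 0.01 * np.abs(run.data).max()

    def test_slow_oscillation_preserved_fallback(self):
        t = np.arange(795) * TR
        run = _run(np.sin(2 * np.pi * 0.05 * t))
        out = highpass_filter(run)
        assert out.data.std() >= 0.95 * run.data.std()

    def test_constant_series_zeroed(self):
        out = highpass_filter(_run(np.full(795, 3.7)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_butterworth_branch_contracts(self):
        # 100 s cutoff on a 1590 s run engages the real filter
        t = np.arange(795) * TR
        trend = highpass_filter(_run(0.01 * t), cutoff_seconds=100.0)
        assert np.std(trend.data[100:-100]) < 0.05 * np.std(0.01 * t)
        osc = _run(np.sin(2 * np.pi * 0.05 * t))
        out = highpass_filter(osc, cutoff_seconds=100.0)
        assert out.data.std() >= 0.95 * osc.data.std()

    def test_cutoff_below_nyquist_period_raises(self, rng):
        with pytest.raises(ValueError):
            highpass_filter(_white(rng, 100), cutoff_seconds=3.0)


class TestLowpass:
    def test_fast_oscillation_attenuated(self):
        t = np.arange(795) * TR
        run = _run(np.cos(2 * np.pi * 0.25 * t))
        out = lowpass_filter(run)
        assert out.data.std() <= 0.10 * run.data.std()

    def test_slow_oscillation_preserved(self):
        t = np.arange(795) * TR
        run = _run(np.sin(2 * np.pi * 0.02 * t))
        out = lowpass_filter(run)
        assert out.data.std() >= 0.95 * run.data.std()

    def test_constant_unchanged(self):
        run = _run(np.full(795, 2.5))
        np.testing.assert_allclose(lowpass_filter(run).data, run.data, atol=1e-8)


class TestZeroPhase:
    @pytest.mark.parametrize("filt", [
        lambda r: highpass_filter(r, 100.0),
        lambda r: lowpass_filter(r, 10.0),
    ])
    def test_time_reversal_symmetry(self, rng, filt):
        run = _white(rng, 400, 3)
        fwd = filt(run).data
        rev = filt(run.with_data(run.data[::-1])).data[::-1]
        np.testing.assert_allclose(fwd, rev, atol=1e-8)


class TestBandstop:
    def test_injected_peak_notched_20db(self, rng):
        t = np.arange(795) * TR
        noise = rng.standard_normal((795, 20))
        run = TimeSeriesRun(noise + (5.0 * np.sin(2 * np.pi * 0.2 * t))[:, None], TR)
        filtered, notched = dynamic_bandstop(run)
        assert len(notched) >= 1
        assert abs(notched[0] - 0.2) < 0.01
        from scipy.signal import periodogram
        f, pb = periodogram(run.data.mean(axis=1), fs=1 / TR)
        _, pa = periodogram(filtered.data.mean(axis=1), fs=1 / TR)
        i = np.argmax(pb)
        assert 10 * np.log10(pb[i] / pa[i]) >= 20.0

    def test_white_noise_never_notched(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            _, notched = dynamic_bandstop(_white(rng, 795, 10))
            assert notched == []

    def test_peak_outside_search_band_untouched(self, rng):
        t = np.arange(795) * TR
        run = _run(rng.standard_normal(795) + 5 * np.sin(2 * np.pi * 0.05 * t))
        out, notched = dynamic_bandstop(run, search_band=(0.1, 0.25))
        assert notched == []
        np.testing.assert_array_equal(out.data, run.data)

    def test_empty_band_raises(self, rng):
        with pytest.raises(ValueError):
            dynamic_bandstop(_white(rng), search_band=(0.2, 0.2))


class TestNuisanceDesign:
    def _confounds(self, rng, t=200, n_wm=5, n_csf=5):
        return ConfoundRecord(rng.standard_normal((t, 6)),
                              rng.standard_normal((t, n_wm)),
                              rng.standard_normal((t, n_csf)))

    def test_volterra_column_count(self, rng):
        design = build_nuisance_design(self._confounds(rng))
        volterra = [l for l in design.column_labels if l.startswith("b0_")]
        assert len(volterra) == 24  # 6 linear + 6 lagged + 12 squares
        # full design: 3 wm + 3 csf + 24 + intercept
        assert design.columns.shape[1] == 31
        assert design.column_labels[-1] == "intercept"

    def test_constant_b0_trace_kept_constant(self, rng):
        conf = self._confounds(rng)
        conf.b0_params[:, 0] = 2.0
        design = build_nuisance_design(conf)
        i = design.column_labels.index("b0_1")
        j = design.column_labels.index("b0_1_sq")
        assert np.ptp(design.columns[:, i]) == 0
        assert np.ptp(design.columns[:, j]) == 0
        # collinearity with the intercept is absorbed by the pseudoinverse
        run = TimeSeriesRun(rng.standard_normal((200, 3)), TR)
        regress_confounds(run, design)

    def test_rank_one_compartment_yields_single_pc(self, rng):
        base = rng.standard_normal(200)
        conf = ConfoundRecord(rng.standard_normal((200, 6)),
                              np.column_stack([base, 2 * base, -base]),
                              rng.standard_normal((200, 3)))
        design = build_nuisance_design(conf)
        assert "wm_pc1" in design.column_labels
        assert "wm_pc2" not in design.column_labels

    def test_cross_terms_flag(self, rng):
        design = build_nuisance_design(self._confounds(rng), include_cross_terms=True)
        assert sum(l.endswith("_x_lag") for l in design.column_labels) == 6


class TestRegression:
    def test_design_column_data_zeroed(self, rng):
        conf = ConfoundRecord(rng.standard_normal((100, 6)),
                              rng.standard_normal((100, 5)),
                              rng.standard_normal((100, 5)))
        design = build_nuisance_design(conf)
        run = TimeSeriesRun(np.column_stack([design.columns[:, 0],
                                             design.columns[:, 3]]), TR)
        out = regress_confounds(run, design)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        conf = ConfoundRecord(rng.standard_normal((150, 6)),
                              rng.standard_normal((150, 5)),
                              rng.standard_normal((150, 5)))
        design = build_nuisance_design(conf)
        run = TimeSeriesRun(rng.standard_normal((150, 8)), TR)
        resid = regress_confounds(run, design).data
        cols = design.columns / np.linalg.norm(design.columns, axis=0)
        assert np.abs(cols.T @ resid).max() < 1e-8

    def test_orthogonal_data_unchanged(self, rng):
        t = 120
        conf = ConfoundRecord(np.zeros((t, 6)) + rng.standard_normal((t, 6)),
                              rng.standard_normal((t, 3)),
                              rng.standard_normal((t, 3)))
        design = build_nuisance_design(conf)
        raw = rng.standard_normal((t, 2))
        proj = design.columns @ (np.linalg.pinv(design.columns) @ raw)
        run = TimeSeriesRun(raw - proj, TR)
        out = regress_confounds(run, design)
        np.testing.assert_allclose(out.data, run.data, atol=1e-10)

    def test_length_mismatch_raises(self, rng):
        conf = ConfoundRecord(rng.standard_normal((50, 6)),
                              rng.standard_normal((50, 5)),
                              rng.standard_normal((50, 5)))
        design = build_nuisance_design(conf)
        with pytest.raises(ValueError):
            regress_confounds(_white(rng, 60), design)


class TestConcatenate:
    def test_three_runs_stacked_and_segmentwise_demeaned(self, rng):
        runs = [_white(rng, 795, 4) for _ in range(3)]
        out = demean_and_concatenate(runs)
        assert out.shape == (2385, 4)
        for k in range(3):
            seg = out[k * 795:(k + 1) * 795]
            np.testing.assert_allclose(seg.mean(axis=0), 0.0, atol=1e-12)

    def test_single_run_demeaned_copy(self, rng):
        run = _white(rng, 50, 2)
        out = demean_and_concatenate([run])
        np.testing.assert_allclose(out, run.data - run.data.mean(0), atol=1e-12)

    def test_point_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            demean_and_concatenate([_white(rng, 50, 2), _white(rng, 50, 3)])


class TestGroupPCA:
    def test_full_rank_reconstruction_lossless(self, rng):
        x = rng.standard_normal((40, 6))
        x -= x.mean(axis=0)
        y = group_pca_reduce([x], n_components=6)
        np.testing.assert_allclose(y.T @ y, x.T @ x, atol=1e-8)

    def test_duplicated_subject_leaves_subspace_unchanged(self, rng):
        from scipy.linalg import subspace_angles
        x = rng.standard_normal((30, 8))
        one = group_pca_reduce([x], 3)
        two = group_pca_reduce([x, x], 3)
        assert subspace_angles(one.T, two.T).max() < 1e-8

    def test_matches_direct_eigendecomposition(self, rng):
        from scipy.linalg import subspace_angles
        subjects = [rng.standard_normal((30, 8)) for _ in range(3)]
        reduced = group_pca_reduce(subjects, 4)
        stack = np.vstack(subjects)
        w, v = np.linalg.eigh(stack.T @ stack)  # direct oracle
        top = v[:, np.argsort(w)[::-1][:4]]
        assert subspace_angles(reduced.T, top).max() < 1e-6

    def test_too_many_components_raises(self, rng):
        with pytest.raises(ValueError):
            group_pca_reduce([rng.standard_normal((10, 4))], 5)
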