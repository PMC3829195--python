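"""Percentile ROIs, trace extraction/resampling and cross-location correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import vsdcontext as v
from vsdcontext.timecourse import DegenerateRoiError, percentile_threshold


def profile_from(values, cond="A1"):
    return v.ActivityProfile(values=np.asarray(values, dtype=float),
                             condition=cond, window_ms=(0.0, 750.0))


class TestDefineRoi:
    def test_documented_percentile_boundary_case(self):
        # 100 pixels valued 1..100 at pct=95 -> pixels 95..100 (6, inclusive)
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        thr = percentile_threshold(vals, 95)
        assert thr == 95.0
        other = np.zeros((10, 10))
        other[0, 0] = 1.0  # distinct, non-overlapping second profile
        roi = v.define_roi(profile_from(vals), profile_from(other, "B1"), pct=95)
        assert roi.mask_A.sum() == 6
        assert set(vals[roi.mask_A]) == {95, 96, 97, 98, 99, 100}

    @given(hnp.arrays(np.float64, (12, 12), elements=st.floats(-1, 1, width=32)))
    @settings(max_examples=40, deadline=None)
    def test_matches_sort_based_oracle(self, vals):
        if np.ptp(vals) == 0:
            return
        thr = percentile_threshold(vals, 95)
        flat = np.sort(vals.ravel())
        brute = flat[int(np.floor((flat.size - 1) * 0.95))]
        assert thr == brute
        mask = vals >= thr
        assert mask.sum() == (vals >= brute).sum() > 0

    def test_constant_profile_rejected(self):
        with pytest.raises(DegenerateRoiError):
            v.define_roi(profile_from(np.ones((8, 8))), profile_from(np.zeros((8, 8))))

    def test_masks_non_overlapping_and_nonempty(self, experiment):
        for roi in experiment.roi.values():
            assert not (roi.mask_A & roi.mask_B).any()
            assert roi.mask_A.any() and roi.mask_B.any()

    def test_mask_centroids_near_spot_centers(self, noiseless_experiment):
        # centroid of the top tail of a sampled Gaussian sits at its center
        ds, _, cfg = noiseless_experiment
        roi = v.define_roi(v.time_average(ds, "A1", (0, cfg.analysis_ms)),
                           v.time_average(ds, "B1", (0, cfg.analysis_ms)))
        for mask, center in ((roi.mask_A, cfg.centerA), (roi.mask_B, cfg.centerB)):
            rr, cc = np.nonzero(mask)
            assert np.hypot(rr.mean() - center[0], cc.mean() - center[1]) <= 2.0

    def test_overlapping_peaks_assigned_to_larger_value(self):
        a = np.zeros((6, 6))
        b = np.zeros((6, 6))
        a[2, 2], a[2, 3] = 10.0, 4.0
        b[2, 3], b[3, 3] = 10.0, 4.0
        roi = v.define_roi(profile_from(a), profile_from(b, "B1"), pct=90)
        assert roi.mask_A[2, 2] and not roi.mask_B[2, 2]
        assert roi.mask_B[2, 3] and not roi.mask_A[2, 3]


class TestRoiTrace:
    def _dataset(self, data, ys=2, xs=2, rate=200.0, prestim=0):
        return v.EvokedDataset(data=data, ys=ys, xs=xs, frame_rate_hz=rate,
                               prestim_samples=prestim, cond_map={"A1": 0})

    def test_single_pixel_mask_returns_that_trace(self, rng):
        data = rng.normal(size=(4, 30, 1))
        ds = self._dataset(data)
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True  # column-major index 1
        _, trace = v.roi_trace(ds, "A1", mask, rate_out=200.0)
        np.testing.assert_allclose(trace, data[1, :, 0])

    def test_spatially_constant_frames_independent_of_mask(self, rng):
        values = rng.normal(size=30)
        data = np.tile(values, (4, 1))[:, :, None]
        ds = self._dataset(data)
        mask = np.array([[True, False], [True, True]])
        _, trace = v.roi_trace(ds, "A1", mask, rate_out=200.0)
        np.testing.assert_allclose(trace, values)

    def test_resampling_preserves_sinusoid_amplitude(self):
        # 5 Hz sinusoid, 220 -> 200 Hz, amplitude within 1%
        t = np.arange(0, 2.0, 1 / 220.0)
        trace = np.sin(2 * np.pi * 5.0 * t)
        _, out = v.resample_trace(trace, 220.0, 200.0)
        assert out.max() == pytest.approx(1.0, abs=0.01)
        assert out.min() == pytest.approx(-1.0, abs=0.01)

    def test_empty_mask_rejected(self, rng):
        ds = self._dataset(rng.normal(size=(4, 10, 1)))
        with pytest.raises(DegenerateRoiError):
            v.roi_trace(ds, "A1", np.zeros((2, 2), dtype=bool))


class TestTypeTraces:
    def test_noiseless_coherent_dominates_direct(self, noiseless_experiment):
        ds, _, cfg = noiseless_experiment
        roi = v.define_roi(v.time_average(ds, "A1", (0, cfg.analysis_ms)),
                           v.time_average(ds, "B1", (0, cfg.analysis_ms)))
        traces = v.type_traces(ds, roi)
        stim = traces.times_ms >= 0
        # facilitation gain > 1: coherent >= direct at every stimulus bin
        assert np.all(traces.median["coherent"][stim] >= traces.median["direct"][stim] - 1e-12)

    def test_identical_inputs_give_zero_difference(self, rng):
        data = rng.normal(size=(16, 40, 10)) * 1e-4
        data[:, :, :] = data[:, :, [0] * 10]  # all conditions identical
        ds = v.EvokedDataset(data=data, ys=4, xs=4, frame_rate_hz=200.0, prestim_samples=5)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        mask2 = np.zeros((4, 4), dtype=bool)
        mask2[2, 2] = True
        roi = v.RoiPair(mask_A=mask, mask_B=mask2, source_conditions=("A1", "B1"))
        traces = v.type_traces(ds, roi)
        np.testing.assert_allclose(traces.diff_median["coherent_minus_direct"], 0.0, atol=1e-15)
        np.testing.assert_allclose(traces.diff_median["coherent_minus_incoherent"], 0.0, atol=1e-15)

    def test_missing_condition_rejected(self, rng):
        ds = v.EvokedDataset(data=rng.normal(size=(16, 10, 3)), ys=4, xs=4,
                             cond_map={"A1": 0, "B1": 1, "A1B1": 2})
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        roi = v.RoiPair(mask_A=mask, mask_B=~mask, source_conditions=("A1", "B1"))
        with pytest.raises(ValueError, match="missing"):
            v.type_traces(ds, roi)


class TestTimecourseCorrelations:
    def test_full_coherence_noiseless_r_single_is_one(self):
        cfg = v.SyntheticConfig.small(seed=13, drive_coh=1.0, noise_sd=0.0, n_trials=2)
        stacks, _ = v.generate_experiment(cfg)
        ds = v.preprocess_experiment(stacks, ys=cfg.ys, xs=cfg.xs)
        roi = v.define_roi(v.time_average(ds, "A1", (0, cfg.analysis_ms)),
                           v.time_average(ds, "B1", (0, cfg.analysis_ms)))
        corr = v.timecourse_correlations(ds, roi)
        assert corr.loc[corr["movie"] == 1, "r_single"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_independent_drives_uncoupled_r_incoherent_near_zero(self):
        cfg = v.SyntheticConfig.small(seed=13, drive_coh=0.0, pair_coupling_frac=0.0,
                                      noise_sd=0.0, n_trials=2)
        stacks, _ = v.generate_experiment(cfg)
        ds = v.preprocess_experiment(stacks, ys=cfg.ys, xs=cfg.xs)
        roi = v.define_roi(v.time_average(ds, "A1", (0, cfg.analysis_ms)),
                           v.time_average(ds, "B1", (0, cfg.analysis_ms)))
        corr = v.timecourse_correlations(ds, roi)
        assert abs(corr.loc[corr["movie"] == 1, "r_incoherent"].iloc[0]) < 0.25

    def test_correlations_invariant_to_affine_trace_rescaling(self, experiment):
        ds = experiment.dataset
        scaled = v.EvokedDataset(
            data=ds.data * 3.7 + 0.002, ys=ds.ys, xs=ds.xs,
            frame_rate_hz=ds.frame_rate_hz, prestim_samples=ds.prestim_samples,
            cond_map=dict(ds.cond_map),
        )
        r0 = v.timecourse_correlations(ds, experiment.roi[1])
        r1 = v.timecourse_correlations(scaled, experiment.roi[1])
        np.testing.assert_allclose(r1[["r_single", "r_coherent", "r_incoherent"]],
                                   r0[["r_single", "r_coherent", "r_incoherent"]], atol=1e-12)
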