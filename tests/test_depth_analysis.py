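import numpy as np
import pytest

import laminarsim as ls
from conftest import gaussian_voxel_mean_oracle


def _sample(patch, field, voxel=0.75, offset=(0.0, 0.0), snr=float("inf"), seed=None):
    g = ls.place_grid(patch, voxel, offset_mm=offset) if offset is not None else ls.place_grid(
        patch, voxel, jitter_seed=seed
    )
    return ls.measure(field, patch, g, snr, seed=seed)


class TestUpsampleAndBin:
    def test_constant_field_gives_flat_profile(self, flat_patch):
        s = _sample(flat_patch, ls.ConstantField(3.0))
        prof = ls.upsample_and_bin(s, flat_patch, 21)
        assert not prof.has_missing()
        assert np.allclose(prof.values, 3.0, atol=1e-9)

    def test_single_bin_is_overall_gm_mean(self, flat_patch):
        s = _sample(flat_patch, ls.induced_psf())
        prof = ls.upsample_and_bin(s, flat_patch, 1)
        assert prof.n_depths == 1
        assert np.isfinite(prof.values[0])

    def test_profile_orientation_and_bin_centres(self, flat_patch):
        s = _sample(flat_patch, ls.induced_psf())
        prof = ls.upsample_and_bin(s, flat_patch, 21)
        assert prof.depths[0] == pytest.approx(0.5 / 21)  # index 0 = CSFB
        assert np.all(np.diff(prof.depths) > 0)

    def test_mid_depth_psf_peaks_mid_profile(self, flat_patch):
        s = _sample(flat_patch, ls.induced_psf(0.5, 0.2, 1.0))
        prof = ls.upsample_and_bin(s, flat_patch, 21)
        assert abs(int(np.nanargmax(prof.values)) - 10) <= 1

    def test_jitter_average_matches_boxcar_convolution(self, flat_patch):
        # oracle: Gaussian x 0.75 mm boxcar closed form at bin centres;
        # averaging many jittered reconstructions approaches it
        psf = ls.induced_psf(0.5, 0.2, 1.0)
        meas = ls.VoxelMeasurer(flat_patch, psf)
        n_off, nd = 60, 21
        acc = np.zeros(nd)
        for k in range(n_off):
            g = ls.place_grid(flat_patch, 0.75, offset_mm=(0.0, 0.75 * (k + 0.5) / n_off))
            prof = ls.upsample_and_bin(meas.sample(g, float("inf")), flat_patch, nd)
            acc += prof.values
        mean_prof = acc / n_off
        sigma_mm = psf.sigma * 3.0
        centres_mm = 3.0 * (1.0 - (np.arange(nd) + 0.5) / nd)
        oracle = np.array(
            [
                gaussian_voxel_mean_oracle(1.5, sigma_mm, 1.0, c - 0.375, c + 0.375)
                for c in centres_mm
            ]
        )
        # upsampling adds interpolation smoothing on top of the voxel boxcar,
        # so agreement is approximate: same peak bin, unimodal, similar scale
        assert np.corrcoef(mean_prof, oracle)[0, 1] > 0.95
        assert int(np.argmax(mean_prof)) == int(np.argmax(oracle)) == nd // 2
        rising, falling = np.diff(mean_prof[: nd // 2]), np.diff(mean_prof[nd // 2 :])
        assert np.all(rising > 0) and np.all(falling < 0)
        # smoothing broadens (never amplifies) the peak but conserves area
        assert 0.5 * oracle.max() < mean_prof.max() <= oracle.max()
        assert mean_prof.mean() == pytest.approx(oracle.mean(), rel=0.1)

    def test_empty_bins_flagged_as_missing(self, flat_patch):
        s = _sample(flat_patch, ls.induced_psf(), voxel=0.75)
        prof = ls.upsample_and_bin(s, flat_patch, 400, upsample_factor=2)
        assert prof.has_missing()
        assert np.isnan(prof.values[~(prof.n_samples > 0)]).all()

    def test_no_gm_voxels_rejected(self, flat_patch):
        import dataclasses

        s = _sample(flat_patch, ls.induced_psf())
        all_csf = dataclasses.replace(
            s, centroid_tissue=np.zeros_like(s.centroid_tissue)
        )
        with pytest.raises(ValueError):
            ls.upsample_and_bin(all_csf, flat_patch, 21)
        with pytest.raises(ValueError):
            ls.upsample_and_bin(s, flat_patch, 21, col_range=(5, 2))
        with pytest.raises(ValueError):
            ls.upsample_and_bin(s, flat_patch, 0)

    def test_tangential_translation_invariance_on_flat_patch(self, flat_patch):
        a = _sample(flat_patch, ls.induced_psf(), offset=(0.0, 0.2))
        b = _sample(flat_patch, ls.induced_psf(), offset=(0.33, 0.2))
        pa = ls.upsample_and_bin(a, flat_patch, 21, col_range=(2, 10))
        pb = ls.upsample_and_bin(b, flat_patch, 21, col_range=(2, 10))
        assert np.allclose(pa.values, pb.values, rtol=1e-6)


class TestCentroidSortProfile:
    def test_half_open_binning_at_exact_half(self, flat_patch):
        g = ls.place_grid(flat_patch, 0.75, offset_mm=(0.0, 0.625))
        s = ls.measure(ls.ConstantField(1.0), flat_patch, g, float("inf"))
        d = s.centroid_depth[s.gm_mask()]
        assert np.any(np.isclose(d, 0.5))
        prof = ls.centroid_sort_profile(s, 2)
        assert prof.n_samples[1] >= 1  # d = 0.5 falls in the second bin

    def test_four_row_grid_matches_erf_oracle(self, fine_flat_patch):
        psf = ls.induced_psf(0.5, 0.2, 1.0)
        g = ls.place_grid(fine_flat_patch, 0.75, offset_mm=(0.0, 0.0))
        s = ls.measure(psf, fine_flat_patch, g, float("inf"))
        prof = ls.centroid_sort_profile(s, 4)
        ye = g.y_edges()
        gm_rows = np.nonzero(s.gm_mask()[:, 0])[0]
        sigma_mm = psf.sigma * 3.0
        oracle = [
            gaussian_voxel_mean_oracle(1.5, sigma_mm, 1.0, ye[i], ye[i + 1])
            for i in gm_rows
        ]
        # rows are ordered WM->CSF in y; profile is ordered CSFB->WMB
        assert np.allclose(prof.values, oracle[::-1], rtol=1e-6)

    def test_sparse_voxels_leave_missing_bins(self, flat_patch):
        g = ls.place_grid(flat_patch, 0.75, offset_mm=(0.0, 0.0))
        s = ls.measure(ls.ConstantField(2.0), flat_patch, g, float("inf"))
        prof = ls.centroid_sort_profile(s, 50)
        assert prof.has_missing()
        filled = prof.n_samples > 0
        assert np.allclose(prof.values[filled], 2.0)

    def test_agrees_with_upsample_for_binwidth_voxels(self, flat_patch):
        # voxel size == bin width and voxel rows aligned to the bin edges:
        # without interpolation the two estimators coincide
        s = _sample(flat_patch, ls.induced_psf(), offset=(0.0, 0.25))
        a = ls.centroid_sort_profile(s, 4)
        b = ls.upsample_and_bin(s, flat_patch, 4, upsample_factor=1)
        assert np.allclose(a.values, b.values, rtol=1e-9)


class TestWindowExtraction:
    def _make(self, depth_gain=(3.0, 1.0), undershoot=0.35):
        m = ls.TimecourseModel(
            trial_amplitude_sd=0.0,
            undershoot_ratio=undershoot,
            depth_gain_csf=depth_gain[0],
            depth_gain_wm=depth_gain[1],
        )
        depths = (np.arange(30) + 0.5) / 30
        tc = m.depth_gain(depths)[:, None] * m.response()[None, :]
        return m, depths, tc

    def test_boxcar_response_recovers_amplitude(self):
        m = ls.TimecourseModel()
        t = m.times()
        amp = 1.7
        box = amp * ((t >= m.stimulus_onset_s) & (t <= m.stimulus_onset_s + m.stimulus_duration_s))
        tc = np.tile(box, (5, 1))
        pos, und = ls.extract_positive_and_undershoot(
            tc, t, (np.arange(5) + 0.5) / 5, m.stimulus_onset_s, m.stimulus_duration_s
        )
        assert np.allclose(pos.values, amp)
        assert np.allclose(und.values, 0.0)

    def test_undershoot_profile_negative_when_modelled(self):
        m, depths, tc = self._make()
        _, und = ls.extract_positive_and_undershoot(
            tc, m.times(), depths, m.stimulus_onset_s, m.stimulus_duration_s
        )
        assert np.all(und.values < 0)

    def test_positive_profile_monotone_toward_csfb(self):
        m, depths, tc = self._make()
        pos, _ = ls.extract_positive_and_undershoot(
            tc, m.times(), depths, m.stimulus_onset_s, m.stimulus_duration_s
        )
        assert np.all(np.diff(pos.values) < 0)

    def test_window_outside_range_rejected(self):
        m, depths, tc = self._make()
        with pytest.raises(ValueError):
            ls.extract_positive_and_undershoot(
                tc, m.times(), depths, m.stimulus_onset_s, 100.0
            )


class TestNormalizeProfile:
    def _profile(self, values):
        v = np.asarray(values, dtype=float)
        return ls.DepthProfile(depths=(np.arange(v.size) + 0.5) / v.size, values=v)

    def test_peak_mode(self):
        out = ls.normalize_profile(self._profile([2.0, 4.0]), "peak")
        assert np.allclose(out.values, [0.5, 1.0])
        assert out.normalization == "peak"

    def test_unit_area_idempotent(self):
        prof = self._profile(np.exp(-((np.linspace(0, 1, 21) - 0.5) ** 2) / 0.02))
        once = ls.normalize_profile(prof, "unit_area")
        twice = ls.normalize_profile(once, "unit_area")
        assert np.allclose(once.values, twice.values, rtol=1e-12)

    def test_unit_area_trapezoid_is_one(self):
        d = (np.arange(21) + 0.5) / 21
        prof = ls.DepthProfile(depths=d, values=np.exp(-((d - 0.5) ** 2) / 0.01))
        out = ls.normalize_profile(prof, "unit_area")
        assert np.trapezoid(out.values, out.depths) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_peak_rejected(self):
        with pytest.raises(ValueError):
            ls.normalize_profile(self._profile([0.0, 0.0, 0.0]), "peak")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ls.normalize_profile(self._profile([1.0, 2.0]), "zscore")


def test_depth_profile_tsv_round_trip(tmp_path):
    prof = ls.DepthProfile(
        depths=(np.arange(5) + 0.5) / 5,
        values=np.array([1.0, np.nan, 3.0, 2.0, 0.5]),
        n_samples=np.array([4, 0, 2, 9, 1]),
        normalization="none",
    )
    path = tmp_path / "prof.tsv"
    prof.to_tsv(path)
    back = ls.DepthProfile.from_tsv(path)
    assert np.allclose(back.depths, prof.depths)
    assert np.allclose(back.values, prof.values, equal_nan=True)
    assert back.normalization == "none"
    assert np.array_equal(back.n_samples, prof.n_samples)
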