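"""Phantom geometry, platform surrogates and scan simulation."""

import numpy as np
import pytest

from radrobust import phantom_synth as ph


@pytest.fixture(scope="module")
def spec():
    return ph.default_phantom_spec()


def _quiet_platform(noise_sd=1e-12, fwhm=0.0, bias=0.0, dev=0.0):
    return ph.PlatformModel(
        platform_id=1, scanner_type="dsDECT",
        hu_bias={t: bias for t in ph.IMAGE_TYPES},
        hu_insert_deviation={(t, i): dev for t in ph.IMAGE_TYPES
                             for i in range(1, 17)},
        noise_sd={t: noise_sd for t in ph.IMAGE_TYPES},
        kernel_fwhm_px=fwhm)


class TestPhantomSpec:
    def test_layout_counts(self, spec):
        assert len(spec.inserts) == 16
        kinds = [i.kind for i in spec.inserts]
        assert kinds.count("iodine") == 5
        assert kinds.count("density_rod") == 11
        assert spec.disk_diameter_mm == 330.0
        assert spec.insert_diameter_mm == 28.0

    def test_nominal_value_ranges(self, spec):
        for ins in spec.inserts:
            if ins.kind == "iodine":
                assert 2.0 <= ins.nominal_value <= 15.0
            else:
                assert 0.44 <= ins.nominal_value <= 1.69

    def test_inserts_disjoint_and_inside_disk(self, spec):
        centers = np.array([i.center_xy for i in spec.inserts])
        r = np.hypot(centers[:, 0], centers[:, 1])
        assert np.all(r + 14.0 <= 165.0 + 1e-9)
        d = np.hypot(centers[:, None, 0] - centers[None, :, 0],
                     centers[:, None, 1] - centers[None, :, 1])
        np.fill_diagonal(d, np.inf)
        assert d.min() > 28.0

    def test_validate_rejects_wrong_count(self, spec):
        bad = ph.PhantomSpec(inserts=spec.inserts[:15])
        with pytest.raises(ValueError, match="16 inserts"):
            bad.validate()


class TestPlatformModels:
    def test_reference_platform_is_neutral(self):
        models = ph.default_platform_models(2, seed=1, spread_hu=15.0)
        ref = models[0]
        assert all(v == 0.0 for v in ref.hu_bias.values())
        assert all(v == 0.0 for v in ref.hu_insert_deviation.values())

    def test_zero_spread_zero_bias_gives_identical_platforms(self):
        models = ph.default_platform_models(10, seed=7, spread_hu=0.0,
                                            bias_sd_hu=0.0, kernel_jitter=0.0)
        for m in models:
            assert all(v == 0.0 for v in m.hu_insert_deviation.values())
            assert all(v == 0.0 for v in m.hu_bias.values())
            assert m.kernel_fwhm_px == models[0].kernel_fwhm_px

    def test_deterministic_in_seed(self):
        a = ph.default_platform_models(10, seed=7, spread_hu=15.0)
        b = ph.default_platform_models(10, seed=7, spread_hu=15.0)
        for ma, mb in zip(a, b):
            assert ma.hu_insert_deviation == mb.hu_insert_deviation
            assert ma.hu_bias == mb.hu_bias

    def test_vue_spread_exceeds_vmi_spread(self):
        models = ph.default_platform_models(10, seed=3, spread_hu=15.0,
                                            vue_spread_factor=2.0)
        vue = [v for m in models[1:] for (t, _), v in m.hu_insert_deviation.items()
               if t == ph.VUE]
        vmi = [v for m in models[1:] for (t, _), v in m.hu_insert_deviation.items()
               if t == ph.VMI70KEV]
        assert np.std(vue) > np.std(vmi)

    def test_too_few_platforms_rejected(self):
        with pytest.raises(ValueError):
            ph.default_platform_models(1, seed=0, spread_hu=10.0)

    def test_scanner_type_assignment(self):
        models = ph.default_platform_models(10, seed=0, spread_hu=5.0)
        types = [m.scanner_type for m in models]
        assert types == ["dsDECT"] * 6 + ["rsDECT"] * 3 + ["dlDECT"]


class TestSimulateScan:
    def test_noiseless_rasterization_is_exact(self, spec):
        plat = _quiet_platform(bias=5.0, dev=2.0)
        img = ph.rasterize(spec, plat, ph.VMI70KEV)
        half = (ph.MATRIX_SIZE - 1) / 2.0
        for ins in spec.inserts:
            r = int(round(half + ins.center_xy[1] / ph.PIXEL_SPACING_MM))
            c = int(round(half + ins.center_xy[0] / ph.PIXEL_SPACING_MM))
            expected = ins.reference_hu[ph.VMI70KEV] + 5.0 + 2.0
            assert img[r, c] == expected
        assert img[0, 0] == ph.AIR_HU
        assert img[int(half), int(half)] == 5.0  # water background + bias

    def test_unknown_image_type_rejected(self, spec):
        with pytest.raises(ValueError, match="image type"):
            ph.rasterize(spec, _quiet_platform(), "VMI40keV")

    def test_deterministic_given_seed(self, spec):
        plat = ph.default_platform_models(2, seed=0, spread_hu=10.0)[1]
        a = ph.simulate_scan(spec, plat, ph.VUE, 2, seed=123)
        b = ph.simulate_scan(spec, plat, ph.VUE, 2, seed=123)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.applied_shift_px == b.applied_shift_px

    def test_repeat_shift_bounds_and_repeat1_unshifted(self, spec):
        plat = _quiet_platform()
        s1 = ph.simulate_scan(spec, plat, ph.VUE, 1, seed=5)
        s2 = ph.simulate_scan(spec, plat, ph.VUE, 2, seed=5)
        assert s1.applied_shift_px == (0.0, 0.0)
        assert all(abs(v) <= 3.0 for v in s2.applied_shift_px)

    def test_shift_bookkeeping_recenters_insert_centroid(self, spec):
        # noiseless case: centroid of the densest insert must move by the
        # recorded shift, to sub-pixel accuracy
        plat = _quiet_platform()
        s1 = ph.simulate_scan(spec, plat, ph.VMI70KEV, 1, seed=11)
        s2 = ph.simulate_scan(spec, plat, ph.VMI70KEV, 2, seed=11)
        dx, dy = s2.applied_shift_px

        def centroid(img):
            rr, cc = np.where(img > 900.0)
            return rr.mean(), cc.mean()

        r1, c1 = centroid(s1.pixels)
        r2, c2 = centroid(s2.pixels)
        assert abs((r2 - dy) - r1) < 0.5
        assert abs((c2 - dx) - c1) < 0.5

    def test_roi_mean_sampling_error_matches_analytic(self, spec):
        # repeat-2 ROI mean differs from repeat 1 by less than 3 standard
        # errors of the mean over a 529-pixel ROI (no smoothing)
        plat = _quiet_platform(noise_sd=10.0)
        ins = spec.inserts[0]
        half = (ph.MATRIX_SIZE - 1) / 2.0
        diffs = []
        for seed in range(20):
            s1 = ph.simulate_scan(spec, plat, ph.VUE, 1, seed=2 * seed)
            s2 = ph.simulate_scan(spec, plat, ph.VUE, 2, seed=2 * seed + 1)
            r1 = int(round(half + ins.center_xy[1] / ph.PIXEL_SPACING_MM))
            c1 = int(round(half + ins.center_xy[0] / ph.PIXEL_SPACING_MM))
            r2 = int(round(r1 + s2.applied_shift_px[1]))
            c2 = int(round(c1 + s2.applied_shift_px[0]))
            m1 = s1.pixels[r1 - 6:r1 + 7, c1 - 6:c1 + 7].mean()
            m2 = s2.pixels[r2 - 6:r2 + 7, c2 - 6:c2 + 7].mean()
            diffs.append(m2 - m1)
        # each mean has SE = 10/sqrt(169); the difference has sqrt(2) of that
        se_diff = np.sqrt(2.0) * 10.0 / np.sqrt(169)
        assert np.std(diffs) < 2.0 * se_diff
        assert abs(np.mean(diffs)) < 3.0 * se_diff / np.sqrt(len(diffs)) + 0.5

    @pytest.mark.parametrize("fwhm", [0.0, 2.0, 4.0])
    def test_roi_mean_unbiased_and_sd_scales(self, spec, fwhm):
        # ROI-mean estimator: unbiased for the analytic HU; its SD is
        # noise_sd*c/sqrt(N) with c <= 1 shrinking as smoothing grows
        plat = _quiet_platform(noise_sd=10.0, fwhm=fwhm)
        ins = spec.inserts[3]
        half = (ph.MATRIX_SIZE - 1) / 2.0
        r0 = int(round(half + ins.center_xy[1] / ph.PIXEL_SPACING_MM))
        c0 = int(round(half + ins.center_xy[0] / ph.PIXEL_SPACING_MM))
        means = []
        for seed in range(200):
            s = ph.simulate_scan(spec, plat, ph.VUE, 1, seed=seed)
            means.append(s.pixels[r0 - 6:r0 + 7, c0 - 6:c0 + 7].mean())
        means = np.array(means)
        analytic = ins.reference_hu[ph.VUE]
        assert abs(means.mean() - analytic) < 0.5
        c = means.std(ddof=1) * np.sqrt(169) / 10.0
        if fwhm == 0.0:
            assert abs(c - 1.0) < 0.2
        else:
            assert c < 1.0
        TestSimulateScan._c_by_fwhm[fwhm] = c

    _c_by_fwhm: dict = {}

    def test_correlation_factor_decreases_with_smoothing(self):
        c = TestSimulateScan._c_by_fwhm
        assert set(c) == {0.0, 2.0, 4.0}
        assert c[0.0] > c[2.0] > c[4.0]


class TestSimulateStudy:
    def test_factorial_counts(self, spec, tmp_path):
        plats = ph.default_platform_models(2, seed=1, spread_hu=5.0)
        manifest, scans = ph.simulate_study(spec, plats, [ph.VUE], 2, seed=9)
        assert len(manifest) == len(scans) == 4
        manifest2, _ = ph.simulate_study(spec, plats, ph.IMAGE_TYPES, 2, seed=9)
        assert len(manifest2) == 8
        assert manifest2["file_path"].is_unique

    def test_single_repeat_rejected(self, spec):
        plats = ph.default_platform_models(2, seed=1, spread_hu=5.0)
        with pytest.raises(ValueError, match="n_repeats"):
            ph.simulate_study(spec, plats, [ph.VUE], 1, seed=0)

    def test_written_images_byte_identical_across_runs(self, spec, tmp_path):
        plats = ph.default_platform_models(2, seed=1, spread_hu=5.0)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1, _ = ph.simulate_study(spec, plats, [ph.VUE], 2, seed=77, out_dir=d1)
        m2, _ = ph.simulate_study(spec, plats, [ph.VUE], 2, seed=77, out_dir=d2)
        for f in m1["file_path"]:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes()
        assert (d1 / "manifest.csv").read_text() == (d2 / "manifest.csv").read_text()

    def test_roundtrip_via_nifti(self, spec, tmp_path):
        plats = ph.default_platform_models(2, seed=1, spread_hu=5.0)
        manifest, scans = ph.simulate_study(spec, plats, [ph.VUE], 2, seed=3,
                                            out_dir=tmp_path)
        row = manifest.iloc[0]
        loaded = ph.load_scan(tmp_path / row.file_path, row.platform_id,
                              row.image_type, row.repeat_idx)
        np.testing.assert_allclose(loaded.pixels, scans[0].pixels, atol=1e-3)
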