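"""Single-case SPM: t-map variants, RFT thresholds, regions, patterns, end-to-end."""

import numpy as np
import pytest
from scipy import ndimage, stats

import plantarmap as pm
from plantarmap.spm_outliers import (
    REGION_NAMES,
    RegionGeometry,
    critical_t_rft,
    estimate_smoothness,
    expected_euler_characteristic,
    rft_threshold,
)


@pytest.fixture(scope="module")
def smoothness(model55):
    return estimate_smoothness(model55)


def domain_pixel(model, k):
    rows, cols = model.domain_indices
    return rows[k], cols[k]


class TestResidualMap:
    def test_patient_equal_to_prediction_gives_zero(self, model55):
        z = pm.Demographics(45, 1, 80, 175, 42)
        pred = pm.predict_pressures(model55, z)
        res = pm.residual_map(pred, pred, domain=model55.domain)
        assert np.all(res.data == 0)

    def test_matches_elementwise_subtraction(self, model55, rng):
        a = pm.PressureImage(rng.uniform(0, 50, model55.domain.data.shape), (3, 3))
        b = pm.PressureImage(rng.uniform(0, 50, model55.domain.data.shape), (3, 3))
        res = pm.residual_map(a, b, domain=model55.domain)
        expected = np.where(model55.domain.data, a.data - b.data, 0.0)
        np.testing.assert_array_equal(res.data, expected)

    def test_grid_mismatch_rejected(self, model55):
        a = pm.PressureImage(np.zeros((5, 5)), (3, 3))
        b = pm.PressureImage(np.zeros((6, 5)), (3, 3))
        with pytest.raises(ValueError, match="grid"):
            pm.residual_map(a, b)


class TestTMap:
    @pytest.mark.parametrize("variant", ["crawford", "naive", "literal"])
    def test_matches_scalar_formula_oracle(self, model55, rng, variant):
        resid_img = pm.PressureImage(
            rng.normal(0, 5, model55.domain.data.shape), (3, 3)
        )
        tmap = pm.t_map(resid_img, model55, pm.Demographics(45, 1, 80, 175, 42),
                        variant=variant)
        rows, cols = model55.domain_indices
        z = pm.Demographics(45, 1, 80, 175, 42).vector
        lev = float(z @ np.linalg.pinv(model55.design.T @ model55.design) @ z)
        for k in rng.choice(len(rows), 30, replace=False):
            r, c = rows[k], cols[k]
            s = model55.residual_sd[r, c]
            denom = {
                "crawford": s * np.sqrt(1 + lev),
                "naive": s,
                "literal": s / np.sqrt(model55.n_subjects),
            }[variant]
            expected = resid_img.data[r, c] / denom if denom > 0 else 0.0
            assert tmap.t[r, c] == pytest.approx(expected, abs=1e-12 * max(1, abs(expected)))

    def test_zero_residuals_give_zero_t_for_every_variant(self, model55):
        zero = pm.PressureImage(np.zeros(model55.domain.data.shape), (3, 3))
        for variant in ("crawford", "naive", "literal"):
            tmap = pm.t_map(zero, model55, pm.Demographics(45, 1, 80, 175, 42), variant)
            assert np.all(tmap.t == 0)

    def test_naive_hand_example(self, model55):
        """Single pixel with s=2 and R=4 gives t=2 under the naive variant."""
        r, c = domain_pixel(model55, 50)
        resid = np.zeros(model55.domain.data.shape)
        resid[r, c] = 4.0
        doctored_sd = model55.residual_sd.copy()
        model = pm.PixelwiseModel(
            template=model55.template, domain=model55.domain,
            coefficients=model55.coefficients, residual_sd=doctored_sd,
            residual_matrix=model55.residual_matrix, design=model55.design,
            n_subjects=model55.n_subjects,
        )
        model.residual_sd[r, c] = 2.0
        tmap = pm.t_map(pm.PressureImage(resid, (3, 3)), model,
                        pm.Demographics(45, 1, 80, 175, 42), variant="naive")
        assert tmap.t[r, c] == pytest.approx(2.0)

    def test_crawford_is_strictly_smaller_than_naive(self, model55, rng):
        resid_img = pm.PressureImage(
            rng.normal(0, 5, model55.domain.data.shape), (3, 3)
        )
        z = pm.Demographics(45, 1, 80, 175, 42)
        t_c = pm.t_map(resid_img, model55, z, "crawford").t
        t_n = pm.t_map(resid_img, model55, z, "naive").t
        nz = t_n != 0
        assert np.all(np.abs(t_c[nz]) < np.abs(t_n[nz]))

    def test_dof_is_n_minus_p(self, model55):
        zero = pm.PressureImage(np.zeros(model55.domain.data.shape), (3, 3))
        tmap = pm.t_map(zero, model55, pm.Demographics(45, 1, 80, 175, 42))
        assert tmap.dof == model55.n_subjects - 6


class TestSmoothness:
    def _model_with_residuals(self, model, residual_fields):
        rows, cols = model.domain_indices
        matrix = np.stack([f[rows, cols] for f in residual_fields])
        return pm.PixelwiseModel(
            template=model.template, domain=model.domain,
            coefficients=model.coefficients,
            residual_sd=model.residual_sd, residual_matrix=matrix,
            design=model.design, n_subjects=model.n_subjects,
        )

    def test_known_smoothness_recovered(self, model55):
        """Residual fields smoothed at FWHM=4 px are estimated within 20%."""
        rng = np.random.default_rng(1)
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        estimates = []
        for _ in range(5):
            fields = [
                ndimage.gaussian_filter(rng.normal(size=model55.domain.data.shape), sigma)
                for _ in range(model55.n_subjects)
            ]
            doctored = self._model_with_residuals(model55, fields)
            estimates.append(estimate_smoothness(doctored).fwhm)
        assert np.mean(estimates) == pytest.approx(4.0, rel=0.2)

    def test_white_noise_is_near_the_lattice_floor(self, model55):
        rng = np.random.default_rng(2)
        fields = [rng.normal(size=model55.domain.data.shape)
                  for _ in range(model55.n_subjects)]
        doctored = self._model_with_residuals(model55, fields)
        assert estimate_smoothness(doctored).fwhm < 1.8

    def test_resels_scale_with_area(self, smoothness):
        assert smoothness.resels[2] == pytest.approx(
            smoothness.area_px / (smoothness.fwhm_per_axis[0] * smoothness.fwhm_per_axis[1])
        )


class TestRFTThreshold:
    def test_critical_t_monotone_in_alpha_and_resels(self):
        resels = (1.0, 10.0, 50.0)
        t_strict = critical_t_rft(49, resels, alpha=0.01)
        t_loose = critical_t_rft(49, resels, alpha=0.10)
        assert t_strict > t_loose
        t_small = critical_t_rft(49, (1.0, 5.0, 10.0), alpha=0.05)
        t_large = critical_t_rft(49, (1.0, 20.0, 200.0), alpha=0.05)
        assert t_large > t_small

    def test_expected_ec_matches_gaussian_limit(self):
        # at huge dof the t-field EC densities approach the Gaussian ones
        t = 3.0
        resels = (0.0, 0.0, 10.0)
        ec_t = expected_euler_characteristic(t, 10_000, resels)
        rho2_gauss = (4 * np.log(2)) / (2 * np.pi) ** 1.5 * t * np.exp(-t * t / 2)
        assert ec_t == pytest.approx(10.0 * rho2_gauss, rel=1e-2)

    def test_subthreshold_map_is_empty(self, model55, smoothness):
        t = np.zeros(model55.domain.data.shape)
        tmap = pm.TMap(t=t, dof=49, variant="crawford", domain=model55.domain)
        ab = rft_threshold(tmap, smoothness)
        assert ab.n_suprathreshold == 0 and ab.clusters == []

    def test_thresholding_never_creates_pixels(self, model55, smoothness, rng):
        t = np.where(model55.domain.data, rng.normal(0, 2, model55.domain.data.shape), 0)
        tmap = pm.TMap(t=t, dof=49, variant="crawford", domain=model55.domain)
        ab = rft_threshold(tmap, smoothness)
        assert np.all((ab.thresholded_t != 0) <= (t != 0))
        assert sum(c.extent for c in ab.clusters) == ab.n_suprathreshold

    def test_invalid_alpha_rejected(self, model55, smoothness):
        tmap = pm.TMap(t=np.zeros(model55.domain.data.shape), dof=49,
                       variant="crawford", domain=model55.domain)
        with pytest.raises(ValueError, match="alpha"):
            rft_threshold(tmap, smoothness, alpha=0.0)


class TestRegionMask:
    def test_blob_centers_receive_intended_labels(self, model55):
        spec = pm.CohortSpec()
        ph = spec.phenotype
        regions = pm.build_region_mask(model55.domain)
        expected = {
            "heel": "heel", "midfoot": "midfoot", "mt1": "mt1",
            "mt3": "mt2_5", "mt5": "mt2_5", "hallux": "toes", "toes2_5": "toes",
        }
        for locus, region in expected.items():
            r, c = (int(round(v)) for v in ph.blob_center_px(ph.loci[locus]))
            assert REGION_NAMES[regions.labels[r, c]] == region, locus

    def test_regions_partition_the_silhouette(self, model55):
        regions = pm.build_region_mask(model55.domain)
        assert (regions.labels > 0).sum() == model55.domain.data.sum()
        assert np.all((regions.labels > 0) == model55.domain.data)

    def test_mirroring_swaps_the_mt1_side(self, model55):
        mirrored = pm.SilhouetteMask(model55.domain.data[:, ::-1], 5.0, (3, 3))
        high = pm.build_region_mask(model55.domain, RegionGeometry(medial_side="high"))
        low = pm.build_region_mask(mirrored, RegionGeometry(medial_side="low"))
        np.testing.assert_array_equal(high.labels, low.labels[:, ::-1])

    def test_empty_silhouette_rejected(self):
        empty = pm.SilhouetteMask(np.zeros((10, 10), bool), 5.0, (3, 3))
        with pytest.raises(ValueError, match="empty"):
            pm.build_region_mask(empty)


class TestClassifyPatterns:
    def _abmap(self, model, pixels, sign):
        t = np.zeros(model.domain.data.shape)
        for r, c in pixels:
            t[r, c] = sign * 6.0
        clusters = [pm.spm_outliers.Cluster(
            pixels=np.array(pixels), sign=sign, peak_t=sign * 6.0, extent=len(pixels)
        )]
        return pm.AbnormalityMap(
            thresholded_t=t, critical_t=4.0, clusters=clusters, fwhm=4.0,
            resels=(1, 10, 50), alpha=0.05, two_sided=True, dof=49,
        )

    def _region_pixels(self, regions, name, n):
        px = np.argwhere(regions.labels == REGION_NAMES.index(name))
        return [tuple(p) for p in px[:n]]

    def test_empty_map_reports_no_abnormality(self, model55):
        regions = pm.build_region_mask(model55.domain)
        ab = pm.AbnormalityMap(
            thresholded_t=np.zeros(model55.domain.data.shape), critical_t=4.0,
            clusters=[], fwhm=4.0, resels=(1, 10, 50), alpha=0.05,
            two_sided=True, dof=49,
        )
        report = pm.classify_patterns(ab, regions)
        assert report.no_abnormality and not report.mt1_increase

    def test_positive_mt1_cluster_sets_only_mt1(self, model55):
        regions = pm.build_region_mask(model55.domain)
        ab = self._abmap(model55, self._region_pixels(regions, "mt1", 30), +1)
        report = pm.classify_patterns(ab, regions)
        assert report.mt1_increase and not report.heel_abnormal
        assert not report.no_abnormality

    def test_negative_mt1_cluster_does_not_flag_mt1(self, model55):
        """The MT1 pattern is an increase; deficits there do not count."""
        regions = pm.build_region_mask(model55.domain)
        ab = self._abmap(model55, self._region_pixels(regions, "mt1", 30), -1)
        assert not pm.classify_patterns(ab, regions).mt1_increase

    def test_negative_heel_cluster_flags_heel(self, model55):
        regions = pm.build_region_mask(model55.domain)
        ab = self._abmap(model55, self._region_pixels(regions, "heel", 30), -1)
        assert pm.classify_patterns(ab, regions).heel_abnormal

    def test_cluster_straddling_two_regions_sets_both(self, model55):
        regions = pm.build_region_mask(model55.domain)
        pixels = (self._region_pixels(regions, "heel", 6)
                  + self._region_pixels(regions, "midfoot", 6))
        ab = self._abmap(model55, pixels, +1)
        report = pm.classify_patterns(ab, regions)
        assert report.heel_abnormal and report.midfoot_increase

    def test_overlap_below_minimum_ignored(self, model55):
        regions = pm.build_region_mask(model55.domain)
        ab = self._abmap(model55, self._region_pixels(regions, "mt1", 3), +1)
        assert not pm.classify_patterns(ab, regions, min_overlap_px=4).mt1_increase


class TestAnalyzePatient:
    def test_noise_free_self_patient_is_clean(self, model55, cohort55):
        z = cohort55.demographics_records[0]
        patient = pm.simulate_patient_from_model(model55, z, seed=1, noise_scale=0.0)
        abmap, report, qc = pm.analyze_patient(patient, z, model55, align=False)
        assert abmap.n_suprathreshold == 0
        assert report.no_abnormality
        assert not qc["unreliable"]

    def test_strong_mt1_injection_detected_reliably(self, model55, cohort55):
        """A +6 SD metatarsal-1 overload is flagged in nearly every run."""
        spec = pm.CohortSpec()
        center = spec.phenotype.blob_center_px(spec.phenotype.loci["mt1"])
        rng = np.random.default_rng(31)
        hits = 0
        n_runs = 20
        for _ in range(n_runs):
            z = cohort55.demographics_records[int(rng.integers(55))]
            patient = pm.simulate_patient_from_model(model55, z, rng)
            patient, _ = pm.inject_abnormality(patient, center, 2.82, 6.0, model55)
            _, report, _ = pm.analyze_patient(patient, z, model55, align=False)
            hits += report.mt1_increase
        assert hits >= 0.9 * n_runs

    def test_negative_hallux_injection_makes_negative_cluster(self, model55, cohort55):
        spec = pm.CohortSpec()
        center = spec.phenotype.blob_center_px(spec.phenotype.loci["hallux"])
        z = cohort55.demographics_records[3]
        patient = pm.simulate_patient_from_model(model55, z, seed=9, noise_scale=0.0)
        patient, _ = pm.inject_abnormality(patient, center, 2.82, -6.0, model55)
        abmap, report, _ = pm.analyze_patient(patient, z, model55, align=False)
        assert any(c.sign < 0 for c in abmap.clusters)
        assert report.toes_abnormal

    def test_positive_t_means_measured_above_predicted(self, model55, cohort55):
        z = cohort55.demographics_records[1]
        patient = pm.simulate_patient_from_model(model55, z, seed=2, noise_scale=0.0)
        bumped = pm.PressureImage(patient.data + 10.0 * model55.domain.data,
                                  patient.spacing)
        _, _, qc = pm.analyze_patient(bumped, z, model55, align=False)
        assert np.all(qc["t_map"].t[model55.domain.data] > 0)

    def test_misaligned_patient_comes_back_aligned(self, model55, cohort55):
        z = cohort55.demographics_records[2]
        patient = pm.simulate_patient_from_model(model55, z, seed=4)
        center = (108.0, 60.0)
        pert = pm.RigidTransform2D(np.deg2rad(8), (6.0, -5.0), center)
        moved = pm.apply_transform(patient, rigid=pert)
        _, _, qc = pm.analyze_patient(moved, z, model55, align=True, seed=0)
        assert qc["alignment_dice"] > 0.95

    def test_rescaled_video_gives_identical_result(self, model55, cohort55):
        """Total-mean normalization removes global magnitude before testing."""
        z = cohort55.demographics_records[4]
        patient = pm.simulate_patient_from_model(model55, z, seed=6)
        # keep loaded samples clear of the 5 kPa contact threshold so the
        # contact set is identical before and after rescaling
        loaded = np.where(patient.data > 10.0, patient.data, 0.0)
        video = pm.PressureVideo(
            data=np.stack([0.6 * loaded, loaded], axis=2),
            spacing=patient.spacing, frequency=500.0, side="left",
        )
        from plantarmap.spm_outliers import _preprocess_video

        a = _preprocess_video(video, target_mm=3.0, tau_kpa=5.0)
        video2 = pm.PressureVideo(data=2.0 * video.data, spacing=video.spacing,
                                  frequency=500.0, side="left")
        b = _preprocess_video(video2, target_mm=3.0, tau_kpa=5.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)
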