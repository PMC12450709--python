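import math

import numpy as np
import pytest

from petsynth.preprocess import (
    GenotypeAdjustment,
    PreprocessConfig,
    PreprocessWarning,
    SmoothingSpec,
    apply_genotype_adjustment,
    fit_genotype_adjustment,
    fwhm_to_sigma,
    gaussian_smooth,
    minmax_scale_pet,
    preprocess_cohort,
    robust_scale_mri,
)
from petsynth.volumes import Cohort, Genotype, Group, Modality, PairedScan, Volume

from conftest import make_micro_cohort, make_micro_scan


def _vol(data, modality=Modality.MRI, vs=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data, dtype=np.float32), vs, modality)


class TestRobustScaling:
    def test_linear_map_between_percentiles(self):
        # 101 values 10..110 -> p1 = 11, p99 = 109 by linear interpolation
        data = np.linspace(10, 110, 101).reshape(1, 1, 101)
        out = robust_scale_mri(_vol(data))
        p1, p99 = np.percentile(data, [1, 99])
        idx = 50  # value 60
        expected = (60.0 - p1) / (p99 - p1)
        assert out.data[0, 0, idx] == pytest.approx(expected, abs=1e-6)

    def test_values_above_p99_clip_to_one(self):
        data = np.concatenate([np.linspace(10, 110, 100), [200.0]]).reshape(1, 1, 101)
        out = robust_scale_mri(_vol(data))
        assert out.data[0, 0, -1] == 1.0

    def test_constant_volume_yields_zeros_and_warns(self):
        with pytest.warns(PreprocessWarning):
            out = robust_scale_mri(_vol(np.full((3, 3, 3), 7.0)))
        assert np.all(out.data == 0)

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(0)
        once = robust_scale_mri(_vol(rng.normal(50, 20, (6, 6, 6))))
        assert once.data.min() >= 0 and once.data.max() <= 1

    def test_idempotent_when_tails_saturate_percentiles(self):
        # with >= 1% of voxels at each extreme, p1/p99 hit the extremes and a
        # second application is an exact identity
        rng = np.random.default_rng(0)
        data = rng.uniform(10, 20, 1000)
        data[:30], data[-30:] = 10.0, 20.0
        vol = _vol(data.reshape(10, 10, 10))
        once = robust_scale_mri(vol)
        twice = robust_scale_mri(once)
        assert np.allclose(twice.data, once.data, atol=1e-9)

    def test_minmax_idempotent(self):
        rng = np.random.default_rng(3)
        vol = _vol(rng.random((5, 5, 5)) * 7 + 2, Modality.PET)
        once = minmax_scale_pet(vol)
        twice = minmax_scale_pet(once)
        assert np.allclose(twice.data, once.data, atol=1e-9)


class TestMinMaxScaling:
    def test_three_point_map(self):
        data = np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3)
        out = minmax_scale_pet(_vol(data, Modality.PET))
        assert np.allclose(out.data.ravel(), [0.0, 0.5, 1.0])

    def test_identity_on_unit_interval_volume(self):
        rng = np.random.default_rng(1)
        data = rng.random((4, 4, 4))
        data.ravel()[0], data.ravel()[1] = 0.0, 1.0
        out = minmax_scale_pet(_vol(data, Modality.PET))
        assert np.allclose(out.data, data, atol=1e-6)

    def test_constant_volume_yields_zeros_and_warns(self):
        with pytest.warns(PreprocessWarning):
            out = minmax_scale_pet(_vol(np.full((3, 3, 3), 2.5), Modality.PET))
        assert np.all(out.data == 0)

    def test_out_of_mask_voxels_zeroed(self):
        data = np.arange(8, dtype=np.float32).reshape(2, 2, 2) + 1
        mask = np.zeros((2, 2, 2), dtype=np.uint8)
        mask[0] = 1
        out = minmax_scale_pet(_vol(data, Modality.PET), Volume(mask, modality=Modality.MASK))
        assert np.all(out.data[1] == 0)
        assert out.data[0].max() == 1.0


class TestGenotypeAdjustment:
    def _cohort_with_effect(self, hab_value=0.8, mab_value=0.4, shape=(3, 3, 3)):
        scans = []
        for i, (geno, val) in enumerate(
            [(Genotype.HAB, hab_value)] * 2 + [(Genotype.MAB, mab_value)] * 2
        ):
            scan = make_micro_scan(f"s{i}", 1, genotype=geno, shape=shape, seed=i)
            scans.append(
                PairedScan(
                    subject_id=scan.subject_id, session=1, group=scan.group, genotype=geno,
                    mri=scan.mri, pet=_vol(np.full(shape, val), Modality.PET), mask=scan.mask,
                )
            )
        return Cohort(scans)

    def test_closed_form_ols_on_binary_regressor(self):
        adj = fit_genotype_adjustment(self._cohort_with_effect())
        assert np.allclose(adj.per_voxel_intercept, 0.8, atol=1e-6)
        assert np.allclose(adj.per_voxel_genotype_coefficient, -0.4, atol=1e-6)

    def test_null_effect_gives_zero_coefficient(self):
        adj = fit_genotype_adjustment(self._cohort_with_effect(0.5, 0.5))
        assert np.allclose(adj.per_voxel_genotype_coefficient, 0.0, atol=1e-7)

    def test_single_genotype_subset_rejected(self):
        cohort = make_micro_cohort({"a": 1, "b": 1})
        with pytest.raises(ValueError, match="single genotype"):
            fit_genotype_adjustment(cohort)

    def test_adjustment_restores_reference_level(self):
        cohort = self._cohort_with_effect()
        adj = fit_genotype_adjustment(cohort)
        hab_scan = cohort.scans[0]
        mab_scan = cohort.scans[2]
        assert np.allclose(apply_genotype_adjustment(hab_scan, adj).pet.data, 0.8)
        # MAB voxel 0.4 with coefficient -0.4 -> 0.8
        assert np.allclose(apply_genotype_adjustment(mab_scan, adj).pet.data, 0.8, atol=1e-6)

    def test_zero_coefficient_adjustment_is_identity(self):
        scan = make_micro_scan("s1", genotype=Genotype.MAB)
        adj = GenotypeAdjustment(
            per_voxel_intercept=np.zeros(scan.pet.shape, np.float32),
            per_voxel_genotype_coefficient=np.zeros(scan.pet.shape, np.float32),
        )
        out = apply_genotype_adjustment(scan, adj)
        assert np.array_equal(out.pet.data, scan.pet.data)

    def test_refit_on_adjusted_scans_gives_zero_coefficient(self):
        rng = np.random.default_rng(4)
        shape = (4, 4, 4)
        scans = []
        for i in range(6):
            geno = Genotype.HAB if i % 2 else Genotype.MAB
            base = rng.random(shape) + (0.3 if geno is Genotype.MAB else 0.0)
            s = make_micro_scan(f"s{i}", 1, genotype=geno, shape=shape, seed=i)
            scans.append(
                PairedScan(
                    subject_id=s.subject_id, session=1, group=s.group, genotype=geno,
                    mri=s.mri, pet=_vol(base, Modality.PET), mask=s.mask,
                )
            )
        cohort = Cohort(scans)
        adj = fit_genotype_adjustment(cohort)
        adjusted = Cohort([apply_genotype_adjustment(s, adj) for s in cohort])
        refit = fit_genotype_adjustment(adjusted)
        assert np.abs(refit.per_voxel_genotype_coefficient).max() <= 1e-6


class TestSmoothing:
    def test_fwhm_to_sigma_closed_form(self):
        assert fwhm_to_sigma(4.0) == pytest.approx(4.0 / (2 * math.sqrt(2 * math.log(2))), abs=1e-9)
        assert fwhm_to_sigma(4.0) == pytest.approx(1.69864, abs=1e-5)
        assert SmoothingSpec(fwhm_mm=4.0).sigma_mm == pytest.approx(1.69864, abs=1e-5)

    def test_constant_volume_preserved(self):
        out = gaussian_smooth(_vol(np.full((10, 10, 10), 3.25)))
        assert np.allclose(out.data, 3.25, atol=1e-6)

    def test_impulse_peak_matches_directly_evaluated_kernel(self):
        spec = SmoothingSpec(fwhm_mm=4.0)
        data = np.zeros((21, 21, 21), dtype=np.float32)
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(_vol(data, vs=(1.0, 1.0, 1.0)), spec)
        # brute-force normalized 1-D kernel at integer offsets, truncated
        sigma = spec.sigma_mm
        radius = int(spec.truncation_sigmas * sigma + 0.5)
        offs = np.arange(-radius, radius + 1)
        k1d = np.exp(-0.5 * (offs / sigma) ** 2)
        k1d /= k1d.sum()
        expected_peak = float(k1d[radius] ** 3)
        assert out.data[10, 10, 10] == pytest.approx(expected_peak, rel=1e-5)

    def test_anisotropic_voxels_scale_sigma_per_axis(self):
        data = np.zeros((21, 21, 21), dtype=np.float32)
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(_vol(data, vs=(1.0, 2.0, 1.0)))
        # larger voxels -> smaller sigma in voxels -> sharper falloff along axis 1
        assert out.data[10, 11, 10] < out.data[11, 10, 10]

    def test_mean_preserved_for_interior_support(self):
        rng = np.random.default_rng(2)
        data = np.zeros((40, 40, 40), dtype=np.float32)
        data[14:26, 14:26, 14:26] = rng.random((12, 12, 12)) + 1.0
        out = gaussian_smooth(_vol(data))
        assert out.data.mean() == pytest.approx(data.mean(), rel=5e-3)


class TestPreprocessCohort:
    def test_full_chain_outputs_unit_interval(self, tiny_spec):
        from petsynth.phantom import generate_cohort

        cohort = generate_cohort(4, [1, 1, 1, 1], {"HC": 1.0}, {"HAB": 0.5, "MAB": 0.5}, tiny_spec)
        processed, adj = preprocess_cohort(cohort, PreprocessConfig())
        assert adj is not None
        for s in processed:
            assert s.mri.data.min() >= 0 and s.mri.data.max() <= 1
            assert s.pet.data.max() <= 1

    def test_single_genotype_cohort_skips_adjustment_with_warning(self):
        cohort = make_micro_cohort({"a": 1, "b": 1})
        with pytest.warns(PreprocessWarning, match="single-genotype"):
            _, adj = preprocess_cohort(cohort, PreprocessConfig())
        assert adj is None

    def test_config_json_round_trip(self):
        cfg = PreprocessConfig(fwhm_mm=6.0, order="scale_then_adjust")
        assert PreprocessConfig.from_json(cfg.to_json()) == cfg
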