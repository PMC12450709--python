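"""Metric implementations vs independent brute-force oracles, plus contracts."""
import itertools
import math

import numpy as np
import pytest

from petsynth.metrics import (
    RoiSample,
    bland_altman,
    cnr,
    draw_roi_pairs,
    evaluate_cohort,
    mann_whitney_u,
    median_cnr,
    median_split,
    mse,
    normdiff,
    pearson,
    percent_diff,
    regionwise_means,
    remove_outliers,
    subject_specificity,
)
from petsynth.phantom import PhantomSpec, generate_cohort, generate_phantom, noiseless_spec
from petsynth.volumes import Genotype, Group, Modality, Volume

RNG = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# brute-force oracles (explicit loops, no shared code with the implementation)
# ---------------------------------------------------------------------------

def brute_mse(a, b, m):
    total, count = 0.0, 0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                if m[i, j, k]:
                    d = float(a[i, j, k]) - float(b[i, j, k])
                    total += d * d
                    count += 1
    return total / count


def brute_normdiff_stats(r, t, m, eps=1e-8):
    vals = []
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            for k in range(r.shape[2]):
                denom = float(r[i, j, k]) + float(t[i, j, k])
                if m[i, j, k] and denom >= eps:
                    vals.append((float(r[i, j, k]) - float(t[i, j, k])) / denom)
    return float(np.mean(vals)), float(np.std(vals))


def brute_percent_mean(r, t, m, eps=1e-8):
    vals = []
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            for k in range(r.shape[2]):
                if m[i, j, k] and float(t[i, j, k]) >= eps:
                    vals.append(100.0 * (float(r[i, j, k]) - float(t[i, j, k])) / float(t[i, j, k]))
    return float(np.mean(vals))


def brute_cnr(x, y):
    pooled = list(x) + list(y)
    mu = sum(pooled) / len(pooled)
    var = sum((v - mu) ** 2 for v in pooled) / len(pooled)
    return (sum(x) / len(x) - sum(y) / len(y)) / math.sqrt(var)


def brute_region_means(v, lab):
    sums, counts = {}, {}
    for i in range(v.shape[0]):
        for j in range(v.shape[1]):
            for k in range(v.shape[2]):
                r = int(lab[i, j, k])
                if r > 0:
                    sums[r] = sums.get(r, 0.0) + float(v[i, j, k])
                    counts[r] = counts.get(r, 0) + 1
    return {r: sums[r] / counts[r] for r in sums}


def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def brute_bland_altman(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def brute_mann_whitney_exact(x, y):
    """Exact two-sided p by enumerating all label arrangements (no ties)."""
    combined = sorted(list(x) + list(y))
    n = len(x)

    def u_of(subset):
        xs = [combined[i] for i in subset]
        ys = [combined[i] for i in range(len(combined)) if i not in subset]
        return sum(1 for a in xs for b in ys if a > b)

    observed = sum(1 for a in x for b in y if a > b)
    us = [u_of(s) for s in itertools.combinations(range(len(combined)), n)]
    p_le = sum(1 for u in us if u <= observed) / len(us)
    p_ge = sum(1 for u in us if u >= observed) / len(us)
    return observed, min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# oracle-equivalence tests
# ---------------------------------------------------------------------------

def _random_pair(rng, shape=(5, 5, 5)):
    a = rng.random(shape)
    b = rng.random(shape)
    m = rng.random(shape) > 0.3
    m.ravel()[0] = True
    return a, b, m


class TestOracleEquivalence:
    N = 120

    def test_mse_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(self.N):
            a, b, m = _random_pair(rng)
            assert mse(a, b, m) == pytest.approx(brute_mse(a, b, m), abs=1e-10)

    def test_normdiff_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(self.N):
            a, b, m = _random_pair(rng)
            _, mean, sd = normdiff(a, b, m)
            bmean, bsd = brute_normdiff_stats(a, b, m)
            assert mean == pytest.approx(bmean, abs=1e-10)
            assert sd == pytest.approx(bsd, abs=1e-10)

    def test_percent_diff_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(self.N):
            a, b, m = _random_pair(rng)
            _, mean = percent_diff(a, b, m)
            assert mean == pytest.approx(brute_percent_mean(a, b, m), abs=1e-8)

    def test_cnr_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(self.N):
            x = rng.random(int(rng.integers(2, 30)))
            y = rng.random(int(rng.integers(2, 30)))
            assert cnr(x, y) == pytest.approx(brute_cnr(list(x), list(y)), abs=1e-10)

    def test_regionwise_means_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(self.N):
            v = rng.random((6, 6, 6))
            lab = rng.integers(0, 4, (6, 6, 6))
            if not (lab > 0).any():
                lab[0, 0, 0] = 1
            got = regionwise_means(v, lab)
            want = brute_region_means(v, lab)
            assert got.keys() == want.keys()
            for r in want:
                assert got[r] == pytest.approx(want[r], abs=1e-10)

    def test_pearson_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(self.N):
            x = rng.random(20)
            y = rng.random(20)
            r, _ = pearson(x, y)
            assert r == pytest.approx(brute_pearson(list(x), list(y)), abs=1e-12)

    def test_bland_altman_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(self.N):
            x = rng.random(15)
            y = rng.random(15)
            got = bland_altman(x, y)
            want = brute_bland_altman(list(x), list(y))
            for g, w in zip(got, want):
                assert g == pytest.approx(w, abs=1e-10)

    def test_mann_whitney_exact_matches_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(self.N):
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 6))
            # continuous draws: ties have probability zero
            x = rng.random(nx)
            y = rng.random(ny)
            u, p = mann_whitney_u(x, y)
            bu, bp = brute_mann_whitney_exact(list(x), list(y))
            assert u == pytest.approx(bu, abs=1e-10)
            assert p == pytest.approx(bp, abs=1e-10)


class TestMetricContracts:
    def test_mse_identity_and_hand_sum(self):
        assert mse(np.ones((2, 1, 1)), np.ones((2, 1, 1))) == 0.0
        a = np.array([0.0, 1.0]).reshape(2, 1, 1)
        b = np.array([1.0, 1.0]).reshape(2, 1, 1)
        assert mse(a, b) == pytest.approx(0.5)

    def test_mse_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            mse(np.ones((2, 2, 2)), np.ones((2, 2, 2)), np.zeros((2, 2, 2)))

    def test_normdiff_identity_substitution_and_bounds(self):
        r = np.full((2, 2, 2), 3.0)
        t = np.full((2, 2, 2), 3.0)
        m, mean, sd = normdiff(r, t)
        assert np.all(m == 0) and mean == 0 and sd == 0
        m2, _, _ = normdiff(np.full((1, 1, 1), 3.0), np.full((1, 1, 1), 1.0))
        assert m2[0, 0, 0] == pytest.approx(0.5)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.random((4, 4, 4)) * 10, rng.random((4, 4, 4)) * 10
            mmap, _, _ = normdiff(a, b)
            assert mmap.min() >= -1.0 and mmap.max() <= 1.0

    def test_percent_diff_examples_and_asymmetry(self):
        m, mean = percent_diff(np.full((1, 1, 1), 1.1), np.full((1, 1, 1), 1.0))
        assert mean == pytest.approx(10.0, abs=1e-9)
        _, up = percent_diff(np.full((1, 1, 1), 2.0), np.full((1, 1, 1), 1.0))
        _, down = percent_diff(np.full((1, 1, 1), 1.0), np.full((1, 1, 1), 2.0))
        assert up == pytest.approx(100.0) and down == pytest.approx(-50.0)

    def test_cnr_worked_example_and_antisymmetry(self):
        # population SD of {2,2,1,1} is 0.5 -> CNR = (2-1)/0.5 = 2
        assert cnr([2, 2], [1, 1]) == pytest.approx(2.0)
        assert cnr([1, 1], [2, 2]) == pytest.approx(-2.0)
        assert cnr([3, 4], [3, 4]) == 0.0
        rng = np.random.default_rng(1)
        x, y = rng.random(10), rng.random(12)
        assert cnr(x, y) == pytest.approx(-cnr(y, x), abs=1e-12)

    def test_cnr_constant_rois_zero(self):
        assert cnr([5.0, 5.0], [5.0, 5.0]) == 0.0

    def test_bland_altman_hand_example(self):
        # d = {1, 1, 4}: mean 2, sample SD sqrt(3)
        mean, lo, hi = bland_altman([2, 3, 8], [1, 2, 4])
        sd = math.sqrt(3)
        assert mean == pytest.approx(2.0)
        assert lo == pytest.approx(2 - 1.96 * sd, abs=1e-5)
        assert hi == pytest.approx(2 + 1.96 * sd, abs=1e-5)
        assert hi - mean == pytest.approx(mean - lo)

    def test_bland_altman_identical_measurements(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0, 0.0)

    def test_bland_altman_limits_cover_gaussian_differences(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        mean, lo, hi = bland_altman(x, y)
        d = x - y
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage >= 0.90

    def test_pearson_perfect_lines(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_median_split_examples(self):
        low, high = median_split([1, 2, 3, 4])
        assert list(low) == [1, 2] and list(high) == [3, 4]
        low, high = median_split([1, 2, 3])  # median 2, ties to Low
        assert list(low) == [1, 2] and list(high) == [3]
        low, high = median_split([5, 5, 5])
        assert len(low) == 3 and len(high) == 0

    def test_mann_whitney_small_sample_examples(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(2 / 6, abs=1e-12)
        _, p_same = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p_same == pytest.approx(1.0, abs=0.05)

    def test_mann_whitney_u_sum_identity(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.random(int(rng.integers(2, 15)))
            y = rng.random(int(rng.integers(2, 15)))
            ux, _ = mann_whitney_u(x, y)
            uy, _ = mann_whitney_u(y, x)
            assert ux + uy == pytest.approx(len(x) * len(y))

    def test_remove_outliers_examples_and_idempotence(self):
        out = remove_outliers([1, 2, 3, 100])
        assert list(out) == [1, 2, 3]
        clean = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert list(remove_outliers(clean)) == list(clean)
        # idempotent: re-applying (short inputs pass through unchanged)
        assert list(remove_outliers(out)) == list(out)
        assert list(remove_outliers(clean)) == list(remove_outliers(remove_outliers(clean)))


@pytest.fixture(scope="module")
def scan():
    return generate_phantom(PhantomSpec(shape=(24, 24, 24), seed=3), "s", 1, Group.HC, Genotype.HAB)


@pytest.fixture(scope="module")
def phantom_cohort():
    spec = PhantomSpec(shape=(20, 20, 20), n_blobs=2, blob_amplitude=1.2, noise_sd_pet=0.03, seed=13)
    return generate_cohort(5, [1, 1, 1, 1, 1], {"HC": 1.0}, {"HAB": 1.0}, spec)


class TestRoiSampling:
    def test_rois_meet_mask_and_overlap_constraints(self, scan):
        sample = RoiSample(n_samples=50, seed=4)
        pairs = draw_roi_pairs(scan.mask, sample)
        assert len(pairs) == 50
        m = scan.mask.data.astype(bool)
        for c1, c2 in pairs:
            for c in (c1, c2):
                sl = tuple(slice(a, a + s) for a, s in zip(c, sample.roi_shape))
                frac = m[sl].mean()
                assert frac >= sample.min_in_mask
            assert any(abs(a - b) >= s for a, b, s in zip(c1, c2, sample.roi_shape))

    def test_constant_volume_has_zero_median_cnr(self, scan):
        const = Volume(scan.mask.data.astype(np.float32) * 2.0, modality=Modality.PET)
        sample = RoiSample(n_samples=40, seed=1)
        assert median_cnr(const, scan.mask, sample) == 0.0

    def test_median_cnr_deterministic_given_seed(self, scan):
        sample = RoiSample(n_samples=30, seed=9)
        a = median_cnr(scan.pet, scan.mask, sample)
        b = median_cnr(scan.pet, scan.mask, sample)
        assert a == b

    def test_default_sampling_plan_matches_protocol(self):
        sample = RoiSample()
        assert sample.roi_shape == (4, 4, 3)
        assert sample.n_samples == 1000

    def test_mask_too_small_rejected(self):
        tiny_mask = np.zeros((6, 6, 6), dtype=np.uint8)
        tiny_mask[0, 0, 0] = 1
        with pytest.raises(ValueError, match="too small"):
            draw_roi_pairs(tiny_mask, RoiSample(n_samples=5, seed=0, max_tries=2000))


class TestSubjectSpecificity:
    def test_matched_lower_mse_with_distinct_blobs(self, phantom_cohort):
        clean = {}
        spec = PhantomSpec(shape=(20, 20, 20), n_blobs=2, blob_amplitude=1.2, noise_sd_pet=0.03, seed=13)
        for s in phantom_cohort:
            noiseless = generate_phantom(noiseless_spec(spec), s.subject_id, s.session, s.group, s.genotype)
            clean[s.key] = noiseless.pet
        res = subject_specificity(clean, phantom_cohort)
        assert np.mean(res.matched_mse) < np.mean(res.mismatched_mse)
        assert len(res.mismatched_mse) == len(clean) * (len(phantom_cohort.subjects) - 1)

    def test_identical_predictions_give_high_p(self, phantom_cohort):
        shared = next(iter(phantom_cohort)).pet
        preds = {s.key: shared for s in phantom_cohort}
        res = subject_specificity(preds, phantom_cohort)
        assert res.p_one_sided > 0.2

    def test_single_subject_rejected(self):
        spec = PhantomSpec(shape=(16, 16, 16), seed=1)
        cohort = generate_cohort(1, [1], {"HC": 1.0}, {"HAB": 1.0}, spec)
        preds = {s.key: s.pet for s in cohort}
        with pytest.raises(ValueError, match="2 subjects"):
            subject_specificity(preds, cohort)


class TestSmoothedTargetPattern:
    def test_smooth_predictor_prefers_smoothed_truth(self):
        """With i.i.d. voxel noise on the target, a smooth reconstruction is
        closer to the smoothed target than to the raw one: the reconstruction
        carries no voxel noise, so comparing against the smoothed target
        removes noise without introducing structure mismatch."""
        from petsynth.preprocess import SmoothingSpec, gaussian_smooth

        spec = PhantomSpec(shape=(24, 24, 24), n_blobs=0, noise_sd_pet=0.08, seed=5)
        scan = generate_phantom(spec, "s", 1, Group.HC, Genotype.HAB)
        clean = generate_phantom(noiseless_spec(spec), "s", 1, Group.HC, Genotype.HAB).pet
        smoothing = SmoothingSpec(fwhm_mm=4.0)
        pred = gaussian_smooth(clean, smoothing)  # a smooth predictor
        smoothed_truth = gaussian_smooth(scan.pet, smoothing)
        assert mse(pred, smoothed_truth, scan.mask) < mse(pred, scan.pet, scan.mask)


class TestEvaluateCohort:
    def test_report_contents_and_determinism(self):
        spec = PhantomSpec(shape=(20, 20, 20), n_blobs=1, seed=31)
        cohort = generate_cohort(3, [1, 1, 2], {"HC": 1.0}, {"HAB": 0.5, "MAB": 0.5}, spec)
        preds = {
            s.key: generate_phantom(noiseless_spec(spec), s.subject_id, s.session, s.group, s.genotype).pet
            for s in cohort
        }
        sample = RoiSample(n_samples=25, seed=2)
        rep1 = evaluate_cohort(preds, cohort, roi_sample=sample)
        rep2 = evaluate_cohort(preds, cohort, roi_sample=sample)
        assert rep1.to_json() == rep2.to_json()
        assert set(rep1.per_scan.columns) >= {
            "mse", "mse_vs_smoothed", "normdiff_mean", "normdiff_sd",
            "percdiff_mean", "median_cnr_true", "median_cnr_recon",
        }
        assert (rep1.per_scan["mse"] >= 0).all()
        assert rep1.region_table is not None
        assert len(rep1.region_table) == spec.n_regions
        assert rep1.specificity is not None
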