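"""Image-quality metrics and agreement statistics for synthesized PET volumes.

Per scan: masked MSE (against raw and smoothed truth), normalized difference
NormDiff = (recon - true) / (recon + true) (bounded in [-1, 1]), percentage
difference 100 * (recon - true) / true, and a global contrast-to-noise ratio
summarized as the median CNR over many randomly sampled ROI pairs with the
same coordinates reused across the true/reconstructed pair of a scan.

Cohort-wide: region-wise mean SUV tables, Pearson correlations with p-values,
Bland-Altman agreement (mean difference and +/- 1.96 SD limits), median-split
Low/High SUV comparisons with the Mann-Whitney U test (exact by enumeration
at small n, normal approximation with tie correction otherwise), Tukey-fence
outlier removal, and a matched-vs-mismatched subject-specificity analysis.
"""
from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import SmoothingSpec, gaussian_smooth
from .volumes import Cohort, Genotype, PairedScan, Volume, conform

__all__ = [
    "RoiSample",
    "MetricReport",
    "mse",
    "normdiff",
    "percent_diff",
    "cnr",
    "draw_roi_pairs",
    "median_cnr",
    "regionwise_means",
    "bland_altman",
    "pearson",
    "median_split",
    "mann_whitney_u",
    "remove_outliers",
    "subject_specificity",
    "evaluate_cohort",
    "benjamini_hochberg",
]

_EPS = 1e-8


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def _mask_bool(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    m = _as_array(mask).astype(bool)
    if m.shape != shape:
        raise ValueError(f"mask shape {m.shape} does not match volume shape {shape}")
    return m


# ---------------------------------------------------------------------------
# voxel-level metrics
# ---------------------------------------------------------------------------

def mse(a, b, mask=None) -> float:
    """Mean squared voxel difference within the mask."""
    a, b = _as_array(a), _as_array(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    m = _mask_bool(mask, a.shape)
    if not m.any():
        raise ValueError("empty mask")
    d = a[m].astype(np.float64) - b[m].astype(np.float64)
    return float(np.mean(d * d))


def normdiff(recon, truth, mask=None, eps: float = _EPS) -> tuple[np.ndarray, float, float]:
    """Voxelwise normalized difference (recon - true) / (recon + true).

    Voxels whose denominator is below ``eps`` are set to 0 in the map and
    excluded from the mask-restricted mean and SD. Values are bounded in
    [-1, 1] for non-negative inputs.
    """
    r, t = _as_array(recon).astype(np.float64), _as_array(truth).astype(np.float64)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    m = _mask_bool(mask, r.shape)
    denom = r + t
    valid = denom >= eps
    out = np.zeros_like(r)
    np.divide(r - t, denom, out=out, where=valid)
    sel = m & valid
    if sel.any():
        mean, sd = float(out[sel].mean()), float(out[sel].std())
    else:
        mean, sd = float("nan"), float("nan")
    return out, mean, sd


def percent_diff(recon, truth, mask=None, eps: float = _EPS) -> tuple[np.ndarray, float]:
    """Voxelwise percentage difference 100 * (recon - true) / true.

    Voxels with true value below ``eps`` are excluded (0 in the map)."""
    r, t = _as_array(recon).astype(np.float64), _as_array(truth).astype(np.float64)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    m = _mask_bool(mask, r.shape)
    valid = t >= eps
    out = np.zeros_like(r)
    np.divide(100.0 * (r - t), t, out=out, where=valid)
    sel = m & valid
    mean = float(out[sel].mean()) if sel.any() else float("nan")
    return out, mean


def cnr(
    roi1_values,
    roi2_values,
    pooling: str = "concat",
    sd: str = "population",
) -> float:
    """Contrast-to-noise ratio between two ROIs.

    (mean(ROI1) - mean(ROI2)) / std(ROI1 + ROI2), where "ROI1 + ROI2" is read
    as the concatenated voxel set by default (``pooling='concat'``); the
    alternative reading, the SD of the voxelwise sum, is available with
    ``pooling='sum'`` (requires equal lengths). ``sd`` selects population
    (ddof=0, default) or sample (ddof=1) standard deviation.
    """
    x = np.asarray(roi1_values, dtype=np.float64).ravel()
    y = np.asarray(roi2_values, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty ROI")
    ddof = 0 if sd == "population" else 1
    if pooling == "concat":
        pooled = np.concatenate([x, y])
    elif pooling == "sum":
        if x.size != y.size:
            raise ValueError("pooling='sum' requires equal ROI sizes")
        pooled = x + y
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    denom = float(pooled.std(ddof=ddof))
    num = float(x.mean() - y.mean())
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        raise FloatingPointError("zero pooled SD with unequal means")
    return num / denom


@dataclass(frozen=True)
class RoiSample:
    """Random ROI-pair sampling plan for the global CNR estimate.

    Each draw picks two box ROIs of ``roi_shape`` voxels whose corners are
    uniform over the grid, accepting a box only if at least ``min_in_mask`` of
    its voxels lie in the brain mask, and accepting the pair only if the two
    boxes do not overlap. Sampling is fully determined by (mask, seed), so
    two volumes of one scan evaluated with the same plan share coordinates.
    """

    roi_shape: tuple[int, int, int] = (4, 4, 3)
    n_samples: int = 1000
    seed: int = 0
    min_in_mask: float = 0.8
    max_tries: int = 200_000

    def __post_init__(self) -> None:
        if self.n_samples < 1 or any(s < 1 for s in self.roi_shape):
            raise ValueError("n_samples and roi_shape must be positive")
        if not 0 < self.min_in_mask <= 1:
            raise ValueError("min_in_mask must lie in (0, 1]")


def draw_roi_pairs(mask, sample: RoiSample) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Draw ``n_samples`` seeded non-overlapping ROI corner pairs inside the mask."""
    m = _as_array(mask).astype(bool)
    rs = sample.roi_shape
    if any(ms < s for ms, s in zip(m.shape, rs)):
        raise ValueError("mask grid smaller than the ROI shape")
    rng = np.random.default_rng(sample.seed)
    hi = [ms - s + 1 for ms, s in zip(m.shape, rs)]
    roi_size = int(np.prod(rs))
    need = math.ceil(sample.min_in_mask * roi_size)

    # integral image for O(1) in-mask counts per candidate box
    cum = np.pad(m.astype(np.int64), ((1, 0), (1, 0), (1, 0))).cumsum(0).cumsum(1).cumsum(2)

    def in_mask_count(c):
        x0, y0, z0 = c
        x1, y1, z1 = x0 + rs[0], y0 + rs[1], z0 + rs[2]
        return (
            cum[x1, y1, z1] - cum[x0, y1, z1] - cum[x1, y0, z1] - cum[x1, y1, z0]
            + cum[x0, y0, z1] + cum[x0, y1, z0] + cum[x1, y0, z0] - cum[x0, y0, z0]
        )

    def overlap(a, b):
        return all(abs(ai - bi) < s for ai, bi, s in zip(a, b, rs))

    pairs = []
    tries = 0
    while len(pairs) < sample.n_samples:
        if tries >= sample.max_tries:
            raise ValueError(
                "mask too small to host two disjoint ROIs meeting the in-mask constraint"
            )
        tries += 1
        c1 = tuple(int(rng.integers(0, h)) for h in hi)
        if in_mask_count(c1) < need:
            continue
        c2 = tuple(int(rng.integers(0, h)) for h in hi)
        if in_mask_count(c2) < need or overlap(c1, c2):
            continue
        pairs.append((c1, c2))
    return pairs


def _roi_values(data: np.ndarray, corner, shape) -> np.ndarray:
    sl = tuple(slice(c, c + s) for c, s in zip(corner, shape))
    return data[sl].ravel()


def median_cnr(
    volume,
    mask,
    sample: RoiSample = RoiSample(),
    pairs: Optional[Sequence] = None,
) -> float:
    """Median CNR over seeded random ROI pairs.

    Pass the ``pairs`` returned by :func:`draw_roi_pairs` to reuse identical
    coordinates across two volumes of one scan (a paired comparison); by
    default they are drawn from (mask, seed), which is itself reproducible.
    """
    data = _as_array(volume).astype(np.float64)
    if pairs is None:
        pairs = draw_roi_pairs(mask, sample)
    values = [
        cnr(_roi_values(data, c1, sample.roi_shape), _roi_values(data, c2, sample.roi_shape))
        for c1, c2 in pairs
    ]
    return float(np.median(values))


# ---------------------------------------------------------------------------
# region-level and statistical analyses
# ---------------------------------------------------------------------------

def regionwise_means(volume, labels) -> dict[int, float]:
    """Mean of the volume over each nonzero label's voxels."""
    v, lab = _as_array(volume), _as_array(labels)
    if v.shape != lab.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {lab.shape}")
    regions = np.unique(lab)
    regions = regions[regions > 0]
    if regions.size == 0:
        raise ValueError("no nonzero labels")
    return {int(r): float(v[lab == r].mean()) for r in regions}


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference and limits of agreement (mean +/- 1.96 sample SD)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean_diff, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t-transform."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def median_split(values) -> tuple[np.ndarray, np.ndarray]:
    """Split values at their median: <= median -> Low (ties to Low), > -> High."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    med = float(np.median(v))
    return v[v <= med], v[v > med]


def _mw_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x with midrank tie handling."""
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def _exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Counts of rank arrangements per U value for sample sizes n, m (no ties).

    Standard recurrence on the largest observation: it is either an x (adding
    m to U, reducing to sizes (n-1, m)) or a y (leaving U, reducing to
    (n, m-1)): f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u).
    """
    max_u = n * m
    # table[i][j] = distribution of U for sample sizes (i, j)
    prev = [np.ones(1) for _ in range(m + 1)]  # i = 0: U identically 0
    for i in range(1, n + 1):
        cur: list[np.ndarray] = [np.ones(1)]  # j = 0: U identically 0
        for j in range(1, m + 1):
            dist = np.zeros(i * j + 1)
            a = prev[j]  # f(i-1, j, u-j)
            dist[j : j + a.size] += a
            b = cur[j - 1]  # f(i, j-1, u)
            dist[: b.size] += b
            cur.append(dist)
        prev = cur
    counts = np.zeros(max_u + 1)
    counts[: prev[m].size] = prev[m]
    return counts


def mann_whitney_u(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    The U statistic uses midranks for ties. The p-value is exact (by
    enumeration of the null U distribution) when the combined sample size is
    <= ``exact_max_n`` and there are no ties; otherwise a normal approximation
    with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    n, m = x.size, y.size
    u = _mw_u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if n + m <= exact_max_n and not has_ties:
        dist = _exact_u_distribution(n, m)
        total = dist.sum()
        ui = int(round(u))
        p_le = dist[: ui + 1].sum() / total
        p_ge = dist[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, float(p)
    mu = n * m / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    nm = n + m
    var = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1.0)))
    if var == 0:
        return u, 1.0
    z = (u - mu - math.copysign(0.5, u - mu)) / math.sqrt(var) if u != mu else 0.0
    p = 2.0 * sps.norm.sf(abs(z))
    return u, float(min(1.0, p))


def mann_whitney_one_sided_less(x, y) -> tuple[float, float]:
    """One-sided Mann-Whitney: alternative 'values in x are smaller than in y'."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    res = sps.mannwhitneyu(x, y, alternative="less")
    return float(res.statistic), float(res.pvalue)


def remove_outliers(values) -> np.ndarray:
    """Drop values outside Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics. Fewer than 4
    values are returned unchanged (fences are not meaningful)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 4:
        return v
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(pvalues, dtype=np.float64).ravel()
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# subject specificity
# ---------------------------------------------------------------------------

@dataclass
class SpecificityResult:
    matched_mse: list[float]
    mismatched_mse: list[float]
    matched_normdiff: list[float]
    mismatched_normdiff: list[float]
    matched_percdiff: list[float]
    mismatched_percdiff: list[float]
    u_statistic: float
    p_one_sided: float

    def summary(self) -> dict:
        def ms(v):
            a = np.asarray(v, dtype=np.float64)
            return {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if a.size > 1 else 0.0}

        return {
            "matched": {
                "mse": ms(self.matched_mse),
                "normdiff": ms(self.matched_normdiff),
                "percdiff": ms(self.matched_percdiff),
                "n": len(self.matched_mse),
            },
            "mismatched": {
                "mse": ms(self.mismatched_mse),
                "normdiff": ms(self.mismatched_normdiff),
                "percdiff": ms(self.mismatched_percdiff),
                "n": len(self.mismatched_mse),
            },
            "mann_whitney_u": self.u_statistic,
            "p_one_sided_matched_less": self.p_one_sided,
        }


def subject_specificity(
    predictions: Mapping[tuple[str, int], Volume],
    cohort: Cohort,
) -> SpecificityResult:
    """Matched vs mismatched reconstruction similarity.

    Each prediction is compared (MSE, mean NormDiff, mean percent difference)
    against its own scan's true PET (matched) and against one representative
    true PET per other subject -- the subject's first scan in cohort order --
    (mismatched), on the intersection of the two brain masks after grid
    conformance. A one-sided Mann-Whitney test asks whether matched MSEs are
    stochastically smaller than mismatched ones.
    """
    scans = {s.key: s for s in cohort}
    rep: dict[str, PairedScan] = {}
    for s in cohort:
        rep.setdefault(s.subject_id, s)
    if len(rep) < 2:
        raise ValueError("subject specificity requires at least 2 subjects")

    res = SpecificityResult([], [], [], [], [], [], 0.0, 1.0)
    for key, pred in predictions.items():
        if key not in scans:
            raise KeyError(f"prediction key {key} not present in cohort")
        own = scans[key]

        def compare(other: PairedScan, matched: bool):
            truth, tmask = other.pet, other.mask
            if truth.shape != pred.shape:
                truth = conform(truth, pred.shape)
                tmask = conform(tmask, pred.shape)
            joint = (own.mask.data.astype(bool)) & (tmask.data.astype(bool))
            if not joint.any():
                return
            m = mse(pred, truth, joint)
            _, nd_mean, _ = normdiff(pred, truth, joint)
            _, pd_mean = percent_diff(pred, truth, joint)
            if matched:
                res.matched_mse.append(m)
                res.matched_normdiff.append(nd_mean)
                res.matched_percdiff.append(pd_mean)
            else:
                res.mismatched_mse.append(m)
                res.mismatched_normdiff.append(nd_mean)
                res.mismatched_percdiff.append(pd_mean)

        compare(own, matched=True)
        for sid, other in rep.items():
            if sid != key[0]:
                compare(other, matched=False)

    u, p = mann_whitney_one_sided_less(res.matched_mse, res.mismatched_mse)
    res.u_statistic, res.p_one_sided = u, p
    return res


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-scan and cohort-level evaluation results."""

    per_scan: pd.DataFrame
    region_table: Optional[pd.DataFrame]
    specificity: Optional[dict]
    smoothing_fwhm_mm: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "smoothing_fwhm_mm": self.smoothing_fwhm_mm,
                "per_scan": self.per_scan.to_dict(orient="records"),
                "region_table": (
                    self.region_table.to_dict(orient="records")
                    if self.region_table is not None
                    else None
                ),
                "specificity": self.specificity,
            },
            allow_nan=True,
        )

    def summary(self) -> dict:
        cols = [
            "mse",
            "mse_vs_smoothed",
            "normdiff_mean",
            "normdiff_sd",
            "percdiff_mean",
            "median_cnr_true",
            "median_cnr_recon",
        ]
        out = {}
        for c in cols:
            vals = self.per_scan[c].to_numpy(dtype=float)
            out[c] = {"mean": float(np.nanmean(vals)), "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0}
        return out


def evaluate_cohort(
    predictions: Mapping[tuple[str, int], Volume],
    cohort: Cohort,
    smoothing: SmoothingSpec = SmoothingSpec(),
    roi_sample: RoiSample = RoiSample(),
    with_regions: bool = True,
    with_specificity: bool = True,
    adjust_pvalues: bool = False,
) -> MetricReport:
    """Full evaluation battery for a set of reconstructed PET volumes.

    ``predictions`` maps (subject_id, session) to reconstructed PET volumes on
    the same grid as the cohort's (preprocessed) scans.
    """
    scans = {s.key: s for s in cohort}
    rows = []
    region_rows: dict[int, dict[str, list]] = {}
    for key, pred in predictions.items():
        scan = scans[key]
        truth = scan.pet
        smoothed = gaussian_smooth(truth, smoothing)
        mask = scan.mask
        _, nd_mean, nd_sd = normdiff(pred, truth, mask)
        _, pd_mean = percent_diff(pred, truth, mask)
        sample = dataclasses.replace(roi_sample, seed=roi_sample.seed)
        pairs = draw_roi_pairs(mask, sample)
        row = {
            "subject_id": key[0],
            "session": key[1],
            "group": scan.group.value,
            "genotype": scan.genotype.value,
            "mse": mse(pred, truth, mask),
            "mse_vs_smoothed": mse(pred, smoothed, mask),
            "normdiff_mean": nd_mean,
            "normdiff_sd": nd_sd,
            "percdiff_mean": pd_mean,
            "median_cnr_true": median_cnr(truth, mask, sample, pairs=pairs),
            "median_cnr_recon": median_cnr(pred, mask, sample, pairs=pairs),
        }
        rows.append(row)
        if with_regions and scan.labels is not None:
            rm_true = regionwise_means(smoothed, scan.labels)
            rm_recon = regionwise_means(pred, scan.labels)
            for region in rm_true:
                rec = region_rows.setdefault(region, {"true_smoothed": [], "recon": [], "genotype": []})
                rec["true_smoothed"].append(rm_true[region])
                rec["recon"].append(rm_recon[region])
                rec["genotype"].append(scan.genotype.value)

    per_scan = pd.DataFrame(rows)

    region_table = None
    if region_rows:
        table = []
        for region, rec in sorted(region_rows.items()):
            t = np.asarray(rec["true_smoothed"])
            r = np.asarray(rec["recon"])
            geno = np.asarray(rec["genotype"])
            entry: dict = {
                "region": region,
                "n_scans": len(t),
                "mean_true_smoothed": float(t.mean()),
                "mean_recon": float(r.mean()),
            }
            if len(t) >= 3 and t.std() > 0 and r.std() > 0:
                entry["pearson_r"], entry["pearson_p"] = pearson(r, t)
            else:
                entry["pearson_r"] = entry["pearson_p"] = float("nan")
            if len(t) >= 2:
                md, lo, hi = bland_altman(r, t)
                entry.update(ba_mean_diff=md, ba_loa_low=lo, ba_loa_high=hi)
            entry["mw_p_all"] = _median_split_test(t, r)
            for g in (Genotype.HAB.value, Genotype.MAB.value):
                sel = geno == g
                entry[f"mw_p_{g}"] = (
                    _median_split_test(t[sel], r[sel]) if sel.sum() >= 2 else float("nan")
                )
            table.append(entry)
        region_table = pd.DataFrame(table)
        if adjust_pvalues and "mw_p_all" in region_table:
            valid = region_table["mw_p_all"].notna()
            region_table.loc[valid, "mw_p_all_adj"] = benjamini_hochberg(
                region_table.loc[valid, "mw_p_all"].to_numpy()
            )

    spec_summary = None
    if with_specificity and len({k[0] for k in predictions}) >= 2:
        spec_summary = subject_specificity(predictions, cohort).summary()

    return MetricReport(
        per_scan=per_scan,
        region_table=region_table,
        specificity=spec_summary,
        smoothing_fwhm_mm=smoothing.fwhm_mm,
    )


def _median_split_test(true_vals: np.ndarray, recon_vals: np.ndarray) -> float:
    """Mann-Whitney p for reconstructed values split by the true-value median."""
    if len(true_vals) < 2:
        return float("nan")
    med = float(np.median(true_vals))
    low = recon_vals[true_vals <= med]
    high = recon_vals[true_vals > med]
    if low.size == 0 or high.size == 0:
        warnings.warn("degenerate median split (all values equal); test skipped")
        return float("nan")
    _, p = mann_whitney_u(low, high)
    return p
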