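"""Group-level inference on feature maps.

Covers the demographic table statistics (pooled two-sample t, Pearson
chi-square), the voxelwise group GLM with covariates, Gaussian-random-field
(GRF) cluster-extent correction with residual-based smoothness estimation, a
permutation-based alternative used as a validation oracle, cluster extraction
and per-cluster mean features, and Pearson clinical correlations with
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, special, stats

from .io import PATIENT, FeatureMap, NetworkMask, SubjectRecord

__all__ = [
    "InferenceConfig",
    "VoxelStatMap",
    "Cluster",
    "ClusterTable",
    "CorrelationResult",
    "pooled_t_test",
    "chi_square_2x2",
    "voxelwise_glm",
    "estimate_smoothness",
    "grf_cluster_extent",
    "permutation_cluster_extent",
    "extract_clusters",
    "cluster_means",
    "clinical_correlations",
]


@dataclass
class InferenceConfig:
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    two_tailed: bool = True
    connectivity: int = 18
    correction: str = "grf"  # or "permutation"
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        for p in (self.voxel_p, self.cluster_p):
            if not 0 < p < 1:
                raise ValueError(f"p thresholds must be in (0,1), got {p}")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.correction not in ("grf", "permutation"):
            raise ValueError(f"unknown correction: {self.correction!r}")

    @property
    def voxel_p_per_tail(self) -> float:
        return self.voxel_p / 2 if self.two_tailed else self.voxel_p

    @property
    def cluster_p_per_tail(self) -> float:
        # Bonferroni across the two tails keeps total cluster-level FWER at
        # nominal cluster_p when both tails are searched.
        return self.cluster_p / 2 if self.two_tailed else self.cluster_p


# ---------------------------------------------------------------------------
# Demographic statistics
# ---------------------------------------------------------------------------


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Equal-variance two-sample t from summary statistics.

    Returns (t, df, two-tailed p); df = n1 + n2 - 2.  If both SDs are zero and
    the means are equal, t is defined as 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        if diff == 0:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table
    [[a, b], [c, d]], df = 1."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: expected counts undefined")
    expected = np.outer(rows, cols) / n
    x2 = float(((counts - expected) ** 2 / expected).sum())
    return x2, float(stats.chi2.sf(x2, df=1))


# ---------------------------------------------------------------------------
# Voxelwise GLM
# ---------------------------------------------------------------------------


@dataclass
class VoxelStatMap:
    """Voxelwise t-statistics for the group contrast (patient - control)."""

    t_values: np.ndarray  # 3D, NaN outside mask
    df: int
    contrast: str
    covariates: tuple[str, ...]
    mask: NetworkMask
    residuals: np.ndarray | None = None  # n_subjects x V (mask voxels)

    @property
    def masked_t(self) -> np.ndarray:
        return self.t_values[self.mask.binary]


_COVARIATE_GETTERS = {
    "age": lambda r: r.age_years,
    "sex": lambda r: 1.0 if r.sex == "female" else 0.0,
    "education": lambda r: r.education_years,
    "mean_fd": lambda r: r.mean_fd_mm,
}


def voxelwise_glm(
    maps: Sequence[FeatureMap],
    records: Sequence[SubjectRecord],
    mask: NetworkMask,
    covariates: Sequence[str] = ("age", "sex", "mean_fd"),
) -> VoxelStatMap:
    """Per-voxel OLS of the (standardized) feature value on
    [intercept, group indicator, covariates]; t for the group coefficient.

    The group indicator codes patients 1, controls 0, so positive t means
    patient > control.
    """
    if len(maps) != len(records):
        raise ValueError("maps and records must align")
    groups = np.array([1.0 if r.is_patient else 0.0 for r in records])
    if (groups == 1).sum() < 3 or (groups == 0).sum() < 3:
        raise ValueError("need at least 3 subjects per group")
    cols = [np.ones(len(records)), groups]
    names = ["intercept", "group"]
    for cov in covariates:
        getter = _COVARIATE_GETTERS.get(cov)
        if getter is None:
            raise ValueError(f"unknown covariate: {cov!r}")
        vals = [getter(r) for r in records]
        if any(v is None for v in vals):
            raise ValueError(f"covariate {cov!r} missing for some subjects")
        v = np.asarray(vals, dtype=float)
        cols.append(v - v.mean())
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"collinear design: columns {names}")

    Y = np.stack([m.masked(mask) for m in maps])  # n x V
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    t = beta[1] / se
    out = np.full(mask.label_data.shape, np.nan)
    out[mask.binary] = t
    return VoxelStatMap(
        t_values=out,
        df=df,
        contrast="patient - control",
        covariates=tuple(covariates),
        mask=mask,
        residuals=resid,
    )


# ---------------------------------------------------------------------------
# Smoothness estimation & GRF cluster-extent threshold
# ---------------------------------------------------------------------------


def estimate_smoothness(
    residual_maps: np.ndarray | Sequence[np.ndarray],
    mask: NetworkMask,
) -> np.ndarray:
    """Per-axis smoothness FWHM (mm) from the gradient variance of the
    residual fields.

    For each subject the residual map is scaled to unit within-mask variance;
    lambda_i = E[(forward difference along axis i)^2] over mask-interior pairs,
    averaged over subjects, gives FWHM_i = sqrt(4 ln 2 / lambda_i) voxels.
    Unsmoothed white noise yields lambda = 2, i.e. FWHM ~ 1.18 voxels.
    """
    if isinstance(residual_maps, np.ndarray) and residual_maps.ndim == 2:
        flat = residual_maps
        vols = []
        for row in flat:
            vol = np.full(mask.label_data.shape, np.nan)
            vol[mask.binary] = row
            vols.append(vol)
    else:
        vols = [np.asarray(v, dtype=float) for v in residual_maps]
    if len(vols) < 2:
        raise ValueError("need at least 2 residual maps")
    m = mask.binary
    lam = np.zeros(3)
    counts = np.zeros(3)
    for vol in vols:
        inside = vol[m]
        var = inside.var()
        if var <= 0:
            continue
        r = vol / np.sqrt(var)
        for ax in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[ax] = slice(0, -1)
            sl_b[ax] = slice(1, None)
            pair = m[tuple(sl_a)] & m[tuple(sl_b)]
            if not np.any(pair):
                continue
            diff = (r[tuple(sl_b)] - r[tuple(sl_a)])[pair]
            lam[ax] += (diff**2).sum()
            counts[ax] += diff.size
    if np.any(counts == 0):
        raise ValueError("mask has no interior voxel pairs along some axis")
    lam /= counts
    lam = np.maximum(lam, 1e-12)
    fwhm_vox = np.sqrt(4.0 * np.log(2.0) / lam)
    return fwhm_vox * mask.voxel_size_mm


def _grf_cluster_p(k: float, u: float, resels: float, n_mask_voxels: int) -> float:
    """P(at least one cluster of size >= k voxels) under the stationary
    Gaussian-field expected-cluster-size approximation (3D)."""
    D = 3
    em = resels * (4 * np.log(2.0)) ** (D / 2) * (2 * np.pi) ** (-(D + 1) / 2) * u ** (D - 1) * np.exp(-(u**2) / 2)
    p0 = stats.norm.sf(u)
    en_total = n_mask_voxels * p0  # expected suprathreshold voxel count
    if em <= 0 or en_total <= 0:
        return 0.0
    beta = (special.gamma(D / 2 + 1) * em / en_total) ** (2.0 / D)
    p_ge_k = np.exp(-beta * k ** (2.0 / D))
    return float(1.0 - np.exp(-em * p_ge_k))


def grf_cluster_extent(
    stat: VoxelStatMap,
    fwhm_mm: Sequence[float],
    config: InferenceConfig | None = None,
) -> int:
    """Smallest cluster extent k (voxels) whose familywise probability under
    the Gaussian-random-field approximation is below the cluster threshold.

    The voxel-height threshold is the standard-normal quantile of the
    (per-tail) voxel p; smoothness enters through the resel count
    mask_voxels / prod(FWHM in voxels).
    """
    config = config or InferenceConfig()
    mask = stat.mask
    fwhm_vox = np.asarray(fwhm_mm, dtype=float) / mask.voxel_size_mm
    fwhm_vox = np.maximum(fwhm_vox, 1e-3)
    resels = mask.n_voxels / np.prod(fwhm_vox)
    u = stats.norm.isf(config.voxel_p_per_tail)
    S = mask.n_voxels
    for k in range(1, S + 1):
        if _grf_cluster_p(k, u, resels, S) < config.cluster_p_per_tail:
            return k
    return S


def permutation_cluster_extent(
    maps: Sequence[FeatureMap],
    records: Sequence[SubjectRecord],
    mask: NetworkMask,
    config: InferenceConfig | None = None,
    covariates: Sequence[str] = ("age", "sex", "mean_fd"),
    rng: np.random.Generator | None = None,
) -> int:
    """Cluster-extent threshold from a group-label permutation null of the
    maximum suprathreshold cluster size (the validation oracle for the GRF
    analytic threshold)."""
    config = config or InferenceConfig()
    rng = rng or np.random.default_rng(0)
    records = list(records)
    max_sizes = np.zeros(config.n_permutations, dtype=int)
    structure = _connectivity_structure(config.connectivity)
    for i in range(config.n_permutations):
        perm = rng.permutation(len(records))
        groups = [records[j].group for j in perm]
        perm_records = [
            _with_group(records[j], groups[j]) for j in range(len(records))
        ]
        stat = voxelwise_glm(maps, perm_records, mask, covariates)
        thr = stats.t.isf(config.voxel_p_per_tail, stat.df)
        biggest = 0
        for tail in (1, -1) if config.two_tailed else (1,):
            supra = np.nan_to_num(stat.t_values * tail) > thr
            labels, n = ndimage.label(supra, structure=structure)
            if n:
                biggest = max(biggest, int(np.bincount(labels.ravel())[1:].max()))
        max_sizes[i] = biggest
    # smallest k with P(max >= k) < cluster_p
    k = int(np.quantile(max_sizes, 1.0 - config.cluster_p, method="higher")) + 1
    return k


def _with_group(record: SubjectRecord, group: str) -> SubjectRecord:
    from dataclasses import replace

    return replace(record, group=group, illness_duration_months=None)


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    peak_mni_mm: tuple[float, float, float]
    n_voxels: int
    peak_t: float
    sign: str  # "positive" | "negative"
    label: str
    peak_ijk: tuple[int, int, int]
    voxel_indices: np.ndarray = field(repr=False)


@dataclass
class ClusterTable:
    clusters: list[Cluster]
    voxel_t_threshold: float
    k_min: int

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": i + 1,
                "region": c.label,
                "peak_x_mm": c.peak_mni_mm[0],
                "peak_y_mm": c.peak_mni_mm[1],
                "peak_z_mm": c.peak_mni_mm[2],
                "n_voxels": c.n_voxels,
                "peak_t": c.peak_t,
                "sign": c.sign,
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster",
                "region",
                "peak_x_mm",
                "peak_y_mm",
                "peak_z_mm",
                "n_voxels",
                "peak_t",
                "sign",
            ],
        )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def extract_clusters(
    stat: VoxelStatMap,
    k_min: int,
    config: InferenceConfig | None = None,
) -> ClusterTable:
    """Connected components of suprathreshold voxels, each tail separately,
    discarding components smaller than ``k_min``.

    Peak is the most extreme t in the component; ties break on the lowest
    linear (C-order) voxel index, which is what ``argmax`` returns first.
    Clusters are ordered by descending |peak t|.
    """
    config = config or InferenceConfig()
    mask = stat.mask
    thr = float(stats.t.isf(config.voxel_p_per_tail, stat.df))
    structure = _connectivity_structure(config.connectivity)
    t = np.nan_to_num(stat.t_values, nan=0.0)
    clusters: list[Cluster] = []
    tails = ((1, "positive"), (-1, "negative")) if config.two_tailed else ((1, "positive"),)
    for tail_sign, tail_name in tails:
        supra = (t * tail_sign > thr) & mask.binary
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            comp = labels == lab
            size = int(comp.sum())
            if size < k_min:
                continue
            signed = np.where(comp, t * tail_sign, -np.inf)
            flat_peak = int(np.argmax(signed))
            ijk = np.unravel_index(flat_peak, t.shape)
            peak_t = float(t[ijk])
            region_label = int(mask.label_data[ijk])
            name = mask.region_names.get(region_label, str(region_label))
            clusters.append(
                Cluster(
                    peak_mni_mm=tuple(np.round(mask.voxel_to_mm(ijk), 6)),
                    n_voxels=size,
                    peak_t=peak_t,
                    sign=tail_name,
                    label=name,
                    peak_ijk=tuple(int(v) for v in ijk),
                    voxel_indices=np.argwhere(comp),
                )
            )
    clusters.sort(key=lambda c: -abs(c.peak_t))
    return ClusterTable(clusters=clusters, voxel_t_threshold=thr, k_min=int(k_min))


def cluster_means(
    maps: Sequence[FeatureMap],
    clusters: Iterable[Cluster] | ClusterTable,
) -> np.ndarray:
    """Per subject and cluster, the mean map value over the cluster's voxels.

    Returns an (n_subjects, n_clusters) array; a cluster touching undefined
    (outside-mask) voxels of any map is an error.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValueError("no clusters to average")
    out = np.empty((len(maps), len(clusters)))
    for j, cl in enumerate(clusters):
        idx = tuple(cl.voxel_indices.T)
        for i, m in enumerate(maps):
            vals = m.values[idx]
            if not np.all(np.isfinite(vals)):
                raise ValueError(
                    f"cluster {j + 1} overlaps voxels undefined in map of "
                    f"subject {m.subject_id!r}"
                )
            out[i, j] = vals.mean()
    return out


# ---------------------------------------------------------------------------
# Clinical correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    feature: str
    score: str
    r: float
    p_uncorrected: float
    p_bonferroni: float
    n: int


_SCORE_GETTERS: Mapping[str, callable] = {
    "ybocs_total": lambda r: r.ybocs_total,
    "ybocs_obsessive": lambda r: r.ybocs_obsessive,
    "ybocs_compulsive": lambda r: r.ybocs_compulsive,
    "hamd": lambda r: r.hamd,
    "hama": lambda r: r.hama,
    "illness_duration": lambda r: r.illness_duration_months,
}


def pearson_r_to_p(r: float, n: int) -> float:
    """Two-tailed p for a Pearson r at sample size n via
    t = r sqrt(n-2) / sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def clinical_correlations(
    features: Mapping[str, np.ndarray],
    records: Sequence[SubjectRecord],
    scores: Sequence[str] = ("ybocs_total", "ybocs_obsessive", "ybocs_compulsive", "hamd", "hama"),
    family_size: int | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations between per-patient cluster features and clinical
    scores, with Bonferroni correction over the whole family.

    Only patients enter; missing scores are dropped pairwise (never imputed).
    """
    patients = [r for r in records if r.group == PATIENT]
    if len(patients) != len(next(iter(features.values()))):
        raise ValueError("feature vectors must align with the patient records")
    m = family_size if family_size is not None else len(features) * len(scores)
    results: list[CorrelationResult] = []
    for feat_name, values in features.items():
        values = np.asarray(values, dtype=float)
        for score in scores:
            getter = _SCORE_GETTERS.get(score)
            if getter is None:
                raise ValueError(f"unknown clinical score: {score!r}")
            pairs = [
                (v, getter(r))
                for v, r in zip(values, patients)
                if getter(r) is not None and np.isfinite(v)
            ]
            if len(pairs) < 4:
                raise ValueError(
                    f"fewer than 4 complete pairs for {feat_name} vs {score}"
                )
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            if x.std() == 0 or y.std() == 0:
                raise ValueError(f"zero variance in {feat_name} vs {score}")
            r = float(np.corrcoef(x, y)[0, 1])
            p = pearson_r_to_p(r, len(pairs))
            results.append(
                CorrelationResult(
                    feature=feat_name,
                    score=score,
                    r=r,
                    p_uncorrected=p,
                    p_bonferroni=min(1.0, m * p),
                    n=len(pairs),
                )
            )
    return results
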