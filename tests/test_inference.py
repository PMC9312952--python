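"""Group-level inference tests: demographics, GLM, GRF, clusters, correlations."""

import numpy as np
import pytest
from scipy import ndimage, stats

from conftest import make_records
from restnh.io import FeatureMap, NetworkMask, SubjectRecord
from restnh.inference import (
    Cluster,
    InferenceConfig,
    VoxelStatMap,
    chi_square_2x2,
    clinical_correlations,
    cluster_means,
    estimate_smoothness,
    extract_clusters,
    grf_cluster_extent,
    pearson_r_to_p,
    permutation_cluster_extent,
    pooled_t_test,
    voxelwise_glm,
)
from restnh.synth import SyntheticConfig, generate_mask


def _maps_from_matrix(values: np.ndarray, mask: NetworkMask, kind="nh"):
    maps = []
    for row in values:
        vol = np.full(mask.label_data.shape, np.nan)
        vol[mask.binary] = row
        maps.append(FeatureMap(vol, kind=kind))
    return maps


@pytest.fixture(scope="module")
def synth_mask():
    return generate_mask(SyntheticConfig())


# ---------------------------------------------------------------------------
# Demographic statistics
# ---------------------------------------------------------------------------


def test_pooled_t_matches_raw_data_oracle(rng):
    a = rng.normal(5, 2, 23)
    b = rng.normal(4, 3, 31)
    t, df, p = pooled_t_test(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
    t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)
    assert df == 52


def test_pooled_t_identical_groups():
    t, df, p = pooled_t_test(3.0, 1.0, 10, 3.0, 1.0, 12)
    assert t == 0.0 and p == 1.0
    t0, _, p0 = pooled_t_test(3.0, 0.0, 10, 3.0, 0.0, 12)
    assert t0 == 0.0 and p0 == 1.0


def test_pooled_t_errors():
    with pytest.raises(ValueError, match="n >= 2"):
        pooled_t_test(1.0, 1.0, 1, 2.0, 1.0, 5)
    with pytest.raises(ValueError, match="zero pooled variance"):
        pooled_t_test(1.0, 0.0, 5, 2.0, 0.0, 5)


def test_chi_square_proportional_table_zero():
    x2, p = chi_square_2x2(10, 10, 20, 20)
    assert x2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_matches_longhand(rng):
    for _ in range(20):
        a, b, c, d = rng.integers(1, 40, size=4)
        x2, p = chi_square_2x2(a, b, c, d)
        counts = np.array([[a, b], [c, d]], dtype=float)
        n = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / n
        x2_ref = float(((counts - expected) ** 2 / expected).sum())
        assert x2 == pytest.approx(x2_ref, abs=1e-12)
        ref = stats.chi2_contingency(counts, correction=False)
        assert x2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_chi_square_zero_margin():
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2(0, 0, 5, 7)


# ---------------------------------------------------------------------------
# Voxelwise GLM
# ---------------------------------------------------------------------------


def test_glm_no_covariates_equals_pooled_t(rng, flat_mask):
    records = make_records(10, 12)
    values = rng.normal(size=(22, flat_mask.n_voxels))
    maps = _maps_from_matrix(values, flat_mask)
    stat = voxelwise_glm(maps, records, flat_mask, covariates=())
    pat, ctl = values[:10], values[10:]
    for v in range(flat_mask.n_voxels):
        t_ref, _, _ = pooled_t_test(
            pat[:, v].mean(), pat[:, v].std(ddof=1), 10,
            ctl[:, v].mean(), ctl[:, v].std(ddof=1), 12,
        )
        assert stat.masked_t[v] == pytest.approx(t_ref, abs=1e-8)
    assert stat.df == 20
    assert stat.contrast == "patient - control"


def test_glm_positive_means_patient_greater(rng, flat_mask):
    records = make_records(8, 8)
    values = rng.normal(size=(16, flat_mask.n_voxels))
    values[:8] += 2.0
    stat = voxelwise_glm(_maps_from_matrix(values, flat_mask), records, flat_mask, covariates=())
    assert np.mean(stat.masked_t) > 0


def test_glm_missing_covariate_errors(rng, flat_mask):
    records = make_records(4, 4)
    records[0].mean_fd_mm = None
    maps = _maps_from_matrix(rng.normal(size=(8, flat_mask.n_voxels)), flat_mask)
    with pytest.raises(ValueError, match="mean_fd"):
        voxelwise_glm(maps, records, flat_mask, covariates=("age", "mean_fd"))


def test_glm_collinear_design_errors(rng, flat_mask):
    records = make_records(4, 4)
    for r in records:
        r.sex = "male"  # constant covariate column after centering
    maps = _maps_from_matrix(rng.normal(size=(8, flat_mask.n_voxels)), flat_mask)
    with pytest.raises(ValueError, match="collinear"):
        voxelwise_glm(maps, records, flat_mask, covariates=("sex",))


def test_glm_group_size_minimum(rng, flat_mask):
    records = make_records(2, 6)
    maps = _maps_from_matrix(rng.normal(size=(8, flat_mask.n_voxels)), flat_mask)
    with pytest.raises(ValueError, match="3 subjects"):
        voxelwise_glm(maps, records, flat_mask, covariates=())


def test_glm_permutation_type_one_rate(rng, flat_mask):
    # voxelwise false-positive rate at alpha = 0.05 under label permutation
    n = 20
    records = make_records(10, 10)
    values = rng.normal(size=(n, flat_mask.n_voxels))
    maps = _maps_from_matrix(values, flat_mask)
    groups = np.array([r.group for r in records])
    hits = total = 0
    for _ in range(400):
        perm = rng.permutation(n)
        shuffled = [
            SubjectRecord(r.subject_id, groups[perm[i]], r.age_years, r.sex, r.education_years)
            for i, r in enumerate(records)
        ]
        stat = voxelwise_glm(maps, shuffled, flat_mask, covariates=())
        p = 2 * stats.t.sf(np.abs(stat.masked_t), stat.df)
        hits += int((p < 0.05).sum())
        total += p.size
    rate = hits / total
    # 12000 (correlated across voxels, not across permutations) draws: generous CI
    assert 0.035 < rate < 0.065


# ---------------------------------------------------------------------------
# Smoothness estimation and cluster-extent thresholds
# ---------------------------------------------------------------------------


def _smoothed_noise_maps(rng, shape, n_maps, sigma_vox):
    return [ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox) for _ in range(n_maps)]


def test_smoothness_recovers_known_fwhm(rng):
    mask = NetworkMask(np.ones((24, 24, 24), dtype=int), np.diag([2.0, 2.0, 2.0, 1.0]))
    fwhm_mm = 8.0
    sigma_vox = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / 2.0
    maps = _smoothed_noise_maps(rng, (24, 24, 24), 6, sigma_vox)
    est = estimate_smoothness(maps, mask)
    assert np.all(np.abs(est - fwhm_mm) / fwhm_mm < 0.15)


def test_smoothness_white_noise_near_voxel_size(rng):
    mask = NetworkMask(np.ones((20, 20, 20), dtype=int), np.diag([3.0, 3.0, 3.0, 1.0]))
    maps = [rng.standard_normal((20, 20, 20)) for _ in range(6)]
    est = estimate_smoothness(maps, mask)
    assert np.all(np.abs(est - 3.0) / 3.0 < 0.25)


def test_smoothness_duplicate_maps_degenerate(rng):
    mask = NetworkMask(np.ones((16, 16, 16), dtype=int), np.diag([2.0, 2.0, 2.0, 1.0]))
    m = _smoothed_noise_maps(rng, (16, 16, 16), 1, 1.5)[0]
    two = estimate_smoothness([m, m], mask)
    four = estimate_smoothness([m, m, m, m], mask)
    assert np.allclose(two, four, atol=1e-12)
    with pytest.raises(ValueError, match="at least 2"):
        estimate_smoothness([m], mask)


def _stat_from_t(t_map: np.ndarray, mask: NetworkMask, df: int = 70) -> VoxelStatMap:
    vals = np.where(mask.binary, t_map, np.nan)
    return VoxelStatMap(
        t_values=vals, df=df, contrast="patient - control", covariates=(), mask=mask
    )


def test_grf_k_min_grows_with_moderate_smoothness(synth_mask):
    # over moderate smoothness the required extent grows; at extreme
    # smoothness the expected cluster count collapses and k can shrink again,
    # so only the moderate range is checked for monotonicity
    stat = _stat_from_t(np.zeros(synth_mask.label_data.shape), synth_mask)
    ks = [grf_cluster_extent(stat, [f, f, f]) for f in (3.0, 6.0, 9.0)]
    assert all(k >= 1 for k in ks)
    assert ks == sorted(ks)
    assert ks[-1] > ks[0]


def test_grf_vs_permutation_within_40pct(rng, synth_mask):
    # matched null: same smoothed-noise maps feed both threshold constructions
    records = make_records(10, 10)
    sigma_vox = 2.0 * 0.42466090014400953  # FWHM 2 voxels
    maps = []
    for _ in range(len(records)):
        vol = ndimage.gaussian_filter(rng.standard_normal(synth_mask.label_data.shape), sigma_vox)
        v = np.full(synth_mask.label_data.shape, np.nan)
        v[synth_mask.binary] = vol[synth_mask.binary]
        maps.append(FeatureMap(v, kind="nh"))
    config = InferenceConfig(n_permutations=300)
    stat = voxelwise_glm(maps, records, synth_mask, covariates=())
    fwhm = estimate_smoothness(stat.residuals, synth_mask)
    k_grf = grf_cluster_extent(stat, fwhm, config)
    k_perm = permutation_cluster_extent(
        maps, records, synth_mask, config, covariates=(), rng=np.random.default_rng(42)
    )
    assert abs(k_perm - k_grf) <= 0.4 * max(k_grf, k_perm)


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


def test_extract_clusters_empty_on_null(synth_mask):
    stat = _stat_from_t(np.zeros(synth_mask.label_data.shape), synth_mask)
    table = extract_clusters(stat, k_min=1)
    assert len(table) == 0
    assert table.to_dataframe().empty


def test_extract_clusters_direct_rule(synth_mask):
    t = np.zeros(synth_mask.label_data.shape)
    region = synth_mask.label_data == 1  # 123-voxel sphere
    idx = np.argwhere(region)[:30]
    t[tuple(idx.T)] = 10.0
    stat = _stat_from_t(t, synth_mask)
    table = extract_clusters(stat, k_min=25)
    assert len(table) == 1
    cl = table.clusters[0]
    assert cl.n_voxels == 30
    assert cl.sign == "positive"
    assert cl.peak_t == pytest.approx(10.0)
    assert cl.label == "right_frontal"
    table_high = extract_clusters(stat, k_min=31)
    assert len(table_high) == 0


def _bfs_components(supra: np.ndarray, connectivity: int):
    """Flood-fill oracle: connected component sizes of a boolean volume."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros_like(supra, dtype=bool)
    sizes = []
    for start in map(tuple, np.argwhere(supra)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            size += 1
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if any(c < 0 or c >= s for c, s in zip(nb, supra.shape)):
                    continue
                if supra[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_extract_clusters_matches_flood_fill_oracle(rng, connectivity):
    labels = np.ones((10, 10, 8), dtype=int)
    mask = NetworkMask(labels, np.diag([3.0, 3.0, 3.0, 1.0]), {1: "all"})
    df = 40
    thr = stats.t.isf(0.0005, df)
    for _ in range(5):
        t = np.where(rng.random((10, 10, 8)) < 0.25, thr + 1.0, 0.0)
        t *= rng.choice([-1.0, 1.0], size=t.shape)
        stat = _stat_from_t(t, mask, df=df)
        table = extract_clusters(stat, k_min=1, config=InferenceConfig(connectivity=connectivity))
        got = sorted(c.n_voxels for c in table.clusters)
        expected = _bfs_components(t > thr, connectivity) + _bfs_components(-t > thr, connectivity)
        assert got == sorted(expected)


def test_cluster_peak_tie_break_lowest_linear_index(synth_mask):
    t = np.zeros(synth_mask.label_data.shape)
    region_idx = np.argwhere(synth_mask.label_data == 2)
    t[tuple(region_idx[:10].T)] = 8.0  # ten equal peaks
    stat = _stat_from_t(t, synth_mask)
    table = extract_clusters(stat, k_min=1)
    # components of those 10 voxels: the reported peak of each is its lowest C-order voxel
    for cl in table.clusters:
        flat = [np.ravel_multi_index(tuple(v), t.shape) for v in cl.voxel_indices]
        assert np.ravel_multi_index(cl.peak_ijk, t.shape) == min(flat)


def test_clusters_sorted_by_abs_peak_t(synth_mask):
    t = np.zeros(synth_mask.label_data.shape)
    t[synth_mask.label_data == 1] = 5.0
    t[synth_mask.label_data == 2] = -9.0
    stat = _stat_from_t(t, synth_mask)
    table = extract_clusters(stat, k_min=1)
    peaks = [abs(c.peak_t) for c in table.clusters]
    assert peaks == sorted(peaks, reverse=True)
    assert table.clusters[0].sign == "negative"


def test_cluster_means_and_oracle(rng, synth_mask):
    t = np.zeros(synth_mask.label_data.shape)
    t[synth_mask.label_data == 1] = 9.0
    stat = _stat_from_t(t, synth_mask)
    table = extract_clusters(stat, k_min=1)
    values = rng.normal(size=(5, synth_mask.n_voxels))
    maps = _maps_from_matrix(values, synth_mask)
    feats = cluster_means(maps, table)
    assert feats.shape == (5, 1)
    cl = table.clusters[0]
    for i, m in enumerate(maps):
        acc = [m.values[tuple(v)] for v in cl.voxel_indices]
        assert feats[i, 0] == pytest.approx(np.mean(acc), abs=1e-12)
    const = _maps_from_matrix(np.full((2, synth_mask.n_voxels), 3.14), synth_mask)
    assert np.allclose(cluster_means(const, table), 3.14, atol=1e-12)


def test_cluster_means_outside_mask_errors(rng, synth_mask):
    bad = Cluster(
        peak_mni_mm=(0, 0, 0), n_voxels=1, peak_t=5.0, sign="positive", label="x",
        peak_ijk=(0, 0, 0), voxel_indices=np.array([[0, 0, 0]]),  # outside every region
    )
    maps = _maps_from_matrix(rng.normal(size=(2, synth_mask.n_voxels)), synth_mask)
    with pytest.raises(ValueError, match="undefined"):
        cluster_means(maps, [bad])


# ---------------------------------------------------------------------------
# Clinical correlations
# ---------------------------------------------------------------------------


def test_pearson_r_to_p_matches_scipy(rng):
    for _ in range(10):
        x, y = rng.normal(size=(2, 25))
        r, p_ref = stats.pearsonr(x, y)
        assert pearson_r_to_p(float(r), 25) == pytest.approx(p_ref, abs=1e-10)
    assert pearson_r_to_p(1.0, 10) == 0.0
    with pytest.raises(ValueError, match="n >= 3"):
        pearson_r_to_p(0.5, 2)


def test_clinical_correlations_bonferroni_and_pairwise(rng):
    records = make_records(10, 3, seed=5)
    patients = [r for r in records if r.is_patient]
    patients[0].ybocs_total = None  # dropped pairwise, not imputed
    feats = {"1": rng.normal(size=10), "2": rng.normal(size=10)}
    out = clinical_correlations(feats, records, scores=("ybocs_total",))
    assert len(out) == 2
    for res in out:
        assert res.n == 9
        assert res.p_bonferroni == pytest.approx(min(1.0, 2 * res.p_uncorrected))
        assert res.p_bonferroni >= res.p_uncorrected
        assert res.p_bonferroni <= 1.0
    forced = clinical_correlations(feats, records, scores=("ybocs_total",), family_size=9)
    assert forced[0].p_bonferroni == pytest.approx(min(1.0, 9 * forced[0].p_uncorrected))


def test_clinical_correlations_too_few_pairs(rng):
    records = make_records(5, 3)
    for r in records:
        if r.is_patient:
            r.hamd = None
    with pytest.raises(ValueError, match="fewer than 4"):
        clinical_correlations({"1": rng.normal(size=5)}, records, scores=("hamd",))


def test_clinical_correlations_zero_variance(rng):
    records = make_records(6, 3)
    with pytest.raises(ValueError, match="zero variance"):
        clinical_correlations({"1": np.ones(6)}, records, scores=("ybocs_total",))


def test_inference_config_validation():
    with pytest.raises(ValueError, match="connectivity"):
        InferenceConfig(connectivity=10)
    with pytest.raises(ValueError, match="thresholds"):
        InferenceConfig(voxel_p=0.0)
    cfg = InferenceConfig()
    assert cfg.voxel_p_per_tail == pytest.approx(0.0005)
    assert cfg.cluster_p_per_tail == pytest.approx(0.025)
    one_tail = InferenceConfig(two_tailed=False)
    assert one_tail.voxel_p_per_tail == pytest.approx(0.001)
    assert one_tail.cluster_p_per_tail == pytest.approx(0.05)
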