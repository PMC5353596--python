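"""Normalization, pooled clustering, TES/RV enrichment, group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenolink import (
    ConfigurationError,
    DataError,
    HeterogeneityModel,
    compare_groups,
    enrichment_scores,
    hierarchical_cluster,
    normalize_expression,
    relative_variability,
)
from phenolink.simulate import StudyConfig, default_expression_design, simulate_expression_matrix
from phenolink.simulate import _build_manifest


def brute_force_tes(labels, groups, group):
    """Cell-by-cell TES oracle: sum over clusters of f * (f/p)."""
    cells = list(labels.index)
    n_total = len(cells)
    clusters = sorted(set(labels))
    members = [c for c in cells if groups[c] == group]
    tes = 0.0
    for cl in clusters:
        n_i = sum(1 for c in cells if labels[c] == cl)
        n_gi = sum(1 for c in members if labels[c] == cl)
        p = n_i / n_total
        f = n_gi / len(members)
        tes += f * (f / p)
    return tes


def random_assignment(rng, n, k, n_groups):
    """Random cluster labels (each cluster non-empty) + group labels."""
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    groups = np.concatenate(
        [np.arange(n_groups), rng.integers(0, n_groups, size=n - n_groups)]
    )
    rng.shuffle(groups)
    idx = pd.Index([f"c{i}" for i in range(n)])
    label_series = pd.Series(labels, index=idx)
    occupancy = label_series.value_counts().sort_index()
    from phenolink.heterogeneity import ClusterAssignment

    assignment = ClusterAssignment(
        labels=label_series, k=k, linkage_method="ward", distance_metric="euclidean",
        occupancy=occupancy, p=occupancy / n,
    )
    return assignment, pd.Series([f"g{g}" for g in groups], index=idx)


class TestNormalize:
    def test_identical_values_all_zero(self):
        mat = pd.DataFrame(np.full((4, 6), 7.0),
                           index=[f"g{i}" for i in range(4)],
                           columns=[f"c{i}" for i in range(6)])
        norm = normalize_expression(mat)
        assert np.allclose(norm.values.to_numpy(), 0.0)

    def test_single_gene_sample_sd_convention(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        z = normalize_expression(mat).values.to_numpy()[0]
        assert np.allclose(z, [-1.0, 0.0, 1.0])  # sample SD of [1,2,3] is 1

    def test_per_gene_moments_over_detected(self, rng):
        mat = pd.DataFrame(rng.normal(5, 2, size=(20, 30)))
        mat[mat < 3] = np.nan
        mat = mat.loc[mat.notna().sum(axis=1) >= 3]
        norm = normalize_expression(mat)
        det = norm.values.where(norm.detected)
        assert np.allclose(det.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(det.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_sparse_genes_dropped_and_imputation_flagged(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, np.nan, np.nan], [1.0, 2.0, np.nan, 4.0]],
            index=["keep", "drop", "imputed"], columns=list("abcd"),
        )
        norm = normalize_expression(mat)
        assert norm.dropped_genes == ["drop"]
        assert norm.imputed.loc["imputed"].sum() == 1
        assert "drop" not in norm.values.index

    def test_empty_matrix_rejected(self):
        with pytest.raises(DataError):
            normalize_expression(pd.DataFrame())


class TestHierarchicalCluster:
    def test_singleton_clusters_when_k_equals_n(self, rng):
        x = pd.DataFrame(rng.standard_normal((7, 3)))
        a = hierarchical_cluster(x, k=7)
        assert sorted(a.labels) == list(range(1, 8))

    def test_separated_clouds_recovered(self, rng):
        x = np.vstack([rng.standard_normal((15, 4)), rng.standard_normal((15, 4)) + 50.0])
        a = hierarchical_cluster(x, k=2)
        labs = a.labels.to_numpy()
        assert len(set(labs[:15])) == 1 and len(set(labs[15:])) == 1
        assert labs[0] != labs[-1]

    def test_occupancy_conservation(self, rng):
        x = pd.DataFrame(rng.standard_normal((40, 5)))
        a = hierarchical_cluster(x, k=6)
        assert a.occupancy.sum() == 40
        assert a.p.sum() == pytest.approx(1.0)
        assert (a.occupancy > 0).all()

    def test_partition_invariant_to_cell_order(self, rng):
        x = pd.DataFrame(rng.standard_normal((30, 6)), index=[f"c{i}" for i in range(30)])
        perm = rng.permutation(30)
        a1 = hierarchical_cluster(x, k=4)
        a2 = hierarchical_cluster(x.iloc[perm], k=4)
        merged = pd.concat([a1.labels.rename("a"), a2.labels.rename("b")], axis=1)
        # same partition: the label pairing must be a bijection
        assert merged.groupby("a")["b"].nunique().eq(1).all()
        assert merged.groupby("b")["a"].nunique().eq(1).all()

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(rng.standard_normal((5, 2)), k=6)

    def test_ocr_vector_clustering(self, rng):
        ocr = pd.Series(np.concatenate([rng.normal(1, 0.1, 10), rng.normal(5, 0.1, 10)]))
        a = hierarchical_cluster(ocr, k=2)
        assert a.k == 2 and a.n_total == 20

    def test_newick_export(self, rng):
        x = pd.DataFrame(rng.standard_normal((6, 3)), index=[f"c{i}" for i in range(6)])
        nwk = hierarchical_cluster(x, k=2).to_newick()
        assert nwk.endswith(";") and "c0" in nwk


class TestEnrichment:
    def test_exclusive_cluster_reaches_upper_bound(self, rng):
        # a group of 20 out of 170 that fully owns one cluster: TES = 8.5
        n, n_g = 170, 20
        labels = pd.Series(
            [1] * n_g + list(rng.integers(2, 6, size=n - n_g)),
            index=[f"c{i}" for i in range(n)],
        )
        groups = pd.Series(
            ["own"] * n_g + ["rest"] * (n - n_g), index=labels.index
        )
        from phenolink.heterogeneity import ClusterAssignment

        occ = labels.value_counts().sort_index()
        a = ClusterAssignment(labels, k=5, linkage_method="ward",
                              distance_metric="euclidean", occupancy=occ, p=occ / n)
        res = enrichment_scores(a, groups)
        assert res.tes["own"] == pytest.approx(n / n_g)  # 8.5

    def test_matched_occupancy_gives_unit_tes(self):
        # group occupancies equal to pooled p_i exactly -> TES = 1
        labels = pd.Series([1] * 4 + [2] * 6, index=[f"c{i}" for i in range(10)])
        groups = pd.Series(["g1", "g1", "g2", "g2", "g1", "g1", "g1", "g2", "g2", "g2"],
                           index=labels.index)
        from phenolink.heterogeneity import ClusterAssignment

        occ = labels.value_counts().sort_index()
        a = ClusterAssignment(labels, k=2, linkage_method="ward",
                              distance_metric="euclidean", occupancy=occ, p=occ / 10)
        res = enrichment_scores(a, groups)
        assert res.tes["g1"] == pytest.approx(1.0)
        assert res.tes["g2"] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(10, 51))
            k = int(rng.integers(2, min(9, n)))
            n_groups = int(rng.integers(2, 4))
            a, groups = random_assignment(rng, n, k, n_groups)
            res = enrichment_scores(a, groups)
            for g in res.tes.index:
                assert res.tes[g] == pytest.approx(brute_force_tes(a.labels, groups, g))

    def test_tes_bounds(self, rng):
        for _ in range(25):
            n = int(rng.integers(12, 50))
            k = int(rng.integers(2, 8))
            a, groups = random_assignment(rng, n, k, 3)
            res = enrichment_scores(a, groups)
            for g in res.tes.index:
                n_g = res.group_sizes[g]
                assert res.tes[g] >= 1.0 - 1e-12
                assert res.tes[g] <= n / n_g + 1e-12

    def test_occupancy_fractions_sum_to_one(self, rng):
        a, groups = random_assignment(rng, 40, 5, 3)
        res = enrichment_scores(a, groups)
        assert np.allclose(res.f.sum(axis=1), 1.0)

    def test_missing_group_label_rejected(self, rng):
        a, groups = random_assignment(rng, 20, 3, 2)
        with pytest.raises(DataError):
            enrichment_scores(a, groups.iloc[:-1])


class TestRelativeVariability:
    def test_identity_ratio(self):
        assert relative_variability(3.3, 3.3).rounded == 1.00

    def test_direction_control_over_hypoxia(self):
        rv = relative_variability(2.0, 4.0)
        assert rv.raw == pytest.approx(0.5)

    def test_nonpositive_tes_rejected(self):
        with pytest.raises(DataError):
            relative_variability(0.0, 2.0)


class TestCompareGroups:
    @staticmethod
    def table(control, hypoxia, cell_type="CP-A"):
        rows = [{"cell_id": f"c{i}", "cell_type": cell_type, "strain": "control",
                 "ocr_fmol_min": v} for i, v in enumerate(control)]
        rows += [{"cell_id": f"h{i}", "cell_type": cell_type, "strain": "hypoxia",
                  "ocr_fmol_min": v} for i, v in enumerate(hypoxia)]
        return pd.DataFrame(rows)

    def test_identical_samples_rank_p_near_one(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        out = compare_groups(self.table(vals, vals))
        assert out["mw_p"].iloc[0] > 0.9

    def test_degenerate_identical_constant_groups_flagged(self):
        out = compare_groups(self.table([2.0] * 5, [2.0] * 5))
        assert out["degenerate"].iloc[0]
        assert out["t_p"].iloc[0] == 1.0

    def test_large_shift_detected(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)  # 5 pooled SDs apart
        out = compare_groups(self.table(a, b))
        assert out["t_p_adj"].iloc[0] < 0.001
        assert out["mw_p_adj"].iloc[0] < 0.001

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2024)
        n_rep, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_rep):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rejections += p < alpha
        rate = rejections / n_rep
        sd = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= 3 * sd

    def test_small_groups_rejected(self):
        with pytest.raises(DataError):
            compare_groups(self.table([1.0, 2.0], [1.0, 2.0, 3.0]))


class TestHeterogeneityModel:
    def test_rv_near_unity_for_identical_generative_settings(self):
        # control and hypoxia strains share centroids and noise, so TES
        # should match between them: median RV across seeds near 1
        medians = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            cfg = StudyConfig()
            manifest = _build_manifest(cfg, rng)
            design = default_expression_design(cfg, rng)
            expr = simulate_expression_matrix(design, manifest, seed=rng.integers(0, 2**31))
            res = HeterogeneityModel(expr, manifest).fit(k=10)
            medians.extend(res.rv_table["rv"].tolist())
        med = float(np.median(medians))
        assert 0.85 <= med <= 1.18

    def test_summary_contains_tes_and_rv(self, study_dir):
        _, manifest, _, expr = study_dir
        res = HeterogeneityModel(expr, manifest).fit(k=10)
        text = res.summary()
        assert "TES" in text and "RV" in text
        assert len(res.rv_table) == 4
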