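"""DEG filtering, profile scaling, k selection, k-means clustering,
JNK-dependent gene assignment, overlaps and half-life cross-referencing."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from jnkdyn import (
    TimecourseKMeans,
    build_profile_matrix,
    choose_k,
    cluster_genes,
    cluster_overlap,
    crossref_halflives,
    filter_degs,
    gen_archetype_profiles,
    jnk_dependent_genes,
)


def toy_deg_table():
    """Six genes: one fails each criterion, one passes all, one passes
    only via the 6-h timepoint."""
    rows = [
        # gene, biotype, fc2, fc4, fc6, fc8, fdr, mgm
        ("pass_all", "protein_coding", 2.5, 0.1, 0.0, 0.0, 0.01, 5.0),
        ("fail_fdr", "protein_coding", 2.5, 0.1, 0.0, 0.0, 0.20, 5.0),
        ("fail_fc", "protein_coding", 0.5, 0.6, 0.4, 0.2, 0.01, 5.0),
        ("fail_mgm", "protein_coding", 2.5, 0.1, 0.0, 0.0, 0.01, 0.5),
        ("fail_bio", "lncRNA", 2.5, 0.1, 0.0, 0.0, 0.01, 5.0),
        ("late_only", "protein_coding", 0.0, 0.0, -1.8, 0.3, 0.02, 3.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "biotype", "log2fc_2h", "log2fc_4h", "log2fc_6h",
                 "log2fc_8h", "fdr", "max_group_mean"],
    )


def test_filter_applies_all_four_criteria():
    got = filter_degs(toy_deg_table())
    assert got == {"pass_all", "late_only"}


def test_filter_empty_table_and_idempotence():
    table = toy_deg_table()
    assert filter_degs(table.iloc[0:0]) == set()
    first = filter_degs(table)
    again = filter_degs(table[table["gene_id"].isin(first)])
    assert again == first
    shuffled = filter_degs(table.sample(frac=1, random_state=1))
    assert shuffled == first


def test_filter_reports_missing_columns():
    with pytest.raises(ValueError, match="fdr"):
        filter_degs(toy_deg_table().drop(columns=["fdr"]))


def test_profile_matrix_scaling():
    table = toy_deg_table().assign(
        log2fc_2h=[1.0, 0, 0, 0, 0, 0],
        log2fc_4h=[2.0, 0, 0, 0, 0, 0],
        log2fc_6h=[3.0, 0, 0, 0, 0, 0],
        log2fc_8h=[4.0, 0, 0, 0, 0, 0],
    )
    mat = build_profile_matrix(table, {"pass_all", "fail_fc"})
    assert mat.shape == (2, 5)
    np.testing.assert_allclose(mat.loc["pass_all"], [0, 0.25, 0.5, 0.75, 1.0])
    np.testing.assert_allclose(mat.loc["fail_fc"], 0.0)  # constant row
    with pytest.raises(KeyError):
        build_profile_matrix(table, {"missing_gene"})


def test_scaling_preserves_peak_timepoint():
    rng = np.random.default_rng(2)
    fc = rng.normal(0, 2, (20, 4))
    table = pd.DataFrame(fc, columns=["log2fc_2h", "log2fc_4h", "log2fc_6h", "log2fc_8h"])
    table.insert(0, "gene_id", [f"g{i}" for i in range(20)])
    table["biotype"] = "protein_coding"
    table["fdr"] = 0.01
    table["max_group_mean"] = 2.0
    mat = build_profile_matrix(table, set(table["gene_id"]))
    raw = np.column_stack([np.zeros(20), fc])
    for i, gene in enumerate(table["gene_id"]):
        assert int(np.argmax(mat.loc[gene].to_numpy())) == int(np.argmax(raw[i]))


def test_choose_k_finds_three_archetypes():
    matrix, _ = gen_archetype_profiles(n_per_archetype=50, noise_sd=0.05, seed=5)
    rec, diag = choose_k(matrix, seed=5)
    assert rec == 3
    assert list(diag["k"]) == list(range(2, 11))
    assert {"silhouette", "within_ss", "size_cv"} <= set(diag.columns)


def test_choose_k_degenerate_matrix():
    matrix = pd.DataFrame(np.ones((30, 5)), columns=[0.0, 2.0, 4.0, 6.0, 8.0])
    rec, diag = choose_k(matrix, k_range=range(2, 5), seed=0)
    assert rec == 2
    assert diag.attrs["degenerate"]


def test_choose_k_requires_enough_rows():
    matrix, _ = gen_archetype_profiles(n_per_archetype=2, seed=0)
    with pytest.raises(ValueError):
        choose_k(matrix, k_range=range(2, 11))


def test_clustering_recovers_archetypes_across_seeds():
    matrix, truth = gen_archetype_profiles(n_per_archetype=50, noise_sd=0.05, seed=8)
    for seed in range(5):
        cs = cluster_genes(matrix, k=3, seed=seed)
        ari = adjusted_rand_score(truth, cs.assignments.loc[truth.index])
        assert ari > 0.9


def test_clustering_deterministic_and_label_convention():
    matrix, _ = gen_archetype_profiles(seed=3)
    a = cluster_genes(matrix, 3, seed=7)
    b = cluster_genes(matrix, 3, seed=7)
    assert a.assignments.equals(b.assignments)
    assert set(a.assignments.unique()) == {1, 2, 3}
    assert int(a.sizes.sum()) == matrix.shape[0]
    # labels ordered by descending peak time of the cluster mean
    peak_times = [
        a.profiles.columns[int(np.argmax(a.profiles.loc[lb]))]
        for lb in sorted(a.profiles.index)
    ]
    assert peak_times == sorted(peak_times, reverse=True)
    assert (a.profiles.to_numpy() >= 0).all() and (a.profiles.to_numpy() <= 1).all()


def test_kmeans_degenerate_k_equals_rows():
    matrix, _ = gen_archetype_profiles(n_per_archetype=2, noise_sd=0.2, seed=1)
    est = TimecourseKMeans(n_clusters=6, random_state=0).fit(matrix)
    assert len(set(est.labels_)) == 6
    with pytest.raises(ValueError):
        TimecourseKMeans(n_clusters=7).fit(matrix)


def test_jnk_dependent_genes_threshold_and_counts():
    contrast = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(5)],
            "log2fc_2h": [1.5, 0.2, 0.0, 0.0, 0.4],
            "log2fc_6h": [0.0, 0.0, -1.2, 0.9, 0.0],
        }
    )
    genes = jnk_dependent_genes(contrast)
    assert genes == {"g0", "g2"}
    assert jnk_dependent_genes(contrast, signed=True) == {"g0"}
    zero = contrast.assign(log2fc_2h=0.0, log2fc_6h=0.0)
    assert jnk_dependent_genes(zero) == set()

    matrix, _ = gen_archetype_profiles(n_per_archetype=4, seed=0)
    cs = cluster_genes(matrix, 3, seed=0)
    contrast_all = pd.DataFrame(
        {"gene_id": matrix.index[:6], "log2fc_2h": 2.0}
    )
    got, counts = jnk_dependent_genes(contrast_all, cluster_set=cs)
    assert counts.sum() == len(got & set(matrix.index))


def test_cluster_overlap_metrics():
    a = set(range(1, 11))
    b = set(range(6, 16))
    rep = cluster_overlap(a, b)
    assert rep["n_intersection"] == 5
    assert rep["jaccard"] == pytest.approx(5 / 15)
    assert rep["frac_a"] == rep["frac_b"] == 0.5
    same = cluster_overlap(a, a)
    assert same["jaccard"] == same["frac_a"] == same["shared_frac_smaller"] == 1.0
    disjoint = cluster_overlap({1, 2}, {3, 4})
    assert disjoint["jaccard"] == 0.0
    # symmetry
    ba = cluster_overlap(b, a)
    assert ba["jaccard"] == rep["jaccard"]
    with pytest.raises(ValueError):
        cluster_overlap(set(), a)


def test_crossref_halflives_means_and_missing_cells():
    matrix, _ = gen_archetype_profiles(n_per_archetype=3, noise_sd=0.2, seed=2)
    cs = cluster_genes(matrix, 3, seed=0)
    g1 = sorted(cs.genes(1))
    hl = pd.DataFrame(
        {
            "study_id": ["s1", "s1", "s2"],
            "gene_id": [g1[0], g1[1], g1[0]],
            "half_life_h": [2.0, 4.0, 10.0],
        }
    )
    out = crossref_halflives(cs, hl)
    cell = out[(out["cluster"] == 1) & (out["study_id"] == "s1")].iloc[0]
    assert cell["mean_half_life_h"] == pytest.approx(3.0)
    assert cell["n_matched"] == 2
    empty = out[(out["cluster"] == 2) & (out["study_id"] == "s1")].iloc[0]
    assert np.isnan(empty["mean_half_life_h"]) and empty["n_matched"] == 0
    assert set(out["study_id"]) == {"s1", "s2"}
    with pytest.raises(ValueError):
        crossref_halflives(cs, hl.assign(half_life_h=-1.0))
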