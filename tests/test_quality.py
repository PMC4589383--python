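"""PCA, ANOVA/Tukey, distance matrix, clustering and forensics."""

from __future__ import annotations

import numpy as np
import pytest

from aeroprint.classify import SVMParams, kfold_cv
from aeroprint.quality import (
    DistanceMatrix,
    anova_tukey,
    distance_matrix,
    forensics,
    hierarchical_subgroups,
    pca3,
    render,
)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_recovers_three_dimensional_subspace():
    rng = np.random.default_rng(0)
    basis = np.linalg.qr(rng.standard_normal((20, 3)))[0]
    X = rng.standard_normal((200, 3)) @ basis.T + 5.0
    res = pca3(X)
    assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-10)
    # orthonormal loadings, diagonal score covariance
    G = res.components.T @ res.components
    assert np.allclose(G, np.eye(3), atol=1e-10)
    C = np.cov(res.scores, rowvar=False)
    off = C - np.diag(np.diag(C))
    assert np.abs(off).max() < 1e-10 * max(C.max(), 1.0)


def test_pca_isotropic_variance_fractions():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((5000, 32))
    res = pca3(X)
    assert np.all(np.abs(res.explained_variance - 1 / 32) < 0.008)
    assert np.all(np.diff(res.explained_variance) <= 1e-15)


def test_pca_invariant_to_sample_duplication():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((50, 6))
    a, b = pca3(X), pca3(np.vstack([X, X]))
    assert np.allclose(a.components, b.components, atol=1e-8)
    assert np.allclose(a.explained_variance, b.explained_variance, atol=1e-10)


def test_pca_rank_deficiency_flagged():
    rng = np.random.default_rng(3)
    plane = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 8))
    res = pca3(plane)
    assert res.rank_deficient and res.n_components == 2


# ---------------------------------------------------------------------------
# ANOVA / Tukey
# ---------------------------------------------------------------------------


def test_anova_power_at_huge_effect():
    rng = np.random.default_rng(4)
    values = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
    groups = np.repeat(["a", "b"], 20)
    res = anova_tukey(values, groups)
    assert res.p < 1e-6
    assert res.group_means["b"] - res.group_means["a"] == pytest.approx(5.0, abs=1.0)
    assert bool(res.tukey["reject"].iloc[0])


def test_anova_invariant_to_within_group_order():
    rng = np.random.default_rng(5)
    values = rng.normal(size=40)
    groups = np.repeat([0, 1], 20)
    res1 = anova_tukey(values, groups)
    perm = np.concatenate([rng.permutation(20), 20 + rng.permutation(20)])
    res2 = anova_tukey(values[perm], groups[perm])
    assert res1.F == pytest.approx(res2.F, rel=1e-12)
    assert res1.p == pytest.approx(res2.p, rel=1e-12)


def test_anova_degenerate_inputs():
    with pytest.raises(ValueError):
        anova_tukey([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])  # zero within-variance
    with pytest.raises(ValueError):
        anova_tukey([1.0, 2.0], ["a", "b"])  # single sample per group


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------


def test_distance_matrix_basic_properties():
    dm = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
    assert dm.values[0, 1] == 1.0 and dm.values[1, 0] == 1.0
    assert dm.normalization == pytest.approx(5.0)
    three = distance_matrix(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))
    assert three.values[0, 1] == 0.0
    with pytest.raises(ValueError):
        distance_matrix(np.ones((4, 3)))


def test_distance_matrix_matches_double_loop_oracle():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((5, 7))
    dm = distance_matrix(X)
    brute = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            brute[i, j] = np.sqrt(((X[i] - X[j]) ** 2).sum())
    brute /= brute.max()
    assert np.allclose(dm.values, brute, atol=1e-12)
    assert np.allclose(dm.values, dm.values.T) and np.all(np.diag(dm.values) == 0)


def test_distance_matrix_triangle_inequality():
    rng = np.random.default_rng(7)
    V = distance_matrix(rng.standard_normal((30, 5))).values
    idx = rng.integers(0, 30, size=(200, 3))
    for i, j, k in idx:
        assert V[i, j] <= V[i, k] + V[k, j] + 1e-12


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _planted(rng, centers, n_per, spread=0.3):
    X = np.vstack([c + spread * rng.standard_normal((n_per, len(c))) for c in centers])
    labels = np.repeat([str(i) for i in range(len(centers))], n_per)
    return X, labels


def test_three_planted_clusters_recovered_pure():
    rng = np.random.default_rng(8)
    X, labels = _planted(rng, np.array([[0, 0], [10, 0], [0, 10]], dtype=float), 15)
    tree = hierarchical_subgroups(distance_matrix(X), labels=labels)
    assert tree.cut_k == 3 and tree.n_pure == 3 and tree.mean_purity == 1.0


def test_clustering_invariant_to_sample_order():
    rng = np.random.default_rng(9)
    X, labels = _planted(rng, np.array([[0, 0], [8, 0], [0, 8], [8, 8]], dtype=float), 10)
    perm = rng.permutation(len(X))
    t1 = hierarchical_subgroups(distance_matrix(X), labels=labels)
    t2 = hierarchical_subgroups(distance_matrix(X[perm]), labels=labels[perm])
    co1 = t1.subgroups[:, None] == t1.subgroups[None, :]
    co2 = t2.subgroups[:, None] == t2.subgroups[None, :]
    assert np.array_equal(co1[np.ix_(perm, perm)], co2)


def test_clustering_arguments():
    dm = distance_matrix(np.random.default_rng(0).standard_normal((8, 3)))
    with pytest.raises(ValueError, match="linkage"):
        hierarchical_subgroups(dm, linkage="centroidish", k=2)
    with pytest.raises(ValueError):
        hierarchical_subgroups(dm)  # neither k nor labels
    fixed = hierarchical_subgroups(dm, k=4)
    assert len(np.unique(fixed.subgroups)) == 4


def test_ideal_design_forms_twelve_pure_subgroups(ideal_table, ideal_features):
    """The 108-sample ideal set splits into 12 subgroups, one per
    (disease level, flow rate) combination, at the purity-maximising cut."""
    X, _ = ideal_features
    combos = np.array(
        [f"D{d}/Q{int(q)}" for d, q in zip(ideal_table["D"], ideal_table["Q_lpm"])]
    )
    tree = hierarchical_subgroups(
        distance_matrix(X, sample_ids=ideal_table["sample_id"].to_numpy()),
        labels=combos,
    )
    assert tree.cut_k == 12
    assert tree.n_pure == 12
    assert set(tree.composition["dominant_label"]) == set(combos)


# ---------------------------------------------------------------------------
# forensics
# ---------------------------------------------------------------------------


def test_forensics_empty_without_misclassifications(blobs4):
    X, y = blobs4
    ids = np.array([f"S{i+1}" for i in range(len(y))])
    rep = kfold_cv(X, y, k=10, seed=0, params=SVMParams(gamma=0.5), sample_ids=ids)
    dm = distance_matrix(X, sample_ids=ids)
    tree = hierarchical_subgroups(dm, labels=y.astype(str))
    assert forensics(rep, dm, tree) == []


def test_forensics_dossier_structure_and_neighbor_oracle():
    """Planted wrong-label samples appear in the dossier with nearest
    neighbours matching a brute-force scan and drawn from the predicted
    (generative) class."""
    rng = np.random.default_rng(10)
    centers = np.array([[0, 0], [7, 0], [0, 7], [7, 7]], dtype=float)
    X = np.vstack([c + 0.5 * rng.standard_normal((25, 2)) for c in centers])
    y = np.repeat(np.arange(4), 25)
    planted = [5, 60]
    y_bad = y.copy()
    for i in planted:
        y_bad[i] = (y[i] + 1) % 4
    ids = np.array([f"S{i+1}" for i in range(len(y))])
    rep = kfold_cv(X, y_bad, k=10, seed=1, params=SVMParams(gamma=0.5), sample_ids=ids)
    dm = distance_matrix(X, sample_ids=ids)
    tree = hierarchical_subgroups(dm, labels=y_bad.astype(str))
    dossier = forensics(rep, dm, tree, n_neighbors=5)
    listed = {d["sample_id"] for d in dossier}
    assert {f"S{i+1}" for i in planted} <= listed
    pos = {s: i for i, s in enumerate(ids)}
    for entry in dossier:
        i = pos[entry["sample_id"]]
        d = dm.values[i].copy()
        d[i] = np.inf
        expected = sorted(np.argsort(d, kind="stable")[:5].tolist())
        got = sorted(pos[n["sample_id"]] for n in entry["neighbors"])
        assert got == expected
        if i in planted:
            # a planted sample's neighbours are overwhelmingly its
            # generative class, which is what the classifier predicts
            neighbor_classes = [y[pos[n["sample_id"]]] for n in entry["neighbors"]]
            assert np.mean(np.array(neighbor_classes) == entry["predicted_label"]) >= 0.8


def test_forensics_id_mismatch_rejected(blobs4):
    X, y = blobs4
    ids = np.array([f"S{i+1}" for i in range(len(y))])
    rep = kfold_cv(X, y, k=10, seed=0, params=SVMParams(gamma=0.5), sample_ids=ids)
    dm = distance_matrix(X[:100], sample_ids=ids[:100])
    tree = hierarchical_subgroups(dm, labels=y[:100].astype(str))
    with pytest.raises(ValueError):
        forensics(rep, dm, tree)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def test_render_writes_deterministic_figures(tmp_path):
    import matplotlib.image as mpimg

    rng = np.random.default_rng(12)
    X, labels = _planted(rng, np.array([[0, 0], [6, 6]], dtype=float), 10)
    dm = distance_matrix(X)
    tree = hierarchical_subgroups(dm, labels=labels)
    pca = pca3(np.hstack([X, rng.standard_normal((20, 2))]))
    files = render(
        tmp_path / "a", dm=dm, tree=tree, pca=pca, pca_labels=labels,
        anova_values=X[:, 0], anova_groups=labels,
    )
    assert len(files) == 3
    for f in files:
        assert (tmp_path / "a" / f.split("/")[-1]).stat().st_size > 0
    files2 = render(
        tmp_path / "b", dm=dm, tree=tree, pca=pca, pca_labels=labels,
        anova_values=X[:, 0], anova_groups=labels,
    )
    for f1, f2 in zip(files, files2):
        assert np.array_equal(mpimg.imread(f1), mpimg.imread(f2))


def test_render_refuses_single_sample(tmp_path):
    dm = DistanceMatrix(values=np.zeros((1, 1)), sample_ids=np.array(["S1"]),
                        normalization=1.0)
    with pytest.raises(ValueError):
        render(tmp_path, dm=dm)
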