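"""Database quality evaluation and misclassification forensics.

Pre-test checks of a fingerprint feature table: covariance PCA projection
onto three components, one-way ANOVA with Tukey HSD comparisons on a
region-of-interest fractal dimension, a max-normalised Euclidean distance
matrix, and agglomerative clustering into subgroups.  Post-test, the
distance matrix and cluster tree are interrogated around each misclassified
sample (its subgroup, nearest neighbours and their label composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PCAResult",
    "AnovaResult",
    "DistanceMatrix",
    "ClusterTree",
    "pca3",
    "anova_tukey",
    "distance_matrix",
    "hierarchical_subgroups",
    "forensics",
    "render",
]


@dataclass
class PCAResult:
    """Top principal components of a mean-centred covariance decomposition."""

    components: np.ndarray          # (p, m) orthonormal loading vectors (columns)
    scores: np.ndarray              # (n, m) sample coordinates
    explained_variance: np.ndarray  # m fractions, non-increasing
    n_components: int
    rank_deficient: bool = False


def pca3(features, n_components: int = 3) -> PCAResult:
    """Covariance PCA onto the top components (default 3).

    Mean-centred, not variance-scaled.  Deterministic sign convention: the
    largest-magnitude loading of each component is positive.  If the data
    rank is below ``n_components`` the available components are returned
    with ``rank_deficient`` set.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 features")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    rank = int((evals > 1e-12 * max(total, 1e-300)).sum())
    m = min(n_components, rank) if rank else n_components
    deficient = m < n_components
    comps = evecs[:, :m].copy()
    for j in range(m):  # sign convention
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]
    scores = Xc @ comps
    frac = evals[:m] / total if total > 0 else np.zeros(m)
    return PCAResult(
        components=comps,
        scores=scores,
        explained_variance=frac,
        n_components=m,
        rank_deficient=deficient,
    )


@dataclass
class AnovaResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons."""

    F: float
    p: float
    group_means: dict
    tukey: pd.DataFrame  # group1, group2, meandiff, lower, upper, p_adj, reject


def anova_tukey(values, groups, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of a per-sample scalar (e.g. the ROI fractal dimension)
    across factor levels, with Tukey comparisons at the given alpha."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need at least two samples per group")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("degenerate input: zero within-group variance everywhere")
    F, p = stats.f_oneway(*samples)
    hsd = pairwise_tukeyhsd(values, groups, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    means = {g.item() if hasattr(g, "item") else g: float(s.mean())
             for g, s in zip(levels, samples)}
    return AnovaResult(F=float(F), p=float(p), group_means=means, tukey=tukey)


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean dissimilarities scaled so the maximum is 1."""

    values: np.ndarray
    sample_ids: np.ndarray
    normalization: float  # the pre-scaling maximum distance

    @property
    def n(self) -> int:
        return len(self.values)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def distance_matrix(features, sample_ids=None) -> DistanceMatrix:
    """Pairwise Euclidean distances on the retained features, divided by the
    maximum off-diagonal distance so values span [0, 1]."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need at least two samples")
    ids = (
        np.asarray(sample_ids)
        if sample_ids is not None
        else np.array([f"S{i + 1}" for i in range(len(X))])
    )
    d = pdist(X, metric="euclidean")
    dmax = d.max()
    if dmax == 0:
        raise ValueError("degenerate normalization: all samples identical")
    return DistanceMatrix(values=squareform(d / dmax), sample_ids=ids, normalization=float(dmax))


@dataclass
class ClusterTree:
    """Agglomerative merge history with a flat subgroup cut."""

    linkage_matrix: np.ndarray
    leaf_order: np.ndarray
    subgroups: np.ndarray            # per-sample subgroup id (1-based)
    sample_ids: np.ndarray
    cut_k: int
    composition: pd.DataFrame        # per subgroup: size, label combos, purity
    n_pure: int
    mean_purity: float


_LINKAGES = ("complete", "average", "ward", "single")


def _purity_at(assign: np.ndarray, labels: np.ndarray) -> tuple[float, int, pd.DataFrame]:
    rows = []
    total = 0.0
    pure = 0
    for g in np.unique(assign):
        members = labels[assign == g]
        vals, counts = np.unique(members, return_counts=True)
        purity = counts.max() / len(members)
        total += purity * len(members)
        pure += int(purity == 1.0)
        rows.append(
            {
                "subgroup": int(g),
                "size": len(members),
                "dominant_label": vals[np.argmax(counts)],
                "purity": purity,
                "composition": {str(v): int(c) for v, c in zip(vals, counts)},
            }
        )
    return total / len(labels), pure, pd.DataFrame(rows)


def hierarchical_subgroups(
    dm: DistanceMatrix,
    linkage: str = "complete",
    k: int | None = None,
    labels=None,
    max_k: int | None = None,
) -> ClusterTree:
    """Agglomerative clustering of the distance matrix with a flat cut.

    The cut is either a fixed subgroup count ``k`` or, when per-sample
    ``labels`` are given (e.g. "D2/Q30" combination strings), the smallest
    k maximising sample-weighted mean subgroup label purity.  Reports each
    subgroup's label composition and the number of label-pure subgroups.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if k is None and labels is None:
        raise ValueError("provide either a fixed k or labels for a purity cut")
    condensed = squareform(dm.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaf_order = np.asarray(hierarchy.leaves_list(Z))

    if labels is not None:
        labels = np.asarray(labels)
    if k is not None:
        assign = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        cut_k = k
    else:
        hi = max_k if max_k is not None else max(2, dm.n // 3)
        best = None
        for kk in range(2, hi + 1):
            a = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
            purity, _, _ = _purity_at(a, labels)
            if best is None or purity > best[0] + 1e-12:
                best = (purity, kk, a)
        _, cut_k, assign = best
    if labels is not None:
        mean_purity, n_pure, comp = _purity_at(assign, labels)
    else:
        mean_purity, n_pure, comp = float("nan"), 0, pd.DataFrame(
            {"subgroup": np.unique(assign)}
        )
    return ClusterTree(
        linkage_matrix=Z,
        leaf_order=leaf_order,
        subgroups=assign,
        sample_ids=dm.sample_ids,
        cut_k=int(len(np.unique(assign))),
        composition=comp,
        n_pure=n_pure,
        mean_purity=mean_purity,
    )


def forensics(report, dm: DistanceMatrix, tree: ClusterTree, n_neighbors: int = 5) -> list[dict]:
    """Machine-readable dossier for each cross-validation misclassification.

    For every misclassified sample: its true/predicted labels, its subgroup
    and that subgroup's label composition, and its nearest neighbours by
    normalised distance with their subgroups.
    """
    if set(report.sample_ids) != set(dm.sample_ids):
        raise ValueError("CV report and distance matrix cover different sample ids")
    if len(tree.sample_ids) != len(dm.sample_ids):
        raise ValueError("cluster tree and distance matrix disagree")
    pos = {s: i for i, s in enumerate(dm.sample_ids)}
    rep_pos = {s: i for i, s in enumerate(report.sample_ids)}
    dossier = []
    for sid in report.misclassified_ids:
        i = pos[sid]
        ri = rep_pos[sid]
        d = dm.values[i].copy()
        d[i] = np.inf
        nn = np.argsort(d, kind="stable")[:n_neighbors]
        sub = int(tree.subgroups[i])
        comp_row = tree.composition[tree.composition["subgroup"] == sub]
        dossier.append(
            {
                "sample_id": str(sid),
                "true_label": report.true_labels[ri].item()
                if hasattr(report.true_labels[ri], "item")
                else report.true_labels[ri],
                "predicted_label": report.predicted_labels[ri].item()
                if hasattr(report.predicted_labels[ri], "item")
                else report.predicted_labels[ri],
                "subgroup": sub,
                "subgroup_composition": comp_row.iloc[0]["composition"]
                if len(comp_row) and "composition" in comp_row.columns
                else {},
                "neighbors": [
                    {
                        "sample_id": str(dm.sample_ids[j]),
                        "distance": float(dm.values[i, j]),
                        "subgroup": int(tree.subgroups[j]),
                    }
                    for j in nn
                ],
            }
        )
    return dossier


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render(
    out_dir,
    dm: DistanceMatrix | None = None,
    tree: ClusterTree | None = None,
    pca: PCAResult | None = None,
    pca_labels=None,
    anova_values=None,
    anova_groups=None,
) -> list[str]:
    """Write the diagnostic figures (deterministic styling, PNG).

    Produces whichever of the three figures its inputs allow: distance
    heat-map with marginal dendrogram, 3-D PCA scatter coloured by label,
    and ANOVA box plots.  Returns the list of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if dm is not None:
        if dm.n < 2:
            raise ValueError("cannot render a distance matrix with fewer than 2 samples")
        order = tree.leaf_order if tree is not None else np.arange(dm.n)
        fig = plt.figure(figsize=(8, 7))
        if tree is not None:
            ax_d = fig.add_axes([0.05, 0.1, 0.12, 0.8])
            hierarchy.dendrogram(
                tree.linkage_matrix, orientation="left", no_labels=True,
                ax=ax_d, color_threshold=0, above_threshold_color="k",
            )
            ax_d.axis("off")
        ax = fig.add_axes([0.22, 0.1, 0.7, 0.8])
        im = ax.imshow(dm.values[np.ix_(order, order)], cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, fraction=0.046)
        path = out / "distance_matrix.png"
        fig.savefig(path, dpi=100, metadata={"Software": None})
        plt.close(fig)
        written.append(str(path))

    if pca is not None:
        if len(pca.scores) < 2:
            raise ValueError("cannot render a PCA scatter with fewer than 2 samples")
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(projection="3d")
        lab = np.asarray(pca_labels) if pca_labels is not None else np.zeros(len(pca.scores))
        for v in np.unique(lab):
            m = lab == v
            s = pca.scores[m]
            z = s[:, 2] if pca.n_components >= 3 else np.zeros(m.sum())
            ax.scatter(s[:, 0], s[:, 1], z, label=str(v), s=14, depthshade=False)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_zlabel("PC3")
        ax.legend(loc="upper right", fontsize=8)
        path = out / "pca_scatter.png"
        fig.savefig(path, dpi=100, metadata={"Software": None})
        plt.close(fig)
        written.append(str(path))

    if anova_values is not None and anova_groups is not None:
        values = np.asarray(anova_values, dtype=float)
        groups = np.asarray(anova_groups)
        levels = list(np.unique(groups))
        if len(values) < 2:
            raise ValueError("cannot render box plots for fewer than 2 samples")
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.boxplot([values[groups == g] for g in levels], tick_labels=[str(g) for g in levels])
        ax.set_ylabel("ROI fractal dimension")
        path = out / "anova_boxplot.png"
        fig.savefig(path, dpi=100, metadata={"Software": None})
        plt.close(fig)
        written.append(str(path))

    return written
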