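"""Fold-change profiles, average-linkage clustering, PCA and correlation.

Profiles (one per source or per subject group) are rows of log2 fold-change
ratios over features.  Clustering uses average linkage (UPGMA) on Euclidean
distances; *not detected* features are excluded pairwise from the distances
rather than imputed.  The dendrogram serializes to Newick with branch
lengths derived from merge heights.  PCA centers columns internally and uses
a deterministic sign convention (the largest-magnitude loading of each
component is positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SKPCA

from .diffexp import FoldChangeRecord
from .io_formats import ConfigurationError

__all__ = [
    "Dendrogram",
    "PCAResult",
    "fold_change_profile_matrix",
    "pairwise_euclidean",
    "hierarchical_cluster",
    "pca",
    "pearson_r",
    "plot_heatmap",
    "plot_pca_scores",
]


@dataclass
class Dendrogram:
    """Average-linkage merge tree over profile labels.

    ``linkage`` is a scipy linkage matrix; merge heights are non-decreasing
    (guaranteed for average linkage on a metric).
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def merge_order(self) -> list[tuple[frozenset, float]]:
        """Leaf-label sets of each merge with its height, in merge order."""
        clusters: dict[int, frozenset] = {i: frozenset([lab]) for i, lab in enumerate(self.labels)}
        n = len(self.labels)
        out = []
        for i, (a, b, h, _) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + i] = merged
            out.append((merged, float(h)))
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths split merge heights between children."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        node_repr = {i: _escape(lab) for i, lab in enumerate(self.labels)}
        for i, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - node_height[a]
            lb = h - node_height[b]
            node_repr[n + i] = f"({node_repr[a]}:{la:.6g},{node_repr[b]}:{lb:.6g})"
            node_height[n + i] = h
        return node_repr[n + len(self.linkage) - 1] + ";"


def _escape(label: str) -> str:
    return label.replace(" ", "_").replace("(", "_").replace(")", "_").replace(",", "_").replace(":", "_").replace(";", "_")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # profiles × components
    loadings: pd.DataFrame  # features × components
    explained_variance_ratio: np.ndarray


def fold_change_profile_matrix(
    records_by_profile: Mapping[str, Sequence[FoldChangeRecord]],
) -> pd.DataFrame:
    """Profiles × features matrix of log2 fold-change ratios.

    Features absent from a profile are NaN (*not detected*) and are excluded
    pairwise by downstream distances.
    """
    if len(records_by_profile) < 2:
        raise ConfigurationError("need at least two profiles")
    rows = {
        profile: {r.feature_id: np.log2(r.ratio) for r in records}
        for profile, records in records_by_profile.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def pairwise_euclidean(profiles: pd.DataFrame) -> np.ndarray:
    """Condensed Euclidean distance over pairwise-complete features.

    For each pair of profiles the distance uses only features observed in
    both, rescaled by sqrt(p/m) (p features total, m shared) so distances on
    different overlap sizes stay comparable.  A pair with no shared feature
    is an error.
    """
    X = profiles.to_numpy(dtype=float)
    n, p = X.shape
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(X[i]) & np.isfinite(X[j])
            m = int(mask.sum())
            if m == 0:
                raise ConfigurationError(
                    f"profiles {profiles.index[i]!r} and {profiles.index[j]!r} share no features"
                )
            d = np.sqrt(np.sum((X[i, mask] - X[j, mask]) ** 2) * (p / m))
            out.append(d)
    return np.asarray(out)


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Average-linkage (UPGMA-style) tree on pairwise Euclidean distances.

    Duplicate profiles merge at height 0.  Ties are broken toward the
    lowest-index pair (scipy's deterministic ordering), documented for
    reproducibility.
    """
    if len(profiles) < 2:
        raise ConfigurationError("need at least two profiles to cluster")
    if profiles.isna().all(axis=1).any():
        bad = profiles.index[profiles.isna().all(axis=1)][0]
        raise ConfigurationError(f"profile {bad!r} has no detected features")
    d = pairwise_euclidean(profiles)
    Z = hierarchy.linkage(d, method="average")
    return Dendrogram(tuple(str(i) for i in profiles.index), Z)


def pca(profiles: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of the profile matrix (columns centered internally).

    Features with any missing value are dropped before decomposition.
    Components are ordered by explained variance; each component's sign is
    fixed so its largest-magnitude loading is positive.  ``n_components``
    beyond the rank is truncated with a warning.
    """
    if len(profiles) < 2:
        raise ConfigurationError("need at least two profiles")
    complete = profiles.dropna(axis=1)
    if complete.shape[1] == 0:
        raise ConfigurationError("no feature is observed in every profile")
    max_rank = min(len(complete) - 1, complete.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(f"n_components={n_components} exceeds rank {max_rank}; truncated")
        n_components = max_rank
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(complete.to_numpy(dtype=float))
    loadings = model.components_.T  # features × components
    for c in range(loadings.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=complete.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=complete.columns, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation over pairwise-complete observations.

    Requires at least three complete pairs and nonzero variance in both
    vectors over those pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least three complete pairs")
    xs, ys = x[mask], y[mask]
    if np.var(xs) == 0 or np.var(ys) == 0:
        raise ValueError("zero variance in one of the inputs")
    return float(stats.pearsonr(xs, ys).statistic)


# ---------------------------------------------------------------------------
# figures (green/red/grey heatmap semantics; grey = not detected)
# ---------------------------------------------------------------------------

def plot_heatmap(profiles: pd.DataFrame, path) -> None:
    """Log2 fold-change heatmap: green down, red up, grey not detected."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

    cmap = LinearSegmentedColormap.from_list("greenred", ["green", "black", "red"])
    cmap.set_bad("0.6")
    vals = profiles.to_numpy(dtype=float)
    lim = np.nanmax(np.abs(vals)) or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.05 * profiles.shape[1] + 2), 0.4 * len(profiles) + 2))
    im = ax.imshow(vals, aspect="auto", cmap=cmap, norm=TwoSlopeNorm(0, -lim, lim),
                   interpolation="nearest")
    ax.set_yticks(range(len(profiles)), profiles.index)
    ax.set_xticks([])
    ax.set_xlabel(f"{profiles.shape[1]} features")
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca_scores(result: PCAResult, path, color_by=None) -> None:
    """Scatter of the first two component scores."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = result.scores.iloc[:, 0]
    ys = result.scores.iloc[:, 1] if result.scores.shape[1] > 1 else np.zeros(len(xs))
    if color_by is not None:
        groups = pd.Series(color_by)
        for g in sorted(set(groups)):
            sel = groups == g
            ax.scatter(xs[sel.to_numpy()], ys[sel.to_numpy()], label=str(g), s=30)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(xs, ys, s=30)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]*100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]*100:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
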