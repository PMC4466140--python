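"""The SH3 specificity landscape: profile correlations, clustering, classes.

All domains' binding profiles are compared by pairwise Pearson correlation;
the correlation matrix is hierarchically clustered (distance ``1 − r``),
and the main clusters are labeled with the canonical specificity classes
(Type I / II / III) by the majority motif class of each cluster's
top-binding peptides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import motifs
from .normalize import PeptideLibrary, ProfilePanel

LINKAGE_METHODS = ("single", "complete", "average", "ward")


def filter_panel(panel: ProfilePanel, min_species_per_family: int = 3) -> ProfilePanel:
    """Keep only domains whose family spans enough species.

    Mirrors restricting the clustered panel to families represented in at
    least ``min_species_per_family`` distinct species.
    """
    meta = panel.metadata
    if meta is None or meta[["family", "species"]].isna().any().any():
        raise ValueError("filter_panel needs family and species metadata")
    n_species = meta.groupby("family")["species"].nunique()
    keep_fams = set(n_species[n_species >= min_species_per_family].index)
    keep = [d for d in panel.domains if meta.loc[d, "family"] in keep_fams]
    return panel.subset(keep)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over domains."""

    domain_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.domain_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-10):
            raise ValueError("correlation entries must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.domain_ids, columns=self.domain_ids)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="domain_id")


def correlation_matrix(panel: ProfilePanel) -> CorrelationMatrix:
    """Pairwise Pearson correlations of all profiles over all probes.

    Zero-variance profiles cannot be correlated; they are excluded with a
    warning.  Domains are ordered lexicographically, which also makes the
    downstream clustering deterministic.
    """
    values = panel.values
    sd = values.std(axis=0, ddof=0)
    dead = list(sd[sd == 0].index)
    if dead:
        warnings.warn(f"excluding zero-variance profiles: {dead}", stacklevel=2)
        values = values.drop(columns=dead)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 domains with non-zero variance")
    ids = sorted(values.columns)
    r = np.corrcoef(values[ids].values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(ids, r)


@dataclass
class ClusterResult:
    """Agglomerative clustering of the correlation matrix (distance 1 − r)."""

    domain_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    order: list[str]  # leaf ordering
    method: str = "average"
    class_of: dict = field(default_factory=dict)

    def cut(self, k: int) -> pd.Series:
        """Cut the tree into k flat clusters (labels 1..k)."""
        if k > len(self.domain_ids):
            raise ValueError(f"k={k} exceeds {len(self.domain_ids)} domains")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.domain_ids, name="cluster")

    def to_newick(self) -> str:
        """Dendrogram as Newick text with heights encoded as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.domain_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def cluster(corr: CorrelationMatrix, linkage_method: str = "average") -> ClusterResult:
    """Hierarchical clustering of domains on distance ``d = 1 − r``.

    ``1 − r`` (not ``1 − |r|``): anti-correlated profiles are maximally
    dissimilar.  Input order is canonicalized lexicographically so ties in
    merge heights break deterministically.
    """
    if linkage_method not in LINKAGE_METHODS:
        raise ValueError(f"linkage_method must be one of {LINKAGE_METHODS}")
    ids = list(corr.domain_ids)
    perm = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in perm]
    d = 1.0 - corr.r[np.ix_(perm, perm)]
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=True)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    order = [ids_sorted[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(ids_sorted, Z, order, method=linkage_method)


def assign_classes(
    clusters: ClusterResult,
    panel: ProfilePanel,
    lib: PeptideLibrary,
    k: int = 3,
    top_n: int = 10,
) -> dict[str, str]:
    """Label the k main clusters with specificity classes I / II / III.

    Each cluster is labeled by the majority motif class among the pooled
    top-``top_n`` peptides of its member domains (Type I* peptides vote
    with Type I, which they resemble at the landscape level); exact ties
    give ``unassigned``.  Also stored on ``clusters.class_of``.
    """
    flat = clusters.cut(k)
    class_of: dict[str, str] = {}
    for c in sorted(flat.unique()):
        members = list(flat[flat == c].index)
        votes: dict[str, int] = {}
        for dom in members:
            top = motifs.select_top_peptides(panel.values[dom], top_n=top_n)
            for pid in top.index:
                cls = motifs.classify_motif(lib.sequences[pid])
                if cls == "I*":
                    cls = "I"
                if cls != "none":
                    votes[cls] = votes.get(cls, 0) + 1
        if not votes:
            label = "unassigned"
        else:
            best = max(votes.values())
            winners = [cls for cls, v in votes.items() if v == best]
            label = winners[0] if len(winners) == 1 else "unassigned"
        for dom in members:
            class_of[dom] = label
    clusters.class_of = class_of
    return class_of


def plot_heatmap(corr: CorrelationMatrix, clusters: ClusterResult, path) -> None:
    """Optional clustered heat-map PNG of the correlation matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clusters.order
    df = corr.to_frame().loc[order, order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(df.values, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
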