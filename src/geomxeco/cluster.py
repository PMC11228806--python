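"""Tumor-segment phenotype clustering and signature extraction.

Segments are clustered by k-means on the log2 Q3-normalized expression of
highly variable genes (Euclidean distance), with the number of clusters
chosen at the elbow of the within-cluster sum-of-squares (WSS) curve.
Phenotype signatures are then read off the PCA loadings: the contribution
of a gene to a component is its squared loading as a fraction of the
component's total; genes contributing more than the uniform expectation are
assigned to the axis (PC1 or PC2) they contribute most to, and split by
loading sign into the three cluster signatures. TME segments inherit the
cluster of the tumor segment they were dissected with (shared region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # genes x components
    scores: pd.DataFrame              # segments x components
    explained_variance_fraction: np.ndarray
    mean: pd.Series                   # per-gene centering mean

    def __post_init__(self) -> None:
        evf = np.asarray(self.explained_variance_fraction, float)
        if np.any(np.diff(evf) > 1e-12):
            raise ValueError("explained variance fractions must be nonincreasing")


@dataclass
class ClusterAssignment:
    labels: pd.Series                 # segment -> 1..k
    k: int
    wss: float
    seed: int
    iterations: int
    attempts: int
    wss_per_k: dict[int, float] = field(default_factory=dict)


@dataclass
class ClusterSignatures:
    """Three disjoint phenotype gene lists with signed PC contributions.

    ``sig_cluster1`` = positive PC1 contributors, ``sig_cluster2`` =
    positive PC2 contributors, ``sig_cluster3`` = negative PC2 contributors.
    """

    sig_cluster1: pd.Series           # gene -> signed contribution
    sig_cluster2: pd.Series
    sig_cluster3: pd.Series

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "cluster1": list(self.sig_cluster1.index),
            "cluster2": list(self.sig_cluster2.index),
            "cluster3": list(self.sig_cluster3.index),
        }


def select_hvg(em: ExpressionMatrix, n: int) -> list[str]:
    """Top-``n`` genes by variance across segments; ties broken by gene name."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(em.genes):
        raise ValueError(f"n={n} exceeds number of genes ({len(em.genes)})")
    var = em.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def run_pca(em: ExpressionMatrix, genes: list[str] | None = None,
            n_components: int | None = None) -> PCAResult:
    """PCA of segments over (a subset of) genes, with a fixed sign convention.

    Sign convention: each component is flipped so that the gene with the
    largest absolute loading has a positive loading, making downstream
    signature extraction reproducible across linear-algebra backends.
    """
    vals = em.values if genes is None else em.values.loc[genes]
    X = vals.T.to_numpy(float)  # segments x genes
    n_comp = n_components or min(X.shape[0] - 1, X.shape[1])
    if n_comp < 1:
        raise ValueError("need at least 2 segments for PCA")
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x components
    # orientation rule: largest-|loading| gene positive per component
    for c in range(loadings.shape[1]):
        top = np.argmax(np.abs(loadings[:, c]))
        if loadings[top, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=vals.index, columns=comp_names),
        scores=pd.DataFrame(scores, index=vals.columns, columns=comp_names),
        explained_variance_fraction=pca.explained_variance_ratio_,
        mean=pd.Series(pca.mean_, index=vals.index),
    )


def orient_pca_by_score(pca: PCAResult, score: pd.Series,
                        components: tuple[str, ...] = ("PC1", "PC2")) -> PCAResult:
    """Flip components so their segment scores anticorrelate with ``score``.

    PCA signs are arbitrary; for signature extraction the convention is that
    the neuroendocrine-low direction is positive. Orienting against an
    orienting score (typically the NE score) pins the sign of each listed
    component deterministically: after flipping, corr(component, score) <= 0,
    so the non-NE cluster sits at positive PC1 and the NE cluster at
    negative PC2.
    """
    loadings = pca.loadings.copy()
    scores = pca.scores.copy()
    s = score.reindex(scores.index).to_numpy(float)
    for comp in components:
        r = np.corrcoef(scores[comp].to_numpy(float), s)[0, 1]
        if r > 0:
            loadings[comp] = -loadings[comp]
            scores[comp] = -scores[comp]
    return PCAResult(loadings=loadings, scores=scores,
                     explained_variance_fraction=pca.explained_variance_fraction,
                     mean=pca.mean)


def kmeans_cluster(em: ExpressionMatrix, k: int, seed: int,
                   iterations: int = 50, attempts: int = 200,
                   orient_by: pd.Series | None = None) -> ClusterAssignment:
    """Best-of-``attempts`` k-means on segments (Euclidean, k-means++ init).

    Labels run 1..k. When ``orient_by`` maps segments to an orienting score
    (typically the NE score), clusters are renumbered by ascending cluster
    mean of that score so that cluster ``k`` is the highest-scoring one;
    otherwise labels follow first appearance in segment order.
    """
    X = em.values.T.to_numpy(float)
    segments = em.segments
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(segments):
        raise ValueError(f"k={k} exceeds number of segments ({len(segments)})")
    km = KMeans(n_clusters=k, n_init=attempts, max_iter=iterations,
                random_state=np.random.RandomState(seed))
    raw = km.fit_predict(X)

    if orient_by is not None:
        score = orient_by.reindex(segments).to_numpy(float)
        means = [(np.nanmean(score[raw == c]), c) for c in range(k)]
        order = [c for _, c in sorted(means, key=lambda t: (t[0], t[1]))]
    else:
        seen: list[int] = []
        for c in raw:
            if c not in seen:
                seen.append(c)
        order = seen + [c for c in range(k) if c not in seen]
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=segments, name="cluster")
    return ClusterAssignment(labels=labels, k=k, wss=float(km.inertia_),
                             seed=seed, iterations=iterations, attempts=attempts)


def choose_k_elbow(em: ExpressionMatrix, k_max: int, seed: int,
                   iterations: int = 50, attempts: int = 10,
                   ) -> tuple[int, dict[int, float]]:
    """Choose k at the elbow of the WSS curve.

    Runs k-means for k = 1..k_max and picks the k in 2..k_max-1 maximizing
    the second forward difference of WSS (the discrete curvature of the
    curve). A flat zero-WSS curve (all segments identical) yields k = 1.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    if len(em.segments) < k_max:
        raise ValueError("need at least k_max segments")
    wss = {}
    for k in range(1, k_max + 1):
        wss[k] = kmeans_cluster(em, k, seed=seed, iterations=iterations,
                                attempts=attempts).wss
    if wss[1] <= 1e-12:
        return 1, wss
    curvature = {k: wss[k - 1] - 2 * wss[k] + wss[k + 1]
                 for k in range(2, k_max)}
    k_star = max(sorted(curvature), key=lambda k: curvature[k])
    return k_star, wss


def extract_pc_signatures(pca: PCAResult, universe: list[str],
                          threshold: float | None = None) -> ClusterSignatures:
    """Derive the three phenotype signatures from PC1/PC2 loading contributions.

    contribution(gene, PC) = loading^2 / sum of squared loadings on that PC.
    A gene is a contributor when its larger contribution exceeds the
    threshold (default: the uniform expectation 1/|universe|); it is assigned
    to the single axis where it contributes more, guaranteeing disjointness.
    """
    if pca.loadings.shape[1] < 2:
        raise ValueError("need >= 2 components")
    load = pca.loadings.loc[universe, ["PC1", "PC2"]]
    denom = (load ** 2).sum(axis=0)
    if (denom < 1e-300).any() or np.allclose(pca.explained_variance_fraction[:2], 0):
        raise ValueError("degenerate PCA: zero variance on PC1/PC2")
    contrib = (load ** 2) / denom
    thr = threshold if threshold is not None else 1.0 / len(universe)

    best = contrib.max(axis=1)
    axis = contrib.idxmax(axis=1)
    is_contrib = best > thr

    pc1 = is_contrib & (axis == "PC1")
    pc2 = is_contrib & (axis == "PC2")
    sig1 = contrib.loc[pc1 & (load["PC1"] > 0), "PC1"]
    sig2 = contrib.loc[pc2 & (load["PC2"] > 0), "PC2"]
    sig3 = -contrib.loc[pc2 & (load["PC2"] < 0), "PC2"]
    srt = lambda s: s.sort_index()
    return ClusterSignatures(sig_cluster1=srt(sig1), sig_cluster2=srt(sig2),
                             sig_cluster3=srt(sig3))


def assign_tme_clusters(tumor_labels: pd.Series, ann: pd.DataFrame) -> pd.Series:
    """Assign each TME segment the cluster of its region-paired tumor segment.

    TME segments whose region has no labeled tumor segment get NA.
    """
    tumors = ann[ann["compartment"].isin(["tumor", "tumor_only"])]
    region_to_label = {}
    for seg, row in tumors.iterrows():
        if seg in tumor_labels.index:
            region_to_label[row["region_id"]] = tumor_labels[seg]
    tme = ann[ann["compartment"] == "TME"]
    out = pd.Series(
        [region_to_label.get(r, pd.NA) for r in tme["region_id"]],
        index=tme.index, dtype="Int64", name="cluster",
    )
    return out


def cluster_markers(em: ExpressionMatrix, labels: pd.Series,
                    alpha: float = 0.05, min_linear_fc: float = 2.0) -> pd.DataFrame:
    """Per-cluster marker genes by Wilcoxon rank-sum and median fold change.

    For every gene and cluster: two-sided Wilcoxon rank-sum p-value (cluster
    vs all other segments) and fold change log2(median Q3 in cluster /
    median Q3 in rest), computed on linear-scale Q3 values. A gene is a
    marker when p < ``alpha`` and the linear fold change exceeds
    ``min_linear_fc`` in either direction. When the denominator median is
    zero, a pseudo-count of 1 is added to both medians and the row flagged.
    """
    if em.state != "q3":
        raise ValueError("cluster_markers expects linear-scale q3 values")
    labels = labels.reindex(em.segments)
    rows = []
    log_min_fc = np.log2(min_linear_fc)
    for cl in sorted(labels.dropna().unique()):
        in_mask = (labels == cl).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            raise ValueError(f"cluster {cl} needs >= 2 segments on both sides")
        sub_in = em.values.loc[:, in_mask].to_numpy(float)
        sub_out = em.values.loc[:, ~in_mask].to_numpy(float)
        med_in = np.median(sub_in, axis=1)
        med_out = np.median(sub_out, axis=1)
        for gi, gene in enumerate(em.genes):
            res = stats.mannwhitneyu(sub_in[gi], sub_out[gi],
                                     alternative="two-sided", method="auto")
            pseudo = med_out[gi] == 0
            if pseudo:
                l2fc = np.log2((med_in[gi] + 1.0) / (med_out[gi] + 1.0))
            else:
                l2fc = np.log2(med_in[gi] / med_out[gi]) if med_in[gi] > 0 else -np.inf
            rows.append({"gene": gene, "cluster": int(cl), "p": float(res.pvalue),
                         "log2fc": float(l2fc), "pseudocount_applied": bool(pseudo)})
    table = pd.DataFrame(rows)
    table["fdr_bh"] = np.nan
    for cl, idx in table.groupby("cluster").groups.items():
        table.loc[idx, "fdr_bh"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]
    table["is_marker"] = (table["p"] < alpha) & (table["log2fc"].abs() > log_min_fc)
    return table
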