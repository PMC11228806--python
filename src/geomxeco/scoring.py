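"""Gene-set and signature scoring.

The workhorse is a single-sample gene-set enrichment (ssGSEA) engine: per
sample, genes are ranked by expression and the enrichment score is the sum
over the ranked list of the difference between the weighted in-set
cumulative distribution (weights |rank value|^alpha) and the uniform
out-of-set cumulative distribution. On top of it sit the neuroendocrine
(NE) differentiation score (correlation to NE / non-NE reference profiles),
ssGSEA-based stromal and immune scores, a linear tumor-purity model,
Shannon diversity of cell-type compositions, the IHC H-score, preranked
GSEA with a gene-permutation null, and pairwise signature correlation with
hierarchical ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix


@dataclass
class GeneSetCollection:
    """Named gene sets (as read from / written to GMT)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ScoreMatrix:
    """Gene-set x segment scores with a method tag."""

    values: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(float)).all():
            if not self.values.isna().any().any():
                raise ValueError("scores must be finite")


@dataclass
class PurityModel:
    """Linear model purity ~ intercept + stromal + immune."""

    intercept: float
    beta_stromal: float
    beta_immune: float
    training_r2: float


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _rank_order(expr: pd.Series) -> np.ndarray:
    """Indices ordering genes by descending expression, gene-name tie-break."""
    df = pd.DataFrame({"x": expr.to_numpy(float), "g": expr.index})
    return df.sort_values(["x", "g"], ascending=[False, True], kind="mergesort").index.to_numpy()


def ssgsea(em: ExpressionMatrix | pd.DataFrame, sets: GeneSetCollection,
           alpha: float = 0.25, normalize: bool = True) -> ScoreMatrix:
    """Single-sample GSEA scores for every set in every segment.

    Per sample the genes are ranked by expression (descending; ties broken
    by gene name for determinism). With rank values N..1 down the list and
    weights ``|rank value|**alpha`` for in-set genes, the enrichment score is

        ES = sum_i [ P_in(i) - P_out(i) ]

    where P_in is the weighted cumulative in-set frequency and P_out the
    uniform cumulative out-of-set frequency. With ``normalize`` the whole
    matrix is divided by its global (max - min), the GSVA convention. Sets
    with no overlap score NaN; overlaps of one gene trigger a warning.
    """
    values = em.values if isinstance(em, ExpressionMatrix) else em
    genes = list(values.index)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rank_values = None

    memberships = {}
    for name, gset in sets.sets.items():
        idx = np.array(sorted(gene_pos[g] for g in gset if g in gene_pos), dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; score is NaN")
        elif idx.size == 1:
            warnings.warn(f"gene set {name!r} overlaps a single gene")
        memberships[name] = idx

    out = pd.DataFrame(np.nan, index=list(sets.sets), columns=values.columns)
    for seg in values.columns:
        order = _rank_order(values[seg])
        rank_values = np.arange(n, 0, -1, dtype=float)  # top gene -> N
        weights = np.abs(rank_values) ** alpha
        in_sorted_pos = np.empty(n, dtype=int)
        in_sorted_pos[order] = np.arange(n)
        for name, idx in memberships.items():
            if idx.size == 0:
                continue
            mask = np.zeros(n, dtype=bool)
            mask[in_sorted_pos[idx]] = True
            w_in = np.where(mask, weights, 0.0)
            denom_in = w_in.sum()
            p_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.cumsum(mask) / mask.sum()
            n_out = n - idx.size
            if n_out == 0:
                p_out = np.zeros(n)
            else:
                p_out = np.cumsum(~mask) / n_out
            out.loc[name, seg] = float(np.sum(p_in - p_out))
    if normalize:
        arr = out.to_numpy(float)
        span = np.nanmax(arr) - np.nanmin(arr)
        if span > 0:
            out = out / span
    return ScoreMatrix(values=out, method="ssgsea")


# ---------------------------------------------------------------------------
# NE score and purity
# ---------------------------------------------------------------------------

def ne_score(em: ExpressionMatrix | pd.DataFrame, ne_profile: pd.Series,
             nonne_profile: pd.Series) -> pd.Series:
    """Neuroendocrine differentiation score in [-1, 1].

    score = (corr(segment, NE profile) - corr(segment, non-NE profile)) / 2
    over the signature genes shared by both profiles and the matrix.
    Zero-variance segments give NaN with a warning.
    """
    values = em.values if isinstance(em, ExpressionMatrix) else em
    genes = sorted(set(ne_profile.index) & set(nonne_profile.index) & set(values.index))
    if len(genes) < 3:
        raise ValueError("need >= 3 shared signature genes for the NE score")
    sub = values.loc[genes].to_numpy(float)
    ne = ne_profile[genes].to_numpy(float)
    nonne = nonne_profile[genes].to_numpy(float)
    out = {}
    for j, seg in enumerate(values.columns):
        x = sub[:, j]
        if np.std(x) == 0 or np.std(ne) == 0 or np.std(nonne) == 0:
            warnings.warn(f"segment {seg!r} has zero variance over signature genes")
            out[seg] = np.nan
            continue
        r_ne = float(np.corrcoef(x, ne)[0, 1])
        r_nonne = float(np.corrcoef(x, nonne)[0, 1])
        out[seg] = (r_ne - r_nonne) / 2.0
    return pd.Series(out, name="ne_score")


def fit_purity_model(training: pd.DataFrame, max_condition: float = 1e8) -> PurityModel:
    """OLS fit of purity ~ stromal + immune on (stromal, immune, purity) triples."""
    required = {"stromal", "immune", "purity"}
    if missing := required - set(training.columns):
        raise ValueError(f"training table missing columns: {sorted(missing)}")
    if len(training) < 3:
        raise ValueError("need >= 3 training triples")
    purity = training["purity"].to_numpy(float)
    if ((purity < 0) | (purity > 1)).any():
        raise ValueError("training purity must lie in [0, 1]")
    X = sm.add_constant(training[["stromal", "immune"]].to_numpy(float))
    if np.linalg.cond(X) > max_condition:
        raise ValueError("collinear stromal/immune predictors (ill-conditioned design)")
    fit = sm.OLS(purity, X).fit()
    return PurityModel(intercept=float(fit.params[0]), beta_stromal=float(fit.params[1]),
                       beta_immune=float(fit.params[2]), training_r2=float(fit.rsquared))


def predict_purity(model: PurityModel, scores: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Predict per-segment purity; values are clamped to [0, 1] and flagged."""
    raw = (model.intercept
           + model.beta_stromal * scores["stromal"].to_numpy(float)
           + model.beta_immune * scores["immune"].to_numpy(float))
    clamped = np.clip(raw, 0.0, 1.0)
    flags = pd.Series(raw != clamped, index=scores.index, name="clamped")
    return pd.Series(clamped, index=scores.index, name="purity"), flags


# ---------------------------------------------------------------------------
# simple indices
# ---------------------------------------------------------------------------

def shannon_index(p, tol: float = 1e-6) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (natural log, 0 ln 0 := 0).

    ``p`` must be nonnegative and sum to 1 within ``tol``; small deviations
    are renormalized.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > tol:
        raise ValueError(f"proportions sum to {total:.6g}, not 1 within {tol}")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> float:
    """IHC H-score = 1*(% weak) + 2*(% moderate) + 3*(% strong), in [0, 300]."""
    pcts = np.array([pct_weak, pct_moderate, pct_strong], dtype=float)
    if (pcts < 0).any():
        raise ValueError("percentages must be nonnegative")
    if pcts.sum() > 100 + 1e-9:
        raise ValueError("stained-nuclei percentages sum above 100")
    return float(pcts @ np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _weighted_ks_es(metric_sorted: np.ndarray, mask: np.ndarray) -> float:
    """Signed max-deviation weighted KS enrichment score on a sorted list."""
    w = np.abs(metric_sorted) * mask
    denom = w.sum()
    if denom == 0:
        w = mask.astype(float)
        denom = w.sum()
    p_hit = np.cumsum(w) / denom
    n_out = (~mask).sum()
    p_miss = np.cumsum(~mask) / n_out if n_out else np.zeros_like(p_hit)
    running = p_hit - p_miss
    i = np.argmax(np.abs(running))
    return float(running[i])


def preranked_gsea(ranked: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps unique genes to a signed metric. ES is the weighted KS
    statistic (weight |metric|); the null redraws same-size gene sets from
    the ranked universe. NES = ES / mean |null ES| of the matching sign; the
    p-value compares |ES| with the same-sign null tail. p-values are
    BH-adjusted across the scored sets. Sets without overlap are skipped and
    listed in the ``skipped`` attribute of the result.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranked list contains duplicate genes")
    if ranked.isna().any():
        raise ValueError("ranked metric contains NaN")
    if len(ranked) < 10:
        raise ValueError("ranked list must contain >= 10 genes")
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    order = pd.DataFrame({"m": ranked, "g": ranked.index}).sort_values(
        ["m", "g"], ascending=[False, True], kind="mergesort")
    metric = order["m"].to_numpy(float)
    pos = {g: i for i, g in enumerate(order["g"])}
    n = len(metric)
    rng = np.random.default_rng(seed)

    rows, skipped = [], []
    for name, genes in sets.sets.items():
        idx = [pos[g] for g in genes if g in pos]
        if not idx:
            skipped.append(name)
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es = _weighted_ks_es(metric, mask)
        size = len(idx)
        null = np.empty(n_perm)
        for b in range(n_perm):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=size, replace=False)] = True
            null[b] = _weighted_ks_es(metric, m)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size:
            nes = es / np.mean(np.abs(same))
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
        else:
            nes, p = np.nan, 1.0
        rows.append({"set": name, "size": size, "es": es, "nes": nes, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    if len(table):
        table["fdr_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    table.attrs["skipped"] = skipped
    return table


def rank_by_signed_logp(markers: pd.DataFrame,
                        p_floor: float = 1e-300) -> pd.Series:
    """Signed -log10(p) ranking metric from a marker table.

    metric = -log10(p) * sign(log2 fold change); p = 0 is floored at
    ``p_floor`` and flagged through a warning. Genes must be unique; the
    returned series is sorted by descending metric with gene-name
    tie-breaks.
    """
    if markers["gene"].duplicated().any():
        raise ValueError("marker table has duplicate genes; subset to one cluster first")
    p = markers["p"].to_numpy(float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 floored at machine-precision floor")
        p = np.maximum(p, p_floor)
    metric = -np.log10(p) * np.sign(markers["log2fc"].to_numpy(float))
    ser = pd.Series(metric, index=markers["gene"].to_numpy())
    df = pd.DataFrame({"m": ser, "g": ser.index}).sort_values(
        ["m", "g"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["m"].to_numpy(), index=df["g"].to_numpy(), name="metric")


def pairwise_signature_correlation(scores: ScoreMatrix | pd.DataFrame,
                                   ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Pearson correlation between score rows with average-linkage ordering.

    Returns (correlation matrix, hierarchical leaf order, excluded rows).
    Zero-variance rows are excluded and reported. Distances are 1 - r.
    """
    values = scores.values if isinstance(scores, ScoreMatrix) else scores
    if values.shape[0] < 2 or values.shape[1] < 3:
        raise ValueError("need >= 2 sets and >= 3 segments")
    var = values.var(axis=1, ddof=0)
    excluded = list(values.index[var == 0])
    kept = values.loc[var > 0]
    if kept.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant score rows")
    corr = pd.DataFrame(np.corrcoef(kept.to_numpy(float)),
                        index=kept.index, columns=kept.index)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.average(squareform(dist, checks=False))
    order = [kept.index[i] for i in hierarchy.leaves_list(link)]
    return corr, order, excluded
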