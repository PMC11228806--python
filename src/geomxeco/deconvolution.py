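"""Reference-based cell-type deconvolution of TME segments.

A segment's linear-scale (Q3-normalized, un-logged) expression is modeled
as a nonnegative simplex-constrained mixture of reference cell-type
profiles: minimize ||R w - x||^2 subject to w >= 0 and sum(w) = 1. The
default solver runs active-set nonnegative least squares and renormalizes
the weights onto the simplex (which also makes the result invariant to the
segment's overall scale); an optional ``qp`` mode solves the fully
constrained problem with SLSQP after normalizing the segment to the
reference scale. Composition diversity is the Shannon index of the
proportion rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix
from .scoring import shannon_index


@dataclass
class ReferenceProfiles:
    """Nonnegative mean expression profiles, genes x cell types."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.profiles.to_numpy(float)
        if (arr < 0).any():
            raise ValueError("reference profiles must be nonnegative")
        if (arr.sum(axis=0) == 0).any():
            raise ValueError("reference profiles contain an all-zero cell type")

    @property
    def celltypes(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.profiles.to_numpy(float)))


def deconvolve(em: ExpressionMatrix, ref: ReferenceProfiles,
               mode: str = "nnls", min_shared_genes: int = 10,
               ) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate per-segment cell-type proportions.

    Returns a (segments x cell types) proportion matrix whose rows lie on
    the simplex, and the per-segment relative residual norm
    ``||R w - x|| / ||x||`` of the underlying least-squares fit.
    """
    if em.state != "q3":
        raise ValueError("deconvolution expects linear-scale q3 expression")
    shared = sorted(set(em.genes) & set(ref.profiles.index))
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between matrix and reference "
            f"(need >= {min_shared_genes})")
    R = ref.profiles.loc[shared].to_numpy(float)
    X = em.values.loc[shared].to_numpy(float)
    k = R.shape[1]

    props = np.empty((X.shape[1], k))
    resid = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        nx = np.linalg.norm(x)
        if mode == "nnls":
            w, _ = optimize.nnls(R, x)
        elif mode == "qp":
            # literal fully constrained fit on the observed scale: the
            # sum(w) = 1 equality enters as a heavily weighted extra row
            lam = 1e6 * R.mean()
            R_aug = np.vstack([R, lam * np.ones((1, k))])
            x_aug = np.concatenate([x, [lam]])
            w, _ = optimize.nnls(R_aug, x_aug)
        else:
            raise ValueError(f"unknown solver mode {mode!r}")
        resid[j] = np.linalg.norm(R @ w - x) / nx if nx > 0 else 0.0
        total = w.sum()
        props[j] = w / total if total > 0 else np.full(k, 1.0 / k)
    prop_df = pd.DataFrame(props, index=em.segments, columns=ref.celltypes)
    return prop_df, pd.Series(resid, index=em.segments, name="relative_residual")


def composition_diversity(props: pd.DataFrame) -> pd.Series:
    """Shannon index H' of each segment's cell-type composition."""
    return pd.Series({seg: shannon_index(row.to_numpy(float))
                      for seg, row in props.iterrows()}, name="shannon")


def correlate_composition_with_ne(props: pd.DataFrame, ne_scores: pd.Series,
                                  ) -> pd.DataFrame:
    """Spearman correlation of each cell-type fraction with the NE score.

    ``ne_scores`` must be indexed like ``props`` (e.g. the paired tumor
    segment's NE score reindexed to the TME segment ids). Constant fractions
    give NaN rho and are flagged; p-values are BH-adjusted across cell
    types.
    """
    shared = [s for s in props.index if s in ne_scores.index]
    if len(shared) < 5:
        raise ValueError("need >= 5 paired segments")
    ne = ne_scores[shared].to_numpy(float)
    rows = []
    for ct in props.columns:
        frac = props.loc[shared, ct].to_numpy(float)
        if np.allclose(frac, frac[0]):
            rows.append({"celltype": ct, "rho": np.nan, "p": np.nan,
                         "constant": True})
            continue
        rho, p = stats.spearmanr(frac, ne)
        rows.append({"celltype": ct, "rho": float(rho), "p": float(p),
                     "constant": False})
    table = pd.DataFrame(rows).set_index("celltype")
    ok = ~table["p"].isna()
    table["fdr_bh"] = np.nan
    if ok.any():
        table.loc[ok, "fdr_bh"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return table
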