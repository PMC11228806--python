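"""Ligand-receptor communication scoring between paired tumor and TME segments.

Each annotated ligand-receptor pair carries a direction: ``in`` scores
TME -> tumor signaling (ligand read in the TME segment, receptor in the
paired tumor segment), ``out`` the reverse. Expression is first min-max
rescaled per gene to [0, 10] across all segments; a pair's ligand (or
receptor) activity is the geometric mean of its subunit values in the
sender (receiver) segment, and the pair score is the geometric mean of the
two activities. Pair scores are summarized per annotated sender/receiver
cell population (max over mapped pairs, with a mean-of-min cross-check
aggregator) and compared between ecosystem groups by Wilcoxon rank-sum
with BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

RESCALE_MAX = 10.0


@dataclass
class LRAnnotation:
    """Ligand-receptor pair annotations.

    ``table`` is indexed by pair_id with columns ligand_genes /
    receptor_genes (lists, multi-subunit allowed), sender_pops /
    receiver_pops (lists of cell-population names) and direction
    ('in' = TME->tumor, 'out' = tumor->TME).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"ligand_genes", "receptor_genes", "sender_pops", "receiver_pops", "direction"}
        if missing := req - set(self.table.columns):
            raise ValueError(f"LR annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate pair ids")
        for pid, row in self.table.iterrows():
            if not row["ligand_genes"] or not row["receptor_genes"]:
                raise ValueError(f"pair {pid} has an empty gene list")
            if row["direction"] not in ("in", "out"):
                raise ValueError(f"pair {pid} has unknown direction {row['direction']!r}")

    @classmethod
    def from_tsv(cls, path) -> "LRAnnotation":
        df = pd.read_csv(path, sep="\t", index_col=0)
        for col in ("ligand_genes", "receptor_genes", "sender_pops", "receiver_pops"):
            df[col] = df[col].map(lambda s: [t for t in str(s).split(";") if t])
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        for col in ("ligand_genes", "receptor_genes", "sender_pops", "receiver_pops"):
            out[col] = out[col].map(";".join)
        out.to_csv(path, sep="\t")


def rescale_expression(em: ExpressionMatrix | pd.DataFrame,
                       upper: float = RESCALE_MAX) -> pd.DataFrame:
    """Min-max rescale each gene to [0, upper] across all segments."""
    values = em.values if isinstance(em, ExpressionMatrix) else em
    if (values.to_numpy(float) < 0).any():
        raise ValueError("expression must be nonnegative before rescaling")
    lo = values.min(axis=1)
    span = values.max(axis=1) - lo
    span = span.replace(0, 1.0)  # constant genes rescale to 0
    return (values.sub(lo, axis=0)).div(span, axis=0) * upper


def _activity(expr: pd.Series, genes: list[str]) -> float | None:
    """Geometric mean of subunit values; None when any subunit is missing."""
    vals = []
    for g in genes:
        if g not in expr.index:
            return None
        v = float(expr[g])
        if v < 0:
            raise ValueError(f"negative expression for gene {g}")
        vals.append(v)
    arr = np.asarray(vals)
    if (arr == 0).any():
        return 0.0
    return float(np.exp(np.log(arr).mean()))


def lr_pair_score(sender_expr: pd.Series, receiver_expr: pd.Series,
                  pair: pd.Series) -> tuple[float, float, float] | None:
    """Score one ligand-receptor pair between a sender and a receiver segment.

    Returns (score, ligand_activity, receptor_activity) on rescaled
    expression, or None when a subunit gene is missing (absence of
    measurement, not absence of signal).
    """
    lig = _activity(sender_expr, pair["ligand_genes"])
    rec = _activity(receiver_expr, pair["receptor_genes"])
    if lig is None or rec is None:
        return None
    return float(np.sqrt(lig * rec)), lig, rec


def score_regions(em: ExpressionMatrix | pd.DataFrame, ann: pd.DataFrame,
                  lr: LRAnnotation) -> pd.DataFrame:
    """Score every annotated pair in every tumor/TME-paired region.

    Returns a long table (region, direction, pair, score, ligand_activity,
    receptor_activity); pairs with missing subunits are reported with NaN
    scores.
    """
    scaled = rescale_expression(em)
    tumor = ann[ann["compartment"] == "tumor"].groupby("region_id").groups
    tme = ann[ann["compartment"] == "TME"].groupby("region_id").groups
    regions = sorted(set(tumor) & set(tme))
    if not regions:
        raise ValueError("no regions with both a tumor and a TME segment")
    rows = []
    for region in regions:
        tseg, mseg = tumor[region][0], tme[region][0]
        if tseg not in scaled.columns or mseg not in scaled.columns:
            continue
        for pid, pair in lr.table.iterrows():
            if pair["direction"] == "in":
                sender, receiver = scaled[mseg], scaled[tseg]
            else:
                sender, receiver = scaled[tseg], scaled[mseg]
            res = lr_pair_score(sender, receiver, pair)
            if res is None:
                rows.append({"region": region, "direction": pair["direction"],
                             "pair": pid, "score": np.nan,
                             "ligand_activity": np.nan, "receptor_activity": np.nan})
            else:
                score, lig, rec = res
                rows.append({"region": region, "direction": pair["direction"],
                             "pair": pid, "score": score,
                             "ligand_activity": lig, "receptor_activity": rec})
    return pd.DataFrame(rows)


def summarize_population_interactions(pair_scores: pd.DataFrame, lr: LRAnnotation,
                                      aggregator: str = "max") -> pd.DataFrame:
    """Summary communication score per (region, direction, sender pop, receiver pop).

    ``max``: the maximum pair score over pairs mapped to the population pair
    (the headline aggregator). ``mean_of_min``: assign each pair the lower
    of its ligand and receptor activities, then average over mapped pairs
    (the cross-check aggregator). Populations with no scored pair are
    reported with NaN.
    """
    if aggregator not in ("max", "mean_of_min"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    expanded = []
    for pid, pair in lr.table.iterrows():
        for sp in pair["sender_pops"]:
            for rp in pair["receiver_pops"]:
                expanded.append({"pair": pid, "sender_pop": sp, "receiver_pop": rp})
    mapping = pd.DataFrame(expanded)
    merged = pair_scores.merge(mapping, on="pair")
    rows = []
    for (region, direction, sp, rp), grp in merged.groupby(
            ["region", "direction", "sender_pop", "receiver_pop"], sort=True):
        scored = grp.dropna(subset=["score"])
        if scored.empty:
            summary = np.nan
        elif aggregator == "max":
            summary = float(scored["score"].max())
        else:
            summary = float(np.minimum(scored["ligand_activity"],
                                       scored["receptor_activity"]).mean())
        rows.append({"region": region, "direction": direction,
                     "sender_pop": sp, "receiver_pop": rp,
                     "summary_score": summary, "n_pairs": len(scored)})
    return pd.DataFrame(rows)


def differential_interactions(pair_scores: pd.DataFrame,
                              groups: pd.Series | dict,
                              fdr_level: float = 0.05) -> pd.DataFrame:
    """Two-group Wilcoxon rank-sum test per (pair, direction) across regions.

    ``groups`` maps region -> group label (exactly two labels, each with
    >= 3 regions). Effect = difference of group medians (first label minus
    second, labels sorted); constant scores give p = 1. BH correction across
    pairs.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    g1 = set(groups.index[groups == labels[0]])
    g2 = set(groups.index[groups == labels[1]])
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need >= 3 regions per group")
    rows = []
    for (pid, direction), grp in pair_scores.groupby(["pair", "direction"], sort=True):
        grp = grp.dropna(subset=["score"])
        x = grp.loc[grp["region"].isin(g1), "score"].to_numpy(float)
        y = grp.loc[grp["region"].isin(g2), "score"].to_numpy(float)
        if len(x) < 3 or len(y) < 3:
            continue
        if np.allclose(np.concatenate([x, y]), x[0] if len(x) else y[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="auto").pvalue)
        rows.append({"pair": pid, "direction": direction,
                     "median_diff": float(np.median(x) - np.median(y)),
                     "group_high": labels[0] if np.median(x) > np.median(y) else labels[1],
                     "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr_bh"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["fdr_bh"] < fdr_level
    return table
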