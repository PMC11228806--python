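"""GeoMx DSP segment preprocessing.

The raw substrate is a probe-level count matrix (probes x segments) in which
each non-negative probe targets one gene and a pool of negative-control
probes measures background. Processing follows the standard DSP workflow:

1. probe -> gene collapse (mean of a gene's probes after outlier removal),
2. per-segment limit of quantification (LOQ) from the negative probes
   (geometric mean plus ``n_sd`` standard deviations),
3. segment QC on sequencing saturation, nuclei count and the fraction of
   genes detected above LOQ,
4. Q3 (third-quartile) normalization so every segment's Q3 equals the
   geometric mean of all segments' Q3s, followed by a log2(x+1) transform.

Expression matrices carry an explicit normalization state (``raw`` ->
``q3`` -> ``log2q3``); transforms applied out of order raise instead of
silently double-normalizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

State = Literal["raw", "q3", "log2q3"]

REQUIRED_PCM_COLUMNS = ("probe_id", "target_gene", "is_negative")
COMPARTMENTS = ("tumor", "TME", "normal", "tumor_only")


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class ProbeCountMatrix:
    """Probe-level counts with probe->gene mapping and negative-probe flags.

    Parameters
    ----------
    probes : DataFrame indexed by probe_id with columns ``target_gene``
        (gene symbol, or the negative-pool name for negative probes) and
        ``is_negative`` (bool).
    counts : DataFrame, probes x segments, nonnegative.
    """

    probes: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"target_gene", "is_negative"} - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        if not self.probes.index.equals(self.counts.index):
            raise ValueError("probe table and count matrix indices differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("probe counts must be nonnegative")
        if not self.probes["is_negative"].any():
            raise ValueError("at least one negative probe is required")

    @property
    def segments(self) -> list[str]:
        return list(self.counts.columns)

    def negative_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.probes["is_negative"].to_numpy()]

    def to_frame(self) -> pd.DataFrame:
        """Single TSV-ready frame: probe_id, target_gene, is_negative, segments."""
        out = self.probes[["target_gene", "is_negative"]].copy()
        return pd.concat([out, self.counts], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProbeCountMatrix":
        probes = df[["target_gene", "is_negative"]].copy()
        probes["is_negative"] = probes["is_negative"].astype(bool)
        counts = df.drop(columns=["target_gene", "is_negative"])
        return cls(probes=probes, counts=counts)


@dataclass
class ExpressionMatrix:
    """Gene x segment expression values with an explicit normalization state."""

    values: pd.DataFrame
    state: State = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "q3", "log2q3"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def segments(self) -> list[str]:
        return list(self.values.columns)

    def subset_segments(self, segment_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(segment_ids)].copy(), self.state)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a segment annotation table (indexed by segment_id).

    Required columns: compartment, patient_id, region_id, area, nuclei,
    saturation. A region_id may link at most one tumor and one TME segment.
    """
    required = {"compartment", "patient_id", "region_id", "area", "nuclei", "saturation"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = set(ann["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartments: {sorted(bad)}")
    sat = ann["saturation"].to_numpy(float)
    if ((sat < 0) | (sat > 1)).any():
        raise ValueError("saturation must lie in [0, 1]")
    for comp in ("tumor", "TME"):
        sub = ann[ann["compartment"] == comp]
        dup = sub["region_id"][sub["region_id"].duplicated()]
        if len(dup):
            raise ValueError(f"region(s) {sorted(set(dup))} link more than one {comp} segment")
    return ann


@dataclass
class QCReport:
    """Per-segment QC metrics, pass flags and failure reasons."""

    table: pd.DataFrame  # segment-indexed: saturation, nuclei, area, frac_above_loq, passed, reasons
    thresholds: "QCThresholds"
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> pd.Series:
        return self.table["passed"]

    @property
    def failed_segments(self) -> list[str]:
        return list(self.table.index[~self.table["passed"]])

    def to_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds),
            "segments": {
                seg: {
                    "saturation": float(row["saturation"]),
                    "nuclei": int(row["nuclei"]),
                    "area": float(row["area"]),
                    "frac_above_loq": float(row["frac_above_loq"]),
                    "passed": bool(row["passed"]),
                    "reasons": row["reasons"],
                }
                for seg, row in self.table.iterrows()
            },
            "notes": list(self.notes),
        }


@dataclass
class QCThresholds:
    """Segment-level QC cutoffs; a segment must meet all of them to pass."""

    min_saturation: float = 0.8
    min_nuclei: int = 20
    min_frac_above_loq: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_saturation <= 1:
            raise ValueError("min_saturation must lie in [0, 1]")
        if self.min_nuclei < 0:
            raise ValueError("min_nuclei must be nonnegative")
        if not 0 <= self.min_frac_above_loq <= 1:
            raise ValueError("min_frac_above_loq must lie in [0, 1]")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def collapse_probes(pcm: ProbeCountMatrix, outlier_fold: float = 10.0,
                    min_probes_for_outlier: int = 3) -> ExpressionMatrix:
    """Collapse probe counts to gene counts by the outlier-trimmed mean.

    For each gene in each segment the value is the arithmetic mean of the
    gene's probe counts after removing outlier probes. A probe is an outlier
    in a segment when its count falls outside ``[median/outlier_fold,
    median*outlier_fold]`` of the gene's probe counts there; the rule is only
    applied when the gene has at least ``min_probes_for_outlier`` probes
    (with fewer probes there is no robust center to trim against). Negative
    probes are excluded from gene rows (they feed the LOQ instead).
    """
    targets = pcm.probes.loc[~pcm.probes["is_negative"], "target_gene"]
    if targets.empty:
        raise ValueError("no non-negative probes to collapse")
    counts = pcm.counts.loc[targets.index].to_numpy(float)
    segments = pcm.segments

    gene_rows: dict[str, np.ndarray] = {}
    order = {}  # first-seen order for stable output
    for i, g in enumerate(targets):
        gene_rows.setdefault(g, []).append(i)
        order.setdefault(g, len(order))
    genes = sorted(gene_rows, key=lambda g: g)

    out = np.empty((len(genes), counts.shape[1]))
    for gi, g in enumerate(genes):
        rows = counts[gene_rows[g]]  # probes x segments
        if rows.shape[0] == 0:
            raise ValueError(f"gene {g} has zero probes")
        if rows.shape[0] < min_probes_for_outlier:
            out[gi] = rows.mean(axis=0)
            continue
        med = np.median(rows, axis=0)
        lo = med / outlier_fold
        hi = med * outlier_fold
        keep = (rows >= lo) & (rows <= hi)
        # never drop every probe: fall back to plain mean in that segment
        n_keep = keep.sum(axis=0)
        safe = np.where(n_keep > 0, n_keep, rows.shape[0])
        summed = np.where(n_keep > 0, (rows * keep).sum(axis=0), rows.sum(axis=0))
        out[gi] = summed / safe
    values = pd.DataFrame(out, index=genes, columns=segments)
    return ExpressionMatrix(values=values, state="raw")


def compute_loq(pcm: ProbeCountMatrix, n_sd: float = 2.0,
                mode: Literal["additive", "geometric"] = "additive") -> pd.Series:
    """Per-segment limit of quantification from the negative probes.

    ``additive`` (default): LOQ = geomean(neg) + n_sd * sd(neg), with the
    sample (ddof=1) arithmetic standard deviation. ``geometric``:
    LOQ = geomean(neg) * gsd(neg)**n_sd, where gsd is the geometric sd.
    Zero counts are replaced by a pseudo-count of 1 so the geometric mean is
    defined; the replacement leaves nonzero counts untouched.
    """
    neg = pcm.negative_counts().to_numpy(float)
    if neg.shape[0] < 2:
        raise ValueError("need >= 2 negative probes per segment for an sd")
    neg = np.where(neg <= 0, 1.0, neg)
    log_neg = np.log(neg)
    geomean = np.exp(log_neg.mean(axis=0))
    if mode == "additive":
        sd = neg.std(axis=0, ddof=1)
        loq = geomean + n_sd * sd
    elif mode == "geometric":
        gsd = np.exp(log_neg.std(axis=0, ddof=1))
        loq = geomean * gsd ** n_sd
    else:
        raise ValueError(f"unknown LOQ mode {mode!r}")
    return pd.Series(loq, index=pcm.segments, name="loq")


def qc_segments(em: ExpressionMatrix, ann: pd.DataFrame, loq: pd.Series,
                thresholds: QCThresholds | None = None,
                ) -> tuple[QCReport, ExpressionMatrix, pd.DataFrame]:
    """Flag and drop segments failing saturation / nuclei / LOQ-detection QC.

    Returns the report plus the expression matrix and annotation restricted
    to passing segments.
    """
    thresholds = thresholds or QCThresholds()
    validate_annotation(ann)
    segs = em.segments
    if set(segs) - set(ann.index) or set(segs) - set(loq.index):
        raise ValueError("expression, annotation and LOQ segment ids must match")

    vals = em.values
    frac_above = (vals.gt(loq[segs], axis=1)).mean(axis=0)

    rows = []
    for seg in segs:
        reasons = []
        sat = float(ann.loc[seg, "saturation"])
        nuc = int(ann.loc[seg, "nuclei"])
        fr = float(frac_above[seg])
        if sat < thresholds.min_saturation:
            reasons.append("saturation")
        if nuc < thresholds.min_nuclei:
            reasons.append("nuclei")
        if fr < thresholds.min_frac_above_loq:
            reasons.append("frac_above_loq")
        rows.append({
            "saturation": sat, "nuclei": nuc, "area": float(ann.loc[seg, "area"]),
            "frac_above_loq": fr, "passed": not reasons, "reasons": reasons,
        })
    table = pd.DataFrame(rows, index=pd.Index(segs, name="segment_id"))
    report = QCReport(table=table, thresholds=thresholds)

    keep = [s for s in segs if table.loc[s, "passed"]]
    return report, em.subset_segments(keep), ann.loc[keep].copy()


def q3_normalize(em: ExpressionMatrix, loq: pd.Series | None = None) -> ExpressionMatrix:
    """Q3-normalize a raw expression matrix.

    Each segment's Q3 (75th percentile) is computed on its genes above LOQ
    (all genes if ``loq`` is None); the segment is scaled by
    ``geomean(all Q3s) / Q3_segment`` so that after scaling every segment's
    Q3 equals the common geometric mean.
    """
    if em.state != "raw":
        raise ValueError(f"q3_normalize expects a raw matrix, got state {em.state!r}")
    vals = em.values
    q3 = {}
    for seg in em.segments:
        col = vals[seg]
        if loq is not None:
            detected = col[col > loq[seg]]
        else:
            detected = col
        if len(detected) == 0:
            raise ValueError(f"segment {seg!r} has no genes above LOQ")
        q = float(np.percentile(detected.to_numpy(float), 75))
        if q == 0:
            raise ValueError(f"segment {seg!r} has zero Q3; cannot normalize")
        q3[seg] = q
    q3_ser = pd.Series(q3)
    target = float(np.exp(np.log(q3_ser.to_numpy()).mean()))
    factors = target / q3_ser
    out = vals.mul(factors, axis=1)
    result = ExpressionMatrix(values=out, state="q3")
    result.q3_factors = factors  # type: ignore[attr-defined]
    return result


def log2_transform(em: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a Q3-normalized matrix."""
    if em.state != "q3":
        raise ValueError(f"log2_transform expects a q3 matrix, got state {em.state!r}")
    return ExpressionMatrix(values=np.log2(em.values + 1.0), state="log2q3")
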