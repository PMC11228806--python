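"""Synthetic GeoMx-like data with planted ground truth.

The generator emulates the segment structure of a DSP whole-transcriptome
study of metastatic small-cell lung cancer: ~10 patients contribute ~40
circular regions of interest; most regions are segmented into a paired
tumor (pan-CK+) and TME (pan-CK-) transcriptome, plus a few tumor-only and
normal segments. Three tumor phenotypes are planted — neuroendocrine (NE),
hybrid-NE and non-NE — each with its own gene program; hybrid segments
additionally express the NE and non-NE (EMT) programs at half their
activated means. TME segments are mixtures of cell-type reference profiles
whose composition covaries with the paired tumor's phenotype (hybrid TME is
fibroblast-dominated, non-NE TME immune-rich), counts are negative
binomial at the probe level, and negative-control probes draw from a low
background mean. Companion generators produce gene-set collections,
ligand-receptor annotations, reference profiles, purity-training triples
and survival cohorts whose hazard depends on a score group.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``(seed, substream)`` pairs, so a fixed seed reproduces identical
output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .communication import LRAnnotation
from .deconvolution import ReferenceProfiles
from .preprocess import ProbeCountMatrix
from .scoring import GeneSetCollection
from .survival import validate_cohort

PHENOTYPES = ("nonNE", "hybrid", "NE")  # cluster 1, 2, 3 label order

DEFAULT_CELLTYPES = ("CAF", "Macrophage", "Tcell_CD4", "Tcell_CD8",
                     "Treg", "Bcell", "NK", "Endothelial")

# baseline TME compositions per tumor phenotype (columns follow
# DEFAULT_CELLTYPES order): hybrid TME is CAF-dominated (low diversity),
# non-NE TME is immune-rich, NE TME sits in between with CAF/macrophage
# weight
_PHENO_COMPOSITION = {
    "nonNE":  np.array([0.08, 0.10, 0.15, 0.17, 0.12, 0.15, 0.15, 0.08]),
    "hybrid": np.array([0.55, 0.15, 0.05, 0.02, 0.05, 0.03, 0.03, 0.12]),
    "NE":     np.array([0.25, 0.25, 0.10, 0.08, 0.08, 0.06, 0.06, 0.12]),
    "normal": np.array([0.15, 0.10, 0.15, 0.15, 0.10, 0.10, 0.10, 0.15]),
}

_STROMAL_TYPES = ("CAF", "Endothelial")
_IMMUNE_TYPES = ("Macrophage", "Tcell_CD4", "Tcell_CD8", "Treg", "Bcell", "NK")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic GeoMx cohort."""

    n_patients: int = 10
    regions_per_patient: tuple[int, int] = (3, 6)
    n_paired_regions: int = 32
    n_tumor_only: int = 4
    n_normal: int = 4
    n_genes: int = 1000
    probes_per_gene: int = 3
    n_negative_probes: int = 50
    phenotype_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    signature_size_per_phenotype: int = 40
    celltypes: tuple[str, ...] = DEFAULT_CELLTYPES
    mixing_link_strength: float = 0.8
    nb_dispersion: float = 10.0
    lr_pairs_active: int = 5
    n_lr_pairs: int = 40
    hazard_ratio_true: float = 2.09
    n_low_quality_tme: int = 2
    program_fold: float = 8.0
    shared_genes_per_program: int = 12
    shared_fold: float = 4.0
    marker_genes_per_celltype: int = 15
    stromal_set_size: int = 30
    immune_set_size: int = 30
    n_decoy_sets: int = 5
    decoy_set_size: int = 40
    negative_probe_mean: float = 2.0
    composition_concentration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.phenotype_fractions, float)
        if abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
            raise ValueError("phenotype_fractions must be a simplex 3-vector")
        for name in ("n_patients", "n_paired_regions", "n_genes", "probes_per_gene",
                     "n_negative_probes", "signature_size_per_phenotype",
                     "n_lr_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.mixing_link_strength <= 1:
            raise ValueError("mixing_link_strength must lie in [0, 1]")
        planted = (3 * self.signature_size_per_phenotype
                   + 2 * self.shared_genes_per_program
                   + self.stromal_set_size + self.immune_set_size
                   + len(self.celltypes) * self.marker_genes_per_celltype)
        if self.n_genes < planted:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {planted} planted genes")

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, substream])


@dataclass
class GroundTruth:
    """Planted truth recorded alongside a synthetic dataset."""

    segment_phenotypes: dict[str, str]
    signature_genes: dict[str, list[str]]
    true_proportions: pd.DataFrame       # TME segments x cell types
    true_purity: dict[str, float]
    active_lr_pairs: list[str]
    hazard_ratio_true: float
    low_quality_segments: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "segment_phenotypes": self.segment_phenotypes,
            "signature_genes": self.signature_genes,
            "true_proportions": {s: dict(r) for s, r in self.true_proportions.iterrows()},
            "true_purity": self.true_purity,
            "active_lr_pairs": self.active_lr_pairs,
            "hazard_ratio_true": self.hazard_ratio_true,
            "low_quality_segments": self.low_quality_segments,
        }


# ---------------------------------------------------------------------------
# deterministic gene architecture (shared by segments and reference assets)
# ---------------------------------------------------------------------------

@dataclass
class _Architecture:
    genes: list[str]
    base_mean: np.ndarray
    programs: dict[str, list[str]]       # phenotype -> exclusive program genes
    shared_ne: list[str]                 # NE-lineage genes co-expressed by hybrid
    shared_emt: list[str]                # EMT genes co-expressed by hybrid
    stromal_set: list[str]
    immune_set: list[str]
    marker_genes: dict[str, list[str]]   # cell type -> marker genes
    lr_table: pd.DataFrame
    active_lr_pairs: list[str]
    reference: pd.DataFrame              # genes x cell types


def _build_architecture(config: SyntheticConfig) -> _Architecture:
    rng = config.rng(0)
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    base = np.clip(rng.lognormal(mean=np.log(30.0), sigma=1.0, size=n), 1.0, 3000.0)

    perm = rng.permutation(n)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        if cursor + k > n:
            raise ValueError(
                "n_genes too small to hold the planted programs, marker "
                "blocks and ligand-receptor genes")
        idx = perm[cursor:cursor + k]
        cursor += k
        return [genes[i] for i in idx]

    s = config.signature_size_per_phenotype
    programs = {ph: take(s) for ph in PHENOTYPES}
    shared_ne = take(config.shared_genes_per_program)
    shared_emt = take(config.shared_genes_per_program)
    stromal = take(config.stromal_set_size)
    immune = take(config.immune_set_size)
    markers = {ct: take(config.marker_genes_per_celltype) for ct in config.celltypes}

    # ligand/receptor genes come from the remaining (null) gene pool
    lr_rows = []
    for i in range(config.n_lr_pairs):
        n_lig = 2 if rng.random() < 0.15 else 1
        n_rec = 2 if rng.random() < 0.15 else 1
        direction = "in" if rng.random() < 0.5 else "out"
        sender = ([rng.choice(config.celltypes)] if direction == "in" else ["Tumor"])
        receiver = (["Tumor"] if direction == "in" else [rng.choice(config.celltypes)])
        lr_rows.append({
            "pair_id": f"LR{i + 1:03d}",
            "ligand_genes": take(n_lig),
            "receptor_genes": take(n_rec),
            "sender_pops": [str(x) for x in sender],
            "receiver_pops": [str(x) for x in receiver],
            "direction": direction,
        })
    lr_table = pd.DataFrame(lr_rows).set_index("pair_id")
    active = list(lr_table.index[:config.lr_pairs_active])

    # reference profiles: every cell type expresses the base means; its own
    # markers are strongly elevated, stromal genes rise in stromal types and
    # immune genes in immune types
    ref = pd.DataFrame(
        np.tile(base[:, None], (1, len(config.celltypes))),
        index=genes, columns=list(config.celltypes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for ct in config.celltypes:
        ref.loc[markers[ct], ct] *= 20.0
        if ct in _STROMAL_TYPES:
            ref.loc[stromal, ct] *= 6.0
        if ct in _IMMUNE_TYPES:
            ref.loc[immune, ct] *= 6.0
    # mild cell-type-specific multiplicative jitter so profiles are not
    # exactly collinear off the marker blocks
    jitter = rng.lognormal(0.0, 0.15, size=ref.shape)
    ref = ref * jitter
    del gene_pos
    return _Architecture(genes=genes, base_mean=base, programs=programs,
                         shared_ne=shared_ne, shared_emt=shared_emt,
                         stromal_set=stromal, immune_set=immune,
                         marker_genes=markers, lr_table=lr_table,
                         active_lr_pairs=active, reference=ref)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draw with var = mu + mu^2/dispersion (Poisson limit)."""
    mean = np.asarray(mean, float)
    if np.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


# ---------------------------------------------------------------------------
# segment generation
# ---------------------------------------------------------------------------

def _program_folds(config: SyntheticConfig) -> dict[str, float]:
    """Per-phenotype activation fold of the exclusive programs.

    The non-NE program is the strongest (its transcriptome is the most
    distinct, mirroring the much larger cluster-1 signature in real data)
    and the hybrid program slightly exceeds the NE program so that the
    PC2 orientation (hybrid side positive) is stable.
    """
    f = config.program_fold
    return {"nonNE": 2.0 * f, "hybrid": 1.25 * f, "NE": f}


def _phenotype_multiplier(arch: _Architecture, config: SyntheticConfig,
                          phenotype: str) -> np.ndarray:
    """Per-gene mean multiplier for a tumor phenotype.

    Each phenotype's exclusive program is elevated by its activation fold.
    The shared NE-lineage genes are elevated in NE segments and at an
    intermediate level (half, on the linear scale) in hybrid segments; the
    shared EMT genes likewise in non-NE and hybrid segments — hybrid tumors
    thus co-express NE and non-NE genes at intermediate levels.
    """
    mult = np.ones(config.n_genes)
    pos = {g: i for i, g in enumerate(arch.genes)}
    if phenotype == "normal":
        return mult
    folds = _program_folds(config)
    for ph in PHENOTYPES:
        if ph == phenotype:
            idx = [pos[g] for g in arch.programs[ph]]
            mult[idx] = folds[ph]
    sh_ne = [pos[g] for g in arch.shared_ne]
    sh_emt = [pos[g] for g in arch.shared_emt]
    if phenotype == "NE":
        mult[sh_ne] = config.shared_fold
    elif phenotype == "nonNE":
        mult[sh_emt] = config.shared_fold
    elif phenotype == "hybrid":
        mult[sh_ne] = config.shared_fold / 2.0
        mult[sh_emt] = config.shared_fold / 2.0
    return mult


def generate_segments(config: SyntheticConfig,
                      ) -> tuple[ProbeCountMatrix, pd.DataFrame, GroundTruth]:
    """Generate the probe-count matrix, segment annotation and ground truth."""
    arch = _build_architecture(config)
    rng = config.rng(1)
    pos = {g: i for i, g in enumerate(arch.genes)}
    celltypes = list(config.celltypes)
    ref_arr = arch.reference.to_numpy(float)
    # rescale reference mixture output to the tumor count scale
    ref_scale = arch.base_mean.mean() / ref_arr.mean()

    # --- region layout ------------------------------------------------------
    n_regions = config.n_paired_regions + config.n_tumor_only + config.n_normal
    lo, hi = config.regions_per_patient
    if not lo * config.n_patients <= n_regions <= hi * config.n_patients:
        raise ValueError("region totals incompatible with regions_per_patient range")
    counts = np.full(config.n_patients, lo)
    # distribute the remaining regions uniformly among patients with headroom
    remaining = n_regions - counts.sum()
    while remaining > 0:
        candidates = np.flatnonzero(counts < hi)
        counts[rng.choice(candidates)] += 1
        remaining -= 1

    region_patient = []
    for p, c in enumerate(counts):
        region_patient += [f"P{p + 1:02d}"] * c
    region_ids = [f"R{i + 1:03d}" for i in range(n_regions)]
    kinds = (["paired"] * config.n_paired_regions
             + ["tumor_only"] * config.n_tumor_only
             + ["normal"] * config.n_normal)
    kinds = [kinds[i] for i in rng.permutation(n_regions)]

    # allocate phenotypes by largest-remainder quota so the realized mix
    # matches phenotype_fractions exactly (a designed cohort, not an iid
    # draw), then shuffle the assignment across regions
    fr = np.asarray(config.phenotype_fractions, float)
    quota = fr * n_regions
    alloc = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - alloc))[: n_regions - alloc.sum()]:
        alloc[i] += 1
    pheno_draw = np.repeat(np.arange(len(PHENOTYPES)), alloc)
    pheno_draw = pheno_draw[rng.permutation(n_regions)]

    # --- per-segment means --------------------------------------------------
    seg_ids, seg_rows, seg_means = [], [], []
    phenotypes: dict[str, str] = {}
    true_props_rows, true_props_index = [], []
    purity: dict[str, float] = {}
    active_dirs = {pid: arch.lr_table.loc[pid, "direction"]
                   for pid in arch.active_lr_pairs}

    def lr_boost(region_pheno: str, compartment: str) -> np.ndarray:
        """Active-pair ligand/receptor upregulation in non-NE ecosystems."""
        boost = np.ones(config.n_genes)
        if region_pheno != "nonNE":
            return boost
        for pid, direction in active_dirs.items():
            lig = arch.lr_table.loc[pid, "ligand_genes"]
            rec = arch.lr_table.loc[pid, "receptor_genes"]
            lig_side = "TME" if direction == "in" else "tumor"
            rec_side = "tumor" if direction == "in" else "TME"
            if compartment in (lig_side, "tumor_only" if lig_side == "tumor" else ""):
                for g in lig:
                    boost[pos[g]] *= 6.0
            if compartment in (rec_side, "tumor_only" if rec_side == "tumor" else ""):
                for g in rec:
                    boost[pos[g]] *= 6.0
        return boost

    patient_effect = {f"P{p + 1:02d}": rng.lognormal(0.0, 0.05, size=config.n_genes)
                      for p in range(config.n_patients)}

    for region, patient, kind, ph_idx in zip(region_ids, region_patient, kinds, pheno_draw):
        pheno = PHENOTYPES[ph_idx] if kind != "normal" else "normal"
        base_alpha = _PHENO_COMPOSITION[pheno][:len(celltypes)].copy()
        base_alpha = base_alpha / base_alpha.sum()
        uniform = np.full(len(celltypes), 1.0 / len(celltypes))
        w = config.mixing_link_strength
        alpha = config.composition_concentration * (w * base_alpha + (1 - w) * uniform)
        props = rng.dirichlet(alpha)
        tme_mean = (ref_arr @ props) * ref_scale
        pe = patient_effect[patient]

        if kind == "normal":
            seg = f"{region}_normal"
            seg_ids.append(seg)
            seg_means.append(arch.base_mean * pe)
            seg_rows.append({"segment_id": seg, "compartment": "normal",
                             "patient_id": patient, "region_id": region})
            phenotypes[seg] = "normal"
            continue

        pur = float(rng.uniform(0.90, 1.0))
        tumor_mult = _phenotype_multiplier(arch, config, pheno)
        tumor_mean = (pur * arch.base_mean * tumor_mult + (1 - pur) * tme_mean) * pe
        comp = "tumor" if kind == "paired" else "tumor_only"
        tseg = f"{region}_tumor"
        seg_ids.append(tseg)
        seg_means.append(tumor_mean * lr_boost(pheno, "tumor"))
        seg_rows.append({"segment_id": tseg, "compartment": comp,
                         "patient_id": patient, "region_id": region})
        phenotypes[tseg] = pheno
        purity[tseg] = pur

        if kind == "paired":
            mseg = f"{region}_TME"
            seg_ids.append(mseg)
            seg_means.append(tme_mean * pe * lr_boost(pheno, "TME"))
            seg_rows.append({"segment_id": mseg, "compartment": "TME",
                             "patient_id": patient, "region_id": region})
            phenotypes[mseg] = pheno
            true_props_rows.append(props)
            true_props_index.append(mseg)

    mean_mat = np.column_stack(seg_means)  # genes x segments

    # --- probe-level counts -------------------------------------------------
    probe_ids, probe_targets, probe_neg = [], [], []
    for g in arch.genes:
        for p in range(config.probes_per_gene):
            probe_ids.append(f"{g}_p{p + 1}")
            probe_targets.append(g)
            probe_neg.append(False)
    for i in range(config.n_negative_probes):
        probe_ids.append(f"NEG_{i + 1:03d}")
        probe_targets.append("NegProbe")
        probe_neg.append(True)

    probe_mean = np.repeat(mean_mat, config.probes_per_gene, axis=0)
    neg_mean = np.full((config.n_negative_probes, len(seg_ids)),
                       config.negative_probe_mean)
    all_mean = np.vstack([probe_mean, neg_mean])
    counts_arr = _nb_draw(rng, all_mean, config.nb_dispersion)

    probes = pd.DataFrame({"target_gene": probe_targets, "is_negative": probe_neg},
                          index=pd.Index(probe_ids, name="probe_id"))
    counts_df = pd.DataFrame(counts_arr, index=probes.index, columns=seg_ids)
    pcm = ProbeCountMatrix(probes=probes, counts=counts_df)

    # --- annotation ---------------------------------------------------------
    ann = pd.DataFrame(seg_rows).set_index("segment_id")
    nseg = len(ann)
    ann["area"] = np.round(rng.normal(196_000.0, 15_000.0, size=nseg), 1)
    ann["nuclei"] = rng.integers(100, 400, size=nseg)
    ann["saturation"] = np.round(rng.uniform(0.85, 0.99, size=nseg), 4)
    ann["site"] = "synthetic"
    tme_segs = list(ann.index[ann["compartment"] == "TME"])
    n_low = min(config.n_low_quality_tme, len(tme_segs))
    low_q = [tme_segs[i] for i in rng.choice(len(tme_segs), size=n_low, replace=False)]
    ann.loc[low_q, "saturation"] = 0.5
    ann.loc[low_q, "nuclei"] = 5

    truth = GroundTruth(
        segment_phenotypes=phenotypes,
        signature_genes={ph: list(arch.programs[ph]) for ph in PHENOTYPES},
        true_proportions=pd.DataFrame(true_props_rows, index=true_props_index,
                                      columns=celltypes),
        true_purity=purity,
        active_lr_pairs=list(arch.active_lr_pairs),
        hazard_ratio_true=config.hazard_ratio_true,
        low_quality_segments=low_q,
    )
    return pcm, ann, truth


# ---------------------------------------------------------------------------
# reference assets
# ---------------------------------------------------------------------------

def generate_reference_assets(config: SyntheticConfig,
                              purity_noise_sd: float = 0.02,
                              n_purity_training: int = 100,
                              training_mode: str = "pseudobulk",
                              ) -> tuple[GeneSetCollection, LRAnnotation,
                                         ReferenceProfiles, pd.DataFrame]:
    """Gene sets, L/R annotations, reference profiles and purity training data.

    The gene-set collection contains the three planted phenotype programs,
    a stromal set, an immune set and uniform-random decoy sets.

    Purity training triples (stromal score, immune score, purity) come in
    two modes. ``pseudobulk`` (default) draws bulk-like samples with known
    tumor purity, mixes tumor and TME expression accordingly, and records
    their un-normalized ssGSEA stromal/immune scores — the same featurization
    the pipeline later applies to segments, so the fitted model transfers.
    ``linear`` emits the exact relation
    ``purity = 1 - 0.8*stromal - 0.8*immune + noise`` on abstract score
    units (useful for exact-recovery checks).
    """
    arch = _build_architecture(config)
    rng = config.rng(2)

    sets = {
        "NE_program": list(arch.programs["NE"]),
        "hybrid_program": list(arch.programs["hybrid"]),
        "nonNE_program": list(arch.programs["nonNE"]),
        "stromal": list(arch.stromal_set),
        "immune": list(arch.immune_set),
    }
    for i in range(config.n_decoy_sets):
        sets[f"decoy_{i + 1}"] = [
            arch.genes[j] for j in rng.choice(config.n_genes,
                                              size=config.decoy_set_size,
                                              replace=False)]
    collection = GeneSetCollection(sets=sets)

    if training_mode == "linear":
        stromal = rng.uniform(0.0, 0.4, size=n_purity_training)
        immune = rng.uniform(0.0, 0.4, size=n_purity_training)
        noise = rng.normal(0.0, purity_noise_sd, size=n_purity_training) \
            if purity_noise_sd > 0 else np.zeros(n_purity_training)
        purity = 1.0 - 0.8 * stromal - 0.8 * immune + noise
        training = pd.DataFrame({"stromal": stromal, "immune": immune,
                                 "purity": np.clip(purity, 0.0, 1.0)})
    elif training_mode == "pseudobulk":
        training = _pseudobulk_purity_training(config, arch, rng,
                                               n_purity_training)
    else:
        raise ValueError(f"unknown training_mode {training_mode!r}")
    return (collection, LRAnnotation(arch.lr_table.copy()),
            ReferenceProfiles(arch.reference.copy()), training)


def _pseudobulk_purity_training(config: SyntheticConfig, arch: _Architecture,
                                rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Bulk-like samples with known purity, scored by ssGSEA stromal/immune.

    Each sample mixes a random tumor phenotype profile with a random TME
    composition at purity p ~ U(0.3, 1); negative-binomial counts are drawn
    and the un-normalized ssGSEA stromal and immune scores recorded. ssGSEA
    is rank-based, so these scores live on the same scale as scores later
    computed on Q3/log2-normalized segments.
    """
    from .scoring import GeneSetCollection as _GSC, ssgsea as _ssgsea

    ref_arr = arch.reference.to_numpy(float)
    ref_scale = arch.base_mean.mean() / ref_arr.mean()
    purity = rng.uniform(0.3, 1.0, size=n)
    cols = {}
    for i in range(n):
        pheno = PHENOTYPES[rng.integers(0, len(PHENOTYPES))]
        mult = _phenotype_multiplier(arch, config, pheno)
        props = rng.dirichlet(np.ones(len(config.celltypes)))
        tme_mean = (ref_arr @ props) * ref_scale
        mean = purity[i] * arch.base_mean * mult + (1 - purity[i]) * tme_mean
        cols[f"B{i + 1:03d}"] = _nb_draw(rng, mean, config.nb_dispersion)
    em = pd.DataFrame(cols, index=arch.genes)
    scores = _ssgsea(em, _GSC({"stromal": list(arch.stromal_set),
                               "immune": list(arch.immune_set)}),
                     normalize=False)
    return pd.DataFrame({"stromal": scores.values.loc["stromal"].to_numpy(),
                         "immune": scores.values.loc["immune"].to_numpy(),
                         "purity": purity})


def reference_phenotype_profiles(config: SyntheticConfig,
                                 ) -> tuple[pd.Series, pd.Series]:
    """Mean expression profiles of pure NE and non-NE tumors over the
    planted NE + non-NE signature genes, for the correlation-based NE score."""
    arch = _build_architecture(config)
    genes = (list(arch.programs["NE"]) + list(arch.programs["nonNE"])
             + list(arch.shared_ne) + list(arch.shared_emt))
    pos = {g: i for i, g in enumerate(arch.genes)}
    ne_mult = _phenotype_multiplier(arch, config, "NE")
    nonne_mult = _phenotype_multiplier(arch, config, "nonNE")
    idx = [pos[g] for g in genes]
    base = arch.base_mean[idx]
    ne = pd.Series(np.log2(base * ne_mult[idx] + 1.0), index=genes, name="NE")
    nonne = pd.Series(np.log2(base * nonne_mult[idx] + 1.0), index=genes, name="nonNE")
    return ne, nonne


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def generate_survival_cohort(n: int, hr: float,
                             score_cutoff_quantile: float = 0.75,
                             seed: int = 0,
                             baseline_hazard: float = 0.03,
                             censoring_hazard: float = 0.01,
                             admin_censor_months: float = 60.0) -> pd.DataFrame:
    """Survival cohort whose hazard is multiplied by ``hr`` above a score quantile.

    Event times are exponential with rate ``baseline_hazard`` (per month),
    multiplied by ``hr`` for samples whose standard-normal score exceeds the
    ``score_cutoff_quantile`` empirical quantile. Censoring is independent:
    an exponential censoring time truncated at ``admin_censor_months``.
    Raises when no events remain (an all-censored cohort admits no log-rank
    comparison).
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    if not 0 < score_cutoff_quantile < 1:
        raise ValueError("score_cutoff_quantile must lie in (0, 1)")
    rng = np.random.default_rng([seed, 3])
    score = rng.normal(0.0, 1.0, size=n)
    cutoff = np.quantile(score, score_cutoff_quantile)
    high = score > cutoff
    rate = baseline_hazard * np.where(high, hr, 1.0)
    t_event = rng.exponential(1.0 / rate)
    t_cens = np.minimum(rng.exponential(1.0 / censoring_hazard, size=n),
                        admin_censor_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        raise ValueError("all observations censored; log-rank test undefined")
    cohort = pd.DataFrame({
        "sample": [f"S{i + 1:03d}" for i in range(n)],
        "time_months": np.maximum(time, 1e-6),
        "event": event,
        "score": score,
        "age": np.round(rng.normal(64.0, 8.0, size=n), 1),
        "sex": rng.integers(0, 2, size=n),
        "stage": rng.integers(1, 5, size=n),
    }).set_index("sample")
    return validate_cohort(cohort)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["celltypes"] = list(d["celltypes"])
    d["phenotype_fractions"] = list(d["phenotype_fractions"])
    d["regions_per_patient"] = list(d["regions_per_patient"])
    return d
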