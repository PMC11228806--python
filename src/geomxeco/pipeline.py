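"""End-to-end pipeline: simulate -> preprocess -> cluster -> score ->
deconvolve -> communicate -> survival.

A run is driven by a single :class:`RunConfig` (YAML-loadable) and writes
every stage's outputs under a fixed directory layout. Stages execute in
dependency order; each records a digest manifest (``<stage>.done.json``) of
its outputs and its parameters, so reruns with an unchanged config resume
from cached stage outputs, and the final report verifies that no stage
mutated another stage's files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cluster import (assign_tme_clusters, choose_k_elbow, cluster_markers,
                      extract_pc_signatures, kmeans_cluster, orient_pca_by_score,
                      run_pca, select_hvg)
from .communication import (LRAnnotation, differential_interactions,
                            score_regions, summarize_population_interactions)
from .deconvolution import (ReferenceProfiles, composition_diversity,
                            correlate_composition_with_ne, deconvolve)
from .preprocess import (ExpressionMatrix, ProbeCountMatrix, QCThresholds,
                         collapse_probes, compute_loq, log2_transform,
                         q3_normalize, qc_segments)
from .scoring import (GeneSetCollection, fit_purity_model, ne_score,
                      pairwise_signature_correlation, predict_purity, ssgsea)
from .survival import cox_hr, dichotomize_at_quantile, km_logrank
from .synthetic import (SyntheticConfig, config_to_dict, generate_reference_assets,
                        generate_segments, generate_survival_cohort,
                        reference_phenotype_profiles)

logger = logging.getLogger("geomxeco")

STAGES = ("simulate", "preprocess", "cluster", "score", "deconvolve",
          "communicate", "survival")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    qc: dict = field(default_factory=dict)          # QCThresholds kwargs
    hvg_n: int = 500
    k_max: int = 10
    kmeans_iterations: int = 50
    kmeans_attempts: int = 200
    elbow_attempts: int = 10
    ssgsea_alpha: float = 0.25
    fdr_level: float = 0.05
    survival_n: int = 81
    survival_quantile: float = 0.75

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.survival_quantile < 1:
            raise ValueError("survival_quantile must lie in (0, 1)")
        if self.hvg_n < 1 or self.k_max < 3:
            raise ValueError("hvg_n must be >= 1 and k_max >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def synthetic_config(self) -> SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", self.seed)
        for key in ("celltypes", "phenotype_fractions", "regions_per_patient"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return SyntheticConfig(**kwargs)


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    integrity_ok: bool = True

    def to_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings,
                "integrity_ok": self.integrity_ok}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_digest(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()


class PipelineRun:
    """Stateful executor for one configured run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.report = RunReport()

    # -- caching helpers ----------------------------------------------------

    def _done_path(self, stage: str) -> Path:
        return self.outdir / f"{stage}.done.json"

    def _is_cached(self, stage: str, params: dict) -> bool:
        done = self._done_path(stage)
        if not done.exists():
            return False
        try:
            manifest = io.read_json(done)
        except json.JSONDecodeError:
            return False
        if manifest.get("config_digest") != _stage_digest(params):
            return False
        for rel, digest in manifest.get("outputs", {}).items():
            f = self.outdir / rel
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def _finish(self, stage: str, params: dict, outputs: list[Path],
                elapsed: float, cached: bool = False) -> None:
        manifest = {
            "config_digest": _stage_digest(params),
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        }
        io.write_json(manifest, self._done_path(stage))
        self.report.stages[stage] = {
            "outputs": manifest["outputs"], "params": params,
            "seconds": round(elapsed, 3), "cached": cached,
        }
        logger.info("stage=%s done cached=%s elapsed=%.2fs", stage, cached, elapsed)

    # -- stages --------------------------------------------------------------

    def run(self) -> RunReport:
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            t0 = time.time()
            params = self._stage_params(stage)
            if self._is_cached(stage, params):
                manifest = io.read_json(self._done_path(stage))
                self.report.stages[stage] = {
                    "outputs": manifest["outputs"], "params": params,
                    "seconds": 0.0, "cached": True,
                }
                logger.info("stage=%s cache hit", stage)
                continue
            try:
                outputs = getattr(self, f"_stage_{stage}")()
            except Exception:
                logger.exception("stage=%s failed", stage)
                raise RuntimeError(f"pipeline stage {stage!r} failed") from None
            self._finish(stage, params, outputs, time.time() - t0)
        self._verify_integrity()
        io.write_json(self.report.to_dict(), self.outdir / "run_report.json")
        return self.report

    def _verify_integrity(self) -> None:
        for stage, info in self.report.stages.items():
            for rel, digest in info["outputs"].items():
                f = self.outdir / rel
                if not f.exists() or _sha256(f) != digest:
                    self.report.integrity_ok = False
                    self.report.warnings.append(
                        f"output {rel} of stage {stage} was modified later")

    def _stage_params(self, stage: str) -> dict:
        cfg = self.config
        base = {"seed": cfg.seed}
        if stage == "simulate":
            return {**base, "synthetic": config_to_dict(cfg.synthetic_config())}
        if stage == "preprocess":
            return {**base, "qc": cfg.qc}
        if stage == "cluster":
            return {**base, "hvg_n": cfg.hvg_n, "k_max": cfg.k_max,
                    "iterations": cfg.kmeans_iterations,
                    "attempts": cfg.kmeans_attempts,
                    "elbow_attempts": cfg.elbow_attempts}
        if stage == "score":
            return {**base, "alpha": cfg.ssgsea_alpha}
        if stage == "communicate":
            return {**base, "fdr_level": cfg.fdr_level}
        if stage == "survival":
            return {**base, "n": cfg.survival_n, "quantile": cfg.survival_quantile}
        return base

    # each stage reads its inputs from the run directory so that stages can
    # be cached and rerun independently

    def _stage_simulate(self) -> list[Path]:
        cfg = self.config.synthetic_config()
        pcm, ann, truth = generate_segments(cfg)
        sets, lr, ref, training = generate_reference_assets(cfg)
        ne_prof, nonne_prof = reference_phenotype_profiles(cfg)
        d = self.outdir / "synthetic"
        d.mkdir(exist_ok=True)
        io.write_matrix_tsv(pcm.to_frame(), d / "probe_counts.tsv")
        ann.to_csv(d / "annotations.csv")
        io.write_gmt(sets.sets, d / "gene_sets.gmt")
        lr.to_tsv(d / "lr_annotations.tsv")
        io.write_matrix_tsv(ref.profiles, d / "reference_profiles.tsv")
        training.to_csv(d / "purity_training.csv", index=False)
        io.write_matrix_tsv(pd.DataFrame({"NE": ne_prof, "nonNE": nonne_prof}),
                            d / "ne_reference_profiles.tsv")
        io.write_json(truth.to_dict(), d / "ground_truth.json")
        return sorted(d.iterdir())

    def _stage_preprocess(self) -> list[Path]:
        d = self.outdir / "preprocess"
        d.mkdir(exist_ok=True)
        src = self.outdir / "synthetic"
        pcm = ProbeCountMatrix.from_frame(io.read_matrix_tsv(src / "probe_counts.tsv"))
        ann = pd.read_csv(src / "annotations.csv", index_col=0)
        em_raw = collapse_probes(pcm)
        loq = compute_loq(pcm)
        report, em_raw, ann = qc_segments(em_raw, ann, loq, QCThresholds(**self.config.qc))
        em_q3 = q3_normalize(em_raw, loq=loq)
        em_log = log2_transform(em_q3)
        io.write_matrix_tsv(em_q3.values, d / "expression_q3.tsv")
        io.write_matrix_tsv(em_log.values, d / "expression_log2q3.tsv")
        loq.to_frame().to_csv(d / "loq.tsv", sep="\t")
        ann.to_csv(d / "annotations_qc.csv")
        io.write_json(report.to_dict(), d / "qc_report.json")
        return sorted(d.iterdir())

    def _load_expression(self, state: str) -> tuple[ExpressionMatrix, pd.DataFrame]:
        d = self.outdir / "preprocess"
        em = ExpressionMatrix(io.read_matrix_tsv(d / f"expression_{state}.tsv"),
                              state=state)
        ann = pd.read_csv(d / "annotations_qc.csv", index_col=0)
        return em, ann

    def _ne_scores(self, em: ExpressionMatrix) -> pd.Series:
        prof = io.read_matrix_tsv(self.outdir / "synthetic" / "ne_reference_profiles.tsv")
        return ne_score(em, prof["NE"], prof["nonNE"])

    def _stage_cluster(self) -> list[Path]:
        cfg = self.config
        d = self.outdir / "cluster"
        d.mkdir(exist_ok=True)
        em, ann = self._load_expression("log2q3")
        tumor_ids = list(ann.index[ann["compartment"].isin(["tumor", "tumor_only"])])
        em_t = em.subset_segments(tumor_ids)
        hvg = select_hvg(em_t, min(cfg.hvg_n, len(em_t.genes)))
        em_hvg = ExpressionMatrix(em_t.values.loc[hvg], state="log2q3")
        k_star, wss = choose_k_elbow(em_hvg, cfg.k_max, seed=cfg.seed,
                                     iterations=cfg.kmeans_iterations,
                                     attempts=cfg.elbow_attempts)
        orient = self._ne_scores(em_t)
        assign = kmeans_cluster(em_hvg, max(k_star, 1), seed=cfg.seed,
                                iterations=cfg.kmeans_iterations,
                                attempts=cfg.kmeans_attempts, orient_by=orient)
        pca = orient_pca_by_score(run_pca(em_t, genes=hvg), orient)
        sigs = extract_pc_signatures(pca, hvg)
        tme_labels = assign_tme_clusters(assign.labels, ann)

        em_q3, _ = self._load_expression("q3")
        markers = cluster_markers(em_q3.subset_segments(tumor_ids), assign.labels)

        (d / "hvg.txt").write_text("\n".join(hvg) + "\n")
        io.write_json({"k_star": k_star, "wss_per_k": {str(k): v for k, v in wss.items()}},
                      d / "elbow.json")
        assign.labels.to_frame().to_csv(d / "tumor_clusters.csv")
        tme_labels.to_frame().to_csv(d / "tme_clusters.csv")
        io.write_gmt(sigs.as_dict(), d / "signatures.gmt")
        markers.to_csv(d / "markers.csv", index=False)
        return sorted(d.iterdir())

    def _stage_score(self) -> list[Path]:
        d = self.outdir / "score"
        d.mkdir(exist_ok=True)
        em, ann = self._load_expression("log2q3")
        sets = GeneSetCollection(io.read_gmt(self.outdir / "synthetic" / "gene_sets.gmt"))
        scores = ssgsea(em, sets, alpha=self.config.ssgsea_alpha)
        io.write_matrix_tsv(scores.values, d / "ssgsea.tsv")

        ne = self._ne_scores(em)
        ne.to_frame().to_csv(d / "ne_scores.csv")

        training = pd.read_csv(self.outdir / "synthetic" / "purity_training.csv")
        model = fit_purity_model(training)
        tumor_ids = list(ann.index[ann["compartment"].isin(["tumor", "tumor_only"])])
        # un-normalized ssGSEA scores: the scale the purity model was trained on
        raw_scores = ssgsea(em.subset_segments(tumor_ids),
                            GeneSetCollection({"stromal": sets.sets["stromal"],
                                               "immune": sets.sets["immune"]}),
                            alpha=self.config.ssgsea_alpha, normalize=False)
        seg_scores = pd.DataFrame({
            "stromal": raw_scores.values.loc["stromal"],
            "immune": raw_scores.values.loc["immune"],
        })
        purity, clamped = predict_purity(model, seg_scores)
        pd.DataFrame({"purity": purity, "clamped": clamped}).to_csv(d / "purity.csv")

        corr, order, excluded = pairwise_signature_correlation(scores)
        io.write_matrix_tsv(corr, d / "score_correlation.tsv")
        io.write_json({"model": asdict(model), "hier_order": order,
                       "excluded_rows": excluded}, d / "score_meta.json")
        return sorted(d.iterdir())

    def _stage_deconvolve(self) -> list[Path]:
        d = self.outdir / "deconvolution"
        d.mkdir(exist_ok=True)
        em, ann = self._load_expression("q3")
        ref = ReferenceProfiles(io.read_matrix_tsv(
            self.outdir / "synthetic" / "reference_profiles.tsv"))
        tme_ids = list(ann.index[ann["compartment"] == "TME"])
        props, resid = deconvolve(em.subset_segments(tme_ids), ref)
        shannon = composition_diversity(props)

        ne = pd.read_csv(self.outdir / "score" / "ne_scores.csv", index_col=0)["ne_score"]
        region = ann["region_id"]
        tumor_by_region = {region[s]: s for s in ann.index
                           if ann.loc[s, "compartment"] == "tumor"}
        paired_ne = pd.Series(
            {s: ne.get(tumor_by_region.get(region[s])) for s in tme_ids},
            dtype=float)
        corr = correlate_composition_with_ne(props, paired_ne.dropna())

        io.write_matrix_tsv(props, d / "proportions.tsv")
        resid.to_frame().to_csv(d / "residuals.csv")
        shannon.to_frame().to_csv(d / "shannon.csv")
        corr.to_csv(d / "ne_correlation.csv")
        return sorted(d.iterdir())

    def _stage_communicate(self) -> list[Path]:
        d = self.outdir / "communication"
        d.mkdir(exist_ok=True)
        em, ann = self._load_expression("q3")
        lr = LRAnnotation.from_tsv(self.outdir / "synthetic" / "lr_annotations.tsv")
        pair_scores = score_regions(em, ann, lr)
        summary = summarize_population_interactions(pair_scores, lr, "max")
        summary_mom = summarize_population_interactions(pair_scores, lr, "mean_of_min")

        labels = pd.read_csv(self.outdir / "cluster" / "tumor_clusters.csv",
                             index_col=0)["cluster"]
        region_group = {}
        for seg, cl in labels.items():
            if ann.loc[seg, "compartment"] != "tumor":
                continue
            region_group[ann.loc[seg, "region_id"]] = (
                "nonNE" if cl == 1 else "NE_hybrid")
        groups = pd.Series(region_group)
        counts = groups.value_counts()
        if len(counts) == 2 and counts.min() >= 3:
            diff = differential_interactions(pair_scores, groups,
                                             fdr_level=self.config.fdr_level)
        else:
            diff = pd.DataFrame()
            self.report.warnings.append(
                "communicate: fewer than 3 regions in a group; differential test skipped")
        pair_scores.to_csv(d / "pair_scores.csv", index=False)
        summary.to_csv(d / "population_summary_max.csv", index=False)
        summary_mom.to_csv(d / "population_summary_mean_of_min.csv", index=False)
        diff.to_csv(d / "differential.csv", index=False)
        return sorted(d.iterdir())

    def _stage_survival(self) -> list[Path]:
        cfg = self.config
        d = self.outdir / "survival"
        d.mkdir(exist_ok=True)
        syn = cfg.synthetic_config()
        cohort = generate_survival_cohort(cfg.survival_n, syn.hazard_ratio_true,
                                          score_cutoff_quantile=cfg.survival_quantile,
                                          seed=cfg.seed)
        strat = dichotomize_at_quantile(cohort, q=cfg.survival_quantile)
        km = km_logrank(strat)
        cox = cox_hr(strat)
        cohort.to_csv(d / "cohort.csv")
        for grp, curve in km.curves.items():
            curve.to_csv(d / f"km_{grp}.csv")
        io.write_json({
            "logrank_chi2": km.chi2, "logrank_p": km.p, "unstable": km.unstable,
            "cox": asdict(cox), "n_high": strat.n_high, "n_low": strat.n_low,
            "cutoff": strat.cutoff,
        }, d / "results.json")
        return sorted(d.iterdir())


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages; see :class:`PipelineRun`."""
    return PipelineRun(config).run()
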