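"""End-to-end orchestration: simulate/load → normalize → filter → score →
QC → concordance → classify.

Stage order and outputs:

1. per-platform normalized matrices (``normalized/``);
2. full-signature (18-gene) scores for every dataset (``scores/``);
3. PCA QC report with flagged samples on the FFPE microarray
   (``qc/``);
4. probe filter report + per-gene max-mean probe selection on the QC-passed
   FFPE microarray samples, giving the reduced signature (``filter/``);
5. reduced-signature scores for every dataset;
6. four concordance tables — {all samples, QC-passed} × {full, reduced
   signature} (``concordance/``);
7. a LOOCV classification report per requested dataset, built on the
   reduced signature at gene level (``classify/``);
8. a run manifest recording seed, parameters and library versions.

Every tabular output is TSV; identical config + seed reproduces every file
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

import ffpesig
from ffpesig.cohort import CohortConfig, SyntheticCohort, generate_cohort, read_cohort
from ffpesig.concordance import ConcordanceTable, pairwise_concordance
from ffpesig.matrix import ExpressionMatrix
from ffpesig.normalization import housekeeping_normalize, log2_zscore_normalize, median_normalize
from ffpesig.nsc import CVReport, nsc_loocv
from ffpesig.probes import (
    FilterReport,
    ProbeFilterParams,
    collapse_by_mean,
    filter_probes,
    restrict_signature,
    select_max_mean_probe,
    write_gene_probe_map,
)
from ffpesig.qc import DEFAULT_PC1_THRESHOLD, QCResult, pca_sample_scores
from ffpesig.scoring import SampleScores, signature_score

logger = logging.getLogger(__name__)

FF_MICROARRAY = "microarray_FF"
FFPE_MICROARRAY = "microarray_FFPE"


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    mode: str = "simulate"  # "simulate" | "load"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_dir: str | None = None  # load mode: directory written by write_cohort
    filter_params: ProbeFilterParams = field(default_factory=ProbeFilterParams)
    pc1_threshold: float = DEFAULT_PC1_THRESHOLD
    delta_grid_size: int = 30
    classify_datasets: tuple[str, ...] = (FF_MICROARRAY, FFPE_MICROARRAY, "nanostring_FFPE")
    positive_class: str = "MUT"
    filter_on_qc_passed: bool = True
    filter_dataset: str = FFPE_MICROARRAY  # drives probe filtration and PCA
    output_dir: str = "ffpesig_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load":
            if self.cohort_dir is None:
                raise ValueError("load mode requires cohort_dir")
            if not Path(self.cohort_dir).is_dir():
                raise FileNotFoundError(f"cohort_dir does not exist: {self.cohort_dir}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "cohort" in d:
            c = d["cohort"]
            for key in ("probes_per_gene_range", "quality_good", "quality_bad"):
                if key in c:
                    c[key] = tuple(c[key])
            d["cohort"] = CohortConfig(**c)
        if "filter_params" in d:
            d["filter_params"] = ProbeFilterParams(**d["filter_params"])
        if "classify_datasets" in d:
            d["classify_datasets"] = tuple(d["classify_datasets"])
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: PipelineConfig
    cohort: SyntheticCohort
    normalized: dict[str, ExpressionMatrix]
    gene_level_full: dict[str, ExpressionMatrix]
    scores_full: dict[str, SampleScores]
    qc: QCResult
    filter_report: FilterReport
    gene_to_probe: dict[str, str]
    reduced_signature: list[str]
    scores_reduced: dict[str, SampleScores]
    concordance: dict[tuple[str, str], ConcordanceTable]  # (samples, geneset) keys
    cv_reports: dict[str, CVReport]
    output_dir: Path


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _normalize_all(cohort: SyntheticCohort) -> dict[str, ExpressionMatrix]:
    """Platform-appropriate normalization for every dataset.

    The microarrays arrive on a post-normalization log2 scale and pass
    through unchanged; counts get housekeeping scaling (NanoString-like)
    or median centering (targeted); FPKM gets log2 + z-score.
    """
    hk = list(cohort.config.housekeeping_genes)
    out: dict[str, ExpressionMatrix] = {}
    out[FF_MICROARRAY] = cohort.ff_microarray
    out[FFPE_MICROARRAY] = cohort.ffpe_microarray
    normalized_counts, _ = housekeeping_normalize(cohort.ffpe_nanostring, hk)
    out["nanostring_FFPE"] = normalized_counts
    out["targeted_FFPE"] = median_normalize(cohort.ffpe_targeted)
    out["rnaseq_FFPE"] = log2_zscore_normalize(cohort.ffpe_fpkm)
    return out


def _gene_level(normalized: dict[str, ExpressionMatrix]) -> dict[str, ExpressionMatrix]:
    """Collapse probe-level datasets to gene level (mean of probes)."""
    out = {}
    for label, mat in normalized.items():
        if mat.feature_to_gene is not None:
            out[label] = collapse_by_mean(mat)
        else:
            out[label] = mat
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write all outputs under ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("cohort", "normalized", "scores", "qc", "filter", "concordance", "classify"):
        (outdir / sub).mkdir(exist_ok=True)

    with _stage("cohort"):
        if config.mode == "simulate":
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            from ffpesig.cohort import write_cohort

            write_cohort(cohort, outdir / "cohort")
        else:
            cohort = read_cohort(config.cohort_dir)
        signature = list(cohort.config.signature_genes)

    with _stage("normalize"):
        normalized = _normalize_all(cohort)
        for label, mat in normalized.items():
            mat.to_tsv(outdir / "normalized" / f"{label}.tsv")
        gene_level_full = _gene_level(normalized)

    with _stage("score_full"):
        scores_full = {}
        for label, mat in gene_level_full.items():
            sig = restrict_signature(signature, mat.values.index)
            scores_full[label] = signature_score(mat, sig, dataset_label=label)
            scores_full[label].to_tsv(outdir / "scores" / f"{label}_full.tsv")

    with _stage("qc"):
        qc_input = normalized[config.filter_dataset]
        qc = pca_sample_scores(qc_input, threshold=config.pc1_threshold)
        qc.to_tsv(outdir / "qc" / "qc_report.tsv")
        # scatter data for a PC2-vs-PC1 plot
        pd.DataFrame({"pc1": qc.pc1, "pc2": qc.pc2}).rename_axis("sample_id").to_csv(
            outdir / "qc" / "pc_scatter.tsv", sep="\t", lineterminator="\n"
        )
        good_samples = [s for s in qc_input.sample_ids if s not in qc.flagged]
        logger.info("QC: %d/%d samples pass", len(good_samples), qc_input.n_samples)

    with _stage("filter"):
        filter_input = normalized[config.filter_dataset]
        if config.filter_on_qc_passed:
            filter_input = filter_input.subset_samples(good_samples)
        report = filter_probes(filter_input, config.filter_params, signature=signature)
        report.to_tsv(outdir / "filter" / "filter_report.tsv")
        selected, gene_to_probe = select_max_mean_probe(filter_input, report.retained_probe_ids)
        write_gene_probe_map(gene_to_probe, outdir / "filter" / "gene_to_probe.tsv")
        reduced_signature = restrict_signature(signature, selected.genes())
        logger.info(
            "filter: %d probes retained, reduced signature has %d of %d genes",
            len(report.retained_probe_ids), len(reduced_signature), len(signature),
        )

    with _stage("score_reduced"):
        # microarray datasets: use the selected (max-mean) probe per reduced-
        # signature gene, values taken for ALL samples; gene-level datasets:
        # plain restriction to the reduced signature.
        scores_reduced = {}
        sig_probes = [gene_to_probe[g] for g in reduced_signature]
        for label, mat in normalized.items():
            if mat.feature_to_gene is not None:
                sub = mat.subset_features(sig_probes)
                gene_vals = sub.values.copy()
                gene_vals.index = [sub.gene_of(p) for p in sub.feature_ids]
                gmat = ExpressionMatrix(gene_vals, mat.scale, None)
                sig = list(reduced_signature)
            else:
                gmat = gene_level_full[label]
                sig = restrict_signature(reduced_signature, gmat.values.index)
            scores_reduced[label] = signature_score(gmat, sig, dataset_label=label)
            scores_reduced[label].to_tsv(outdir / "scores" / f"{label}_reduced.tsv")

    with _stage("concordance"):
        concordance = {}
        for sample_key, exclude in (("all", frozenset()), ("qc_passed", qc.flagged)):
            for gene_key, scores in (("full", scores_full), ("reduced", scores_reduced)):
                table = pairwise_concordance(list(scores.values()), exclude=exclude)
                concordance[(sample_key, gene_key)] = table
                stem = outdir / "concordance" / f"concordance_{sample_key}_{gene_key}"
                table.to_tsv(f"{stem}.tsv", long_path=f"{stem}_long.tsv")

    with _stage("classify"):
        cv_reports = {}
        for label in config.classify_datasets:
            mat = normalized[label]
            if mat.feature_to_gene is not None:
                sub = mat.subset_features([gene_to_probe[g] for g in reduced_signature])
                gene_vals = sub.values.copy()
                gene_vals.index = [sub.gene_of(p) for p in sub.feature_ids]
                Xg = gene_vals
            else:
                sig = restrict_signature(reduced_signature, gene_level_full[label].values.index)
                Xg = gene_level_full[label].values.loc[sig]
            cv = nsc_loocv(
                Xg,
                cohort.labels,
                positive_class=config.positive_class,
                grid_size=config.delta_grid_size,
                dataset_label=label,
            )
            cv_reports[label] = cv
            cv.to_tsv(outdir / "classify" / f"cv_{label}.tsv")
            (outdir / "classify" / f"cv_{label}_summary.txt").write_text(
                cv.summary() + "\n", encoding="utf-8"
            )

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "mode": config.mode,
            "pc1_threshold": config.pc1_threshold,
            "filter_params": dataclasses.asdict(config.filter_params),
            "cohort_config": dataclasses.asdict(cohort.config),
            "n_samples": cohort.latent_log2.shape[1],
            "n_flagged": len(qc.flagged),
            "n_probes_input": cohort.ffpe_microarray.n_features,
            "n_probes_retained": len(report.retained_probe_ids),
            "full_signature_size": len(signature),
            "reduced_signature_size": len(reduced_signature),
            "reduced_signature": list(reduced_signature),
            "versions": {
                "ffpesig": ffpesig.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
        }
        (outdir / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
        )

    return PipelineResult(
        config=config,
        cohort=cohort,
        normalized=normalized,
        gene_level_full=gene_level_full,
        scores_full=scores_full,
        qc=qc,
        filter_report=report,
        gene_to_probe=gene_to_probe,
        reduced_signature=reduced_signature,
        scores_reduced=scores_reduced,
        concordance=concordance,
        cv_reports=cv_reports,
        output_dir=outdir,
    )
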