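"""Synthetic matched FF/FFPE multi-platform cohort generator.

The generator emulates the study design the downstream analysis assumes: a
cohort of tumour samples measured both as fresh-frozen (FF) tissue and as
formalin-fixed paraffin-embedded (FFPE) material, across several expression
platforms, with

* a latent gene × sample log2 expression matrix carrying a two-class
  mutation structure (MUT vs WT) that shifts signature-gene expression;
* probe-level microarray data (1–4 probes per gene, per-probe offsets);
* a NanoString-like count platform including a stable housekeeping panel,
  a targeted count platform, and an FPKM-scale platform;
* a per-sample RNA-quality factor ``q_s`` in (0, 1] that attenuates FFPE
  measurements toward a degradation floor and inflates their noise, with a
  planted subset of low-quality ("bad") samples;
* a planted subset of *problematic* signature genes whose FFPE response is
  strongly attenuated regardless of sample quality, emulating gene-specific
  probe sensitivity to fixation damage.

Degradation model, per FFPE measurement on a log2 signal ``x``:

    y = floor + r_g * q_s**gamma_p * (x - floor) + Normal(0, sd_tech^2 * (2 - q_s))

where ``floor`` is the background log2 level degraded signal collapses
toward, ``q_s`` the sample quality factor, ``r_g`` the gene sensitivity
(1 for ordinary genes, ``problematic_gene_sensitivity`` for planted
problematic signature genes), and ``gamma_p >= 1`` a per-probe fragility
exponent on the microarray platform only: dim probes (low per-probe
offset) degrade faster than bright ones, emulating the differing
sensitivities of gene-specific probes to fixation damage.  Gene-level
platforms (hybridization counts, FPKM) have no probe structure and use
``gamma = 1``, which is why they come out more forgiving of poor-quality
samples than the probe-based microarray.  At ``q_s = 1`` every exponent
collapses and FFPE equals FF exactly (conservation under the null).
Count platforms exponentiate, apply a per-sample size factor and round to
non-negative integers; the FPKM platform exponentiates and scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

from ffpesig.matrix import ExpressionMatrix, read_feature_map, write_feature_map
from ffpesig.resources import housekeeping_genes, signature_genes

logger = logging.getLogger(__name__)

MUT = "MUT"
WT = "WT"

# log2 units of FPKM offset relative to the latent microarray-like scale;
# purely cosmetic (downstream z-scoring removes it).
_FPKM_LOG2_OFFSET = 4.0


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions the analysis is designed for:
    54 matched FF/FFPE pairs, 15 planted degraded samples with quality
    factors well below the good range, a balanced two-class mutation
    structure shifting the 18 signature genes by 1 log2 unit, and 2 planted
    problematic signature genes.
    """

    n_samples: int = 54
    n_background_genes: int = 1000
    signature_genes: list[str] = field(default_factory=signature_genes)
    housekeeping_genes: list[str] = field(default_factory=housekeeping_genes)
    probes_per_gene_range: tuple[int, int] = (1, 4)
    class_fraction_mut: float = 0.5
    signature_effect: float = 1.0
    n_bad_samples: int = 15
    quality_good: tuple[float, float] = (0.85, 1.0)
    quality_bad: tuple[float, float] = (0.2, 0.5)
    noise_sd_biological: float = 0.5
    noise_sd_technical: float = 0.3
    degradation_floor: float = 2.0
    n_problematic_signature_genes: int = 2
    problematic_gene_sensitivity: float = 0.1
    probe_fragility_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_background_genes <= 0:
            raise ValueError("n_background_genes must be positive")
        if self.n_bad_samples < 0 or self.n_bad_samples >= self.n_samples:
            raise ValueError("n_bad_samples must satisfy 0 <= n_bad_samples < n_samples")
        lo, hi = self.probes_per_gene_range
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_gene_range must be an ordered interval with lo >= 1")
        if not 0.0 <= self.class_fraction_mut <= 1.0:
            raise ValueError("class_fraction_mut must lie in [0, 1]")
        for name in ("quality_good", "quality_bad"):
            a, b = getattr(self, name)
            if not (0.0 < a <= b <= 1.0):
                raise ValueError(f"{name} must be an ordered interval within (0, 1]")
        overlap = set(self.signature_genes) & set(self.housekeeping_genes)
        if overlap:
            raise ValueError(f"signature and housekeeping gene lists overlap: {sorted(overlap)}")
        if self.noise_sd_biological < 0 or self.noise_sd_technical < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if not 0 <= self.n_problematic_signature_genes <= len(self.signature_genes):
            raise ValueError("n_problematic_signature_genes out of range")
        if not 0.0 <= self.problematic_gene_sensitivity <= 1.0:
            raise ValueError("problematic_gene_sensitivity must lie in [0, 1]")
        if self.probe_fragility_scale < 0:
            raise ValueError("probe_fragility_scale must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort: latent truth plus one matrix per platform.

    All component matrices share an identical sample-ID ordering; every
    signature and housekeeping gene is represented on every platform.
    """

    config: CohortConfig
    latent_log2: pd.DataFrame  # gene × sample true log2 expression
    ff_microarray: ExpressionMatrix  # probe-level, log2
    ffpe_microarray: ExpressionMatrix  # probe-level, log2
    ffpe_nanostring: ExpressionMatrix  # gene-level counts (signature + housekeeping)
    ffpe_targeted: ExpressionMatrix  # gene-level counts (signature + housekeeping)
    ffpe_fpkm: ExpressionMatrix  # gene-level FPKM, all genes
    quality: pd.Series  # sample → q_s in (0, 1]
    planted_bad: frozenset[str]
    labels: pd.Series  # sample → MUT / WT
    problematic_genes: tuple[str, ...]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.latent_log2.columns)

    def datasets(self) -> dict[str, ExpressionMatrix]:
        """All platform matrices keyed by dataset label."""
        return {
            "microarray_FF": self.ff_microarray,
            "microarray_FFPE": self.ffpe_microarray,
            "nanostring_FFPE": self.ffpe_nanostring,
            "targeted_FFPE": self.ffpe_targeted,
            "rnaseq_FFPE": self.ffpe_fpkm,
        }


def _sample_ids(n: int) -> list[str]:
    # barcode-style zero-padded IDs, 3 digits for typical cohort sizes
    return [f"S{i:03d}" for i in range(101, 101 + n)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort; identical seed reproduces it bit-for-bit."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_ids(cfg.n_samples)

    background = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    genes = list(cfg.signature_genes) + list(cfg.housekeeping_genes) + background
    n_genes = len(genes)
    sig_idx = np.arange(len(cfg.signature_genes))
    hk_idx = np.arange(len(cfg.signature_genes), len(cfg.signature_genes) + len(cfg.housekeeping_genes))

    # gene baselines: housekeepers high and tight, everything else moderate
    mu = rng.normal(8.0, 1.2, size=n_genes)
    mu[hk_idx] = rng.normal(10.0, 0.5, size=hk_idx.size)
    a_s = rng.normal(0.0, 0.2, size=cfg.n_samples)  # per-sample amount-of-RNA offset

    # class labels
    n_mut = int(round(cfg.class_fraction_mut * cfg.n_samples))
    label_arr = np.array([WT] * cfg.n_samples, dtype=object)
    mut_positions = rng.choice(cfg.n_samples, size=n_mut, replace=False)
    label_arr[mut_positions] = MUT
    labels = pd.Series(label_arr, index=samples, name="class")

    # problematic signature genes: FFPE response nearly flat
    prob_positions = rng.choice(sig_idx, size=cfg.n_problematic_signature_genes, replace=False)
    problematic = tuple(sorted(genes[i] for i in prob_positions))
    sensitivity = np.ones(n_genes)
    sensitivity[prob_positions] = cfg.problematic_gene_sensitivity

    # latent truth: baseline + sample offset + class effect on signature genes
    eps = rng.normal(0.0, cfg.noise_sd_biological, size=(n_genes, cfg.n_samples))
    effect = np.zeros((n_genes, cfg.n_samples))
    effect[np.ix_(sig_idx, np.flatnonzero(label_arr == MUT))] = cfg.signature_effect
    latent = mu[:, None] + a_s[None, :] + effect + eps
    latent_df = pd.DataFrame(latent, index=genes, columns=samples)

    # per-sample quality factors with a planted bad subset
    bad_positions = rng.choice(cfg.n_samples, size=cfg.n_bad_samples, replace=False)
    q = rng.uniform(cfg.quality_good[0], cfg.quality_good[1], size=cfg.n_samples)
    q[bad_positions] = rng.uniform(cfg.quality_bad[0], cfg.quality_bad[1], size=cfg.n_bad_samples)
    quality = pd.Series(q, index=samples, name="quality")
    planted_bad = frozenset(samples[i] for i in bad_positions)

    # probe registry shared by FF and FFPE microarrays
    lo, hi = cfg.probes_per_gene_range
    n_probes_per_gene = rng.integers(lo, hi + 1, size=n_genes)
    probe_ids: list[str] = []
    probe_gene_idx: list[int] = []
    for gi, (g, k) in enumerate(zip(genes, n_probes_per_gene)):
        for j in range(k):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)
    probe_offsets = rng.normal(0.0, 0.3, size=len(probe_ids))
    probe_map = {p: genes[gi] for p, gi in zip(probe_ids, probe_gene_idx)}

    probe_signal = latent[probe_gene_idx, :] + probe_offsets[:, None]
    # dim probes are more fragile: gamma = 1 for the brightest, up to
    # 1 + probe_fragility_scale for the dimmest (rank via the offset CDF)
    probe_gamma = 1.0 + cfg.probe_fragility_scale * ndtr(-probe_offsets / 0.3)

    def tech_noise(shape) -> np.ndarray:
        return rng.normal(0.0, cfg.noise_sd_technical, size=shape)

    def degrade(signal: np.ndarray, gene_index: np.ndarray, gamma: np.ndarray | None = None) -> np.ndarray:
        """Apply the FFPE degradation model on the log2 scale."""
        r = sensitivity[gene_index][:, None]
        floor = cfg.degradation_floor
        q_eff = q[None, :] if gamma is None else q[None, :] ** gamma[:, None]
        attenuated = floor + r * q_eff * (signal - floor)
        noise_scale = np.sqrt(np.maximum(2.0 - q[None, :], 0.0))
        return attenuated + tech_noise(signal.shape) * noise_scale

    ff_vals = probe_signal + tech_noise(probe_signal.shape)
    ff_microarray = ExpressionMatrix(
        pd.DataFrame(ff_vals, index=probe_ids, columns=samples), "log2", dict(probe_map)
    )

    ffpe_vals = degrade(probe_signal, probe_gene_idx, gamma=probe_gamma)
    ffpe_microarray = ExpressionMatrix(
        pd.DataFrame(ffpe_vals, index=probe_ids, columns=samples), "log2", dict(probe_map)
    )

    panel_idx = np.concatenate([sig_idx, hk_idx])
    panel_genes = [genes[i] for i in panel_idx]

    def count_platform(gene_index: np.ndarray, names: list[str]) -> ExpressionMatrix:
        log2_deg = degrade(latent[gene_index, :], gene_index)
        size_factor = np.exp(rng.normal(0.0, 0.15, size=cfg.n_samples))
        counts = np.rint(np.maximum(np.exp2(log2_deg) * size_factor[None, :], 0.0))
        return ExpressionMatrix(pd.DataFrame(counts, index=names, columns=samples), "count", None)

    ffpe_nanostring = count_platform(panel_idx, panel_genes)
    ffpe_targeted = count_platform(panel_idx, panel_genes)

    all_idx = np.arange(n_genes)
    fpkm_log2 = degrade(latent, all_idx) - _FPKM_LOG2_OFFSET
    ffpe_fpkm = ExpressionMatrix(
        pd.DataFrame(np.exp2(fpkm_log2), index=genes, columns=samples), "fpkm", None
    )

    logger.info(
        "generated cohort: %d samples (%d bad), %d genes, %d probes, %d MUT / %d WT",
        cfg.n_samples, cfg.n_bad_samples, n_genes, len(probe_ids), n_mut, cfg.n_samples - n_mut,
    )
    return SyntheticCohort(
        config=cfg,
        latent_log2=latent_df,
        ff_microarray=ff_microarray,
        ffpe_microarray=ffpe_microarray,
        ffpe_nanostring=ffpe_nanostring,
        ffpe_targeted=ffpe_targeted,
        ffpe_fpkm=ffpe_fpkm,
        quality=quality,
        planted_bad=planted_bad,
        labels=labels,
        problematic_genes=problematic,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MATRIX_FILES = {
    "ff_microarray": ("microarray_ff.tsv", "log2"),
    "ffpe_microarray": ("microarray_ffpe.tsv", "log2"),
    "ffpe_nanostring": ("nanostring_ffpe.tsv", "count"),
    "ffpe_targeted": ("targeted_ffpe.tsv", "count"),
    "ffpe_fpkm": ("rnaseq_fpkm_ffpe.tsv", "fpkm"),
}


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    """Write every cohort component as TSV; returns the paths written.

    Layout: one matrix TSV per platform (features as rows, header row of
    sample IDs), ``probe_map.tsv`` (probe_id, gene_symbol), ``labels.tsv``
    (sample_id, class), ``quality.tsv`` (sample_id, quality, planted_bad),
    ``latent_log2.tsv`` and ``config.yaml``.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc

    written: list[Path] = []
    for attr, (fname, _) in _MATRIX_FILES.items():
        path = directory / fname
        getattr(cohort, attr).to_tsv(path)
        written.append(path)

    path = directory / "probe_map.tsv"
    write_feature_map(cohort.ff_microarray.feature_to_gene, path)
    written.append(path)

    path = directory / "latent_log2.tsv"
    latent = cohort.latent_log2.copy()
    latent.index.name = "gene_symbol"
    latent.to_csv(path, sep="\t", lineterminator="\n")
    written.append(path)

    path = directory / "labels.tsv"
    cohort.labels.rename_axis("sample_id").to_csv(path, sep="\t", lineterminator="\n")
    written.append(path)

    path = directory / "quality.tsv"
    qdf = pd.DataFrame(
        {
            "quality": cohort.quality,
            "planted_bad": [s in cohort.planted_bad for s in cohort.sample_ids],
        }
    )
    qdf.rename_axis("sample_id").to_csv(path, sep="\t", lineterminator="\n")
    written.append(path)

    path = directory / "config.yaml"
    cfg = asdict(cohort.config)
    cfg["problematic_genes"] = list(cohort.problematic_genes)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
    written.append(path)
    return written


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = Path(directory)
    cfg_raw = yaml.safe_load((directory / "config.yaml").read_text(encoding="utf-8"))
    problematic = tuple(cfg_raw.pop("problematic_genes", ()))
    for key in ("probes_per_gene_range", "quality_good", "quality_bad"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = CohortConfig(**cfg_raw)

    probe_map = read_feature_map(directory / "probe_map.tsv")
    matrices = {}
    for attr, (fname, scale) in _MATRIX_FILES.items():
        fmap = dict(probe_map) if attr.endswith("microarray") else None
        matrices[attr] = ExpressionMatrix.from_tsv(directory / fname, scale, fmap)

    latent = pd.read_csv(directory / "latent_log2.tsv", sep="\t", index_col=0)
    latent.index.name = None
    labels = pd.read_csv(directory / "labels.tsv", sep="\t", index_col=0)["class"]
    qdf = pd.read_csv(directory / "quality.tsv", sep="\t", index_col=0)
    quality = qdf["quality"]
    quality.name = "quality"
    labels.name = "class"
    labels.index = labels.index.astype(str)
    quality.index = quality.index.astype(str)
    planted_bad = frozenset(str(s) for s in qdf.index[qdf["planted_bad"]])
    return SyntheticCohort(
        config=config,
        latent_log2=latent,
        quality=quality,
        planted_bad=planted_bad,
        labels=labels,
        problematic_genes=problematic,
        **matrices,
    )
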