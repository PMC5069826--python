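"""Probe filtration and probe→gene collapse.

Microarray data carries several probes per gene.  Two stages reduce it to
one value per gene:

* :func:`filter_probes` drops probes that are insufficiently variable
  (fold-change criterion against the probe's median) or too often missing;
* :func:`collapse_by_mean` (pre-filtration convention) averages all probes
  of a gene, while :func:`select_max_mean_probe` (post-filtration
  convention) keeps, per gene, the single retained probe with the highest
  mean signal.

:func:`restrict_signature` intersects a signature with the genes that
survive filtration, yielding the reduced signature applied downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ffpesig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

REASON_FOLD_CHANGE = "fold_change_fail"
REASON_MISSINGNESS = "missingness_fail"


@dataclass
class ProbeFilterParams:
    """Retention thresholds.

    A probe is retained iff it shows at least ``fold_change``-fold deviation
    (in either direction) from its own median in at least ``min_fraction``
    of its non-missing samples, and has at most ``max_missing_fraction``
    missing values.  With ``values_are_log2`` the fold-change test is
    ``|x − median| >= log2(fold_change)``; otherwise it is a ratio test.
    """

    fold_change: float = 1.5
    min_fraction: float = 0.20
    max_missing_fraction: float = 0.50
    values_are_log2: bool = True

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


@dataclass
class FilterReport:
    """Exhaustive outcome of a probe filtration run."""

    retained_probe_ids: list[str]
    dropped_probe_ids: dict[str, str]  # probe → reason
    retained_gene_count: int
    dropped_signature_genes: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = [(p, "retained", "") for p in self.retained_probe_ids]
        rows += [(p, "dropped", r) for p, r in self.dropped_probe_ids.items()]
        pd.DataFrame(rows, columns=["probe_id", "status", "reason"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


def filter_probes(
    matrix: ExpressionMatrix,
    params: ProbeFilterParams = ProbeFilterParams(),
    signature: list[str] | None = None,
) -> FilterReport:
    """Apply the fold-change + missingness retention rule to every probe.

    The fold-change fraction uses the non-missing sample count as
    denominator; the missingness fraction uses the total sample count.
    A probe with all entries missing is dropped for missingness.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("filter_probes requires a non-empty matrix")
    values = matrix.values
    n_samples = matrix.n_samples
    retained: list[str] = []
    dropped: dict[str, str] = {}
    threshold = np.log2(params.fold_change)

    for probe in values.index:
        row = values.loc[probe]
        obs = row.dropna()
        missing_frac = 1.0 - len(obs) / n_samples
        if missing_frac > params.max_missing_fraction or len(obs) == 0:
            dropped[probe] = REASON_MISSINGNESS
            continue
        med = float(obs.median())
        if params.values_are_log2:
            hits = (obs - med).abs() >= threshold
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = obs / med
            hits = (ratio >= params.fold_change) | (ratio <= 1.0 / params.fold_change)
        if hits.sum() / len(obs) >= params.min_fraction:
            retained.append(probe)
        else:
            dropped[probe] = REASON_FOLD_CHANGE

    retained_genes = {matrix.gene_of(p) for p in retained}
    dropped_sig: list[str] = []
    if signature is not None:
        dropped_sig = [g for g in signature if g not in retained_genes]
    logger.info(
        "probe filtration: %d/%d probes retained in %d genes (%d signature genes dropped)",
        len(retained), matrix.n_features, len(retained_genes), len(dropped_sig),
    )
    return FilterReport(
        retained_probe_ids=retained,
        dropped_probe_ids=dropped,
        retained_gene_count=len(retained_genes),
        dropped_signature_genes=dropped_sig,
    )


def collapse_by_mean(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> ExpressionMatrix:
    """Average all probes of each gene into one gene-level row.

    ``genes`` restricts (and orders) the output; a requested gene with no
    probes raises.  Missing entries are excluded from each mean.
    """
    gene_map = matrix.gene_map()
    collapsed = matrix.values.groupby(gene_map, sort=False).mean()
    if genes is not None:
        absent = [g for g in genes if g not in collapsed.index]
        if absent:
            raise ValueError(f"genes with no probes in the matrix: {absent}")
        collapsed = collapsed.loc[genes]
    return ExpressionMatrix(collapsed, matrix.scale, None)


def select_max_mean_probe(
    matrix: ExpressionMatrix, retained: set[str] | list[str]
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Keep, per gene, the single retained probe with the highest mean signal.

    Ties on the across-sample mean are broken toward the lexicographically
    smallest probe ID.  Genes with no retained probe are absent from the
    output.  Rows are passed through unmodified (still indexed by probe ID).
    """
    retained = sorted(set(retained))
    missing = [p for p in retained if p not in matrix.values.index]
    if missing:
        raise KeyError(f"retained probes not in matrix: {missing[:5]}")
    if not retained:
        logger.warning("select_max_mean_probe: empty retained set; output is empty")
        empty = matrix.values.iloc[0:0]
        return ExpressionMatrix(empty, matrix.scale, {}), {}

    sub = matrix.values.loc[retained]
    means = sub.mean(axis=1, skipna=True)
    best: dict[str, str] = {}
    for probe in retained:  # lexicographic order ⇒ first seen wins ties
        gene = matrix.gene_of(probe)
        cur = best.get(gene)
        if cur is None or means[probe] > means[cur]:
            best[gene] = probe
    chosen = sorted(best.values())
    fmap = {p: matrix.gene_of(p) for p in chosen}
    out = ExpressionMatrix(matrix.values.loc[chosen].copy(), matrix.scale, fmap)
    return out, {g: p for g, p in best.items()}


def restrict_signature(signature: list[str], available) -> list[str]:
    """Ordered intersection of a signature with the available genes.

    Preserves signature order, logs dropped symbols, errors if nothing
    remains.
    """
    if not signature:
        raise ValueError("signature is empty")
    available = set(available)
    kept = [g for g in signature if g in available]
    dropped = [g for g in signature if g not in available]
    if dropped:
        logger.info("restrict_signature: dropped %d gene(s): %s", len(dropped), ", ".join(dropped))
    if not kept:
        raise ValueError("no signature gene is available after restriction")
    return kept


def write_gene_probe_map(mapping: dict[str, str], path) -> None:
    """Write the gene→selected-probe map as a two-column TSV."""
    pd.Series(mapping, name="probe_id").rename_axis("gene_symbol").sort_index().to_csv(
        Path(path), sep="\t", lineterminator="\n"
    )
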