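"""Composite signature scoring.

The signature score of a sample is the unweighted arithmetic mean of its
gene-level expression values over the signature genes.  The same rule is
applied on every platform and scale; cross-platform comparisons downstream
are rank-based, so absolute scale differences between platforms are
tolerated by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ffpesig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SampleScores:
    """Per-sample composite signature scores for one dataset."""

    scores: pd.Series  # sample → score
    dataset_label: str
    genes_used: list[str]

    @property
    def gene_set_size(self) -> int:
        return len(self.genes_used)

    def to_tsv(self, path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# dataset={self.dataset_label}\tgenes={self.gene_set_size}"
                     f"\tsamples={len(self.scores)}\n")
            self.scores.rename("score").rename_axis("sample_id").to_csv(
                fh, sep="\t", lineterminator="\n"
            )

    @classmethod
    def from_tsv(cls, path) -> "SampleScores":
        path = Path(path)
        header = path.read_text(encoding="utf-8").splitlines()[0]
        label = ""
        if header.startswith("#"):
            fields = dict(
                kv.split("=", 1) for kv in header.lstrip("# ").split("\t") if "=" in kv
            )
            label = fields.get("dataset", "")
        s = pd.read_csv(path, sep="\t", comment="#", index_col=0)["score"]
        s.index = s.index.astype(str)
        return cls(scores=s, dataset_label=label, genes_used=[])


def signature_score(
    gene_matrix: ExpressionMatrix,
    signature: list[str],
    dataset_label: str = "",
) -> SampleScores:
    """Mean expression over the signature genes, per sample.

    Every signature gene must be present as a feature (apply
    :func:`ffpesig.probes.restrict_signature` first otherwise).  Missing
    gene values are excluded from the affected sample's mean with a logged
    warning; a sample missing every signature value raises.
    """
    absent = [g for g in signature if g not in gene_matrix.values.index]
    if absent:
        raise ValueError(f"signature genes absent from matrix: {absent}")
    sub = gene_matrix.values.loc[list(signature)]
    n_obs = sub.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValueError(f"samples with no observed signature values: {empty}")
    n_missing = int(sub.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "signature_score(%s): %d missing signature value(s) excluded from sample means",
            dataset_label or "<unnamed>", n_missing,
        )
    scores = sub.mean(axis=0, skipna=True)
    scores.name = "score"
    return SampleScores(scores=scores, dataset_label=dataset_label, genes_used=list(signature))
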