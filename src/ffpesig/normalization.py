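"""Per-platform normalizations.

Three schemes, each matching the convention of the platform it serves:

* :func:`housekeeping_normalize` — NanoString-style reference-gene scaling:
  each sample is multiplied by (grand mean of per-sample housekeeping
  geometric means) / (its own housekeeping geometric mean), so that after
  normalization every sample has the same housekeeping geometric mean.
* :func:`median_normalize` — targeted-count convention: subtract each
  sample's median from all of its values, producing median-centered data.
* :func:`log2_zscore_normalize` — RNA-seq FPKM convention:
  ``log2(fpkm + pseudocount)`` then per-gene standardization across samples
  (mean 0, sample sd 1, n−1 denominator).

Missing values are excluded from medians and means and propagated
elsewhere; normalized counts are left as real numbers (not re-rounded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ffpesig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Audit record of per-sample factors.

    ``per_sample_factor`` holds multiplicative factors (housekeeping
    method) or additive offsets (median method); ``overall_mean`` is the
    grand mean of housekeeping geometric means (NaN for the median method).
    """

    per_sample_factor: pd.Series
    overall_mean: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.per_sample_factor.to_numpy())):
            raise ValueError("normalization factors must be finite")


def housekeeping_normalize(
    counts: ExpressionMatrix, hk_genes: list[str]
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Scale each sample so housekeeping geometric means agree across samples.

    For sample *s* with housekeeping geometric mean ``g_s``, the factor is
    ``f_s = mean_t(g_t) / g_s`` and every count in *s* is multiplied by
    ``f_s``.  Requires every housekeeping gene present with strictly
    positive counts in every sample.
    """
    if counts.scale != "count":
        raise ValueError(f"housekeeping_normalize expects count-scale data, got {counts.scale!r}")
    gene_map = counts.gene_map()
    hk_features: list[str] = []
    for gene in hk_genes:
        feats = gene_map.index[gene_map == gene].tolist()
        if not feats:
            raise ValueError(f"housekeeping gene {gene!r} is missing from the matrix")
        hk_features.extend(feats)

    hk = counts.values.loc[hk_features]
    bad = ~(hk > 0)
    if bad.to_numpy().any():
        feat, sample = next(
            (f, s) for f in hk.index for s in hk.columns if bool(bad.loc[f, s])
        )
        raise ValueError(
            f"housekeeping count must be strictly positive: feature {feat!r} "
            f"(gene {gene_map[feat]!r}) in sample {sample!r} is {hk.loc[feat, sample]!r}"
        )

    geomeans = np.exp(np.log(hk).mean(axis=0))
    overall = float(geomeans.mean())
    factors = overall / geomeans
    factors.name = "factor"
    normalized = counts.values.mul(factors, axis=1)
    fmap = dict(counts.feature_to_gene) if counts.feature_to_gene is not None else None
    out = ExpressionMatrix(normalized, "count", fmap)
    logger.info(
        "housekeeping normalization: %d reference features, factors in [%.4g, %.4g]",
        len(hk_features), factors.min(), factors.max(),
    )
    return out, NormalizationFactors(factors, overall)


def median_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each sample's median (over non-missing values) from its column."""
    values = counts.values
    n_obs = values.notna().sum(axis=0)
    empty = n_obs.index[n_obs == 0].tolist()
    if empty:
        raise ValueError(f"samples with no non-missing values: {empty}")
    medians = values.median(axis=0, skipna=True)
    centered = values.sub(medians, axis=1)
    fmap = dict(counts.feature_to_gene) if counts.feature_to_gene is not None else None
    return ExpressionMatrix(centered, "median_centered", fmap)


def log2_zscore_normalize(
    fpkm: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2-transform FPKM then z-score each gene across samples.

    ``y = log2(fpkm + pseudocount)``; each feature row is standardized to
    mean 0 and sample standard deviation 1 (n−1 denominator).  Features
    with zero variance after the log transform cannot be standardized and
    are excluded with a logged warning naming them.

    Already-standardized input (scale ``zscore``) skips the log transform,
    making the operation idempotent on its own output.
    """
    if fpkm.scale not in ("fpkm", "zscore"):
        raise ValueError(f"log2_zscore_normalize expects fpkm-scale data, got {fpkm.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if fpkm.scale == "fpkm":
        arr = fpkm.values.to_numpy()
        if np.nanmin(arr) < 0:
            raise ValueError("FPKM values must be non-negative")
        y = np.log2(fpkm.values + pseudocount)
    else:
        y = fpkm.values.copy()
    sd = y.std(axis=1, ddof=1, skipna=True)
    flat = sd.index[~(sd > 0)].tolist()
    if flat:
        logger.warning(
            "excluding %d zero-variance feature(s) from z-score normalization: %s",
            len(flat), ", ".join(map(str, flat[:20])),
        )
        y = y.drop(index=flat)
        sd = sd.drop(index=flat)
    z = y.sub(y.mean(axis=1, skipna=True), axis=0).div(sd, axis=0)
    fmap = None
    if fpkm.feature_to_gene is not None:
        fmap = {f: fpkm.feature_to_gene[f] for f in z.index}
    return ExpressionMatrix(z, "zscore", fmap)
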