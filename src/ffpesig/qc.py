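"""Sample-quality outlier detection by principal component analysis.

Degraded FFPE samples lose dynamic range: their expression collapses
toward a background floor, so across the full feature set they separate
from intact samples along the dominant axis of between-sample covariance.
The QC procedure:

1. center each feature across samples;
2. form the sample × sample covariance matrix over features
   (divisor ``n_features − 1``);
3. take its top-two unit eigenvectors as the per-sample PC1/PC2 scores;
4. flag samples with PC1 strictly below a threshold (default −0.10).

Eigenvector sign is indeterminate, so PC1/PC2 are oriented to correlate
positively with per-sample mean expression; signal-attenuated samples then
land at *low* PC1, which is the direction the −0.10 threshold assumes.
The threshold applies to unit-norm eigenvector entries (for ~54 samples a
uniform vector would have entries ≈ 0.136).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ffpesig.matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_PC1_THRESHOLD = -0.10

_SIGN_CONVENTION = "pearson(pc, per-sample mean expression) >= 0; ties: entry sum >= 0"


@dataclass
class QCResult:
    """PC scores, eigenvalues and the flagged outlier set."""

    pc1: pd.Series
    pc2: pd.Series
    eigenvalues: tuple[float, float]
    variance_fractions: tuple[float, float]
    threshold: float
    flagged: frozenset[str]
    sign_convention: str = _SIGN_CONVENTION

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "pc1": self.pc1,
                "pc2": self.pc2,
                "flagged": [s in self.flagged for s in self.pc1.index],
            }
        )
        df.rename_axis("sample_id").to_csv(Path(path), sep="\t", lineterminator="\n")


def _orient(vec: np.ndarray, sample_means: np.ndarray) -> np.ndarray:
    centered = sample_means - sample_means.mean()
    corr = float(vec @ centered)
    if corr > 0:
        return vec
    if corr < 0:
        return -vec
    return vec if vec.sum() >= 0 else -vec


def pca_sample_scores(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_PC1_THRESHOLD
) -> QCResult:
    """Compute per-sample PC1/PC2 scores and flag low-PC1 outliers.

    Requires ≥3 samples, ≥2 features and no missing values (impute or drop
    upstream).  Raises on degenerate input where all samples coincide.
    """
    X = matrix.values.to_numpy(dtype=float)
    if matrix.n_samples < 3:
        raise ValueError("PCA QC requires at least 3 samples")
    if matrix.n_features < 2:
        raise ValueError("PCA QC requires at least 2 features")
    if np.isnan(X).any():
        raise ValueError("PCA QC input contains missing values; impute or drop upstream")

    centered = X - X.mean(axis=1, keepdims=True)  # center each feature across samples
    cov = centered.T @ centered / (matrix.n_features - 1)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("degenerate input: all samples are identical")

    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    sample_means = X.mean(axis=0)
    pc1 = _orient(eigvecs[:, 0], sample_means)
    pc2 = _orient(eigvecs[:, 1], sample_means)

    samples = matrix.sample_ids
    pc1_s = pd.Series(pc1, index=samples, name="pc1")
    pc2_s = pd.Series(pc2, index=samples, name="pc2")
    flagged = _flag(pc1_s, threshold)
    logger.info(
        "PCA QC: PC1/PC2 explain %.1f%% / %.1f%% of variance; %d sample(s) below %.3g",
        100 * eigvals[0] / total_var, 100 * eigvals[1] / total_var, len(flagged), threshold,
    )
    return QCResult(
        pc1=pc1_s,
        pc2=pc2_s,
        eigenvalues=(float(eigvals[0]), float(eigvals[1])),
        variance_fractions=(float(eigvals[0] / total_var), float(eigvals[1] / total_var)),
        threshold=threshold,
        flagged=flagged,
    )


def _flag(pc1: pd.Series, threshold: float) -> frozenset[str]:
    return frozenset(pc1.index[pc1 < threshold])


def flag_outliers(qc: QCResult, threshold: float) -> frozenset[str]:
    """Samples with PC1 strictly below ``threshold``."""
    return _flag(qc.pc1, threshold)
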