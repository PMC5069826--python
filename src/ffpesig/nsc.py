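"""Nearest shrunken centroids (PAM) classification with nested LOOCV.

The classifier compares a sample to per-class centroids whose standardized
per-gene offsets from the overall centroid are soft-thresholded toward
zero, which performs embedded gene selection.  For gene *j* and class *k*
with ``n_k`` of *n* samples:

    d_kj  = (xbar_kj - xbar_j) / (m_k * (s_j + s0))
    m_k   = sqrt(1/n_k - 1/n)          (variance of the centroid contrast)
    d'_kj = sign(d_kj) * max(|d_kj| - delta, 0)
    xbar'_kj = xbar_j + m_k * (s_j + s0) * d'_kj

where ``s_j`` is the pooled within-class standard deviation (denominator
``n - K``), ``s0`` the median of the ``s_j`` (a variance-stabilising
offset), and ``delta >= 0`` the shrinkage amount.  A sample ``x`` is
assigned the class minimising the discriminant

    delta_k(x) = sum_j (x_j - xbar'_kj)^2 / (s_j + s0)^2 - 2 * log(pi_k).

Model selection runs leave-one-out cross-validation over a grid of
``delta`` values with the *entire* fit — pooled variances, centroids and
hence gene selection — recomputed inside every fold; the chosen ``delta``
minimises the LOOCV error, ties broken toward the largest (most
parsimonious) value.

Surface: statsmodels-style — build a :class:`NearestShrunkenCentroids`
model from data, call :meth:`~NearestShrunkenCentroids.fit` for an
:class:`NSCModel` at one ``delta`` or
:meth:`~NearestShrunkenCentroids.fit_loocv` for a :class:`CVReport` with a
``summary()``.  The plain functions :func:`nsc_train`,
:func:`nsc_predict`, :func:`nsc_loocv` expose the same computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GRID_SIZE = 30


def _validate_inputs(X: pd.DataFrame, y: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(X)
    y = pd.Series(y)
    if list(y.index) != list(X.columns):
        y = y.reindex(X.columns)
    if y.isna().any():
        raise ValueError("labels missing for some samples")
    if X.isna().to_numpy().any():
        raise ValueError("X contains missing values")
    return X, y


@dataclass
class NSCModel:
    """A fitted shrunken-centroid classifier (results object)."""

    classes: list[str]
    overall_centroid: pd.Series  # gene → xbar_j
    class_centroids: pd.DataFrame  # gene × class, unshrunken xbar_kj
    pooled_within_sd: pd.Series  # gene → s_j
    s0: float
    m_k: pd.Series  # class → m_k
    delta: float
    d: pd.DataFrame  # gene × class standardized offsets
    d_shrunk: pd.DataFrame
    shrunken_centroids: pd.DataFrame  # gene × class
    priors: pd.Series  # class → pi_k
    m_variant: str = "minus"

    @property
    def surviving_genes(self) -> list[str]:
        mask = (self.d_shrunk != 0).any(axis=1)
        return list(self.d_shrunk.index[mask])

    def predict(self, X: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
        """Predict labels for gene × sample data ``X``.

        Returns the predicted labels and the per-class discriminant scores
        (classes × samples; smaller is closer).  Exact ties go to the first
        class in ``self.classes``.
        """
        X = pd.DataFrame(X)
        genes = list(self.overall_centroid.index)
        missing = [g for g in genes if g not in X.index]
        if missing:
            raise ValueError(f"genes missing from prediction input: {missing[:5]}")
        Xg = X.loc[genes].to_numpy(dtype=float)  # genes × samples
        denom = (self.pooled_within_sd.to_numpy() + self.s0) ** 2
        scores = np.empty((len(self.classes), Xg.shape[1]))
        for ki, k in enumerate(self.classes):
            cent = self.shrunken_centroids[k].to_numpy()
            scores[ki] = ((Xg - cent[:, None]) ** 2 / denom[:, None]).sum(axis=0)
            scores[ki] -= 2.0 * np.log(float(self.priors[k]))
        labels = [self.classes[i] for i in np.argmin(scores, axis=0)]
        return labels, pd.DataFrame(scores, index=self.classes, columns=X.columns)


def nsc_train(
    X: pd.DataFrame,
    y: pd.Series,
    delta: float = 0.0,
    priors: dict[str, float] | pd.Series | None = None,
    m_variant: str = "minus",
) -> NSCModel:
    """Fit the shrunken-centroid model at one shrinkage amount ``delta``.

    ``X`` is gene × sample; ``y`` maps sample → class label.  Priors
    default to observed class proportions.  ``m_variant`` selects
    ``m_k = sqrt(1/n_k - 1/n)`` ("minus", default) or the ``+`` variant.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if m_variant not in ("minus", "plus"):
        raise ValueError("m_variant must be 'minus' or 'plus'")
    X, y = _validate_inputs(X, y)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = y.value_counts()
    small = [k for k in classes if counts[k] < 2]
    if small:
        raise ValueError(f"each class needs at least 2 samples; too small: {small}")

    n = X.shape[1]
    K = len(classes)
    genes = X.index
    overall = X.mean(axis=1)

    class_centroids = pd.DataFrame(index=genes, columns=classes, dtype=float)
    ss_within = np.zeros(len(genes))
    for k in classes:
        cols = y.index[y == k]
        sub = X[cols]
        cent = sub.mean(axis=1)
        class_centroids[k] = cent
        ss_within += ((sub.sub(cent, axis=0)) ** 2).sum(axis=1).to_numpy()
    s_j = pd.Series(np.sqrt(ss_within / (n - K)), index=genes, name="s_j")
    s0 = float(s_j.median())

    sign = -1.0 if m_variant == "minus" else 1.0
    m_k = pd.Series(
        {k: float(np.sqrt(1.0 / counts[k] + sign * (1.0 / n))) for k in classes}, name="m_k"
    )

    if priors is None:
        priors = (counts / n).reindex(classes)
    else:
        priors = pd.Series(priors, dtype=float).reindex(classes)
        if priors.isna().any():
            raise ValueError("priors must cover every class")
        priors = priors / priors.sum()
    if not np.isclose(float(priors.sum()), 1.0):
        raise ValueError("priors must sum to 1")

    denom = pd.DataFrame(
        {k: m_k[k] * (s_j + s0) for k in classes}, index=genes
    )
    d = (class_centroids.sub(overall, axis=0)) / denom
    d_shrunk = np.sign(d) * np.maximum(d.abs() - delta, 0.0)
    shrunken = class_centroids.copy()
    for k in classes:
        shrunken[k] = overall + denom[k] * d_shrunk[k]

    return NSCModel(
        classes=classes,
        overall_centroid=overall,
        class_centroids=class_centroids,
        pooled_within_sd=s_j,
        s0=s0,
        m_k=m_k,
        delta=float(delta),
        d=d,
        d_shrunk=d_shrunk,
        shrunken_centroids=shrunken,
        priors=priors,
        m_variant=m_variant,
    )


def nsc_predict(model: NSCModel, x) -> tuple[str, pd.Series]:
    """Predict one sample (gene-indexed Series); returns (label, scores)."""
    x = pd.Series(x)
    labels, scores = model.predict(x.to_frame(name="_sample"))
    return labels[0], scores["_sample"]


@dataclass
class CVReport:
    """Leave-one-out cross-validation results over a shrinkage grid."""

    delta_grid: np.ndarray
    errors: np.ndarray  # per-delta LOOCV error rate
    chosen_delta: float
    error_rate: float  # at chosen delta
    sensitivity: float
    specificity: float
    n_true_positive: int
    n_positive: int
    n_true_negative: int
    n_negative: int
    predictions: pd.DataFrame  # sample × delta-index LOOCV predictions
    final_model: NSCModel
    positive_class: str
    dataset_label: str = ""
    n_samples: int = 0
    n_misclassified: int = 0
    surviving_genes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable report (sensitivity shown as a quotient)."""
        neg = [c for c in self.final_model.classes if c != self.positive_class][0]
        lines = [
            "Nearest shrunken centroids — LOOCV report",
            f"dataset: {self.dataset_label or '<unnamed>'}",
            f"samples: {self.n_samples} ({self.n_positive} {self.positive_class}, "
            f"{self.n_negative} {neg})",
            f"delta grid: {len(self.delta_grid)} values in "
            f"[{self.delta_grid[0]:.4g}, {self.delta_grid[-1]:.4g}]",
            f"chosen delta: {self.chosen_delta:.4g}",
            f"LOOCV error rate: {100 * self.error_rate:.0f}% "
            f"({self.n_misclassified}/{self.n_samples})",
            f"sensitivity ({self.positive_class}): "
            f"{self.sensitivity:.3f} = {self.n_true_positive}/{self.n_positive}",
            f"specificity ({neg}): "
            f"{self.specificity:.3f} = {self.n_true_negative}/{self.n_negative}",
            f"surviving genes ({len(self.surviving_genes)}): "
            + (", ".join(self.surviving_genes) if self.surviving_genes else "<none>"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Per-delta grid table: delta, LOOCV error, surviving gene count."""
        rows = []
        for i, (dl, err) in enumerate(zip(self.delta_grid, self.errors)):
            rows.append((i, dl, err, self.n_surviving_at[i]))
        pd.DataFrame(
            rows, columns=["grid_index", "delta", "loocv_error", "n_surviving_genes"]
        ).to_csv(Path(path), sep="\t", index=False, lineterminator="\n")

    n_surviving_at: list[int] = field(default_factory=list)


def _default_grid(X: pd.DataFrame, y: pd.Series, priors, m_variant: str, size: int) -> np.ndarray:
    base = nsc_train(X, y, delta=0.0, priors=priors, m_variant=m_variant)
    dmax = float(base.d.abs().to_numpy().max())
    return np.linspace(0.0, dmax, size)


def nsc_loocv(
    X: pd.DataFrame,
    y: pd.Series,
    delta_grid: np.ndarray | None = None,
    priors: dict[str, float] | None = None,
    positive_class: str = "MUT",
    m_variant: str = "minus",
    grid_size: int = DEFAULT_GRID_SIZE,
    dataset_label: str = "",
) -> CVReport:
    """Leave-one-out CV over a shrinkage grid with fully nested refitting.

    For every held-out sample and every grid ``delta`` the model — pooled
    variances, ``s0``, centroids, and therefore the surviving gene set —
    is recomputed on the remaining ``n − 1`` samples.  The chosen ``delta``
    minimises the LOOCV error (ties → largest ``delta``); the final model
    is refit on all samples at that value.  Sensitivity and specificity
    come from the chosen-delta LOOCV predictions with ``positive_class``
    as the positive label.
    """
    X, y = _validate_inputs(X, y)
    n = X.shape[1]
    if n < 4:
        raise ValueError("LOOCV requires at least 4 samples")
    counts = y.value_counts()
    too_small = [k for k in counts.index if counts[k] < 3]
    if too_small:
        raise ValueError(
            f"LOOCV would leave a class with <2 training samples; too small: {too_small}"
        )
    if delta_grid is None:
        delta_grid = _default_grid(X, y, priors, m_variant, grid_size)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if delta_grid.size == 0:
        raise ValueError("delta grid is empty")

    samples = list(X.columns)
    preds = pd.DataFrame(index=samples, columns=range(delta_grid.size), dtype=object)
    for s in samples:
        train_cols = [c for c in samples if c != s]
        Xt, yt = X[train_cols], y[train_cols]
        base = nsc_train(Xt, yt, delta=0.0, priors=priors, m_variant=m_variant)
        for gi, delta in enumerate(delta_grid):
            # reuse fold statistics; only the soft threshold changes with delta
            d_shrunk = np.sign(base.d) * np.maximum(base.d.abs() - delta, 0.0)
            shrunken = base.class_centroids.copy()
            for k in base.classes:
                shrunken[k] = base.overall_centroid + base.m_k[k] * (
                    base.pooled_within_sd + base.s0
                ) * d_shrunk[k]
            fold = NSCModel(
                classes=base.classes,
                overall_centroid=base.overall_centroid,
                class_centroids=base.class_centroids,
                pooled_within_sd=base.pooled_within_sd,
                s0=base.s0,
                m_k=base.m_k,
                delta=float(delta),
                d=base.d,
                d_shrunk=d_shrunk,
                shrunken_centroids=shrunken,
                priors=base.priors,
                m_variant=m_variant,
            )
            label, _ = nsc_predict(fold, X[s])
            preds.loc[s, gi] = label

    truth = y[samples]
    errors = np.array(
        [float((preds[gi] != truth).mean()) for gi in range(delta_grid.size)]
    )
    best_err = errors.min()
    chosen_idx = int(np.flatnonzero(np.isclose(errors, best_err)).max())  # largest delta wins ties
    chosen_delta = float(delta_grid[chosen_idx])

    final = nsc_train(X, y, delta=chosen_delta, priors=priors, m_variant=m_variant)
    if positive_class not in final.classes:
        raise ValueError(f"positive class {positive_class!r} not among {final.classes}")
    chosen_preds = preds[chosen_idx]
    pos = truth == positive_class
    neg = ~pos
    tp = int(((chosen_preds == positive_class) & pos).sum())
    tn = int(((chosen_preds != positive_class) & neg).sum())
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    n_mis = int((chosen_preds != truth).sum())

    n_surviving_at = []
    for delta in delta_grid:
        m = nsc_train(X, y, delta=float(delta), priors=priors, m_variant=m_variant)
        n_surviving_at.append(len(m.surviving_genes))

    report = CVReport(
        delta_grid=delta_grid,
        errors=errors,
        chosen_delta=chosen_delta,
        error_rate=float(errors[chosen_idx]),
        sensitivity=tp / n_pos if n_pos else float("nan"),
        specificity=tn / n_neg if n_neg else float("nan"),
        n_true_positive=tp,
        n_positive=n_pos,
        n_true_negative=tn,
        n_negative=n_neg,
        predictions=preds,
        final_model=final,
        positive_class=positive_class,
        dataset_label=dataset_label,
        n_samples=n,
        n_misclassified=n_mis,
        surviving_genes=final.surviving_genes,
        n_surviving_at=n_surviving_at,
    )
    logger.info(
        "LOOCV(%s): chosen delta %.4g, error %.0f%%, %d surviving genes",
        dataset_label or "<unnamed>", chosen_delta, 100 * report.error_rate,
        len(report.surviving_genes),
    )
    return report


class NearestShrunkenCentroids:
    """Model object built from data; ``fit`` returns results objects.

    Parameters
    ----------
    X : gene × sample DataFrame (no missing values)
    y : sample → class label
    priors : class priors (default: observed proportions)
    positive_class : label treated as positive for sensitivity/specificity
    m_variant : "minus" (default) or "plus" standard-error convention
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        priors: dict[str, float] | None = None,
        positive_class: str = "MUT",
        m_variant: str = "minus",
    ) -> None:
        self.X, self.y = _validate_inputs(X, y)
        self.priors = priors
        self.positive_class = positive_class
        self.m_variant = m_variant

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str, **kwargs
    ) -> "NearestShrunkenCentroids":
        """Build from a samples × (genes + label) DataFrame."""
        y = df[label_column]
        X = df.drop(columns=[label_column]).T
        return cls(X, y, **kwargs)

    def fit(self, delta: float = 0.0) -> NSCModel:
        return nsc_train(self.X, self.y, delta=delta, priors=self.priors, m_variant=self.m_variant)

    def fit_loocv(
        self,
        delta_grid: np.ndarray | None = None,
        grid_size: int = DEFAULT_GRID_SIZE,
        dataset_label: str = "",
    ) -> CVReport:
        return nsc_loocv(
            self.X,
            self.y,
            delta_grid=delta_grid,
            priors=self.priors,
            positive_class=self.positive_class,
            m_variant=self.m_variant,
            grid_size=grid_size,
            dataset_label=dataset_label,
        )
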