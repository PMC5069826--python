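"""Cross-platform concordance statistics.

* :func:`spearman` — rank correlation with average-rank ties and a
  two-sided p-value from the t approximation
  ``t = rho * sqrt((n-2) / (1-rho^2))`` on ``n-2`` degrees of freedom
  (the convention of mainstream statistical packages for n in the tens);
  an exact-permutation mode is available for small n.
* :func:`pairwise_concordance` — the full table of pairwise correlations
  between per-dataset score vectors, paired by sample ID (6 datasets give
  the 15 unordered pairs).
* :func:`fisher_exact_2x2` — two-sided Fisher exact test by full
  hypergeometric enumeration with the sum-of-small-probabilities rule.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ffpesig.scoring import SampleScores

logger = logging.getLogger(__name__)


def spearman(
    x: pd.Series, y: pd.Series, method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation of two score vectors paired by sample ID.

    Pairs with a missing member are dropped; at least 3 complete pairs and
    non-zero variance in both vectors are required.  ``method="t"`` gives
    the t-approximation p-value; ``method="exact"`` enumerates all rank
    permutations (only sensible for n ≤ 10).  |rho| = 1 reports p = 0.
    """
    x = pd.Series(x)
    y = pd.Series(y)
    common = x.index.intersection(y.index)
    paired = pd.DataFrame({"x": x[common], "y": y[common]}).dropna()
    n = len(paired)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    xv, yv = paired["x"].to_numpy(), paired["y"].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance vector: Spearman correlation undefined")

    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if method != "t":
        raise ValueError(f"unknown p-value method {method!r}")
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


@dataclass
class ConcordanceTable:
    """Symmetric table of pairwise Spearman correlations between datasets."""

    dataset_labels: list[str]
    rho: pd.DataFrame  # label × label
    p: pd.DataFrame
    n_used: pd.DataFrame

    def pair(self, a: str, b: str) -> tuple[float, float, int]:
        return float(self.rho.loc[a, b]), float(self.p.loc[a, b]), int(self.n_used.loc[a, b])

    def to_tsv(self, path, long_path=None) -> None:
        """Write the display table ("rho (p)" cells) and optionally a long format."""
        disp = pd.DataFrame(index=self.dataset_labels, columns=self.dataset_labels, dtype=object)
        for a in self.dataset_labels:
            for b in self.dataset_labels:
                r = self.rho.loc[a, b]
                if a == b:
                    disp.loc[a, b] = "1"
                elif pd.isna(r):
                    disp.loc[a, b] = "NA"
                else:
                    disp.loc[a, b] = f"{r:.3f} ({self.p.loc[a, b]:.4g})"
        disp.rename_axis("dataset").to_csv(Path(path), sep="\t", lineterminator="\n")
        if long_path is not None:
            rows = []
            for a, b in itertools.combinations(self.dataset_labels, 2):
                rows.append(
                    (a, b, self.rho.loc[a, b], self.p.loc[a, b], self.n_used.loc[a, b])
                )
            pd.DataFrame(rows, columns=["dataset_a", "dataset_b", "rho", "p", "n_used"]).to_csv(
                Path(long_path), sep="\t", index=False, lineterminator="\n"
            )


def pairwise_concordance(
    score_sets: list[SampleScores], exclude: set[str] | frozenset[str] = frozenset()
) -> ConcordanceTable:
    """All pairwise Spearman correlations among per-dataset score vectors.

    Each pair is computed on the intersection of the two datasets' sample
    IDs minus ``exclude``.  A pair with fewer than 3 usable samples is
    reported as unavailable (NaN) rather than fabricated.
    """
    if len(score_sets) < 2:
        raise ValueError("need at least 2 score sets")
    labels = [s.dataset_label for s in score_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"dataset labels must be unique, got {labels}")
    rho = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p = pd.DataFrame(np.zeros((len(labels), len(labels))), index=labels, columns=labels)
    n_used = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for s in score_sets:
        keep = [i for i in s.scores.index if i not in exclude]
        n_used.loc[s.dataset_label, s.dataset_label] = len(keep)

    any_pair = False
    for sa, sb in itertools.combinations(score_sets, 2):
        a, b = sa.dataset_label, sb.dataset_label
        xa = sa.scores[[i for i in sa.scores.index if i not in exclude]]
        xb = sb.scores[[i for i in sb.scores.index if i not in exclude]]
        common = xa.index.intersection(xb.index)
        n = int(pd.DataFrame({"x": xa[common], "y": xb[common]}).dropna().shape[0])
        try:
            r, pv = spearman(xa, xb)
        except ValueError as exc:
            logger.warning("pair (%s, %s) unavailable: %s", a, b, exc)
            r, pv, n = np.nan, np.nan, 0
        else:
            any_pair = True
        rho.loc[a, b] = rho.loc[b, a] = r
        p.loc[a, b] = p.loc[b, a] = pv
        n_used.loc[a, b] = n_used.loc[b, a] = n
    if not any_pair:
        raise ValueError("no dataset pair shares at least 3 samples after exclusion")
    return ConcordanceTable(dataset_labels=labels, rho=rho, p=p, n_used=n_used)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test p-value for a 2×2 count table.

    Enumerates every table with the observed margins; the p-value is the
    sum of hypergeometric probabilities of tables whose probability does
    not exceed the observed table's (within 1e-7 relative tolerance).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(int)
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n < 1:
        raise ValueError("table total must be at least 1")

    # cell (0,0) = k follows Hypergeometric(N=n, K=r1, n=c1)
    k_obs = int(t[0, 0])
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(k_obs, n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)
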