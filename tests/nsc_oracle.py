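"""Independent naive-loop reference implementation of the shrunken-centroid
classifier, used only as a test oracle.

Everything is recomputed from scratch with explicit Python loops — class
centroids, pooled within-class variance, the standardization factors, the
soft threshold, and the discriminant — so that any algebraic or
vectorization mistake in the package implementation shows up as a
disagreement here.
"""

import math

import numpy as np


def oracle_fit(X, y, delta, priors=None, m_variant="minus"):
    """X: genes × samples ndarray; y: list of labels.  Returns a dict."""
    X = np.asarray(X, dtype=float)
    y = list(y)
    classes = sorted(set(y))
    n_genes, n = X.shape
    K = len(classes)

    overall = [sum(X[j]) / n for j in range(n_genes)]
    centroids = {}
    counts = {}
    for k in classes:
        cols = [i for i, lab in enumerate(y) if lab == k]
        counts[k] = len(cols)
        centroids[k] = [sum(X[j, i] for i in cols) / len(cols) for j in range(n_genes)]

    s = []
    for j in range(n_genes):
        ss = 0.0
        for k in classes:
            cols = [i for i, lab in enumerate(y) if lab == k]
            ss += sum((X[j, i] - centroids[k][j]) ** 2 for i in cols)
        s.append(math.sqrt(ss / (n - K)))
    s0 = float(np.median(s))

    m = {}
    for k in classes:
        if m_variant == "minus":
            m[k] = math.sqrt(1.0 / counts[k] - 1.0 / n)
        else:
            m[k] = math.sqrt(1.0 / counts[k] + 1.0 / n)

    if priors is None:
        priors = {k: counts[k] / n for k in classes}
    else:
        total = sum(priors.values())
        priors = {k: priors[k] / total for k in classes}

    d = {k: [0.0] * n_genes for k in classes}
    d_shrunk = {k: [0.0] * n_genes for k in classes}
    shrunken = {k: [0.0] * n_genes for k in classes}
    for k in classes:
        for j in range(n_genes):
            denom = m[k] * (s[j] + s0)
            dkj = (centroids[k][j] - overall[j]) / denom
            d[k][j] = dkj
            if abs(dkj) > delta:
                dpr = (1 if dkj > 0 else -1) * (abs(dkj) - delta)
            else:
                dpr = 0.0
            d_shrunk[k][j] = dpr
            shrunken[k][j] = overall[j] + denom * dpr

    surviving = [
        j for j in range(n_genes) if any(d_shrunk[k][j] != 0.0 for k in classes)
    ]
    return {
        "classes": classes,
        "overall": overall,
        "centroids": centroids,
        "s": s,
        "s0": s0,
        "m": m,
        "priors": priors,
        "d": d,
        "d_shrunk": d_shrunk,
        "shrunken": shrunken,
        "surviving": surviving,
    }


def oracle_predict(fit, x):
    """Predict one sample (gene vector) from an oracle fit."""
    scores = {}
    for k in fit["classes"]:
        total = 0.0
        for j in range(len(x)):
            denom = fit["s"][j] + fit["s0"]
            total += (x[j] - fit["shrunken"][k][j]) ** 2 / denom**2
        scores[k] = total - 2.0 * math.log(fit["priors"][k])
    best = min(fit["classes"], key=lambda k: (scores[k], fit["classes"].index(k)))
    return best, scores


def standardized_nearest_centroid_predict(X, y, x, priors=None):
    """Plain nearest-centroid rule on (s_j + s0)-standardized distances —
    what shrinkage delta = 0 must reduce to."""
    fit = oracle_fit(X, y, delta=0.0, priors=priors)
    scores = {}
    for k in fit["classes"]:
        total = 0.0
        for j in range(len(x)):
            denom = fit["s"][j] + fit["s0"]
            total += (x[j] - fit["centroids"][k][j]) ** 2 / denom**2
        scores[k] = total - 2.0 * math.log(fit["priors"][k])
    return min(fit["classes"], key=lambda k: (scores[k], fit["classes"].index(k)))
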