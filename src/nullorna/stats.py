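"""Group-comparison and probability-calibration statistics.

Welch's unequal-variance t test for count comparisons between cancer
and control samples, the Brier score for probabilistic accuracy, and
logistic recalibration: the calibration intercept/slope of a logistic
regression of outcomes on logit(predicted probability), with Platt
scaling as the maximum-likelihood sigmoid correction.  Perfectly
calibrated probabilities give intercept 0 and slope 1; systematically
overconfident probabilities (logits inflated by a factor c) give slope
approximately 1/c.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

PROB_CLIP = 1e-6


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    na, nb = len(a), len(b)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def brier_score(probs, labels) -> float:
    """Mean squared difference between probabilities and binary outcomes."""
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p - y) ** 2))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, PROB_CLIP, 1 - PROB_CLIP)
    return np.log(p / (1 - p))


def _fit_logistic_on_logit(probs, labels) -> tuple[float, float]:
    """ML fit of labels ~ sigmoid(slope * logit(probs) + intercept)."""
    x = _logit(np.asarray(probs, dtype=float))
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if np.ptp(x) == 0:
        raise ValueError("constant probabilities: slope undefined")

    def nll(params):
        b, a = params
        z = a * x + b
        # log(1+exp(z)) computed stably
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    res = optimize.minimize(nll, x0=np.array([0.0, 1.0]), method="BFGS")
    intercept, slope = res.x
    return float(intercept), float(slope)


def calibration_check(probs, labels) -> tuple[float, float]:
    """Calibration (intercept, slope) of outcomes regressed on logit(p)."""
    return _fit_logistic_on_logit(probs, labels)


def platt_recalibrate(probs, labels) -> np.ndarray:
    """Platt scaling: ML sigmoid of logit(p), preserving rank order."""
    intercept, slope = _fit_logistic_on_logit(probs, labels)
    z = slope * _logit(np.asarray(probs, dtype=float)) + intercept
    return 1.0 / (1.0 + np.exp(-z))
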