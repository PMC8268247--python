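"""Independent reference implementations used only to check the package.

These deliberately avoid the package's code paths: NIPALS PLS1 is coded from
the textbook recursion, AUC by brute-force pair counting, Youden by direct
threshold scan, logistic likelihood by golden-section search.
"""

from __future__ import annotations

import numpy as np


def nipals_pls1_weights(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-component NIPALS PLS1: returns (weight vector w, scores t)."""
    yc = y - y.mean()
    w = x.T @ yc
    w = w / np.linalg.norm(w)
    t = x @ w
    return w, t


def brute_force_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the concordant-pair fraction over every (case, control) pair."""
    wins = ties = 0
    for a in cases:
        for b in controls:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def trapezoid_auc(sensitivity: np.ndarray, specificity: np.ndarray) -> float:
    """Area under the ROC polygon traced by (1-specificity, sensitivity)."""
    fpr = 1.0 - np.asarray(specificity)
    tpr = np.asarray(sensitivity)
    order = np.lexsort((tpr, fpr))  # vertical segments ascend in tpr
    fpr, tpr = fpr[order], tpr[order]
    return float(np.trapezoid(tpr, fpr))


def brute_force_youden(scores: np.ndarray, labels: np.ndarray) -> float:
    """Max sensitivity + specificity - 1 over every candidate threshold."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    best = -np.inf
    candidates = np.concatenate([[scores.min() - 1], np.unique(scores), [scores.max() + 1]])
    for th in candidates:
        j = np.mean(cases >= th) + np.mean(controls < th) - 1.0
        best = max(best, j)
    return float(best)


def logistic_loglik(beta0: float, beta1: float, x: np.ndarray, y: np.ndarray) -> float:
    eta = beta0 + beta1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def golden_section_beta1(x: np.ndarray, y: np.ndarray, lo=-10.0, hi=10.0, tol=1e-6) -> float:
    """Profile-likelihood maximum over beta1, maximizing beta0 on a grid inside."""
    from scipy.optimize import minimize_scalar

    def profile(beta1):
        res = minimize_scalar(lambda b0: -logistic_loglik(b0, beta1, x, y), bounds=(-20, 20), method="bounded")
        return -res.fun

    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = profile(c), profile(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = profile(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = profile(d)
    return (a + b) / 2
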