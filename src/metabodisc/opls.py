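"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

OPLS-DA is PLS regression on a binary class label in which variation in X that
is orthogonal to the label is filtered into separate "orthogonal" components
before a single predictive component is extracted.  The predictive scores then
carry all the label-correlated variation, which makes score plots and
downstream ROC analysis easier to read than plain PLS-DA with multiple
components.

The module follows the statsmodels idiom: build ``OPLSDA(y, X)``, call
``fit()``, and work with the returned :class:`OPLSDAResults` (scores,
loadings, R2Y, cross-validated Q2, permutation check, ``summary()``).

Algorithm (per orthogonal component, on the current X):

    w   = X'y / (y'y), normalized        predictive weight estimate
    t   = X w                            predictive scores
    p   = X't / (t't)                    loading
    w_o = p - (w'p) w, normalized        orthogonal weight
    t_o = X w_o                          orthogonal scores
    p_o = X't_o / (t_o't_o)              orthogonal loading
    X  <- X - t_o p_o'                   deflate

followed by one predictive component (w, t, p, c) on the filtered X, with
``c = y't / (t't)`` and R2Y = 1 - ||y - t c||^2 / ||y||^2 (y centered).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OPLSDA",
    "OPLSDAResults",
    "fit_opls_da",
    "q2_cross_validate",
    "permutation_check",
    "select_n_orthogonal",
    "FitStats",
]


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate X: zero-norm {what}")
    return v / n


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("y must contain both classes, coded 0/1")
    return y


class OPLSDA:
    """Two-class OPLS-DA model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Binary class labels (1 = case, 0 = control).
    exog : array-like, shape (n, p)
        Feature matrix, column-centered (typically unit-variance scaled).
    """

    def __init__(self, endog, exog):
        self.endog = _check_two_class(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n_samples, n_features) matching endog")

    def fit(self, n_orthogonal: int = 0) -> "OPLSDAResults":
        if n_orthogonal < 0:
            raise ValueError("n_orthogonal must be >= 0")
        y = self.endog
        y_mean = y.mean()
        yc = y - y_mean
        x = self.exog.copy()

        w_orth, p_orth, t_orth = [], [], []
        for _ in range(n_orthogonal):
            w = _unit(x.T @ yc / (yc @ yc), "predictive weight")
            t = x @ w
            p = x.T @ t / (t @ t)
            wo = p - (w @ p) * w
            wo = _unit(wo, "orthogonal weight")
            to = x @ wo
            po = x.T @ to / (to @ to)
            x = x - np.outer(to, po)
            w_orth.append(wo)
            p_orth.append(po)
            t_orth.append(to)

        w = _unit(x.T @ yc / (yc @ yc), "predictive weight")
        t = x @ w
        p = x.T @ t / (t @ t)
        c = yc @ t / (t @ t)
        r2y = 1.0 - np.sum((yc - t * c) ** 2) / np.sum(yc**2)

        return OPLSDAResults(
            model=self,
            w=w,
            c=float(c),
            p=p,
            W_orth=np.column_stack(w_orth) if w_orth else np.zeros((x.shape[1], 0)),
            P_orth=np.column_stack(p_orth) if p_orth else np.zeros((x.shape[1], 0)),
            t=t,
            T_orth=np.column_stack(t_orth) if t_orth else np.zeros((x.shape[0], 0)),
            y_mean=float(y_mean),
            r2y=float(r2y),
            n_orth=n_orthogonal,
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA parameters and training diagnostics."""

    model: OPLSDA
    w: np.ndarray
    c: float
    p: np.ndarray
    W_orth: np.ndarray
    P_orth: np.ndarray
    t: np.ndarray
    T_orth: np.ndarray
    y_mean: float
    r2y: float
    n_orth: int
    q2: float | None = None

    def predict(self, x_new: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project new samples: (scores, y_hat, predicted class at 0.5).

        ``x_new`` must be scaled with the training centers/scales.  Orthogonal
        components are removed sequentially before scoring, exactly as during
        training, so predicting the training matrix reproduces the training
        scores.
        """
        x = np.asarray(x_new, dtype=float)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x).copy()
        if x.shape[1] != self.w.size:
            raise ValueError(f"expected {self.w.size} features, got {x.shape[1]}")
        for k in range(self.n_orth):
            to = x @ self.W_orth[:, k]
            x = x - np.outer(to, self.P_orth[:, k])
        scores = x @ self.w
        y_hat = scores * self.c + self.y_mean
        klass = (y_hat >= 0.5).astype(int)
        if squeeze:
            return scores[0], y_hat[0], klass[0]
        return scores, y_hat, klass

    def summary(self) -> str:
        lines = [
            "OPLS-DA Results",
            "=" * 40,
            f"{'No. observations:':<28}{self.model.endog.size}",
            f"{'No. features:':<28}{self.w.size}",
            f"{'Predictive components:':<28}1",
            f"{'Orthogonal components:':<28}{self.n_orth}",
            f"{'R2Y:':<28}{self.r2y:.4f}",
        ]
        if self.q2 is not None:
            lines.append(f"{'Q2 (CV):':<28}{self.q2:.4f}")
        lines.append("=" * 40)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "c": self.c,
            "p": self.p.tolist(),
            "W_orth": self.W_orth.tolist(),
            "P_orth": self.P_orth.tolist(),
            "y_mean": self.y_mean,
            "r2y": self.r2y,
            "n_orth": self.n_orth,
            "q2": self.q2,
        }


def fit_opls_da(x: np.ndarray, y: np.ndarray, n_orth: int = 0) -> OPLSDAResults:
    """Functional wrapper: fit OPLS-DA with ``n_orth`` orthogonal components."""
    return OPLSDA(y, x).fit(n_orthogonal=n_orth)


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by class, shuffled within class; with
    folds >= n this degenerates to leave-one-out."""
    if folds >= y.size:
        return np.arange(y.size)
    assign = np.empty(y.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def q2_cross_validate(
    x: np.ndarray, y: np.ndarray, n_orth: int, folds: int = 7, seed: int = 0
) -> float:
    """Q2 = 1 - PRESS/SS by stratified k-fold CV with per-fold refitting.

    Column centers and scales are re-estimated on each training fold and
    applied to the held-out fold, so no preprocessing statistic leaks across
    the fold boundary.
    """
    y = _check_two_class(y)
    x = np.asarray(x, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, y.size)
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        assign = _stratified_folds(y, folds, rng)
        ok = all(len(np.unique(y[assign != f])) == 2 for f in range(folds))
        if ok:
            break
    else:
        raise ValueError("could not draw folds with both classes in every training set")

    press = 0.0
    for f in range(folds):
        train, test = assign != f, assign == f
        if not test.any():
            continue
        centers = x[train].mean(axis=0)
        scales = x[train].std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        res = OPLSDA(y[train], (x[train] - centers) / scales).fit(n_orthogonal=n_orth)
        _, y_hat, _ = res.predict((x[test] - centers) / scales)
        press += np.sum((y[test] - y_hat) ** 2)
    ss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - press / ss)


@dataclass
class FitStats:
    """R2Y/Q2 with the label-permutation null distribution of Q2."""

    r2y: float
    q2: float
    q2_permuted: np.ndarray = field(default_factory=lambda: np.zeros(0))
    perm_p: float = float("nan")


def permutation_check(
    x: np.ndarray, y: np.ndarray, n_orth: int, n_perm: int = 100, folds: int = 7, seed: int = 0
) -> FitStats:
    """Label-permutation check of Q2: how often does a random relabeling of the
    samples cross-validate as well as the observed labels?"""
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a meaningful permutation p-value")
    y = _check_two_class(y)
    q2_obs = q2_cross_validate(x, y, n_orth, folds=folds, seed=seed)
    r2y = fit_opls_da((x - x.mean(axis=0)), y, n_orth).r2y
    rng = np.random.default_rng(seed)
    q2_perm = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        q2_perm[i] = q2_cross_validate(
            x, y_perm, n_orth, folds=folds, seed=int(rng.integers(2**31))
        )
    perm_p = (1.0 + np.sum(q2_perm >= q2_obs)) / (1.0 + n_perm)
    return FitStats(r2y=r2y, q2=q2_obs, q2_permuted=q2_perm, perm_p=float(perm_p))


def select_n_orthogonal(
    x: np.ndarray, y: np.ndarray, max_orth: int = 6, folds: int = 7, seed: int = 0
) -> int:
    """Pick the orthogonal-component count maximizing cross-validated Q2.

    Scans n_orth = 0..max_orth, stopping early once adding a component drops
    Q2 by more than 0.01, then returns the most parsimonious count whose Q2
    lies within 0.01 of the maximum (a gain below CV noise does not justify an
    extra component).  Deterministic given the seed.
    """
    if max_orth < 0:
        raise ValueError("max_orth must be >= 0")
    q2s: list[float] = []
    for k in range(max_orth + 1):
        q2s.append(q2_cross_validate(x, y, k, folds=folds, seed=seed))
        if k > 0 and q2s[k] < q2s[k - 1] - 0.01:
            break
    best = max(q2s)
    return int(next(k for k, q in enumerate(q2s) if q >= best - 0.01))
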