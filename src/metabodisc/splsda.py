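"""Sparse PLS discriminant analysis with exact-cardinality LASSO selection.

Each component's X-weight vector is soft-thresholded so that exactly
``keep`` variables carry nonzero weight: the threshold is set to the
(keep+1)-th largest absolute entry of the un-penalized weight, which is the
"keepX" convention of sparse PLS.  With a binary outcome the Y block is a
single centered dummy column, so the inner power iteration converges
immediately and the method reduces to a sequence of sparse PLS1 components
with regression deflation (mutually orthogonal scores).

Model/results split follows statsmodels: ``SPLSDA(y, X).fit()`` returns
:class:`SPLSDAResults` with loadings, selections, an importance ranking and
``summary()``; the cross-validated error rate uses a nearest-class-centroid
rule in score space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .opls import _check_two_class, _stratified_folds

__all__ = ["SPLSDA", "SPLSDAResults", "fit_spls_da", "soft_threshold", "cv_error_rate"]


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise soft-thresholding: the proximal operator of lam * ||.||_1."""
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def _sparse_weight(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``u`` so exactly ``keep`` entries are nonzero, then
    normalize to unit length."""
    if keep < u.size:
        abs_sorted = np.sort(np.abs(u))[::-1]
        lam = abs_sorted[keep]  # (keep+1)-th largest
        u = soft_threshold(u, lam)
    n = np.linalg.norm(u)
    if n < 1e-12:
        raise ValueError("degenerate sparse weight (all-zero after thresholding)")
    return u / n


class SPLSDA:
    """Two-class sparse PLS-DA model on a scaled feature matrix."""

    def __init__(self, endog, exog, metabolite_ids: list[str] | None = None):
        self.endog = _check_two_class(endog)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n_samples, n_features) matching endog")
        self.metabolite_ids = (
            list(metabolite_ids)
            if metabolite_ids is not None
            else [f"V{j}" for j in range(self.exog.shape[1])]
        )

    def fit(
        self,
        n_components: int = 5,
        keep: int = 15,
        max_iter: int = 100,
        tol: float = 1e-9,
    ) -> "SPLSDAResults":
        m = self.exog.shape[1]
        if keep > m:
            raise ValueError(f"keep={keep} exceeds {m} variables")
        if keep == m:
            warnings.warn("keep equals the number of variables: dense (non-sparse) fit")
        x = self.exog.copy()
        yc = (self.endog - self.endog.mean())[:, None]

        weights, p_load, c_load, scores, selected = [], [], [], [], []
        for h in range(n_components):
            v = yc[:, 0] / np.linalg.norm(yc[:, 0])
            u = _sparse_weight(x.T @ v, keep)
            for _ in range(max_iter):
                t = x @ u
                v = yc[:, 0] * (yc[:, 0] @ t) / max(np.abs(yc[:, 0] @ t), 1e-300)
                v = v / np.linalg.norm(v)
                u_new = _sparse_weight(x.T @ v, keep)
                if np.linalg.norm(u_new - u) < tol:
                    u = u_new
                    break
                u = u_new
            else:
                raise ValueError(f"sparse weight iteration failed to converge at component {h}")
            t = x @ u
            tt = t @ t
            p = x.T @ t / tt
            c = yc.T @ t / tt
            x = x - np.outer(t, p)
            yc = yc - np.outer(t, c)
            weights.append(u)
            p_load.append(p)
            c_load.append(c.ravel())
            scores.append(t)
            selected.append([self.metabolite_ids[j] for j in np.flatnonzero(u)])

        return SPLSDAResults(
            model=self,
            n_components=n_components,
            keep_per_component=keep,
            loadings_x=np.column_stack(weights),
            loadings_p=np.column_stack(p_load),
            loadings_y=np.column_stack(c_load),
            scores=np.column_stack(scores),
            selected=selected,
        )


@dataclass
class SPLSDAResults:
    model: SPLSDA
    n_components: int
    keep_per_component: int
    loadings_x: np.ndarray  # sparse weights, keep nonzeros per column
    loadings_p: np.ndarray  # projection loadings used for deflation
    loadings_y: np.ndarray
    scores: np.ndarray
    selected: list[list[str]]
    error_rate: float | None = None

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Project new (identically scaled) samples into component-score space."""
        x = np.atleast_2d(np.asarray(x_new, dtype=float)).copy()
        if x.shape[1] != self.loadings_x.shape[0]:
            raise ValueError(f"expected {self.loadings_x.shape[0]} features")
        out = np.empty((x.shape[0], self.n_components))
        for h in range(self.n_components):
            t = x @ self.loadings_x[:, h]
            out[:, h] = t
            x = x - np.outer(t, self.loadings_p[:, h])
        return out

    def rank_variables(self) -> list[tuple[str, float]]:
        """Importance ranking: max over components of |weight| weighted by the
        component's share of total score variance; unselected variables rank
        last with importance 0.  Ties break toward the earlier component, then
        lexicographic id."""
        shares = (self.scores**2).sum(axis=0)
        shares = shares / shares.sum()
        ids = self.model.metabolite_ids
        rows = []
        for j, mid in enumerate(ids):
            contrib = np.abs(self.loadings_x[j]) * shares
            best = int(np.argmax(contrib))
            rows.append((mid, float(contrib[best]), best))
        rows.sort(key=lambda r: (-r[1], r[2], r[0]))
        return [(mid, imp) for mid, imp, _ in rows]

    def summary(self) -> str:
        lines = [
            "Sparse PLS-DA Results",
            "=" * 44,
            f"{'No. observations:':<30}{self.model.endog.size}",
            f"{'No. variables:':<30}{self.loadings_x.shape[0]}",
            f"{'Components:':<30}{self.n_components}",
            f"{'Variables kept/component:':<30}{self.keep_per_component}",
        ]
        if self.error_rate is not None:
            lines.append(f"{'CV error rate:':<30}{self.error_rate:.3f}")
        top = ", ".join(mid for mid, _ in self.rank_variables()[:10])
        lines += [f"{'Top 10 variables:':<30}{top}", "=" * 44]
        return "\n".join(lines)


def fit_spls_da(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    keep: int = 15,
    metabolite_ids: list[str] | None = None,
    seed: int = 0,
) -> SPLSDAResults:
    """Functional wrapper around ``SPLSDA(y, x).fit()`` (deterministic; the
    seed is accepted for interface uniformity)."""
    return SPLSDA(y, x, metabolite_ids).fit(n_components=n_components, keep=keep)


def _nearest_centroid_predict(
    scores_train: np.ndarray, y_train: np.ndarray, scores_test: np.ndarray
) -> np.ndarray:
    c0 = scores_train[y_train == 0].mean(axis=0)
    c1 = scores_train[y_train == 1].mean(axis=0)
    d0 = np.sum((scores_test - c0) ** 2, axis=1)
    d1 = np.sum((scores_test - c1) ** 2, axis=1)
    return (d1 < d0).astype(int)


def cv_error_rate(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int = 5,
    keep: int = 15,
    folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """Repeated stratified k-fold misclassification rate of the sPLS-DA model
    with a nearest-class-centroid rule in component-score space."""
    y = _check_two_class(y)
    x = np.asarray(x, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    errors = []
    for _rep in range(n_repeats):
        for _attempt in range(100):
            assign = _stratified_folds(y, folds, rng)
            if all(len(np.unique(y[assign != f])) == 2 for f in range(folds)):
                break
        else:
            raise ValueError("could not draw folds with both classes in every training set")
        wrong = 0
        for f in range(folds):
            train, test = assign != f, assign == f
            res = SPLSDA(y[train], x[train]).fit(n_components=n_components, keep=keep)
            pred = _nearest_centroid_predict(res.scores, y[train], res.transform(x[test]))
            wrong += int(np.sum(pred != y[test]))
        errors.append(wrong / y.size)
    return float(np.mean(errors))
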