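"""Model validation: discovery/validation splits, ROC analysis, MCCV.

The headline validation scheme is repeated random sub-sampling (Monte-Carlo
cross-validation): the study samples are split 70/30 stratified by class, the
full scaling + OPLS-DA fit is repeated on each discovery split, the held-out
validation split is scored, and the AUROC distribution over (by default) 1000
iterations summarizes out-of-sample discrimination.

AUC is computed from the Mann-Whitney U statistic (ties counted 1/2) with
DeLong's asymptotic 95% confidence interval; the Youden index J selects the
equal-weight optimal cutoff by exhaustive threshold scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import Role, SampleMeta
from .opls import OPLSDA

__all__ = [
    "RocResult",
    "MccvResult",
    "stratified_split",
    "split_indices",
    "roc_analysis",
    "monte_carlo_validation",
]


def split_indices(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split: per class, floor(fraction * class size) rows go
    to discovery, drawn uniformly at random within class."""
    y = np.asarray(y)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    disc: list[np.ndarray] = []
    val: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        k = int(np.floor(fraction * idx.size))
        perm = rng.permutation(idx)
        disc.append(perm[:k])
        val.append(perm[k:])
    return np.sort(np.concatenate(disc)), np.sort(np.concatenate(val))


def stratified_split(
    meta: Sequence[SampleMeta], fraction: float, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Split study samples into discovery/validation id lists, stratified by
    class with per-class floor rounding (146/272 at 0.7 -> 102/190 + 44/82)."""
    study = [m for m in meta if m.role is not Role.QC]
    y = np.array([m.y for m in study])
    rng = np.random.default_rng(seed)
    disc_idx, val_idx = split_indices(y, fraction, rng)
    ids = [m.sample_id for m in study]
    return [ids[i] for i in disc_idx], [ids[i] for i in val_idx]


# -- ROC ----------------------------------------------------------------


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_j: float
    youden_threshold: float
    sens_at_j: float
    spec_at_j: float


def _mann_whitney_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    # P(case score > control score) + 1/2 P(tie), via pairwise comparison
    diff = cases[:, None] - controls[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def _delong_ci(cases: np.ndarray, controls: np.ndarray, auc: float) -> tuple[float, float]:
    """DeLong 95% CI from the variance of case/control placement values."""
    n1, n0 = cases.size, controls.size
    # placement of each case among controls and vice versa
    v10 = np.array(
        [(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / n0 for c in cases]
    )
    v01 = np.array(
        [(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / n1 for c in controls]
    )
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    se = np.sqrt(s10 / n1 + s01 / n0)
    z = stats.norm.ppf(0.975)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Full ROC analysis of continuous scores against binary labels.

    The ROC curve is traced over midpoints between adjacent distinct scores
    (plus open ends), predicting "case" when score >= threshold.  Ties in the
    Youden scan are broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    auc = _mann_whitney_auc(cases, controls)
    ci = _delong_ci(cases, controls, auc)

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    sens = np.array([np.mean(cases >= th) for th in thresholds])
    spec = np.array([np.mean(controls < th) for th in thresholds])

    j = sens + spec - 1.0
    best = np.lexsort((-sens, -j))[0]  # max J; ties -> higher sensitivity
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=ci,
        youden_j=float(j[best]),
        youden_threshold=float(thresholds[best]),
        sens_at_j=float(sens[best]),
        spec_at_j=float(spec[best]),
    )


# -- Monte-Carlo cross-validation ---------------------------------------


@dataclass
class MccvResult:
    aucs: np.ndarray
    median: float
    min: float
    max: float
    discovery_fraction: float
    seed: int
    n_retries: int = 0


def monte_carlo_validation(
    x: np.ndarray,
    y: np.ndarray,
    discovery_fraction: float = 0.7,
    n_iterations: int = 1000,
    n_orth: int = 2,
    seed: int = 0,
    preprocessing: str = "discovery",
) -> MccvResult:
    """Repeated random sub-sampling validation of the scaling + OPLS-DA fit.

    Per iteration (seed derived from the master seed): stratified split, fit
    column scaling and OPLS-DA on the discovery split only, score the
    validation split, record the AUROC.  ``preprocessing='global'`` instead
    uses ``x`` as already scaled, mimicking a pre-normalized matrix.

    ``x`` should be the preprocessed (imputed/PQN/glog, QC-corrected) but, for
    the default leakage-safe mode, *unscaled-per-split* study matrix.
    """
    if preprocessing not in ("discovery", "global"):
        raise ValueError("preprocessing must be 'discovery' or 'global'")
    y = np.asarray(y)
    x = np.asarray(x, dtype=float)
    child_seeds = np.random.SeedSequence(seed).spawn(n_iterations)
    aucs = np.empty(n_iterations)
    n_retries = 0
    for i in range(n_iterations):
        rng = np.random.default_rng(child_seeds[i])
        for _attempt in range(3):
            try:
                disc, val = split_indices(y, discovery_fraction, rng)
                assert not set(disc) & set(val)
                if preprocessing == "discovery":
                    centers = x[disc].mean(axis=0)
                    scales = x[disc].std(axis=0, ddof=1)
                    scales[scales == 0] = 1.0
                else:
                    centers, scales = 0.0, 1.0
                res = OPLSDA(y[disc], (x[disc] - centers) / scales).fit(n_orthogonal=n_orth)
                s, _, _ = res.predict((x[val] - centers) / scales)
                aucs[i] = _mann_whitney_auc(s[y[val] == 1], s[y[val] == 0])
                break
            except ValueError:
                n_retries += 1
        else:
            raise ValueError(f"MCCV iteration {i} failed after 3 retries")
    return MccvResult(
        aucs=aucs,
        median=float(np.median(aucs)),
        min=float(aucs.min()),
        max=float(aucs.max()),
        discovery_fraction=discovery_fraction,
        seed=seed,
        n_retries=n_retries,
    )
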