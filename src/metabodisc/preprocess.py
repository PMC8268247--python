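"""Feature-table preprocessing: imputation, PQN, glog, scaling, normality screen.

The fixed stage order is impute -> PQN -> glog -> center/unit-variance scale.
PQN requires positive raw intensities, and the glog transform must precede
scaling because scaling destroys the positivity glog relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import FeatureTable, Role, SampleMeta


# -- missing-value imputation -------------------------------------------


@dataclass
class ImputationResult:
    table: FeatureTable
    chosen_rank: int
    converged: bool
    n_iterations: int
    cv_errors: np.ndarray  # per candidate rank 1..max_rank


def _svd_complete(
    x: np.ndarray, mask: np.ndarray, rank: int, tol: float, max_iter: int
) -> tuple[np.ndarray, bool, int]:
    """Iterative truncated-SVD completion of entries flagged in ``mask``."""
    filled = x.copy()
    col_means = np.array([x[~mask[:, j], j].mean() for j in range(x.shape[1])])
    filled[mask] = np.broadcast_to(col_means, x.shape)[mask]
    scale = max(np.abs(filled).max(), 1.0)
    for it in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        delta = np.abs(recon[mask] - filled[mask]).max() / scale if mask.any() else 0.0
        filled[mask] = recon[mask]
        if delta < tol:
            return filled, True, it
    return filled, False, max_iter


def impute_missing(
    table: FeatureTable,
    max_rank: int = 10,
    cv_fraction: float = 0.05,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> ImputationResult:
    """Impute missing entries by cross-validated iterative SVD completion.

    The completion rank is chosen by additionally masking ``cv_fraction`` of
    the observed entries, imputing at each candidate rank 1..``max_rank``, and
    keeping the rank with the smallest reconstruction error on the held-out
    entries.  Observed entries are never modified.
    """
    x, mask = table.values, table.missing_mask
    n_obs_per_col = (~mask).sum(axis=0)
    bad = np.flatnonzero(n_obs_per_col < 2)
    if bad.size:
        raise ValueError(
            f"metabolite {table.metabolite_ids[bad[0]]!r} has fewer than 2 observed values"
        )
    max_rank = min(max_rank, min(x.shape) - 1)
    if not mask.any():
        return ImputationResult(table.copy(), 0, True, 0, np.zeros(0))

    rng = np.random.default_rng(seed)
    obs = np.argwhere(~mask)
    n_holdout = max(1, int(round(cv_fraction * len(obs))))
    # hold out observed entries, but keep >= 2 observed per column
    order = rng.permutation(len(obs))
    holdout: list[np.ndarray] = []
    col_budget = n_obs_per_col - 2
    for k in order:
        i, j = obs[k]
        if col_budget[j] > 0:
            holdout.append(obs[k])
            col_budget[j] -= 1
            if len(holdout) == n_holdout:
                break
    ho = np.asarray(holdout)
    cv_mask = mask.copy()
    cv_mask[ho[:, 0], ho[:, 1]] = True

    cv_errors = np.empty(max_rank)
    for rank in range(1, max_rank + 1):
        filled, _, _ = _svd_complete(x, cv_mask, rank, tol, max_iter)
        cv_errors[rank - 1] = np.sqrt(np.mean((filled[ho[:, 0], ho[:, 1]] - x[ho[:, 0], ho[:, 1]]) ** 2))
    chosen = int(np.argmin(cv_errors)) + 1

    filled, converged, n_it = _svd_complete(x, mask, chosen, tol, max_iter)
    out = x.copy()
    out[mask] = filled[mask]
    return ImputationResult(table.with_values(out), chosen, converged, n_it, cv_errors)


# -- probabilistic quotient normalization -------------------------------


def pqn_normalize(
    table: FeatureTable,
    meta: Sequence[SampleMeta] | None = None,
    reference: str = "auto",
) -> tuple[FeatureTable, np.ndarray]:
    """Probabilistic quotient normalization against a median reference spectrum.

    Per sample, the dilution factor is the median over metabolites of the
    intensity/reference quotient; every intensity is divided by it.  The
    reference spectrum is the per-metabolite median over QC samples
    (``reference='qc_median'``) or over all study samples (``'study_median'``);
    ``'auto'`` uses the QC median when at least 5 QC samples exist.
    """
    if not table.is_complete:
        raise ValueError("PQN requires a complete table (run imputation first)")
    x = table.values
    qc_rows = []
    study_rows = list(range(table.n_samples))
    if meta is not None:
        by_id = {m.sample_id: m for m in meta}
        qc_rows = [i for i, s in enumerate(table.sample_ids) if by_id[s].role is Role.QC]
        study_rows = [i for i in range(table.n_samples) if i not in set(qc_rows)]
    if reference == "auto":
        reference = "qc_median" if len(qc_rows) >= 5 else "study_median"
    if reference == "qc_median":
        if not qc_rows:
            raise ValueError("qc_median reference requires QC samples in the metadata")
        ref = np.median(x[qc_rows], axis=0)
    elif reference == "study_median":
        ref = np.median(x[study_rows], axis=0)
    else:
        raise ValueError(f"unknown PQN reference {reference!r}")
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive reference intensity for metabolite {table.metabolite_ids[bad[0]]!r}"
        )
    dilution = np.median(x / ref, axis=1)
    return table.with_values(x / dilution[:, None]), dilution


# -- generalized logarithm ----------------------------------------------


def glog_transform(table: FeatureTable, lam: float | str = "auto") -> tuple[FeatureTable, float]:
    """Generalized log transform x -> log2((x + sqrt(x^2 + lambda)) / 2).

    Strictly increasing for any lambda > 0 and well-defined at zero; reduces to
    log2(x) at lambda = 0.  ``lam='auto'`` sets lambda = (m/10)^2 with m the
    smallest positive entry, so the transform is gently regularized near the
    detection limit without distorting large intensities.
    """
    if not table.is_complete:
        raise ValueError("glog requires a complete table")
    x = table.values
    if lam == "auto":
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("cannot auto-select lambda: no positive entries")
        lam = float((positive.min() / 10.0) ** 2)
    lam = float(lam)
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if lam == 0 and (x <= 0).any():
        raise ValueError("lambda = 0 requires strictly positive intensities")
    return table.with_values(np.log2((x + np.sqrt(x * x + lam)) / 2.0)), lam


# -- centering / unit-variance scaling ----------------------------------


@dataclass
class Scaler:
    """Column centers and scales learned on training data, applicable to
    held-out samples (e.g. the validation split of an MCCV iteration)."""

    centers: np.ndarray
    scales: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.centers) / self.scales


def autoscale(table: FeatureTable) -> tuple[FeatureTable, Scaler]:
    """Center each metabolite to mean 0 and scale to unit sample SD (ddof=1)."""
    if not table.is_complete:
        raise ValueError("autoscale requires a complete table")
    x = table.values
    centers = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(scales == 0)
    if bad.size:
        raise ValueError(f"zero-variance metabolite {table.metabolite_ids[bad[0]]!r}")
    scaler = Scaler(centers, scales)
    return table.with_values(scaler.apply(x)), scaler


# -- normality screen ---------------------------------------------------


def normality_screen(table: FeatureTable) -> list[dict]:
    """Shapiro-Wilk test per metabolite; advisory only, nothing is filtered."""
    if not table.is_complete:
        raise ValueError("normality screen requires a complete table")
    if table.n_samples < 3:
        raise ValueError("normality screen requires at least 3 samples")
    out = []
    for j, mid in enumerate(table.metabolite_ids):
        w, p = stats.shapiro(table.values[:, j])
        out.append({"metabolite_id": mid, "statistic": float(w), "p_value": float(p)})
    return out
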