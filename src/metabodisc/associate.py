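"""Per-metabolite association statistics: Welch t-tests with Bonferroni
control and single-predictor binomial logistic regression odds ratios.

Odds ratios are per 1 unit of the *transformed, unit-variance-scaled*
metabolite level — i.e. per 1 SD — since the upstream pipeline autoscales the
glog-transformed matrix.  Models are unadjusted single-predictor fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .datatypes import FeatureTable

__all__ = [
    "AssociationRow",
    "SeparationError",
    "ttest_bonferroni",
    "logistic_or",
    "build_association_table",
]


class SeparationError(ValueError):
    """Raised when logistic regression diverges under (quasi-)complete separation."""


@dataclass
class AssociationRow:
    metabolite_id: str
    mean_case: float
    mean_control: float
    t_stat: float
    p_raw: float
    p_adj: float
    direction: str  # "higher_in_cases" | "lower_in_cases"
    or_estimate: float | None = None
    or_ci: tuple[float, float] | None = None
    or_p: float | None = None
    degenerate: bool = False


def ttest_bonferroni(table: FeatureTable, y: np.ndarray) -> list[AssociationRow]:
    """Welch two-sample t-test per metabolite, Bonferroni-adjusted over all
    metabolites tested (p_adj = min(1, m * p_raw))."""
    y = np.asarray(y).ravel()
    if table.n_samples != y.size:
        raise ValueError("y length must match the number of samples")
    if not table.is_complete:
        raise ValueError("association tests require a complete table")
    cases = table.values[y == 1]
    controls = table.values[y == 0]
    if cases.shape[0] < 2 or controls.shape[0] < 2:
        raise ValueError("need at least 2 samples per class")
    m = table.n_metabolites
    rows = []
    for j, mid in enumerate(table.metabolite_ids):
        a, b = cases[:, j], controls[:, j]
        degenerate = False
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            # exact-equality rule for doubly constant data
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
            degenerate = True
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            AssociationRow(
                metabolite_id=mid,
                mean_case=float(a.mean()),
                mean_control=float(b.mean()),
                t_stat=float(t),
                p_raw=float(p),
                p_adj=float(min(1.0, m * p)),
                direction="higher_in_cases" if a.mean() >= b.mean() else "lower_in_cases",
                degenerate=degenerate,
            )
        )
    return rows


def logistic_or(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """Single-predictor binomial logistic regression: (OR, 95% Wald CI, p).

    Maximum likelihood by IRLS (tol 1e-8, 50 iterations); OR = exp(beta1) per
    unit of x.  Complete or quasi-complete separation raises
    :class:`SeparationError` instead of reporting a divergent estimate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel()
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes, coded 0/1")
    design = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=50, tol=1e-8)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError("complete or quasi-complete separation") from exc
    beta1 = float(fit.params[1])
    se1 = float(fit.bse[1])
    if abs(beta1) > 30 or not np.isfinite(se1) or se1 > 1e3:
        raise SeparationError("diverging coefficient: (quasi-)complete separation")
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(beta1 - z * se1)), float(np.exp(beta1 + z * se1)))
    p = float(2.0 * stats.norm.sf(abs(beta1 / se1)))
    return float(np.exp(beta1)), ci, p


def build_association_table(
    table: FeatureTable, y: np.ndarray, selected: list[str]
) -> list[AssociationRow]:
    """Join t-test and logistic-regression results for selected metabolites,
    sorted by odds ratio; log2(OR) is the forest-plot axis downstream."""
    if not selected:
        raise ValueError("selected metabolite list is empty")
    unknown = [s for s in selected if s not in table.metabolite_ids]
    if unknown:
        raise ValueError(f"unknown metabolite id: {unknown[0]!r}")
    t_rows = {r.metabolite_id: r for r in ttest_bonferroni(table, y)}
    out = []
    for mid in selected:
        row = t_rows[mid]
        j = table.metabolite_ids.index(mid)
        try:
            orr, ci, p = logistic_or(table.values[:, j], y)
            row.or_estimate, row.or_ci, row.or_p = orr, ci, p
        except SeparationError:
            row.degenerate = True
        out.append(row)
    out.sort(key=lambda r: (r.or_estimate if r.or_estimate is not None else np.inf))
    return out
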