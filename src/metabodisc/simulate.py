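"""Synthetic case/control/QC cohort generator with planted ground truth.

The generator emulates a processed untargeted LC-MS plasma feature table at the
level the analysis consumes: log-normal metabolite intensities, per-sample
dilution factors, a low-rank "experimental variability" component shared by QC
and study samples (the exact condition under which QC-subspace correction is
valid), additive log-scale group effects on a small discriminant subset, and a
mixture of completely-at-random and low-intensity-preferential missing values.

Everything is reproducible from ``CohortSpec.seed``; the returned
:class:`TruthRecord` carries the planted truth so downstream stages can be
tested for recovery, not just for running.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import FeatureTable, Role, SampleMeta

_BLOCK_SIZE = 10  # metabolites per correlated block (pathway-like co-regulation)


def _default_effects() -> np.ndarray:
    # 5 up / 5 down at 1.2 baseline-SD on the log scale: moderately strong
    # individual markers (planted single-metabolite AUC ~0.79) that form a
    # strongly discriminating multivariate panel, as in the study condition.
    return np.array([1.2] * 5 + [-1.2] * 5)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the study dimensions: 146 cases, 272 controls, pooled-QC
    injections, 214 identified metabolites.  Effects are log-scale mean shifts
    in units of the per-metabolite biological SD (``baseline_sd``).
    """

    n_cases: int = 146
    n_controls: int = 272
    n_qc: int = 46  # one pooled-QC injection per ~10 study samples
    n_metabolites: int = 214
    n_discriminant: int = 10
    effect_sizes: np.ndarray = field(default_factory=_default_effects)
    baseline_sd: float = 0.28
    dilution_sd: float = 0.3
    nuisance_rank: int = 2
    nuisance_sd: float = 1.0
    noise_sd: float = 0.05
    missing_rate: float = 0.05
    mnar_weight: float = 0.5
    block_correlation: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.n_discriminant > self.n_metabolites:
            raise ValueError("n_discriminant must not exceed n_metabolites")
        if len(self.effect_sizes) != self.n_discriminant:
            raise ValueError(
                f"effect_sizes length {len(self.effect_sizes)} != n_discriminant {self.n_discriminant}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.mnar_weight <= 1.0:
            raise ValueError("mnar_weight must lie in [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        for val, name in [
            (self.baseline_sd, "baseline_sd"),
            (self.dilution_sd, "dilution_sd"),
            (self.nuisance_sd, "nuisance_sd"),
            (self.noise_sd, "noise_sd"),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TruthRecord:
    """Planted ground truth for recovery tests."""

    discriminant_indices: np.ndarray
    effect_sizes: np.ndarray
    dilution_factors: np.ndarray  # per table row, study then QC
    nuisance_scores: np.ndarray  # (n_samples + n_qc) x nuisance_rank
    nuisance_loadings: np.ndarray  # nuisance_rank x n_metabolites, unit rows
    missing_positions: np.ndarray  # (k, 2) row/column indices


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, list[SampleMeta], TruthRecord]:
    """Simulate a cohort; rows ordered cases, controls, then QC injections."""
    rng = np.random.default_rng(spec.seed)
    n_study = spec.n_cases + spec.n_controls
    n_total = n_study + spec.n_qc
    m = spec.n_metabolites

    # per-metabolite log-normal baseline: location and common biological scale
    mu = rng.uniform(8.0, 13.0, size=m)
    sigma = spec.baseline_sd

    disc = rng.choice(m, size=spec.n_discriminant, replace=False)
    disc.sort()

    # block-correlated biological variation (study samples only)
    n_blocks = int(np.ceil(m / _BLOCK_SIZE))
    block_of = np.repeat(np.arange(n_blocks), _BLOCK_SIZE)[:m]
    shared = rng.standard_normal((n_study, n_blocks))
    indep = rng.standard_normal((n_study, m))
    rho = spec.block_correlation
    bio = sigma * (np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * indep)

    # group effect: cases only, discriminant metabolites only, log-additive
    effect = np.zeros((n_study, m))
    effect[: spec.n_cases, disc] = spec.effect_sizes * sigma

    # rank-r nuisance shared by study and QC rows
    scores = spec.nuisance_sd * rng.standard_normal((n_total, spec.nuisance_rank))
    loadings = rng.standard_normal((spec.nuisance_rank, m))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    nuisance = scores @ loadings

    noise = spec.noise_sd * rng.standard_normal((n_total, m))

    log_x = np.empty((n_total, m))
    log_x[:n_study] = mu + bio + effect + nuisance[:n_study] + noise[:n_study]
    # QC = pooled mean profile (cases and controls mixed in cohort proportion)
    qc_profile = mu.copy()
    qc_profile[disc] += (spec.n_cases / n_study) * spec.effect_sizes * sigma
    log_x[n_study:] = qc_profile + nuisance[n_study:] + noise[n_study:]

    dilution = np.exp(spec.dilution_sd * rng.standard_normal(n_total))
    values = np.exp(log_x) * dilution[:, None]

    # missingness: MCAR + low-intensity-preferential mixture
    mask = np.zeros((n_total, m), dtype=bool)
    n_miss = int(round(spec.missing_rate * n_total * m))
    if n_miss > 0:
        flat_log = log_x.ravel()
        n_mnar = int(round(spec.mnar_weight * n_miss))
        n_mcar = n_miss - n_mnar
        chosen: list[np.ndarray] = []
        if n_mnar > 0:
            # low-intensity preference relative to each metabolite's own
            # abundance (detection-limit censoring within the feature)
            z_cols = (log_x - log_x.mean(axis=0)) / log_x.std(axis=0)
            z = z_cols.ravel()
            w = np.exp(-2.0 * z)
            w /= w.sum()
            chosen.append(rng.choice(flat_log.size, size=n_mnar, replace=False, p=w))
        if n_mcar > 0:
            remaining = np.setdiff1d(np.arange(flat_log.size), chosen[0] if chosen else [])
            chosen.append(rng.choice(remaining, size=n_mcar, replace=False))
        flat_idx = np.concatenate(chosen)
        mask.ravel()[flat_idx] = True
        # keep every metabolite observable: >= 2 observed values per column
        for j in np.flatnonzero(mask.sum(axis=0) > n_total - 2):
            hit = np.flatnonzero(mask[:, j])
            keep = hit[np.argsort(values[hit, j])[::-1][: mask[:, j].sum() - (n_total - 2)]]
            mask[keep, j] = False

    sample_ids = (
        [f"CASE{i + 1:03d}" for i in range(spec.n_cases)]
        + [f"CTRL{i + 1:03d}" for i in range(spec.n_controls)]
        + [f"QC{i + 1:03d}" for i in range(spec.n_qc)]
    )
    metabolite_ids = [f"M{j + 1:03d}" for j in range(m)]
    meta = (
        [SampleMeta(s, Role.CASE, 1, run_order=i) for i, s in enumerate(sample_ids[: spec.n_cases])]
        + [
            SampleMeta(s, Role.CONTROL, 0, run_order=spec.n_cases + i)
            for i, s in enumerate(sample_ids[spec.n_cases : n_study])
        ]
        + [
            SampleMeta(s, Role.QC, None, run_order=n_study + i)
            for i, s in enumerate(sample_ids[n_study:])
        ]
    )
    table = FeatureTable(sample_ids, metabolite_ids, values, mask)
    truth = TruthRecord(
        discriminant_indices=disc,
        effect_sizes=spec.effect_sizes.copy(),
        dilution_factors=dilution,
        nuisance_scores=scores,
        nuisance_loadings=loadings,
        missing_positions=np.argwhere(mask),
    )
    return table, meta, truth


def planted_auc(spec: CohortSpec) -> float:
    """Expected AUC of the single best planted metabolite, by normal theory.

    For a metabolite with log-scale case/control mean difference ``d`` and
    within-group SD ``s`` in each arm, AUC = Phi(d / (s * sqrt(2))).  Here
    ``d = |e| * baseline_sd`` for the largest planted effect ``e`` and
    ``s^2 = baseline_sd^2 + noise_sd^2``, giving

        AUC = Phi(|e| / sqrt(2) / sqrt(1 + noise_sd^2 / baseline_sd^2)).

    The formula assumes dilution and nuisance variation have been removed
    (PQN and QC correction), so it calibrates *post-correction* recovery tests.
    """
    if spec.n_discriminant == 0 or np.all(spec.effect_sizes == 0):
        return 0.5
    e = float(np.max(np.abs(spec.effect_sizes)))
    ratio = (spec.noise_sd / spec.baseline_sd) ** 2 if spec.baseline_sd > 0 else 0.0
    return float(stats.norm.cdf(e / np.sqrt(2.0) / np.sqrt(1.0 + ratio)))
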