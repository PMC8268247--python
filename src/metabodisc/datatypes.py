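"""Core data containers shared by every pipeline stage.

The central object is :class:`FeatureTable`, a samples x metabolites intensity
matrix with explicit identifiers and an explicit missing-value mask.  Missing
entries are *never* encoded as NaN sentinels inside computation kernels: each
operation declares how it handles the mask (most require a complete table and
say so in their preconditions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class Role(str, Enum):
    """Role of a sample in the study design."""

    CASE = "case"
    CONTROL = "control"
    QC = "qc"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: role, binary outcome, run order, matching strata.

    ``y`` is 1 for cases, 0 for controls, and ``None`` for pooled-QC samples,
    which carry no outcome by construction.
    """

    sample_id: str
    role: Role
    y: int | None = None
    run_order: int | None = None
    strata: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.role is Role.QC:
            if self.y is not None:
                raise ValueError(f"QC sample {self.sample_id!r} must not carry an outcome")
        else:
            if self.y not in (0, 1):
                raise ValueError(
                    f"{self.role.value} sample {self.sample_id!r} requires a binary outcome"
                )
            expected = 1 if self.role is Role.CASE else 0
            if self.y != expected:
                raise ValueError(
                    f"sample {self.sample_id!r}: outcome {self.y} inconsistent with role "
                    f"{self.role.value}"
                )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Samples x metabolites intensity matrix with ids and missing-value mask.

    Parameters
    ----------
    sample_ids, metabolite_ids
        Unique row / column identifiers.
    values
        ``(n_samples, n_metabolites)`` float array.  Entries flagged in
        ``missing_mask`` have unspecified content and must not be read.
    missing_mask
        Boolean array of the same shape; True marks a missing measurement.
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.metabolite_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.sample_ids)} samples "
                f"x {len(self.metabolite_ids)} metabolites"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.metabolite_ids, "metabolite")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape must match values")

    # -- convenience ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.sample_ids),
            list(self.metabolite_ids),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def with_values(self, values: np.ndarray, missing_mask: np.ndarray | None = None) -> "FeatureTable":
        """New table with the same ids but replaced values (and optionally mask)."""
        mask = missing_mask if missing_mask is not None else np.zeros_like(self.missing_mask)
        return FeatureTable(list(self.sample_ids), list(self.metabolite_ids), values, mask)

    def subset_samples(self, ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(i) for i in ids]
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            list(self.metabolite_ids),
            self.values[idx],
            self.missing_mask[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Render as a DataFrame with NaN marking missing entries (I/O only)."""
        vals = self.values.copy()
        vals[self.missing_mask] = np.nan
        return pd.DataFrame(vals, index=self.sample_ids, columns=self.metabolite_ids)


def check_meta_matches_table(table: FeatureTable, meta: Sequence[SampleMeta]) -> dict[str, SampleMeta]:
    """Validate that every table sample has exactly one metadata record.

    Returns a sample_id -> SampleMeta map for convenient downstream lookup.
    """
    by_id: dict[str, SampleMeta] = {}
    for record in meta:
        if record.sample_id in by_id:
            raise ValueError(f"duplicate metadata record for sample {record.sample_id!r}")
        by_id[record.sample_id] = record
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return by_id


def study_indices(table: FeatureTable, meta: Sequence[SampleMeta]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row indices of (study, qc) samples and the study outcome vector y."""
    by_id = check_meta_matches_table(table, meta)
    study, qc, y = [], [], []
    for i, sid in enumerate(table.sample_ids):
        rec = by_id[sid]
        if rec.role is Role.QC:
            qc.append(i)
        else:
            study.append(i)
            y.append(rec.y)
    return np.asarray(study, dtype=int), np.asarray(qc, dtype=int), np.asarray(y, dtype=int)


# -- configuration ------------------------------------------------------


@dataclass
class ImputationConfig:
    max_rank: int = 10
    cv_fraction: float = 0.05
    tol: float = 1e-6
    max_iter: int = 200


@dataclass
class PqnConfig:
    # "auto": QC-median reference when >= 5 QC samples exist, else study-median
    reference: str = "auto"


@dataclass
class GlogConfig:
    lam: float | str = "auto"


@dataclass
class QcCorrectionConfig:
    n_components: int = 2


@dataclass
class OplsConfig:
    n_orthogonal: int | str = "auto"
    max_orthogonal: int = 6
    cv_folds: int = 7
    n_permutations: int = 100


@dataclass
class ValidationConfig:
    discovery_fraction: float = 0.7
    n_iterations: int = 1000
    # "discovery": refit scaling/QC model on discovery only (leakage-safe);
    # "global": use the globally preprocessed matrix as-is.
    preprocessing: str = "discovery"


@dataclass
class SplsdaConfig:
    n_components: int = 5
    keep_per_component: int = 15
    n_cv_folds: int = 5
    n_cv_repeats: int = 10


@dataclass
class AssociationConfig:
    alpha: float = 0.05
    adjust: str = "bonferroni"


@dataclass
class PipelineConfig:
    """All tunable settings of the pipeline; defaults encode the study settings
    (2 QC principal components, 7-fold CV, 70/30 split, 1000 resamplings,
    5 sparse components x 15 variables, Bonferroni at 0.05)."""

    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    pqn: PqnConfig = field(default_factory=PqnConfig)
    glog: GlogConfig = field(default_factory=GlogConfig)
    qc_correction: QcCorrectionConfig = field(default_factory=QcCorrectionConfig)
    opls: OplsConfig = field(default_factory=OplsConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    splsda: SplsdaConfig = field(default_factory=SplsdaConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, name in [
            (self.imputation.cv_fraction, "imputation.cv_fraction"),
            (self.validation.discovery_fraction, "validation.discovery_fraction"),
        ]:
            if not 0.0 < frac < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {frac}")
        for count, name in [
            (self.imputation.max_rank, "imputation.max_rank"),
            (self.opls.cv_folds, "opls.cv_folds"),
            (self.validation.n_iterations, "validation.n_iterations"),
            (self.splsda.n_components, "splsda.n_components"),
            (self.splsda.keep_per_component, "splsda.keep_per_component"),
            (self.splsda.n_cv_folds, "splsda.n_cv_folds"),
        ]:
            if int(count) < 1:
                raise ValueError(f"{name} must be a positive integer, got {count}")

    def to_dict(self) -> dict:
        def as_dict(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: as_dict(getattr(obj, k)) for k in obj.__dataclass_fields__}
            return obj

        return as_dict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = {}
        section_types = {
            "imputation": ImputationConfig,
            "pqn": PqnConfig,
            "glog": GlogConfig,
            "qc_correction": QcCorrectionConfig,
            "opls": OplsConfig,
            "validation": ValidationConfig,
            "splsda": SplsdaConfig,
            "association": AssociationConfig,
        }
        for key, value in d.items():
            if key in section_types:
                kwargs[key] = section_types[key](**value)
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)
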