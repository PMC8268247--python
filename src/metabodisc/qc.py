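"""QC-subspace correction: remove structured experimental variability.

Pooled-QC injections are replicate measurements of one mixture, so any
structured variation among them is experimental (instrument drift, batch
handling), not biological.  A small PCA model fitted on the QC rows captures
that structure; projecting every sample orthogonally to the QC principal
subspace removes it from study samples as well, because the same instrument
effects act on both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import FeatureTable, Role, SampleMeta


@dataclass
class QcModel:
    """QC mean profile and orthonormal loadings of the experimental subspace."""

    qc_mean: np.ndarray  # (n_metabolites,)
    loadings: np.ndarray  # (n_metabolites, n_components), orthonormal columns

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {"qc_mean": self.qc_mean.tolist(), "loadings": self.loadings.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "QcModel":
        return cls(np.asarray(d["qc_mean"], float), np.asarray(d["loadings"], float))


def fit_qc_model(qc_table: FeatureTable, n_components: int = 2) -> QcModel:
    """PCA model of the QC rows: mean profile + first ``n_components`` PCs.

    Loadings are the leading right singular vectors of the QC-mean-centered QC
    matrix, ordered by decreasing singular value, with the sign fixed so each
    component's largest-magnitude element is positive.
    """
    x = qc_table.values
    if x.shape[0] < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} QC samples for {n_components} components, "
            f"got {x.shape[0]}"
        )
    qc_mean = x.mean(axis=0)
    if n_components == 0:
        return QcModel(qc_mean, np.zeros((x.shape[1], 0)))
    _, _, vt = np.linalg.svd(x - qc_mean, full_matrices=False)
    loadings = vt[:n_components].T
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
    return QcModel(qc_mean, loadings)


def remove_qc_variation(table: FeatureTable, model: QcModel) -> FeatureTable:
    """Project every sample orthogonally to the QC principal subspace.

    Each row x becomes x - ((x - qc_mean) . P) P^T; the correction is an
    idempotent projector applied to study and QC rows alike.
    """
    if table.n_metabolites != model.qc_mean.shape[0]:
        raise ValueError(
            f"table has {table.n_metabolites} metabolites but QC model expects "
            f"{model.qc_mean.shape[0]}"
        )
    if model.n_components == 0:
        return table.copy()
    centered = table.values - model.qc_mean
    scores = centered @ model.loadings
    return table.with_values(table.values - scores @ model.loadings.T)


def fit_and_correct(
    table: FeatureTable, meta: Sequence[SampleMeta], n_components: int = 2
) -> tuple[FeatureTable, QcModel]:
    """Fit the QC model on the table's QC rows and correct the whole table."""
    by_id = {m.sample_id: m for m in meta}
    qc_ids = [s for s in table.sample_ids if by_id[s].role is Role.QC]
    model = fit_qc_model(table.subset_samples(qc_ids), n_components)
    return remove_qc_variation(table, model), model
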