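import pytest

from metabodisc.datatypes import study_indices
from metabodisc.preprocess import autoscale, glog_transform, impute_missing, pqn_normalize
from metabodisc.qc import fit_and_correct
from metabodisc.simulate import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for structural tests: 30/50 study samples, 40 metabolites."""
    spec = CohortSpec(
        n_cases=30, n_controls=50, n_qc=10, n_metabolites=40, seed=11,
    )
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort at the study dimensions (146/272/40 x 214), seed 7."""
    spec = CohortSpec(seed=7)
    return spec, *generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_default(default_cohort):
    """Default cohort taken through the full preprocessing chain; yields the
    centered study matrix, labels and planted truth."""
    spec, table, meta, truth = default_cohort
    imp = impute_missing(table, max_rank=4, seed=1)
    norm, dilution = pqn_normalize(imp.table, meta)
    glogged, _ = glog_transform(norm)
    scaled, _ = autoscale(glogged)
    corrected, _ = fit_and_correct(scaled, meta, n_components=2)
    study, qc_idx, y = study_indices(table, meta)
    x = corrected.values[study]
    x = x - x.mean(axis=0)
    x_uncorrected = scaled.values[study]
    x_uncorrected = x_uncorrected - x_uncorrected.mean(axis=0)
    return {
        "spec": spec,
        "table": table,
        "meta": meta,
        "truth": truth,
        "x": x,
        "x_uncorrected": x_uncorrected,
        "scaled": scaled,
        "y": y,
        "dilution_est": dilution,
        "metabolite_ids": corrected.metabolite_ids,
        "corrected": corrected,
        "study_idx": study,
        "qc_idx": qc_idx,
    }
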