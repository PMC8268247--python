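"""End-to-end orchestration: impute -> PQN -> glog -> scale -> QC-correct ->
OPLS-DA (+ MCCV validation) -> sPLS-DA selection -> association table.

Every random stage consumes a seed derived from the master seed keyed by the
stage name, so each stage is independently reproducible; rerunning with an
identical config reproduces every numerical output exactly.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Sequence

import numpy as np

from . import associate as assoc_mod
from . import preprocess as prep
from . import qc as qc_mod
from .datatypes import FeatureTable, PipelineConfig, SampleMeta, study_indices
from .io import ResultBundle, config_hash
from .opls import OPLSDA, permutation_check, q2_cross_validate, select_n_orthogonal
from .splsda import SPLSDA, cv_error_rate
from .validation import monte_carlo_validation

logger = logging.getLogger("metabodisc")


def derive_seed(master: int, stage: str) -> int:
    """Stage-keyed seed derivation: deterministic, documented, below 2**31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(
    config: PipelineConfig, table: FeatureTable, meta: Sequence[SampleMeta]
) -> ResultBundle:
    """Run the full discovery workflow and collect all stage outputs."""
    study, qc_rows, y = study_indices(table, meta)  # validates meta up front
    bundle = ResultBundle()
    bundle.provenance = {"seed": config.seed, "config_hash": config_hash(config)}
    seed = config.seed

    def stage(name):
        logger.info("stage=%s seed=%s", name, derive_seed(seed, name))
        return derive_seed(seed, name)

    # -- imputation
    imp = prep.impute_missing(
        table,
        max_rank=config.imputation.max_rank,
        cv_fraction=config.imputation.cv_fraction,
        tol=config.imputation.tol,
        max_iter=config.imputation.max_iter,
        seed=stage("impute"),
    )
    bundle.record(
        "impute",
        {"max_rank": config.imputation.max_rank, "cv_fraction": config.imputation.cv_fraction},
        {
            "chosen_rank": imp.chosen_rank,
            "converged": imp.converged,
            "n_missing": int(table.missing_mask.sum()),
        },
    )

    # -- PQN
    normalized, dilution = prep.pqn_normalize(imp.table, meta, reference=config.pqn.reference)
    bundle.record("pqn", {"reference": config.pqn.reference}, {"dilution": dilution})

    # -- glog
    glogged, lam = prep.glog_transform(normalized, lam=config.glog.lam)
    bundle.record("glog", {"lambda": config.glog.lam}, {"lambda_used": lam})

    # -- scaling
    scaled, scaler = prep.autoscale(glogged)
    normality = prep.normality_screen(scaled.subset_samples([scaled.sample_ids[i] for i in study]))
    bundle.record(
        "scale",
        {},
        {"centers": scaler.centers, "scales": scaler.scales, "normality": normality},
    )

    # -- QC-subspace correction
    corrected, qc_model = qc_mod.fit_and_correct(
        scaled, meta, n_components=config.qc_correction.n_components
    )
    bundle.record(
        "qc_correct",
        {"n_components": config.qc_correction.n_components},
        {"qc_model": qc_model.to_dict()},
    )

    x_study = corrected.values[study]
    x_study = x_study - x_study.mean(axis=0)  # recenter study rows for modelling

    # -- OPLS-DA
    opls_seed = stage("opls")
    if config.opls.n_orthogonal == "auto":
        n_orth = select_n_orthogonal(
            x_study, y, max_orth=config.opls.max_orthogonal,
            folds=config.opls.cv_folds, seed=opls_seed,
        )
    else:
        n_orth = int(config.opls.n_orthogonal)
    res = OPLSDA(y, x_study).fit(n_orthogonal=n_orth)
    res.q2 = q2_cross_validate(x_study, y, n_orth, folds=config.opls.cv_folds, seed=opls_seed)
    perm = permutation_check(
        x_study, y, n_orth,
        n_perm=config.opls.n_permutations, folds=config.opls.cv_folds, seed=opls_seed,
    )
    bundle.record(
        "opls",
        {"n_orthogonal": n_orth, "cv_folds": config.opls.cv_folds,
         "n_permutations": config.opls.n_permutations},
        {"r2y": res.r2y, "q2": res.q2, "perm_p": perm.perm_p,
         "q2_permuted": perm.q2_permuted, "model": res.to_dict()},
    )

    # -- MCCV validation
    mccv = monte_carlo_validation(
        x_study, y,
        discovery_fraction=config.validation.discovery_fraction,
        n_iterations=config.validation.n_iterations,
        n_orth=n_orth,
        seed=stage("validate"),
        preprocessing=config.validation.preprocessing,
    )
    bundle.record(
        "validate",
        {"discovery_fraction": config.validation.discovery_fraction,
         "n_iterations": config.validation.n_iterations},
        {"aucs": mccv.aucs, "median": mccv.median, "min": mccv.min, "max": mccv.max},
    )

    # -- sPLS-DA selection
    spls_seed = stage("splsda")
    study_ids = [corrected.sample_ids[i] for i in study]
    spls = SPLSDA(y, x_study, corrected.metabolite_ids).fit(
        n_components=config.splsda.n_components, keep=config.splsda.keep_per_component
    )
    spls.error_rate = cv_error_rate(
        x_study, y,
        n_components=config.splsda.n_components, keep=config.splsda.keep_per_component,
        folds=config.splsda.n_cv_folds, n_repeats=config.splsda.n_cv_repeats, seed=spls_seed,
    )
    ranking = spls.rank_variables()
    bundle.record(
        "splsda",
        {"n_components": config.splsda.n_components,
         "keep_per_component": config.splsda.keep_per_component},
        {"ranking": [[mid, imp] for mid, imp in ranking],
         "selected": spls.selected, "error_rate": spls.error_rate},
    )

    # -- association statistics on the top-10 ranked metabolites
    top10 = [mid for mid, _ in ranking[:10]]
    corrected_study = corrected.subset_samples(study_ids)
    rows = assoc_mod.build_association_table(corrected_study, y, top10)
    bundle.record(
        "associate",
        {"alpha": config.association.alpha, "adjust": config.association.adjust},
        {"table": [
            {
                "metabolite_id": r.metabolite_id,
                "mean_case": r.mean_case,
                "mean_control": r.mean_control,
                "t_stat": r.t_stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "or_estimate": r.or_estimate,
                "or_ci": list(r.or_ci) if r.or_ci else None,
                "or_p": r.or_p,
                "log2_or": (None if r.or_estimate is None else float(np.log2(r.or_estimate))),
            }
            for r in rows
        ]},
    )
    return bundle
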