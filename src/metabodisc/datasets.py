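"""Small published summary datasets used as worked examples and oracles."""

from __future__ import annotations

import numpy as np


def psa_exposure_counts() -> dict[str, int]:
    """Baseline PSA-category counts from the prostate-cancer nested
    case-control cohort the pipeline was designed around: cases and controls
    cross-classified by PSA >= 3 ng/mL at blood draw.

    The 2x2 layout makes the logistic-regression odds ratio available in
    closed form (cross-product ratio), which the association module must
    reproduce.
    """
    return {
        "cases_exposed": 49,
        "cases_unexposed": 97,
        "controls_exposed": 16,
        "controls_unexposed": 256,
    }


def psa_exposure_vectors() -> tuple[np.ndarray, np.ndarray]:
    """Expand the 2x2 PSA counts into (x, y) vectors for regression:
    x = exposure indicator (PSA >= 3 ng/mL), y = case status."""
    c = psa_exposure_counts()
    x = np.concatenate([
        np.ones(c["cases_exposed"]),
        np.zeros(c["cases_unexposed"]),
        np.ones(c["controls_exposed"]),
        np.zeros(c["controls_unexposed"]),
    ])
    y = np.concatenate([
        np.ones(c["cases_exposed"] + c["cases_unexposed"], dtype=int),
        np.zeros(c["controls_exposed"] + c["controls_unexposed"], dtype=int),
    ])
    return x, y
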