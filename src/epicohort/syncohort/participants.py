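"""Participant-table simulation: demographics, availability flags, QC flags."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._seeds import stream
from .config import CohortConfig

__all__ = ["generate_participants"]

_RACE_LABELS = ["white", "black", "asian", "multiracial", "other"]
_RACE_PROBS = [0.70, 0.21, 0.04, 0.03, 0.02]


def _exact_flags(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Boolean vector with exactly ``k`` True entries, positions random."""
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=k, replace=False)] = True
    return flags


def generate_participants(config: CohortConfig) -> pd.DataFrame:
    """Simulate the participant table.

    Availability flags (``wgs_available``, survey completion) and QC
    flags (outlier / related / race mismatch) are independent Bernoulli
    draws unless an exact-count override (``n_wgs``, ``n_qc_flagged``)
    is set, in which case the flagged subset is sampled without
    replacement so the count is deterministic.
    """
    rng = stream(config.seed, "participants")
    n = config.n_participants
    ids = [f"P{i:06d}" for i in range(n)]

    age = np.clip(rng.normal(50.0, 16.0, size=n), 18, 95).round(1)
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    race = rng.choice(_RACE_LABELS, size=n, p=_RACE_PROBS)
    bmi = np.clip(rng.normal(28.5, 6.0, size=n), 15, 60).round(1)

    if config.n_wgs is not None:
        wgs = _exact_flags(rng, n, config.n_wgs)
    else:
        wgs = rng.random(n) < config.wgs_fraction
    completed_a = rng.random(n) < config.exposome_a_fraction
    completed_b = rng.random(n) < config.exposome_b_fraction

    table = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "sex": sex,
            "race": race,
            "bmi": bmi,
            "wgs_available": wgs,
            "completed_he": np.ones(n, dtype=bool),
            "completed_ext": completed_a,
            "completed_int": completed_b,
        }
    )

    qc_cols = list(config.qc_flag_rates)
    if config.n_qc_flagged is not None:
        # distribute the flagged subset over reasons proportionally to the
        # configured rates; a participant may carry several reasons only
        # when rates say so, here each flagged id gets exactly one reason
        flagged = rng.choice(n, size=config.n_qc_flagged, replace=False)
        rates = np.array([config.qc_flag_rates[c] for c in qc_cols], dtype=float)
        probs = rates / rates.sum() if rates.sum() > 0 else np.ones(len(qc_cols)) / len(qc_cols)
        reasons = rng.choice(len(qc_cols), size=config.n_qc_flagged, p=probs)
        for j, col in enumerate(qc_cols):
            flags = np.zeros(n, dtype=bool)
            flags[flagged[reasons == j]] = True
            table[col] = flags
    else:
        for col in qc_cols:
            table[col] = rng.random(n) < config.qc_flag_rates[col]
    return table
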