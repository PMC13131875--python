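"""Configuration and ground-truth records for synthetic cohort generation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = ["CohortConfig", "TruthRecord", "variant_name"]


def variant_name(j: int) -> str:
    """Canonical variant identifier for column index ``j``."""
    return f"v{j:05d}"


_FRACTION_FIELDS = (
    "prevalence_target",
    "wgs_fraction",
    "exposome_a_fraction",
    "exposome_b_fraction",
)


@dataclass
class CohortConfig:
    """Knobs for one synthetic cohort.

    Effects are expressed on the logit scale of the binary outcome:
    ``variant_effects`` maps variant ids (``v00000``...) to per-dosage
    log-odds, ``env_effects`` maps survey variable names to per-unit
    log-odds on their numeric encoding, and ``gxe_effects`` lists
    ``(variant, env_variable, beta3)`` product terms.

    When ``mu`` is None the intercept is calibrated by bisection so the
    expected prevalence matches ``prevalence_target``.
    """

    n_participants: int = 9449
    prevalence_target: float = 0.33
    wgs_fraction: float = 0.481
    exposome_a_fraction: float = 0.347
    exposome_b_fraction: float = 0.296
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_populations: int = 3
    admixture_concentration: float = 0.5
    fst: float = 0.05
    mu: Optional[float] = None
    variant_effects: dict[str, float] = field(default_factory=dict)
    env_effects: dict[str, float] = field(default_factory=dict)
    gxe_effects: list[tuple[str, str, float]] = field(default_factory=list)
    confounder_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.0, "sex": 0.0, "bmi": 0.0}
    )
    item_missing_rate: float = 0.02
    qc_flag_rates: dict[str, float] = field(
        default_factory=lambda: {
            "qc_outlier": 0.010,
            "qc_related": 0.015,
            "qc_race_mismatch": 0.005,
        }
    )
    # exact-count overrides (sampled without replacement when set)
    n_wgs: Optional[int] = None
    n_qc_flagged: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_participants < 1 or self.n_variants < 1 or self.n_populations < 1:
            raise ValueError("n_participants, n_variants, n_populations must be >= 1")
        if self.admixture_concentration <= 0:
            raise ValueError("admixture_concentration must be positive")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        if not 0.0 <= self.item_missing_rate < 1.0:
            raise ValueError("item_missing_rate must lie in [0, 1)")
        valid = {variant_name(j) for j in range(self.n_variants)}
        bad = [v for v in self.variant_effects if v not in valid]
        bad += [v for v, _e, _b in self.gxe_effects if v not in valid]
        if bad:
            raise ValueError(f"effect references to unknown variants: {sorted(set(bad))}")
        if self.n_wgs is not None and not 0 <= self.n_wgs <= self.n_participants:
            raise ValueError("n_wgs out of range")
        if self.n_qc_flagged is not None and not 0 <= self.n_qc_flagged <= self.n_participants:
            raise ValueError("n_qc_flagged out of range")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        if "gxe_effects" in raw:
            raw["gxe_effects"] = [tuple(t) for t in raw["gxe_effects"]]
        return cls(**raw)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict

        data = asdict(self)
        data["maf_range"] = list(self.maf_range)
        data["gxe_effects"] = [list(t) for t in self.gxe_effects]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthRecord:
    """Ground truth retained alongside a generated cohort.

    ``linear_predictor`` is the full logit-scale predictor per
    participant (aligned with the participant table); ``latent_env``
    holds the numeric encoding of every survey variable for every
    participant before block/item missingness is applied, so stored
    effects can be recombined to reproduce the predictor exactly.
    """

    mu: float
    prevalence: float
    variant_effects: dict[str, float]
    env_effects: dict[str, float]
    gxe_effects: list[tuple[str, str, float]]
    confounder_effects: dict[str, float]
    linear_predictor: np.ndarray
    latent_env: pd.DataFrame = field(repr=False)

    def recompute_linear_predictor(
        self, dosages: np.ndarray, variant_index: dict[str, int], confounders: pd.DataFrame
    ) -> np.ndarray:
        """Rebuild the predictor from stored effects and raw data."""
        eta = np.full(len(self.latent_env), self.mu, dtype=float)
        for vid, w in self.variant_effects.items():
            eta += w * dosages[:, variant_index[vid]]
        for name, g in self.env_effects.items():
            eta += g * self.latent_env[name].to_numpy()
        for vid, name, b3 in self.gxe_effects:
            eta += b3 * dosages[:, variant_index[vid]] * self.latent_env[name].to_numpy()
        for name, c in self.confounder_effects.items():
            eta += c * confounders[name].to_numpy()
        return eta
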