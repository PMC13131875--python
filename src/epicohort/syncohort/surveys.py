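"""Survey-table simulation: mixed types, gating/skip logic, missingness.

Three tables mirror a cohort questionnaire layout: a health & exposure
survey completed by everyone, plus two exposome surveys each completed
by a configurable fraction of participants (block missingness). Within
a table, gate variables force their dependents missing ("skipped") and
a configurable fraction of remaining cells is missing at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._seeds import stream
from .config import CohortConfig

__all__ = [
    "SurveyVariable",
    "SurveySchema",
    "DEFAULT_SCHEMAS",
    "generate_surveys",
    "env_variable_names",
]


@dataclass(frozen=True)
class SurveyVariable:
    """One questionnaire item.

    kind: continuous | ordinal | binary | categorical | text.
    ``gate`` is ``(gate_variable, skip_value)``: rows where the gate
    variable equals ``skip_value`` leave this item blank, and its latent
    numeric value (used for phenotype effects) is 0.
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()
    p: float = 0.5  # P(second level) for binary
    mean: float = 0.0
    sd: float = 1.0
    gate: tuple[str, str] | None = None


@dataclass(frozen=True)
class SurveySchema:
    name: str
    variables: tuple[SurveyVariable, ...] = field(default_factory=tuple)

    def names(self) -> list[str]:
        return [v.name for v in self.variables]


_HE = SurveySchema(
    "survey_he",
    (
        SurveyVariable("smoker", "binary", ("no", "yes"), p=0.30),
        SurveyVariable(
            "cigarettes_per_day", "continuous", mean=12.0, sd=6.0, gate=("smoker", "no")
        ),
        SurveyVariable("exercise_level", "ordinal", ("none", "light", "moderate", "heavy")),
        SurveyVariable("health_change", "ordinal", ("worse", "same", "better")),
        SurveyVariable("sleep_hours", "continuous", mean=7.0, sd=1.2),
        SurveyVariable("alcohol_use", "binary", ("no", "yes"), p=0.55),
        SurveyVariable("diabetes", "binary", ("no", "yes"), p=0.12),
        SurveyVariable("hypertension", "binary", ("no", "yes"), p=0.30),
        SurveyVariable(
            "diet_quality", "ordinal", ("poor", "fair", "good", "very_good", "excellent")
        ),
        SurveyVariable("residence_type", "categorical", ("urban", "suburban", "rural")),
        SurveyVariable("injury_notes", "text"),
    ),
)

_EXT = SurveySchema(
    "survey_a",
    (
        SurveyVariable("dye_exposure", "binary", ("no", "yes"), p=0.15),
        SurveyVariable("pesticide_use", "binary", ("no", "yes"), p=0.20),
        SurveyVariable("traffic_exposure", "ordinal", ("low", "medium", "high")),
        SurveyVariable("solvent_hours", "continuous", mean=2.0, sd=1.5),
        SurveyVariable("well_water", "binary", ("no", "yes"), p=0.25),
    ),
)

_INT = SurveySchema(
    "survey_b",
    (
        SurveyVariable("vitamin_e", "binary", ("no", "yes"), p=0.35),
        SurveyVariable("supplement_count", "continuous", mean=1.5, sd=1.0),
        SurveyVariable("sun_exposure", "ordinal", ("rare", "occasional", "frequent")),
        SurveyVariable("plastic_use", "ordinal", ("low", "medium", "high")),
    ),
)

DEFAULT_SCHEMAS: dict[str, SurveySchema] = {s.name: s for s in (_HE, _EXT, _INT)}

_WORDS = ("none", "minor fall", "sprain", "sports injury", "car accident", "burn")


def env_variable_names(schemas: dict[str, SurveySchema] | None = None) -> list[str]:
    """Names usable as environmental effects (numeric-encodable kinds)."""
    schemas = schemas or DEFAULT_SCHEMAS
    out = []
    for schema in schemas.values():
        for v in schema.variables:
            if v.kind in ("continuous", "ordinal", "binary"):
                out.append(v.name)
    return out


def _draw_variable(
    var: SurveyVariable, n: int, rng: np.random.Generator
) -> tuple[pd.Series, np.ndarray]:
    """Return (visible values, numeric encoding) for one item."""
    if var.kind == "continuous":
        x = rng.normal(var.mean, var.sd, size=n)
        if var.mean > 0:
            x = np.clip(x, 0, None)
        return pd.Series(x.round(2)), x
    if var.kind == "binary":
        hit = rng.random(n) < var.p
        labels = np.where(hit, var.levels[1], var.levels[0])
        return pd.Series(labels, dtype=object), hit.astype(float)
    if var.kind == "ordinal":
        k = len(var.levels)
        codes = np.floor(rng.random(n) * k).astype(int).clip(0, k - 1)
        labels = np.asarray(var.levels, dtype=object)[codes]
        return pd.Series(labels, dtype=object), codes.astype(float)
    if var.kind == "categorical":
        labels = rng.choice(np.asarray(var.levels, dtype=object), size=n)
        return pd.Series(labels, dtype=object), np.zeros(n)
    if var.kind == "text":
        labels = rng.choice(np.asarray(_WORDS, dtype=object), size=n)
        return pd.Series(labels, dtype=object), np.zeros(n)
    raise ValueError(f"unknown variable kind {var.kind!r}")


def _synthesize_table(
    schema: SurveySchema, ids: list[str], rng: np.random.Generator, item_missing: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(ids)
    visible = pd.DataFrame(index=pd.Index(ids, name="id"))
    latent = pd.DataFrame(index=pd.Index(ids, name="id"))
    for var in schema.variables:
        values, numeric = _draw_variable(var, n, rng)
        values.index = visible.index
        if var.gate is not None:
            gate_var, skip_value = var.gate
            if gate_var not in visible.columns:
                raise ValueError(f"gate variable {gate_var!r} must precede {var.name!r}")
            skipped = (visible[gate_var] == skip_value).to_numpy()
            values[skipped] = np.nan
            numeric = np.where(skipped, 0.0, numeric)
        if item_missing > 0 and var.gate is None:
            hole = rng.random(n) < item_missing
            values[hole] = np.nan
        visible[var.name] = values
        if var.kind in ("continuous", "ordinal", "binary"):
            latent[var.name] = numeric
    return visible, latent


def generate_surveys(
    config: CohortConfig,
    participants: pd.DataFrame,
    schemas: dict[str, SurveySchema] | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate the three survey tables.

    Returns ``(tables, latent_env)``. ``tables`` maps schema name to the
    visible table, restricted to completer rows (block missingness).
    ``latent_env`` holds the numeric encoding of every effect-eligible
    variable for *all* participants: phenotype effects act on the
    underlying exposures regardless of whether the answer was recorded.
    """
    schemas = schemas or DEFAULT_SCHEMAS
    rng = stream(config.seed, "surveys")
    ids = participants["id"].tolist()
    completion = {
        "survey_he": participants["completed_he"].to_numpy(),
        "survey_a": participants["completed_ext"].to_numpy(),
        "survey_b": participants["completed_int"].to_numpy(),
    }

    tables: dict[str, pd.DataFrame] = {}
    latent_parts = []
    for name, schema in schemas.items():
        visible, latent = _synthesize_table(schema, ids, rng, config.item_missing_rate)
        keep = completion.get(name, np.ones(len(ids), dtype=bool))
        tables[name] = visible.loc[np.asarray(keep)]
        latent_parts.append(latent)
    latent_env = pd.concat(latent_parts, axis=1)
    return tables, latent_env
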