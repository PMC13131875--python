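"""Cohort container and the end-to-end generation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from .config import CohortConfig, TruthRecord
from .genotypes_sim import generate_genotypes
from .participants import generate_participants
from .phenotype import generate_phenotype
from .surveys import DEFAULT_SCHEMAS, SurveySchema, generate_surveys

__all__ = ["Cohort", "generate_cohort"]


@dataclass
class Cohort:
    """A fully generated synthetic cohort.

    ``genotypes`` contains rows exactly for participants whose
    ``wgs_available`` flag is set; survey tables contain rows exactly
    for participants with the corresponding completion flag. The
    outcome covers everyone.
    """

    participants: pd.DataFrame
    survey_he: pd.DataFrame
    survey_a: pd.DataFrame
    survey_b: pd.DataFrame
    genotypes: GenotypeMatrix | None
    outcome: pd.Series
    truth: TruthRecord = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.participants["id"]
        if ids.duplicated().any():
            raise ValueError("participant ids must be unique")
        if len(self.outcome) != len(ids):
            raise ValueError("outcome must cover every participant")
        if self.genotypes is not None:
            wgs_ids = set(ids[self.participants["wgs_available"]])
            if set(self.genotypes.samples) != wgs_ids:
                raise ValueError("genotype rows must match wgs_available participants")
        for table, flag in (
            (self.survey_a, "completed_ext"),
            (self.survey_b, "completed_int"),
        ):
            expected = set(ids[self.participants[flag]])
            if set(table.index) != expected:
                raise ValueError(f"survey rows must match {flag} participants")

    @property
    def ids(self) -> list[str]:
        return self.participants["id"].tolist()

    def outcome_by_id(self) -> pd.Series:
        s = pd.Series(self.outcome.to_numpy(), index=self.participants["id"].to_numpy())
        s.index.name = "id"
        return s


def generate_cohort(
    config: CohortConfig, schemas: dict[str, SurveySchema] | None = None
) -> Cohort:
    """Run the full simulation: participants, genotypes, surveys, outcome."""
    schemas = schemas or DEFAULT_SCHEMAS
    participants = generate_participants(config)
    genotypes_full = generate_genotypes(config, sample_ids=participants["id"].tolist())
    tables, latent_env = generate_surveys(config, participants, schemas)
    outcome, truth = generate_phenotype(config, participants, genotypes_full, latent_env)

    wgs_ids = participants.loc[participants["wgs_available"], "id"].tolist()
    genotypes = genotypes_full.subset_samples(wgs_ids) if wgs_ids else None
    return Cohort(
        participants=participants,
        survey_he=tables["survey_he"],
        survey_a=tables["survey_a"],
        survey_b=tables["survey_b"],
        genotypes=genotypes,
        outcome=outcome,
        truth=truth,
    )
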