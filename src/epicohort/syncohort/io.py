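"""Cohort directory I/O: tab-separated tables plus a JSON truth file."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..genotypes import GenotypeMatrix
from .cohort import Cohort
from .config import TruthRecord

__all__ = ["write_cohort", "read_cohort"]


def write_cohort(cohort: Cohort, out_dir: str | Path, vcf: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    for name in ("survey_he", "survey_a", "survey_b"):
        getattr(cohort, name).to_csv(out / f"{name}.tsv", sep="\t")
    cohort.outcome_by_id().to_frame("outcome").to_csv(out / "outcome.tsv", sep="\t")
    if cohort.genotypes is not None:
        cohort.genotypes.to_tsv(out / "dosages.tsv")
        if vcf:
            cohort.genotypes.to_vcf(out / "genotypes.vcf")
    truth = cohort.truth
    payload = {
        "mu": truth.mu,
        "prevalence": truth.prevalence,
        "variant_effects": truth.variant_effects,
        "env_effects": truth.env_effects,
        "gxe_effects": [list(t) for t in truth.gxe_effects],
        "confounder_effects": truth.confounder_effects,
        "linear_predictor": truth.linear_predictor.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
    truth.latent_env.to_csv(out / "latent_env.tsv", sep="\t")


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    participants = pd.read_csv(src / "participants.tsv", sep="\t")
    tables = {
        name: pd.read_csv(src / f"{name}.tsv", sep="\t", index_col="id")
        for name in ("survey_he", "survey_a", "survey_b")
    }
    outcome_by_id = pd.read_csv(src / "outcome.tsv", sep="\t", index_col="id")["outcome"]
    outcome = pd.Series(
        outcome_by_id.loc[participants["id"]].to_numpy(), index=participants.index,
        name="outcome",
    )
    genotypes = None
    if (src / "dosages.tsv").exists():
        genotypes = GenotypeMatrix.from_tsv(src / "dosages.tsv")
    raw = json.loads((src / "truth.json").read_text())
    truth = TruthRecord(
        mu=raw["mu"],
        prevalence=raw["prevalence"],
        variant_effects=raw["variant_effects"],
        env_effects=raw["env_effects"],
        gxe_effects=[tuple(t) for t in raw["gxe_effects"]],
        confounder_effects=raw["confounder_effects"],
        linear_predictor=np.asarray(raw["linear_predictor"]),
        latent_env=pd.read_csv(src / "latent_env.tsv", sep="\t", index_col="id"),
    )
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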