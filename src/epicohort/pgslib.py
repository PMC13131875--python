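"""Polygenic score computation from harmonized weight files.

Weight files follow the harmonized scoring-file convention: tab-separated
with columns ``rsID, chr_name, chr_position, effect_allele, other_allele,
effect_weight``. Scoring matches variants against the cohort dosage
matrix by chromosome+position+alleles first, falling back to rsID, and
flips the dosage (d -> 2-d) when the effect allele is the cohort's
reference allele. Variants that cannot be matched, or whose alleles are
incompatible, are skipped and counted; they never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeMatrix

__all__ = [
    "WeightSet",
    "PgsVector",
    "score",
    "Standardizer",
    "benchmark_classifier",
    "BenchmarkResult",
]

_WEIGHT_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]


@dataclass
class WeightSet:
    """One polygenic score definition."""

    score_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _WEIGHT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        keys = self.table["rsID"]
        if keys.duplicated().any():
            raise ValueError("duplicate variant keys in weight set")
        same = self.table["effect_allele"] == self.table["other_allele"]
        if same.any():
            raise ValueError("effect and other allele identical in some rows")
        self.table = self.table.reset_index(drop=True)
        self.table["chr_name"] = self.table["chr_name"].astype(str)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_file(cls, path: str | Path, score_id: str | None = None) -> "WeightSet":
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(score_id or Path(path).stem, table)

    def to_file(self, path: str | Path) -> None:
        self.table[_WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class PgsVector:
    """Raw (and optionally standardized) scores for a set of samples."""

    score_id: str
    samples: list[str]
    raw: np.ndarray
    matched: int
    skipped: int
    standardized: np.ndarray | None = None

    def as_series(self, standardized: bool = False) -> pd.Series:
        values = self.standardized if standardized else self.raw
        if values is None:
            raise ValueError("scores have not been standardized")
        s = pd.Series(values, index=pd.Index(self.samples, name="id"), name=self.score_id)
        return s


def score(genotypes: GenotypeMatrix, weights: WeightSet) -> PgsVector:
    """Weighted dosage sum over matched variants.

    Effective dosage is ``d`` when the cohort's alternative allele is
    the effect allele and ``2 - d`` when the reference allele is; any
    other allele configuration is skipped.
    """
    meta = genotypes.variants
    by_pos = {
        (str(r.chrom), int(r.pos)): j for j, r in enumerate(meta.itertuples(index=False))
    }
    by_id = {r.id: j for j, r in enumerate(meta.itertuples(index=False))}

    total = np.zeros(genotypes.n_samples, dtype=float)
    matched = 0
    skipped = 0
    dosages = genotypes.dosages
    for row in weights.table.itertuples(index=False):
        j = by_pos.get((str(row.chr_name), int(row.chr_position)))
        if j is None:
            j = by_id.get(row.rsID)
        if j is None:
            skipped += 1
            continue
        ref, alt = meta.at[j, "ref"], meta.at[j, "alt"]
        pair = {row.effect_allele, row.other_allele}
        if pair != {ref, alt}:
            skipped += 1
            continue
        if row.effect_allele == alt:
            total += dosages[:, j] * row.effect_weight
        else:  # effect allele is the cohort reference: flip dosage
            total += (2 - dosages[:, j]) * row.effect_weight
        matched += 1
    if matched == 0:
        raise ValueError(f"no variants of weight set {weights.score_id!r} matched the cohort")
    return PgsVector(weights.score_id, list(genotypes.samples), total, matched, skipped)


class Standardizer:
    """Z-transform frozen on a reference subset and reusable on new rows."""

    def __init__(self) -> None:
        self.mean_: float | None = None
        self.sd_: float | None = None

    def fit(self, values: np.ndarray) -> "Standardizer":
        values = np.asarray(values, dtype=float)
        self.mean_ = float(values.mean())
        self.sd_ = float(values.std(ddof=0))
        if self.sd_ == 0:
            raise ValueError("cannot standardize zero-variance scores")
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer has not been fit")
        return (np.asarray(values, dtype=float) - self.mean_) / self.sd_


def standardize(pgs: PgsVector, reference_samples: list[str] | None = None) -> PgsVector:
    """Attach standardized scores; statistics come from the reference
    subset (default: all scored samples) and are frozen on the vector."""
    if reference_samples is None:
        ref_values = pgs.raw
    else:
        index = {s: i for i, s in enumerate(pgs.samples)}
        ref_values = pgs.raw[[index[s] for s in reference_samples]]
    scaler = Standardizer().fit(ref_values)
    pgs.standardized = scaler.transform(pgs.raw)
    return pgs


@dataclass
class BenchmarkResult:
    probabilities: pd.Series
    auroc: float
    intercept: float
    slope: float
    separation: bool = False


def benchmark_classifier(pgs: PgsVector, outcome: pd.Series) -> BenchmarkResult:
    """Univariate logistic regression of outcome on the standardized score.

    ``outcome`` is indexed by sample id; only ids present in the score
    vector are used (i.e. genotyped individuals).
    """
    from .metrics import auroc as _auroc

    x = pgs.as_series(standardized=pgs.standardized is not None)
    common = [s for s in pgs.samples if s in outcome.index]
    x = x.loc[common]
    y = outcome.loc[common].astype(int)
    if y.nunique() < 2:
        raise ValueError("outcome must contain both classes")
    design = sm.add_constant(x.to_numpy())
    separation = False
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation detected via params
            fit = sm.Logit(y.to_numpy(), design).fit(disp=0)
        params = fit.params
        if np.abs(params).max() > 1e3:
            separation = True
        probs = fit.predict(design)
    except Exception:  # perfect separation: fall back to a flagged ranking fit
        separation = True
        slope = np.sign(np.corrcoef(x, y)[0, 1]) * 50.0
        params = np.array([0.0, slope])
        probs = 1 / (1 + np.exp(-(params[0] + params[1] * x.to_numpy())))
    series = pd.Series(np.asarray(probs), index=x.index, name="probability")
    return BenchmarkResult(
        probabilities=series,
        auroc=_auroc(series.to_numpy(), y.to_numpy()),
        intercept=float(params[0]),
        slope=float(params[1]),
        separation=separation,
    )
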