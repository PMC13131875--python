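"""Admixed genotype simulation with Balding-Nichols population structure."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .._seeds import stream
from ..genotypes import GenotypeMatrix
from .config import CohortConfig, variant_name

__all__ = ["generate_genotypes", "admixture_proportions"]


def admixture_proportions(config: CohortConfig, n: int | None = None) -> np.ndarray:
    """Per-individual ancestry proportions, Dirichlet(concentration)."""
    rng = stream(config.seed, "admixture")
    n = config.n_participants if n is None else n
    if config.n_populations == 1:
        return np.ones((n, 1))
    alpha = np.full(config.n_populations, config.admixture_concentration)
    return rng.dirichlet(alpha, size=n)


def generate_genotypes(
    config: CohortConfig,
    sample_ids: list[str] | None = None,
    pop_freq: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Simulate a dosage matrix for every participant.

    Per variant an ancestral frequency is drawn uniformly in
    ``maf_range``; per-population frequencies follow the Balding-Nichols
    Beta with divergence ``fst``; each individual's allele frequency is
    the admixture-weighted mix and the dosage is Binomial(2, p).
    ``pop_freq`` (shape ``(n_populations, n_variants)``) pins the
    per-population frequencies instead of drawing them.
    """
    low, high = config.maf_range
    rng = stream(config.seed, "genotypes")
    n = config.n_participants if sample_ids is None else len(sample_ids)
    if sample_ids is None:
        sample_ids = [f"P{i:06d}" for i in range(n)]

    m = config.n_variants
    ancestral = rng.uniform(low, high, size=m)
    if pop_freq is not None:
        pop_freq = np.asarray(pop_freq, dtype=float)
        if pop_freq.shape != (config.n_populations, m):
            raise ValueError("pop_freq must have shape (n_populations, n_variants)")
    elif config.n_populations == 1:
        pop_freq = ancestral[None, :]
    else:
        f = config.fst
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        pop_freq = rng.beta(a, b, size=(config.n_populations, m))
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)

    q = admixture_proportions(config, n)  # (n, K)
    p_ind = q @ pop_freq  # (n, m)
    dosages = (rng.random((n, m)) < p_ind).astype(np.int8)
    dosages += (rng.random((n, m)) < p_ind).astype(np.int8)

    bases = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    p_hat = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "id": [variant_name(j) for j in range(m)],
            "chrom": (rng.integers(1, 23, size=m)).astype(str),
            "pos": np.sort(rng.integers(1, 250_000_000, size=m)),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "maf": np.minimum(p_hat, 1 - p_hat),
        }
    )
    return GenotypeMatrix(dosages, sample_ids, variants)
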