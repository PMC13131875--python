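"""Simulated harmonized weight sets for polygenic-score workflows.

Each generated score covers a random subset of cohort variants with
weights proportional to the cohort's true per-variant effects plus
noise, so scores carry tunable genetic signal. A configurable fraction
of rows lists the reference allele as the effect allele (with the sign
flipped accordingly) to exercise the scorer's allele-flip rule.
"""

from __future__ import annotations

import numpy as np

from .._seeds import stream
from ..genotypes import GenotypeMatrix
from ..pgslib import WeightSet

__all__ = ["generate_weight_sets"]

import pandas as pd


def generate_weight_sets(
    genotypes: GenotypeMatrix,
    variant_effects: dict[str, float],
    n_sets: int = 12,
    seed: int = 0,
    fraction_variants: float = 0.5,
    signal_scale: float = 1.0,
    noise_sd: float = 0.05,
    flip_fraction: float = 0.2,
) -> list[WeightSet]:
    rng = stream(seed, "weight_sets")
    meta = genotypes.variants
    true = np.array([variant_effects.get(vid, 0.0) for vid in meta["id"]])
    out = []
    for k in range(n_sets):
        n_pick = max(1, int(round(fraction_variants * len(meta))))
        picked = np.sort(rng.choice(len(meta), size=n_pick, replace=False))
        weights = signal_scale * true[picked] + rng.normal(0, noise_sd, size=n_pick)
        flip = rng.random(n_pick) < flip_fraction
        rows = []
        for idx, w, fl in zip(picked, weights, flip):
            r = meta.iloc[idx]
            effect, other = (r["ref"], r["alt"]) if fl else (r["alt"], r["ref"])
            rows.append(
                {
                    "rsID": r["id"],
                    "chr_name": r["chrom"],
                    "chr_position": int(r["pos"]),
                    "effect_allele": effect,
                    "other_allele": other,
                    # flipping alleles negates the weight up to a constant
                    # offset in the score, preserving the ranking signal
                    "effect_weight": -w if fl else w,
                }
            )
        out.append(WeightSet(f"SIM{k:03d}", pd.DataFrame(rows)))
    return out
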