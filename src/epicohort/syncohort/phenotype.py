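"""Binary outcome simulation on a logistic liability scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .._seeds import stream
from ..genotypes import GenotypeMatrix
from .config import CohortConfig, TruthRecord

__all__ = ["generate_phenotype", "calibrate_mu", "standardized_confounders"]


def standardized_confounders(participants: pd.DataFrame) -> pd.DataFrame:
    """Numeric confounder block: z-scored age and BMI, sex as 0/1."""
    out = pd.DataFrame(index=participants.index)
    for col in ("age", "bmi"):
        x = participants[col].to_numpy(dtype=float)
        sd = x.std()
        out[col] = (x - x.mean()) / sd if sd > 0 else 0.0
    out["sex"] = participants["sex"].to_numpy(dtype=float)
    return out


def calibrate_mu(eta_without_mu: np.ndarray, target: float, tol: float = 1e-8) -> float:
    """Bisection for the intercept giving expected prevalence ``target``.

    The expectation mean(sigmoid(eta + mu)) is strictly increasing in
    mu, so plain bisection on [-30, 30] converges; the realized
    prevalence then differs from target only by Bernoulli noise.
    """
    lo, hi = -30.0, 30.0

    def mean_prev(mu: float) -> float:
        return float(expit(eta_without_mu + mu).mean())

    if not mean_prev(lo) <= target <= mean_prev(hi):
        raise ValueError("prevalence target unreachable for this predictor")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_prev(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_phenotype(
    config: CohortConfig,
    participants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    latent_env: pd.DataFrame,
) -> tuple[pd.Series, TruthRecord]:
    """Draw the binary outcome from the configured liability model.

    P(Y=1) = sigmoid(mu + sum_j w_j G_j + sum_l gamma_l E_l
    + sum beta3 * G * E + confounder terms). Genotype effects use the
    full (pre-masking) dosage matrix so the outcome model is defined for
    every participant, including those whose genotypes are later hidden.
    """
    variant_index = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    for vid in list(config.variant_effects) + [v for v, _e, _b in config.gxe_effects]:
        if vid not in variant_index:
            raise ValueError(f"variant effect references unknown variant {vid!r}")
    for name in list(config.env_effects) + [e for _v, e, _b in config.gxe_effects]:
        if name not in latent_env.columns:
            raise ValueError(f"environment effect references unknown variable {name!r}")

    dosages = genotypes.dosages.astype(float)
    conf = standardized_confounders(participants)
    eta = np.zeros(len(participants), dtype=float)
    for vid, w in config.variant_effects.items():
        eta += w * dosages[:, variant_index[vid]]
    for name, g in config.env_effects.items():
        eta += g * latent_env[name].to_numpy()
    for vid, name, b3 in config.gxe_effects:
        eta += b3 * dosages[:, variant_index[vid]] * latent_env[name].to_numpy()
    for name, c in config.confounder_effects.items():
        if c != 0.0:
            eta += c * conf[name].to_numpy()

    mu = config.mu if config.mu is not None else calibrate_mu(eta, config.prevalence_target)
    eta = eta + mu

    rng = stream(config.seed, "phenotype")
    y = (rng.random(len(participants)) < expit(eta)).astype(int)
    outcome = pd.Series(y, index=participants.index, name="outcome")
    truth = TruthRecord(
        mu=mu,
        prevalence=float(outcome.mean()),
        variant_effects=dict(config.variant_effects),
        env_effects=dict(config.env_effects),
        gxe_effects=list(config.gxe_effects),
        confounder_effects={k: v for k, v in config.confounder_effects.items() if v != 0.0},
        linear_predictor=eta,
        latent_env=latent_env,
    )
    return outcome, truth
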