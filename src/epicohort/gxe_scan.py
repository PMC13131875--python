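"""Marginal-vs-conditional gene-environment deviation scan.

For every (variant, environment) pair two models are fit:

    marginal:  Y = a0 + a1*G              (+ covariates)
    full:      Y = b0 + b1*G + b2*E + b3*(G*E)  (+ covariates)

Absent a true interaction, the conditional genetic effect b1 is
linearly related to the marginal effect a1 across variants; pairs are
therefore ranked by how far they deviate from the regression of b1 on
a1 (externally studentized residual), within each environment by
default. The default family is linear (a linear probability model for
a binary trait, matching the additive-error form of the equations);
logistic is available per config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genotypes import GenotypeMatrix

__all__ = [
    "ScanConfig",
    "maf_filter",
    "compute_pcs",
    "fit_marginal",
    "fit_full",
    "scan_pairs",
    "deviation_scan",
]


@dataclass
class ScanConfig:
    maf_min: float = 0.05
    n_pcs: int = 0
    covariates: list[str] = field(default_factory=list)
    family: str = "linear"  # or "logistic"
    scope: str = "per-environment"  # or "pooled"
    standardize_g: bool = True
    weight_by_se: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.scope not in ("per-environment", "pooled"):
            raise ValueError("scope must be 'per-environment' or 'pooled'")


def maf_filter(genotypes: GenotypeMatrix, maf_min: float = 0.05) -> np.ndarray:
    """Boolean mask of variants with observed MAF strictly above the cut."""
    p = genotypes.dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1 - p) > maf_min


def compute_pcs(genotypes: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k genotype principal-component scores.

    Dosages are centered by 2*p and scaled by sqrt(2*p*(1-p)) per
    variant before the SVD; each component's sign is fixed so its
    largest-magnitude variant loading is positive.
    """
    if k == 0:
        return np.empty((genotypes.n_samples, 0))
    d = genotypes.dosages.astype(float)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d = d[:, keep]
    p = p[keep]
    if d.shape[1] < k + 1:
        raise ValueError(f"need at least {k + 1} polymorphic variants for {k} PCs")
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum())
    if k > rank:
        raise ValueError(f"requested {k} PCs but matrix rank is {rank}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            scores[:, j] *= -1
    return scores


# ----------------------------------------------------------------------
def _ols(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and standard errors via the normal equations."""
    xtx = design.T @ design
    n, p = design.shape
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("design matrix is (near-)singular")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (design.T @ y)
    resid = y - design @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    return beta, se


def _logistic(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    return np.asarray(fit.params), np.asarray(fit.bse)


def _design(*blocks: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(blocks[0]))]
    for b in blocks:
        if b is None or b.size == 0:
            continue
        cols.append(b if b.ndim == 2 else b[:, None])
    return np.column_stack(cols)


def _check_aligned(*arrays) -> None:
    n = len(arrays[0])
    for a in arrays:
        if a is None:
            continue
        if len(a) != n:
            raise ValueError("inputs are not aligned")
        if np.isnan(np.asarray(a, dtype=float)).any():
            raise ValueError("inputs must not contain missing values")


def fit_marginal(
    y: np.ndarray, g: np.ndarray, covariates: np.ndarray | None = None,
    family: str = "linear",
) -> tuple[float, float]:
    """Coefficient (and SE) of G in Y ~ G + covariates."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    _check_aligned(y, g, covariates)
    if np.ptp(g) == 0:
        raise ValueError("genotype vector is constant")
    design = _design(g, covariates if covariates is not None else np.empty((len(y), 0)))
    fitter = _ols if family == "linear" else _logistic
    beta, se = fitter(y, design)
    return float(beta[1]), float(se[1])


def fit_full(
    y: np.ndarray, g: np.ndarray, e: np.ndarray,
    covariates: np.ndarray | None = None, family: str = "linear",
) -> dict[str, float]:
    """Coefficients of Y ~ G + E + G:E + covariates, keyed by role."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    _check_aligned(y, g, e, covariates)
    if np.ptp(g) == 0:
        raise ValueError("genotype vector is constant")
    if np.ptp(e) == 0:
        raise ValueError("environment vector is constant")
    inter = g * e
    flagged = False
    design = _design(g, e, inter, covariates if covariates is not None else np.empty((len(y), 0)))
    fitter = _ols if family == "linear" else _logistic
    try:
        beta, se = fitter(y, design)
    except np.linalg.LinAlgError:
        # G*E collinear with existing terms (e.g. E constant within
        # dosage groups): flag and drop the interaction
        flagged = True
        design = _design(g, e, covariates if covariates is not None else np.empty((len(y), 0)))
        beta, se = fitter(y, design)
        beta = np.insert(beta, 3, np.nan)
        se = np.insert(se, 3, np.nan)
    return {
        "b1": float(beta[1]), "b1_se": float(se[1]),
        "b2": float(beta[2]), "b2_se": float(se[2]),
        "b3": float(beta[3]), "b3_se": float(se[3]),
        "collinear_interaction": flagged,
    }


# ----------------------------------------------------------------------
def scan_pairs(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    environments: pd.DataFrame,
    config: ScanConfig | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit marginal and full models for every (variant, environment)
    pair passing the MAF filter."""
    config = config or ScanConfig()
    keep = maf_filter(genotypes, config.maf_min)
    sub = genotypes.subset_variants(keep)
    blocks = []
    if config.n_pcs > 0:
        blocks.append(compute_pcs(sub, config.n_pcs))
    if covariates is not None and covariates.size:
        blocks.append(covariates if covariates.ndim == 2 else covariates[:, None])
    cov = np.column_stack(blocks) if blocks else None

    y = np.asarray(y, dtype=float)
    dosages = sub.dosages.astype(float)
    if config.standardize_g:
        mean = dosages.mean(axis=0)
        sd = dosages.std(axis=0)
        dosages = (dosages - mean) / sd

    rows = []
    for env_name in environments.columns:
        e = environments[env_name].to_numpy(dtype=float)
        for j, vid in enumerate(sub.variants["id"]):
            g = dosages[:, j]
            a1, a1_se = fit_marginal(y, g, cov, family=config.family)
            full = fit_full(y, g, e, cov, family=config.family)
            rows.append(
                {
                    "variant": vid,
                    "env": env_name,
                    "a1": a1,
                    "a1_se": a1_se,
                    **full,
                }
            )
    return pd.DataFrame(rows)


def _studentized_residuals(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Externally studentized residuals of y ~ 1 + x (optionally WLS)."""
    design = sm.add_constant(x)
    if w is None:
        fit = sm.OLS(y, design).fit()
    else:
        fit = sm.WLS(y, design, weights=w).fit()
    influence = fit.get_influence()
    return influence.resid_studentized_external, fit.params


def deviation_scan(pairs: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """Rank pairs by deviation from the b1-on-a1 regression.

    Scope groups (per environment by default) with fewer than 3 pairs
    are skipped with a warning; the output adds ``deviation``,
    regression intercept/slope, and a dense 1..n ranking by |deviation|
    (ties broken by variant key).
    """
    config = config or ScanConfig()
    if len(pairs) < 1:
        raise ValueError("no pairs to scan")
    out = pairs.copy()
    out["deviation"] = np.nan
    out["scope_intercept"] = np.nan
    out["scope_slope"] = np.nan
    out["skipped"] = False

    groups = (
        [(env, idx) for env, idx in out.groupby("env").groups.items()]
        if config.scope == "per-environment"
        else [("pooled", out.index)]
    )
    for name, idx in groups:
        block = out.loc[idx]
        ok = block["b1"].notna() & block["a1"].notna()
        if ok.sum() < 3:
            warnings.warn(f"scope {name!r} has fewer than 3 pairs; skipped")
            out.loc[idx, "skipped"] = True
            continue
        sel = block.index[ok]
        a1 = out.loc[sel, "a1"].to_numpy()
        b1 = out.loc[sel, "b1"].to_numpy()
        weights = None
        if config.weight_by_se:
            weights = 1.0 / np.clip(out.loc[sel, "b1_se"].to_numpy() ** 2, 1e-12, None)
        resid, params = _studentized_residuals(a1, b1, weights)
        out.loc[sel, "deviation"] = resid
        out.loc[idx, "scope_intercept"] = params[0]
        out.loc[idx, "scope_slope"] = params[1]

    scored = out["deviation"].notna()
    order = out.loc[scored].sort_values(
        by=["deviation", "variant"],
        key=lambda s: -s.abs() if s.name == "deviation" else s,
        kind="mergesort",
    ).index
    out["rank"] = np.nan
    out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out
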