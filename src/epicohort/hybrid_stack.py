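"""Hybrid survey + polygenic-score classifier via logistic stacking.

A baseline probabilistic classifier is trained on survey features for
everyone; for genotyped individuals its probability is combined with m
standardized polygenic scores through a logistic regression

    P(Y_k) = Xb_k                                   if k lacks genetics
    P(Y_k) = sigmoid(b0 + bb*Xb_k + sum_i bgi*Xg_ki) otherwise

so individuals without genetic data fall back to the baseline output
unchanged. Baseline probabilities used to fit the stack are produced
out-of-fold to avoid optimism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .metrics import auroc

__all__ = ["fit_baseline", "oof_probabilities", "StackedModel", "fit_stack", "evaluate_components"]

_LEARNERS = {
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=300, min_samples_leaf=5, n_jobs=1, random_state=seed
    ),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
}


def fit_baseline(features: pd.DataFrame, outcome: pd.Series, learner: str = "random_forest",
                 seed: int = 0):
    """Fit the survey-only probabilistic classifier."""
    y = np.asarray(outcome, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    if learner not in _LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {sorted(_LEARNERS)}")
    model = _LEARNERS[learner](seed)
    model.fit(features.to_numpy(dtype=float), y)
    return model


def predict_baseline(model, features: pd.DataFrame) -> pd.Series:
    probs = model.predict_proba(features.to_numpy(dtype=float))[:, 1]
    return pd.Series(probs, index=features.index, name="baseline_probability")


def oof_probabilities(
    features: pd.DataFrame, outcome: pd.Series, learner: str = "random_forest",
    seed: int = 0, n_folds: int = 5,
) -> pd.Series:
    """Out-of-fold baseline probabilities on the training rows (standard
    stacking hygiene: the meta-model never sees in-fold predictions)."""
    y = np.asarray(outcome, dtype=int)
    model = _LEARNERS[learner](seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    probs = cross_val_predict(
        model, features.to_numpy(dtype=float), y, cv=cv, method="predict_proba"
    )[:, 1]
    return pd.Series(probs, index=features.index, name="baseline_probability")


@dataclass
class StackedModel:
    """Logistic meta-model over baseline probability and m PGS."""

    beta0: float
    beta_b: float
    beta_g: np.ndarray
    pgs_names: list[str]
    standard_errors: np.ndarray | None = None
    ridge_fallback: bool = False
    logit_transform_xb: bool = False
    baseline_model: object | None = field(default=None, repr=False)

    @property
    def m(self) -> int:
        return len(self.beta_g)

    def _xb_term(self, xb: np.ndarray) -> np.ndarray:
        if self.logit_transform_xb:
            clipped = np.clip(xb, 1e-12, 1 - 1e-12)
            return np.log(clipped / (1 - clipped))
        return xb

    def predict(self, xb, xg=None) -> np.ndarray:
        """Predicted probability; rows of ``xg`` that are entirely NaN
        (or ``xg`` absent) use the baseline branch unchanged."""
        xb = np.asarray(xb, dtype=float)
        if np.any((xb < 0) | (xb > 1)):
            raise ValueError("baseline probabilities must lie in [0, 1]")
        if xg is None:
            return xb.copy()
        xg = np.atleast_2d(np.asarray(xg, dtype=float))
        if xg.shape[0] != xb.shape[0]:
            raise ValueError("xg row count must match xb")
        if xg.shape[1] != self.m:
            raise ValueError(f"expected {self.m} PGS columns, got {xg.shape[1]}")
        # m == 0: a zero-width block is "genetics present" (the all-NaN
        # test is vacuously true on zero columns)
        has_genetics = (
            ~np.isnan(xg).all(axis=1) if self.m > 0 else np.ones(len(xb), dtype=bool)
        )
        out = xb.copy()
        if has_genetics.any():
            eta = (
                self.beta0
                + self.beta_b * self._xb_term(xb[has_genetics])
                + xg[has_genetics] @ self.beta_g
            )
            out[has_genetics] = expit(eta)
        return out

    # ------------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta0": self.beta0,
            "beta_b": self.beta_b,
            "beta_g": self.beta_g.tolist(),
            "pgs_names": self.pgs_names,
            "ridge_fallback": self.ridge_fallback,
            "logit_transform_xb": self.logit_transform_xb,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StackedModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            beta0=raw["beta0"],
            beta_b=raw["beta_b"],
            beta_g=np.asarray(raw["beta_g"], dtype=float),
            pgs_names=raw["pgs_names"],
            ridge_fallback=raw.get("ridge_fallback", False),
            logit_transform_xb=raw.get("logit_transform_xb", False),
        )


def fit_stack(
    xb: pd.Series | np.ndarray,
    xg: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    logit_transform_xb: bool = False,
    ridge_alpha: float = 1e-6,
) -> StackedModel:
    """Maximum-likelihood logistic fit of outcome on (Xb, Xg1..Xgm),
    restricted by the caller to genotyped training rows.

    Falls back to a ridge-stabilized fit (penalty ``ridge_alpha``) when
    the MLE fails, e.g. under collinear PGS, and flags it.
    """
    xb_arr = np.asarray(xb, dtype=float)
    y = np.asarray(outcome, dtype=int)
    pgs_names = list(xg.columns) if isinstance(xg, pd.DataFrame) else [
        f"pgs{i}" for i in range(np.atleast_2d(xg).shape[1])
    ]
    xg_arr = np.asarray(xg, dtype=float)
    if xg_arr.ndim == 1:
        xg_arr = xg_arr.reshape(len(xg_arr), 0) if xg_arr.size == 0 else xg_arr[:, None]

    xb_term = xb_arr
    if logit_transform_xb:
        clipped = np.clip(xb_arr, 1e-12, 1 - 1e-12)
        xb_term = np.log(clipped / (1 - clipped))
    design = sm.add_constant(np.column_stack([xb_term, xg_arr]), has_constant="add")

    ridge_fallback = False
    se = None
    try:
        fit = sm.Logit(y, design).fit(disp=0, maxiter=500)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logit did not converge")
        params = np.asarray(fit.params)
        se = np.asarray(fit.bse)
    except Exception:
        import warnings

        warnings.warn("stack MLE failed; using ridge-stabilized fit", RuntimeWarning)
        ridge_fallback = True
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(  # default penalty is L2
            C=1.0 / max(ridge_alpha * len(y), 1e-12),
            solver="lbfgs", max_iter=1000, fit_intercept=False,
        )
        clf.fit(design, y)
        params = clf.coef_.ravel()
    return StackedModel(
        beta0=float(params[0]),
        beta_b=float(params[1]),
        beta_g=params[2:].astype(float),
        pgs_names=pgs_names,
        standard_errors=se,
        ridge_fallback=ridge_fallback,
        logit_transform_xb=logit_transform_xb,
    )


def evaluate_components(
    y_valid: np.ndarray,
    survey_probs: np.ndarray,
    pgs_probs: np.ndarray | None,
    hybrid_probs: np.ndarray,
    pgs_mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Validation AUROCs for the survey-only, PGS-only, and hybrid
    predictions plus the hybrid-minus-best-component gap. The PGS-only
    metric is computed on genotyped rows (``pgs_mask``) only."""
    report = {
        "auroc_survey": auroc(survey_probs, y_valid),
        "auroc_hybrid": auroc(hybrid_probs, y_valid),
    }
    if pgs_probs is not None:
        if pgs_mask is None:
            pgs_mask = ~np.isnan(pgs_probs)
        report["auroc_pgs"] = auroc(pgs_probs[pgs_mask], y_valid[pgs_mask])
    components = [v for k, v in report.items() if k in ("auroc_survey", "auroc_pgs")]
    report["hybrid_gap"] = report["auroc_hybrid"] - max(components)
    return report
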