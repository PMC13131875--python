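"""Survey-variable filtering, skip-fill, imputation, and encoding.

Transforms are pure and fit/apply separated: statistics (medians,
modes, retained-variable sets) are computed once on training rows and
frozen for reuse on validation/test rows. Skip fills are applied before
missingness is measured, so by-design skips (a gated question left
blank) do not count as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PrepRecipe",
    "ImputeStats",
    "SurveyPrep",
    "apply_skip_fills",
    "filter_variables",
    "fit_impute",
    "impute",
    "encode",
    "decode",
]


@dataclass
class PrepRecipe:
    """Declarative preprocessing rules.

    ``skip_fills`` maps ``(gate_variable, gate_value)`` to a mapping of
    dependent variable -> fill value; fills apply only to missing cells
    of rows where the gate matches. Thresholds are strict: a variable is
    dropped only when its missing fraction *exceeds*
    ``max_missing_fraction`` (and likewise for the mode rule).
    """

    max_missing_fraction: float = 0.05
    max_mode_fraction: float = 0.95
    numeric_impute: str = "median"  # or "mean"
    categorical_impute: str = "mode"
    ordinal_orderings: dict[str, list[str]] = field(default_factory=dict)
    skip_fills: dict[tuple[str, str], dict[str, Any]] = field(default_factory=dict)
    drop_free_text: bool = True
    drop_unordered: bool = False
    apply_mode_filter: bool = False
    collinearity_threshold: float | None = None
    sex_exclusions: list[str] = field(default_factory=list)
    text_variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "max_mode_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.numeric_impute not in ("median", "mean"):
            raise ValueError("numeric_impute must be 'median' or 'mean'")

    @classmethod
    def survey_baseline(cls, **kw) -> "PrepRecipe":
        """Five-percent missingness rule only (baseline-classifier prep)."""
        return cls(apply_mode_filter=False, drop_unordered=True, **kw)

    @classmethod
    def scan_strict(cls, **kw) -> "PrepRecipe":
        """Adds the 95% mode rule, collinearity and sex-dependence screens
        (interaction-scan prep)."""
        kw.setdefault("collinearity_threshold", 0.95)
        return cls(apply_mode_filter=True, drop_unordered=True, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PrepRecipe":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "skip_fills" in raw:
            raw["skip_fills"] = {
                (k.split("=", 1)[0], k.split("=", 1)[1]): v
                for k, v in raw["skip_fills"].items()
            }
        return cls(**raw)


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)


def variable_kind(series: pd.Series, name: str, recipe: PrepRecipe) -> str:
    if name in recipe.text_variables:
        return "text"
    if _is_numeric(series):
        return "continuous"
    if name in recipe.ordinal_orderings:
        return "ordinal"
    n_levels = series.dropna().nunique()
    if n_levels <= 2:
        return "binary"
    return "unordered"


# ----------------------------------------------------------------------
def apply_skip_fills(table: pd.DataFrame, recipe: PrepRecipe) -> pd.DataFrame:
    """Fill missing cells of gated dependents with their configured value."""
    out = table.copy()
    for (gate, value), fills in recipe.skip_fills.items():
        if gate not in out.columns:
            raise KeyError(f"gate variable {gate!r} not in table")
        triggered = out[gate] == value
        for dep, fill in fills.items():
            if dep not in out.columns:
                raise KeyError(f"skip-fill dependent {dep!r} not in table")
            mask = triggered & out[dep].isna()
            out.loc[mask, dep] = fill
    return out


def filter_variables(
    table: pd.DataFrame, recipe: PrepRecipe
) -> tuple[list[str], pd.DataFrame]:
    """Select retained variables; returns (retained names, drop report).

    Rules (each strict): missing fraction > max_missing_fraction; mode
    frequency among non-missing > max_mode_fraction (when the mode
    filter is on); excluded types; explicit sex-dependence exclusions;
    then a pairwise-collinearity sweep over the survivors.
    """
    if table.empty:
        raise ValueError("cannot filter an empty table")
    report_rows = []
    retained: list[str] = []
    for name in table.columns:
        series = table[name]
        kind = variable_kind(series, name, recipe)
        reason = None
        if kind == "text" and recipe.drop_free_text:
            reason = "free_text"
        elif kind == "unordered" and recipe.drop_unordered:
            reason = "unordered_categorical"
        elif name in recipe.sex_exclusions:
            reason = "sex_dependent"
        else:
            miss = float(series.isna().mean())
            if miss > recipe.max_missing_fraction:
                reason = "missing_fraction"
            elif recipe.apply_mode_filter:
                non_missing = series.dropna()
                if len(non_missing) > 0:
                    mode_frac = float(non_missing.value_counts(sort=True).iloc[0]) / len(
                        non_missing
                    )
                    if mode_frac > recipe.max_mode_fraction:
                        reason = "mode_fraction"
        report_rows.append({"variable": name, "kind": kind, "dropped": reason or ""})
        if reason is None:
            retained.append(name)

    if recipe.collinearity_threshold is not None and len(retained) > 1:
        stats = fit_impute(table[retained], recipe)
        filled = impute(table[retained], stats)
        enc, _ = encode(filled, recipe)
        corr = enc.corr().abs().to_numpy()
        drop = set()
        names = list(enc.columns)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if names[j] in drop or names[i] in drop:
                    continue
                if corr[i, j] > recipe.collinearity_threshold:
                    drop.add(names[j])
        if drop:
            retained = [n for n in retained if n not in drop]
            for row in report_rows:
                if row["variable"] in drop:
                    row["dropped"] = "collinear"
    return retained, pd.DataFrame(report_rows)


# ----------------------------------------------------------------------
@dataclass
class ImputeStats:
    """Frozen per-variable imputation values computed on training rows."""

    values: dict[str, Any]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values)


def _mode_first_seen(series: pd.Series):
    """Most frequent non-missing level, ties broken by first appearance."""
    best, best_count = None, -1
    counts = series.value_counts(sort=False)
    for level in series.dropna().unique():  # appearance order
        c = int(counts[level])
        if c > best_count:
            best, best_count = level, c
    return best


def fit_impute(table: pd.DataFrame, recipe: PrepRecipe) -> ImputeStats:
    values: dict[str, Any] = {}
    for name in table.columns:
        series = table[name]
        if series.isna().all():
            raise ValueError(
                f"column {name!r} is entirely missing; it should have been filtered"
            )
        if _is_numeric(series):
            values[name] = (
                float(series.median()) if recipe.numeric_impute == "median"
                else float(series.mean())
            )
        else:
            values[name] = _mode_first_seen(series)
    return ImputeStats(values)


def impute(table: pd.DataFrame, stats: ImputeStats) -> pd.DataFrame:
    """Fill missing cells using frozen statistics; row count unchanged."""
    out = table.copy()
    for name in out.columns:
        if name not in stats.values:
            raise KeyError(f"no imputation statistic for column {name!r}")
        out[name] = out[name].fillna(stats.values[name])
    return out


# ----------------------------------------------------------------------
def encode(
    table: pd.DataFrame,
    recipe: PrepRecipe,
    column_map: dict[str, dict] | None = None,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Encode to a numeric matrix: binary -> 0/1, ordinal -> integer
    ranks per recipe ordering, continuous passthrough.

    Returns the matrix and a column map recording each variable's kind
    and level order so the encoding is invertible. Pass a previously
    fitted ``column_map`` to reuse frozen level orders on new rows.
    """
    frozen = column_map or {}
    out = pd.DataFrame(index=table.index)
    column_map = {}
    for name in table.columns:
        series = table[name]
        if _is_numeric(series):
            out[name] = series.astype(float)
            column_map[name] = {"kind": "continuous"}
            continue
        if name in frozen and "levels" in frozen[name]:
            levels = list(frozen[name]["levels"])
        elif name in recipe.ordinal_orderings:
            levels = list(recipe.ordinal_orderings[name])
        else:
            observed = series.dropna().unique().tolist()
            if len(observed) > 2:
                raise ValueError(
                    f"variable {name!r} has >2 levels and no ordinal ordering"
                )
            levels = sorted(observed, key=str)
        unknown = set(series.dropna().unique()) - set(levels)
        if unknown:
            raise ValueError(f"levels {sorted(map(str, unknown))} of {name!r} not in ordering")
        rank = {lvl: i for i, lvl in enumerate(levels)}
        out[name] = series.map(rank).astype(float)
        column_map[name] = {"kind": "ordinal" if len(levels) > 2 else "binary",
                            "levels": levels}
    return out, column_map


def decode(encoded: pd.DataFrame, column_map: dict[str, dict]) -> pd.DataFrame:
    out = pd.DataFrame(index=encoded.index)
    for name in encoded.columns:
        info = column_map[name]
        if info["kind"] == "continuous":
            out[name] = encoded[name]
        else:
            levels = info["levels"]
            out[name] = encoded[name].map(lambda i: levels[int(i)])
    return out


# ----------------------------------------------------------------------
class SurveyPrep:
    """Fitted preprocessing pipeline: skip fills -> variable filter ->
    imputation -> encoding, with all statistics frozen on training rows."""

    def __init__(self, recipe: PrepRecipe):
        self.recipe = recipe
        self.retained_: list[str] | None = None
        self.report_: pd.DataFrame | None = None
        self.stats_: ImputeStats | None = None
        self.column_map_: dict[str, dict] | None = None

    def fit(self, train_table: pd.DataFrame) -> "SurveyPrep":
        filled = apply_skip_fills(train_table, self.recipe)
        self.retained_, self.report_ = filter_variables(filled, self.recipe)
        subset = filled[self.retained_]
        self.stats_ = fit_impute(subset, self.recipe)
        _, self.column_map_ = encode(impute(subset, self.stats_), self.recipe)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.retained_ is None:
            raise RuntimeError("SurveyPrep must be fit before transform")
        filled = apply_skip_fills(table, self.recipe)
        subset = filled[self.retained_]
        completed = impute(subset, self.stats_)
        encoded, _ = encode(completed, self.recipe, column_map=self.column_map_)
        return encoded

    def fit_transform(self, train_table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train_table).transform(train_table)
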