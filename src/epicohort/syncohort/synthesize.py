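"""Sequential per-column table synthesis.

Generates a same-shape synthetic table: the first column is resampled
from its empirical marginal, and each later column is drawn from a
depth-limited decision tree fit on the *original* table's preceding
columns and applied to the already-synthesized columns. Values are
sampled from the empirical distribution within each leaf, so marginals
and within-table dependence are approximately preserved. Because each
table is synthesized independently, any correlation *across* separately
synthesized tables is destroyed. Missingness is modelled explicitly
(as a category for categorical columns, as a per-leaf missingness model
for numeric ones), so "NA" patterns are reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .._seeds import stream

__all__ = ["sequential_synthesize"]

_NA_CODE = -1.0


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)


class _PredictorEncoder:
    """Stable numeric encoding of predictor columns (categories frozen
    on the original table so synthetic values map to the same codes)."""

    def __init__(self, table: pd.DataFrame, columns: list[str]):
        self.columns = columns
        self.categories: dict[str, pd.Index] = {}
        for col in columns:
            if not _is_numeric(table[col]):
                self.categories[col] = pd.Index(
                    pd.unique(table[col].dropna())
                )

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        blocks = []
        for col in self.columns:
            if col in self.categories:
                codes = pd.Categorical(
                    table[col], categories=self.categories[col]
                ).codes.astype(float)
                codes[codes == -1] = np.nan
                # separate channel marks missing so NaN-in-X support is
                # not required for categorical predictors
                blocks.append(np.where(np.isnan(codes), _NA_CODE, codes))
            else:
                blocks.append(table[col].to_numpy(dtype=float))
        return np.column_stack(blocks) if blocks else np.empty((len(table), 0))


def _leaf_sample(tree, x_fit, values, x_apply, rng: np.random.Generator) -> np.ndarray:
    """Draw one value per apply-row from the empirical distribution of
    training values falling in the same leaf."""
    leaves_fit = tree.apply(x_fit)
    leaves_apply = tree.apply(x_apply)
    by_leaf: dict[int, np.ndarray] = {}
    values = np.asarray(values, dtype=object)
    for leaf in np.unique(leaves_fit):
        by_leaf[leaf] = values[leaves_fit == leaf]
    out = np.empty(len(x_apply), dtype=object)
    for leaf in np.unique(leaves_apply):
        pool = by_leaf[leaf]
        rows = np.nonzero(leaves_apply == leaf)[0]
        out[rows] = pool[rng.integers(0, len(pool), size=len(rows))]
    return out


def _fit_sample_categorical(
    y: pd.Series, x_fit: np.ndarray, x_apply: np.ndarray, rng, max_depth: int
) -> pd.Series:
    labels = y.astype(object).where(y.notna(), "__NA__")
    if labels.nunique() == 1 or x_fit.shape[1] == 0:
        sampled = labels.to_numpy(dtype=object)[
            rng.integers(0, len(labels), size=len(x_apply))
        ]
    else:
        tree = DecisionTreeClassifier(
            max_depth=max_depth, min_samples_leaf=5, random_state=int(rng.integers(2**31))
        )
        tree.fit(x_fit, labels)
        sampled = _leaf_sample(tree, x_fit, labels.to_numpy(dtype=object), x_apply, rng)
    out = pd.Series(sampled, dtype=object)
    return out.mask(out == "__NA__", np.nan)


def _fit_sample_numeric(
    y: pd.Series, x_fit: np.ndarray, x_apply: np.ndarray, rng, max_depth: int
) -> pd.Series:
    observed = y.notna().to_numpy()
    n_apply = len(x_apply)
    # model missingness first so NA patterns carry over
    if observed.all():
        is_na = np.zeros(n_apply, dtype=bool)
    elif not observed.any():
        return pd.Series(np.full(n_apply, np.nan))
    else:
        na_tree = DecisionTreeClassifier(
            max_depth=max_depth, min_samples_leaf=5, random_state=int(rng.integers(2**31))
        )
        na_tree.fit(x_fit, ~observed)
        drawn = _leaf_sample(na_tree, x_fit, ~observed, x_apply, rng)
        is_na = drawn.astype(bool)

    if x_fit.shape[1] == 0 or y[observed].nunique() == 1:
        vals = y.dropna().to_numpy(dtype=float)
        sampled = vals[rng.integers(0, len(vals), size=n_apply)]
    else:
        tree = DecisionTreeRegressor(
            max_depth=max_depth, min_samples_leaf=5, random_state=int(rng.integers(2**31))
        )
        tree.fit(x_fit[observed], y.to_numpy(dtype=float)[observed])
        sampled = _leaf_sample(
            tree, x_fit[observed], y.to_numpy(dtype=float)[observed], x_apply, rng
        ).astype(float)
    out = pd.Series(sampled, dtype=float)
    out[is_na] = np.nan
    return out


def sequential_synthesize(
    table: pd.DataFrame, seed: int, max_depth: int = 8
) -> pd.DataFrame:
    """Synthesize a same-shape table column by column.

    Parameters
    ----------
    table
        Original table; at least two rows (a single row cannot support
        model fitting).
    seed
        Master seed; the synthesis stream is derived from it.
    max_depth
        Depth limit for the per-column trees.
    """
    if len(table) < 2:
        raise ValueError("cannot synthesize from a table with fewer than 2 rows")
    rng = stream(seed, "sequential_synthesize")
    columns = list(table.columns)
    synth = pd.DataFrame(index=pd.RangeIndex(len(table)))

    for j, col in enumerate(columns):
        y = table[col].reset_index(drop=True)
        if j == 0:
            sampled = y.to_numpy(dtype=object)[rng.integers(0, len(y), size=len(y))]
            first = pd.Series(sampled, dtype=object)
            synth[col] = first.astype(float) if _is_numeric(y) else first
            continue
        encoder = _PredictorEncoder(table, columns[:j])
        x_fit = encoder.transform(table)
        x_apply = encoder.transform(synth)
        if _is_numeric(y):
            synth[col] = _fit_sample_numeric(y, x_fit, x_apply, rng, max_depth).to_numpy()
        else:
            synth[col] = _fit_sample_categorical(y, x_fit, x_apply, rng, max_depth).to_numpy()

    synth.index = table.index
    return synth
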