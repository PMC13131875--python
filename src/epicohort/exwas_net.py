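"""Exposure-wide association screen and correlation-network feature
selection.

Each exposure is tested in its own logistic regression of the outcome
on that exposure plus covariates. Redundant features are then pruned by
building a graph whose edges link feature pairs with |correlation|
above a threshold and keeping one representative per connected
component: the member with the largest screen odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "run_exwas",
    "FeatureGraph",
    "build_feature_graph",
    "connected_components",
    "select_representatives",
]


def _fit_one(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None) -> dict:
    blocks = [x[:, None]]
    if covariates is not None and covariates.size:
        blocks.append(covariates)
    design = sm.add_constant(np.column_stack(blocks))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation handled below
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        beta = float(fit.params[1])
        p = float(fit.pvalues[1])
        if not fit.mle_retvals.get("converged", True) or abs(beta) > 15:
            # quasi-separation: coefficient diverging
            return {"beta": np.inf * np.sign(beta or 1.0), "p": np.nan, "separation": True}
        return {"beta": beta, "p": p, "separation": False}
    except Exception:
        sign = np.sign(np.corrcoef(x, y)[0, 1]) or 1.0
        return {"beta": np.inf * sign, "p": np.nan, "separation": True}


def run_exwas(
    outcome: pd.Series,
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One logistic fit per feature; Wald p-value for the feature term.

    Rows with a missing value for a given feature are dropped for that
    feature only. Perfectly separating features are flagged (infinite
    effect) rather than raised.
    """
    y_all = outcome.to_numpy(dtype=float)
    if set(np.unique(y_all)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    rows = []
    for name in features.columns:
        x_series = features[name]
        keep = x_series.notna().to_numpy()
        x = x_series.to_numpy(dtype=float)[keep]
        y = y_all[keep]
        cov = None
        if covariates is not None:
            cov = covariates.to_numpy(dtype=float)[keep]
        if np.unique(y).size < 2 or np.unique(x).size < 2:
            rows.append(
                {"variable": name, "beta": np.nan, "odds_ratio": np.nan,
                 "p": np.nan, "n": int(keep.sum()), "separation": False}
            )
            continue
        res = _fit_one(y, x, cov)
        rows.append(
            {
                "variable": name,
                "beta": res["beta"],
                "odds_ratio": float(np.exp(res["beta"])),
                "p": res["p"],
                "n": int(keep.sum()),
                "separation": res["separation"],
            }
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class FeatureGraph:
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["correlation"]) for u, v, d in self.graph.edges(data=True)]

    def to_edge_list(self, path) -> None:
        pd.DataFrame(self.edges(), columns=["u", "v", "correlation"]).to_csv(
            path, sep="\t", index=False
        )

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_feature_graph(
    correlations: pd.DataFrame, threshold: float = 0.6, absolute: bool = True
) -> FeatureGraph:
    """Graph with an edge wherever |r| (or r) strictly exceeds the threshold."""
    values = correlations.to_numpy(dtype=float)
    if correlations.shape[0] != correlations.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(values, values.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(values), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    names = list(correlations.columns)
    g = nx.Graph()
    g.add_nodes_from(names)
    strength = np.abs(values) if absolute else values
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if strength[i, j] > threshold:
                g.add_edge(names[i], names[j], correlation=float(values[i, j]))
    return FeatureGraph(g, threshold)


def connected_components(graph: FeatureGraph) -> list[set[str]]:
    """Maximal connected node sets; isolated nodes come out as singletons.
    Deterministic order: by lexicographically smallest member."""
    comps = [set(c) for c in nx.connected_components(graph.graph)]
    return sorted(comps, key=lambda c: min(c))


def select_representatives(
    components: list[set[str]], exwas: pd.DataFrame
) -> list[str]:
    """One feature per component: maximal odds ratio, ties broken
    lexicographically."""
    out = []
    for comp in components:
        missing = [m for m in comp if m not in exwas.index]
        if missing:
            raise KeyError(f"no screen result for features: {sorted(missing)}")
        best = max(sorted(comp), key=lambda m: (exwas.at[m, "odds_ratio"], ))
        # max() keeps the first (lexicographically smallest) on exact ties
        out.append(best)
    return sorted(out)
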