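"""Composite-based path analysis of microbial control on DOM humification.

The causal structure follows the humification hypothesis: a microbial-community
composite (dominant phylum abundances) acts on protein-like, microbial
humic-like and humic-like DOM composites, which in turn act on the
degree of humification (the fluorescence-intensity ratio of protein-like
to humic-like substances).  Composites are means of z-scored indicators;
each endogenous composite is regressed on its parents by OLS in
topological order, giving standardized path coefficients with classical
standard errors — a composite (PLS-style) approximation to latent-variable
SEM that keeps identical path semantics while remaining fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm


class PathModelError(ValueError):
    pass


@dataclass
class PathSpec:
    """Composite definitions and the directed acyclic path structure.

    ``composites`` maps a composite name to its indicator columns;
    ``paths`` is a list of (from, to) composite pairs; ``ratio_composite``
    optionally names a composite computed as a ratio
    ``sum(numerator indicators) / sum(denominator indicators)`` before
    standardization (used for the humification degree).
    """

    composites: dict[str, list[str]]
    paths: list[tuple[str, str]]
    ratio_composite: dict | None = None

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.paths)
        if not nx.is_directed_acyclic_graph(g):
            raise PathModelError("path structure contains a cycle")
        known = set(self.composites)
        if self.ratio_composite:
            known.add(self.ratio_composite["name"])
        for a, b in self.paths:
            for name in (a, b):
                if name not in known:
                    raise PathModelError(f"path references unknown composite "
                                         f"{name!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PathSpec":
        return cls(composites={k: list(v) for k, v in d["composites"].items()},
                   paths=[tuple(p) for p in d["paths"]],
                   ratio_composite=d.get("ratio_composite"))


def dry_season_spec() -> PathSpec:
    """Dry-season preset: microbes -> protein/microbial-humic/humic ->
    humification ratio."""
    return PathSpec(
        composites={
            "Microbes": ["Proteobacteria", "Actinobacteriota",
                         "Cyanobacteria", "Firmicutes", "Bacteroidota",
                         "Verrucomicrobiota"],
            "Protein": ["D1", "D4", "D5", "D6"],
            "MicrobialHumic": ["D2"],
            "Humic": ["D3"],
        },
        paths=[("Microbes", "Protein"), ("Microbes", "MicrobialHumic"),
               ("Microbes", "Humic"), ("Protein", "MicrobialHumic"),
               ("MicrobialHumic", "Humification"),
               ("Humic", "Humification")],
        ratio_composite={"name": "Humification",
                         "numerator": ["D1", "D4", "D5", "D6"],
                         "denominator": ["D2", "D3"]},
    )


def wet_season_spec() -> PathSpec:
    """Wet-season preset with the W-component blocks."""
    return PathSpec(
        composites={
            "Microbes": ["Proteobacteria", "Actinobacteriota",
                         "Cyanobacteria", "Firmicutes", "Bacteroidota",
                         "Verrucomicrobiota"],
            "Protein": ["W2", "W5", "W6"],
            "MicrobialHumic": ["W1"],
            "Humic": ["W3", "W4"],
        },
        paths=[("Microbes", "Protein"), ("Microbes", "MicrobialHumic"),
               ("Microbes", "Humic"), ("Protein", "Humification"),
               ("MicrobialHumic", "Humification"),
               ("Humic", "Humification")],
        ratio_composite={"name": "Humification",
                         "numerator": ["W2", "W5", "W6"],
                         "denominator": ["W1", "W3", "W4"]},
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise PathModelError("constant indicator cannot be standardized")
    return (x - x.mean()) / sd


def build_composites(tables: pd.DataFrame, spec: PathSpec) -> pd.DataFrame:
    """Sample x composite matrix: mean of z-scored indicators, re-standardized.

    Single-indicator composites equal the indicator's z-score.  A ratio
    composite is computed on the raw indicator scale first, then
    standardized.
    """
    if tables.shape[0] < 5:
        raise PathModelError(f"need >=5 samples, got {tables.shape[0]}")
    out = {}
    for name, indicators in spec.composites.items():
        for ind in indicators:
            if ind not in tables.columns:
                raise PathModelError(f"composite {name!r}: indicator "
                                     f"{ind!r} missing from input")
        z = np.column_stack([_zscore(tables[ind].to_numpy(dtype=float))
                             for ind in indicators])
        out[name] = _zscore(z.mean(axis=1))
    if spec.ratio_composite:
        rc = spec.ratio_composite
        for ind in rc["numerator"] + rc["denominator"]:
            if ind not in tables.columns:
                raise PathModelError(f"ratio composite {rc['name']!r}: "
                                     f"indicator {ind!r} missing")
        num = tables[rc["numerator"]].sum(axis=1).to_numpy(dtype=float)
        den = tables[rc["denominator"]].sum(axis=1).to_numpy(dtype=float)
        if np.any(den == 0):
            raise PathModelError("ratio composite denominator hits zero")
        out[rc["name"]] = _zscore(num / den)
    return pd.DataFrame(out, index=tables.index)


@dataclass
class PathModel:
    """Fitted recursive path model."""

    coefficients: pd.DataFrame   # rows: (from, to, beta, se, p)
    r_squared: dict[str, float]
    n: int

    def coefficient(self, src: str, dst: str) -> float:
        row = self.coefficients[(self.coefficients["from"] == src)
                                & (self.coefficients["to"] == dst)]
        if row.empty:
            raise KeyError(f"no path {src} -> {dst}")
        return float(row["beta"].iloc[0])


def fit_path_model(composites: pd.DataFrame, spec: PathSpec) -> PathModel:
    """OLS regressions of each endogenous composite on its parents.

    Composites are standardized, so the coefficients are standardized
    path coefficients; classical standard errors and two-sided p-values
    are reported, with R^2 per endogenous composite.
    """
    g = nx.DiGraph(spec.paths)
    n = composites.shape[0]
    rows = []
    r2 = {}
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        if n <= len(parents) + 2:
            raise PathModelError(
                f"{node}: n={n} too small for {len(parents)} predictors")
        X = composites[parents].to_numpy(dtype=float)
        if np.linalg.cond(X.T @ X) > 1e8:
            raise PathModelError(f"{node}: collinear parents {parents}")
        y = composites[node].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        for k, parent in enumerate(parents):
            rows.append({"from": parent, "to": node,
                         "beta": float(fit.params[k + 1]),
                         "se": float(fit.bse[k + 1]),
                         "p": float(fit.pvalues[k + 1])})
        r2[node] = float(fit.rsquared)
    return PathModel(
        coefficients=pd.DataFrame(rows,
                                  columns=["from", "to", "beta", "se", "p"]),
        r_squared=r2, n=n)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def export_path_diagram(model: PathModel, name: str = "path_model") -> str:
    """DOT-format diagram with signed, starred coefficients on edges."""
    lines = [f"digraph {name} {{", "  rankdir=LR;"]
    nodes = set()
    for _, row in model.coefficients.iterrows():
        nodes.add(row["from"])
        nodes.add(row["to"])
    for node in sorted(nodes):
        lines.append(f'  "{node}";')
    for _, row in model.coefficients.iterrows():
        label = f"{row['beta']:.2f}{significance_stars(row['p'])}"
        lines.append(f'  "{row["from"]}" -> "{row["to"]}" '
                     f'[label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
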