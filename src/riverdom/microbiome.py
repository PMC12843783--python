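"""OTU-table handling, taxonomy aggregation, alpha diversity and
taxa-DOM correlation summaries.

The microbial counting unit is the OTU (97%-identity sequence cluster);
read processing and clustering are upstream of this package, which starts
from a counts matrix plus ranked lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

RANKS = ["domain", "phylum", "class", "order", "family", "genus"]
_RANK_PREFIX = {"domain": "d__", "phylum": "p__", "class": "c__",
                "order": "o__", "family": "f__", "genus": "g__"}


@dataclass
class OTUTable:
    """OTU x sample integer counts plus per-OTU ranked lineages.

    ``counts`` is a DataFrame indexed by OTU id with sample columns;
    ``lineages`` a Series of semicolon-separated rank strings like
    ``d__Bacteria;p__Proteobacteria;...``, aligned to the same OTU ids.
    """

    counts: pd.DataFrame
    lineages: pd.Series

    def __post_init__(self) -> None:
        if not np.issubdtype(self.counts.to_numpy().dtype, np.number):
            raise ValueError("counts must be numeric")
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        missing = self.counts.index.difference(self.lineages.index)
        if len(missing):
            raise ValueError(f"OTUs without lineage: {list(missing)[:5]}")
        self.counts = self.counts.astype(int)
        self.lineages = self.lineages.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def rank_of(self, otu: str, rank: str) -> str:
        """Taxon name of an OTU at a rank; 'unclassified' when absent."""
        prefix = _RANK_PREFIX[rank]
        for part in str(self.lineages.loc[otu]).split(";"):
            part = part.strip()
            if part.startswith(prefix) and part != prefix:
                return part[len(prefix):]
        return "unclassified"


def read_otu_table(counts_path, taxonomy_path) -> OTUTable:
    """Read OTU counts and taxonomy TSVs (first column = OTU id)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    return OTUTable(counts=counts, lineages=tax.iloc[:, 0])


def aggregate_taxonomy(table: OTUTable, rank: str = "phylum",
                       top_n: int | None = None) -> pd.DataFrame:
    """Relative abundances per taxon at a rank (taxa x samples).

    Counts are summed per taxon, converted to per-sample proportions;
    with ``top_n``, taxa outside the top n by mean abundance are pooled
    as ``"others"``.  Proportions sum to 1 per nonempty sample.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    taxa = pd.Index([table.rank_of(o, rank) for o in table.counts.index],
                    name=rank)
    summed = table.counts.groupby(taxa).sum()
    totals = summed.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"empty sample columns: {list(totals.index[empty])}")
    props = summed.div(totals.where(~empty), axis=1)
    if top_n is not None and top_n < len(props):
        keep = props.mean(axis=1).nlargest(top_n).index
        others = props.drop(index=keep).sum(axis=0)
        props = props.loc[keep]
        props.loc["others"] = others
    return props


def shannon_index(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (nats) over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1_index(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


@dataclass
class DiversityProfile:
    """Per-sample alpha diversity: Shannon (nats), Chao1, observed OTUs."""

    shannon: pd.Series
    chao1: pd.Series
    observed: pd.Series


def alpha_diversity(table: OTUTable) -> DiversityProfile:
    arr = table.counts.to_numpy()
    samples = table.samples
    return DiversityProfile(
        shannon=pd.Series([shannon_index(arr[:, j]) for j in range(arr.shape[1])],
                          index=samples, name="shannon"),
        chao1=pd.Series([chao1_index(arr[:, j]) for j in range(arr.shape[1])],
                        index=samples, name="chao1"),
        observed=pd.Series((arr > 0).sum(axis=0), index=samples,
                           name="observed"),
    )


def rarefaction(table: OTUTable, depths: list[int], reps: int = 10,
                seed: int = 0) -> pd.DataFrame:
    """Mean observed OTU richness at each subsampling depth.

    Subsampling is without replacement; depths beyond a sample's total
    are omitted for that sample with a warning.  Returns a depth x sample
    DataFrame of means over ``reps`` draws.
    """
    rng = np.random.default_rng(seed)
    arr = table.counts.to_numpy()
    out = pd.DataFrame(index=pd.Index(sorted(depths), name="depth"),
                       columns=table.samples, dtype=float)
    for j, sample in enumerate(table.samples):
        col = arr[:, j]
        total = int(col.sum())
        pool = np.repeat(np.arange(col.size), col)
        for depth in out.index:
            if depth > total:
                warnings.warn(
                    f"depth {depth} exceeds total {total} for {sample}; "
                    "point omitted")
                continue
            obs = [
                np.unique(rng.choice(pool, size=depth, replace=False)).size
                for _ in range(reps)
            ]
            out.loc[depth, sample] = float(np.mean(obs))
    return out


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! orderings of one variable (Pearson on ranks, so
    ties are handled), counting permutations with |rho| at least the
    observed value.  Feasible for n <= 8.
    """
    from itertools import permutations

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    rx = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
    ry = (ry - ry.mean()) / np.sqrt(((ry - ry.mean()) ** 2).sum())
    rho = float(rx @ ry)
    perms = np.array(list(permutations(range(n))))
    dist = ry[perms] @ rx
    p = float(np.mean(np.abs(dist) >= abs(rho) - 1e-12))
    return rho, p


def correlate_taxa_components(taxa: pd.DataFrame, components: pd.DataFrame,
                              method: str = "spearman",
                              adjust: bool = True,
                              exact_max_n: int = 8) -> pd.DataFrame:
    """Taxon x component correlation table with significance stars.

    ``taxa`` is taxa x samples relative abundance; ``components`` is
    sample x component (e.g. Fmax).  Returns long-format rows
    (taxon, component, rho, p, stars[, p_adj]); pairs with a constant
    vector are reported with missing rho/p.  For Spearman with at most
    ``exact_max_n`` samples the p-value is an exact permutation p.  Stars follow raw p
    (* p<0.05, ** p<0.01); the Benjamini-Hochberg column is a
    side-channel, not used for the stars.
    """
    shared = [s for s in taxa.columns if s in components.index]
    if len(shared) < 4:
        raise ValueError(f"need >=4 shared samples, got {len(shared)}")
    rows = []
    for taxon in taxa.index:
        x = taxa.loc[taxon, shared].to_numpy(dtype=float)
        for comp in components.columns:
            y = components.loc[shared, comp].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append((taxon, comp, np.nan, np.nan, ""))
                continue
            if method == "spearman":
                if len(shared) <= exact_max_n:
                    rho, p = spearman_exact(x, y)
                else:
                    rho, p = stats.spearmanr(x, y)
            elif method == "pearson":
                rho, p = stats.pearsonr(x, y)
            else:
                raise ValueError(f"unknown method {method!r}")
            stars = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            rows.append((taxon, comp, float(rho), float(p), stars))
    out = pd.DataFrame(rows, columns=["taxon", "component", "rho", "p",
                                      "stars"])
    if adjust:
        from statsmodels.stats.multitest import multipletests
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
    return out
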