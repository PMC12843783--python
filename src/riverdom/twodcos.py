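"""Two-dimensional correlation spectroscopy (2D-COS) and sequential-order
inference by Noda's rules.

Given band signals measured along an ordered perturbation series (here
typically PARAFAC component Fmax along a site or chemistry gradient),
the synchronous map Phi captures in-phase covariation and the
asynchronous map Psi (via the Hilbert-Noda transform) captures the lag
between band responses.  Noda's sign rules on (Phi, Psi) pairs give the
order in which bands respond to the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class TwoDCosError(ValueError):
    pass


@dataclass
class PerturbationSeries:
    """Band signals along an ordered perturbation.

    ``order_values`` defines the sample ordering (ties broken by sample
    id); ``bands`` is a sample x band DataFrame of signals.
    """

    bands: pd.DataFrame
    order_values: pd.Series | None = None
    order_name: str = "sample order"

    def sorted_bands(self) -> pd.DataFrame:
        if self.bands.shape[0] < 3:
            raise TwoDCosError("need at least 3 samples in the series")
        if self.order_values is None:
            return self.bands
        ov = self.order_values.loc[self.bands.index]
        order = sorted(self.bands.index, key=lambda s: (ov.loc[s], str(s)))
        return self.bands.loc[order]


@dataclass
class CorrelationMaps:
    """Synchronous (Phi) and asynchronous (Psi) band x band maps."""

    phi: pd.DataFrame
    psi: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    order_name: str = "sample order"

    @property
    def band_labels(self) -> list[str]:
        return list(self.phi.index)


def hilbert_noda(m: int) -> np.ndarray:
    """Hilbert-Noda transform matrix: N[j, k] = 1 / (pi (k - j)), 0 on the
    diagonal."""
    if m < 2:
        raise TwoDCosError("Hilbert-Noda matrix needs m >= 2")
    j = np.arange(m)
    diff = j[None, :] - j[:, None]
    with np.errstate(divide="ignore"):
        N = 1.0 / (np.pi * diff)
    N[diff == 0] = 0.0
    return N


def compute_2dcos(series: PerturbationSeries) -> CorrelationMaps:
    """Synchronous and asynchronous correlation maps of a series.

    With the dynamic matrix Y (band signals minus their series mean),
    ``Phi = Y'Y / (m - 1)`` and ``Psi = Y' N Y / (m - 1)`` where N is
    the Hilbert-Noda matrix.  Constant bands are excluded from the
    sequencing step and reported in ``excluded``.
    """
    bands = series.sorted_bands()
    m = bands.shape[0]
    Y = bands.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    constant = [lab for lab, col in zip(bands.columns, Y.T)
                if np.allclose(col, 0.0)]
    N = hilbert_noda(m)
    phi = Y.T @ Y / (m - 1)
    psi = Y.T @ N @ Y / (m - 1)
    labels = list(bands.columns)
    return CorrelationMaps(
        phi=pd.DataFrame(phi, index=labels, columns=labels),
        psi=pd.DataFrame(psi, index=labels, columns=labels),
        excluded=constant, order_name=series.order_name)


def pairwise_precedence(phi: float, psi: float,
                        zero_level: float) -> int:
    """Noda's rule for one band pair.

    Returns +1 if band 1 responds before band 2, -1 for after, and 0
    for simultaneous (|Psi| at or below the zero level).  A negative
    synchronous correlation reverses the asynchronous interpretation.
    """
    if abs(psi) <= zero_level:
        return 0
    first = psi > 0
    if phi < 0:
        first = not first
    return 1 if first else -1


def sequential_order(maps: CorrelationMaps,
                     zero_tol: float = 0.05) -> dict:
    """Aggregate pairwise Noda precedences into an ordered sequence.

    Each unordered pair votes via :func:`pairwise_precedence`; bands are
    ranked by descending Copeland score (wins minus losses), ties grouped
    as simultaneous.  Cyclic precedences are flagged.  Returns a dict
    with ``groups`` (ordered lists of simultaneous bands), ``sequence``
    (flat order), ``pairs`` (the pairwise table) and ``has_cycle``.
    """
    labels = [b for b in maps.band_labels if b not in maps.excluded]
    if len(labels) < 2:
        raise TwoDCosError("need at least 2 non-constant bands to sequence")
    psi_abs_max = float(np.abs(maps.psi.loc[labels, labels].to_numpy()).max())
    phi_scale = float(np.abs(maps.phi.loc[labels, labels].to_numpy()).max())
    # numerical floor: a Psi that is zero up to roundoff carries no order
    zero_level = zero_tol * psi_abs_max + 1e-12 * max(phi_scale, 1.0)
    score = {b: 0 for b in labels}
    pairs = []
    beats: dict[str, set[str]] = {b: set() for b in labels}
    for i, b1 in enumerate(labels):
        for b2 in labels[i + 1:]:
            phi = float(maps.phi.loc[b1, b2])
            psi = float(maps.psi.loc[b1, b2])
            rel = pairwise_precedence(phi, psi, zero_level)
            pairs.append({"band1": b1, "band2": b2, "phi": phi, "psi": psi,
                          "precedence": rel})
            if rel == 1:
                score[b1] += 1
                score[b2] -= 1
                beats[b1].add(b2)
            elif rel == -1:
                score[b1] -= 1
                score[b2] += 1
                beats[b2].add(b1)
    ordered = sorted(labels, key=lambda b: (-score[b], str(b)))
    groups: list[list[str]] = []
    for b in ordered:
        if groups and score[groups[-1][0]] == score[b]:
            groups[-1].append(b)
        else:
            groups.append([b])
    import networkx as nx
    dg = nx.DiGraph()
    dg.add_nodes_from(labels)
    for b, succ in beats.items():
        for s in succ:
            dg.add_edge(b, s)
    has_cycle = not nx.is_directed_acyclic_graph(dg)
    return {"groups": groups, "sequence": ordered, "pairs": pairs,
            "scores": score, "has_cycle": has_cycle,
            "order_variable": maps.order_name, "excluded": maps.excluded}
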