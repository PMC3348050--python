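"""Effect radius of a drug combination over the genetic interaction network.

The distance between two drugs i and j is the minimum, over target pairs
(t_i, t_j), of the unweighted shortest-path hop distance between t_i and t_j
in the genetic interaction network. The effect radius R of a combination is
the mean drug-drug distance over its unordered member pairs D:

    R = sum_{(i,j) in D} dis(i, j) / |D|

restricted to pairs whose distance is defined: pairs with no connecting path
are excluded from both numerator and denominator (their count is reported so
the alternative — imputing a large constant — can be audited). R is UNDEFINED
when no member pair is reachable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_ingest import CombinationRecord, DrugRecord

logger = logging.getLogger(__name__)

#: Sentinel for gene/drug pairs with no connecting path (compares as +inf).
UNREACHABLE = math.inf

#: Default boundary between "small" and "large" effect radius strata.
DEFAULT_RADIUS_THRESHOLD = 3.0


class DistanceIndex:
    """Lazy all-pairs shortest-path oracle over an undirected gene network.

    Distances are unweighted hop counts. A breadth-first search is run from a
    query gene the first time it is used as a source and cached; the contract
    is the distance mapping, not the computation order. ``dist(g, g) = 0``
    for any gene, including genes absent from the network; distinct genes in
    different components (or absent from the network) are UNREACHABLE.
    """

    def __init__(self, network: nx.Graph):
        self._graph = network
        self._cache: dict[str, dict[str, int]] = {}

    @property
    def network(self) -> nx.Graph:
        return self._graph

    def _lengths_from(self, source: str) -> dict[str, int]:
        lengths = self._cache.get(source)
        if lengths is None:
            lengths = dict(nx.single_source_shortest_path_length(self._graph, source))
            self._cache[source] = lengths
        return lengths

    def distance(self, a: str, b: str) -> float:
        if a == b:
            return 0
        if a not in self._graph or b not in self._graph:
            return UNREACHABLE
        if b in self._cache and a not in self._cache:
            a, b = b, a
        return self._lengths_from(a).get(b, UNREACHABLE)


def shortest_path_distance(index: DistanceIndex, a: str, b: str) -> float:
    """Hop distance between genes ``a`` and ``b`` (UNREACHABLE across components)."""
    return index.distance(a, b)


def drug_distance(index: DistanceIndex, drug_i: DrugRecord, drug_j: DrugRecord) -> float:
    """Minimum target-to-target hop distance between two drugs.

    UNREACHABLE iff every target pair is unreachable. Raises on empty target
    sets, which the upstream annotation filter should have removed.
    """
    if not drug_i.targets or not drug_j.targets:
        raise ValueError(
            f"drug_distance requires non-empty target sets "
            f"({drug_i.drug_id!r}, {drug_j.drug_id!r})"
        )
    return min(
        index.distance(ti, tj) for ti in drug_i.targets for tj in drug_j.targets
    )


@dataclass
class RadiusResult:
    """Per-combination effect radius plus pair bookkeeping."""

    combo_id: str
    radius: float | None  # None = UNDEFINED (no reachable member pair)
    n_pairs_used: int
    n_pairs_unreachable: int

    @property
    def defined(self) -> bool:
        return self.radius is not None


def effect_radius(
    index: DistanceIndex,
    combo: CombinationRecord,
    drugs: Mapping[str, DrugRecord],
) -> RadiusResult:
    """Effect radius of one combination: mean drug-drug distance over D.

    D is the set of all C(k,2) unordered member pairs. Pairs with UNREACHABLE
    distance are excluded from the mean and counted separately; the radius is
    UNDEFINED (None) when every pair is unreachable.
    """
    distances = [
        drug_distance(index, drugs[i], drugs[j]) for i, j in combo.member_pairs()
    ]
    used = [d for d in distances if d != UNREACHABLE]
    radius = sum(used) / len(used) if used else None
    return RadiusResult(
        combo_id=combo.combo_id,
        radius=radius,
        n_pairs_used=len(used),
        n_pairs_unreachable=len(distances) - len(used),
    )


def radius_distribution(
    results: Iterable[RadiusResult], bin_edges: list[float]
) -> dict[str, float]:
    """Proportion of combinations per radius bin.

    ``bin_edges = [e1 < e2 < ...]`` defines bins (-inf, e1], (e1, e2], ...,
    (e_last, inf), labelled "<=e1", "(e1,e2]", ">e_last". UNDEFINED radii are
    excluded with a logged count; all-UNDEFINED input is an error. The
    returned proportions sum to 1.
    """
    edges = list(bin_edges)
    if not edges or sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin_edges must be non-empty and strictly increasing")
    results = list(results)
    defined = [r for r in results if r.defined]
    n_undefined = len(results) - len(defined)
    if n_undefined:
        logger.info("radius_distribution: excluded %d UNDEFINED radii", n_undefined)
    if not defined:
        raise ValueError("radius_distribution: every radius is UNDEFINED")
    labels = (
        [f"<={edges[0]:g}"]
        + [f"({lo:g},{hi:g}]" for lo, hi in zip(edges, edges[1:])]
        + [f">{edges[-1]:g}"]
    )
    counts = [0] * (len(edges) + 1)
    for res in defined:
        k = 0
        while k < len(edges) and res.radius > edges[k]:
            k += 1
        counts[k] += 1
    total = len(defined)
    return {label: count / total for label, count in zip(labels, counts)}


def stratify_by_radius(
    results: Iterable[RadiusResult], threshold: float = DEFAULT_RADIUS_THRESHOLD
) -> tuple[set[str], set[str]]:
    """Partition defined-radius combinations into (R <= t) and (R > t) sets.

    The boundary is inclusive on the left: a radius exactly at the threshold
    lands in the small-radius stratum. UNDEFINED radii belong to neither.
    """
    small = {r.combo_id for r in results if r.defined and r.radius <= threshold}
    large = {r.combo_id for r in results if r.defined and r.radius > threshold}
    return small, large


def write_radius_table(results: Iterable[RadiusResult], path: str | Path) -> None:
    """Write per-combination radii as TSV (UNDEFINED rendered as NA)."""
    frame = pd.DataFrame(
        [
            {
                "combo_id": r.combo_id,
                "radius": r.radius,
                "n_pairs_used": r.n_pairs_used,
                "n_pairs_unreachable": r.n_pairs_unreachable,
            }
            for r in sorted(results, key=lambda r: r.combo_id)
        ]
    )
    frame.to_csv(Path(path), sep="\t", index=False, na_rep="NA")
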