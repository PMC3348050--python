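"""Drug cocktail network and the degree-preserving null ensemble.

The cocktail network has drugs as nodes and an edge between every pair of
drugs that appear together in an effective combination (a k-drug combination
contributes all C(k,2) pairs). Random combinations are generated by
double-edge swaps that preserve every node's degree; each shuffled edge is
then re-interpreted as a pairwise "random combination" for downstream
effect-radius and pathway-profile scoring.
"""

from __future__ import annotations

import csv
import json
import logging
import random
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .io_ingest import CombinationRecord

logger = logging.getLogger(__name__)

#: Default attempted swaps per edge in one shuffle pass.
DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class NullEnsemble:
    """An ordered collection of degree-preserving shuffles of one network."""

    replicates: list[nx.Graph]
    seed: int
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def build_cocktail_network(combos: list[CombinationRecord] | tuple) -> nx.Graph:
    """Build the drug cocktail network from filtered combinations.

    Node set: union of member drugs. Edge set: union over combinations of all
    unordered member pairs; repeated pairs collapse to one edge.
    """
    net = nx.Graph()
    for combo in combos:
        net.add_nodes_from(combo.members)
        net.add_edges_from(combo.member_pairs())
    logger.info(
        "cocktail network: %d drugs, %d edges from %d combinations",
        net.number_of_nodes(),
        net.number_of_edges(),
        len(list(combos)),
    )
    return net


def _edge_key(u, v) -> tuple:
    return (u, v) if u <= v else (v, u)


def shuffle_preserving_degree(
    net: nx.Graph, seed: int, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE
) -> nx.Graph:
    """Randomize edges by double-edge swaps, preserving every node's degree.

    Repeatedly picks two distinct edges (u,v), (x,y) and rewires them to
    (u,x), (v,y) when the result is still a simple graph (no self-loop, no
    multi-edge); rejected proposals count against the attempt budget of
    ``n_swaps_per_edge * |E|``. Deterministic given ``seed``. If not one
    proposal succeeds within the budget (e.g. a star, whose degree sequence
    admits a unique simple graph), the input is returned unchanged with a
    warning.
    """
    out = net.copy()
    n_edges = out.number_of_edges()
    if n_edges < 2:
        logger.warning(
            "shuffle_preserving_degree: network has %d edge(s); nothing to swap",
            n_edges,
        )
        return out
    rng = random.Random(seed)
    edges = sorted(_edge_key(u, v) for u, v in out.edges())
    edge_set = set(edges)
    budget = n_swaps_per_edge * n_edges
    successes = 0
    for _ in range(budget):
        i = rng.randrange(n_edges)
        j = rng.randrange(n_edges)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:  # random orientation of the second edge
            x, y = y, x
        # proposed rewiring: (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue  # would create a self-loop
        new_a, new_b = _edge_key(u, x), _edge_key(v, y)
        if new_a in edge_set or new_b in edge_set:
            continue  # would create a multi-edge
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(new_a)
        edge_set.add(new_b)
        edges[i], edges[j] = new_a, new_b
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(*new_a)
        out.add_edge(*new_b)
        successes += 1
    if successes == 0:
        logger.warning(
            "shuffle_preserving_degree: no valid swap found in %d attempts; "
            "returning the input unchanged",
            budget,
        )
    return out


def generate_null_ensemble(
    net: nx.Graph,
    n_replicates: int,
    seed: int,
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> NullEnsemble:
    """Generate ``n_replicates`` independent degree-preserving shuffles.

    Replicate ``r`` is shuffled with derived seed ``seed + r`` so the whole
    ensemble is reproducible from one master seed.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    replicates = [
        shuffle_preserving_degree(net, seed + r, n_swaps_per_edge)
        for r in range(n_replicates)
    ]
    return NullEnsemble(replicates, seed=seed, n_swaps_per_edge=n_swaps_per_edge)


def null_edges_as_combinations(ens: NullEnsemble) -> list[list[CombinationRecord]]:
    """Re-interpret each replicate's edges as pairwise random combinations."""
    per_replicate: list[list[CombinationRecord]] = []
    for r, replicate in enumerate(ens.replicates):
        combos = [
            CombinationRecord(f"null-r{r:04d}-e{k:05d}", frozenset((u, v)))
            for k, (u, v) in enumerate(sorted(_edge_key(u, v) for u, v in replicate.edges()))
        ]
        per_replicate.append(combos)
    return per_replicate


def save_ensemble(ens: NullEnsemble, directory: str | Path) -> None:
    """Persist an ensemble as per-replicate edge-list TSVs plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r, replicate in enumerate(ens.replicates):
        with (directory / f"replicate_{r:04d}.tsv").open(
            "w", encoding="utf-8", newline=""
        ) as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["drug_a", "drug_b"])
            for u, v in sorted(_edge_key(u, v) for u, v in replicate.edges()):
                writer.writerow([u, v])
    nodes = sorted(ens.replicates[0].nodes()) if ens.replicates else []
    manifest = {
        "seed": ens.seed,
        "n_replicates": ens.n_replicates,
        "n_swaps_per_edge": ens.n_swaps_per_edge,
        "nodes": nodes,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n", encoding="utf-8"
    )


def load_ensemble(directory: str | Path) -> NullEnsemble:
    """Load an ensemble previously written by :func:`save_ensemble`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text(encoding="utf-8"))
    replicates = []
    for r in range(manifest["n_replicates"]):
        net = nx.Graph()
        net.add_nodes_from(manifest["nodes"])
        with (directory / f"replicate_{r:04d}.tsv").open(
            "r", encoding="utf-8", newline=""
        ) as handle:
            reader = csv.reader(handle, delimiter="\t")
            next(reader)  # header
            for u, v in reader:
                net.add_edge(u, v)
        replicates.append(net)
    return NullEnsemble(
        replicates,
        seed=manifest["seed"],
        n_swaps_per_edge=manifest["n_swaps_per_edge"],
    )
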