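"""Pathway-pair classification for drug combinations.

Each drug is associated with the pathways containing at least one of its
target genes. For every pair of member drugs in a combination, every
(pathway of A) x (pathway of B) pair is classified into exactly one of four
relations:

* IDENTICAL      — same pathway identifier;
* CROSS_TALKING  — distinct pathways sharing at least one gene;
* INTERACTING    — disjoint gene sets bridged by at least one
                   genetic-interaction edge;
* PARALLEL       — neither shared genes nor bridging interactions.

Precedence is IDENTICAL > CROSS_TALKING > INTERACTING > PARALLEL: a pair that
both shares a gene and has bridging edges counts as cross-talking, since a
shared gene is the stronger, containment-like relation. Identity is decided
by pathway identifier, so two differently named pathways with equal gene
sets are cross-talking, not identical. The per-combination proportions of
the four relations form the combination's pathway profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_ingest import CombinationRecord, DrugRecord, PathwayGeneSet

logger = logging.getLogger(__name__)

#: Default selection threshold on the interacting-pair proportion (strict >).
DEFAULT_INTERACTING_THRESHOLD = 0.4


class PathwayPairRelation(str, Enum):
    IDENTICAL = "identical"
    CROSS_TALKING = "cross_talking"
    INTERACTING = "interacting"
    PARALLEL = "parallel"


def _as_mapping(
    pathways: Iterable[PathwayGeneSet] | Mapping[str, PathwayGeneSet],
) -> Mapping[str, PathwayGeneSet]:
    if isinstance(pathways, Mapping):
        return pathways
    return {p.pathway_id: p for p in pathways}


def drug_pathways(
    drug: DrugRecord,
    pathways: Iterable[PathwayGeneSet] | Mapping[str, PathwayGeneSet],
) -> set[str]:
    """Identifiers of pathways whose gene set intersects the drug's targets."""
    mapping = _as_mapping(pathways)
    return {
        pid for pid, pw in mapping.items() if pw.genes & drug.targets
    }


def classify_pathway_pair(
    pa: PathwayGeneSet, pb: PathwayGeneSet, net: nx.Graph
) -> PathwayPairRelation:
    """Classify one pathway pair against the genetic interaction network."""
    if pa.pathway_id == pb.pathway_id:
        return PathwayPairRelation.IDENTICAL
    if pa.genes & pb.genes:
        return PathwayPairRelation.CROSS_TALKING
    small, large = sorted((pa.genes, pb.genes), key=len)
    for gene in small:
        if gene in net and not net.adj[gene].keys().isdisjoint(large):
            return PathwayPairRelation.INTERACTING
    return PathwayPairRelation.PARALLEL


class PathwayPairClassifier:
    """Memoizing wrapper around :func:`classify_pathway_pair`.

    Shares one classification cache across all combinations scored against
    the same pathway collection and interaction network.
    """

    def __init__(
        self,
        pathways: Iterable[PathwayGeneSet] | Mapping[str, PathwayGeneSet],
        net: nx.Graph,
    ):
        self.pathways = _as_mapping(pathways)
        self.net = net
        self._cache: dict[frozenset[str], PathwayPairRelation] = {}
        self._drug_cache: dict[str, set[str]] = {}

    def classify(self, pathway_a: str, pathway_b: str) -> PathwayPairRelation:
        key = frozenset((pathway_a, pathway_b))
        relation = self._cache.get(key)
        if relation is None:
            relation = classify_pathway_pair(
                self.pathways[pathway_a], self.pathways[pathway_b], self.net
            )
            self._cache[key] = relation
        return relation

    def pathways_of(self, drug: DrugRecord) -> set[str]:
        cached = self._drug_cache.get(drug.drug_id)
        if cached is None:
            cached = drug_pathways(drug, self.pathways)
            self._drug_cache[drug.drug_id] = cached
        return cached


@dataclass
class PathwayProfile:
    """Per-combination counts and proportions of the four pair relations."""

    combo_id: str
    counts: dict[PathwayPairRelation, int]

    @property
    def n_pairs(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[PathwayPairRelation, float]:
        total = self.n_pairs
        if total == 0:
            return {}
        return {rel: count / total for rel, count in self.counts.items()}

    def proportion(self, relation: PathwayPairRelation) -> float:
        return self.proportions.get(relation, 0.0)


def combination_profile(
    combo: CombinationRecord,
    drugs: Mapping[str, DrugRecord],
    pathways: Iterable[PathwayGeneSet] | Mapping[str, PathwayGeneSet],
    net: nx.Graph,
    classifier: PathwayPairClassifier | None = None,
) -> PathwayProfile:
    """Pathway profile of one combination.

    For every unordered member-drug pair and every (pathway of A) x
    (pathway of B) pair, classify and count; proportions normalize the
    counts. A member drug with no associated pathway contributes no pairs;
    a combination with zero pairs overall yields an empty profile and is
    logged as skipped.
    """
    if classifier is None:
        classifier = PathwayPairClassifier(pathways, net)
    counts: dict[PathwayPairRelation, int] = {rel: 0 for rel in PathwayPairRelation}
    member_pathways = {
        member: classifier.pathways_of(drugs[member]) for member in combo.members
    }
    for drug_a, drug_b in combo.member_pairs():
        for pid_a in member_pathways[drug_a]:
            for pid_b in member_pathways[drug_b]:
                counts[classifier.classify(pid_a, pid_b)] += 1
    profile = PathwayProfile(combo.combo_id, counts)
    if profile.n_pairs == 0:
        logger.info(
            "combination %s: no pathway pairs (a member targets no pathway); "
            "profile left empty",
            combo.combo_id,
        )
    return profile


def select_interacting_targeters(
    profiles: Iterable[PathwayProfile],
    threshold: float = DEFAULT_INTERACTING_THRESHOLD,
) -> set[str]:
    """Combinations whose INTERACTING proportion strictly exceeds ``threshold``.

    The comparison is strict: a proportion exactly at the threshold is
    excluded. Empty profiles (no pathway pairs) are never selected.
    """
    return {
        p.combo_id
        for p in profiles
        if p.proportion(PathwayPairRelation.INTERACTING) > threshold
    }


def write_profiles(profiles: Iterable[PathwayProfile], path: str | Path) -> None:
    """Write profiles as TSV: combo_id, n_pairs, count+proportion per relation."""
    rows = []
    for profile in sorted(profiles, key=lambda p: p.combo_id):
        row: dict[str, object] = {"combo_id": profile.combo_id, "n_pairs": profile.n_pairs}
        for rel in PathwayPairRelation:
            row[f"n_{rel.value}"] = profile.counts.get(rel, 0)
            row[f"prop_{rel.value}"] = profile.proportion(rel)
        rows.append(row)
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
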