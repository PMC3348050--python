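"""Synthetic input bundles with planted structure.

The generator emulates the shape of the real inputs — a sparse gene-gene
interaction network, pathway gene sets with tunable overlap, drugs with a
handful of targets, ATC codes drawn from the 14 real level-1 classes, and a
combination list — and plants the two effects the analysis is designed to
detect:

* with probability ``planted_radius_bias`` a true combination's two drugs
  receive targets within ``d_plant`` hops of each other, so true
  combinations have systematically shorter effect radii than degree-matched
  random pairs;
* with probability ``planted_crosstalk_bias`` the partners receive targets
  in a pathway pair bridged by a genetic-interaction edge (falling back to a
  gene-sharing pair when the network has no bridged pair), raising the
  interacting/cross-talking proportions of true combinations.

Decoy interaction rows at or above the p-value threshold and a configurable
fraction of drugs stripped of targets or ATC codes are included deliberately
to exercise the strict ingestion filters. All outputs are written in the
ingestion module's TSV/GMT dialects and are byte-identical for a fixed seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io_ingest import (
    CombinationRecord,
    DrugRecord,
    PathwayGeneSet,
    write_combinations,
    write_drug_atc,
    write_drug_targets,
    write_pathways,
)
from .pathway_relations import PathwayPairRelation, classify_pathway_pair

logger = logging.getLogger(__name__)

#: The 14 anatomical main groups of the ATC classification.
ATC_LEVEL1_LETTERS = "ABCDGHJLMNPRSV"


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic bundle generator.

    Defaults describe the standard benchmark condition: a 400-gene
    interaction network at mean degree 3, 40 pathways of 5-15 genes with
    modest pairwise overlap (roughly a fifth of pathway pairs share a gene,
    comparable to curated pathway collections), 150 drugs with 1-5 targets,
    and 100 true combinations planted at radius <= 1 with probability 0.8
    and at edge-bridged pathway pairs with probability 0.8.
    """

    n_genes: int = 400
    interaction_density: float = 3.0  # expected interaction edges per gene
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (5, 15)
    pathway_overlap_prob: float = 0.2
    n_drugs: int = 150
    targets_per_drug_range: tuple[int, int] = (1, 5)
    n_true_combos: int = 100
    planted_radius_bias: float = 0.8
    d_plant: int = 1
    planted_crosstalk_bias: float = 0.8
    seed: int = 42
    p_threshold: float = 1.0e-7
    decoy_fraction: float = 0.1  # decoy rows at/above threshold, per kept edge
    unannotated_fraction: float = 0.1  # drugs stripped of targets or ATC
    network_model: str = "erdos_renyi"  # or "preferential_attachment"

    def validate(self) -> None:
        for name in ("n_genes", "n_pathways", "n_drugs", "n_true_combos"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "pathway_overlap_prob",
            "planted_radius_bias",
            "planted_crosstalk_bias",
            "decoy_fraction",
            "unannotated_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("pathway_size_range", "targets_per_drug_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.pathway_size_range[1] > self.n_genes:
            raise ValueError("pathway sizes exceed the number of genes")
        if self.targets_per_drug_range[1] > self.n_genes:
            raise ValueError("target counts exceed the number of genes")
        if self.n_drugs < 2:
            raise ValueError("need at least 2 drugs to form combinations")
        max_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_true_combos > max_pairs:
            raise ValueError("n_true_combos exceeds the number of drug pairs")
        if self.d_plant < 0:
            raise ValueError("d_plant must be >= 0")
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.network_model not in ("erdos_renyi", "preferential_attachment"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if self.interaction_density <= 0:
            raise ValueError("interaction_density must be positive")


@dataclass
class SyntheticBundle:
    """File paths of one generated bundle plus its manifest."""

    interactions: Path
    targets: Path
    atc: Path
    combinations: Path
    pathways: Path
    manifest_path: Path
    manifest: dict = field(default_factory=dict)


def _interaction_graph(cfg: GeneratorConfig, rng: np.random.Generator) -> nx.Graph:
    graph_seed = int(rng.integers(2**31))
    if cfg.network_model == "erdos_renyi":
        p_edge = min(1.0, cfg.interaction_density / max(1, cfg.n_genes - 1))
        raw = nx.fast_gnp_random_graph(cfg.n_genes, p_edge, seed=graph_seed)
    else:
        m = max(1, round(cfg.interaction_density / 2))
        raw = nx.barabasi_albert_graph(cfg.n_genes, m, seed=graph_seed)
    return nx.relabel_nodes(raw, {i: f"g{i:04d}" for i in raw.nodes()})


def _sample_pathways(
    cfg: GeneratorConfig, genes: list[str], rng: np.random.Generator
) -> list[PathwayGeneSet]:
    pathways: list[PathwayGeneSet] = []
    assigned: list[str] = []  # genes already used by some pathway, with repeats
    lo, hi = cfg.pathway_size_range
    for k in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        attempts = 0
        while len(members) < size and attempts < 50 * size:
            attempts += 1
            if assigned and rng.random() < cfg.pathway_overlap_prob:
                gene = assigned[int(rng.integers(len(assigned)))]
            else:
                gene = genes[int(rng.integers(len(genes)))]
            members.add(gene)
        pathways.append(PathwayGeneSet(f"P{k:03d}", members))
        assigned.extend(sorted(members))
    return pathways


def _random_atc_code(rng: np.random.Generator) -> str:
    letter = ATC_LEVEL1_LETTERS[int(rng.integers(len(ATC_LEVEL1_LETTERS)))]
    upper = "".join(
        chr(ord("A") + int(rng.integers(26))) for _ in range(2)
    )
    return f"{letter}{int(rng.integers(100)):02d}{upper}{int(rng.integers(100)):02d}"


def _bridged_pathway_pairs(
    pathways: list[PathwayGeneSet], net: nx.Graph
) -> tuple[list[tuple[str, str]], list[tuple[int, int]]]:
    """Planting material for related pathway pairs.

    Returns ``(bridging_edges, crosstalking_pairs)``: one bridging
    genetic-interaction edge (x, y) per INTERACTING (edge-bridged, disjoint)
    pathway pair, and the index pairs of CROSS_TALKING (gene-sharing) pairs
    as a fallback for networks without any bridged pair.
    """
    bridging_edges: list[tuple[str, str]] = []
    crosstalking: list[tuple[int, int]] = []
    for i, j in itertools.combinations(range(len(pathways)), 2):
        relation = classify_pathway_pair(pathways[i], pathways[j], net)
        if relation is PathwayPairRelation.INTERACTING:
            for gene in sorted(pathways[i].genes):
                if gene not in net:
                    continue
                partners = sorted(set(net.adj[gene]) & pathways[j].genes)
                if partners:
                    bridging_edges.append((gene, partners[0]))
                    break
        elif relation is PathwayPairRelation.CROSS_TALKING:
            crosstalking.append((i, j))
    return bridging_edges, crosstalking


def _min_distance_within(
    net: nx.Graph, targets_a: set[str], targets_b: set[str], cutoff: int
) -> bool:
    """True if some target pair is already within ``cutoff`` hops."""
    for gene in targets_a:
        if gene in targets_b:
            return True
        if gene not in net:
            continue
        ball = nx.single_source_shortest_path_length(net, gene, cutoff=cutoff)
        if not targets_b.isdisjoint(ball):
            return True
    return False


def generate_bundle(cfg: GeneratorConfig, outdir: str | Path) -> SyntheticBundle:
    """Generate a complete synthetic input bundle under ``outdir``.

    Deterministic given ``cfg.seed``: two calls with equal configs produce
    byte-identical files. Raises on unsatisfiable configs before writing.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]

    net = _interaction_graph(cfg, rng)
    kept_edges = sorted(tuple(sorted(e)) for e in net.edges())
    edge_rows: list[tuple[str, str, float]] = [
        (a, b, cfg.p_threshold * float(rng.random())) for a, b in kept_edges
    ]

    # Decoy rows at/above the threshold, on non-edge pairs; the first decoy
    # sits exactly at the threshold to probe the strict "<" comparison.
    n_decoys = round(cfg.decoy_fraction * len(kept_edges))
    edge_set = set(kept_edges)
    decoys: list[tuple[str, str, float]] = []
    guard = 0
    while len(decoys) < n_decoys and guard < 100 * max(1, n_decoys):
        guard += 1
        i, j = rng.integers(cfg.n_genes), rng.integers(cfg.n_genes)
        if i == j:
            continue
        a, b = sorted((genes[int(i)], genes[int(j)]))
        if (a, b) in edge_set:
            continue
        if not decoys:
            p = cfg.p_threshold
        else:
            p = cfg.p_threshold + (1.0 - cfg.p_threshold) * float(rng.random())
        decoys.append((a, b, p))
        edge_set.add((a, b))

    pathways = _sample_pathways(cfg, genes, rng)

    lo_t, hi_t = cfg.targets_per_drug_range
    drug_targets: dict[str, set[str]] = {}
    drug_atc: dict[str, set[str]] = {}
    drug_ids = [f"d{i:04d}" for i in range(cfg.n_drugs)]
    for drug_id in drug_ids:
        n_targets = int(rng.integers(lo_t, hi_t + 1))
        picks = rng.choice(cfg.n_genes, size=n_targets, replace=False)
        drug_targets[drug_id] = {genes[int(i)] for i in picks}
        drug_atc[drug_id] = {_random_atc_code(rng)}

    # True combinations: distinct unordered drug pairs.
    pair_set: set[tuple[str, str]] = set()
    guard = 0
    while len(pair_set) < cfg.n_true_combos and guard < 1000 * cfg.n_true_combos:
        guard += 1
        i, j = rng.integers(cfg.n_drugs), rng.integers(cfg.n_drugs)
        if i == j:
            continue
        pair_set.add(tuple(sorted((drug_ids[int(i)], drug_ids[int(j)]))))
    if len(pair_set) < cfg.n_true_combos:
        raise ValueError("could not sample enough distinct drug pairs")
    pairs = sorted(pair_set)

    bridging_edges, crosstalking_pairs = _bridged_pathway_pairs(pathways, net)
    if cfg.planted_crosstalk_bias > 0 and not bridging_edges:
        logger.warning(
            "no edge-bridged pathway pair exists; crosstalk planting falls "
            "back to gene-sharing pairs"
        )

    net_nodes = sorted(net.nodes())
    combo_types = sorted(("synergistic", "additive", "antagonistic", "potentiative"))
    statuses = sorted(("approved", "clinical", "preclinical"))
    combos: list[CombinationRecord] = []
    planted_radius = 0
    planted_crosstalk = 0
    radius_coin = [float(rng.random()) < cfg.planted_radius_bias for _ in pairs]
    crosstalk_coin = [float(rng.random()) < cfg.planted_crosstalk_bias for _ in pairs]

    # Crosstalk planting replaces the partners' targets with the endpoints of
    # a genetic-interaction edge bridging two disjoint pathways, so their
    # pathway sets are genuinely related (every pathway pair containing the
    # two endpoints is bridged by that edge). Done in a first pass so the
    # radius planting below, which only adds targets, is never undone.
    for coin, (drug_a, drug_b) in zip(crosstalk_coin, pairs):
        if not coin:
            continue
        if bridging_edges:
            planted_crosstalk += 1
            x, y = bridging_edges[int(rng.integers(len(bridging_edges)))]
            drug_targets[drug_a] = {x}
            drug_targets[drug_b] = {y}
        elif crosstalking_pairs:
            planted_crosstalk += 1
            pi, pj = crosstalking_pairs[int(rng.integers(len(crosstalking_pairs)))]
            shared = sorted(pathways[pi].genes & pathways[pj].genes)
            other = sorted(pathways[pj].genes)
            drug_targets[drug_a] = {shared[int(rng.integers(len(shared)))]}
            drug_targets[drug_b] = {other[int(rng.integers(len(other)))]}
    # Radius planting adds one target to each partner within d_plant hops of
    # the other. Combos whose current targets already sit within d_plant
    # (e.g. because a bridging edge was just planted) are left untouched, so
    # the crosstalk planting is not diluted with extra pathway pairs.
    for coin, (drug_a, drug_b) in zip(radius_coin, pairs):
        if not coin:
            continue
        planted_radius += 1
        if _min_distance_within(
            net, drug_targets[drug_a], drug_targets[drug_b], cfg.d_plant
        ):
            continue
        source = net_nodes[int(rng.integers(len(net_nodes)))]
        ball = sorted(
            nx.single_source_shortest_path_length(net, source, cutoff=cfg.d_plant)
        )
        target = ball[int(rng.integers(len(ball)))]
        drug_targets[drug_a].add(source)
        drug_targets[drug_b].add(target)
    for k, (drug_a, drug_b) in enumerate(pairs):
        combos.append(
            CombinationRecord(
                f"c{k:04d}",
                frozenset((drug_a, drug_b)),
                combo_type=combo_types[int(rng.integers(len(combo_types)))],
                status=statuses[int(rng.integers(len(statuses)))],
            )
        )

    # Strip annotation from a fraction of drugs to exercise the filters.
    n_unannotated = round(cfg.unannotated_fraction * cfg.n_drugs)
    stripped: list[str] = []
    if n_unannotated:
        picks = rng.choice(cfg.n_drugs, size=n_unannotated, replace=False)
        for i in sorted(int(i) for i in picks):
            drug_id = drug_ids[i]
            stripped.append(drug_id)
            if float(rng.random()) < 0.5:
                drug_targets[drug_id] = set()
            else:
                drug_atc[drug_id] = set()

    # --- write the bundle -------------------------------------------------
    interactions_path = outdir / "interactions.tsv"
    rows = sorted(edge_rows + decoys)
    with interactions_path.open("w", encoding="utf-8", newline="") as handle:
        handle.write("gene_a\tgene_b\tp_value\n")
        for a, b, p in rows:
            handle.write(f"{a}\t{b}\t{p:.12e}\n")

    drugs = [
        DrugRecord(d, drug_targets[d], drug_atc[d])
        for d in drug_ids
    ]
    targets_path = outdir / "targets.tsv"
    atc_path = outdir / "atc.tsv"
    combos_path = outdir / "combinations.tsv"
    pathways_path = outdir / "pathways.gmt"
    write_drug_targets(drugs, targets_path)
    write_drug_atc(drugs, atc_path)
    write_combinations(combos, combos_path)
    write_pathways(pathways, pathways_path)

    manifest = {
        "config": asdict(cfg),
        "n_interaction_edges_kept": len(kept_edges),
        "n_decoy_rows": len(decoys),
        "n_planted_radius": planted_radius,
        "n_planted_crosstalk": planted_crosstalk,
        "n_bridged_pathway_pairs_available": len(bridging_edges),
        "stripped_drugs": stripped,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    logger.info(
        "bundle written to %s: %d genes, %d kept edges (+%d decoys), "
        "%d pathways, %d drugs (%d stripped), %d combinations",
        outdir,
        cfg.n_genes,
        len(kept_edges),
        len(decoys),
        cfg.n_pathways,
        cfg.n_drugs,
        len(stripped),
        len(combos),
    )
    return SyntheticBundle(
        interactions=interactions_path,
        targets=targets_path,
        atc=atc_path,
        combinations=combos_path,
        pathways=pathways_path,
        manifest_path=manifest_path,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Hand-computed worked toy bundle
# ---------------------------------------------------------------------------

_TOY_INTERACTIONS = """\
gene_a	gene_b	p_value
g1	g2	1e-08
g2	g1	1e-09
g2	g3	1e-09
g3	g4	1e-09
g4	g5	1e-09
g5	g6	1e-09
g7	g8	1e-09
g9	g10	1e-09
g5	g10	1e-09
g4	g4	1e-09
g11	g12	0.5
"""

_TOY_TARGETS = """\
drug_id	gene_id
d1	g1
d2	g1
d3	g5
d4	g4
d5	g6
d6	g3
d7	g7
d8	g4
d9	g2
d9	g4
d9	g10
d9	g11
"""

_TOY_ATC = """\
drug_id	atc_code
d1	C01AA05
d2	N05AH02
d3	C07AB02
d4	A10BA02
d5	L01XX01
d7	B01AC06
d8	N02BA01
d9	C03CA01
"""

_TOY_COMBINATIONS = """\
combo_id	drug_ids	combo_type	status
C1	d1;d2	synergistic	approved
C2	d1;d3	additive	clinical
C3	d2;d6	potentiative	preclinical
C4	d3;d4;d5	synergistic	preclinical
C5	d2;d7	unknown	approved
C6	d1;d8	synergistic	approved
C7	d3;d9	additive	clinical
"""

_TOY_PATHWAYS = """\
P1	na	g1	g2
P2	na	g2	g5
P3	na	g4	g6
P4	na	g7	g11
P5	na	g10	g12
"""

#: Every expected value below was computed by hand from the tables above.
#: The kept interaction edges are g1-g2 (p collapses to 1e-9), g2-g3, g3-g4,
#: g4-g5, g5-g6, g7-g8, g9-g10, g5-g10; the g4 self-loop row is dropped (node
#: kept) and the g11-g12 row fails the strict p < 1e-7 filter. C3 is discarded
#: because d6 carries no ATC code.
TOY_MANIFEST: dict = {
    "network": {
        "n_nodes": 10,
        "n_edges": 8,
        "edges": [
            ["g1", "g2"], ["g2", "g3"], ["g3", "g4"], ["g4", "g5"],
            ["g5", "g6"], ["g5", "g10"], ["g7", "g8"], ["g9", "g10"],
        ],
        "p_value_g1_g2": 1e-09,
    },
    "retained_combos": ["C1", "C2", "C4", "C5", "C6", "C7"],
    "discarded_combos": ["C3"],
    "radius": {
        # combo_id -> [radius or None, n_pairs_used, n_pairs_unreachable]
        "C1": [0.0, 1, 0],
        "C2": [4.0, 1, 0],
        "C4": [4.0 / 3.0, 3, 0],
        "C5": [None, 0, 1],
        "C6": [3.0, 1, 0],
        "C7": [1.0, 1, 0],
    },
    "strata_at_3": {
        "small": ["C1", "C4", "C6", "C7"],  # boundary R = 3 inclusive
        "large": ["C2"],
    },
    "profiles": {
        # combo_id -> proportions per relation (absent = 0)
        "C1": {"identical": 1.0},
        "C2": {"cross_talking": 1.0},
        "C4": {"interacting": 2.0 / 3.0, "identical": 1.0 / 3.0},
        "C5": {"parallel": 1.0},
        "C6": {"parallel": 1.0},
        "C7": {
            "cross_talking": 0.2,
            "identical": 0.2,
            "interacting": 0.4,  # exactly at threshold -> excluded (strict >)
            "parallel": 0.2,
        },
    },
    "interacting_targeters_at_0.4": ["C4"],
    "tallies": {
        "combo_type_retained": {"synergistic": 3, "additive": 2, "unknown": 1},
        "atc_level1_small_stratum": {"A": 1, "C": 5, "L": 1, "N": 2},
    },
    "cocktail_network": {
        "n_nodes": 8,
        "n_edges": 8,
        "degrees": {
            "d1": 3, "d2": 2, "d3": 4, "d4": 2,
            "d5": 2, "d7": 1, "d8": 1, "d9": 1,
        },
    },
}


def worked_toy_bundle(outdir: str | Path) -> SyntheticBundle:
    """Write the hand-computed 12-gene toy bundle and its expectation manifest.

    The bundle exercises every ingestion rule (duplicate edge collapse,
    self-loop drop, strict p filter, discard on missing ATC), an unreachable
    drug pair (UNDEFINED radius), the inclusive R = 3 stratum boundary, and
    an interacting-pathway proportion of exactly 0.4 (excluded by the strict
    selection). All values in :data:`TOY_MANIFEST` were enumerated by hand.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "interactions.tsv": _TOY_INTERACTIONS,
        "targets.tsv": _TOY_TARGETS,
        "atc.tsv": _TOY_ATC,
        "combinations.tsv": _TOY_COMBINATIONS,
        "pathways.gmt": _TOY_PATHWAYS,
    }
    for name, content in files.items():
        (outdir / name).write_text(content, encoding="utf-8")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(TOY_MANIFEST, indent=2) + "\n", encoding="utf-8"
    )
    return SyntheticBundle(
        interactions=outdir / "interactions.tsv",
        targets=outdir / "targets.tsv",
        atc=outdir / "atc.tsv",
        combinations=outdir / "combinations.tsv",
        pathways=outdir / "pathways.gmt",
        manifest_path=manifest_path,
        manifest=TOY_MANIFEST,
    )
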