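"""Reading, validation and filtering of the pipeline's input tables.

The analysis consumes five plain-text inputs:

* a genetic-interaction edge list (TSV: ``gene_a``, ``gene_b``, ``p_value``),
  kept only where the interaction p-value is *strictly* below a threshold
  (default ``1e-7``);
* a drug → target-gene table (TSV: ``drug_id``, ``gene_id``);
* a drug → ATC-code table (TSV: ``drug_id``, ``atc_code``; the first character
  of a 7-character ATC code is the level-1 therapeutic class);
* a drug-combination list (TSV: ``combo_id``, ``drug_ids`` semicolon-separated,
  ``combo_type``, ``status``);
* pathway gene sets in GMT format (set name, description, genes...).

Combinations containing any drug that lacks target or ATC annotation are
discarded, mirroring the curation rule applied to the source databases.
Identifier matching is exact, case-sensitive string equality throughout.
"""

from __future__ import annotations

import csv
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Default strict upper bound on genetic-interaction p-values.
DEFAULT_P_THRESHOLD = 1.0e-7

#: Closed vocabulary of combination-effect categories (plus "unknown").
COMBINATION_TYPES = frozenset(
    {"synergistic", "additive", "antagonistic", "potentiative", "unknown"}
)

#: Closed vocabulary of development statuses (plus "unknown").
DEVELOPMENT_STATUSES = frozenset({"approved", "clinical", "preclinical", "unknown"})


class IngestError(ValueError):
    """Malformed input data; the message names the offending file and line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DrugRecord:
    """A drug with its target gene set and ATC classification codes."""

    drug_id: str
    targets: set[str] = field(default_factory=set)
    atc_codes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")
        self.targets = set(self.targets)
        self.atc_codes = set(self.atc_codes)

    @property
    def is_annotated(self) -> bool:
        """True when the drug has both targets and at least one ATC code."""
        return bool(self.targets) and bool(self.atc_codes)

    def atc_level1(self) -> set[str]:
        """Level-1 (anatomical main group) classes: first ATC character."""
        return {code[0] for code in self.atc_codes if code}


@dataclass
class CombinationRecord:
    """A drug combination: >= 2 distinct member drugs plus metadata."""

    combo_id: str
    members: frozenset[str]
    combo_type: str = "unknown"
    status: str = "unknown"

    def __post_init__(self) -> None:
        if not self.combo_id:
            raise ValueError("combo_id must be non-empty")
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise ValueError(
                f"combination {self.combo_id!r} needs >= 2 distinct members"
            )
        if self.combo_type not in COMBINATION_TYPES:
            raise ValueError(f"unknown combo_type {self.combo_type!r}")
        if self.status not in DEVELOPMENT_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")

    def member_pairs(self) -> Iterator[tuple[str, str]]:
        """All unordered member pairs, in sorted deterministic order."""
        return itertools.combinations(sorted(self.members), 2)


@dataclass
class PathwayGeneSet:
    """A named gene set (one KEGG-like pathway)."""

    pathway_id: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")


# ---------------------------------------------------------------------------
# Low-level TSV plumbing
# ---------------------------------------------------------------------------


def _iter_tsv(path: str | Path, columns: Sequence[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield ``(line_number, row)`` for a header-checked TSV file.

    Accepts LF or CRLF line endings; blank lines are skipped. Any row whose
    column count differs from the header raises :class:`IngestError` naming
    the line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path}: empty file, expected header {list(columns)}")
        header = [h.strip() for h in header]
        if header != list(columns):
            raise IngestError(
                f"{path}:1: expected header {list(columns)}, found {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(columns):
                raise IngestError(
                    f"{path}:{lineno}: expected {len(columns)} columns, "
                    f"found {len(row)}"
                )
            yield lineno, [cell.strip() for cell in row]


# ---------------------------------------------------------------------------
# Genetic interaction network
# ---------------------------------------------------------------------------


def read_genetic_interactions(
    path: str | Path, p_threshold: float = DEFAULT_P_THRESHOLD
) -> nx.Graph:
    """Read a genetic-interaction edge list, keeping rows with ``p < p_threshold``.

    The comparison is strict: a row whose p-value equals the threshold is
    excluded. Duplicate gene pairs collapse to a single edge carrying the
    minimum p-value. Self-loop rows are dropped with a warning, but the node
    is retained. Rows failing the filter contribute neither edges nor nodes.

    Returns an undirected simple :class:`networkx.Graph` whose edges carry a
    ``p_value`` attribute.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    path = Path(path)
    net = nx.Graph()
    for lineno, (gene_a, gene_b, p_raw) in _iter_tsv(
        path, ("gene_a", "gene_b", "p_value")
    ):
        try:
            p_value = float(p_raw)
        except ValueError:
            raise IngestError(f"{path}:{lineno}: non-numeric p_value {p_raw!r}")
        if not (0.0 <= p_value <= 1.0):
            raise IngestError(f"{path}:{lineno}: p_value {p_value} outside [0, 1]")
        if not gene_a or not gene_b:
            raise IngestError(f"{path}:{lineno}: empty gene identifier")
        if gene_a == gene_b:
            logger.warning(
                "%s:%d: self-loop on %r dropped (node retained)", path, lineno, gene_a
            )
            net.add_node(gene_a)
            continue
        if p_value >= p_threshold:
            continue
        if net.has_edge(gene_a, gene_b):
            net[gene_a][gene_b]["p_value"] = min(net[gene_a][gene_b]["p_value"], p_value)
        else:
            net.add_edge(gene_a, gene_b, p_value=p_value)
    logger.info(
        "%s: kept %d interaction edges over %d genes (p < %g)",
        path,
        net.number_of_edges(),
        net.number_of_nodes(),
        p_threshold,
    )
    return net


def write_genetic_interactions(net: nx.Graph, path: str | Path) -> None:
    """Write an interaction network back to the three-column TSV dialect."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "p_value"])
        for a, b in sorted(tuple(sorted(e)) for e in net.edges()):
            writer.writerow([a, b, format(net[a][b].get("p_value", 0.0), ".12g")])


# ---------------------------------------------------------------------------
# Drugs
# ---------------------------------------------------------------------------


def read_drugs(
    targets_path: str | Path, atc_path: str | Path
) -> dict[str, DrugRecord]:
    """Read target and ATC tables into one :class:`DrugRecord` per drug.

    A drug appearing in only one of the two files gets an empty set for the
    other annotation; such drugs exist at read time and are removed later by
    :func:`filter_drugs` / :func:`filter_combinations`.
    """
    targets: dict[str, set[str]] = {}
    atc: dict[str, set[str]] = {}
    for lineno, (drug_id, gene_id) in _iter_tsv(targets_path, ("drug_id", "gene_id")):
        if not drug_id or not gene_id:
            raise IngestError(f"{targets_path}:{lineno}: empty identifier")
        targets.setdefault(drug_id, set()).add(gene_id)
    for lineno, (drug_id, atc_code) in _iter_tsv(atc_path, ("drug_id", "atc_code")):
        if not drug_id or not atc_code:
            raise IngestError(f"{atc_path}:{lineno}: empty identifier")
        atc.setdefault(drug_id, set()).add(atc_code)
    drugs = {
        drug_id: DrugRecord(
            drug_id, targets.get(drug_id, set()), atc.get(drug_id, set())
        )
        for drug_id in sorted(set(targets) | set(atc))
    }
    logger.info("read %d drugs (%d with targets, %d with ATC)", len(drugs), len(targets), len(atc))
    return drugs


def filter_drugs(drugs: Mapping[str, DrugRecord]) -> dict[str, DrugRecord]:
    """Keep only drugs with both non-empty targets and non-empty ATC codes."""
    kept = {d: r for d, r in drugs.items() if r.is_annotated}
    logger.info("filter_drugs: kept %d / %d annotated drugs", len(kept), len(drugs))
    return kept


def write_drug_targets(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_id", "gene_id"])
        for drug in sorted(drugs, key=lambda d: d.drug_id):
            for gene in sorted(drug.targets):
                writer.writerow([drug.drug_id, gene])


def write_drug_atc(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["drug_id", "atc_code"])
        for drug in sorted(drugs, key=lambda d: d.drug_id):
            for code in sorted(drug.atc_codes):
                writer.writerow([drug.drug_id, code])


# ---------------------------------------------------------------------------
# Combinations
# ---------------------------------------------------------------------------


def read_combinations(path: str | Path) -> list[CombinationRecord]:
    """Read the combination list (members semicolon-separated)."""
    path = Path(path)
    combos: list[CombinationRecord] = []
    seen: set[str] = set()
    for lineno, (combo_id, drug_ids, combo_type, status) in _iter_tsv(
        path, ("combo_id", "drug_ids", "combo_type", "status")
    ):
        if combo_id in seen:
            raise IngestError(f"{path}:{lineno}: duplicate combo_id {combo_id!r}")
        seen.add(combo_id)
        members = frozenset(m.strip() for m in drug_ids.split(";") if m.strip())
        try:
            combos.append(CombinationRecord(combo_id, members, combo_type, status))
        except ValueError as exc:
            raise IngestError(f"{path}:{lineno}: {exc}")
    return combos


def write_combinations(combos: Iterable[CombinationRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["combo_id", "drug_ids", "combo_type", "status"])
        for combo in sorted(combos, key=lambda c: c.combo_id):
            writer.writerow(
                [
                    combo.combo_id,
                    ";".join(sorted(combo.members)),
                    combo.combo_type,
                    combo.status,
                ]
            )


def filter_combinations(
    combos: Iterable[CombinationRecord], drugs: Mapping[str, DrugRecord]
) -> list[CombinationRecord]:
    """Discard combinations with any member lacking targets or ATC annotation.

    A member absent from the drug table counts as unannotated: the combination
    is discarded with a warning rather than raising. Idempotent.
    """
    kept: list[CombinationRecord] = []
    discarded = 0
    for combo in combos:
        missing = [m for m in sorted(combo.members) if m not in drugs]
        if missing:
            logger.warning(
                "combination %s references unknown drug(s) %s; discarded",
                combo.combo_id,
                ",".join(missing),
            )
            discarded += 1
            continue
        if all(drugs[m].is_annotated for m in combo.members):
            kept.append(combo)
        else:
            discarded += 1
    logger.info(
        "filter_combinations: retained %d, discarded %d", len(kept), discarded
    )
    return kept


# ---------------------------------------------------------------------------
# Pathways (GMT)
# ---------------------------------------------------------------------------


def read_pathways(path: str | Path) -> list[PathwayGeneSet]:
    """Read GMT pathway gene sets: name, description (ignored), genes...

    Duplicate pathway identifiers and lines with fewer than three fields are
    hard errors; duplicate genes within a line collapse by set semantics.
    """
    path = Path(path)
    pathways: list[PathwayGeneSet] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8", newline="") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IngestError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            pathway_id = fields[0].strip()
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if pathway_id in seen:
                raise IngestError(f"{path}:{lineno}: duplicate pathway_id {pathway_id!r}")
            seen.add(pathway_id)
            if not genes:
                raise IngestError(f"{path}:{lineno}: pathway {pathway_id!r} has no genes")
            pathways.append(PathwayGeneSet(pathway_id, genes))
    logger.info("%s: read %d pathway gene sets", path, len(pathways))
    return pathways


def write_pathways(pathways: Iterable[PathwayGeneSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            handle.write("\t".join([pw.pathway_id, "na", *sorted(pw.genes)]) + "\n")
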