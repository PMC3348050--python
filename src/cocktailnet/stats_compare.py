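"""Rank-sum comparison of real vs. random combinations, and category tallies.

Real-combination statistics (effect radii, pathway-pair proportions) are
compared against the degree-preserving null ensemble with the Wilcoxon /
Mann-Whitney rank-sum test. Small tie-free problems (n + m <= 12) use exact
enumeration of the rank-sum null distribution; larger or tied problems use
the normal approximation with midranks, tie correction and continuity
correction. Category tallies reproduce the descriptive breakdowns by ATC
level-1 class, combination type and target-protein function class.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats

from .effect_radius import RadiusResult
from .io_ingest import CombinationRecord, DrugRecord
from .pathway_relations import PathwayPairRelation, PathwayProfile

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two_sided", "real_less", "real_greater")

#: Largest pooled sample size for which the exact null is enumerated.
EXACT_ENUMERATION_LIMIT = 12

_SCIPY_ALTERNATIVE = {
    "two_sided": "two-sided",
    "real_less": "less",
    "real_greater": "greater",
}


@dataclass
class ComparisonResult:
    """Outcome of one real-vs-null rank-sum comparison."""

    statistic_name: str
    real_values: tuple[float, ...]
    null_values: tuple[float, ...]
    rank_sum_statistic: float
    p_value: float
    alternative: str
    method: str = "exact"  # "exact" | "asymptotic" | "degenerate"
    pooling: str | None = None
    rank_biserial: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "n_real": len(self.real_values),
            "n_null": len(self.null_values),
            "rank_sum_statistic": self.rank_sum_statistic,
            "p_value": self.p_value,
            "alternative": self.alternative,
            "method": self.method,
            "pooling": self.pooling,
            "rank_biserial": self.rank_biserial,
        }


def _exact_tail_probabilities(
    ranks: Sequence[float], n: int, w_observed: float
) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) by enumerating all C(N, n) rank assignments."""
    n_le = 0
    n_ge = 0
    n_total = 0
    for subset in itertools.combinations(ranks, n):
        w = sum(subset)
        n_total += 1
        if w <= w_observed + 1e-9:
            n_le += 1
        if w >= w_observed - 1e-9:
            n_ge += 1
    return n_le / n_total, n_ge / n_total


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    statistic_name: str = "statistic",
) -> ComparisonResult:
    """Wilcoxon rank-sum test of sample ``x`` (real) against ``y`` (null).

    The reported statistic is W, the sum of midranks of ``x`` in the pooled
    sample. ``real_less`` is the lower-tail alternative (x stochastically
    smaller), ``real_greater`` the upper tail; the two-sided p doubles the
    smaller tail (capped at 1). Exact enumeration is used when
    ``len(x) + len(y) <= 12`` with no ties; otherwise the normal
    approximation with tie and continuity corrections. Two samples with zero
    pooled spread are degenerate: p = 1 with a warning.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x_arr = np.asarray(list(x), dtype=float)
    y_arr = np.asarray(list(y), dtype=float)
    if x_arr.size == 0 or y_arr.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    pooled = np.concatenate([x_arr, y_arr])
    ranks = scipy.stats.rankdata(pooled)
    w_observed = float(ranks[: x_arr.size].sum())
    rank_biserial = _rank_biserial(x_arr, y_arr, ranks)

    if np.ptp(pooled) == 0.0:
        logger.warning(
            "rank_sum_test(%s): degenerate comparison, all %d pooled values "
            "identical; p = 1",
            statistic_name,
            pooled.size,
        )
        return ComparisonResult(
            statistic_name,
            tuple(x_arr),
            tuple(y_arr),
            w_observed,
            1.0,
            alternative,
            method="degenerate",
            rank_biserial=rank_biserial,
        )

    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_ENUMERATION_LIMIT and not has_ties:
        p_le, p_ge = _exact_tail_probabilities(ranks, x_arr.size, w_observed)
        if alternative == "real_less":
            p_value = p_le
        elif alternative == "real_greater":
            p_value = p_ge
        else:
            p_value = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        result = scipy.stats.mannwhitneyu(
            x_arr,
            y_arr,
            alternative=_SCIPY_ALTERNATIVE[alternative],
            use_continuity=True,
            method="asymptotic",
        )
        p_value = float(result.pvalue)
        method = "asymptotic"
    return ComparisonResult(
        statistic_name,
        tuple(x_arr),
        tuple(y_arr),
        w_observed,
        p_value,
        alternative,
        method=method,
        rank_biserial=rank_biserial,
    )


def _rank_biserial(x: np.ndarray, y: np.ndarray, ranks: np.ndarray) -> float:
    """Rank-biserial effect size r = 2U/(nm) - 1, printed for context."""
    n, m = x.size, y.size
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    return float(2.0 * u / (n * m) - 1.0)


# ---------------------------------------------------------------------------
# Comparisons of pipeline statistics
# ---------------------------------------------------------------------------


def _pool_null(
    per_replicate_values: Sequence[Sequence[float]], pooling: str
) -> list[float]:
    if pooling == "pooled":
        return [v for replicate in per_replicate_values for v in replicate]
    if pooling == "replicate_mean":
        means = [
            float(np.mean(replicate))
            for replicate in per_replicate_values
            if len(replicate)
        ]
        return means
    raise ValueError(f"pooling must be 'pooled' or 'replicate_mean', got {pooling!r}")


def compare_radius(
    real: Iterable[RadiusResult],
    null_per_replicate: Sequence[Iterable[RadiusResult]],
    alternative: str = "real_less",
    pooling: str = "pooled",
) -> ComparisonResult:
    """Rank-sum test of real effect radii against the null ensemble's radii.

    UNDEFINED radii are excluded on both sides. The null sample pools all
    replicates by default; ``pooling='replicate_mean'`` reduces each
    replicate to its mean radius first. The pooling mode is recorded in the
    result.
    """
    real_radii = [r.radius for r in real if r.defined]
    null_values = _pool_null(
        [[r.radius for r in replicate if r.defined] for replicate in null_per_replicate],
        pooling,
    )
    result = rank_sum_test(
        real_radii, null_values, alternative, statistic_name="effect_radius"
    )
    result.pooling = pooling
    return result


def compare_pathway_proportion(
    real_profiles: Iterable[PathwayProfile],
    null_profiles_per_replicate: Sequence[Iterable[PathwayProfile]],
    category: PathwayPairRelation,
    alternative: str = "real_greater",
    pooling: str = "pooled",
) -> ComparisonResult:
    """Rank-sum test on per-combination proportions of one pair relation.

    Combinations with empty profiles (no pathway pairs) are excluded on both
    sides.
    """
    real_values = [p.proportion(category) for p in real_profiles if p.n_pairs > 0]
    null_values = _pool_null(
        [
            [p.proportion(category) for p in replicate if p.n_pairs > 0]
            for replicate in null_profiles_per_replicate
        ],
        pooling,
    )
    result = rank_sum_test(
        real_values,
        null_values,
        alternative,
        statistic_name=f"proportion_{category.value}",
    )
    result.pooling = pooling
    return result


# ---------------------------------------------------------------------------
# Category tallies
# ---------------------------------------------------------------------------

GROUPINGS = ("atc_level1", "combo_type", "target_function")


@dataclass
class CategoryTally:
    """Counts and proportions of a categorical breakdown over combinations."""

    grouping_name: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {label: count / total for label, count in self.counts.items()}

    def to_dict(self) -> dict:
        return {
            "grouping_name": self.grouping_name,
            "counts": dict(sorted(self.counts.items())),
            "proportions": dict(sorted(self.proportions.items())),
        }


def tally_categories(
    combo_ids: Iterable[str],
    drugs: Mapping[str, DrugRecord],
    combos: Mapping[str, CombinationRecord],
    grouping: str,
    annotation: Mapping[str, str] | None = None,
) -> CategoryTally:
    """Tally a categorical breakdown over the selected combinations.

    * ``atc_level1`` — each (member drug, level-1 ATC class) incidence counts
      once per combination membership, so a drug in several selected
      combinations contributes once per combination, and a drug with ATC
      codes in two classes contributes to both.
    * ``combo_type`` — one count per combination, by effect category.
    * ``target_function`` — each member drug's target genes counted by the
      supplied gene -> function-class annotation; unannotated genes fall
      under ``"unclassified"``.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    if grouping == "target_function" and annotation is None:
        raise ValueError("grouping='target_function' requires an annotation mapping")
    counts: dict[str, int] = {}
    for combo_id in sorted(set(combo_ids)):
        combo = combos[combo_id]
        if grouping == "combo_type":
            counts[combo.combo_type] = counts.get(combo.combo_type, 0) + 1
            continue
        for member in sorted(combo.members):
            drug = drugs[member]
            if grouping == "atc_level1":
                for level1 in sorted(drug.atc_level1()):
                    counts[level1] = counts.get(level1, 0) + 1
            else:  # target_function
                for gene in sorted(drug.targets):
                    label = annotation.get(gene, "unclassified")
                    counts[label] = counts.get(label, 0) + 1
    return CategoryTally(grouping_name=grouping, counts=counts)


def write_tally(tally: CategoryTally, path: str | Path) -> None:
    """Write one tally as TSV: label, count, proportion."""
    proportions = tally.proportions
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        handle.write("label\tcount\tproportion\n")
        for label in sorted(tally.counts):
            handle.write(
                f"{label}\t{tally.counts[label]}\t{proportions[label]:.6g}\n"
            )


def write_comparisons(
    comparisons: Mapping[str, ComparisonResult], path: str | Path
) -> None:
    """Serialize a set of comparison results to JSON."""
    payload = {name: result.to_dict() for name, result in comparisons.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
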