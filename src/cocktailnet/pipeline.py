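"""End-to-end orchestration: ingest -> cocktail network -> null ensemble ->
effect radii + pathway profiles -> rank-sum comparisons -> report.

The pipeline composes the other modules into a single deterministic run
driven by one :class:`RunConfig` (defaults: strict p < 1e-7 interaction
filter, 1000 degree-preserving null replicates, radius stratum boundary 3,
interacting-proportion selection threshold 0.4, two-sided tests, pooled
nulls). All outputs are plain text under the configured output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

import importlib

# Submodules are imported via importlib because the package namespace
# re-exports functions (e.g. effect_radius) that shadow the module names.
cn = importlib.import_module(".cocktail_network", __package__)
er = importlib.import_module(".effect_radius", __package__)
io = importlib.import_module(".io_ingest", __package__)
pr = importlib.import_module(".pathway_relations", __package__)
sc = importlib.import_module(".stats_compare", __package__)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (caught before any computation)."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; field names mirror the CLI flags."""

    interactions: Path
    targets: Path
    atc: Path
    combinations: Path
    pathways: Path
    outdir: Path
    p_threshold: float = io.DEFAULT_P_THRESHOLD
    n_null_replicates: int = 1000
    seed: int = 0
    radius_stratum_threshold: float = er.DEFAULT_RADIUS_THRESHOLD
    interacting_proportion_threshold: float = pr.DEFAULT_INTERACTING_THRESHOLD
    alternative: str = "two_sided"
    pooling: str = "pooled"
    n_swaps_per_edge: int = cn.DEFAULT_SWAPS_PER_EDGE

    def __post_init__(self) -> None:
        for name in ("interactions", "targets", "atc", "combinations", "pathways", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ConfigError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if self.n_null_replicates < 1:
            raise ConfigError(
                f"n_null_replicates must be >= 1, got {self.n_null_replicates}"
            )
        if self.radius_stratum_threshold < 0:
            raise ConfigError("radius_stratum_threshold must be >= 0")
        if not (0.0 <= self.interacting_proportion_threshold <= 1.0):
            raise ConfigError("interacting_proportion_threshold must be in [0, 1]")
        if self.alternative not in sc.ALTERNATIVES:
            raise ConfigError(f"alternative must be one of {sc.ALTERNATIVES}")
        if self.pooling not in ("pooled", "replicate_mean"):
            raise ConfigError("pooling must be 'pooled' or 'replicate_mean'")
        if self.n_swaps_per_edge < 1:
            raise ConfigError("n_swaps_per_edge must be >= 1")
        for name in ("interactions", "targets", "atc", "combinations", "pathways"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise ConfigError(f"input file for --{name} not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from a YAML mapping, with keyword overrides."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        missing = {f.name for f in dataclasses.fields(cls) if f.default is dataclasses.MISSING} - set(data)
        if missing:
            raise ConfigError(f"missing required config keys {sorted(missing)}")
        return cls(**data)


@dataclass
class RunReport:
    """In-memory results of one pipeline run (also written to disk)."""

    config: RunConfig
    n_combinations_read: int
    n_combinations_retained: int
    radius_results: list[er.RadiusResult]
    null_radius_results: list[list[er.RadiusResult]]
    profiles: list[pr.PathwayProfile]
    null_profiles: list[list[pr.PathwayProfile]]
    comparisons: dict[str, sc.ComparisonResult]
    strata: tuple[set[str], set[str]]
    interacting_targeters: set[str]
    tallies: dict[str, sc.CategoryTally]
    output_files: dict[str, Path] = field(default_factory=dict)

    @property
    def n_radius_undefined(self) -> int:
        return sum(1 for r in self.radius_results if not r.defined)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; see the module docstring for the stages."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage ingest: reading inputs")
    net = io.read_genetic_interactions(cfg.interactions, cfg.p_threshold)
    drugs = io.read_drugs(cfg.targets, cfg.atc)
    combos_all = io.read_combinations(cfg.combinations)
    pathways = io.read_pathways(cfg.pathways)
    combos = io.filter_combinations(combos_all, drugs)
    if not combos:
        raise ConfigError("no combination survives the annotation filter")
    combo_lookup = {c.combo_id: c for c in combos}

    logger.info("stage cocktail: building network and %d-replicate null ensemble",
                cfg.n_null_replicates)
    cocktail = cn.build_cocktail_network(combos)
    ensemble = cn.generate_null_ensemble(
        cocktail, cfg.n_null_replicates, cfg.seed, cfg.n_swaps_per_edge
    )
    null_combos = cn.null_edges_as_combinations(ensemble)

    logger.info("stage radius: computing real and null effect radii")
    index = er.DistanceIndex(net)
    radius_results = [er.effect_radius(index, c, drugs) for c in combos]
    null_radius_results = [
        [er.effect_radius(index, c, drugs) for c in replicate]
        for replicate in null_combos
    ]

    logger.info("stage pathways: profiling real and null combinations")
    classifier = pr.PathwayPairClassifier(pathways, net)
    profiles = [
        pr.combination_profile(c, drugs, pathways, net, classifier) for c in combos
    ]
    null_profiles = [
        [pr.combination_profile(c, drugs, pathways, net, classifier) for c in replicate]
        for replicate in null_combos
    ]

    logger.info("stage compare: rank-sum tests (%s, %s nulls)",
                cfg.alternative, cfg.pooling)
    comparisons = {
        "effect_radius": sc.compare_radius(
            radius_results, null_radius_results, cfg.alternative, cfg.pooling
        ),
        "proportion_cross_talking": sc.compare_pathway_proportion(
            profiles, null_profiles, pr.PathwayPairRelation.CROSS_TALKING,
            cfg.alternative, cfg.pooling,
        ),
        "proportion_interacting": sc.compare_pathway_proportion(
            profiles, null_profiles, pr.PathwayPairRelation.INTERACTING,
            cfg.alternative, cfg.pooling,
        ),
    }

    strata = er.stratify_by_radius(radius_results, cfg.radius_stratum_threshold)
    targeters = pr.select_interacting_targeters(
        profiles, cfg.interacting_proportion_threshold
    )
    non_targeters = {
        p.combo_id for p in profiles if p.n_pairs > 0
    } - targeters
    tallies = {
        "atc_level1_small_radius": sc.tally_categories(
            strata[0], drugs, combo_lookup, "atc_level1"
        ),
        "atc_level1_large_radius": sc.tally_categories(
            strata[1], drugs, combo_lookup, "atc_level1"
        ),
        "combo_type_interacting_targeters": sc.tally_categories(
            targeters, drugs, combo_lookup, "combo_type"
        ),
        "atc_level1_interacting_targeters": sc.tally_categories(
            targeters, drugs, combo_lookup, "atc_level1"
        ),
        "atc_level1_non_targeters": sc.tally_categories(
            non_targeters, drugs, combo_lookup, "atc_level1"
        ),
    }
    # Empty strata produce empty tallies, which serialize as empty tables.

    report = RunReport(
        config=cfg,
        n_combinations_read=len(combos_all),
        n_combinations_retained=len(combos),
        radius_results=radius_results,
        null_radius_results=null_radius_results,
        profiles=profiles,
        null_profiles=null_profiles,
        comparisons=comparisons,
        strata=strata,
        interacting_targeters=targeters,
        tallies=tallies,
    )
    _write_outputs(report, outdir)
    return report


def _write_outputs(report: RunReport, outdir: Path) -> None:
    cfg = report.config
    files: dict[str, Path] = {}

    files["radius"] = outdir / "radius.tsv"
    er.write_radius_table(report.radius_results, files["radius"])

    files["profiles"] = outdir / "pathway_profiles.tsv"
    pr.write_profiles(report.profiles, files["profiles"])

    files["comparisons"] = outdir / "comparisons.json"
    sc.write_comparisons(report.comparisons, files["comparisons"])

    for name, tally in report.tallies.items():
        files[f"tally_{name}"] = outdir / f"tally_{name}.tsv"
        sc.write_tally(tally, files[f"tally_{name}"])

    files["summary"] = outdir / "summary.txt"
    files["summary"].write_text(render_summary(report), encoding="utf-8")

    files["run_config"] = outdir / "run_config.json"
    cfg_dict = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in dataclasses.asdict(cfg).items()
    }
    files["run_config"].write_text(
        json.dumps(cfg_dict, indent=2) + "\n", encoding="utf-8"
    )
    report.output_files = files


def render_summary(report: RunReport) -> str:
    """Human-readable run summary mirroring the analysis' result structure."""
    cfg = report.config
    small, large = report.strata
    n_defined = sum(1 for r in report.radius_results if r.defined)
    n_unreachable_pairs = sum(r.n_pairs_unreachable for r in report.radius_results)
    lines = [
        "Drug combination network analysis",
        "=================================",
        "",
        "Ingestion",
        f"  combinations read:      {report.n_combinations_read}",
        f"  combinations retained:  {report.n_combinations_retained}",
        f"  combinations discarded: {report.n_combinations_read - report.n_combinations_retained}",
        "",
        "Effect radius (drug-drug shortest-path distance over the genetic interaction network)",
        f"  defined radii:          {n_defined}",
        f"  UNDEFINED radii:        {report.n_radius_undefined}",
        f"  unreachable drug pairs: {n_unreachable_pairs}",
        f"  R <= {cfg.radius_stratum_threshold:g}: {len(small)} combinations"
        f" ({_pct(len(small), n_defined)})",
        f"  R >  {cfg.radius_stratum_threshold:g}: {len(large)} combinations"
        f" ({_pct(len(large), n_defined)})",
        "",
        "Pathway-pair relations",
        f"  interacting-proportion > {cfg.interacting_proportion_threshold:g}: "
        f"{len(report.interacting_targeters)} combinations",
        "",
        f"Rank-sum comparisons vs {cfg.n_null_replicates}-replicate degree-preserving null"
        f" ({cfg.alternative}, {cfg.pooling} nulls)",
    ]
    for name, result in report.comparisons.items():
        lines.append(
            f"  {name}: p = {result.p_value:.3g} "
            f"(W = {result.rank_sum_statistic:g}, method = {result.method}, "
            f"n_real = {len(result.real_values)}, n_null = {len(result.null_values)}, "
            f"rank-biserial = {result.rank_biserial:+.3f})"
        )
    lines.append("")
    lines.append("Category tallies")
    for name, tally in report.tallies.items():
        body = ", ".join(
            f"{label}={count}" for label, count in sorted(tally.counts.items())
        )
        lines.append(f"  {name}: {body if body else '(empty)'}")
    lines.append("")
    return "\n".join(lines)


def _pct(part: int, whole: int) -> str:
    if whole == 0:
        return "n/a"
    return f"{100.0 * part / whole:.1f}%"
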