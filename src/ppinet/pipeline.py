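"""End-to-end pipeline: gather -> consolidate -> score -> filter -> report.

Everything here is deterministic: re-running with identical inputs and
configuration yields byte-identical output files. Each stage logs its
record counts so losses are attributable (validation filter, identifier
mapping, consolidation, context filters).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ppinet.consolidate import Interactome, build_generic_interactome
from ppinet.filtering import ContextSpec, ExpressionProfile, filter_by_context
from ppinet.go_annotations import AnnotationSet, TermSelection, load_annotations
from ppinet.mitab_io import (IdMap, MethodWhitelist, filter_experimental,
                             map_identifiers, parse_mitab_file)
from ppinet.netstats import NetworkStats, compute_stats, plot_distributions
from ppinet.scoring import MethodGrouping, score_interactome

logger = logging.getLogger(__name__)


@dataclass
class ExpressionInput:
    path: str
    label: str | None = None
    threshold: float = 0.0
    pvalue_threshold: float | None = None


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``mitab`` maps source-database label -> MITAB file path. Scoring is
    performed when ``go_terms`` is non-empty (requires ``annotations``).
    Context filtering applies when expression inputs or ``filter_go_terms``
    are given. ``symbol_map`` optionally translates gene identifiers to a
    secondary namespace (e.g. gene symbols) for a second copy of each
    edge file.
    """

    mitab: dict[str, str]
    idmap: str
    annotations: str | None = None
    whitelist: str | None = None
    grouping: str | None = None
    go_terms: list[str] = field(default_factory=list)
    max_term_size: int | None = None
    allowed_evidence: list[str] | None = None
    pseudocount: float = 1.0
    prior: float = 0.5
    expression: list[ExpressionInput] = field(default_factory=list)
    expression_mode: str = "any"
    filter_go_terms: list[str] = field(default_factory=list)
    symbol_map: str | None = None
    outdir: str = "."
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        expr = [ExpressionInput(**e) for e in data.pop("expression", [])]
        return cls(expression=expr, **data)

    def validate(self) -> None:
        """Fail fast: every referenced path must exist before work starts."""
        missing = []
        paths = list(self.mitab.values()) + [self.idmap]
        for p in (self.annotations, self.whitelist, self.grouping,
                  self.symbol_map):
            if p is not None:
                paths.append(p)
        paths += [e.path for e in self.expression]
        for p in paths:
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")
        if self.go_terms and self.annotations is None:
            raise ValueError("scoring requested (go_terms set) but no "
                             "annotation table was given")
        if self.filter_go_terms and self.annotations is None:
            raise ValueError("GO filtering requested but no annotation "
                             "table was given")

    def digest(self) -> str:
        """Short stable hash of the configuration, stamped into outputs
        for provenance. The output directory and plot switch do not
        affect the hash: they describe where results go, not what was
        computed."""
        payload = asdict(self)
        payload.pop("outdir", None)
        payload.pop("plots", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class StageCounts:
    parsed: int = 0
    skipped_rows: int = 0
    discarded_by_whitelist: int = 0
    dropped_unmappable: int = 0
    mapped: int = 0
    generic_edges: int = 0
    filtered_edges: int = 0


@dataclass
class PipelineResult:
    generic: Interactome
    filtered: Interactome
    counts: StageCounts
    stats_generic: NetworkStats
    stats_filtered: NetworkStats
    weight_histogram: list[int] | None
    outputs: list[Path]


def _load_symbol_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) >= 2:
            out.setdefault(cols[0], cols[1])
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write the output file set under
    ``config.outdir``.

    Writes the generic and filtered interactome edge lists (each twice
    when a symbol map is given: primary identifiers and symbols), a
    network-statistics TSV covering both networks, and optionally the
    degree / weight distribution plots.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = StageCounts()

    whitelist = (MethodWhitelist.load(config.whitelist)
                 if config.whitelist else MethodWhitelist.default())
    grouping = (MethodGrouping.load(config.grouping)
                if config.grouping else MethodGrouping.default())
    idmap = IdMap.load(config.idmap)

    record_sets: dict[str, list] = {}
    for label, path in config.mitab.items():
        records, skipped = parse_mitab_file(path, source=label)
        counts.parsed += len(records)
        counts.skipped_rows += skipped
        kept, discarded = filter_experimental(records, whitelist)
        counts.discarded_by_whitelist += discarded
        mapped, dropped = map_identifiers(kept, idmap)
        counts.dropped_unmappable += dropped
        counts.mapped += len(mapped)
        record_sets[label] = mapped
        logger.info("%s: %d parsed, %d skipped, %d non-experimental, "
                    "%d unmappable, %d mapped records",
                    label, len(records), skipped, discarded, dropped,
                    len(mapped))

    generic = build_generic_interactome(record_sets)
    counts.generic_edges = len(generic)
    logger.info("generic interactome: %d proteins, %d PPIs",
                len(generic.nodes()), len(generic))

    ann: AnnotationSet | None = None
    if config.annotations:
        ann = load_annotations(config.annotations)

    weight_hist: list[int] | None = None
    if config.go_terms:
        sel = TermSelection(
            terms=frozenset(config.go_terms),
            max_term_size=config.max_term_size,
            allowed_evidence=(frozenset(config.allowed_evidence)
                              if config.allowed_evidence else None))
        generic, weight_hist = score_interactome(
            generic, ann, sel, grouping,
            pseudocount=config.pseudocount, prior=config.prior)

    profiles = [
        ExpressionProfile.load(e.path, resource=e.label,
                               threshold=e.threshold,
                               pvalue_threshold=e.pvalue_threshold)
        for e in config.expression
    ]
    context = ContextSpec(
        profiles=profiles,
        go_terms=(frozenset(config.filter_go_terms)
                  if config.filter_go_terms else None))
    filtered = (generic.copy() if context.is_empty()
                else filter_by_context(generic, context, ann=ann,
                                       mode=config.expression_mode))
    counts.filtered_edges = len(filtered)
    logger.info("filtered interactome: %d proteins, %d PPIs",
                len(filtered.nodes()), len(filtered))

    stats_generic = compute_stats(generic)
    stats_filtered = compute_stats(filtered)

    # -- outputs ---------------------------------------------------------
    comment = f"ppinet config_hash={config.digest()}"
    outputs: list[Path] = []

    def emit(net: Interactome, stem: str) -> None:
        path = outdir / f"{stem}.tsv"
        net.write_tsv(path, comment=comment)
        outputs.append(path)
        if config.symbol_map:
            sym = _load_symbol_map(config.symbol_map)
            path = outdir / f"{stem}_symbols.tsv"
            net.write_tsv(path, id_map=sym, comment=comment)
            outputs.append(path)

    emit(generic, "generic_interactome")
    emit(filtered, "filtered_interactome")

    stats_path = outdir / "network_stats.tsv"
    stats_generic.to_tsv(outdir / "generic_stats.tsv")
    stats_filtered.to_tsv(outdir / "filtered_stats.tsv")
    _write_combined_stats(stats_path, stats_generic, stats_filtered)
    outputs += [outdir / "generic_stats.tsv", outdir / "filtered_stats.tsv",
                stats_path]

    if config.plots:
        outputs += plot_distributions(stats_generic, outdir, "generic")
        outputs += plot_distributions(stats_filtered, outdir, "filtered")

    return PipelineResult(generic=generic, filtered=filtered, counts=counts,
                          stats_generic=stats_generic,
                          stats_filtered=stats_filtered,
                          weight_histogram=weight_hist, outputs=outputs)


def _write_combined_stats(path: Path, generic: NetworkStats,
                          filtered: NetworkStats) -> None:
    rows = [
        ("proteins", generic.n_proteins, filtered.n_proteins),
        ("ppis", generic.n_ppis, filtered.n_ppis),
        ("self_loops", generic.n_self_loops, filtered.n_self_loops),
        ("connected_components", generic.n_components,
         filtered.n_components),
        ("avg_clustering_coefficient",
         f"{generic.avg_clustering:.6g}", f"{filtered.avg_clustering:.6g}"),
    ]
    lines = ["measure\tgeneric\tfiltered"]
    lines += [f"{name}\t{g}\t{f}" for name, g, f in rows]
    path.write_text("\n".join(lines) + "\n")
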