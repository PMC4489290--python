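"""Seeded synthetic inputs for end-to-end pipeline testing.

The generator writes everything the pipeline reads — per-source MITAB
files, an identifier map, GO annotation and term-description tables, and
expression tables — with planted, exactly known structure:

* a two-block edge model: edges inside planted GO modules carry a
  "boosted" coimmunoprecipitation method (so its likelihood ratio must
  come out above 1), while every edge carries a "neutral" two-hybrid
  method (whose ratio must sit near 1);
* duplicate interaction pairs planted across two sources (consolidation
  must merge them);
* records whose only method is computational prediction (the
  experimental-validation filter must discard them);
* raw identifiers mapping to two genes (record multiplication) and
  unmappable identifiers (counted drops);
* malformed short rows (parser skips);
* per-resource expressed / silent gene sets with independent thresholds.

A JSON manifest records every planted quantity, computed with plain set
arithmetic inside the generator, so a pipeline run can be checked
against ground truth stage by stage. Identical spec + seed reproduces
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ppinet.mitab_io import InteractionRecord, write_mitab

NEUTRAL_METHOD = "MI:0018"          # two hybrid: planted on every edge
BOOSTED_METHODS = ("MI:0006", "MI:0007")  # coimmunoprecipitation group
BOOSTED_GROUP = "coimmunoprecipitation"
NEUTRAL_GROUP = "two hybrid"
NONEXPERIMENTAL_METHOD = "MI:0063"  # interaction prediction

MODULE_TERMS = ("GO:0000001", "GO:0000002")
MODULE_DESCRIPTIONS = ("signal transduction", "mitochondrion organization")
BROAD_TERM = "GO:0000999"
BROAD_DESCRIPTION = "cellular process"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults describe a small but structurally complete interactome:
    80 genes, 150 unique interactions over 3 source databases, two GO
    modules dense enough that method likelihood ratios are stable, and
    two expression resources with realistic expressed fractions.
    """

    n_genes: int = 80
    n_edges: int = 150
    n_sources: int = 3
    go_module_sizes: tuple[int, ...] = (15, 12)
    fraction_module_edges: float = 0.30
    fraction_mixed_edges: float = 0.20
    fraction_nonexperimental: float = 0.15
    n_duplicate_pairs: int = 10
    n_multi_map: int = 4
    n_unmappable: int = 3
    n_malformed: int = 2
    n_self_loops: int = 1
    expression_resources: tuple[tuple[str, float], ...] = (
        ("tissue_a", 0.75), ("tissue_b", 0.60))
    expression_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.go_module_sizes) > self.n_genes:
            raise ValueError("GO modules cannot exceed the gene universe")
        if not 0 <= self.fraction_nonexperimental <= 1:
            raise ValueError("fraction_nonexperimental must lie in [0, 1]")


@dataclass
class FixtureSet:
    """Paths of one generated dataset plus its ground-truth manifest."""

    outdir: Path
    mitab_paths: dict[str, Path]
    idmap_path: Path
    annotation_path: Path
    term_description_path: Path
    expression_paths: dict[str, Path]
    manifest_path: Path
    manifest: dict


def _gene_id(i: int) -> str:
    return f"ENSG{i:08d}"


def _raw_id(i: int) -> str:
    return f"P{i:05d}"


def _sample_pairs(rng: np.random.Generator, pool_a: list[str],
                  pool_b: list[str], n: int,
                  used: set[tuple[str, str]]) -> list[tuple[str, str]]:
    """Sample n distinct canonical pairs (a from pool_a, b from pool_b,
    a != b) not already in `used`."""
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("pair pool exhausted; reduce n_edges")
        a = pool_a[rng.integers(len(pool_a))]
        b = pool_b[rng.integers(len(pool_b))]
        if a == b:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair in used:
            continue
        used.add(pair)
        out.append(pair)
    return out


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> FixtureSet:
    """Write one synthetic dataset under ``outdir`` and return its paths
    and ground-truth manifest (also saved as ``manifest.json``)."""
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes = [_gene_id(i) for i in range(spec.n_genes)]

    # -- GO modules ------------------------------------------------------
    modules: list[list[str]] = []
    cursor = 0
    for size in spec.go_module_sizes:
        modules.append(genes[cursor:cursor + size])
        cursor += size
    annotated = sorted({g for mod in modules for g in mod})
    unannotated = [g for g in genes if g not in set(annotated)]

    # -- edge placement (two-block model) --------------------------------
    n_module = int(round(spec.fraction_module_edges * spec.n_edges))
    n_mixed = int(round(spec.fraction_mixed_edges * spec.n_edges))
    n_background = spec.n_edges - n_module - n_mixed
    used: set[tuple[str, str]] = set()
    module_edges: list[tuple[str, str]] = []
    per_module = [n_module // len(modules)] * len(modules)
    per_module[0] += n_module - sum(per_module)
    for mod, n in zip(modules, per_module):
        module_edges += _sample_pairs(rng, mod, mod, n, used)
    mixed_edges = _sample_pairs(rng, annotated, unannotated, n_mixed, used)
    background_edges = _sample_pairs(rng, unannotated, unannotated,
                                     n_background, used)
    self_loop_genes = [unannotated[int(i)] for i in
                       rng.choice(len(unannotated), size=spec.n_self_loops,
                                  replace=False)]
    self_loops = [(g, g) for g in self_loop_genes]
    for loop in self_loops:
        used.add(loop)

    def methods_for(pair: tuple[str, str], is_module: bool) -> frozenset[str]:
        methods = {NEUTRAL_METHOD}
        if is_module:
            methods.add(BOOSTED_METHODS[int(rng.integers(2))])
        return frozenset(methods)

    edge_methods: dict[tuple[str, str], frozenset[str]] = {}
    for pair in module_edges:
        edge_methods[pair] = methods_for(pair, True)
    for pair in mixed_edges + background_edges + self_loops:
        edge_methods[pair] = methods_for(pair, False)
    all_edges = module_edges + mixed_edges + background_edges + self_loops

    # -- identifier map --------------------------------------------------
    raw_of = {g: _raw_id(i) for i, g in enumerate(genes)}
    map_pairs = [(raw_of[g], g) for g in genes]
    # aliases mapping to two background genes each; used by extra records
    multi_raw: list[tuple[str, tuple[str, str]]] = []
    if spec.n_multi_map:
        picks = rng.choice(len(unannotated), size=2 * spec.n_multi_map,
                           replace=False)
        for j in range(spec.n_multi_map):
            g1 = unannotated[int(picks[2 * j])]
            g2 = unannotated[int(picks[2 * j + 1])]
            alias = f"PX{j:03d}"
            multi_raw.append((alias, (g1, g2)))
            map_pairs += [(alias, g1), (alias, g2)]

    # -- records per source ----------------------------------------------
    sources = [f"source_{chr(ord('a') + i)}" for i in range(spec.n_sources)]
    records_by_source: dict[str, list[InteractionRecord]] = {
        s: [] for s in sources}

    def record(raw_a: str, raw_b: str, methods: frozenset[str],
               source: str) -> InteractionRecord:
        return InteractionRecord(interactor_a=raw_a, interactor_b=raw_b,
                                 methods=methods, source=source)

    edge_sources: dict[tuple[str, str], list[str]] = {}
    for pair in all_edges:
        primary = sources[int(rng.integers(len(sources)))]
        edge_sources[pair] = [primary]
    dup_idx = rng.choice(len(all_edges), size=min(spec.n_duplicate_pairs,
                                                  len(all_edges)),
                         replace=False)
    duplicate_pairs = [all_edges[int(i)] for i in sorted(dup_idx)]
    for pair in duplicate_pairs:
        primary = edge_sources[pair][0]
        others = [s for s in sources if s != primary]
        edge_sources[pair].append(others[int(rng.integers(len(others)))])

    for pair, srcs in edge_sources.items():
        for s in srcs:
            records_by_source[s].append(
                record(raw_of[pair[0]], raw_of[pair[1]],
                       edge_methods[pair], s))

    # extra records through multi-mapped aliases (neutral method only, so
    # the planted likelihood-ratio signs stay valid)
    multi_record_edges: list[tuple[str, str]] = []
    for alias, (g1, g2) in multi_raw:
        # partner chosen so both expanded edges are new (exact bookkeeping:
        # every mapped record beyond the planted duplicates is its own edge)
        while True:
            partner = unannotated[int(rng.integers(len(unannotated)))]
            if partner in (g1, g2):
                continue
            pairs = [tuple(sorted((g, partner))) for g in (g1, g2)]
            if any(p in used for p in pairs):
                continue
            break
        used.update(pairs)
        s = sources[int(rng.integers(len(sources)))]
        records_by_source[s].append(
            record(alias, raw_of[partner], frozenset({NEUTRAL_METHOD}), s))
        multi_record_edges.extend(pairs)

    # records that must fall to the experimental-validation filter
    n_base_records = sum(len(v) for v in records_by_source.values())
    n_nonexp = int(round(spec.fraction_nonexperimental * n_base_records))
    for _ in range(n_nonexp):
        a, b = (genes[int(i)] for i in
                rng.choice(spec.n_genes, size=2, replace=False))
        s = sources[int(rng.integers(len(sources)))]
        records_by_source[s].append(
            record(raw_of[a], raw_of[b],
                   frozenset({NONEXPERIMENTAL_METHOD}), s))

    # records with an unmappable interactor
    for j in range(spec.n_unmappable):
        b = genes[int(rng.integers(spec.n_genes))]
        s = sources[int(rng.integers(len(sources)))]
        records_by_source[s].append(
            record(f"UNMAPPED{j:03d}", raw_of[b],
                   frozenset({NEUTRAL_METHOD}), s))

    # -- write MITAB files ------------------------------------------------
    mitab_paths: dict[str, Path] = {}
    for s in sources:
        path = outdir / f"{s}.mitab.tsv"
        lines = list(write_mitab(records_by_source[s]))
        if s == sources[0]:
            lines += ["truncated\trow"] * spec.n_malformed
        path.write_text("\n".join(lines) + "\n")
        mitab_paths[s] = path

    # -- write identifier map ---------------------------------------------
    idmap_path = outdir / "idmap.tsv"
    idmap_path.write_text("\n".join(
        f"{raw}\t{gene}" for raw, gene in sorted(map_pairs)) + "\n")

    # -- write GO annotations ---------------------------------------------
    ann_rows: list[str] = []
    for term, mod in zip(MODULE_TERMS, modules):
        for g in mod:
            ann_rows.append(f"{g}\t{term}\tIDA\tP")
    # a broad electronic-evidence term over most of the universe, for
    # term-size and evidence-code filtering
    n_broad = int(round(0.9 * spec.n_genes))
    broad_genes = sorted(genes[i] for i in
                         rng.choice(spec.n_genes, size=n_broad,
                                    replace=False))
    for g in broad_genes:
        ann_rows.append(f"{g}\t{BROAD_TERM}\tIEA\tP")
    annotation_path = outdir / "go_annotations.tsv"
    annotation_path.write_text("\n".join(sorted(ann_rows)) + "\n")

    term_description_path = outdir / "go_terms.tsv"
    term_description_path.write_text("\n".join(
        [f"{t}\t{d}" for t, d in zip(MODULE_TERMS, MODULE_DESCRIPTIONS)]
        + [f"{BROAD_TERM}\t{BROAD_DESCRIPTION}"]) + "\n")

    # -- write expression tables ------------------------------------------
    expression_paths: dict[str, Path] = {}
    expressed_by_resource: dict[str, list[str]] = {}
    for label, frac in spec.expression_resources:
        n_expr = int(round(frac * spec.n_genes))
        expr_set = sorted(genes[int(i)] for i in
                          rng.choice(spec.n_genes, size=n_expr,
                                     replace=False))
        expressed_by_resource[label] = expr_set
        rows = ["gene\tvalue"]
        for g in genes:
            if g in set(expr_set):
                value = spec.expression_threshold + rng.uniform(1.0, 9.0)
            else:
                value = rng.uniform(0.0, 0.5 * spec.expression_threshold)
            rows.append(f"{g}\t{value:.4f}")
        path = outdir / f"expression_{label}.tsv"
        path.write_text("\n".join(rows) + "\n")
        expression_paths[label] = path

    # -- ground-truth manifest (plain set arithmetic) ----------------------
    generic_edges = sorted(set(all_edges) | set(multi_record_edges))
    annotated_set = set(annotated)
    positive = [e for e in generic_edges
                if e[0] in annotated_set and e[1] in annotated_set]
    negative = [e for e in generic_edges
                if e[0] not in annotated_set and e[1] not in annotated_set]
    mixed = [e for e in generic_edges
             if (e[0] in annotated_set) != (e[1] in annotated_set)]
    expressed_union = sorted(
        set().union(*expressed_by_resource.values()))
    expr_set_union = set(expressed_union)
    edges_after_expression = [e for e in generic_edges
                              if e[0] in expr_set_union
                              and e[1] in expr_set_union]
    go_filter_terms = [MODULE_TERMS[0]]
    module0 = set(modules[0])
    edges_after_go = [e for e in generic_edges
                      if e[0] in module0 and e[1] in module0]

    n_records = {s: len(records_by_source[s]) for s in sources}
    n_total = sum(n_records.values())
    manifest = {
        "spec": asdict(spec),
        "sources": sources,
        "n_records_per_source": n_records,
        "n_records_total": n_total,
        "n_malformed_rows": spec.n_malformed,
        "n_nonexperimental_records": n_nonexp,
        "n_records_after_filter": n_total - n_nonexp,
        "n_unmappable_records": spec.n_unmappable,
        "n_records_after_mapping":
            n_total - n_nonexp - spec.n_unmappable + len(multi_raw),
        "n_duplicate_pairs": len(duplicate_pairs),
        "duplicate_pairs": [list(p) for p in duplicate_pairs],
        "n_edges_generic": len(generic_edges),
        "n_self_loops": spec.n_self_loops,
        "module_terms": list(MODULE_TERMS),
        "broad_term": BROAD_TERM,
        "annotated_genes": annotated,
        "n_positive_edges": len(positive),
        "n_negative_edges": len(negative),
        "n_mixed_edges": len(mixed),
        "boosted_group": BOOSTED_GROUP,
        "neutral_group": NEUTRAL_GROUP,
        "expressed_by_resource": expressed_by_resource,
        "expressed_union": expressed_union,
        "expression_threshold": spec.expression_threshold,
        "n_edges_after_expression": len(edges_after_expression),
        "go_filter_terms": go_filter_terms,
        "n_edges_after_go_filter": len(edges_after_go),
    }
    manifest = json.loads(json.dumps(manifest))  # normalize tuples -> lists
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True)
                             + "\n")

    return FixtureSet(
        outdir=outdir,
        mitab_paths=mitab_paths,
        idmap_path=idmap_path,
        annotation_path=annotation_path,
        term_description_path=term_description_path,
        expression_paths=expression_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )
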