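"""Consolidation of interaction records into a non-redundant interactome.

Records from all selected source databases are merged into one undirected
network: each unordered gene pair is stored once, under lexicographic
canonical ordering, and carries the union of its detection methods (each
PSI-MI accession at most once per edge, so overlapping evidence across
databases is ignored) and the set of contributing source databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

from ppinet.mitab_io import InteractionRecord


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair under a deterministic (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Evidence:
    """Everything known about one consolidated interaction."""

    methods: set[str] = field(default_factory=set)
    sources: set[str] = field(default_factory=set)
    weight: float | None = None


class Interactome:
    """Undirected PPI network: canonical gene pair -> :class:`Evidence`.

    Self-interactions are legitimate edges (homodimers) and are retained
    in the edge count; network statistics exclude them from clustering,
    following the usual graph convention.
    """

    def __init__(self) -> None:
        self._edges: dict[tuple[str, str], Evidence] = {}

    def add_record(self, record: InteractionRecord) -> None:
        pair = canonical_pair(record.interactor_a, record.interactor_b)
        ev = self._edges.setdefault(pair, Evidence())
        ev.methods |= record.methods
        if record.source:
            ev.sources.add(record.source)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._edges

    def __getitem__(self, pair: tuple[str, str]) -> Evidence:
        return self._edges[canonical_pair(*pair)]

    def edges(self) -> Iterator[tuple[tuple[str, str], Evidence]]:
        """Edges in canonical-pair sorted order (deterministic)."""
        for pair in sorted(self._edges):
            yield pair, self._edges[pair]

    def nodes(self) -> set[str]:
        return {g for pair in self._edges for g in pair}

    def copy(self) -> "Interactome":
        out = Interactome()
        for pair, ev in self._edges.items():
            out._edges[pair] = Evidence(set(ev.methods), set(ev.sources),
                                        ev.weight)
        return out

    def subset(self, keep: Iterable[tuple[str, str]]) -> "Interactome":
        """New interactome restricted to the given pairs; evidence and
        weights are carried through unchanged."""
        wanted = {canonical_pair(*p) for p in keep}
        out = Interactome()
        for pair in wanted & self._edges.keys():
            ev = self._edges[pair]
            out._edges[pair] = Evidence(set(ev.methods), set(ev.sources),
                                        ev.weight)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), ev in self._edges.items():
            g.add_edge(a, b, methods=sorted(ev.methods),
                       sources=sorted(ev.sources), weight=ev.weight)
        return g

    # -- TSV edge-list persistence (Cytoscape-ingestible) ----------------

    HEADER = "gene_a\tgene_b\tmethods\tsources\tweight"

    def write_tsv(self, path: str | Path,
                  id_map: Mapping[str, str] | None = None,
                  comment: str | None = None) -> None:
        """Write the edge list as TSV: gene_a, gene_b, pipe-joined methods,
        pipe-joined sources, weight (empty until scored).

        ``id_map`` optionally translates gene identifiers to a secondary
        namespace (e.g. gene symbols); untranslatable genes keep their
        primary identifier.
        """
        def name(g: str) -> str:
            return id_map.get(g, g) if id_map is not None else g

        lines = []
        if comment:
            lines.append(f"# {comment}")
        lines.append(self.HEADER)
        for (a, b), ev in self.edges():
            w = "" if ev.weight is None else f"{ev.weight:.6g}"
            lines.append("\t".join([
                name(a), name(b),
                "|".join(sorted(ev.methods)),
                "|".join(sorted(ev.sources)),
                w,
            ]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Interactome":
        net = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#") \
                    or line.startswith("gene_a\t"):
                continue
            cols = line.split("\t")
            a, b = cols[0], cols[1]
            ev = net._edges.setdefault(canonical_pair(a, b), Evidence())
            if len(cols) > 2 and cols[2]:
                ev.methods |= set(cols[2].split("|"))
            if len(cols) > 3 and cols[3]:
                ev.sources |= set(cols[3].split("|"))
            if len(cols) > 4 and cols[4]:
                ev.weight = float(cols[4])
        return net


def build_generic_interactome(
    record_sets: Mapping[str, Iterable[InteractionRecord]]
                 | Iterable[Iterable[InteractionRecord]],
) -> Interactome:
    """Merge validated, gene-mapped records from all sources into one
    non-redundant undirected interactome.

    ``record_sets`` maps source label -> records (a bare iterable of
    record sequences also works; each record then keeps its own source
    field). The result is independent of input-source order, and
    consolidating an already-consolidated edge list is a no-op.
    """
    net = Interactome()
    if isinstance(record_sets, Mapping):
        for label, records in record_sets.items():
            for rec in records:
                net.add_record(rec if rec.source else
                               InteractionRecord(rec.interactor_a,
                                                 rec.interactor_b,
                                                 rec.methods, label,
                                                 rec.taxon_a, rec.taxon_b))
    else:
        for records in record_sets:
            for rec in records:
                net.add_record(rec)
    return net
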