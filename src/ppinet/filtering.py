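"""Context filters: expression-based and GO-based edge selection.

A physical interaction cannot occur if either partner is absent from the
modeled condition, so every filter here applies a dual-endpoint rule: an
edge survives only when BOTH genes pass. Expression resources are
thresholded independently (cross-platform signals are not comparable and
no normalization is attempted); a gene expressed in any selected
resource counts as expressed (OR semantics, with an AND mode for
stringent use).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ppinet.consolidate import Interactome
from ppinet.go_annotations import AnnotationSet, TermSelection, annotated_genes


@dataclass
class ExpressionProfile:
    """One expression resource with its own threshold.

    A gene passes this resource iff its value exceeds ``threshold``
    (strictly by default; set ``inclusive`` for >=) and, when both a
    p-value column and ``pvalue_threshold`` are present, its p-value is
    at most that threshold. Genes absent from the table never pass —
    missing data is not imputed.
    """

    resource: str
    values: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] | None = None
    threshold: float = 0.0
    pvalue_threshold: float | None = None
    inclusive: bool = False

    def passes(self, gene: str) -> bool:
        if gene not in self.values:
            return False
        v = self.values[gene]
        ok = v >= self.threshold if self.inclusive else v > self.threshold
        if ok and self.pvalue_threshold is not None:
            p = (self.pvalues or {}).get(gene)
            ok = p is not None and p <= self.pvalue_threshold
        return ok

    @classmethod
    def load(cls, path: str | Path, resource: str | None = None,
             threshold: float = 0.0,
             pvalue_threshold: float | None = None,
             inclusive: bool = False) -> "ExpressionProfile":
        """Load a TSV with columns gene, value[, pvalue]. A first line
        whose value column is not numeric is treated as a header."""
        values: dict[str, float] = {}
        pvalues: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                value = float(cols[1])
            except (IndexError, ValueError):
                continue  # header or malformed row
            values[cols[0]] = value
            if len(cols) > 2 and cols[2]:
                pvalues[cols[0]] = float(cols[2])
        return cls(resource=resource or Path(path).stem, values=values,
                   pvalues=pvalues or None, threshold=threshold,
                   pvalue_threshold=pvalue_threshold, inclusive=inclusive)


@dataclass
class ContextSpec:
    """The cellular context to filter by: expression profiles and/or a
    set of GO terms. At least one filter must be present when filtering
    is requested."""

    profiles: list[ExpressionProfile] = field(default_factory=list)
    go_terms: frozenset[str] | None = None

    def is_empty(self) -> bool:
        return not self.profiles and not self.go_terms


def expressed_genes(profiles: Sequence[ExpressionProfile],
                    mode: str = "any") -> set[str]:
    """Genes considered expressed across the selected resources.

    ``mode='any'`` (default): expressed in at least one resource.
    ``mode='all'``: must pass every resource (stringent).
    """
    if not profiles:
        raise ValueError("at least one expression profile is required")
    if mode not in {"any", "all"}:
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    universe = set().union(*(p.values.keys() for p in profiles))
    if mode == "any":
        return {g for g in universe if any(p.passes(g) for p in profiles)}
    return {g for g in universe if all(p.passes(g) for p in profiles)}


def filter_by_expression(net: Interactome,
                         profiles: Sequence[ExpressionProfile],
                         mode: str = "any") -> Interactome:
    """Keep edges whose BOTH endpoints are expressed; evidence and
    weights are carried through unchanged."""
    expressed = expressed_genes(profiles, mode=mode)
    keep = [pair for pair, _ in net.edges()
            if pair[0] in expressed and pair[1] in expressed]
    return net.subset(keep)


def filter_by_go(net: Interactome, ann: AnnotationSet,
                 terms: Iterable[str],
                 ancestors=None) -> Interactome:
    """Keep edges whose BOTH endpoints carry at least one direct
    annotation among ``terms`` (ancestor propagation optional)."""
    sel = TermSelection(terms=frozenset(terms))
    annotated = annotated_genes(ann, sel, ancestors=ancestors)
    keep = [pair for pair, _ in net.edges()
            if pair[0] in annotated and pair[1] in annotated]
    return net.subset(keep)


def filter_by_context(net: Interactome, context: ContextSpec,
                      ann: AnnotationSet | None = None,
                      mode: str = "any") -> Interactome:
    """Apply every filter in the context spec (the filters commute)."""
    out = net
    if context.profiles:
        out = filter_by_expression(out, context.profiles, mode=mode)
    if context.go_terms:
        if ann is None:
            raise ValueError("GO filtering requires an annotation set")
        out = filter_by_go(out, ann, context.go_terms)
    return out
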