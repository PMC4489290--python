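"""Gene Ontology annotations: loading, selection filters, keyword ranking.

Annotations are read from local tables (4-column TSV or a GAF 2.x
subset) rather than fetched live, so every run is reproducible offline.
"Annotated to a term" means direct annotation by default; annotation via
GO-graph ancestors is available behind an explicit ``ancestors`` argument.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: GO evidence codes recognized for the pass-through warning in
#: :func:`load_annotations`. EXP-family codes are experimental; IEA is
#: electronic inference.
KNOWN_EVIDENCE_CODES = frozenset({
    "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
    "HTP", "HDA", "HMP", "HGI", "HEP",
    "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
    "TAS", "NAS", "IC", "ND", "IEA",
})

#: Words excluded from keyword ranking; the keyword list is meant to hold
#: content words, not connectives or the ubiquitous GO framing terms.
KEYWORD_STOPWORDS = frozenset({
    "of", "to", "the", "via", "process", "activity",
    "and", "or", "in", "by", "a", "an", "with", "from",
})

#: Fixed, documented affix lists for the lightweight stemmer. Longest
#: suffix wins; one suffix and one prefix at most are stripped.
STEM_SUFFIXES = ("ation", "ing", "ion", "es", "s")
STEM_PREFIXES = ("de", "re")


@dataclass
class TermInfo:
    description: str = ""
    size: int = 0


@dataclass
class AnnotationSet:
    """GO annotations: gene -> {(term, evidence code)} plus per-term
    description and annotated-gene count.

    The ``size`` stored for a term always equals the number of distinct
    genes carrying it in ``gene_terms``.
    """

    gene_terms: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    term_info: dict[str, TermInfo] = field(default_factory=dict)

    def add(self, gene: str, term: str, evidence: str = "") -> None:
        anns = self.gene_terms.setdefault(gene, set())
        info = self.term_info.setdefault(term, TermInfo())
        had_term = any(t == term for t, _ in anns)
        anns.add((term, evidence))
        if not had_term:
            info.size += 1

    def set_description(self, term: str, description: str) -> None:
        self.term_info.setdefault(term, TermInfo()).description = description

    def terms_of(self, gene: str) -> set[str]:
        return {t for t, _ in self.gene_terms.get(gene, set())}

    def term_size(self, term: str) -> int:
        info = self.term_info.get(term)
        return info.size if info else 0

    def genes(self) -> set[str]:
        return set(self.gene_terms)


@dataclass(frozen=True)
class TermSelection:
    """A GO-term selection with optional breadth and evidence limits.

    ``max_term_size`` drops terms annotated to more genes than the limit
    (terms that broad carry little specificity); ``allowed_evidence``
    restricts which annotations count (all codes count when unset).
    """

    terms: frozenset[str]
    max_term_size: int | None = None
    allowed_evidence: frozenset[str] | None = None

    def effective_terms(self, ann: AnnotationSet) -> frozenset[str]:
        if self.max_term_size is None:
            return self.terms
        return frozenset(t for t in self.terms
                         if ann.term_size(t) <= self.max_term_size)


def _looks_like_gaf(lines: list[str]) -> bool:
    if any(line.startswith("!") for line in lines[:5]):
        return True
    for line in lines:
        if line.strip() and not line.startswith("#"):
            return len(line.split("\t")) >= 15
    return False


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load gene -> GO-term annotations from a local table.

    Accepts either a 4-column TSV (gene, term, evidence, aspect) or a
    GAF 2.x file (gene from the DB-object-ID column, term from column 5,
    evidence from column 7). Duplicate rows are idempotent; unknown
    evidence codes pass through with a warning.
    """
    lines = Path(path).read_text().splitlines()
    gaf = _looks_like_gaf(lines)
    ann = AnnotationSet()
    unknown: set[str] = set()
    for line in lines:
        if not line.strip() or line.startswith(("#", "!")):
            continue
        cols = line.rstrip("\n").split("\t")
        if gaf:
            gene, term, evidence = cols[1], cols[4], cols[6]
        else:
            if len(cols) < 2:
                raise ValueError(f"annotation row needs >=2 columns: {line!r}")
            gene, term = cols[0], cols[1]
            evidence = cols[2] if len(cols) > 2 else ""
        if evidence and evidence not in KNOWN_EVIDENCE_CODES:
            unknown.add(evidence)
        ann.add(gene, term, evidence)
    if unknown:
        logger.warning("unknown evidence codes passed through: %s",
                       sorted(unknown))
    return ann


def load_term_descriptions(path: str | Path,
                           ann: AnnotationSet | None = None
                           ) -> dict[str, str]:
    """Load a 2-column TSV (term, description); optionally attach the
    descriptions to an existing :class:`AnnotationSet`."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            continue
        out[cols[0]] = cols[1]
        if ann is not None:
            ann.set_description(cols[0], cols[1])
    return out


def annotated_genes(
    ann: AnnotationSet,
    sel: TermSelection,
    ancestors: Mapping[str, set[str]] | None = None,
) -> set[str]:
    """Genes carrying at least one annotation to a selected term.

    An annotation counts iff its term is in the selection after the
    term-size limit and its evidence code is allowed. When ``ancestors``
    is given (term -> set of ancestor terms), an annotation to a term also
    counts toward every ancestor of that term (GO-graph propagation,
    off by default).
    """
    if not sel.terms:
        raise ValueError("term selection is empty")
    effective = sel.effective_terms(ann)
    out: set[str] = set()
    for gene, anns in ann.gene_terms.items():
        for term, evidence in anns:
            if sel.allowed_evidence is not None \
                    and evidence not in sel.allowed_evidence:
                continue
            reachable = {term}
            if ancestors is not None:
                reachable |= ancestors.get(term, set())
            if reachable & effective:
                out.add(gene)
                break
    return out


def stem(token: str) -> str:
    """Strip one documented prefix and one documented suffix from a
    lower-cased token. Deliberately lightweight: the goal is only to
    merge trivial inflection variants (``signaling``/``signal``), not
    full morphological analysis."""
    token = token.lower()
    for prefix in STEM_PREFIXES:
        if token.startswith(prefix) and len(token) - len(prefix) >= 4:
            token = token[len(prefix):]
            break
    for suffix in STEM_SUFFIXES:
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            token = token[: -len(suffix)]
            break
    return token


def extract_keywords(
    term_info: Mapping[str, TermInfo] | Mapping[str, str],
    k: int,
) -> list[str]:
    """Rank keywords by the number of distinct GO terms whose description
    contains them, and return the top ``k``.

    Description tokens are lower-cased, stripped of documented affixes
    and stop words, and de-duplicated within each term, so a word
    repeated inside one description still counts that term once. Ties
    break alphabetically.
    """
    if k <= 0:
        return []
    counts: dict[str, int] = {}
    for info in term_info.values():
        desc = info.description if isinstance(info, TermInfo) else info
        tokens = re.findall(r"[A-Za-z]+", desc.lower())
        stems = {stem(t) for t in tokens
                 if t not in KEYWORD_STOPWORDS} - {""}
        for s in stems:
            counts[s] = counts.get(s, 0) + 1
    ranked = sorted(counts, key=lambda w: (-counts[w], w))
    return ranked[:k]
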