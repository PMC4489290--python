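"""Two-step Bayesian reliability scoring of interactions.

Step one anchors the scheme to biology: a user-selected set of GO terms
defines a positive reference set (edges whose two endpoints are both
annotated to the selected terms) and a negative reference set (edges
whose endpoints are both unannotated). Each combined detection method
``m`` then earns a likelihood ratio

    lr(m) = ((TP + a) / (|P| + 2a)) / ((FP + a) / (|N| + 2a))

where TP / FP count the positive / negative edges the method detected
and ``a`` is a Laplace pseudocount (default 1) that keeps every ratio
finite and strictly positive.

Step two weights each edge by naive-Bayes combination of its methods:
L = prod over distinct combined methods of lr(m), and

    weight = pi * L / (pi * L + 1 - pi)

with prior ``pi`` (default 0.5, so weight = L / (L + 1)). Because the
consolidation step records each PSI-MI accession at most once per edge,
and grouping de-duplicates accessions into combined methods, overlapping
evidence never double-counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from ppinet.consolidate import Interactome
from ppinet.go_annotations import AnnotationSet, TermSelection, annotated_genes

logger = logging.getLogger(__name__)

#: Fixed histogram bin edges for the weight-distribution diagram.
WEIGHT_BINS = [i * 0.05 for i in range(21)]


class ReferenceSetError(ValueError):
    """Raised when the GO term selection yields an unusable reference set."""


@dataclass(frozen=True)
class MethodGrouping:
    """Mapping PSI-MI accession -> combined-method label.

    Sparse detection methods that differ only slightly are scored under
    one shared label so their likelihood ratios rest on enough edges.
    Accessions without a group entry fall back to themselves.
    """

    group_of: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, accession: str) -> str:
        return self.group_of.get(accession, accession)

    @classmethod
    def load(cls, path: str | Path) -> "MethodGrouping":
        """Load a 2-column TSV (MI accession, combined-method label)."""
        group_of: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"grouping row needs 2 columns: {line!r}")
            group_of[cols[0]] = cols[1]
        return cls(group_of=group_of)

    @classmethod
    def default(cls) -> "MethodGrouping":
        path = resources.files("ppinet.data").joinpath("method_grouping.tsv")
        group_of: dict[str, str] = {}
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            mi, label = line.rstrip("\n").split("\t")[:2]
            group_of[mi] = label
        return cls(group_of=group_of)


@dataclass
class ReferenceSets:
    """Positive and negative reference edge sets (canonical pairs)."""

    positive: set[tuple[str, str]]
    negative: set[tuple[str, str]]

    def __post_init__(self) -> None:
        overlap = self.positive & self.negative
        if overlap:
            raise ValueError(f"reference sets overlap: {sorted(overlap)[:3]}")


@dataclass
class MethodScores:
    """Per-combined-method likelihood ratios plus the scoring parameters."""

    lr: dict[str, float]
    pseudocount: float = 1.0
    prior: float = 0.5

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not 0 < self.prior < 1:
            raise ValueError("prior must lie in (0, 1)")


def group_methods(methods: Iterable[str],
                  grouping: MethodGrouping) -> set[str]:
    """Image of a PSI-MI accession set under the grouping, de-duplicated."""
    return {grouping[m] for m in methods}


def build_reference_sets(net: Interactome, ann: AnnotationSet,
                         sel: TermSelection,
                         ancestors=None) -> ReferenceSets:
    """Split interactome edges into positive / negative reference sets.

    Positive: both endpoints annotated to the selected GO terms.
    Negative: neither endpoint annotated. Edges with exactly one
    annotated endpoint belong to neither set (their label would be
    ambiguous and would contaminate the ratios).

    Raises
    ------
    ReferenceSetError
        If either set comes out empty — the term selection must then be
        broadened (more positives) or narrowed (more negatives).
    """
    annotated = annotated_genes(ann, sel, ancestors=ancestors)
    positive: set[tuple[str, str]] = set()
    negative: set[tuple[str, str]] = set()
    for (a, b), _ in net.edges():
        in_a, in_b = a in annotated, b in annotated
        if in_a and in_b:
            positive.add((a, b))
        elif not in_a and not in_b:
            negative.add((a, b))
    if not positive:
        raise ReferenceSetError(
            "positive reference set is empty: broaden the selected GO terms "
            "or relax the evidence/term-size limits")
    if not negative:
        raise ReferenceSetError(
            "negative reference set is empty: narrow the selected GO terms "
            "so some edges have no annotated endpoint")
    return ReferenceSets(positive=positive, negative=negative)


def score_methods(net: Interactome, refs: ReferenceSets,
                  grouping: MethodGrouping,
                  pseudocount: float = 1.0,
                  prior: float = 0.5) -> MethodScores:
    """Likelihood ratio of every combined method observed in the network.

    For method ``m`` with TP positive-set detections out of ``|P|`` and
    FP negative-set detections out of ``|N|``, the pseudocounted ratio is
    ``((TP+a)/(|P|+2a)) / ((FP+a)/(|N|+2a))`` — finite and strictly
    positive for every method, including ones never seen in either set.
    """
    n_pos, n_neg = len(refs.positive), len(refs.negative)
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    observed: set[str] = set()
    for pair, ev in net.edges():
        groups = group_methods(ev.methods, grouping)
        observed |= groups
        if pair in refs.positive:
            for g in groups:
                tp[g] = tp.get(g, 0) + 1
        elif pair in refs.negative:
            for g in groups:
                fp[g] = fp.get(g, 0) + 1
    a = pseudocount
    lr = {
        g: ((tp.get(g, 0) + a) / (n_pos + 2 * a))
           / ((fp.get(g, 0) + a) / (n_neg + 2 * a))
        for g in observed
    }
    return MethodScores(lr=lr, pseudocount=pseudocount, prior=prior)


def score_interaction(groups: Iterable[str],
                      scores: MethodScores) -> float:
    """Posterior weight of one edge from its combined-method labels.

    Each distinct label contributes its likelihood ratio exactly once;
    a label without a score (never observed during method scoring) is
    treated as uninformative (lr = 1) with a warning.
    """
    groups = set(groups)
    if not groups:
        raise ValueError("an edge must carry at least one detection method")
    L = 1.0
    for g in groups:
        if g in scores.lr:
            L *= scores.lr[g]
        else:
            logger.warning("method group %r has no score; treated as lr=1", g)
    pi = scores.prior
    return pi * L / (pi * L + (1.0 - pi))


def weight_histogram(weights: Iterable[float]) -> list[int]:
    """Counts over the 20 fixed bins on [0, 1], right-closed.

    A weight w falls in bin i iff ``WEIGHT_BINS[i] < w <= WEIGHT_BINS[i+1]``
    (w == 0 joins the first bin)."""
    counts = [0] * (len(WEIGHT_BINS) - 1)
    edges = np.asarray(WEIGHT_BINS)
    for w in weights:
        i = int(np.searchsorted(edges, w, side="left")) - 1
        counts[max(i, 0)] += 1
    return counts


def score_interactome(
    net: Interactome,
    ann: AnnotationSet,
    sel: TermSelection,
    grouping: MethodGrouping | None = None,
    pseudocount: float = 1.0,
    prior: float = 0.5,
    ancestors=None,
) -> tuple[Interactome, list[int]]:
    """Weight every edge of the interactome; return the weighted network
    and the weight histogram over the fixed bins.

    The input network is not modified.
    """
    if grouping is None:
        grouping = MethodGrouping.default()
    refs = build_reference_sets(net, ann, sel, ancestors=ancestors)
    scores = score_methods(net, refs, grouping,
                           pseudocount=pseudocount, prior=prior)
    out = net.copy()
    weights = []
    for pair, ev in out.edges():
        w = score_interaction(group_methods(ev.methods, grouping), scores)
        ev.weight = w
        weights.append(w)
    return out, weight_histogram(weights)
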