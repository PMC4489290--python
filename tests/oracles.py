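"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles on plain dicts/sets and
deliberately shares no code path with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations


def brute_consolidate(records):
    """Multiset union of records into canonical-pair -> (methods, sources).

    ``records`` is an iterable of (a, b, methods, source) tuples.
    """
    edges = {}
    for a, b, methods, source in records:
        pair = tuple(sorted((a, b)))
        m, s = edges.setdefault(pair, (set(), set()))
        m.update(methods)
        if source:
            s.add(source)
    return edges


def brute_reference_sets(edges, annotated):
    """Partition edges into positive / negative / mixed by endpoint
    annotation (both / neither / exactly one)."""
    positive, negative, mixed = set(), set(), set()
    for a, b in edges:
        n_in = (a in annotated) + (b in annotated)
        {2: positive, 0: negative, 1: mixed}[n_in].add((a, b))
    return positive, negative, mixed


def brute_method_lr(edge_methods, positive, negative, group_of, alpha=1.0):
    """Per-combined-method likelihood ratio by direct enumeration.

    ``edge_methods`` maps canonical pair -> set of PSI-MI accessions;
    ``group_of`` maps accession -> label (identity when absent).
    """
    def groups(pair):
        return {group_of.get(m, m) for m in edge_methods[pair]}

    all_groups = set()
    for pair in edge_methods:
        all_groups |= groups(pair)
    lr = {}
    for g in all_groups:
        tp = sum(1 for p in positive if g in groups(p))
        fp = sum(1 for p in negative if g in groups(p))
        lr[g] = ((tp + alpha) / (len(positive) + 2 * alpha)) \
            / ((fp + alpha) / (len(negative) + 2 * alpha))
    return lr


def brute_weight(groups, lr, prior=0.5):
    """Naive-Bayes posterior from per-group likelihood ratios."""
    L = 1.0
    for g in set(groups):
        L *= lr.get(g, 1.0)
    return prior * L / (prior * L + (1.0 - prior))


def brute_components(nodes, edges):
    """Connected-component count by label propagation to a fixpoint."""
    label = {v: v for v in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            small = min(label[a], label[b])
            for v in (a, b):
                if label[v] != small:
                    label[v] = small
                    changed = True
        # propagate through chains
        for v in nodes:
            if label[label[v]] != label[v]:
                label[v] = label[label[v]]
                changed = True
    return len(set(label.values()))


def brute_avg_clustering(nodes, edges):
    """Average clustering by direct triangle enumeration; self-loops are
    ignored and nodes with fewer than two neighbors contribute zero."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    if not nodes:
        return 0.0
    total = 0.0
    for v in nodes:
        neigh = adj[v]
        d = len(neigh)
        if d < 2:
            continue
        links = sum(1 for x, y in combinations(sorted(neigh), 2)
                    if y in adj[x])
        total += 2.0 * links / (d * (d - 1))
    return total / len(nodes)
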