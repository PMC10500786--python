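"""Independent brute-force oracles used by the tests.

These deliberately re-derive results through different machinery than the
package: relationship labels via networkx path queries over the parent
graph, the double-entry correlation via the raw moment formula, and the
one-way ANOVA ICC(1) estimator.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from famres.pedigree import Pedigree


def brute_force_labels(ped: Pedigree, fid: str) -> dict[frozenset, str]:
    """Relation label per unordered pair, by explicit predicate testing.

    Builds the parent->child digraph with networkx and tests each relation
    predicate over all pairs, applying the same precedence the package
    documents (spouse > parent-offspring > full sib > half sib >
    grandparent > avuncular > cousin).  Labels are sex-agnostic relation
    kinds; use them to compare groupings, not sexed naming.
    """
    members = ped.family_members(fid)
    g = nx.DiGraph()
    g.add_nodes_from(m.iid for m in members)
    for m in members:
        for p in (m.father, m.mother):
            if p is not None:
                g.add_edge(p, m.iid)

    def parents(x):
        return set(g.predecessors(x))

    def full_sib(x, y):
        px, py = parents(x), parents(y)
        return len(px) == 2 and px == py

    def half_sib(x, y):
        return len(parents(x) & parents(y)) == 1

    def predicate(x, y):
        if set(g.successors(x)) & set(g.successors(y)):
            return "spouse"
        if g.has_edge(x, y) or g.has_edge(y, x):
            return "parent-offspring"
        if full_sib(x, y):
            return "full-sibling"
        if half_sib(x, y):
            return "half-sibling"
        for a, b in ((x, y), (y, x)):
            if any(
                len(p) == 3 for p in nx.all_simple_paths(g, a, b, cutoff=2)
            ):
                return "grandparent"
        for a, b in ((x, y), (y, x)):
            if any(full_sib(a, p) for p in parents(b)):
                return "avuncular"
        if any(
            pa != pb and full_sib(pa, pb)
            for pa in parents(x)
            for pb in parents(y)
        ):
            return "cousin"
        return None

    out = {}
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            label = predicate(a.iid, b.iid)
            if label is not None:
                out[frozenset((a.iid, b.iid))] = label
    return out


def double_entry_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Double-entry intraclass correlation from raw moments."""
    xs = np.concatenate([x, y])
    ys = np.concatenate([y, x])
    mx, my = xs.mean(), ys.mean()
    num = ((xs - mx) * (ys - my)).sum()
    den = np.sqrt(((xs - mx) ** 2).sum() * ((ys - my) ** 2).sum())
    return float(num / den)


def anova_icc1(x: np.ndarray, y: np.ndarray) -> float:
    """One-way random-effects ICC(1) for pairs (k = 2 members per group)."""
    data = np.column_stack([x, y])
    n = data.shape[0]
    grand = data.mean()
    group_means = data.mean(axis=1)
    msb = 2.0 * ((group_means - grand) ** 2).sum() / (n - 1)
    msw = ((data - group_means[:, None]) ** 2).sum() / n
    return float((msb - msw) / (msb + msw))
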