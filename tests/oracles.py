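"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: exhaustive
enumeration over internal-state labelings for parsimony, direct clade
counting for loss-only reconstruction, and direct summation for binomial
tails.
"""

from __future__ import annotations

import itertools
import math

PRESENT, ABSENT = "present", "absent"


def _label(nd):
    return nd.taxon.label if nd.taxon is not None else nd.label


def _clade(nd):
    if nd.is_leaf():
        return (_label(nd),)
    return tuple(sorted(_label(l) for l in nd.leaf_iter()))


def brute_force_histories(tree, pattern):
    """All minimum-event histories by exhaustive labeling of internal nodes
    (and unknown leaves).  Returns a set of (root_state, frozenset of
    (kind, clade)) pairs and the minimum cost."""
    nodes = list(tree.preorder_node_iter())
    fixed = {}
    free = []
    for nd in nodes:
        if nd.is_leaf() and pattern.get(_label(nd)) in (PRESENT, ABSENT):
            fixed[id(nd)] = pattern[_label(nd)]
        else:
            free.append(nd)
    best = math.inf
    out = set()
    for combo in itertools.product((PRESENT, ABSENT), repeat=len(free)):
        assign = dict(fixed)
        assign.update({id(nd): s for nd, s in zip(free, combo)})
        cost = 0
        events = []
        for nd in nodes:
            if nd.parent_node is None:
                continue
            ps, cs = assign[id(nd.parent_node)], assign[id(nd)]
            if ps != cs:
                cost += 1
                kind = "loss" if cs == ABSENT else "gain"
                events.append((kind, _clade(nd)))
        if cost < best:
            best = cost
            out = set()
        if cost == best:
            out.add((assign[id(tree.seed_node)], frozenset(events)))
    return out, best


def maximal_absent_clades(tree, pattern):
    """Number of maximal clades whose known leaves are all absent and that
    contain at least one absent leaf (loss-only reconstruction count when an
    outgroup keeps the root present)."""
    def status(nd):
        # 'absent' if every known leaf below is absent (and one exists)
        leaves = [l for l in nd.leaf_iter()]
        states = [pattern.get(_label(l)) for l in leaves]
        known = [s for s in states if s in (PRESENT, ABSENT)]
        if not known:
            return "unknown"
        return ABSENT if all(s == ABSENT for s in known) else "mixed"

    count = 0

    def walk(nd, covered):
        nonlocal count
        if not covered and status(nd) == ABSENT:
            count += 1
            covered = True
        for ch in nd.child_nodes():
            walk(ch, covered)

    walk(tree.seed_node, False)
    return count


def binomial_upper_tail(k, n, p):
    """P(X >= k) by direct summation."""
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


def random_tree_newick(rng, n_leaves):
    """Random (possibly multifurcating) rooted tree over a1..aN."""
    labels = [f"a{i}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(items):
        if len(items) == 1:
            return items[0]
        k = min(len(items), int(rng.integers(2, 4)))
        parts = [[] for _ in range(k)]
        for i, it in enumerate(items):
            parts[i % k].append(it)
        parts = [p for p in parts if p]
        if len(parts) == 1:
            return build(parts[0])
        return "(" + ",".join(build(p) for p in parts) + ")"

    return build(labels) + ";"
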