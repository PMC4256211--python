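"""Unrestricted-parsimony reconstruction of intron loss/gain histories.

Given a rooted gene tree (polytomies allowed) and a leaf presence/absence
pattern, the engine enumerates *every* minimum-event history: an assignment
of present/absent to the root plus a set of (branch, loss|gain) events, each
costing one, that replays the observed leaf states.  Unknown leaves
(unalignable or missing genes) impose no constraint.  The root state is
free -- an outgroup leaf fixes it only through parsimony itself.

A branch is identified by the frozenset of leaf labels below it, which makes
histories comparable across re-rootings and outgroup augmentation.

Dollo mode (``gain_cost=inf``) disallows gains; the minimum loss count then
equals the number of maximal absent-leaf clades.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .species import DatedSpeciesTree

PRESENT, ABSENT = "present", "absent"


@dataclass(frozen=True, order=True)
class Event:
    """A state change on the branch above the clade ``clade``."""

    kind: str                    # "loss" | "gain"
    clade: tuple[str, ...]       # sorted leaf labels below the branch

    def __repr__(self) -> str:
        return f"{self.kind}@{{{','.join(self.clade)}}}"


@dataclass(frozen=True)
class EventHistory:
    root_state: str
    events: frozenset[Event]

    @property
    def cost(self) -> int:
        return len(self.events)

    @property
    def losses(self) -> int:
        return sum(e.kind == "loss" for e in self.events)

    @property
    def gains(self) -> int:
        return sum(e.kind == "gain" for e in self.events)

    def sorted_events(self) -> list[Event]:
        return sorted(self.events)

    def replay(self, tree: dendropy.Tree) -> dict[str, str]:
        """Apply the events from the root down; returns leaf -> state."""
        by_clade = {e.clade: e.kind for e in self.events}
        out: dict[str, str] = {}

        def walk(node: dendropy.Node, state: str) -> None:
            clade = _clade_key(node)
            kind = by_clade.get(clade)
            if kind == "loss":
                state = ABSENT
            elif kind == "gain":
                state = PRESENT
            if node.is_leaf():
                out[clade[0]] = state
            else:
                for ch in node.child_nodes():
                    walk(ch, state)

        root = tree.seed_node
        walk(root, self.root_state)
        return out


class TooManyHistories(RuntimeError):
    """Optimal-history enumeration exceeded the cap."""


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _clade_key(node: dendropy.Node) -> tuple[str, ...]:
    if node.is_leaf():
        return (_leaf_label(node),)
    return tuple(sorted(_leaf_label(l) for l in node.leaf_iter()))


def enumerate_min_histories(tree: dendropy.Tree,
                            pattern: Mapping[str, str],
                            loss_cost: float = 1.0,
                            gain_cost: float = 1.0,
                            max_histories: int = 10000
                            ) -> list[EventHistory]:
    """All minimum-total-cost histories of ``pattern`` on ``tree``.

    ``pattern`` maps leaf labels to ``present``/``absent``; labels that are
    missing or mapped to anything else are treated as unknown.  Histories are
    canonical (events keyed by clade leafsets) so equality tests uniqueness.
    """
    leaves = [_leaf_label(l) for l in tree.leaf_node_iter()]
    known = {l: pattern[l] for l in leaves
             if pattern.get(l) in (PRESENT, ABSENT)}
    if not known:
        raise ValueError("pattern has no known-state leaf")

    S = (ABSENT, PRESENT)
    INF = math.inf

    def trans(parent: str, child: str) -> float:
        if parent == child:
            return 0.0
        return loss_cost if child == ABSENT else gain_cost

    cost: dict[int, dict[str, float]] = {}
    nodes = list(tree.postorder_node_iter())
    for nd in nodes:
        if nd.is_leaf():
            lab = _leaf_label(nd)
            if lab in known:
                cost[id(nd)] = {s: (0.0 if s == known[lab] else INF) for s in S}
            else:
                cost[id(nd)] = {s: 0.0 for s in S}
        else:
            c: dict[str, float] = {}
            for s in S:
                tot = 0.0
                for ch in nd.child_nodes():
                    tot += min(cost[id(ch)][cs] + trans(s, cs) for cs in S)
                c[s] = tot
            cost[id(nd)] = c

    root = tree.seed_node
    best = min(cost[id(root)][s] for s in S)
    if not math.isfinite(best):
        raise ValueError("pattern is unreachable under the given event costs")

    memo: dict[tuple[int, str], list[frozenset[Event]]] = {}

    def frags(nd: dendropy.Node, state: str) -> list[frozenset[Event]]:
        key = (id(nd), state)
        if key in memo:
            return memo[key]
        if nd.is_leaf():
            memo[key] = [frozenset()]
            return memo[key]
        per_child: list[list[frozenset[Event]]] = []
        for ch in nd.child_nodes():
            target = min(cost[id(ch)][cs] + trans(state, cs) for cs in S)
            opts: list[frozenset[Event]] = []
            for cs in S:
                if cost[id(ch)][cs] + trans(state, cs) != target:
                    continue
                edge_event: frozenset[Event] = frozenset()
                if cs != state:
                    kind = "loss" if cs == ABSENT else "gain"
                    edge_event = frozenset({Event(kind, _clade_key(ch))})
                for sub in frags(ch, cs):
                    opts.append(sub | edge_event)
            # identical event sets can arise via different hidden states
            per_child.append(list(dict.fromkeys(opts)))
        combined: set[frozenset[Event]] = set()
        for combo in itertools.product(*per_child):
            u = frozenset().union(*combo) if combo else frozenset()
            combined.add(u)
            if len(combined) > max_histories:
                raise TooManyHistories(
                    f"more than {max_histories} optimal histories")
        memo[key] = sorted(combined, key=lambda fs: sorted(fs))
        return memo[key]

    histories: list[EventHistory] = []
    seen: set[tuple[str, frozenset[Event]]] = set()
    for s in S:
        if cost[id(root)][s] != best:
            continue
        for ev in frags(root, s):
            key = (s, ev)
            if key not in seen:
                seen.add(key)
                histories.append(EventHistory(s, ev))
    histories.sort(key=lambda h: (h.root_state, h.sorted_events()))
    return histories


def min_dollo_losses(tree: dendropy.Tree, pattern: Mapping[str, str]) -> int:
    """Minimum loss count with gains disallowed (root forced by parsimony)."""
    hists = enumerate_min_histories(tree, pattern, gain_cost=math.inf)
    return hists[0].cost


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

CATEGORIES = ("single_loss", "single_gain", "recurrent_loss",
              "recurrent_gain", "mixed", "conserved", "unresolved")


@dataclass
class GroupClassification:
    category: str
    histories: list[EventHistory]
    mixed_order: str | None = None      # loss_then_gain | gain_then_loss
    affected: tuple[str, ...] = ()

    @property
    def history(self) -> EventHistory | None:
        return self.histories[0] if len(self.histories) == 1 else None

    @property
    def n_events(self) -> int | None:
        h = self.history
        return h.cost if h is not None else None


def classify_group(histories: Sequence[EventHistory]) -> GroupClassification:
    """Category by event composition of the unique minimum history; more
    than one minimum history means unresolved."""
    if not histories:
        raise ValueError("empty history set")
    if len(histories) > 1:
        return GroupClassification("unresolved", list(histories))
    h = histories[0]
    nl, ng = h.losses, h.gains
    affected = tuple(sorted({leaf for e in h.events for leaf in e.clade}))
    if nl == 0 and ng == 0:
        return GroupClassification("conserved", [h], affected=affected)
    if nl and ng:
        order = _mixed_order(h)
        return GroupClassification("mixed", [h], mixed_order=order,
                                   affected=affected)
    if nl == 1:
        return GroupClassification("single_loss", [h], affected=affected)
    if ng == 1:
        return GroupClassification("single_gain", [h], affected=affected)
    if nl >= 2:
        return GroupClassification("recurrent_loss", [h], affected=affected)
    return GroupClassification("recurrent_gain", [h], affected=affected)


def _mixed_order(h: EventHistory) -> str | None:
    losses = [set(e.clade) for e in h.events if e.kind == "loss"]
    gains = [set(e.clade) for e in h.events if e.kind == "gain"]
    if any(g < l for l in losses for g in gains):
        return "loss_then_gain"
    if any(l < g for l in losses for g in gains):
        return "gain_then_loss"
    return None


# ---------------------------------------------------------------------------
# paralog collapsing and species-branch mapping
# ---------------------------------------------------------------------------

def collapse_paralog_events(classification: GroupClassification,
                            gene_tree: dendropy.Tree,
                            species_of: Mapping[str, str]) -> int:
    """Species-level event count of the resolved history.

    Events already sit on single branches, so a loss shared by a
    species-specific duplicate pair counts once by construction.  As a
    defensive normalization, two same-type events on sibling terminal
    branches of a same-species pair are merged into one.
    """
    h = classification.history
    if h is None:
        raise ValueError("classification is not resolved")
    parent_of: dict[str, dendropy.Node] = {}
    for leaf in gene_tree.leaf_node_iter():
        parent_of[_leaf_label(leaf)] = leaf.parent_node
    count = len(h.events)
    terminal = [e for e in h.events if len(e.clade) == 1]
    merged: set[Event] = set()
    for a, b in itertools.combinations(terminal, 2):
        if b in merged or a in merged or a.kind != b.kind:
            continue
        la, lb = a.clade[0], b.clade[0]
        if (species_of.get(la) == species_of.get(lb)
                and parent_of.get(la) is parent_of.get(lb)
                and parent_of.get(la) is not None):
            merged.add(b)
    return count - len(merged)


def assign_events_to_species_branches(history: EventHistory,
                                      species_of: Mapping[str, str],
                                      species_tree: DatedSpeciesTree
                                      ) -> tuple[list[tuple[str, str]],
                                                 list[Event]]:
    """Map each gene-tree event to a species-tree branch.

    The event maps to the branch above the MRCA of the species under its
    gene-tree branch.  If that MRCA subtends additional species that are
    present in the gene tree (a gene-tree/species-tree conflict), the event
    is flagged unmappable.  Returns ``(mapped, unmappable)`` where mapped
    entries are ``(species_branch_name, kind)``.
    """
    tree_species = {species_of[l] for l in species_of}
    mapped: list[tuple[str, str]] = []
    unmappable: list[Event] = []
    for ev in sorted(history.events):
        sset = {species_of[l] for l in ev.clade}
        node = species_tree.mrca(sset)
        under = species_tree.leafset(node) & tree_species
        if under != sset:
            unmappable.append(ev)
            continue
        name = node.taxon.label if node.taxon else node.label
        mapped.append((name, ev.kind))
    return mapped, unmappable


# ---------------------------------------------------------------------------
# outgroup augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationResult:
    original: GroupClassification
    augmented: GroupClassification | None
    transition: str                      # e.g. "recurrent_gain->recurrent_loss"
    boundary_lost: bool = False


def augment_with_outgroups(original: GroupClassification,
                           augmented_tree: dendropy.Tree,
                           augmented_pattern: Mapping[str, str] | None
                           ) -> AugmentationResult:
    """Re-run enumeration+classification after adding outgroup genes.

    ``augmented_pattern`` is the presence map at the same boundary in the
    augmented alignment (``None`` when the boundary is no longer alignable,
    in which case the original classification is kept and flagged).
    """
    if augmented_pattern is None:
        return AugmentationResult(original, None,
                                  f"{original.category}->boundary_lost",
                                  boundary_lost=True)
    hists = enumerate_min_histories(augmented_tree, augmented_pattern)
    new = classify_group(hists)
    return AugmentationResult(original, new,
                              f"{original.category}->{new.category}")


# ---------------------------------------------------------------------------
# processed-copy (retroposition / cDNA-conversion) candidates
# ---------------------------------------------------------------------------

@dataclass
class ProcessedCopyCandidate:
    cluster_id: str
    clade: tuple[str, ...]
    n_ancestral_introns: int
    label: str                           # cDNA_conversion | retroposition


def detect_processed_copy_clades(cluster_id: str,
                                 gene_tree: dendropy.Tree,
                                 groups: Sequence,
                                 synteny_flags: Mapping[str, bool],
                                 min_introns: int = 8
                                 ) -> list[ProcessedCopyCandidate]:
    """Flag clades missing every one of >= ``min_introns`` ancestral introns.

    An intron is ancestral relative to a clade when some gene outside the
    clade is present at its boundary.  A clade qualifies when all of its
    members verifiably lack all such introns.  Syntenic candidates (every
    member synteny-flagged) are labelled cDNA_conversion, the rest
    retroposition.  Only maximal qualifying clades are reported.
    """
    out: list[ProcessedCopyCandidate] = []
    claimed: set[str] = set()
    for nd in gene_tree.preorder_node_iter():
        clade = _clade_key(nd)
        if nd.parent_node is None or set(clade) <= claimed:
            continue
        n_anc = 0
        ok = True
        for g in groups:
            outside_present = any(m not in clade for m in g.present)
            if not outside_present:
                continue
            n_anc += 1
            if any(g.states.get(m) != "absent" for m in clade):
                ok = False
                break
        if ok and n_anc >= min_introns:
            label = ("cDNA_conversion"
                     if all(synteny_flags.get(m, False) for m in clade)
                     else "retroposition")
            out.append(ProcessedCopyCandidate(cluster_id, clade, n_anc, label))
            claimed.update(clade)
    return out
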