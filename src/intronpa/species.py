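"""Dated species tree for the grass family and its outgroups.

The default tree carries the divergence times used throughout the package
(million years, MY): maize--sorghum 12, +foxtail millet 26, Panicoid--BEP 60,
Brachypodium--rice 47, grasses--Arabidopsis 150.  Deeper splits (banana,
spikemoss, moss) are set to literature-typical ages; they matter only for
simulation and outgroup rooting, never for rate arithmetic on grass branches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

#: 4-letter genome codes, tip order of the grass subtree.
GRASS_SPECIES = ("Zmay", "Sbic", "Sita", "Bdis", "Osat")

#: Outgroup species ranked from shallowest to deepest.
OUTGROUP_RANK = {"Muca": 1, "Atha": 2, "Smoe": 3, "Ppat": 4}

ALL_SPECIES = GRASS_SPECIES + ("Muca", "Atha", "Smoe", "Ppat")

#: Number of analyzed introns per grass genome (used for per-intron rates).
ANALYZED_INTRON_COUNTS = {
    "Bdis": 31685,
    "Osat": 30685,
    "Sbic": 32386,
    "Sita": 33230,
    "Zmay": 37119,
}

_FULL_NEWICK = (
    "(((((((Zmay:12,Sbic:12)Andropogoneae:14,Sita:26)Panicoid:34,"
    "(Bdis:47,Osat:47)BEP:13)Grass:50,Muca:110)Monocot:40,Atha:150)"
    "Angiosperm:250,Smoe:400)Tracheophyte:100,Ppat:500)Root;"
)

_GRASS_NEWICK = (
    "(((Zmay:12,Sbic:12)Andropogoneae:14,Sita:26)Panicoid:34,"
    "(Bdis:47,Osat:47)BEP:13)Grass;"
)

_GRASS_OUTGROUP_NEWICK = (
    "((((Zmay:12,Sbic:12)Andropogoneae:14,Sita:26)Panicoid:34,"
    "(Bdis:47,Osat:47)BEP:13)Grass:90,Atha:150)Angiosperm;"
)


@dataclass
class DatedSpeciesTree:
    """Rooted, ultrametric species tree with branch lengths in MY.

    ``intron_counts`` maps terminal species codes to the number of analyzed
    introns in that genome (for events/intron/year rates).
    """

    tree: dendropy.Tree
    intron_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        self._by_name: dict[str, dendropy.Node] = {}
        for nd in self.tree.preorder_node_iter():
            name = _node_name(nd)
            if name:
                self._by_name[name] = nd

    @classmethod
    def from_newick(cls, newick: str, intron_counts: dict[str, int] | None = None
                    ) -> "DatedSpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=False)
        return cls(tree, dict(intron_counts or {}))

    # -- structure ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace
                      if any(l.taxon is t for l in self.tree.leaf_node_iter()))

    def leaf_labels(self) -> list[str]:
        return [_node_name(l) for l in self.tree.leaf_node_iter()]

    def node(self, name: str) -> dendropy.Node:
        return self._by_name[name]

    def branch_length(self, name: str) -> float:
        nd = self._by_name[name]
        return nd.edge.length if nd.edge.length is not None else 0.0

    def branch_names(self, include_root: bool = False) -> list[str]:
        out = []
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None and not include_root:
                continue
            out.append(_node_name(nd))
        return out

    def mrca(self, species: set[str]) -> dendropy.Node:
        if len(species) == 1:
            (sp,) = species
            return self._by_name[sp]
        return self.tree.mrca(taxon_labels=sorted(species))

    def leafset(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(_node_name(l) for l in node.leaf_iter())

    def check_ultrametric(self, tol: float = 1e-6) -> bool:
        depths: list[float] = []
        for leaf in self.tree.leaf_node_iter():
            d, nd = 0.0, leaf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        return max(depths) - min(depths) <= tol

    def write_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(file=buf, schema="newick",
                        suppress_rooting=True, suppress_annotations=True)
        return buf.getvalue().strip()


def _node_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None and nd.taxon.label:
        return nd.taxon.label
    return nd.label or ""


def default_species_tree(outgroups: bool = True) -> DatedSpeciesTree:
    """The dated tree of the five grasses plus Arabidopsis (and, if
    ``outgroups``, banana/spikemoss/moss)."""
    nwk = _FULL_NEWICK if outgroups else _GRASS_OUTGROUP_NEWICK
    return DatedSpeciesTree.from_newick(nwk, ANALYZED_INTRON_COUNTS)


def grass_tree(with_outgroup: bool = True) -> DatedSpeciesTree:
    """The five-grass subtree, optionally with the Arabidopsis outgroup tip."""
    nwk = _GRASS_OUTGROUP_NEWICK if with_outgroup else _GRASS_NEWICK
    return DatedSpeciesTree.from_newick(nwk, ANALYZED_INTRON_COUNTS)


def species_of_gene(gene_id: str, prefix_map: dict[str, str] | None = None) -> str:
    """Resolve the species code of a gene id.

    By default the id is expected to start with a 4-letter code followed by
    ``_`` (the simulator's convention); a ``prefix_map`` of id-prefix ->
    species code overrides this for real-world id schemes.
    """
    if prefix_map:
        for prefix, code in sorted(prefix_map.items(), key=lambda kv: -len(kv[0])):
            if gene_id.startswith(prefix):
                return code
    head = gene_id.split("_", 1)[0]
    if head in ALL_SPECIES:
        return head
    raise KeyError(f"cannot resolve species of gene id {gene_id!r}")
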