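"""Forward simulator for intron presence/absence evolution on the dated
grass species tree, with full rendering to the pipeline's input formats.

Each cluster starts from one ancestral gene whose exon scaffold carries a
set of intron sites.  Lineages evolve down the species tree (optionally
duplicating); each site runs a continuous-time two-state process: losses at
``loss_rate`` (times ``hot_multiplier`` for hot introns) while present,
(re)gains at ``gain_rate`` while absent.  Only the first realized event per
gene-tree branch takes effect -- exactly what parsimony can ever see.

Rendering is exact by default: member CDS sequences are identical, so the
cluster alignment is gap-free and every true site projects to its true
boundary column.  Opt-in junction noise deletes two CDS bases at a junction
of an intron-absent member, which the detector must score unalignable.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .io_formats import GeneModel
from .groups import revcomp
from .species import (DatedSpeciesTree, GRASS_SPECIES, default_species_tree,
                      grass_tree)

PRESENT, ABSENT = "present", "absent"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic datasets.

    Rates are per intron per million years.  Defaults mirror the observed
    grass regime: a loss rate giving a few percent of sites polymorphic, a
    ~7-fold lower gain rate, a small fraction of "hot" introns with a
    strongly elevated loss rate, and CG-depletion that is weaker in
    loss-prone introns (lower TG/CG in recurrently lost introns).
    """

    n_clusters: int = 200
    mean_introns: float = 4.0           # Poisson, clipped to >= 1
    loss_rate: float = 1e-4
    gain_rate: float = 1.4e-5
    novel_sites_mean: float = 0.15      # ancestrally-absent sites per cluster
    hot_fraction: float = 0.05
    hot_multiplier: float = 20.0
    duplication_rate: float = 0.0005    # per lineage per MY
    min_exon: int = 60                  # bp; also enforces boundary spacing
    max_exon: int = 300
    intron_length_median: float = 300.0
    intron_length_sigma: float = 0.6    # lognormal sigma
    hot_intron_scale: float = 0.6       # hot introns run shorter
    exon_gc: float = 0.55
    intron_gc: float = 0.39
    cg_depletion_cold: float = 0.6      # P(CG -> CA) in cold introns
    cg_depletion_hot: float = 0.3
    deep_outgroups: bool = False        # add Muca/Smoe/Ppat tips
    junction_noise: float = 0.0         # P(2-bp junction deletion | absent)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "gain_rate", "duplication_rate",
                     "novel_sites_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.hot_fraction <= 1:
            raise ValueError("hot_fraction must lie in [0, 1]")

    def species_tree(self) -> DatedSpeciesTree:
        if self.deep_outgroups:
            return default_species_tree(outgroups=True)
        return grass_tree(with_outgroup=True)


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

@dataclass
class GNode:
    """Gene-tree node; ``species_branch`` is the species-tree branch the
    edge above this node runs along."""

    species_branch: str
    length: float
    children: list["GNode"] = field(default_factory=list)
    label: str = ""

    def leaves(self) -> list["GNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def newick(self) -> str:
        def fmt(nd: GNode) -> str:
            if not nd.children:
                return f"{nd.label}:{nd.length:g}"
            inner = ",".join(fmt(c) for c in nd.children)
            return f"({inner}):{nd.length:g}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def _simulate_lineage(sp_node, remaining: float, rate: float,
                      rng: np.random.Generator) -> GNode:
    """One gene lineage travelling down a species-tree branch; may
    duplicate (splitting into two lineages) before reaching the far end."""
    t_dup = rng.exponential(1.0 / rate) if rate > 0 else math.inf
    name = _branch_name(sp_node)
    if t_dup < remaining:
        node = GNode(name, t_dup)
        node.children = [
            _simulate_lineage(sp_node, remaining - t_dup, rate, rng)
            for _ in range(2)]
        return node
    node = GNode(name, remaining)
    if sp_node.child_nodes():
        node.children = [
            _simulate_lineage(ch, ch.edge.length or 0.0, rate, rng)
            for ch in sp_node.child_nodes()]
    return node


def _branch_name(nd) -> str:
    return nd.taxon.label if nd.taxon is not None else (nd.label or "")


def simulate_gene_tree(species_tree: DatedSpeciesTree, cluster_id: str,
                       duplication_rate: float, rng: np.random.Generator
                       ) -> GNode:
    root = GNode(_branch_name(species_tree.tree.seed_node), 0.0)
    root.children = [
        _simulate_lineage(ch, ch.edge.length or 0.0, duplication_rate, rng)
        for ch in species_tree.tree.seed_node.child_nodes()]
    counters: dict[str, int] = {}
    for leaf in root.leaves():
        sp = leaf.species_branch
        counters[sp] = counters.get(sp, 0) + 1
        leaf.label = f"{sp}_{cluster_id}_g{counters[sp]}"
    return root


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    kind: str                       # loss | gain
    species_branch: str
    clade: tuple[str, ...]          # gene-tree leaves below the branch


@dataclass
class SiteTruth:
    cluster_id: str
    site_index: int                 # 0-based within the ancestral scaffold
    breakpoint: int                 # ancestral CDS breakpoint == boundary col
    root_state: str
    hot: bool
    intron_length: int
    events: list[TruthEvent]
    presence: dict[str, bool]       # gene id -> carries the intron

    @property
    def boundary(self) -> int:
        return self.breakpoint

    @property
    def category(self) -> str:
        nl = sum(e.kind == "loss" for e in self.events)
        ng = sum(e.kind == "gain" for e in self.events)
        if not any(self.presence.values()):
            return "invisible"
        if nl == 0 and ng == 0:
            return "conserved"
        if nl and ng:
            return "mixed"
        if nl == 1:
            return "single_loss"
        if ng == 1:
            return "single_gain"
        return "recurrent_loss" if nl else "recurrent_gain"

    def in_scope(self, ingroup: tuple[str, ...] = GRASS_SPECIES) -> bool:
        """Whether the detector analyzes this site: fully conserved, or
        polymorphic among the ingroup (grass) members.  Outgroup-only
        polymorphism is outside the study's scope."""
        if not any(self.presence.values()):
            return False
        if all(self.presence.values()):
            return True
        ing = [p for g, p in self.presence.items()
               if g.split("_", 1)[0] in ingroup]
        return any(ing) and not all(ing)


@dataclass
class ClusterSim:
    cluster_id: str
    gene_tree: GNode
    exon_lengths: list[int]         # ancestral scaffold, S+1 exons
    exon_seqs: list[str]
    sites: list[SiteTruth]
    intron_seqs: list[str]
    noise: dict[tuple[str, int], int] = field(default_factory=dict)
    # (gene, site_index) -> bp deleted at the upstream junction

    @property
    def genes(self) -> list[str]:
        return [l.label for l in self.gene_tree.leaves()]


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    clusters: list[ClusterSim]

    def table(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            for st in cl.sites:
                if st.category == "invisible" or not st.in_scope():
                    continue
                rows.append({
                    "cluster_id": cl.cluster_id,
                    "boundary": st.boundary,
                    "category": st.category,
                    "hot": st.hot,
                    "root_state": st.root_state,
                    "n_events": len(st.events),
                    "events": ";".join(
                        f"{e.kind}@{e.species_branch}" for e in st.events),
                    "present": ",".join(sorted(
                        g for g, p in st.presence.items() if p)),
                    "absent": ",".join(sorted(
                        g for g, p in st.presence.items() if not p)),
                })
        cols = ["cluster_id", "boundary", "category", "hot", "root_state",
                "n_events", "events", "present", "absent"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# history simulation
# ---------------------------------------------------------------------------

def _evolve_site(node: GNode, state: str, loss: float, gain: float,
                 rng: np.random.Generator, events: list[TruthEvent],
                 presence: dict[str, bool]) -> None:
    if node.length > 0:
        rate = loss if state == PRESENT else gain
        t = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if t < node.length:
            state = ABSENT if state == PRESENT else PRESENT
            events.append(TruthEvent(
                "loss" if state == ABSENT else "gain",
                node.species_branch,
                tuple(sorted(l.label for l in node.leaves()))))
    if not node.children:
        presence[node.label] = state == PRESENT
    for ch in node.children:
        _evolve_site(ch, state, loss, gain, rng, events, presence)


def simulate_histories(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> SyntheticTruth:
    """Simulate gene trees and per-site loss/gain histories (no rendering)."""
    rng = rng or np.random.default_rng(config.seed)
    sp = config.species_tree()
    clusters: list[ClusterSim] = []
    for k in range(config.n_clusters):
        cid = f"c{k:04d}"
        gtree = simulate_gene_tree(sp, cid, config.duplication_rate, rng)
        n_anc = max(1, int(rng.poisson(config.mean_introns)))
        n_novel = int(rng.poisson(config.novel_sites_mean))
        n_sites = n_anc + n_novel
        exon_lengths = list(rng.integers(config.min_exon, config.max_exon + 1,
                                         size=n_sites + 1))
        pad = (3 - sum(exon_lengths) % 3) % 3
        exon_lengths[-1] += pad
        novel_idx = set(rng.choice(n_sites, size=n_novel, replace=False)
                        .tolist()) if n_novel else set()
        breakpoints = np.cumsum(exon_lengths[:-1])
        sites: list[SiteTruth] = []
        intron_seqs: list[str] = []
        for j in range(n_sites):
            hot = bool(rng.random() < config.hot_fraction)
            loss = config.loss_rate * (config.hot_multiplier if hot else 1.0)
            root_state = ABSENT if j in novel_idx else PRESENT
            events: list[TruthEvent] = []
            presence: dict[str, bool] = {}
            for ch in gtree.children:
                _evolve_site(ch, root_state, loss, config.gain_rate, rng,
                             events, presence)
            length = _intron_length(config, hot, rng)
            sites.append(SiteTruth(cid, j, int(breakpoints[j]), root_state,
                                   hot, length, events, presence))
            intron_seqs.append(_intron_sequence(config, hot, length, rng))
        exon_seqs = [_random_seq(int(L), config.exon_gc, rng)
                     for L in exon_lengths]
        clusters.append(ClusterSim(cid, gtree, [int(x) for x in exon_lengths],
                                   exon_seqs, sites, intron_seqs))
    return SyntheticTruth(config, clusters)


def _intron_length(config: SimulationConfig, hot: bool,
                   rng: np.random.Generator) -> int:
    med = config.intron_length_median * (config.hot_intron_scale if hot else 1)
    L = int(round(float(rng.lognormal(math.log(med),
                                      config.intron_length_sigma))))
    return max(60, L)


_BASES = np.array(list("ACGT"))


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _intron_sequence(config: SimulationConfig, hot: bool, length: int,
                     rng: np.random.Generator) -> str:
    """GT + body + AG, with CG-dinucleotide depletion (CG -> CA) applied at
    the configured per-category strength."""
    body = list(_random_seq(length - 4, config.intron_gc, rng))
    depl = config.cg_depletion_hot if hot else config.cg_depletion_cold
    for i in range(len(body) - 1):
        if body[i] == "C" and body[i + 1] == "G" and rng.random() < depl:
            body[i + 1] = "A"
    return "GT" + "".join(body) + "AG"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedDataset:
    truth: SyntheticTruth
    genomes: dict[str, dict[str, str]]          # species -> chrom -> seq
    models: dict[str, list[GeneModel]]          # species -> gene models
    cds: dict[str, str]                         # gene -> CDS
    alignments: dict[str, dict[str, str]]       # cluster -> gene -> row
    trees: dict[str, str]                       # cluster -> newick
    clusters: dict[str, list[str]]              # cluster -> gene ids


def render_dataset(truth: SyntheticTruth,
                   rng: np.random.Generator | None = None) -> RenderedDataset:
    """Render gene models, genomes, alignments and trees consistent with the
    simulated histories."""
    config = truth.config
    rng = rng or np.random.default_rng(config.seed + 1)
    if config.junction_noise > 0:
        _inject_noise(truth, rng)

    genomes: dict[str, dict[str, str]] = {}
    models: dict[str, list[GeneModel]] = {}
    cds: dict[str, str] = {}
    alignments: dict[str, dict[str, str]] = {}
    trees: dict[str, str] = {}
    clusters: dict[str, list[str]] = {}
    chrom_parts: dict[str, list[str]] = {}
    offsets: dict[str, int] = {}
    gene_index: dict[str, int] = {}

    for cl in truth.clusters:
        trees[cl.cluster_id] = cl.gene_tree.newick()
        clusters[cl.cluster_id] = cl.genes
        aln_len = sum(cl.exon_lengths)
        rows: dict[str, str] = {}
        for leaf in cl.gene_tree.leaves():
            gid = leaf.label
            species = gid.split("_", 1)[0]
            row, gene_cds, tx_exons, tx_introns = _render_gene(cl, gid)
            rows[gid] = row
            cds[gid] = gene_cds
            idx = gene_index.get(species, 0)
            gene_index[species] = idx + 1
            strand = "+" if idx % 2 == 0 else "-"
            spacer = _random_seq(300, 0.42, rng)
            chrom_parts.setdefault(species, []).append(spacer)
            offset = offsets.get(species, 0) + len(spacer)
            model, gseq = _place_gene(gid, species, strand, offset,
                                      tx_exons, tx_introns)
            chrom_parts[species].append(gseq)
            offsets[species] = offset + len(gseq)
            models.setdefault(species, []).append(model)
        assert all(len(r) == aln_len for r in rows.values())
        alignments[cl.cluster_id] = rows

    for species, parts in chrom_parts.items():
        genomes[species] = {"chr1": "".join(parts)}
    return RenderedDataset(truth, genomes, models, cds, alignments, trees,
                           clusters)


def _inject_noise(truth: SyntheticTruth, rng: np.random.Generator) -> None:
    for cl in truth.clusters:
        for st in cl.sites:
            if st.category == "invisible":
                continue
            for gid, present in st.presence.items():
                if not present and rng.random() < truth.config.junction_noise:
                    cl.noise[(gid, st.site_index)] = 2


def _render_gene(cl: ClusterSim, gid: str
                 ) -> tuple[str, str, list[str], list[str | None]]:
    """Alignment row, CDS, and per-ancestral-exon transcript pieces.

    ``tx_introns[j]`` is the intron sequence after ancestral exon j (None
    when the gene lacks it)."""
    present = {st.site_index for st in cl.sites if st.presence.get(gid)}
    row_parts: list[str] = []
    tx_exons: list[str] = []
    tx_introns: list[str | None] = []
    for j, exon in enumerate(cl.exon_seqs):
        # junction noise deletes bases from the end of the exon upstream of
        # site j; the alignment keeps the columns as gaps
        cut = cl.noise.get((gid, j), 0)
        exon_out = exon[:-cut] if cut else exon
        row_parts.append(exon_out + "-" * cut)
        tx_exons.append(exon_out)
        if j < len(cl.sites):
            tx_introns.append(cl.intron_seqs[j] if j in present else None)
    row = "".join(row_parts)
    gene_cds = row.replace("-", "")
    return row, gene_cds, tx_exons, tx_introns


def _place_gene(gid: str, species: str, strand: str, offset: int,
                tx_exons: list[str], tx_introns: list[str | None]
                ) -> tuple[GeneModel, str]:
    """Lay the transcript on the chromosome; returns the gene model (exons
    merged across absent introns) and the genomic sequence appended."""
    pieces: list[tuple[str, str]] = []      # (kind, seq) in transcription order
    for j, ex in enumerate(tx_exons):
        if pieces and pieces[-1][0] == "exon" and (
                j == 0 or tx_introns[j - 1] is None):
            pieces[-1] = ("exon", pieces[-1][1] + ex)
        else:
            pieces.append(("exon", ex))
        if j < len(tx_introns) and tx_introns[j] is not None:
            pieces.append(("intron", tx_introns[j]))
    tx_seq = "".join(s for _, s in pieces)
    total = len(tx_seq)
    exon_ivals_tx: list[tuple[int, int]] = []
    at = 0
    for kind, s in pieces:
        if kind == "exon":
            exon_ivals_tx.append((at, at + len(s)))
        at += len(s)
    if strand == "+":
        gseq = tx_seq
        exons = [(offset + a, offset + b) for a, b in exon_ivals_tx]
    else:
        gseq = revcomp(tx_seq)
        exons = [(offset + total - b, offset + total - a)
                 for a, b in exon_ivals_tx]
    return GeneModel(gid, species, "chr1", strand, exons), gseq


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_dataset(ds: RenderedDataset, outdir: str) -> None:
    """Write the rendered dataset in the exact formats the pipeline reads."""
    os.makedirs(outdir, exist_ok=True)
    for sub in ("genomes", "genes", "alignments"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)
    for species, chroms in sorted(ds.genomes.items()):
        io_formats.write_fasta(chroms,
                               os.path.join(outdir, "genomes",
                                            f"{species}.fasta"))
        io_formats.write_gff3(ds.models[species],
                              os.path.join(outdir, "genes",
                                           f"{species}.gff3"))
    io_formats.write_fasta(dict(sorted(ds.cds.items())),
                           os.path.join(outdir, "cds.fasta"))
    for cid, rows in sorted(ds.alignments.items()):
        io_formats.write_fasta(rows, os.path.join(outdir, "alignments",
                                                  f"{cid}.fasta"))
    with open(os.path.join(outdir, "trees.tsv"), "w") as fh:
        for cid, nwk in sorted(ds.trees.items()):
            fh.write(f"{cid}\t{nwk}\n")
    rows = [{"cluster_id": cid, "gene_id": g}
            for cid, genes in sorted(ds.clusters.items()) for g in genes]
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "clusters.tsv"),
                              sep="\t", index=False)
    ds.truth.table().to_csv(os.path.join(outdir, "truth.tsv"),
                            sep="\t", index=False)
    cfg = asdict(ds.truth.config)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def simulate_dataset(config: SimulationConfig, outdir: str | None = None
                     ) -> RenderedDataset:
    """Convenience: simulate histories, render, optionally write."""
    truth = simulate_histories(config)
    ds = render_dataset(truth)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def recovery_score(truth_table: pd.DataFrame,
                   predicted: pd.DataFrame) -> dict:
    """Compare pipeline output with simulator truth, keyed by
    (cluster_id, boundary).

    Returns per-category precision/recall, the confusion matrix and the
    headline accuracy (fraction of truth groups with exactly recovered
    category).  A truth group missing from the prediction counts as recall
    loss under a pseudo-category ``missing``.
    """
    t = truth_table.set_index(["cluster_id", "boundary"])
    p = predicted.set_index(["cluster_id", "boundary"])
    extra = p.index.difference(t.index)
    if len(extra):
        raise ValueError(f"predictions for unknown groups: {list(extra[:3])}")
    pairs = []
    for key, row in t.iterrows():
        cat_true = row["category"]
        cat_pred = (p.loc[key, "category"] if key in p.index else "missing")
        pairs.append((cat_true, cat_pred))
    cm = pd.crosstab(
        pd.Series([a for a, _ in pairs], name="truth"),
        pd.Series([b for _, b in pairs], name="predicted"))
    accuracy = sum(a == b for a, b in pairs) / len(pairs) if pairs else math.nan
    scores = {}
    cats = sorted({a for a, _ in pairs} | {b for _, b in pairs})
    for cat in cats:
        tp = sum(a == b == cat for a, b in pairs)
        fn = sum(a == cat and b != cat for a, b in pairs)
        fp = sum(a != cat and b == cat for a, b in pairs)
        scores[cat] = {
            "precision": tp / (tp + fp) if tp + fp else math.nan,
            "recall": tp / (tp + fn) if tp + fn else math.nan,
        }
    return {"accuracy": accuracy, "confusion": cm, "per_category": scores}
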