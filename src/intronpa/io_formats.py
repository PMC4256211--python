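"""Readers and writers for every external format the pipeline touches.

Coordinate conventions: gene-model coordinates are stored 0-based half-open
and sorted in transcription order (ascending on ``+``, descending on ``-``);
GFF3 I/O converts to/from the format's 1-based inclusive intervals at the
boundary.  Alignment columns are 1-based throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO

from .species import OUTGROUP_RANK, species_of_gene


class FormatError(ValueError):
    """Malformed input data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Exon structure of one representative (longest-CDS) transcript.

    ``exons`` are the CDS-bearing intervals, 0-based half-open genomic
    coordinates, ordered in transcription order.
    """

    gene_id: str
    species: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        ivals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if e1 > s2:
                raise FormatError(f"{self.gene_id}: overlapping exons")
        want = ivals if self.strand == "+" else ivals[::-1]
        if list(self.exons) != want:
            raise FormatError(f"{self.gene_id}: exons not in transcription order")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def frame_flag(self) -> bool:
        """True when the CDS length is not a codon multiple (annotation slop)."""
        return self.cds_length % 3 != 0

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class ClusterTable:
    """cluster_id -> member gene ids; each gene belongs to at most one cluster."""

    members: dict[str, list[str]]
    species_prefix_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cid, genes in self.members.items():
            for g in genes:
                if g in seen:
                    raise FormatError(
                        f"gene {g} in both clusters {seen[g]} and {cid}")
                seen[g] = cid
        self.cluster_of = seen

    def species(self, gene_id: str) -> str:
        return species_of_gene(gene_id, self.species_prefix_map)

    def size(self, cluster_id: str) -> int:
        return len(self.members[cluster_id])


@dataclass
class ClusterAlignment:
    """Codon-aware CDS alignment of one cluster (uppercase DNA + '-')."""

    cluster_id: str
    rows: dict[str, str]
    flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"cluster {self.cluster_id}: no rows")
        lens = {len(r) for r in self.rows.values()}
        if len(lens) != 1:
            raise FormatError(f"cluster {self.cluster_id}: ragged alignment")
        (self.length,) = lens

    def ungapped(self, gene_id: str) -> str:
        return self.rows[gene_id].replace("-", "")

    def column(self, gene_id: str, col: int) -> str:
        """1-based column access."""
        return self.rows[gene_id][col - 1]


@dataclass
class CentromereTable:
    """Per (species, chromosome): centromere position and chromosome length."""

    table: pd.DataFrame  # columns: species, chromosome, centromere, length

    def __post_init__(self) -> None:
        t = self.table
        bad = t[(t.centromere <= 0) | (t.centromere >= t.length)]
        if len(bad):
            raise FormatError("centromere position outside (0, length) for "
                              + ", ".join(bad.chromosome.astype(str)))
        self._idx = {(r.species, r.chromosome): (r.centromere, r.length)
                     for r in t.itertuples()}

    def lookup(self, species: str, chromosome: str) -> tuple[float, float]:
        return self._idx[(species, chromosome)]


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def parse_fasta(source: str | TextIO) -> dict[str, str]:
    """Read a FASTA file/stream into an id -> uppercase-sequence dict."""
    if isinstance(source, str):
        with open(source) as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def parse_gene_models(gff3: str | TextIO, species: str) -> tuple[list[GeneModel], int]:
    """Parse gene models from GFF3, one per gene (longest-CDS transcript,
    ties broken by lexicographic transcript id).

    Returns ``(models, n_skipped)`` where skipped transcripts are mRNAs
    without CDS features.  Raises :class:`FormatError` on malformed lines.
    """
    if isinstance(gff3, str):
        if "\n" not in gff3 and os.path.exists(gff3):
            with open(gff3) as fh:
                text = fh.read()
        else:
            text = gff3
    else:
        text = gff3.read()
    _validate_gff_lines(text)
    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            merge_strategy="create_unique", keep_order=True)
    models: list[GeneModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene", order_by="start"):
        best: tuple[int, str, list[tuple[int, int]]] | None = None
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if not cds:
                n_skipped += 1
                continue
            ivals = sorted((c.start - 1, c.end) for c in cds)
            length = sum(e - s for s, e in ivals)
            key = (-length, mrna.id)
            if best is None or key < (-best[0], best[1]):
                best = (length, mrna.id, ivals)
        if best is None:
            continue
        _, _, ivals = best
        if gene.strand == "-":
            ivals = ivals[::-1]
        models.append(GeneModel(gene.id, species, gene.seqid, gene.strand, ivals))
    return models, n_skipped


def _validate_gff_lines(text: str) -> None:
    for i, line in enumerate(text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"malformed GFF3 feature at line {i}: "
                              f"{len(parts)} columns")
        try:
            s, e = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise FormatError(f"malformed GFF3 coordinates at line {i}") from exc
        if s < 1 or e < s:
            raise FormatError(f"invalid GFF3 interval at line {i}")


def parse_cluster_table(source: str | TextIO,
                        species_prefix_map: dict[str, str] | None = None
                        ) -> ClusterTable:
    """TSV with columns ``cluster_id`` and ``gene_id`` (one member per row)."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    if not {"cluster_id", "gene_id"} <= set(df.columns):
        raise FormatError("cluster table needs cluster_id and gene_id columns")
    members: dict[str, list[str]] = {}
    for r in df.itertuples():
        members.setdefault(r.cluster_id, []).append(r.gene_id)
    return ClusterTable(members, species_prefix_map)


def parse_alignment(source: str | TextIO, cluster_id: str,
                    cds: Mapping[str, str] | None = None) -> ClusterAlignment:
    """Read one aligned FASTA; if ``cds`` is given, rows whose gap-stripped
    sequence does not reproduce the CDS are flagged unusable."""
    rows = parse_fasta(source)
    aln = ClusterAlignment(cluster_id, rows)
    if cds is not None:
        for gid, row in rows.items():
            if gid in cds and row.replace("-", "") != cds[gid]:
                aln.flagged.add(gid)
    return aln


def parse_alignment_set(sources: Mapping[str, str | TextIO],
                        cluster_table: ClusterTable,
                        cds: Mapping[str, str] | None = None
                        ) -> dict[str, ClusterAlignment]:
    """Read one aligned FASTA per cluster (``sources``: cluster_id -> path)."""
    out = {}
    for cid, src in sorted(sources.items()):
        aln = parse_alignment(src, cid, cds)
        for gid in aln.rows:
            if gid not in cluster_table.cluster_of:
                raise FormatError(f"alignment row {gid} not in cluster table")
        out[cid] = aln
    return out


def parse_centromere_table(source: str | TextIO) -> CentromereTable:
    """TSV with columns species, chromosome, centromere, length (bp)."""
    df = pd.read_csv(source, sep="\t")
    need = {"species", "chromosome", "centromere", "length"}
    if not need <= set(df.columns):
        raise FormatError(f"centromere table needs columns {sorted(need)}")
    return CentromereTable(df)


def root_gene_tree(tree: dendropy.Tree, cluster_table: ClusterTable | None = None,
                   species_prefix_map: dict[str, str] | None = None) -> dendropy.Tree:
    """Root an (possibly unrooted) gene tree on the deepest-ranked outgroup
    leaf (moss > spikemoss > Arabidopsis > banana).  Deterministic: ties are
    broken by leaf label."""
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in gene tree")
    if cluster_table is not None:
        for lab in labels:
            if lab not in cluster_table.cluster_of:
                raise FormatError(f"gene-tree leaf {lab} not in cluster table")
    prefix_map = species_prefix_map or (
        cluster_table.species_prefix_map if cluster_table else None)
    ranked = sorted(
        ((OUTGROUP_RANK.get(species_of_gene(l, prefix_map), 0), l) for l in labels),
        key=lambda t: (-t[0], t[1]))
    rank, outgroup = ranked[0]
    tree.is_rooted = True
    if rank > 0:
        node = next(l for l in tree.leaf_node_iter()
                    if l.taxon.label == outgroup)
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
    return tree


def parse_gene_trees(source: str | TextIO,
                     cluster_table: ClusterTable | None = None
                     ) -> dict[str, dendropy.Tree]:
    """Read per-cluster gene trees from a TSV of ``cluster_id<TAB>newick``
    lines; each tree is rooted deterministically (see :func:`root_gene_tree`)."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    out: dict[str, dendropy.Tree] = {}
    for line in lines:
        if not line.strip():
            continue
        cid, nwk = line.split("\t", 1)
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        out[cid] = root_gene_tree(tree, cluster_table)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gff3(models: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS), 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda m: (m.chromosome, m.span)):
            lo, hi = m.span
            attrs = f"ID={m.gene_id}"
            fh.write(f"{m.chromosome}\tintronpa\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{m.strand}\t.\t{attrs}\n")
            tid = f"{m.gene_id}.1"
            fh.write(f"{m.chromosome}\tintronpa\tmRNA\t{lo + 1}\t{hi}\t.\t"
                     f"{m.strand}\t.\tID={tid};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(sorted(m.exons), 1):
                for ftype in ("exon", "CDS"):
                    fh.write(f"{m.chromosome}\tintronpa\t{ftype}\t{s + 1}\t{e}"
                             f"\t.\t{m.strand}\t0\t"
                             f"ID={tid}.{ftype}{i};Parent={tid}\n")


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_tables(results: Mapping[str, pd.DataFrame], outdir: str) -> list[str]:
    """Write each result DataFrame as a deterministic TSV (sorted rows where a
    (cluster_id, boundary) key exists, fixed column order, one header line)."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for name in sorted(results):
        df = results[name].copy()
        keys = [c for c in ("cluster_id", "boundary") if c in df.columns]
        if keys:
            df = df.sort_values(keys, kind="stable")
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
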