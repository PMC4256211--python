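"""Intron sites, their projection onto cluster alignments, and the filter
cascade that calls conserved vs presence/absence (PA) intron groups.

An intron site is keyed by its CDS breakpoint: the number of CDS bases
upstream of the intron (the intron interrupts the CDS between base ``i`` and
``i+1``; phase = ``i mod 3``).  Projected onto the cluster alignment, a site
becomes a boundary "after column c" (columns 1-based); all member genes are
scored present / absent / unalignable at each boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import ClusterAlignment, GeneModel
from .species import species_of_gene

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IntronSite:
    """One intron of one gene, on the transcription strand."""

    gene_id: str
    ordinal: int            # 1-based, transcription order
    start: int              # genomic span, 0-based half-open
    end: int
    cds_breakpoint: int     # CDS bases upstream of the intron
    phase: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntronGroup:
    """One alignment boundary with its per-gene presence map."""

    cluster_id: str
    boundary: int                       # intron lies after this column
    states: dict[str, str]              # gene -> present|absent|unalignable
    sites: dict[str, IntronSite]        # present members only
    status: str = ""                    # conserved|PA|unscored
    flags: list[str] = field(default_factory=list)
    transcript_support: bool | None = None

    def __post_init__(self) -> None:
        if not self.status:
            self.status = _status(self.states)

    @property
    def present(self) -> list[str]:
        return sorted(g for g, s in self.states.items() if s == "present")

    @property
    def absent(self) -> list[str]:
        return sorted(g for g, s in self.states.items() if s == "absent")

    @property
    def unalignable(self) -> list[str]:
        return sorted(g for g, s in self.states.items() if s == "unalignable")


def _status(states: Mapping[str, str],
            ingroup_genes: set[str] | None = None) -> str:
    """Group status.  PA requires presence/absence polymorphism among the
    ingroup members (outgroup-only absences are outside the analysis scope);
    conserved requires every member scored and present."""
    n_present = sum(s == "present" for s in states.values())
    n_absent = sum(s == "absent" for s in states.values())
    n_un = sum(s == "unalignable" for s in states.values())
    if n_present and not n_absent and n_un == 0:
        return "conserved"
    ing = states if ingroup_genes is None else {
        g: s for g, s in states.items() if g in ingroup_genes}
    ing_present = sum(s == "present" for s in ing.values())
    ing_absent = sum(s == "absent" for s in ing.values())
    if ing_present and ing_absent:
        return "PA"
    if n_present and n_absent:
        return "outgroup_only"
    return "unscored"


# ---------------------------------------------------------------------------
# extraction and projection
# ---------------------------------------------------------------------------

def extract_introns(model: GeneModel, chromosome_seq: str | None = None
                    ) -> list[IntronSite]:
    """One :class:`IntronSite` per gap between consecutive CDS exons.

    Minus-strand intron sequences are reverse-complemented so that every
    sequence reads along the transcription strand.
    """
    sites: list[IntronSite] = []
    cds_so_far = 0
    for k, (prev, nxt) in enumerate(zip(model.exons, model.exons[1:]), 1):
        cds_so_far += prev[1] - prev[0]
        if model.strand == "+":
            lo, hi = prev[1], nxt[0]
        else:
            lo, hi = nxt[1], prev[0]
        if hi <= lo:
            raise ValueError(f"{model.gene_id}: zero-length intron after exon {k}")
        seq = ""
        if chromosome_seq is not None:
            if hi > len(chromosome_seq):
                raise ValueError(f"{model.gene_id}: exon beyond chromosome end")
            seq = chromosome_seq[lo:hi]
            if model.strand == "-":
                seq = revcomp(seq)
        sites.append(IntronSite(model.gene_id, k, lo, hi, cds_so_far,
                                cds_so_far % 3, seq))
    return sites


def map_breakpoint_to_alignment(aligned_row: str, cds_breakpoint: int) -> int:
    """Return the 1-based alignment column occupied by CDS base
    ``cds_breakpoint`` (the last exonic base before the intron)."""
    if cds_breakpoint < 1:
        raise ValueError("breakpoint must be >= 1")
    seen = 0
    for col, ch in enumerate(aligned_row, 1):
        if ch != "-":
            seen += 1
            if seen == cds_breakpoint:
                return col
    raise ValueError(f"breakpoint {cds_breakpoint} beyond row length {seen}")


def _window_columns(boundary: int, length: int, w: int) -> tuple[range, range]:
    up = range(max(1, boundary - w + 1), boundary + 1)
    down = range(boundary + 1, min(length, boundary + w) + 1)
    return up, down


def identify_intron_groups(alignment: ClusterAlignment,
                           introns: Mapping[str, Sequence[IntronSite]],
                           junction_window: int = 3,
                           ingroup_species: set[str] | None = None,
                           species_prefix_map: dict[str, str] | None = None
                           ) -> list[IntronGroup]:
    """Project every member's introns onto the alignment and build one
    (unfiltered) group per boundary column at which >=1 member has an intron.

    A member without an intron at a boundary scores *absent* only when its
    row is gap-free across the junction window (``junction_window`` columns
    each side); a gap there makes it *unalignable* -- missing data never
    counts as absence.  When ``ingroup_species`` is given, PA status
    additionally requires polymorphism among ingroup members (genes whose
    species cannot be resolved count as ingroup).
    """
    ingroup_genes: set[str] | None = None
    if ingroup_species is not None:
        ingroup_genes = set()
        for gid in alignment.rows:
            try:
                sp = species_of_gene(gid, species_prefix_map)
            except KeyError:
                sp = None
            if sp is None or sp in ingroup_species:
                ingroup_genes.add(gid)
    by_boundary: dict[int, dict[str, IntronSite]] = {}
    for gid in alignment.rows:
        if gid in alignment.flagged:
            continue
        for site in introns.get(gid, ()):  # genes absent from mapping: no introns
            col = map_breakpoint_to_alignment(alignment.rows[gid],
                                              site.cds_breakpoint)
            by_boundary.setdefault(col, {})[gid] = site

    groups: list[IntronGroup] = []
    for boundary in sorted(by_boundary):
        present = by_boundary[boundary]
        states: dict[str, str] = {}
        for gid, row in alignment.rows.items():
            if gid in alignment.flagged:
                states[gid] = "unalignable"
                continue
            if gid in present:
                states[gid] = "present"
                continue
            up, down = _window_columns(boundary, alignment.length,
                                       junction_window)
            window = [row[c - 1] for c in up] + [row[c - 1] for c in down]
            states[gid] = "absent" if "-" not in window else "unalignable"
        groups.append(IntronGroup(alignment.cluster_id, boundary, states,
                                  dict(present),
                                  status=_status(states, ingroup_genes)))
    return groups


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the group filter cascade."""

    min_cluster: int = 3
    max_cluster: int = 200
    max_te_fraction: float = 0.30
    junction_window: int = 3
    flank_window: int = 20
    min_flank_identity: float = 0.60
    min_intron_length: int = 11     # introns <= 10 bp rejected
    min_spacing: int = 20           # PA boundaries < 20 columns apart rejected


def _consensus(alignment: ClusterAlignment, cols: range) -> dict[int, str]:
    """Column-majority consensus over non-gap symbols; ties alphabetical."""
    cons: dict[int, str] = {}
    rows = list(alignment.rows.values())
    for c in cols:
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[c - 1]
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            cons[c] = min(counts, key=lambda ch: (-counts[ch], ch))
    return cons


def _flank_identity(row: str, cols: range, cons: Mapping[int, str]) -> float:
    hits = total = 0
    for c in cols:
        ch = row[c - 1]
        if ch == "-" or c not in cons:
            continue
        total += 1
        hits += ch == cons[c]
    return hits / total if total else 0.0


def apply_group_filters(groups: Sequence[IntronGroup],
                        alignment: ClusterAlignment,
                        te_flags: Mapping[str, bool] | None = None,
                        config: FilterConfig = FilterConfig()
                        ) -> tuple[list[IntronGroup], pd.DataFrame]:
    """Apply the filter cascade in order; returns retained groups and a
    rejection log (cluster_id, boundary, rule).

    Rules, in order: cluster size 3--200; transposon-protein fraction <= 30%
    of members; groups scoring neither conserved nor PA dropped (unscored);
    junction perfection (present members gap-free over the junction window);
    flanking identity >= 60% to the window consensus on both sides for every
    scored member; no present member with an intron <= 10 bp; no two PA
    boundaries within < 20 columns (both rejected).
    """
    log: list[tuple[str, int, str]] = []
    cid = alignment.cluster_id

    def reject(gs: Sequence[IntronGroup], rule: str) -> None:
        for g in gs:
            log.append((cid, g.boundary, rule))

    kept = list(groups)
    n = len(alignment.rows)
    if not (config.min_cluster <= n <= config.max_cluster):
        reject(kept, "cluster_size")
        kept = []
    if kept and te_flags is not None:
        members = list(alignment.rows)
        frac = sum(bool(te_flags.get(g, False)) for g in members) / len(members)
        if frac > config.max_te_fraction:
            reject(kept, "te_fraction")
            kept = []

    nxt = []
    for g in kept:
        if g.status in ("conserved", "PA"):
            nxt.append(g)
        else:
            # "unscored" (no verifiable absence) or "outgroup_only"
            # (polymorphism confined to outgroup members)
            log.append((cid, g.boundary, g.status))
    kept = nxt

    nxt = []
    for g in kept:
        up, down = _window_columns(g.boundary, alignment.length,
                                   config.junction_window)
        ok = all("-" not in [alignment.rows[m][c - 1] for c in up] +
                 [alignment.rows[m][c - 1] for c in down]
                 for m in g.present)
        if ok:
            nxt.append(g)
        else:
            log.append((cid, g.boundary, "junction_gap"))
    kept = nxt

    nxt = []
    for g in kept:
        up = range(max(1, g.boundary - config.flank_window + 1), g.boundary + 1)
        down = range(g.boundary + 1,
                     min(alignment.length, g.boundary + config.flank_window) + 1)
        cons_up = _consensus(alignment, up)
        cons_down = _consensus(alignment, down)
        scored = g.present + g.absent
        ok = all(_flank_identity(alignment.rows[m], up, cons_up)
                 >= config.min_flank_identity
                 and _flank_identity(alignment.rows[m], down, cons_down)
                 >= config.min_flank_identity
                 for m in scored)
        if ok:
            nxt.append(g)
        else:
            log.append((cid, g.boundary, "flank_identity"))
    kept = nxt

    nxt = []
    for g in kept:
        if any(s.length < config.min_intron_length for s in g.sites.values()):
            log.append((cid, g.boundary, "short_intron"))
        else:
            nxt.append(g)
    kept = nxt

    pa = [g for g in kept if g.status == "PA"]
    close: set[int] = set()
    for a, b in zip(pa, pa[1:]):
        if b.boundary - a.boundary < config.min_spacing:
            close.update((a.boundary, b.boundary))
    nxt = []
    for g in kept:
        if g.status == "PA" and g.boundary in close:
            log.append((cid, g.boundary, "spacing"))
        else:
            nxt.append(g)
    kept = nxt

    log_df = pd.DataFrame(log, columns=["cluster_id", "boundary", "rule"])
    return kept, log_df


def group_table(groups: Sequence[IntronGroup]) -> pd.DataFrame:
    """Flatten groups into the per-boundary output table."""
    rows = []
    for g in sorted(groups, key=lambda g: (g.cluster_id, g.boundary)):
        phases = sorted({s.phase for s in g.sites.values()})
        lengths = sorted(s.length for s in g.sites.values())
        rows.append({
            "cluster_id": g.cluster_id,
            "boundary": g.boundary,
            "status": g.status,
            "n_present": len(g.present),
            "n_absent": len(g.absent),
            "n_unalignable": len(g.unalignable),
            "present": ",".join(g.present),
            "absent": ",".join(g.absent),
            "unalignable": ",".join(g.unalignable),
            "phase": ",".join(map(str, phases)),
            "intron_lengths": ",".join(map(str, lengths)),
            "transcript_support": g.transcript_support,
        })
    cols = ["cluster_id", "boundary", "status", "n_present", "n_absent",
            "n_unalignable", "present", "absent", "unalignable", "phase",
            "intron_lengths", "transcript_support"]
    return pd.DataFrame(rows, columns=cols)
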