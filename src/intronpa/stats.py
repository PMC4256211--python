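"""Downstream statistics on detected intron turnover.

Covers the recurrent-loss randomization null, per-branch frequencies and
per-intron rates, the adjacent-loss binomial test, positional and
chromosomal distributions with bootstrap envelopes, intron size comparison,
phase/enrichment contingency tests, dinucleotide composition profiles, and
the summary (category counts and the loss:gain ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import parsimony
from .parsimony import classify_group, enumerate_min_histories
from .species import DatedSpeciesTree, GRASS_SPECIES, grass_tree


# ---------------------------------------------------------------------------
# randomization null for recurrent loss
# ---------------------------------------------------------------------------

@dataclass
class RandomizationResult:
    replicates: int
    seed: int
    counts: np.ndarray                  # per-replicate recurrent-loss events
    observed: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def max(self) -> int:
        return int(np.max(self.counts))

    @property
    def p_value(self) -> float | None:
        """Empirical upper-tail p = (#replicates >= observed)/replicates."""
        if self.observed is None:
            return None
        return float(np.mean(self.counts >= self.observed))

    @property
    def p_string(self) -> str | None:
        p = self.p_value
        if p is None:
            return None
        if p == 0.0:
            return f"<{1 / self.replicates:g}"
        return f"{p:g}"


def _pattern_lookup(species_tree: DatedSpeciesTree, tips: Sequence[str],
                    outgroup: str, mode: str) -> list[int]:
    """Per absent-tip bitmask: loss events contributed by a group with that
    pattern (0 unless it is a recurrent-loss configuration).

    strict_unique: count losses only when the unique minimum history has
    >= 2 losses and no gain.  dollo: minimum loss count with gains
    disallowed, counted when >= 2.
    """
    tree = species_tree.tree
    table = [0] * (1 << len(tips))
    for mask in range(1, 1 << len(tips)):
        pattern = {outgroup: parsimony.PRESENT}
        for i, t in enumerate(tips):
            pattern[t] = (parsimony.ABSENT if mask >> i & 1
                          else parsimony.PRESENT)
        if mode == "dollo":
            n = parsimony.min_dollo_losses(tree, pattern)
            table[mask] = n if n >= 2 else 0
        else:
            cls = classify_group(enumerate_min_histories(tree, pattern))
            if cls.category == "recurrent_loss":
                table[mask] = cls.history.losses
    return table


def randomization_test(n_groups: int,
                       tips_per_group: int,
                       species_tree: DatedSpeciesTree | None = None,
                       n_absences: int = 257,
                       replicates: int = 10000,
                       seed: int = 0,
                       resolution_mode: str = "strict_unique",
                       observed: int | None = None) -> RandomizationResult:
    """Randomly assign ``n_absences`` intron absences (without replacement)
    to ``n_groups * tips_per_group`` locations and count recurrent-loss
    events per replicate.

    Each group is one tip per grass species on the species tree with a
    present outgroup.  Only groups receiving >= 2 absences are reconstructed
    (a single absence is a single loss by construction); reconstruction uses
    a precomputed lookup over the 2^tips presence patterns.
    """
    if resolution_mode not in ("strict_unique", "dollo"):
        raise ValueError(f"unknown resolution_mode {resolution_mode!r}")
    if species_tree is None:
        species_tree = grass_tree(with_outgroup=True)
    tips = [s for s in GRASS_SPECIES
            if s in species_tree.leaf_labels()][:tips_per_group]
    if len(tips) != tips_per_group:
        raise ValueError("species tree does not carry enough grass tips")
    outgroup = next(l for l in species_tree.leaf_labels() if l not in tips)
    n_locations = n_groups * tips_per_group
    if n_absences > n_locations:
        raise ValueError("more absences than intron locations")

    lookup = _pattern_lookup(species_tree, tips, outgroup, resolution_mode)
    rng = np.random.default_rng(seed)
    counts = np.zeros(replicates, dtype=np.int64)
    for r in range(replicates):
        locs = rng.choice(n_locations, size=n_absences, replace=False)
        groups = locs // tips_per_group
        order = np.argsort(groups, kind="stable")
        groups = groups[order]
        tips_idx = (locs % tips_per_group)[order]
        total = 0
        i = 0
        n = len(groups)
        while i < n:
            j = i + 1
            while j < n and groups[j] == groups[i]:
                j += 1
            if j - i >= 2:
                mask = 0
                for k in range(i, j):
                    mask |= 1 << int(tips_idx[k])
                total += lookup[mask]
            i = j
        counts[r] = total
    return RandomizationResult(replicates, seed, counts, observed)


def expected_recurrent_pairs(n_absences: int, n_locations: int,
                             tips_per_group: int = 5,
                             cross_pair_fraction: float | None = None,
                             species_tree: DatedSpeciesTree | None = None
                             ) -> float:
    """Analytic pair-only approximation of the randomization mean.

    Expected recurrent events ~= 2 * C(n,2) * (t-1)/(N-1) * f, with f the
    fraction of unordered tip pairs whose two-absence pattern is a unique
    two-loss history (computed from the parsimony engine unless given).
    """
    if cross_pair_fraction is None:
        if species_tree is None:
            species_tree = grass_tree(with_outgroup=True)
        tips = list(GRASS_SPECIES[:tips_per_group])
        outgroup = next(l for l in species_tree.leaf_labels()
                        if l not in tips)
        lookup = _pattern_lookup(species_tree, tips, outgroup, "strict_unique")
        pair_masks = [(1 << i) | (1 << j)
                      for i in range(tips_per_group)
                      for j in range(i + 1, tips_per_group)]
        cross_pair_fraction = (sum(lookup[m] == 2 for m in pair_masks)
                               / len(pair_masks))
    n_pairs = n_absences * (n_absences - 1) / 2
    p_same_group = (tips_per_group - 1) / (n_locations - 1)
    return 2.0 * n_pairs * p_same_group * cross_pair_fraction


# ---------------------------------------------------------------------------
# branch frequencies and per-intron rates
# ---------------------------------------------------------------------------

def compute_rates(events: pd.DataFrame,
                  species_tree: DatedSpeciesTree) -> pd.DataFrame:
    """Per-branch event frequencies (events/MY) and, for terminal branches,
    rates in events/intron/year from the per-genome analyzed-intron counts.

    ``events`` needs columns ``branch`` and ``kind``; an optional
    ``category`` column adds per-category breakdowns.
    """
    rows = []
    cats = ["all"]
    if "category" in events.columns:
        cats += sorted(events["category"].dropna().unique())
    for branch in species_tree.branch_names():
        length = species_tree.branch_length(branch)
        terminal = species_tree.node(branch).is_leaf()
        n_introns = species_tree.intron_counts.get(branch)
        for cat in cats:
            sub = events if cat == "all" else events[events.category == cat]
            count = int((sub.branch == branch).sum())
            freq = count / length if length > 0 else math.nan
            rate = (count / (length * 1e6 * n_introns)
                    if terminal and n_introns and length > 0 else math.nan)
            rows.append({"branch": branch, "category": cat, "count": count,
                         "branch_length_my": length,
                         "frequency_per_my": freq,
                         "rate_per_intron_per_year": rate,
                         "flag_zero_length": length == 0})
    return pd.DataFrame(rows)


def per_site_rate(n_sites: int, total_sites: int, span_my: float) -> float:
    """Recurrent-site rate = sites / (total analyzed sites x MY)."""
    return n_sites / (total_sites * span_my)


# ---------------------------------------------------------------------------
# adjacent intron loss
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyResult:
    adjacent_pairs: int
    same_lineage_pairs: int
    trials: int
    p0: float
    p_value: float

    @property
    def reject_at_005(self) -> bool:
        return self.p_value < 0.05


def adjacent_loss_test(group_table: pd.DataFrame) -> AdjacencyResult:
    """Exact binomial upper-tail test of adjacent PA groups.

    ``group_table`` needs cluster_id, boundary, status and (optionally)
    ``absent`` (comma-joined absent genes; used to call same-lineage pairs).
    Null: each neighbor of a PA intron is PA independently with
    p0 = (n_PA - 1) / (n_total - 1); trials = consecutive boundary pairs
    containing at least one PA group; a run of three adjacent PA groups
    counts as two pairs.
    """
    df = group_table.sort_values(["cluster_id", "boundary"], kind="stable")
    n_total = len(df)
    n_pa = int((df.status == "PA").sum())
    if n_total < 2 or df.groupby("cluster_id").size().max() < 2:
        raise ValueError("adjacency test undefined: no cluster with 2+ groups")
    adjacent = same_lineage = trials = 0
    for _, sub in df.groupby("cluster_id", sort=False):
        recs = list(sub.itertuples())
        for a, b in zip(recs, recs[1:]):
            a_pa, b_pa = a.status == "PA", b.status == "PA"
            if a_pa or b_pa:
                trials += 1
            if a_pa and b_pa:
                adjacent += 1
                if (getattr(a, "absent", None) is not None
                        and a.absent == b.absent):
                    same_lineage += 1
    p0 = (n_pa - 1) / (n_total - 1)
    p = float(sps.binom.sf(adjacent - 1, trials, p0)) if trials else 1.0
    return AdjacencyResult(adjacent, same_lineage, trials, p0, p)


# ---------------------------------------------------------------------------
# positional distributions with bootstrap envelopes
# ---------------------------------------------------------------------------

def _histogram_pct(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    hist, _ = np.histogram(values, bins=edges)
    return 100.0 * hist / max(len(values), 1)


def _bootstrap_envelope(reference: np.ndarray, sample_size: int,
                        edges: np.ndarray, n_boot: int,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    boots = np.empty((n_boot, len(edges) - 1))
    for b in range(n_boot):
        res = rng.choice(reference, size=sample_size, replace=True)
        boots[b] = _histogram_pct(res, edges)
    return boots.mean(axis=0), boots.std(axis=0)


def gene_position_distribution(positions: Sequence[float],
                               reference: Sequence[float],
                               bins: int = 10,
                               bootstrap: int = 1000,
                               seed: int = 0) -> pd.DataFrame:
    """Decile histogram of relative intron positions (breakpoint/CDS length,
    in (0,1)) with a resampling envelope from the reference intron set."""
    pos = np.asarray(positions, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if np.any((pos <= 0) | (pos >= 1)) or np.any((ref <= 0) | (ref >= 1)):
        raise ValueError("relative positions must lie in (0, 1)")
    edges = np.linspace(0.0, 1.0, bins + 1)
    rng = np.random.default_rng(seed)
    mean, sd = _bootstrap_envelope(ref, len(pos), edges, bootstrap, rng)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "pct": _histogram_pct(pos, edges),
        "ref_mean": mean, "ref_sd": sd,
    })


def relative_position(cds_breakpoint: int, cds_length: int) -> float:
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    return cds_breakpoint / cds_length


def position_bin(rel: float, bins: int = 10) -> int:
    """Half-open bins [k/bins, (k+1)/bins), last bin closed."""
    return min(int(rel * bins), bins - 1)


def normalized_chromosome_position(pos: float, centromere: float,
                                   length: float) -> float:
    """Distance from centromere / arm length; negative on the short arm
    (arm containing coordinate 0 when the centromere sits past the middle is
    by convention the left arm)."""
    if not (0 <= pos <= length):
        raise ValueError("gene position beyond chromosome length")
    if pos < centromere:
        return (pos - centromere) / centromere
    return (pos - centromere) / (length - centromere)


def chromosome_position_distribution(positions: Sequence[float],
                                     reference: Sequence[float],
                                     bins: int = 20,
                                     bootstrap: int = 1000,
                                     seed: int = 0) -> pd.DataFrame:
    """Histogram over [-1, 1] of centromere-normalized gene positions, plus
    envelope and the per-bin density ratio (affected / reference)."""
    pos = np.asarray(positions, dtype=float)
    ref = np.asarray(reference, dtype=float)
    edges = np.linspace(-1.0, 1.0, bins + 1)
    rng = np.random.default_rng(seed)
    mean, sd = _bootstrap_envelope(ref, len(pos), edges, bootstrap, rng)
    pct = _histogram_pct(pos, edges)
    ref_pct = _histogram_pct(ref, edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref_pct > 0, pct / ref_pct, np.nan)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:], "pct": pct,
        "ref_mean": mean, "ref_sd": sd, "density_ratio": ratio,
    })


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


@dataclass
class CompositionProfile:
    category: str
    region: str                          # intron | flank
    n_sequences: int
    gc: float
    dinucleotides: dict[str, int] = field(default_factory=dict)
    truncated: bool = False

    @property
    def dinucleotide_freqs(self) -> dict[str, float]:
        total = sum(self.dinucleotides.values())
        return {d: (c / total if total else math.nan)
                for d, c in self.dinucleotides.items()}

    @property
    def tg_cg(self) -> float:
        cg = self.dinucleotides.get("CG", 0)
        if cg == 0:
            return math.nan               # undefined, flagged by NaN
        return self.dinucleotides.get("TG", 0) / cg


def dinucleotide_counts(seq: str) -> dict[str, int]:
    """Overlapping dinucleotide counts; a length-L sequence has L-1."""
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    s = seq.upper()
    for i in range(len(s) - 1):
        d = s[i:i + 2]
        if d in counts:
            counts[d] += 1
    return counts


def gc_fraction(seqs: Sequence[str]) -> float:
    tot = sum(len(s) for s in seqs)
    gc = sum(s.upper().count("G") + s.upper().count("C") for s in seqs)
    return gc / tot if tot else math.nan


def composition_profile(by_category: Mapping[str, Sequence[tuple[str, str, str]]],
                        flank: int = 20
                        ) -> tuple[list[CompositionProfile], pd.DataFrame]:
    """Composition per category of (intron_seq, upstream_flank,
    downstream_flank) triples: G+C, dinucleotide counts/frequencies, TG/CG;
    plus pairwise chi-square comparisons of intron TG/CG counts with
    Bonferroni adjustment (alpha = 0.05 / #comparisons)."""
    profiles: list[CompositionProfile] = []
    for cat, triples in by_category.items():
        introns = [t[0] for t in triples]
        flanks, truncated = [], False
        for _, up, down in triples:
            if len(up) < flank or len(down) < flank:
                truncated = True
            flanks.append(up[-flank:])
            flanks.append(down[:flank])
        for region, seqs in (("intron", introns), ("flank", flanks)):
            counts = dict.fromkeys(DINUCLEOTIDES, 0)
            for s in seqs:
                for d, c in dinucleotide_counts(s).items():
                    counts[d] += c
            profiles.append(CompositionProfile(
                cat, region, len(seqs), gc_fraction(seqs), counts,
                truncated and region == "flank"))
    intron_profiles = {p.category: p for p in profiles if p.region == "intron"}
    cats = sorted(intron_profiles)
    comparisons = []
    pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1:]]
    alpha = 0.05 / len(pairs) if pairs else math.nan
    for a, b in pairs:
        pa, pb = intron_profiles[a], intron_profiles[b]
        table = [[pa.dinucleotides["TG"], pa.dinucleotides["CG"]],
                 [pb.dinucleotides["TG"], pb.dinucleotides["CG"]]]
        chi2, p = contingency_tests(table)
        comparisons.append({"category_a": a, "category_b": b,
                            "chi2": chi2, "p": p,
                            "bonferroni_alpha": alpha,
                            "significant": p < alpha})
    return profiles, pd.DataFrame(comparisons)


# ---------------------------------------------------------------------------
# intron sizes, contingency tests, summary
# ---------------------------------------------------------------------------

def compare_intron_sizes(sample_a: Sequence[float], sample_b: Sequence[float]
                         ) -> dict[str, float]:
    """Means and two-sided Mann-Whitney U p (exact where scipy can)."""
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("both samples must be non-empty")
    u, p = sps.mannwhitneyu(sample_a, sample_b, alternative="two-sided")
    return {"mean_a": float(np.mean(sample_a)),
            "mean_b": float(np.mean(sample_b)),
            "U": float(u), "p": float(p)}


def contingency_tests(table: Sequence[Sequence[float]],
                      continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-square with optional Yates continuity correction
    (applies to 2x2 only, matching the usual convention)."""
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(arr, correction=continuity)
    return float(res.statistic), float(res.pvalue)


def loss_gain_ratio(n_loss_events: int, n_gain_events: int) -> float:
    if n_gain_events == 0:
        return math.nan
    return n_loss_events / n_gain_events


def build_summary(classifications: Sequence) -> pd.DataFrame:
    """Category counts, event counts and affected-gene counts (one gene may
    appear under several categories), plus the loss:gain event ratio."""
    rows = {c: {"groups": 0, "events": 0, "genes": set()}
            for c in parsimony.CATEGORIES}
    for cls in classifications:
        r = rows[cls.category]
        r["groups"] += 1
        if cls.history is not None:
            r["events"] += cls.history.cost
            r["genes"].update(cls.affected)
    total_losses = total_gains = 0
    for cls in classifications:
        if cls.history is not None:
            total_losses += cls.history.losses
            total_gains += cls.history.gains
    out = []
    for cat in parsimony.CATEGORIES:
        r = rows[cat]
        out.append({"category": cat, "groups": r["groups"],
                    "events": r["events"] if cat != "unresolved" else None,
                    "affected_genes": len(r["genes"])})
    df = pd.DataFrame(out)
    df.attrs["loss_gain_ratio"] = loss_gain_ratio(total_losses, total_gains)
    df.attrs["total_loss_events"] = total_losses
    df.attrs["total_gain_events"] = total_gains
    return df
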