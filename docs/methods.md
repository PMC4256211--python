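# Methods

This note records the models, conventions and design choices behind
`intronpa`, in the order the pipeline applies them.

## Coordinates and intron sites

Gene models are stored 0-based half-open in transcription order; GFF3 I/O
converts at the boundary (1-based inclusive). Only CDS-interrupting introns
are considered: an intron is keyed by its CDS breakpoint *i* — the number
of coding bases upstream — so that phase is *i* mod 3 and the site is
well-defined on every transcript regardless of UTR annotation. The
representative transcript per gene is the one with the longest CDS, ties
broken by lexicographic transcript id. Minus-strand intron sequences are
reverse-complemented to the transcription strand before any composition
analysis.

## Group detection and scope

The breakpoint of each intron is projected through its gene's gapped
alignment row onto the column occupied by CDS base *i*; the group key is
"after column *c*". At a boundary, a member without an intron scores
*absent* only if its row is gap-free over a junction window of 3 alignment
columns on each side; any gap there makes it *unalignable* — missing data
never counts as absence. Group status:

* **conserved** — every member present and every member scored;
* **PA** — at least one present and one verifiably absent member *among
  the ingroup (grass) members*;
* **outgroup_only** — polymorphism confined to outgroup members. These
  sites are outside the analysis scope (the study design is grass-centric:
  conserved groups require all members, PA groups require grass
  polymorphism) and are dropped with their own rejection-rule id. This
  scoping also removes the structurally unresolvable class of single
  events on the two root-adjacent branches, where a loss in the outgroup
  is indistinguishable from a gain in the ingroup stem;
* **unscored** — no verifiably absent member (only present + unalignable).

## Filter cascade

Applied in order, each rejection logged with a rule id so the cascade is
auditable: (1) cluster size 3–200 members; (2) reject clusters with >30%
transposon-protein-matching members (mostly mis-annotated pseudogenes);
(3) drop unscored/outgroup-only groups; (4) junction perfection — present
members must be gap-free over the junction window; (5) flanking identity —
every scored member must match the column-majority consensus at ≥60% over
20 columns on each side (identity over the member's non-gap positions;
consensus ties broken alphabetically); (6) reject groups containing an
intron ≤10 bp (annotation artifacts); (7) reject both members of any pair
of PA boundaries closer than 20 alignment columns (intron sliding can
masquerade as adjacent loss+gain). The 3-column junction window and the
20-column identity window are package choices: the junction window is the
smallest that still catches single-codon misalignments, and the identity
window matches the 20-bp flanking-exon windows used in the composition
analyses. Filtering is idempotent and conserves counts
(groups in = retained + rejected).

## Parsimony engine

Losses and gains cost 1 each (events are counted, not weighted); at most
one event per branch (a loss and regain on one branch is invisible and
never minimal); the root state is free — an outgroup pins it only through
parsimony itself. Unknown leaves (unalignable members, missing genes)
impose no constraint. The engine runs a two-state Sankoff pass over the
rooted gene tree (polytomies handled natively, children independent) and
then back-tracks through all cost-optimal child states, collecting event
sets; histories differing only in hidden states of unknown leaves collapse
to the same canonical event set (events are keyed by the leafset under
their branch, which also makes histories comparable across outgroup
augmentation). A group is resolved iff exactly one minimum-cost event set
exists. Enumeration is capped (default 10,000 optimal histories) to bound
pathological ties.

Two counting conventions are exposed: `strict_unique` (the default;
recurrent loss requires a unique history of ≥2 losses and no gain) and
`dollo` (gains disallowed; the minimum loss count equals the number of
maximal absent clades). The five-taxon detectability bound uses the Dollo
convention; the randomization test uses strict uniqueness.

Events in paralogs arising from a species-specific duplication sit on one
ancestral branch and therefore count once by construction; a defensive
normalization additionally merges same-type events on sibling terminal
branches of a same-species pair. Species-branch assignment maps each event
to the branch above the MRCA of the species under its gene-tree branch and
flags the event unmappable when that MRCA subtends species that the gene
tree places elsewhere (gene-tree/species-tree conflict); unmappable events
are excluded from rate sums and reported in diagnostics.

## Dated species tree

Topology `(((((((Zmay,Sbic)12,Sita)26,(Bdis,Osat)47)60,Muca)110,Atha)150,
Smoe)400,Ppat)500` with node ages in MY. The grass and Arabidopsis ages
(12, 26, 47, 60, 150) are the divergence times used for all rate
arithmetic. The banana/spikemoss/moss ages (110, 400, 500 MY) are
literature-typical round values; they affect only simulation and outgroup
rooting, never a rate on a grass branch. Per-genome analyzed-intron counts
(Bdis 31,685; Osat 30,685; Sbic 32,386; Sita 33,230; Zmay 37,119) convert
terminal branch frequencies (events/MY) into rates (events/intron/year).

## Randomization null for recurrent loss

`randomization_test` scatters *n* intron absences uniformly without
replacement over *G* × 5 (group, tip) locations on the five-grass tree
with a present outgroup, reconstructs every group that received ≥2
absences (single-absence groups are single losses by construction) and
sums loss events of strictly-resolved recurrent-loss groups. Because every
group shares one topology, reconstruction reduces to a 32-entry lookup
precomputed with the engine itself. The empirical p for an observed count
is the raw fraction of replicates at or above it, printed as
"<1/replicates" when no replicate reaches it. A closed-form pair-only
approximation (2·C(n,2)·(t−1)/(N−1)·f, with f the engine-computed fraction
of tip pairs giving a unique two-loss history — 6/10 on this topology:
exactly the cross-clade pairs) serves as an independent check of the mean.

## Other statistics

* **Adjacency.** The null probability that a neighbor of a PA intron is PA
  is p0 = (n_PA−1)/(n_total−1); trials are the consecutive boundary pairs
  containing at least one PA group; a run of three adjacent PA groups
  counts as two pairs; one-sided exact binomial upper tail. The trial
  definition is a package choice (the source convention for it is not
  published).
* **Positions.** Relative intron position = breakpoint / CDS length,
  binned into half-open deciles with the last bin closed; chromosome
  positions are (position − centromere)/arm length, negative on the short
  arm, over 20 bins in [−1, 1]. Envelopes are mean ± sd of bin percentages
  over 1,000 sample-size-matched resamples (with replacement) from the
  reference intron set.
* **Contingency tests.** Pearson chi-square; Yates continuity correction
  on by default for 2×2 tables (this convention reproduces the published
  single-intron-gene enrichment p of 1.75e-8, using the single-intron
  genes vs all-introns table with overlapping counts). TG/CG category
  comparisons use a chi-square on the (TG, CG) count pairs with Bonferroni
  α = 0.05/3; TG/CG is flagged undefined (NaN) when CG = 0.
* **Sizes.** Two-sided Mann–Whitney U (exact where scipy supports it).
  When absent members need a size/composition proxy, the closest
  intron-bearing sister lineage in the gene tree is used and flagged.

## Simulator

Each cluster draws an exon scaffold (uniform 60–300 bp exons, last exon
padded to a codon multiple — the 60 bp minimum keeps boundaries clear of
the 20-column spacing filter by construction; boundary positions are
otherwise unconstrained so all three phases occur) and a Poisson(4) number
of ancestral intron sites, plus a small Poisson(0.15) number of
ancestrally-absent sites that can be gained. Each site runs a two-state
continuous-time process down the (optionally duplicating) gene tree:
losses at 1e-4 /intron/MY, gains at 1.4e-5 (the ~7:1 loss:gain regime);
5% of introns are "hot" with a 20× loss multiplier. Only the first
realized event per branch takes effect — exactly what parsimony can ever
observe. These defaults put ~4–5% of sites in the PA class, matching the
observed fraction in the real grass data, and were fixed once as the study
conditions.

Rendering is exact by default: all members share the ancestral exon
sequences, so cluster alignments are gap-free and every true site projects
onto its true boundary column. Introns render as `GT` + body + `AG`;
intron bodies are drawn at 39% G+C (exons at 55%) with CG→CA depletion
that is *weaker* for hot introns (0.3 vs 0.6), reproducing the direction
of the TG/CG signal (recurrently lost introns less CG-depleted than
conserved ones). Opt-in junction noise deletes two CDS bases at the
junction of an intron-absent member and renders them as alignment gaps,
which the detector must score unalignable.

What the simulator does **not** emulate: exonic substitutions and indels
(alignments are exact unless noise is requested), codon usage and
selection, gene conversion, annotation error beyond the junction-noise
mode, and assembly artifacts. Passing tests therefore demonstrate the
correctness of projection, reconstruction and counting — not robustness
to alignment error in real data, which is exactly what the filter cascade
is for.

## Problem sizes and determinism

The test suite runs the full 10,000-replicate randomization (sub-second:
the pattern-lookup reduction makes replicates O(n absences)), compares the
engine against an exhaustive internal-labeling oracle on 1,000 random
trees of ≤12 leaves, and validates end-to-end recovery on simulated
datasets of 60–120 clusters — sizes chosen so the whole suite completes in
well under a minute while every property is exercised at full fidelity.
One global seed fans out to per-stage seeds by stable hashing; identical
seeds give byte-identical datasets, artifact tables and acceptance JSON.

## Known limitations

* Parsimony understates loss when losses greatly outnumber gains: some
  true multi-loss histories are called single gains or remain unresolved.
  The package reports these categories rather than correcting for them;
  the Dollo switch and outgroup augmentation are the provided remedies.
* Single events on a root-adjacent branch of the rooted gene tree are
  intrinsically ambiguous; the grass-centric scope removes the common
  case, outgroup augmentation the rest.
* Species-branch mapping uses MRCA projection, not full gene-tree/
  species-tree reconciliation; conflicting events are flagged, not
  reconciled.
* The adjacency null treats neighbor slots as independent Bernoulli
  trials, which is conservative for clusters with many PA groups.
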