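# Methods

This note documents the models, conventions and design choices behind
`mybkit`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Landmark model of the R2R3 domain

The scanner treats the ~108-residue DBD as a rigid coordinate frame with
seven scoring landmarks: Trp at positions 9, 29, 49, 62, 81, 100 and Cys at
45 (1-based domain coordinates, matching the conventional residue numbering
of plant R2R3 alignments).  Position 62 accepts {W, F, I, L, Y}, because in
real families this is the one tryptophan routinely replaced, almost always
by another hydrophobic residue.  Cys-41, the LRPD linker (53–56, consensus
`L-R-P-[DN]`) and the R2 helix-2/3 insertion residue (position 38, L or G)
are recorded per hit and summarized by `profile_alignment`, but do not
score: Cys-45 is the invariant cysteine, Cys-41 the variable one.  Helix
annotations in `DomainModel` are descriptive defaults only — the true
boundaries vary by a residue or two between members — and nothing computes
from them.

Scoring replaces homology-search E-values deliberately: it is
self-contained, database-free, and exactly reproducible.  Each window start
is evaluated ungapped and under every single-indel interpretation (one
insertion or deletion at any inter-landmark interval, window width
107–109), reflecting the rarity of indels inside the domain; the
best-scoring interpretation wins.  Overlap resolution keeps the higher
score, then prefers the ungapped interpretation, then the leftmost window —
the middle rule exists because a spurious single-indel reading one residue
away from a true domain can tie it on score.  The default reporting
threshold is 5/7 (sensitive screening); recovery benchmarks and the
synthetic pipeline use 6/7, at which chance windows in random sequence are
effectively impossible.  A brute-force window check is the test oracle.

## Gene structure

Coordinates are GFF3 1-based inclusive throughout; an intron is the open
gap between consecutive CDS intervals of a transcript, reported 5′→3′ in
coding orientation.  The splicing phase is the codon-interruption
convention — coding nucleotides upstream of the splice, mod 3.  This is
*not* the GFF3 CDS `phase` column, which gives the offset to the next codon
start; the conversion `intron_phase = (3 − cds_phase) % 3` is implemented
and cross-checked in the tests, alongside a translation oracle (spliced-CDS
translation must reproduce the protein on every synthetic gene, on both
strands).

An intron maps into the domain as the 1-based index of the codon it
interrupts (phase 1/2) or of the codon it follows (phase 0), relative to
the domain start.  The pattern taxonomy is an editable table of
site-window/phase requirement sets; a gene matches a label when its domain
introns biject onto the label's sites.  Exact positions for the canonical
R2 and R3 sites are only known graphically in the source material, so the
shipped windows (R2 45–50 phase 1; R3 93–100 phase 2; three auxiliary sites
for the rare patterns) are calibrated defaults with tolerance built into
the window, not measured coordinates; taxonomy validation rejects
configurations in which one intron set could satisfy two labels.  For
multi-transcript genes the longest-CDS transcript is the representative
(deterministic, standard gene-family practice); transcript-variant counting
compares ordered exon-interval structures, not transcript ids.

## Phylogeny

Distances: p-distance with pairwise deletion (columns gapped in either row
of a pair are skipped for that pair; a pair with no comparable columns is
an error surfaced per pair), Poisson-corrected as −ln(1 − p).  Saturated
pairs (p ≥ 1) raise rather than silently truncating.

Neighbor joining follows Saitou–Nei exactly, with two determinism rules:
Q-matrix ties break toward the lexicographically smallest pair of cluster
ids (a cluster is named by its smallest leaf), and negative branch-length
estimates are clamped to zero with the deficit moved to the sibling so the
joined distance is preserved.  On additive matrices the tree reproduces the
input path lengths exactly; the suite verifies topology recovery on 100
random additive trees (n ≤ 12) and cross-checks against an independent NJ
implementation (scikit-bio).

Bootstrap resamples alignment columns with replacement to the original
length; replicates with a saturated or incomparable pair are dropped and
counted.  Support is the percentage of successful replicates containing
each internal bipartition of the point-estimate tree.

Subgroup assignment takes maximal clades with support ≥ 50 % and ≥ 2
members.  Because an NJ tree is unrooted and support belongs to edges, not
sides, reading clades off an arbitrary rooting can credit a stem edge's
support to the complement of the group it delimits — merging well-separated
groups or splitting one across the root.  `assign_subgroups(reroot=True)`
therefore tries every internal node as root and keeps the rooting with the
fewest unassigned leaves (ties: highest mean subgroup support, then fewest
subgroups, then traversal order).  This recovers a planted partition
exactly when there are at least three groups; with only two, side identity
on the single supported edge is inherently ambiguous.  Whole-protein trees
use the same machinery over a center-star progressive alignment
(BLOSUM62, gap open −10 / extend −0.5) — a documented simplification of a
full progressive aligner, adequate for the low-divergence inputs the
package targets.

## Duplication

"Similarity" is operationalized as global-alignment identity
(matches / alignment columns, end gaps included), computed with Biopython's
pairwise aligner under needle-like parameters.  Cluster thresholds are
conjunctive and inclusive (DBD ≥ 90, full ≥ 60); single linkage builds the
clusters.  Tandem calls fire on either the rank rule (≤ 2 intervening
genes) or the distance rule (≤ 250 kb, configurable) — both criteria exist
because "physically near" is scale-dependent across genomes.  Without a
duplicated-block file, cross-chromosome linked pairs are called segmental
heuristically; with one (6-column paired BED-like format) calls become
evidence-based, including same-chromosome segmental events.  A tandem
array is a connected component of tandem-classified pairs.

## Motifs

Discovery is deterministic conserved-block extraction rather than EM: over
a center-star alignment of one subgroup's C-terminal regions (everything
after the domain hit), a block is a maximal run of columns that are gapless
in ≥ `min_member_fraction` of members, majority-dominated (≥ 75 %, the
conventional alignment-shading rule) and informative (plug-in IC ≥ 1.5
bits).  The majority rule matters: with a handful of sequences the plug-in
IC of a *random* column is strongly biased upward (with n = 6 draws from 20
residues, observed IC ≈ 1.7 bits even when nothing is conserved), so an IC
floor alone would hallucinate blocks; requiring a dominant residue removes
that failure mode without an explicit small-sample correction.  Width
bounds (6–300), the one-occurrence-per-sequence rule and the 100-block cap
are honored; blocks rank by total IC.  Scanning regularizes frequencies
with pseudocount 0.01, uses a uniform background (overridable), and scores
windows by summed log-odds; the default threshold is half the block's
maximum attainable score, at which every recorded occurrence of a
discovered block is rediscovered (closure is a tested invariant).

## Profiles

Expression input is ordinal (band calls 0–3); presence floor 1 and
preference ratio 2 are explicit, configurable renderings of a qualitative
readout.  Categories partition the gene set: below-floor everywhere →
`none`; a unique maximum ≥ ratio × runner-up → `preferential:<tissue>`;
otherwise the top tissues within the ratio of the maximum form either
`ubiquitous` (all tissues) or `balanced:<set>`.

The miRNA scanner adopts the standard plant complementarity-penalty
convention — mismatch 1.0, G:U wobble 0.5, doubled at miRNA positions 2–13
from the 5′ end, cutoff 4.0 — as an explicit convention, since target
prediction rules are rarely stated precisely in survey papers.  The mature
miRNA (19–24 nt) is slid antiparallel along each transcript; scanning
defaults to full transcripts (the pipeline uses spliced CDS, the natural
choice when no UTR annotation exists).

## Synthetic families

The generator emulates exactly the features the analysis measures, and no
more: no codon bias (uniform synonymous codons), no realistic nucleotide
composition, no repeat content, no promoters, no UTRs.  Passing tests
therefore demonstrate correctness of the *methods* under controlled truth,
not performance on real genomes, where domain divergence, fragmented gene
models and assembly artifacts add noise the generator does not model.

Conditions (defaults chosen once): 3 subgroups × 6 genes, mutation rate
0.02/residue (bounded at 0.05 in recovery benchmarks), landmark/linker/
insertion positions protected, subgroup divergence = 3 × mutation rate
realized as disjoint marker-substitution sets so that between-subgroup
signal dominates within-subgroup noise and deep edges carry no shared
signal (matching the low deep-node support seen in real family trees);
2 three-gene tandem arrays (members 2–50 kb apart, same chromosome) and 2
segmental pairs (different chromosomes), with near-identical copies so the
90/60 identity rule separates planted duplicates from ordinary subgroup
siblings; singleton intergenic spacing ≥ 300 kb puts non-duplicates
unambiguously outside the tandem rule; per-subgroup random C-terminal
motifs of 18 residues inside 60–110-residue random flanks; a survey-scale
intron-pattern mix dominated by pattern `a` (44 %); expression categories
drawn from a fixed mix and realized noise-free (an optional dropout flag
exists for robustness experiments).  Everything derives from one integer
seed and reruns byte-identically.

## Problem sizes

The shipped tests and the acceptance script run at family sizes of 12–30
genes, 100–200 bootstrap replicates, and 100 NJ recovery trials at n ≤ 12 —
sizes chosen so the whole validation cycle completes in well under a minute
while every stage still exercises its full code path.  The pipeline itself
has no size assumptions beyond O(n²) pairwise alignment in the duplication
and alignment stages.

## Known limitations

* The landmark scanner assumes the R2R3 architecture; 1R-, 3R- and
  4R-MYBs are only flagged (multi-hit proteins), not modeled.
* Center-star alignment degrades on deeply diverged inputs; real surveys
  would substitute a full progressive aligner upstream and feed the
  alignment in via `phylogeny.Alignment`.
* Segmental calls without a block file are heuristic by construction.
* Subgroup recovery requires ≥ 3 groups (unrooted-tree ambiguity, above).
* Maximum-likelihood trees, profile-HMM search, E-value statistics, Ka/Ks
  dating and de novo synteny detection are out of scope.
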