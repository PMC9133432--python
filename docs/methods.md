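# Methods

This note documents the models, conventions and numerical choices behind
`gpcrsel`, and what the synthetic study conditions do and do not show.

## Ortholog selection

Gene trees are rooted on a designated outgroup leaf (by convention a
distant human paralog).  Rooting re-orients the tree around the edge above
the outgroup; polytomies are then resolved deterministically, ordering a
node's children by their smallest leaf name and folding them into a
ladder, so the result depends only on leaf names and never on input child
order.  The ortholog walk starts at the human target leaf and climbs
parent by parent: a newly joined sibling subtree is absorbed when its
species set is disjoint from the species collected so far, excluded (with
reason `reseen_species`) when it re-shows a species — re-seeing a species
below the current level indicates differential gene loss — and the walk
stops, without absorbing, at the first sibling containing a human leaf
other than the target, which marks the gene-duplication boundary.
Duplicate species *within* a single absorbed subtree do not trigger
exclusion; only cross-step re-sightings do.  Species comparison is a
case-insensitive exact match on the parsed species token.

## Paralog trimming

Every internal node with two child clades is assessed leaves-up
(post-order); leaves of a removed clade are excluded from all later
assessments.  A node is assessed only when its child clades share at
least one species.  With ≥ 3 leaves on both sides, the clades must first
be evolutionarily comparable: a two-sample *t* test on per-leaf counts of
taxonomic ranks shared with the human lineage (set intersection of rank
lists) must not reject at the same α (default 0.1).  If comparable, a
two-sample *t* test on global alignment scores against the human target
decides removal of the lower-mean clade at *P* ≤ 0.1.  With < 3 leaves on
both sides, the lower-average clade is removed without a test (an exact
tie removes nothing); mixed sizes remove nothing.

Conventions: *t* tests are classic two-sided equal-variance Student tests
(Welch available via `equal_var=False`); the "significantly lower"
direction is checked on the means after the two-sided test.  Alignment
scores are Needleman–Wunsch optimal global scores with BLOSUM62 and
affine gaps — a gap of length k costs 11 + (k−1)·1, the
EMBOSS/BLAST-like default, since only the matrix is prescribed by the
method.  A zero-variance *t* test (identical constant samples) is read as
*P* = 1, i.e. no evidence of a difference.  If a removal would take out
the clade containing the human target, the pipeline raises a diagnostic
error rather than removing it silently.

## Conservation and specificity

Column conservation is `(count(modal) + count(allowed)) / non-gap` with
*allowed* meaning BLOSUM80 score strictly greater than 2 against the modal
residue ("higher than 2" is taken strictly: ≥ 3 on the integer half-bit
matrix).  Columns with more than 50 % gaps are gap-flagged and unscored;
exactly 50 % is still scored.  Modal ties break alphabetically.  `X`
counts in the non-gap denominator but can never be modal or allowed.  The
BLOSUM matrices are the standard half-bit integer tables shipped with
biopython.

Position labels use strict threshold comparisons (> 0.9, < 0.7) matching
the "more than"/"lower than" semantics of the thresholds.  On the integer
matrix the consensus similarity cutoff (> 1) and the specificity
dissimilarity cutoff (< 2) partition cleanly: a modal-pair score of
exactly 2 is treated as similar in both rules, the only self-consistent
reading of the three cutoffs.  Consensus across a receptor panel is
defined as the consensus label in every pairwise family comparison
(fraction configurable).

## Enrichment

The specific approach counts ordered coupler/non-coupler family pairs
(n·m comparisons) and ordered within-coupler pairs (n·(n−1)); a column is
reported iff its cross frequency is positive and its within frequency is
exactly zero.  Ordered and unordered counting give the same zero/nonzero
decision; ordered is used because the comparison counts are quoted that
way.  The sensitive approach compares one pooled alignment of all
couplers and their orthologs against each non-coupler family and reports
columns with frequency strictly above a configurable minimum (default 0,
mirroring the specific approach's positivity requirement).  G12 and G13
are excluded from the sensitive approach by default (few couplers, high
false-positive risk); the exclusion list is configurable.  Families are
compared under a shared coordinate system — the identity column map over
equal-length alignments, i.e. the "combined MSA split in two" setting —
with an optional explicit column subset.

## RRCS and networks

RRCS constants: d_min = 3.23 Å, d_max = 4.63 Å; contact weight 1 below
d_min, 0 at or above d_max, linear between.  For residue pairs on the
same chain with sequence separation < 5, backbone atoms (N, CA, C, O) are
excluded.  These constants follow the published contact-score method and
are exposed in the API.

ΔRRCS is active − inactive, so positive means a contact formed upon
activation (the sign convention matching "red = increasing contact"
network renderings); a pair absent on one side contributes zero.  Edges
with |ΔRRCS| ≤ 0.2 are dropped; the conserved-residue pool restriction
requires both endpoints in the pool by default (`either` available).
The common network keeps edges present in at least `min_count` (default
36) of the per-pair networks, counting occurrences regardless of sign.
Gα-specific networks compare the per-pair ΔRRCS values of a coupler group
against all remaining receptors with a two-sample *t* test per edge
(absent edges contribute zero), retaining edges at the per-subtype α
(defaults 0.01; 0.1 for Gi1) valued by the group-minus-rest mean
(ΔΔRRCS).  When both samples are constant, equal means are skipped and
distinct means are kept with *P* = 0 — a persistent all-or-nothing
contact difference is maximally significant, and the nominal *t* test is
undefined there.  An exclusion list removes receptors or individual
structures from both samples, supporting leave-one-out re-tests.
`PairingPlan` builds per-receptor active × inactive Cartesian products
and accepts an explicit pair list for curated pairings.

## Trajectory analysis

Frames are sampled on the grid start, start+step, …, end (nearest frame
per grid time, both endpoints inclusive): 0–500 ns at 50 ns gives 11
frames per replicate, hence 77 frames for 7 active replicates and 22 for
2 inactive ones.  WT-vs-mutant contact changes are two-sided two-sample
*t* tests on per-frame RRCS values per residue pair, at α = 0.05 by
default (a stricter reporting α can be applied downstream); pairs
constant-zero on both sides are skipped.  The cross-mutant intersection
keeps edges significant in every mutant's network.  State classification
uses the GPCRdb two-distance metric d(2x41–6x38) − d(3x44–7x52) on Cα
atoms (the atom choice is a convention; the metric definition does not
fix it): active above 7.15 Å, inactive below 2 Å, intermediate otherwise,
with strict inequalities so the exact boundary values are intermediate.

## Synthetic study conditions

The generators are pure functions of spec + seed and emit their ground
truth alongside the data (JSON sidecars via the `save_*` helpers).

* **Families/cohorts** use i.i.d. per-column substitution noise with no
  phylogenetic correlation — sufficient to exercise the scoring
  arithmetic, but real ortholog alignments carry correlated substitutions
  and alignment errors that these fixtures do not emulate.  Cohorts share
  one background residue profile across families (so non-determinant
  columns can only be consensus), plant determinants as one coupler
  residue versus a BLOSUM80-dissimilar (score ≤ 1) non-coupler residue,
  and default to 3 couplers, 3 non-couplers, 12 orthologs per family,
  60 columns, 3 determinants and 20 % variable columns.
* **Paralog trees** hold an ortholog clade (human target + 5 species by
  default) and a paralog clade with fully overlapping species, evolved
  from a shared 120-residue ancestor at a 5 % per-site base substitution
  rate plus an extra per-site probability 1 − exp(−divergence) for the
  paralogs.  Species share a constant four taxonomic ranks with the human
  lineage, so the comparability test never fires on these fixtures and
  the false-removal rate isolates the score test's type-I error.
* **Structure pairs** place one Cα pseudo-atom per residue on an 8 Å
  grid (no accidental contacts) and realise planted contacts through
  side-chain pseudo-atoms 3.0 Å apart; contact sites of distinct pairs
  are offset sideways, but geometrically crossing pairs can still touch —
  with a single planted pair the realised contact set is exact.
* **Trajectories** are convex combinations of two coordinate templates
  plus Gaussian noise with timestamps uniform over 0–500 ns; they model
  none of the kinetics of real MD and serve only the sampling,
  statistics and classification machinery.  The marker templates place
  the four activation markers at metric 10.0 Å (active) and 0.5 Å
  (inactive), far from both cutoffs relative to the default noise.

## Problem sizes of the checks

The acceptance script and test suite use: 1000 random columns and 20
random 20-residue structures for kernel/oracle agreement (exact rational
arithmetic for conservation, ≤ 1e-9 for RRCS); 50 cohort seeds at 2 %
substitution noise for determinant recovery; 100 tree seeds each for the
paralog false-removal rate (divergence 0) and removal power (divergence
1.0, i.e. ~63 % extra per-site substitution probability); 200 seeds per α
for the null-retention calibrations, with target-clade diagnostics counted
as removal events.  These sizes give binomial standard errors small
enough to check the nominal rates while keeping the full run in the
minutes range on one CPU.

## Known limitations

* Sequence fixtures lack phylogenetic correlation, indels beyond i.i.d.
  gaps, and rate heterogeneity; passing recovery tests shows the scoring
  and bookkeeping are correct, not that thresholds are optimal for real
  alignments.
* The generic-number map is always an input; no structure-based numbering
  is computed.
* Group-specific network tests treat structure pairs within a receptor as
  independent samples, as the group-wise comparison requires; real pairs
  of the same receptor are correlated, so the nominal α is approximate
  there.
* Frames are consumed as in-memory models or multi-model PDB; binary
  trajectory formats are out of scope.
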