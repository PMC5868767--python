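# Methods

## The inference problem

Multi-spanning membrane proteins are hard to relate by sequence. Their
transmembrane segments (TMSs) are low-complexity hydrophobic stretches, so
two channels with no common ancestry can reach alignment E-values that
would count as highly significant for soluble proteins. On the synthetic
data used throughout this package, unrelated 10-TMS proteins of ~700
residues routinely align with Karlin–Altschul expectations far below
1e-10 — a fixed E-value cutoff demonstrates nothing in this regime.

The package therefore builds homology inference on a *shuffle z-score*:

    z = (S_real − mean(S_shuffled)) / sd(S_shuffled)

where `S` is the global affine-gap alignment score (BLOSUM62, gap open 8,
extend 2 — the classical FASTA-era global defaults) and the null sample
comes from re-aligning composition-preserving shuffles of both sequences
(500 shuffles for screening, 1000 for verification; shuffling both inputs
is the default because it destroys residual structure in either one, and a
single-sequence mode is available). Shuffling preserves composition, so
the statistic discounts exactly the hydrophobic-composition similarity
that inflates E-values. The z-score is never converted into a p-value; it
is a ranking scale calibrated against negative controls (below).

## Transitivity pipeline

Homology between two families A and D is judged through a path
A → B → C → D:

1. **Expansion.** Each family is searched against a local sequence
   database with exhaustive Smith–Waterman. Hits must cover ≥ 45% of the
   query at E < 1e-2; the aligned region of each hit is extracted, and the
   regions are redundancy-reduced greedily (longest first) at 90% identity
   over the shorter sequence, with redundancy allowed when the length
   ratio exceeds 1.8 (a fragment is not redundant with a full-length
   protein).
2. **Candidate pairing.** All pairs between the two expanded lists are
   locally aligned and given an initial 500-shuffle z-score on the aligned
   regions; each sequence's TMS peaks are mapped through the alignment and
   a TMS counts as overlapping when at least half of its aligned columns
   fall inside a TMS of the partner. Candidates need ≥ 5 overlapping TMSs
   and ≥ 150 aligned residues to proceed.
3. **Verification.** For a candidate (B, C) the three legs A–B, B–C, C–D
   are re-scored with 1000 shuffles on terminal-trimmed sequences
   (hydrophilic N-/C-tails outside the first/last TMS peak ± 10 residues
   removed). The *comparison score* is the minimum of the three legs. B
   and C may be the same database protein, in which case the middle leg is
   a self-comparison over the selected region.
4. **Verdict.** The comparison score is compared with a threshold equal to
   the highest comparison score observed over negative-control family
   pairs plus a 2 SD safety margin. Controls run through the same
   expansion/pairing machinery; only a control path's cross-family legs
   are given full shuffle scoring, because within-family legs are
   self-matches whose z-scores are an order of magnitude above any cross
   leg and can never be the minimum.

The min-leg rule is the load-bearing safeguard: expansions of unrelated
families genuinely pick up common junk matches (coverage-passing
hydrophobic alignments), and such paths always contain one cross-family
leg that collapses to the control band.

### Search economics

When a candidate cap is set, pairs are pre-ranked by the weakest link of
the prospective path — min(anchor raw score on the A side, pair raw
score, anchor raw score on the D side) — so that genuinely bridging pairs
are screened ahead of high-scoring but unanchored self-matches; an
uncapped run scores every pair. During verification the cheapest-to-refute
leg (lowest raw local score) is z-scored first and the path is abandoned
as soon as any leg falls below the threshold; the search ends early once a
path clears the threshold by 4 SD, or after three consecutive failures.
These short-circuits change which paths are *examined*, never how a path
is *scored*.

## Topology analysis

Per-residue hydropathy uses the Kyte–Doolittle scale averaged over a
19-residue window (the span of a membrane-crossing helix); windows are
truncated at sequence ends so profiles keep one value per residue, which
is what allows mapping profiles through alignment columns. `X` contributes
scale value 0. TMSs are called as maximal runs of profile values ≥ 1.0
scale units, merging runs separated by fewer than 5 positions and
discarding runs shorter than 9. Amphipathicity is the Eisenberg
hydrophobic-moment magnitude at 100°/residue over the same window.

Family-level curves average each member's ungapped profile through the
alignment's gap structure. Alignments are first trimmed to columns with at
most 30% gaps, and a column only contributes when at least 30% of members
provide a residue there. Similarity per column is the mean normalised
substitution score of residue pairs, s(x,y)/√(s(x,x)s(y,y)) under
BLOSUM62, min–max scaled over retained columns — a fully conserved
alignment is maximal everywhere regardless of which residues it conserves.

## Clustering

All-vs-all local bit scores (Karlin–Altschul normalised, BLOSUM62 11/1)
define the dissimilarity d(i,j) = 1 − S(i,j)/min(S(i,i), S(j,j)), clipped
to [0, 1]. Ward linkage (scipy) clusters the matrix; quality is reported
both as the cophenetic correlation (primary) and the agglomerative
coefficient, because "clustering coefficient" is used for either quantity
in the literature. Dendrograms export to Newick with branch lengths
derived from merge heights.

## Motif analyses

Anchor residues (labelled positions on a reference sequence, e.g. the six
Ca²⁺-binding residues of a reference channel structure) are mapped through
the reference row of a family MSA; members gapped at an anchor column are
flagged and excluded from logos. Motif windows span the columns between
anchor pairs, yielding per-family frequency matrices and information
content in bits. The helical-neighbour scan looks 3/4 and 7/8 residues up-
and downstream of each anchor in ungapped member coordinates — one and two
turns of an α-helix (3.6 residues/turn), i.e. the same helix face — and
reports fractions of D/E/N/Q (candidate Ca²⁺ ligands) and K/R/S
(stabilisers). PWM scanning computes exact hit p-values by dynamic
programming over the background composition (scores discretised at 1e-3
bits) and E-values as p × number of offsets; motif *discovery* is an
optional wrapper around an external tool that raises a capability error
when absent.

## Repeats

Internal sequence repeats: two non-overlapping regions (≥ 40 residues) of
one protein are compared with the shuffle z-score. Structural repeats:
consecutive, non-overlapping bundles of 3/4/5 helices are superposed by
Kabsch on Cα atoms with sequential helix correspondence (helix i onto
helix i; no combinatorial rematching — real-structure RMSDs are therefore
approximate relative to graph-matching superposition tools, within ~0.5 Å
in our comparisons of alternative correspondences on synthetic bundles).
Unequal helices are slid to the offset minimising overall RMSD; loops are
compared centre-trimmed when included. A superposition is significant when
RMSD < 4 Å over ≥ 60 residues.

## Synthetic data: what it emulates and what it does not

Synthetic proteins alternate hydrophobic segments (21 ± 2 residues, drawn
from an I/L/V/F/A/M-weighted pool) and hydrophilic loops (45 ± 12, from a
D/E/K/R/S/T/N/Q/G/P-weighted pool) with ~40-residue termini — ten TMSs and
~700 residues by default, matching the compact end of real channel
families. Families evolve from an ancestor by matrix-biased substitution
(P(b|a) ∝ exp(BLOSUM62[a,b]/2), conditioned on segment type so membrane
residues stay membrane-compatible — the selective constraint real
membrane proteins evolve under; without it, deep divergence erodes the TMS
architecture, which real superfamilies do not show) and by short indels
restricted to loops, so per-member TMS truth stays well defined. The
per-member substitution rate for a target pairwise identity t is
1 − √t.

Superfamily chains derive each next family ancestor through three equal
sub-steps of divergence with full segment-length remodelling per step
(loop and TMS lengths redrawn from the family distributions); the two
intermediates per edge are emitted into the database as bridge sequences.
An edge retains 25% residue identity, so bridge-mediated path legs (at
most two-thirds of an edge, ~40% identity) score far above the control
band while chain-end pairs (two edges, ~6% residual identity with
independent loop architecture) compare like negative controls — homology
that only the transitivity path can demonstrate. Negative-control and
unrelated families are generated independently with the same architecture
and composition, which is precisely the hard null a shuffle-calibrated
statistic must beat.

What the generator does not emulate: site-rate heterogeneity, realistic
tree shapes (only stars and chains), domain gain/loss, fusion proteins,
signal peptides, re-entrant loops, or biased loop compositions beyond the
pool weights. Passing tests on this ground truth show the pipeline's
statistics and filters behave as designed under the stated null; they do
not certify performance on real databases, where composition bias and
domain mosaicism are richer.

Helix bundles are ideal α-traces (100°/residue, 1.5 Å rise, 2.3 Å radius)
antiparallel on a circle, joined by interpolated loops; the noise level is
the expected per-atom RMS 3-D displacement (per-coordinate σ/√3).

## Problem sizes and numerical choices

The verification studies run at: 32 negative-control family pairs for
threshold calibration; 20 seeded superfamilies (3 related + 2 unrelated
families of 3 members each) for the recovery study in the test suite, 5
in the acceptance script; 100 proteins for topology recovery; 7 × 3
sequences per clustering replicate; 100 seeds for the structural noise
band. Alignment scores are integer dynamic programming (int32) with a
deterministic traceback preferring diagonal, then up, then left; gap cost
is open + (L−1)·extend. E-values use published Karlin–Altschul parameters
(BLOSUM62 gapped 11/1: λ = 0.267, K = 0.041; ungapped: λ = 0.3176,
K = 0.134); parameter sets without published fits raise an error rather
than fitting λ on the fly, for determinism. The spec of every threshold
(coverage 45%, E < 1e-2, identity 90%, ratio 1.8, 5 TMSs, 150 residues,
500/1000 shuffles, rescue E < 1e-3 at 70% overlap, distant-member
E < 1e-5, gap fractions 15–30%, RMSD < 4 Å over ≥ 60 residues, scan
E < 1e-5) is a named configuration key with these defaults.

## Known limitations

* Karlin–Altschul E-values carry no composition correction, so on
  membrane proteins they are uniformly tiny; every E-value-based filter
  here is a coarse pre-filter, and the calibrated z-score does the real
  discrimination. The distant-member cascade's "already known" E cutoff
  must be chosen for the database at hand.
* The homology threshold is only as good as the negative controls: they
  must match the positives' composition and architecture, and the control
  maximum depends on how adversarially the candidate search is allowed to
  optimise over paths — calibration therefore runs the same search
  machinery as the verdicts.
* Sequential helix correspondence understates structural repeat quality
  when helix order is permuted between bundles.
* The similarity curve and the TMS caller are documented stand-ins for
  unpublished web-tool internals; their defaults are configuration, not
  ground truth.
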