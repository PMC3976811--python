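# Methods

This note documents the models, rules and numerical choices behind
`wrkytools`, and what the synthetic-data tests do and do not demonstrate.

## Domain model and classification

A WRKY domain is detected as a grammar match rather than a profile-HMM hit:
the heptapeptide `W p2 p3 Y G p6 K` with `p2 ∈ {R,K,L,S,V}`,
`p3 ∈ {R,K,C}`, `p6 ∈ {Q,Y,E,L,K}` (the union of the named natural
variants WRRY/WSKY/WKRY/WVKY/WKKY and the observed single-residue
substitutions), followed by the nearest downstream zinc finger whose first
cysteine starts within 50 residues of the heptapeptide end.  Two finger
grammars are tried at each anchor, C2H2 (`C X{4,5} C X{22,23} H X H`)
first, then C2HC (`C X{5,8} C X{25,28} H X{1,2} C`).  The 50-residue
window and the C2H2 precedence are package choices: the finger spacings
are fixed by the family literature but no search window or precedence is
defined there, and both choices are deterministic and conservative.  `X`
in a protein can occupy spacer positions but never satisfies a named
C/H position.

Groups follow the standard scheme — two heptapeptide hits with at least
one complete domain ⇒ group I (a degraded C-terminal domain does not
disqualify an otherwise intact two-domain protein); one complete domain ⇒
II or III by finger class; anything weaker is UNCLASSIFIED.  Candidates
are dropped when no complete domain reaches 40 residues
(heptapeptide start to finger end), i.e. 2/3 of the nominal 60-residue
domain.

Group II subgroups are assigned by the nearest labelled reference domain
under p-distance on a pairwise global alignment, ties to the earlier
reference, and an "unplaced" label beyond distance 0.6.  This is a
deterministic, testable proxy for tree-based subgroup assignment; users
who want the tree route can build one with the phylogenetics module.  The
packaged default references are the synthetic subgroup templates (below),
not natural sequences.

The zinc-finger spacing signature (e.g. `CX4CX23HXH`) is reported as a
diagnostic only: the observed spacing classes overlap between subgroups
(one subgroup can show two spacings), so classification never uses it.

Pseudogene evidence is computed from the CDS alone: any in-frame stop
before the final codon, and "frameshift" operationalised as CDS length not
divisible by three.  No alignment against an intact paralog is attempted
— the package has no procedure to locate compensatory indels, so this is
the strongest definition supportable from a single sequence.

## Genome organization

Duplicate pairs use strict thresholds: aligned nucleotide coverage of the
longer CDS > 0.70 *and* amino-acid identity > 0.70 (a pair at exactly
0.70 fails).  Coverage counts residue-on-residue columns over the longer
length; identity counts identical columns over all aligned columns.
Pairwise alignment is Needleman–Wunsch with affine gaps (BLOSUM62,
open 10/extend 1 for proteins; +2/−3 with open 5/extend 2 for
nucleotides; a gap of length k costs open + k·extend).  The scoring
parameters are package defaults — the survey protocol named its aligner
but not its parameters — and no reported result depends on borderline
scores.  Pairs with an unplaced member cannot be tandem and are labelled
segmental with a caveat flag.

Clusters are single-linkage chains of representative coordinates: per
chromosome, sorted genes join one cluster while consecutive gaps are
≤ 200 kb, and chains with ≥ 2 members are reported.  Only a single
coordinate per gene is available in the packaged table, so chaining on
representative positions is the only rule consistent with the printed
definition.  Note the documented discrepancy: the survey this table was
curated from reported 13 genes in six clusters (two each on chromosomes 2
and 4), but the strict rule applied to the printed coordinates yields four
clusters over nine genes — chromosome 2 chains into a single 3-gene
cluster and chromosome 4 holds one ≤ 200-kb pair.  The pipeline emits the
rule-faithful result and logs the comparison.

## Gene structure

Intron phase is the cumulative upstream coding length mod 3.  An R-type
intron is phase 2 and splits a codon encoding R between the heptapeptide
start and the first zinc-finger cysteine (when several R codons precede
the finger, the first is the planted/checked anchor).  A V-type intron is
phase 0 immediately before the codon at second-cysteine + 6, and requires
a C2H2 finger per its definition; C2HC (group III) genes can only host
R-type or OTHER introns.  Classification depends only on exon geometry
and the protein, so adding UTR-like constant offsets to exon coordinates
does not change calls.

## Phylogenetics

Distances are p or Poisson-corrected (−ln(1−p)) with pairwise gap
deletion; a pair with no comparable sites, or a saturated pair (p = 1)
under the Poisson model, is an error naming the pair.  NJ is the
Saitou–Nei Q-criterion with two determinism policies: ties break on the
smallest index pair, and a negative pendant length is clamped to zero with
the deficit moved to its sister so path lengths are preserved.  Bootstrap
resamples columns with replacement and reports, for each internal edge of
the full-data tree, the percentage of replicate trees containing the same
bipartition; a majority-rule consensus is deliberately not constructed
(supports belong on one tree).  The progressive aligner is intentionally
basic: UPGMA guide tree on pairwise NW p-distances, profiles merged by
affine-gap NW on mean BLOSUM62 column scores.  It is adequate for
~60-residue domain sequences; it is not a substitute for a production MSA
tool on long, gappy proteins.

## Codon models and selection

The substitution process is GY94 over the 61 sense codons of the
universal code (stop-containing codons in input data are rejected at
load — stop-carrying pseudogenes must be excluded upstream): single-
nucleotide changes have rate π_j multiplied by κ for transitions and ω
for nonsynonymous changes, scaled to one expected substitution per codon
per unit branch length, so branch lengths read as substitutions/codon.
Codon frequencies default to F3x4 (positional nucleotide frequencies of
the data, floored at 1e-8 and renormalised); F61-style custom frequencies
can be passed explicitly.

Site models: M0 (one ω), M3 (three free ω classes with free weights), M7
(ω ~ Beta(p, q) in 10 equal-probability classes, using within-bin means),
M8 (proportion p0 from Beta(p, q) plus a class at ω_s ≥ 1).  Likelihoods
use Felsenstein pruning with per-node rescaling and site-pattern
compression; gaps are missing data (unit partials).

Fitting: M0 optimises κ, ω and all branch lengths jointly (log-scale
L-BFGS-B; bounds κ ∈ [0.1, 20], ω ∈ [1e-4, 50], branch ∈ [1e-8, 20];
three fixed starting points).  M3/M7/M8 keep the M0 branch-length
*proportions* and optimise κ, a global branch scale and the
ω-distribution parameters (beta parameters bounded [0.05, 99]), starting
from the null model's optimum — M3 starts at the exact M0 point and M8 at
the exact M7 point (p0 = 1) — so the nesting inequalities
lnL(M3) ≥ lnL(M0) and lnL(M8) ≥ lnL(M7) hold by construction; the best
parameter vector ever evaluated is kept.  This branch-scale treatment is
the package's design choice for keeping the richer fits inside a small
compute budget; it is exact at the null point and standard practice when
branch lengths are nuisance parameters.  A fit whose optimiser never
reports convergence is flagged, not silently returned, as is an
effectively zero-length tree (ω unidentifiable).

LRTs accept only the nested pairs M0 ⊂ M3 (df 4) and M7 ⊂ M8 (df 2);
2ΔlnL within −1e-3 of zero is clamped to 0 (optimiser tolerance), more
negative values are an error.  Because the null hypotheses sit on
boundary points of the alternatives, the χ² reference is conservative.
Positive sites are naive empirical Bayes: per-site class posteriors at
the MLEs, thresholded at 0.95 total mass on ω > 1 classes.  A full Bayes
empirical Bayes treatment (integrating parameter uncertainty) is out of
scope; NEB is the documented approximation and the qualitative
conclusions here (purifying selection, at most isolated positive sites)
are threshold-level.  With few taxa the per-site likelihood ratio is
bounded, so NEB at 0.95 has limited power: in our own measurements, 8
sequences on a total tree length ≈ 5 with 10% of sites at ω = 4 leave
most true positives below the threshold, while a deeper tree
(length ≈ 12) with stronger contrast (ω = 8) recovers the majority with
essentially no false positives.  The tests encode both regimes.

## Synthetic data

The generator's defaults mirror the family design of the curated survey:
group/subgroup counts 12/5/8/13/5/9/2/7 (61 genes), 9 pseudogenes
distributed 3/2/2/1/1 over I/IIa/IIc/IIx/IIe (≈30% frameshifts, the rest
premature stops), 10 structurally defective decoys (heptapeptide without
a finger) that the filter must remove, one 90%-identity tandem duplicate
pair in subgroup IIc on chromosome 4, two planted 2-gene clusters inside
the 200-kb window, R-type introns in group I (C-terminal domain),
IIc/IId/IIe/III, V-type in IIa/IIb, none in IIx, and conserved intron
lengths uniform on [400, 800] bp (mean 600, matching the reported
~600-bp average for this genome).  Coordinates are laid out on a
kilobase-scale genome (genes ≥ 250 kb apart unless planted closer) so the
whole complement generates in seconds.

Subgroup templates are synthetic reference domains: one per subgroup with
that subgroup's observed finger-spacing class, a distinct linker/spacer
vocabulary, a fixed R between heptapeptide and finger (the R-type anchor)
and V at second-C + 6 (the V-type anchor).  Planted domains are mutated
at 4% per non-anchor site; backgrounds are drawn from an alphabet that
cannot create C/H/W/R anchors, with whole-protein rejection if an
accidental heptapeptide appears.  Because truth is planted exactly,
recovery tests measure the pipeline's rules, not biological realism: real
proteomes have compositional bias, domain erosion and annotation noise
that these genomes do not emulate, so passing tests demonstrate internal
correctness of the grammar/rules, not expected field accuracy on new
genomes.

A note on frameshifted pseudogenes: the generator plants the intron
before applying the 1-nt deletion, which genuinely shifts downstream
intron phase.  Their planted intron types are therefore not recoverable
by a phase-based classifier — this is correct behaviour, and recovery
tests exclude frameshifted genes.

Codon alignments are simulated under the same GY94 machinery used for
inference (root from π, per-branch exp(Qt) per site class), with uniform
codon frequencies by default; per-site class labels are returned as truth.

## Determinism and sizes

Every stochastic step takes an explicit seed (NumPy `default_rng`), and
fixed seeds give byte-identical output bundles.  Default analysis sizes —
500-codon/8-taxon M0 recovery, 100-codon nesting checks, 30-replicate
null calibration at 40 codons, 100 additive NJ instances, 200-1000
bootstrap replicates — were chosen so the full suite and the acceptance
script each complete in minutes on a single CPU while leaving the
statistical assertions comfortably powered.
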