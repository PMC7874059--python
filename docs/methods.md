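# Methods

This note records the statistical conventions, default parameters and
design choices behind `mlstpop`, and what the synthetic-data tests do
and do not demonstrate about real data.

## Typing model

An isolate is typed by exact sequence identity of eight housekeeping
fragments against a numbered per-locus allele database.  Within a locus
all alleles must have equal length; a fragment with an indel relative to
the database cannot be expressed in this representation and is rejected
with an explicit error rather than aligned.  Sequences containing
ambiguity codes (N) FAIL rather than guess — resequencing, not
imputation, is the intended remedy.  The canonical profile order is
`pyrG, rpoB, groEL, recA, uvrC, carB, murC, pheS`; allele numbers and ST
labels are assigned max+1 in first-seen order, mirroring profile-database
conventions.  Consequently allele/ST numbering is reproducible only
relative to a given registration order (or to the packaged fixture,
which carries its published labels explicitly).

Fragment extraction from longer reads uses exact primer matching only:
the leftmost forward-primer hit and the nearest subsequent hit of the
reverse-complemented reverse primer delimit the fragment, both primers
trimmed.  Degenerate in-silico PCR is out of scope.  A fragment whose
length deviates more than 10% from the scheme's expected length warns
but does not fail, since the exact-match allele call will adjudicate.
Orientation is resolved by identity count against the known alleles,
keeping the forward presentation on ties.

## Clonal-complex inference

Groups are connected components of the SLV graph (profiles sharing 7 of
8 loci; `group_def` is exposed for other n/L choices).  Components with
≥ 3 member STs are clonal complexes, 2 are doublets, 1 singletons.  The
founder of a complex is the ST with the most SLVs inside the complex;
ties break by more DLVs, then more isolates, then the lower ST number.
The DLV tie-break is inserted purely for determinism — the classical
heuristic (SLV count, then frequency) leaves rare ties unresolved.
Bootstrap support for founders is not computed.

The minimum spanning tree runs Prim's algorithm on the complete graph of
STs weighted by profile mismatch counts.  Tie-breaking among
equal-weight frontier edges prefers the in-tree endpoint with more
isolates, then the lower ST number on the new endpoint, then the lower
in-tree ST; growth starts from the most-sampled ST.  Equal-weight MSTs
are generally non-unique, so only the total weight is a tie-invariant
quantity; the edge list is deterministic under the documented rule but
should not be over-interpreted edge by edge.

## Diversity and linkage statistics

* **Hunter–Gaston D** is Simpson's index with finite-sample correction.
  The 95% CI uses the large-sample variance
  `σ² = (4/N)[Σp³ − (Σp²)²]` with a ±1.96σ interval, clipped to [0, 1].
* **Alignment statistics** (S, π, Tajima's D, dN/dS) use complete
  deletion: any column containing a non-ACGT symbol is dropped before
  counting.  π is the mean pairwise difference count divided by the
  retained length.  Tajima's D follows the standard constants
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and is reported as not-computable
  when S = 0; n ≥ 4 sequences are required.  By default statistics run
  on per-isolate sequence sets, with a `--unique-alleles` switch to run
  on the deduplicated allele set instead; the two conventions weight
  common alleles very differently and should not be mixed.
* **dN/dS** uses Nei–Gojobori (1986) counting: synonymous site counts
  per codon as the fraction of the three possible changes per position
  that preserve the residue, averaged between the two sequences;
  multi-difference codons average over all equally weighted mutational
  pathways (pathways passing through a premature stop are retained,
  with stop treated as a residue); Jukes–Cantor correction
  `d = −(3/4)ln(1 − 4p/3)`, with p ≥ 3/4 reported as saturated.  A
  locus value is mean-dN / mean-dS over all pairs (not a mean of
  ratios), which avoids instability from dS = 0 pairs; saturated pairs
  are excluded with a warning.
* **Index of association**: V_O is the population variance (divisor =
  number of pairs) of pairwise profile mismatch counts; V_E = Σ_l
  h_l(1−h_l) with h_l = 1 − Σ p² the plug-in per-locus mismatch
  probability, with no small-sample correction.  This plug-in
  convention makes I_A slightly negatively biased at small n (order
  1/n), which is why the linkage-equilibrium null tests shuffle the
  observed 42-isolate profiles rather than toy-sized tables; the
  permutation p-value (independent within-locus shuffles, seeded) is
  the calibrated significance measure and is what should be reported.
  Units default to isolates, with `unit="unique"` for the per-ST
  convention.

## Clustering

ST dendrograms are UPGMA (unweighted average linkage) on the categorical
distance (mismatched loci / L).  Merge heights are half the merge
distance, so cophenetic distances equal merge distances and the tree is
ultrametric.  Ties are broken by merging the pair whose smallest member
labels sort first — deterministic, with no effect on heights.

Phenotype clustering takes per-strain ternary 49-well carbon-source
scores (negative 0, weak positive 0.5, positive 1; 48-h reading by
default) and uses Manhattan distance / 49, which keeps the weak-positive
category at half weight; a Jaccard-on-binarised metric is available for
sensitivity analysis.  Genotype–phenotype concordance between tree cuts
is the Adjusted Rand Index; the default number of cut clusters is the
number of SLV groups observed, exposed as a parameter.

## Synthetic populations

The generator emulates a clonally expanding collection: per-locus
ancestral allele pools (6 alleles, pairwise Hamming ≥ 3 by default, at
the scheme's true fragment lengths), founder profiles drawn at pairwise
distance ≥ 4 so descendant groups stay separable, and descendants that
copy their founder and then (i) with probability `slv_rate` (default
0.3) gain a novel allele one substitution away at one locus — an SLV at
the profile level and Hamming-1 at the sequence level — and (ii) with
probability `recombination_rate` (default 0) swap one locus to a random
existing pool allele.  The `qinghai` preset mirrors the study
collection's shape: 45 strains = 41 field isolates in nine founder
groups (sources potato 16, Qula 16, oat 7, wheat 2) plus 4 reference
singletons.  Phenotypes give each founder group a random ternary
prototype which strains copy wellwise with probability κ (default 0.9),
else draw uniformly.

These simulations validate bookkeeping and inference mechanics (exact
ST round trips, founder/component recovery, I_A behaviour under
clonality vs recombination, concordance rising with κ).  They do not
model coalescent genealogies, selection, rate heterogeneity among loci,
or realistic phenotype noise structure, so passing them says the
pipeline is correct, not that real populations satisfy its assumptions.

## Fixture caveats

The packaged profile matrix is the published table exactly as printed:
42 isolates over 24 STs.  Three further isolates (qz543, qz568, qz772)
and the label ST11 appear in the source's totals (45 isolates, 25 STs)
but not in its printed matrix; they are documented as known omissions
and never imputed.  Fixture-derived counts therefore bound, rather than
equal, a few of the published per-locus allele totals (groEL, recA,
pheS), and collection-wide statistics quoted from the full 45-strain
data (discriminatory index, I_A) are reproduced as formula identities
on the reconstructed ST spectrum and as behavioural properties, not as
re-derivations from unpublished sequences.  Published per-locus
sequence statistics cannot be recomputed without the underlying reads;
the implementations are instead verified against independent
brute-force oracles (exhaustive pairwise/pathway enumeration, exact
rational arithmetic) to 1e-9 on randomized alignments with n ≤ 8 and
L ≤ 300, and the pathway-averaging step exhaustively over the full
codon table.

## Problem sizes

Default test and validation sizes — 100-replicate simulation sweeps of
45-strain populations, 500-permutation linkage tests, random alignments
up to 8 × 300 bp — complete in well under a minute on a single core
while leaving all statistical checks comfortably powered.
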