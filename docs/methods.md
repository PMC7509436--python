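# Methods

This note documents the models, estimators, numerical choices and
limitations behind `amplihap`.  Notation: a *segment* is a short PCR
amplicon genotyped as one multi-allelic locus; its alleles are
*haplotypes* (phased base strings over the segment's SNP sites);
p_i denotes a haplotype's relative frequency and a_k = Σ p_i^k.

## Peak-ratio heterozygote calling

Sanger traces of a diploid show a heterozygous position as two
superimposed peaks.  A secondary peak is accepted as a second allele
when secondary_signal / primary_signal is *strictly greater* than a
threshold: 0.50 for single-copy amplicons and 0.30 for duplicated
(2-copy) amplicons, where the minor allele occupies only one of four
gene copies and its relative signal is correspondingly diluted.  Ties
at the threshold are homozygous ("higher than" is read literally).
Signals are treated as already-normalised linear intensities; baseline
correction and mobility normalisation are upstream concerns.  A
primary `N` or zero primary signal yields `N`.  No quantitative rule
exists for poor-quality trace regions, so `call_consensus` accepts a
per-position mask instead of guessing one; masked positions are
emitted as `N`.

Duplicated segments are modelled as ONE composite diploid locus with
its own haplotype alphabet; the copy number only selects the calling
threshold.  How four physical gene copies collapse into a two-haplotype
genotype is not observable from a single mixed trace, and the
composite-diploid reading is the one consistent with downstream
pairwise statistics.

## SNP extraction

A column of the aligned IUPAC consensus sequences is a SNP site when,
after expanding each sample's symbol to its unordered base pair
(R → {A,G} etc.), at least two distinct bases occur among non-missing
samples.  `N` and gaps are missing; three/four-allele codes (B/D/H/V)
are treated as missing because a diploid cannot carry three alleles —
such calls are upstream noise.  Columns gapped in more than half the
samples are skipped outright; the target amplicons are indel-free, so
this rule only guards degenerate inputs.

## Haplotype reconstruction (gene-counting EM)

An unphased genotype with h heterozygous sites is compatible with
max(1, 2^(h−1)) unordered haplotype pairs (enumeration is refused
above h = 20).  Frequencies are estimated by EM: the E-step weights
each compatible pair (h₁,h₂) by c·p(h₁)p(h₂), c = 2 for h₁ ≠ h₂,
normalised per accession; the M-step sets p to expected counts over 2N
gene copies.  The observed-data log-likelihood is asserted
non-decreasing at every iteration; convergence is max |Δp| < tol
(default 1e-8, max 1000 iterations).  Frequencies below 1e-12 are
pruned and the remainder renormalised.

Initialisation is uniform over the compatible haplotype set, making
the procedure fully deterministic.  The uniform start can be a
*symmetric saddle*: if no homozygote or single-het anchors a multiple
heterozygote, all its pairings stay exactly tied and EM stalls below
the global optimum.  `restarts > 0` therefore runs additional EM
passes from seeded Dirichlet-jittered starts (concentration 5 around
uniform) and keeps the highest-likelihood solution, ties resolved in
favour of the uniform start; default is 0 restarts.  MAP pairs are the
highest-posterior compatible pair, exact ties broken toward the
lexicographically smallest pair.  Accessions with a missing site at a
segment are excluded from that segment's estimation and get a missing
genotype there.  A deterministic EM replaces MCMC phasing here for
reproducibility and testability; on short amplicons with strong
linkage the MAP configurations coincide in practice.

Haplotype IDs are assigned 1..k in descending frequency, ties by
lexicographic sequence order.  Accessions collapse into distinct
genotypes under exact equality of all canonical pairs (missing matches
only missing); groups are numbered by descending size, then first
appearance.

## Diversity and identity statistics

Per segment: Hd = 1 − a₂, by default with the unbiased sample factor
n/(n−1) (n = counted gene copies); the distinction is below two
printed decimals for n ≥ 144, and the biased form is a flag away.
PIC = 1 − a₂ − (a₂² − a₄).  Observed heterozygosity is the fraction of
non-missing diploids with two distinct haplotype IDs.  Summary tables
can be computed over all accessions or over distinct genotypes only
(`on_collapsed`); the latter is the right sample when clone families
would otherwise re-count one genome many times, and column means are
unweighted across segments.

Identity under HWE: PI = 2a₂² − a₄ and
PI_sib = ¼ + ½a₂ + ½a₂² − ¼a₄.  Per-genotype match probabilities:
homozygote (i,i) — random p_i², parent/offspring p_i, sibling
((1+p_i)/2)²; heterozygote (i,j) — random 2p_ip_j, parent/offspring
(p_i+p_j)/2, sibling (1+p_i+p_j+2p_ip_j)/4.  The parent/offspring
homozygote value p_i reads: the relative certainly carries one copy of
i and must draw i again from the population.  All per-locus values are
verified in the test suite against exhaustive genotype-pair
enumeration under Mendelian segregation; multi-locus values multiply
across the (unlinked) segments.

Discrimination capacity converts a cumulative PI into the largest n
with n(n−1)/2 · PI ≤ α (default α = 0.05): the expected number of
colliding pairs among n individuals stays below α.  This pairwise-
collision rule exactly reproduces both published capacity pairs
(6.4e-10 → 12,500; 1.5e-4 → 26), which is how it was identified.

The minimal fingerprinting set is found by exact search over subset
sizes s = 1, 2, …, returning *all* subsets of the first separating
size (greedy-only search could miss alternatives).  Pruning: a subset
whose per-segment distinct-genotype counts cannot multiply up to the
number of profiles is skipped.  With 19 segments and s* ≈ 4 the search
is a few thousand subset evaluations.

## Kinship

DSN counts segments with differing canonical pairs; segments missing
in either profile are skipped and reported separately.  Pair tiers:
DSN 0 identical (clone/synonym); 1..somatic_threshold somatic variant;
above, distinct lineage.  The default somatic_threshold of 3 sits
between the observed somatic-variant DSN of 1 (a single
loss-of-heterozygosity) and the minimum DSN of 4 among distinct
non-clonal lineages in the motivating collection; it is an exposed
flag.  Candidate parent–offspring pairs are distinct non-somatic
genotypes whose pairs intersect at every segment (a failed amplicon
cannot exclude); edges are undirected because genotypes alone cannot
orient them, and the rule admits chance matches at a per-pair rate of
Π_l P(share ≥ 1 allele), which becomes non-negligible when every
segment carries one very common haplotype.

Non-exclusion probabilities are computed by exact enumeration over
HWE genotype configurations and Mendelian transmission — never from
transcribed closed forms, eliminating transcription risk; the
Jamieson–Taylor closed forms live only in the test suite as an
independent oracle (agreement to 1e-10).  Scenarios: candidate as
second parent with the first known (P1), candidate as sole tested
parent (P2), candidate pair (P3); P3 ≤ P1 ≤ P2 always.  Enumeration
is O(k²)–O(k³) per locus after candidate-genotype marginals are
accumulated once; the parent-pair scenario refuses k > 40.

## Clustering, ordination, core sets

Simple-matching similarity of two diploid genotypes at one segment is
m/2, where m ∈ {0,1,2} counts shared alleles *with multiplicity*
(heterozygote vs homozygote sharing one allele scores ½); distance is
one minus the mean over comparable segments.  UPGMA and NJ trees come
from scikit-bio; NJ branch lengths that come out negative on
non-additive input are clamped to zero with the deficit moved to the
adjacent branch; the two-leaf case splits the single edge evenly.
Bootstrap resamples *segments* with replacement (the locus is the unit
of the distance), rebuilds the tree, and scores each internal edge by
the percentage of replicates containing the same leaf bipartition
(canonicalised by the side not containing the alphabetically first
leaf; trivial splits excluded), deterministic for a fixed seed.
PCoA Gower-centres −D²/2 and eigendecomposes; axes with negative
eigenvalues (non-Euclidean residue) are dropped from both coordinates
and the explained-variance denominator.

Core sets maximise allele coverage: the fraction of observed
(segment, haplotype) pairs carried by the selected genotypes.  The
optimiser is greedy seeding with seeded random tie-breaks followed by
steepest-ascent single-swap exchange, over 8 seeded restarts by
default, and each size also considers extending the previous size's
best set, which makes the coverage curve non-decreasing by
construction.  This is a plain exchange heuristic, not a full
metaheuristic schedule; the test suite certifies it against brute
force for panels ≤ 20 and core sizes ≤ 4.

## Synthetic panels

The generator reproduces the statistical structure the analysis
assumes, with defaults at the motivating study's scale: 19 segments
with the published per-segment haplotype counts (mean 7.8 alleles) and
copy numbers, 141 accessions collapsing to 72 distinct base genotypes.
Haplotype frequencies are Dirichlet with concentration 0.3, giving one
common haplotype plus a tail of rares (mean SNP minor-allele frequency
near 8–9%); base genotypes are HWE draws; clone families are grown by
preferential attachment (many singletons, a few large families, capped
at 18); somatic variants mutate a configurable number of segments in a
progenitor (default one loss-of-heterozygosity, converting het (i,j)
to hom (i,i); optionally a novel haplotype one mutation step away);
offspring are independent Mendelian draws per segment.  Truth tables
(clone groups, somatic events, trio links) are first-class outputs and
all recovery tests score against them, never against re-derived state.
Peak traces give matching positions a unit primary peak and
near-zero secondary, heterozygous positions a secondary at
`het_ratio` of the primary (defaults 0.8 single-copy / 0.4
duplicated), with optional zero-truncated Gaussian noise; a single
forward-strand trace is produced per amplicon, double-strand
reconciliation being out of scope for indel-free amplicons.

What the generator does *not* emulate: genotyping error and allelic
dropout, linkage between segments, population structure or selection,
null alleles, and real trace artefacts (dye blobs, mobility shifts).
Passing recovery tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to every
failure mode of real Sanger data.

## Problem sizes used in the test suite

Checks are run at sizes where exact oracles exist: EM vs exhaustive
ML on ≤ 6 individuals × ≤ 3 heterozygous sites; identity and
non-exclusion formulas vs enumeration at k ≤ 6 alleles; core selection
vs brute force at 20 genotypes × size ≤ 4; frequency recovery at
N = 500 diploids; Mendelian non-exclusion over 10⁴ simulated trios;
end-to-end trace→fingerprint recovery on a 24-accession panel and
clone/somatic/pedigree recovery on the full 141-accession default.
Exact-recovery pedigree checks use near-even haplotype frequencies
(Dirichlet concentration 2), where the chance-sharing rate across 19
segments is vanishing; under the skewed study-scale frequencies chance
candidates are expected and only the planted-edge subset property is
asserted.

## Known limitations

* The composite treatment of duplicated segments is an approximation;
  paralog-specific variation within a duplicated pair is not modelled.
* EM phasing returns a point MAP configuration without phase
  uncertainty; a sampler could be added behind the same interface.
* Candidate parent–offspring detection is exact-sharing with no
  tolerance for genotyping error, and cannot separate parent–offspring
  from other relationships that happen to share an allele everywhere.
* SNP density per segment is reported but not certified: the published
  per-segment densities are not consistent with SNP count divided by
  amplicon length, and the intended denominator is unstated.
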