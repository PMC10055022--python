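# Methods

This note documents the statistical conventions, model assumptions and
design choices behind `hybridplan`, in the spirit of the methods sections
of established population-genetics toolkits.

## Genotype model

A dataset is a samples × loci matrix of biallelic SNP calls coded
`0` (homozygous A), `1` (homozygous B), `2` (heterozygous), with a
distinct `MISSING` sentinel that is never conflated with a valid code.
All statistics operate on complete-call loci: the completeness filter
drops every locus with at least one missing call, mirroring the
conservative practice of reduced-representation sequencing studies where
missingness is informative of locus dropout. Sample and locus order is
preserved from input everywhere, so all outputs are deterministic.

Upstream depth filtering and multi-allelic splitting are variant-caller
responsibilities; the VCF reader only enforces biallelism (single-base
REF/ALT) and counts what it skips. The per-sample missingness threshold
for excluding poorly genotyped individuals defaults to 0.2 and is
configurable — studies rarely publish the exact cutoff, so it is exposed
rather than hard-coded.

## Diversity statistics (GenAlEx conventions)

Per locus and population, with p the allele-A frequency and q = 1 − p:

* na = number of alleles present; ne = 1/(p² + q²);
* He = 2pq, uncorrected for sample size (the convention of the GenAlEx
  lineage of tools; a small-sample-corrected variant exists only inside
  the divergence estimator below);
* Ho = fraction of heterozygous calls;
* F = (He − Ho)/He, averaged over loci with He > 0.

The summary table averages these over loci per population, and its mean
row is the **unweighted** mean of per-population values (not weighted by
sample size). Private alleles are alleles observed in exactly one
population; because the denominator of a "private-allele percentage" is
not standardised across tools, both the raw count and the count as a
percentage of all alleles observed in that population are reported.

F-statistics use unweighted population means per locus: Hs = mean of
2pq, Ht = 2p̄q̄ from the unweighted mean frequency, H̄o = mean observed
heterozygote frequency; F_IS = (Hs − H̄o)/Hs, F_IT = (Ht − H̄o)/Ht,
F_ST = (Ht − Hs)/Ht, each averaged **per locus** over loci with a
positive denominator, with standard errors sd/√L across loci. Gene flow
is the island-model Nm = (1 − F_ST)/(4 F_ST) from the mean F_ST; it is
infinite (flagged) at F_ST = 0.

### Divergence-parameter estimation

The per-locus-averaged F_ST above is the table convention, but it is a
biased estimator of the generating divergence parameter θ when only a
few populations are surveyed: with k demes an Nei-style Gst estimates
θ(1 − 1/k)/(1 − θ/k), not θ (for k = 4 and θ = 0.48 the expectation is
≈ 0.41, and Jensen effects from per-locus averaging lower it further).
`FStatistics.theta_hat` therefore reports a dedicated recovery
estimator: the Nei–Chesser sample-size-corrected Gst computed as a ratio
of sums over loci, then inverted through the finite-k relation above.
On cohorts simulated under the Balding–Nichols model this estimator is
unbiased to within Monte-Carlo error (mean 0.480 ± 0.005 over 50
replicates at θ = 0.48, 4 × 25 samples, 2000 loci — recomputed by the
test suite), while the conventional per-locus F_ST on the same data
averages ≈ 0.36. Both numbers are reported; they answer different
questions.

## AMOVA

The inter-individual distance is the codominant genotypic squared
distance: per locus 0 (identical genotypes), 1 (homozygote vs
heterozygote) or 4 (opposite homozygotes) — half the squared Euclidean
distance between allele-count vectors — summed over loci. An alternative
Hamming-style genotype distance was considered and rejected as the
default because the 0/1/4 metric is the documented basis of the
codominant AMOVA in the software family this implementation follows.

Sums of squares come from the standard distance-matrix identities
(SS_total = Σ_{i<j} d²ᵢⱼ/N within the whole set and per group), with
df k − 1 and N − k. Variance components use the unequal-sample-size
coefficient n0 = (N − Σn²ᵢ/N)/(k − 1): σ²_within = MS_within and
σ²_among = (MS_among − MS_within)/n0, floored at zero with a flag when
negative. Φ_PT = σ²_among/σ²_total. The permutation test shuffles whole
individuals across population labels (999 permutations by default,
seeded) and reports p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1), so p can
never be zero and the floor at 999 permutations is 0.001.
`amova_from_summaries` exposes the estimation equations directly so a
published AMOVA table can be reconstructed from its printed SS/df and
sample sizes.

## Similarity, clustering, ordination

Rohlf's simple matching coefficient is computed on the allele-presence
expansion of each locus (two binary variables: A present, B present),
which yields per-locus scores of 1 / 0.5 / 0 for identical /
homozygote-vs-heterozygote / opposite-homozygote pairs. This expansion
is the convention of NTSYS-style analyses of codominant markers and is
the reason a het-vs-hom pair earns half credit. GS relates to a
normalised distance by GS = 1 − d/L.

UPGMA runs on D = 1 − GS through average-linkage clustering; node
heights are merge distance / 2, so the tree is ultrametric by
construction, and Newick output carries branch lengths in distance
units. Tie-breaking is deterministic (SciPy's linkage ordering).

PCoA Gower-centres −½D∘D and eigendecomposes; coordinates are
eigenvectors scaled by √λ. Axis percentages divide each positive
eigenvalue by the sum of positive eigenvalues; negative eigenvalues
(D = 1 − GS is not guaranteed Euclidean) are excluded from the
denominator and reported separately. A √(1 − GS) option gives a fully
Euclidean embedding when that matters. Axis signs are fixed by orienting
the largest-magnitude loading positive.

## Parental selection and progeny prediction

Parents are selected greedily per population: rank by observed
homozygosity (ties broken by input order), seed with the top individual,
then repeatedly add the highest-ranked candidate whose GS to every
already-selected parent exceeds the threshold (default 0.90). If the
quota (default 10) cannot be met cohesively, remaining slots are filled
in homozygosity order and the result is flagged as relaxed — this
operationalises "high within-population GS where possible" as a
deterministic algorithm.

Expected progeny heterozygosity per locus follows Mendelian
segregation: 0 for matching homozygote parents, 1 for opposite
homozygotes, ½ whenever either parent is heterozygous. The genome-wide
expectation is the mean over loci. Linkage is deliberately ignored: for
single-generation expectations the per-locus means are exact regardless
of linkage (linkage affects the variance among progeny, not the mean),
and no recombination map is available for chicory anyway. Two exact
identities follow and are enforced by tests: selfing He equals half the
parent's own heterozygosity, and predicted He = 1 iff the parents are
opposite homozygotes everywhere. Expected progeny homozygosity is
1 − He. The full-sib prediction is the expectation for a cross of two
specific sibs, not of the sibship's pooled gametes, because breeding
decisions are made between named individuals.

## CAPS assay

The in-silico assay amplifies with exact primer matching by default
(mismatch allowance configurable; a 3′-terminal mismatch always
disqualifies, as it would in PCR), digests with a configurable
recognition site defaulting to Tru1I's canonical 5′-T^TAA-3′, merges
the two alleles' fragment sets into a band pattern, and classifies
against the reference sizes ~300 / ~230 / ~70 bp with a ±15 bp
tolerance (a gel-resolution proxy). {300} → MsMs, {300, 230, 70} →
Msms, {230, 70} → msms; anything else is an explicit no-call. Because
the ~70 bp fragment is often invisible on agarose gels, a
`low_band_dropout` mode additionally accepts {300, 230} as Msms and
{230} as msms. Sterility is recessive with full penetrance, so msms ⇒
sterile and Ms/– ⇒ fertile.

A wording ambiguity is worth recording: the insertion allele is the 4-nt
palindrome AATT, while Tru1I's canonical recognition site is TTAA. The
two readings coincide in practice because the insertion lands after a TT
dinucleotide, creating a TTAA site; the motif and cut offset are
configurable, and the synthetic fixture places the insertion so either
reading cuts the sterile allele. Fragment arithmetic (230 + 72 ≈ 302)
identifies the 302 bp amplicon with the insertion-bearing allele; the
wild-type amplicon is 298 bp.

Coordinates are 1-based inclusive throughout the assay module, matching
wet-lab convention.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not any real dataset:

* **Ancestral frequencies**: Uniform(0.1, 0.9) — SNP panels are
  ascertained against rare variants, so the support excludes extreme
  frequencies.
* **Divergence**: Balding–Nichols — founder frequencies
  Beta(p(1−θ)/θ, (1−p)(1−θ)/θ) per population, the standard
  F_ST-parameterised divergence model; founders drawn in Hardy–Weinberg
  proportions. Default θ = 0.5, chosen to land the cohort in the strong
  differentiation regime the analysis targets.
* **Inbreeding**: repeated full-sib mating (default 3 generations, the
  point where expected inbreeding reaches F = 0.5), one family per
  population per generation, offspring by independent Mendelian gamete
  draws. A selfing mode exists for comparison.
* **Admixture**: the first population rebuilt at the gamete level with a
  50:50 draw from its own founders and its neighbour's — an F1-like
  mixed ancestry emulating a derived breeding line.
* **Missing data**: independent per-call dropout at rate 0.012, which
  with 94 samples leaves roughly one third of ~9300 loci complete
  (~3000), the regime the completeness filter is designed for.
* **Ms locus**: a fertile 298 bp amplicon with no restriction site and a
  sterile allele with the AATT insertion placed so the cut yields
  230 + 72 bp, embedded in random flanks, with the published primer
  pair; construction is rejected-sampled until all guarantees hold and
  is deterministic given the seed.

Defaults (population sizes 15/17/37/25, ~9351 loci) reproduce the
surveyed cohort's shape: within-population GS in 0.80–0.95, mean
homozygosity 0.70–0.92, AMOVA among-population percentage above 50%,
and four monophyletic UPGMA clusters. Every generator returns a truth
record (ancestral and founder frequencies, pedigree, missing mask) so
tests compare estimates against generating values analytically.

Each operation derives its RNG stream from the master seed by stable
labelled splitting (CRC-32 of the operation label as a spawn key), so
adding a new operation never perturbs existing outputs, and all draws go
through NumPy's integer-state PCG64 generator for cross-platform
determinism.

What the generator does **not** emulate: linkage between loci, locus
dropout correlated with divergence (missingness is independent of
genotype), genotyping error, allele-frequency ascertainment against the
reference genome, and selection during line development. Tests passing
on synthetic cohorts therefore validate the estimators and the pipeline
logic, not robustness to those real-data artefacts.

## Numerical conventions

* Percentages are reported on the 0–100 scale; printed tables round
  half-up to 2 decimals (`round_half_up`), full precision is retained in
  JSON and in-memory results.
* Ratio statistics average per-locus values over loci with positive
  denominators; fully degenerate cases (no polymorphic locus, zero total
  variance, zero replicate variance in ΔK) return NaN with an explicit
  flag rather than raising.
* Standard errors are sd(ddof = 1)/√n over the relevant units (loci, or
  pairs for GS summaries).
* Evanno's ΔK uses replicate means for the second difference,
  |L(K+1) − 2L(K) + L(K−1)|/sd(L(K)); endpoints and zero-sd rows are
  undefined and flagged, and the best K is the argmax over defined rows.

## Problem sizes used in the test suite

Unit tests run on hand-built matrices of ≤ 8 samples; cohort-level tests
use 250–800 loci and 20–40 samples; the parameter-recovery suite uses 50
replicates of 4 × 25 samples × 2000 loci; the Mendelian oracle simulates
10⁵ offspring per pair for 100 pairs on a 500-locus panel via an
aggregated (distributionally exact) gamete sampler. These sizes were
chosen so the statistical tolerances (3 standard errors, ±0.05 on θ) are
meaningful while the whole suite stays fast.

## Known limitations

* The AMOVA is single-level (among/within populations); hierarchical
  designs with regions are out of scope.
* No multi-generation inbreeding-coefficient recursions or
  combining-ability estimation: progeny predictions are one-generation
  Mendelian expectations.
* The CAPS module does no primer thermodynamics; primer matching is
  string matching with optional mismatches.
* Published Nm values from other tools may disagree with the island-model
  formula applied to the same printed F_ST; such pairs cannot always be
  reconciled, and this package always derives Nm from its own F_ST.
* Admixture-model fitting itself (STRUCTURE-style MCMC) is out of scope;
  only its log-likelihood summaries are consumed for ΔK.
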