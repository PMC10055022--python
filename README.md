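# hybridplan

Tools for designing inbred lines and F1 hybrids in leaf chicory (radicchio)
— and similar outcrossing crops — from a biallelic SNP genotype matrix.

Radicchio breeding works against two reproductive barriers: sporophytic
self-incompatibility, which makes selfing-based inbred lines hard to obtain
(full-sib mating is used instead), and nuclear male sterility (NMS), which
can be exploited to force cross-pollination when producing F1 hybrid seed.
Given genotyping-by-sequencing data for a set of candidate breeding
populations, `hybridplan` answers the questions a breeder actually asks:

* How diverse and how uniform is each population, and how differentiated
  are they from one another?
* Which individuals make the best parents for inbreeding or for hybrid
  seed production?
* What heterozygosity should the progeny of a given cross be expected to
  show, under selfing, full-sib mating, or a between-population cross?
* Which plants carry the recessive male-sterility allele?

## What it computes

Genotypes are coded per locus as `0` (homozygous for allele A), `1`
(homozygous for allele B), `2` (heterozygous) or `NA`.

* **Diversity statistics** per population: observed/effective allele
  numbers (na, ne = 1/(p² + q²)), observed and expected heterozygosity
  (Ho, He = 2pq), fixation index F = (He − Ho)/He, percentage of
  polymorphic loci and private alleles; plus Wright's F-statistics
  (F_IS, F_IT, F_ST) and island-model gene flow Nm = (1 − F_ST)/4F_ST.
* **AMOVA** on inter-individual squared genotypic distances (0/1/4 per
  locus), partitioning molecular variance among and within populations,
  with Φ_PT and a label-permutation test.
* **Genetic similarity**: Rohlf's simple matching coefficient on
  allele-presence-coded genotypes (1 / 0.5 / 0 per locus), per-individual
  observed homozygosity, within/among-population GS summaries, a UPGMA
  dendrogram (Newick) and principal coordinate analysis.
* **Cross planning**: greedy selection of up to k elite parents per
  population (highest homozygosity, mutual GS above a threshold), and
  Mendelian prediction of expected progeny heterozygosity for every
  parent pair — exactly 0, ½ or 1 per locus depending on the parental
  genotypes, averaged over loci — summarised by mating strategy
  (S = selfing, FS = full-sib, F1 = between-population cross).
* **CAPS assay**: in-silico PCR with the CiMyb80 primer pair, Tru1I
  (T^TAA) digestion and band-pattern genotyping of the *myb80-like*
  male-sterility locus (MsMs / Msms / msms), plus marker concordance.
* **Evanno ΔK** from admixture-run log-likelihood summaries.
* **Synthetic cohorts**: a seeded generator (Balding–Nichols divergence,
  full-sib mating, gamete-level admixture, missing-call injection, and a
  synthetic fertile/sterile allele pair for the CAPS assay) so the whole
  pipeline is testable without sequencing data.

## Worked example

```python
from hybridplan import (CohortConfig, synth_cohort, filter_complete_loci,
                        amova, simple_matching_gs, observed_homozygosity,
                        select_parents, cross_prediction_matrix, strategy_summary)

ds, _ = synth_cohort(CohortConfig(seed=1))   # 94 plants, 4 populations
complete = filter_complete_loci(ds)          # 2938 complete-call loci

res = amova(complete, n_permutations=999, seed=1)
print(res.pct_among, res.p_value)            # 87.11 0.001

sim = simple_matching_gs(complete)
hom = observed_homozygosity(complete)
sel = select_parents(complete, sim, hom, k=10, gs_threshold=0.90)
summary = strategy_summary(cross_prediction_matrix(complete, sel))
print(summary.groupby("strategy")["mean"].mean().round(3))
# F1    0.373
# FS    0.112
# S     0.069
```

87% of the molecular variance lies among populations (permutation
p = 0.001, the floor at 999 permutations): the four lines are strongly
differentiated. Selfed progenies are predicted to be the least
heterozygous, full-sib progenies a little more, and between-population F1
progenies by far the most (0.37 on average) — so hybrid parents should be
drawn from different populations, and the best specific combination is
read off the F1 rows of the summary.

The `examples/` directory holds one short script per capability
(diversity, structure/AMOVA, cross planning, CAPS assay, ΔK); each prints
its results with a note on how to read them. A thin CLI mirrors the
library: `hybridplan import | stats | amova | similarity | tree | pcoa |
deltak | select-parents | predict-cross | strategy-summary | caps |
concordance | simulate | run`.

## Layout

```
src/hybridplan/     genotype.py   data model, table/VCF I/O, filters
                    popgen.py     diversity stats, F-statistics, Evanno dK
                    amova.py      distances, variance components, permutation test
                    similarity.py GS, homozygosity, UPGMA, PCoA
                    breeding.py   parental selection, progeny-He prediction
                    caps.py       in-silico PCR, digestion, genotype calling
                    simulate.py   synthetic cohorts and Ms-locus alleles
                    pipeline.py   end-to-end run with manifest
                    cli.py        command-line interface
tests/              pytest suite (unit, property and acceptance tests)
examples/           narrative scripts, one per capability
docs/methods.md     models, assumptions, parameter choices, limitations
```
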