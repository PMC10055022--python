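"""Partition molecular variance and recover population structure.

Runs the distance-based AMOVA with a permutation test on a synthetic
cohort, then clusters the plants by simple-matching similarity (UPGMA) and
embeds them with PCoA. A large among-population percentage plus four clean
UPGMA clusters means the lines are well differentiated — the precondition
for choosing divergent parents for F1 hybrids.
"""

from collections import Counter

from hybridplan import (
    CohortConfig,
    amova,
    filter_complete_loci,
    pcoa,
    simple_matching_gs,
    synth_cohort,
    upgma,
)

ds, _ = synth_cohort(CohortConfig(seed=1))
complete = filter_complete_loci(ds)

res = amova(complete, n_permutations=999, seed=1)
print(
    f"AMOVA: {res.pct_among:.2f}% among / {res.pct_within:.2f}% within populations"
)
print(f"PhiPT = {res.phi_pt:.3f}, permutation p = {res.p_value:.3f}")

sim = simple_matching_gs(complete)
clusters = upgma(sim).cut(4)
members = Counter(
    (complete.populations[s], c) for s, c in clusters.items()
)
print("\nUPGMA cluster composition (population, cluster) -> count:")
for key, count in sorted(members.items()):
    print(f"  {key}: {count}")

emb = pcoa(sim, n_axes=2)
print(
    "\nPCoA axis variance: "
    + ", ".join(f"{p:.1f}%" for p in emb.pct_variance[:2])
    + f" (total {emb.pct_variance[:2].sum():.1f}%)"
)
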