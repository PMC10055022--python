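"""Select elite parents and predict progeny heterozygosity per strategy.

Chooses up to 10 plants per population (highest homozygosity, mutual GS
above 90% where possible), builds the cross-prediction matrix (GS below
the diagonal, expected progeny heterozygosity above it) and summarises the
three mating strategies. Selfing (S) should always give the least
heterozygous progenies, full-sib crosses (FS) a little more, and
between-population F1 crosses by far the most — the basis for picking
hybrid parents.
"""

from hybridplan import (
    CohortConfig,
    cross_prediction_matrix,
    filter_complete_loci,
    observed_homozygosity,
    select_parents,
    simple_matching_gs,
    strategy_summary,
    synth_cohort,
)

ds, _ = synth_cohort(CohortConfig(seed=1))
complete = filter_complete_loci(ds)
sim = simple_matching_gs(complete)
hom = observed_homozygosity(complete)

selection = select_parents(complete, sim, hom, k=10, gs_threshold=0.90)
for pop, sel in selection.items():
    flag = " (threshold relaxed)" if sel.relaxed else ""
    print(f"{pop}: {len(sel.selected)} parents{flag}, best = {sel.selected[0]}")

cpm = cross_prediction_matrix(complete, selection)
print(f"\ncross-prediction matrix: {len(cpm.parent_ids)} x {len(cpm.parent_ids)}")

summary = strategy_summary(cpm)
by_strategy = summary.groupby("strategy")["mean"].mean()
print("\nmean expected progeny heterozygosity by strategy:")
for strategy in ("S", "FS", "F1"):
    print(f"  {strategy}: {by_strategy[strategy]:.3f}")

best_f1 = summary[summary["strategy"] == "F1"].nlargest(1, "mean").iloc[0]
print(f"\nbest F1 combination: {best_f1['group']} (mean He {best_f1['mean']:.3f})")
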