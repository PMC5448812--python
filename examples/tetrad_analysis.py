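"""Tetrad genetics: map distances and MI nondisjunction from spore colours.

Simulates the three-colour spore-autonomous fluorescence assay for a
wild-type-like strain and a crossover-deficient strain, classifies every
tetrad from its spore colour pattern, estimates Perkins map distances for
the two test intervals, and compares the strains.
"""

from meioquant import simulate
from meioquant.tetrads import (
    INTERVALS,
    classify_tetrads,
    compare_strains,
    nondisjunction_rate,
    perkins_distance,
    tally,
)

N = 20_000

wt = simulate.simulate_tetrads(N, seed=1, **simulate.WT_TETRAD_CONDITIONS)
mut = simulate.simulate_tetrads(N, seed=2, **simulate.MLH3_DELETION_TETRAD_CONDITIONS)

wt_counts = tally(classify_tetrads(wt.patterns))
mut_counts = tally(classify_tetrads(mut.patterns))

for label, counts in (("wild-type-like", wt_counts), ("crossover-deficient", mut_counts)):
    print(f"{label} strain ({counts.n} tetrads):")
    for interval in INTERVALS:
        d = perkins_distance(counts, interval)
        print(f"  {interval}: {d.cM:.2f} +/- {d.se:.2f} cM (Perkins)")
    nd = nondisjunction_rate(counts)
    print(
        f"  MI nondisjunction: {nd.percent:.2f}% "
        f"+/- {nd.percent_half_width:.2f}% (95% CI)"
    )

cmp = compare_strains(mut_counts, wt_counts)
print("\nmutant vs wild type:")
for interval in INTERVALS:
    g = cmp.crossover_tests[interval]
    print(
        f"  {interval}: {cmp.percent_of_reference[interval]:.0f}% of wild-type "
        f"crossovers (G = {g.statistic:.2f}, p = {g.p_value:.3g})"
    )
print(f"  nondisjunction difference: Fisher exact p = {cmp.nd_test.p_value:.2g}")
print(
    "\nA lower percent-of-wild-type with a small Fisher p means the mutant "
    "loses crossovers and missegregates chromosome VIII more often."
)
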