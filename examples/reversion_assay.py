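"""Mismatch-repair reversion frequencies from plating assays.

Simulates Poisson revertant counts for independent cultures of a
repair-deficient strain, estimates the revertants-per-CFU frequency, and
normalises a partially defective strain to the deletion reference — the
standard presentation of mismatch-repair defects.
"""

from meioquant import simulate
from meioquant.stats import reversion_frequency

TRUE_DELETION_FREQ = 1.7e-4  # Lys+ revertants per CFU, repair-null reference

deletion = simulate.simulate_reversion_assay(
    TRUE_DELETION_FREQ, cfu_per_culture=1e6, n_cultures=6, seed=21
)
ref = reversion_frequency(list(zip(deletion.revertants, deletion.cfu)))
print(
    f"repair-null strain: {ref.aggregate:.2e} +/- {ref.sd:.1e} revertants/CFU "
    f"(mean +/- SD of {len(ref.replicate_frequencies)} cultures; truth {TRUE_DELETION_FREQ:.1e})"
)

partial = simulate.simulate_reversion_assay(
    0.4 * TRUE_DELETION_FREQ, cfu_per_culture=1e6, n_cultures=6, seed=22
)
res = reversion_frequency(
    list(zip(partial.revertants, partial.cfu)), reference=ref.aggregate
)
print(
    f"partial mutant:     {res.aggregate:.2e} revertants/CFU "
    f"= {100 * res.normalized:.0f}% of the deletion strain"
)
print(
    "A mutant near 100% of the deletion is repair-dead; near 0% it retains "
    "mismatch repair despite its other defects."
)
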