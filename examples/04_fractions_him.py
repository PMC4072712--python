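"""Membrane-fraction analysis: hIM membership and compartment composition.

Generates synthetic IM/hIM/OM fraction lists with a localization
annotation, selects heavy-inner-membrane (hIM) proteins by the strict
score > 30 rule, summarises their compartments of origin, and prints a
fraction profile row in the 'nd'-for-not-detected table style.
"""

from membranome import (
    AnalysisConfig,
    SynthConfig,
    fraction_profile,
    generate_fraction_lists,
    localization_composition,
    select_him_proteins,
)

config = AnalysisConfig()
fractions, annotation = generate_fraction_lists(SynthConfig(seed=2, n_proteins=200))

members = select_him_proteins(fractions["hIM"], config)
composition = localization_composition(members, annotation)

print(f"hIM proteins (score > {config.him_score_threshold:g}): {len(members)}")
for compartment, count in composition.counts.items():
    pct = composition.percentages[compartment]
    print(f"  {compartment:<12} {count:>3}  ({pct}%)")

acc = sorted(members)[0]
profile = fraction_profile(acc, fractions)
print(f"\nfraction profile of {acc} [IM sc, hits | hIM | OM]:")
print("  " + "  ".join(profile.row()))

# The hIM is the denser membrane fraction that appears when LPS transport
# is blocked; the composition summary shows which compartments its
# proteins normally come from (percentages are integers rounded
# half-away-from-zero and sum to 100 within rounding).
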