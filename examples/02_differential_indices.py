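"""DAve and DCI on hand-sized protein lists.

Shows the two indices on an alignment of two small consensus lists,
including the +/-2.00 extremes for proteins detected in only one
condition.
"""

from membranome import AnalysisConfig
from membranome.differential import compare_conditions, consensus_from_scores

# secA detected only in the reference; ybhO only under depletion
reference = consensus_from_scores(
    "LptC+", {"murG": 60.0, "ftsZ": 18.0, "secA": 50.0}
)
test = consensus_from_scores(
    "LptC-depleted", {"murG": 20.0, "ftsZ": 28.0, "ybhO": 45.0}
)

records = compare_conditions(reference, test, AnalysisConfig())
print(f"{'accession':<10}{'sc_ref':>8}{'sc_test':>9}{'DAve':>8}{'DCI':>10}  call")
for r in sorted(records, key=lambda r: r.accession):
    flag = "differential" if r.significant else "-"
    print(
        f"{r.accession:<10}{r.sc_ref:>8.1f}{r.sc_test:>9.1f}"
        f"{r.dave:>8.2f}{r.dci:>10.1f}  {flag}"
    )

# DAve = (R-T)/((R+T)/2) is bounded in [-2, +2]: secA (present only in the
# reference) hits exactly +2.00 and ybhO (present only under depletion)
# exactly -2.00.  DCI = ((R+T)/2)(R-T) weights the same difference by the
# mean score.  murG (60 vs 20) clears both cuts; ftsZ (18 vs 28) clears
# DAve (-0.43) but not DCI (-230), so it is NOT called - both indices must
# pass, which is what makes the rule stringent.
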