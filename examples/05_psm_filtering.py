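"""From peptide-spectrum matches to a filtered protein list.

Builds a handful of PSMs, applies the charge-tiered Xcorr / probability
acceptance filters, and assembles the survivors into proteins with
consensus scores (sum of best Xcorr per distinct peptide; proteins with
SC < 10 are dropped).
"""

from membranome import PSM, AnalysisConfig, assemble_proteins, filter_psms

psms = [
    PSM("MKTAYIAK", 1, 1.8, 1e-4, "P1"),   # 1+ tier is 1.5 -> kept
    PSM("GVLSEYGV", 1, 1.4, 1e-4, "P1"),   # below the 1+ tier -> rejected
    PSM("PEPTIDER", 2, 4.2, 1e-4, "P1"),   # kept
    PSM("PEPTIDER", 2, 3.0, 1e-4, "P1"),   # duplicate peptide, lower Xcorr
    PSM("ELVISLIVES", 2, 5.1, 1e-4, "P1"), # kept
    PSM("AAAGGGSSK", 3, 2.4, 1e-4, "P2"),  # below the 3+ tier (2.5)
    PSM("CCCDDDEEK", 2, 6.0, 0.05, "P2"),  # probability too high
    PSM("WWWYYYHHK", 2, 5.5, 1e-4, "P3"),  # kept, but SC 5.5 < 10
]

config = AnalysisConfig()
accepted = filter_psms(psms, config)
proteins = assemble_proteins(accepted, config)

print(f"PSMs in: {len(psms)}, accepted: {len(accepted)}")
for entry in proteins:
    print(f"  {entry.accession}: SC={entry.sc:.1f}, distinct peptides={entry.hits}")

# P1 keeps three distinct peptides (the duplicate contributes only its
# best Xcorr): SC = 1.8 + 4.2 + 5.1 = 11.1 >= 10, so it survives the
# consensus cut.  P2 loses both PSMs to the filters and P3's single
# peptide leaves SC below 10, so neither appears.
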