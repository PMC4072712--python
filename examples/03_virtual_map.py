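"""Virtual 2D map: theoretical pI vs MW with score classes.

Computes theoretical pI (bisection on the Henderson-Hasselbalch charge
curve, EMBOSS pKa set) and average-mass MW for a few proteins and places
them on the map with the three score classes (high SC >= 35, mid, low
SC <= 15).
"""

from membranome import AnalysisConfig, ProteinEntry, build_virtual_map

entries = [
    ProteinEntry("acidic_hi", sc=48.0, hits=8),
    ProteinEntry("basic_mid", sc=22.0, hits=4),
    ProteinEntry("neutral_lo", sc=9.0, hits=2),
]
sequences = {
    "acidic_hi": "MDEEDDLEEAIDESAEEDDGSMKT" * 6,
    "basic_mid": "MKRKLAKRVKRGGKARKLLSK" * 4,
    "neutral_lo": "MGAVLGSTAGLVNAGTQLSG" * 3,
}

points = build_virtual_map(entries, sequences, AnalysisConfig())
print(f"{'accession':<12}{'pI':>6}{'MW (kDa)':>10}{'SC':>6}  class")
for p in points:
    print(f"{p.accession:<12}{p.pi:>6.2f}{p.mw_kda:>10.2f}{p.sc:>6.1f}  {p.sc_class}")

# Acid-rich sequences sit at low pI, Lys/Arg-rich ones at high pI; the
# class encodes identification confidence (consensus score), mirroring the
# colour/shape legend of a virtual 2D gel: high = red circle, mid = blue
# square, low = yellow triangle.
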