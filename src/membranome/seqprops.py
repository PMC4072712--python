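"""Theoretical molecular weight and isoelectric point; virtual 2D maps.

The virtual 2D map emulates a two-dimensional electrophoresis gel: every
identified protein is plotted at its theoretical pI (x, pH units) and MW
(y, kDa), coloured by consensus-score class (high: SC ≥ 35, mid:
15 < SC < 35, low: SC ≤ 15).

pI is computed from the Henderson–Hasselbalch net-charge curve over the two
termini and the ionizable side chains (D, E, C, Y, H, K, R).  The curve is
strictly decreasing in pH, so its unique zero crossing on [0, 14] is found by
bisection.  The pKa set is pinned (EMBOSS values by default) and selectable
by table id, since theoretical pI is only reproducible relative to a stated
pKa table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from Bio.Data.IUPACData import protein_weights, monoisotopic_protein_weights
from Bio.SeqUtils import molecular_weight

from membranome.config import AnalysisConfig
from membranome.errors import ValidationError
from membranome.identification import AMINO_ACIDS, ProteinEntry

log = logging.getLogger(__name__)

_WATER = {"average": 18.0153, "monoisotopic": 18.010565}

ScClass = Literal["high", "mid", "low"]


@dataclass(frozen=True)
class PkaTable:
    """A pinned pKa set: two termini plus the seven ionizable side chains."""

    table_id: str
    n_term: float
    c_term: float
    side_chain: Mapping[str, float]  # keys among D, E, C, Y, H, K, R

    def __post_init__(self) -> None:
        values = [self.n_term, self.c_term, *self.side_chain.values()]
        if any(not 0 < v < 14 for v in values):
            raise ValidationError("pKa values must lie in (0, 14)")


#: Registry of shipped pKa tables, keyed by ``AnalysisConfig.pka_table_id``.
PKA_TABLES: dict[str, PkaTable] = {
    "emboss": PkaTable(
        table_id="emboss",
        n_term=8.6,
        c_term=3.6,
        side_chain={
            "D": 3.9,
            "E": 4.1,
            "C": 8.5,
            "Y": 10.1,
            "H": 6.5,
            "K": 10.8,
            "R": 12.5,
        },
    ),
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class MapPoint:
    """One protein's position on the virtual 2D map."""

    accession: str
    pi: float
    mw: float  # Daltons
    sc: float
    sc_class: ScClass

    @property
    def mw_kda(self) -> float:
        return self.mw / 1000.0


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValidationError("sequence must be non-empty")
    sequence = sequence.upper()
    bad = set(sequence) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValidationError(f"invalid residues {sorted(bad)} in sequence")
    return sequence


def compute_mw(sequence: str, mass_table: str = "average") -> float:
    """Theoretical molecular weight in Daltons: residue masses + one water.

    ``mass_table`` is ``"average"`` (default, matching how 2D-gel MW axes are
    usually drawn) or ``"monoisotopic"``.  An ``X`` contributes the mean of
    the 20 residue masses.
    """
    sequence = _validate_sequence(sequence)
    if mass_table not in _WATER:
        raise ValidationError(f"unknown mass table {mass_table!r}")
    mono = mass_table == "monoisotopic"
    weights = monoisotopic_protein_weights if mono else protein_weights
    water = _WATER[mass_table]
    mean_residue = sum(weights[a] - water for a in AMINO_ACIDS) / len(AMINO_ACIDS)
    n_x = sequence.count("X")
    core = sequence.replace("X", "")
    if core:
        mw = molecular_weight(core, seq_type="protein", monoisotopic=mono)
    else:
        mw = water
    return mw + n_x * mean_residue


def net_charge(sequence: str, ph: float, pka: PkaTable) -> float:
    """Net charge at a given pH from the Henderson–Hasselbalch sums.

    Positive groups (N-terminus, K, R, H) contribute ``1/(1+10^(pH-pKa))``
    each; negative groups (C-terminus, D, E, C, Y) contribute
    ``-1/(1+10^(pKa-pH))``.  Strictly decreasing in pH.
    """
    sequence = _validate_sequence(sequence)
    positive = 1.0 / (1.0 + 10.0 ** (ph - pka.n_term))
    negative = 1.0 / (1.0 + 10.0 ** (pka.c_term - ph))
    for residue in _BASIC:
        n = sequence.count(residue)
        if n:
            positive += n / (1.0 + 10.0 ** (ph - pka.side_chain[residue]))
    for residue in _ACIDIC:
        n = sequence.count(residue)
        if n:
            negative += n / (1.0 + 10.0 ** (pka.side_chain[residue] - ph))
    return positive - negative


def compute_pi(
    sequence: str,
    pka: PkaTable | str = "emboss",
    tol: float = 1e-3,
) -> float:
    """Theoretical isoelectric point: the pH where the net charge is zero.

    Bisection on [0, 14] to ``tol`` pH units; the charge curve is strictly
    decreasing so the root is unique.
    """
    if isinstance(pka, str):
        pka = PKA_TABLES[pka]
    sequence = _validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    # charge(0) > 0 > charge(14) always: the termini alone guarantee a sign
    # change on the interval.
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_sc(sc: float, bounds: tuple[float, float] = (15.0, 35.0)) -> ScClass:
    """Score class for the map legend: high iff SC ≥ upper bound, low iff
    SC ≤ lower bound, mid otherwise (both boundaries inclusive outward)."""
    low, high = bounds
    if sc >= high:
        return "high"
    if sc <= low:
        return "low"
    return "mid"


def build_virtual_map(
    entries: Iterable[ProteinEntry],
    sequences: Mapping[str, str],
    config: AnalysisConfig | None = None,
) -> list[MapPoint]:
    """One :class:`MapPoint` per entry whose accession has a sequence.

    Entries without a sequence are skipped with a logged warning (their
    count is reported once).
    """
    config = config or AnalysisConfig()
    pka = PKA_TABLES[config.pka_table_id]
    points: list[MapPoint] = []
    skipped = 0
    for entry in entries:
        seq = sequences.get(entry.accession)
        if seq is None:
            skipped += 1
            continue
        points.append(
            MapPoint(
                accession=entry.accession,
                pi=compute_pi(seq, pka),
                mw=compute_mw(seq, config.mass_table_id),
                sc=entry.sc,
                sc_class=classify_sc(entry.sc, config.sc_class_bounds),
            )
        )
    if skipped:
        log.warning("virtual map: %d entries had no sequence and were skipped", skipped)
    return points


def write_map(points: Iterable[MapPoint], path) -> None:
    """Export the map as TSV [accession, pi, mw_kda, sc, sc_class]."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["accession", "pi", "mw_kda", "sc", "sc_class"])
        for p in points:
            w.writerow([p.accession, f"{p.pi:.2f}", f"{p.mw_kda:.2f}", p.sc, p.sc_class])


def plot_map(points, ax=None):
    """Optional scatter rendering of the virtual map (requires matplotlib).

    Red circles for the high class, blue squares for mid, yellow triangles
    for low; MW on a log axis in kDa, as on a 2D gel.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    styles = {
        "high": dict(color="red", marker="o"),
        "mid": dict(color="blue", marker="s"),
        "low": dict(color="gold", marker="^"),
    }
    for cls, style in styles.items():
        xs = [p.pi for p in points if p.sc_class == cls]
        ys = [p.mw_kda for p in points if p.sc_class == cls]
        ax.scatter(xs, ys, label=cls, s=18, **style)
    ax.set_xlabel("theoretical pI")
    ax.set_ylabel("theoretical MW (kDa)")
    ax.set_yscale("log")
    ax.legend(title="SC class")
    return ax
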