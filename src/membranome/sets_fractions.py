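"""Presence/absence Venn partitioning, hIM membership and fraction profiles.

These operations summarise which proteins appear where: disjoint Venn
regions across two or three named protein lists, membership in the heavy
inner-membrane (hIM) fraction by the strict score > 30 rule, per-protein
profiles across the IM/hIM/OM sucrose-gradient fractions, and compartment
composition of a protein set given a localization annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from membranome.config import AnalysisConfig
from membranome.differential import ConsensusList
from membranome.errors import ValidationError

FRACTIONS = ("IM", "hIM", "OM")
COMPARTMENTS = ("IM", "OM", "cytoplasmic", "periplasmic", "unknown")


@dataclass
class VennPartition:
    """Disjoint presence/absence regions over named protein lists.

    ``regions`` maps a subset signature (frozenset of list names) to the
    accessions detected in exactly those lists.  Regions are pairwise
    disjoint and their union is the universe of all detected accessions.
    """

    names: tuple[str, ...]
    regions: dict[frozenset, set] = field(default_factory=dict)

    @property
    def universe(self) -> set:
        out: set = set()
        for accs in self.regions.values():
            out |= accs
        return out

    @property
    def sizes(self) -> dict[frozenset, int]:
        return {sig: len(accs) for sig, accs in self.regions.items()}

    def size(self, *names: str) -> int:
        """Size of the region for exactly this set of list names."""
        return len(self.regions.get(frozenset(names), set()))


@dataclass(frozen=True)
class FractionProfile:
    """Per-fraction (score, hits) for one accession; (0, 0) = not detected."""

    accession: str
    fractions: Mapping[str, tuple[float, int]]

    def row(self, nd: str = "nd", decimal: str = ".") -> list[str]:
        """Render as a table row [IM score, IM hits, hIM ..., OM ...] with
        ``nd`` marking fractions where the protein was not detected."""
        cells: list[str] = []
        for frac in FRACTIONS:
            sc, hits = self.fractions.get(frac, (0.0, 0))
            if sc == 0:
                cells += [nd, nd]
            else:
                cells += [f"{sc:.2f}".replace(".", decimal), str(hits)]
        return cells


@dataclass(frozen=True)
class CompositionSummary:
    """Counts and integer percentages per subcellular compartment."""

    counts: Mapping[str, int]
    percentages: Mapping[str, int]
    total: int


def _accessions(lst) -> set:
    if isinstance(lst, ConsensusList):
        return lst.accessions
    return set(lst)


def venn_partition(lists: Mapping[str, object]) -> VennPartition:
    """Partition accessions by exactly which of 2–3 named lists contain them.

    ``lists`` maps a unique name to a ConsensusList or any iterable of
    accessions.  Each accession lands in exactly one region — the signature
    of the lists it appears in — so region sizes sum to the universe size.
    """
    names = tuple(lists)
    if len(names) != len(set(names)):
        raise ValidationError("list names must be unique")
    if not 2 <= len(names) <= 3:
        raise ValidationError("venn_partition supports 2 or 3 lists")
    sets = {name: _accessions(lst) for name, lst in lists.items()}
    regions: dict[frozenset, set] = {}
    universe = set().union(*sets.values())
    for acc in universe:
        sig = frozenset(name for name in names if acc in sets[name])
        regions.setdefault(sig, set()).add(acc)
    return VennPartition(names=names, regions=regions)


def select_him_proteins(
    fraction_list: ConsensusList, config: AnalysisConfig | None = None
) -> set[str]:
    """hIM membership: accessions whose score is strictly greater than the
    threshold (default 30)."""
    config = config or AnalysisConfig()
    t = config.him_score_threshold
    return {acc for acc, (sc, _) in fraction_list.scores.items() if sc > t}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def localization_composition(
    accessions: Iterable[str],
    annotation: Mapping[str, str],
) -> CompositionSummary:
    """Compartment composition of a protein set.

    Accessions missing from the annotation (or annotated with an
    unrecognised compartment) count as "unknown".  Percentages are
    100·count/total rounded half-away-from-zero to integers, so they sum to
    100 within ±1.
    """
    accs = list(accessions)
    if not accs:
        raise ValidationError("composition of an empty protein set is undefined")
    counts = {c: 0 for c in COMPARTMENTS}
    for acc in accs:
        compartment = annotation.get(acc, "unknown")
        if compartment not in counts:
            compartment = "unknown"
        counts[compartment] += 1
    total = len(accs)
    percentages = {c: _round_half_away(100.0 * n / total) for c, n in counts.items()}
    return CompositionSummary(counts=counts, percentages=percentages, total=total)


def fraction_profile(
    accession: str,
    fraction_lists: Mapping[str, ConsensusList],
) -> FractionProfile:
    """(score, hits) of one accession across the membrane fractions.

    Fraction names must be among IM, hIM, OM; fractions where the protein
    was not detected — or that were not supplied — record (0, 0).
    """
    unknown = set(fraction_lists) - set(FRACTIONS)
    if unknown:
        raise ValidationError(f"unknown fraction names: {sorted(unknown)}")
    profile = {
        frac: fraction_lists[frac].scores.get(accession, (0.0, 0))
        if frac in fraction_lists
        else (0.0, 0)
        for frac in FRACTIONS
    }
    return FractionProfile(accession=accession, fractions=profile)


def read_annotation(path, delimiter: str = "\t") -> dict[str, str]:
    """Read an accession→compartment TSV (two columns, header optional)."""
    import csv

    out: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if len(row) < 2 or row[0] == "accession":
                continue
            out[row[0].strip()] = row[1].strip()
    return out
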