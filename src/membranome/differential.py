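"""Replicate merging, list alignment, and the DAve/DCI differential call.

Label-free comparison here is score-based: the protein consensus score (SC)
stands in for abundance.  For a protein with reference score R and test
score T,

    DAve = (R − T) / ((R + T) / 2)          (relative ratio, in [−2, +2])
    DCI  = ((R + T) / 2) × (R − T)          (absolute score variation)

DAve is the difference normalised by the mean of the two scores, so a
protein detected in only one condition sits exactly at ±2; DCI weights the
same difference by the mean score, so only proteins with both a large
relative and a large absolute change pass the dual threshold.  The sign
convention is positive = more abundant in the *reference* condition.

A protein is called differential only when BOTH indexes clear their strict
thresholds with the same sign: (DAve > 0.4 and DCI > 400) or (DAve < −0.4
and DCI < −400) at the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from membranome.config import AnalysisConfig, MergePolicy
from membranome.errors import ValidationError
from membranome.identification import RunIdentification


@dataclass
class ConsensusList:
    """Condition-level protein list after replicate merging.

    ``scores`` maps accession → (sc, hits); absence from the map means the
    protein was not detected in the condition (never stored as score 0).
    """

    condition: str
    scores: dict[str, tuple[float, int]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for acc, (sc, hits) in self.scores.items():
            if sc <= 0 or hits < 0:
                raise ValidationError(
                    f"{acc}: stored scores must be positive (absence is "
                    f"omission from the map), got sc={sc}"
                )

    @property
    def accessions(self) -> set[str]:
        return set(self.scores)

    def sc(self, accession: str) -> float:
        """Score of an accession, 0.0 when not detected."""
        return self.scores.get(accession, (0.0, 0))[0]


@dataclass
class DifferentialRecord:
    """One aligned accession across the two compared conditions."""

    accession: str
    sc_ref: float
    sc_test: float
    dave: float | None = None
    dci: float | None = None
    significant: bool = False
    description: str = ""


def merge_replicates(
    runs: Sequence[RunIdentification],
    policy: MergePolicy = "max",
) -> ConsensusList:
    """Merge a condition's replicate runs into one consensus list.

    The accession set is the union over runs (a protein seen in any
    replicate is present); the score per accession aggregates over the runs
    where it was detected — ``max`` (default), ``mean`` or ``sum`` — and
    hits aggregate the same way (mean hits rounded to nearest integer).
    """
    if not runs:
        raise ValidationError("merge_replicates requires at least one run")
    conditions = {r.condition for r in runs}
    if len(conditions) != 1:
        raise ValidationError(f"mixed condition labels: {sorted(conditions)}")
    pooled: dict[str, list[tuple[float, int]]] = {}
    descriptions: dict[str, str] = {}
    for run in runs:
        for entry in run.entries:
            pooled.setdefault(entry.accession, []).append((entry.sc, entry.hits))
            if entry.description:
                descriptions.setdefault(entry.accession, entry.description)
    scores: dict[str, tuple[float, int]] = {}
    for acc, observed in pooled.items():
        scs = [s for s, _ in observed]
        hit_counts = [h for _, h in observed]
        if policy == "max":
            i = max(range(len(scs)), key=scs.__getitem__)
            scores[acc] = (scs[i], hit_counts[i])
        elif policy == "mean":
            scores[acc] = (
                sum(scs) / len(scs),
                round(sum(hit_counts) / len(hit_counts)),
            )
        elif policy == "sum":
            scores[acc] = (sum(scs), sum(hit_counts))
        else:  # pragma: no cover - guarded by AnalysisConfig literal
            raise ValidationError(f"unknown merge policy {policy!r}")
    return ConsensusList(
        condition=conditions.pop(),
        scores=scores,
        provenance=[r.sample_id for r in runs],
        descriptions=descriptions,
    )


def align_lists(
    reference: ConsensusList, test: ConsensusList
) -> list[DifferentialRecord]:
    """Full outer join of two consensus lists on accession.

    An accession absent from one list gets score 0 on that side; the record
    count is the size of the union.  DAve/DCI are left unset.
    """
    if reference.condition == test.condition:
        raise ValidationError(
            f"cannot align a condition with itself ({reference.condition!r})"
        )
    union = sorted(reference.accessions | test.accessions)
    return [
        DifferentialRecord(
            accession=acc,
            sc_ref=reference.sc(acc),
            sc_test=test.sc(acc),
            description=reference.descriptions.get(acc)
            or test.descriptions.get(acc, ""),
        )
        for acc in union
    ]


def compute_dave(sc_ref: float, sc_test: float) -> float:
    """DAve = (R − T) / ((R + T)/2); bounded in [−2, +2].

    Exactly +2 when the protein is detected only in the reference, −2 when
    only in the test condition.  Undefined (error) when both scores are 0 —
    such accessions never enter an alignment.
    """
    if sc_ref < 0 or sc_test < 0:
        raise ValidationError("scores must be >= 0")
    mean = (sc_ref + sc_test) / 2.0
    if mean == 0:
        raise ValidationError("DAve undefined for two zero scores")
    return (sc_ref - sc_test) / mean


def compute_dci(sc_ref: float, sc_test: float) -> float:
    """DCI = ((R + T)/2) × (R − T); same sign as DAve, unbounded."""
    if sc_ref < 0 or sc_test < 0:
        raise ValidationError("scores must be >= 0")
    if sc_ref + sc_test == 0:
        raise ValidationError("DCI undefined for two zero scores")
    return ((sc_ref + sc_test) / 2.0) * (sc_ref - sc_test)


def compute_indices(
    records: Iterable[DifferentialRecord],
) -> list[DifferentialRecord]:
    """Fill dave/dci on aligned records, in place; returns the list."""
    out = list(records)
    for rec in out:
        rec.dave = compute_dave(rec.sc_ref, rec.sc_test)
        rec.dci = compute_dci(rec.sc_ref, rec.sc_test)
    return out


def flag_differential(
    records: Iterable[DifferentialRecord],
    config: AnalysisConfig | None = None,
) -> list[DifferentialRecord]:
    """Set the significance flag with the strict dual-threshold rule.

    significant ⇔ (DAve > +t_dave AND DCI > +t_dci) OR
                  (DAve < −t_dave AND DCI < −t_dci)

    Both inequalities are strict; both indexes must agree in sign and clear
    their threshold.  Records with unset indexes get them computed first.
    All records are returned with flags set.
    """
    config = config or AnalysisConfig()
    td, tc = config.dave_threshold, config.dci_threshold
    out = list(records)
    for rec in out:
        if rec.dave is None or rec.dci is None:
            rec.dave = compute_dave(rec.sc_ref, rec.sc_test)
            rec.dci = compute_dci(rec.sc_ref, rec.sc_test)
        rec.significant = (rec.dave > td and rec.dci > tc) or (
            rec.dave < -td and rec.dci < -tc
        )
    return out


def compare_conditions(
    reference: ConsensusList,
    test: ConsensusList,
    config: AnalysisConfig | None = None,
) -> list[DifferentialRecord]:
    """Convenience: align, compute DAve/DCI, and flag in one call."""
    return flag_differential(compute_indices(align_lists(reference, test)), config)


def consensus_from_scores(
    condition: str, scores: Mapping[str, float], hits: Mapping[str, int] | None = None
) -> ConsensusList:
    """Build a ConsensusList from a plain accession→score mapping (zero and
    negative scores rejected; hits default to 1)."""
    return ConsensusList(
        condition=condition,
        scores={
            acc: (float(sc), (hits or {}).get(acc, 1)) for acc, sc in scores.items()
        },
    )
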