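"""Reading PSM tables, protein lists and FASTA; SEQUEST-style acceptance
filtering and protein assembly.

A peptide-spectrum match (PSM) is accepted when its Xcorr strictly exceeds
the charge-specific minimum and its probability is at most the cap.  Accepted
PSMs are grouped by parent protein; the protein consensus score (SC) is the
sum of the best Xcorr per distinct peptide sequence and proteins below the
consensus minimum are dropped.  SC is the abundance proxy used by every
downstream comparison.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from membranome.config import AnalysisConfig
from membranome.errors import (
    FormatError,
    MissingColumnError,
    RowParseError,
    ValidationError,
)

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: default column names of a PSM table; a dialect maps these canonical keys
#: to the actual header names in the file.
PSM_COLUMNS = ("peptide", "charge", "xcorr", "probability", "accession")
PROTEIN_COLUMNS = ("accession", "description", "score", "hits")


@dataclass(frozen=True)
class PSM:
    """One peptide-spectrum match, the unit the acceptance filters act on."""

    peptide: str
    charge: int
    xcorr: float
    probability: float
    protein_accession: str

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValidationError("peptide must be non-empty")
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.peptide!r} has non-standard residues {sorted(bad)}"
            )
        if self.charge < 1:
            raise ValidationError("charge must be >= 1")
        if self.xcorr < 0:
            raise ValidationError("xcorr must be >= 0")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError("probability must lie in [0, 1]")


@dataclass(frozen=True)
class ProteinEntry:
    """An identified protein in one run or consensus.

    ``sc`` is the consensus score (unitless, >= 0) and ``hits`` the number
    of accepted distinct peptides.  A protein with no accepted peptides has
    no entry at all, hence sc = 0 iff hits = 0 (both only via the degenerate
    explicit construction).
    """

    accession: str
    description: str = ""
    sc: float = 0.0
    hits: int = 0
    mw: float | None = None
    pi: float | None = None
    localization: str | None = None

    def __post_init__(self) -> None:
        if self.sc < 0:
            raise ValidationError(f"{self.accession}: score must be >= 0")
        if self.hits < 0:
            raise ValidationError(f"{self.accession}: hits must be >= 0")
        if (self.sc == 0) != (self.hits == 0):
            raise ValidationError(
                f"{self.accession}: sc = 0 iff hits = 0 (got sc={self.sc}, "
                f"hits={self.hits})"
            )


@dataclass
class RunIdentification:
    """One MudPIT run's protein list plus its place in the replicate design."""

    sample_id: str
    condition: str
    bio_replicate: int = 1
    tech_replicate: int = 1
    entries: list[ProteinEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(accs) != len(set(accs)):
            raise ValidationError(
                f"run {self.sample_id}: accessions must be unique"
            )

    def score_map(self) -> dict[str, tuple[float, int]]:
        return {e.accession: (e.sc, e.hits) for e in self.entries}


def _open_rows(path: str | Path, delimiter: str = "\t"):
    fh = open(path, newline="", encoding="utf-8")
    return fh, csv.reader(fh, delimiter=delimiter)


def read_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[PSM]:
    """Read a delimited PSM table into a list of :class:`PSM`, row order kept.

    Parameters
    ----------
    path : file path
        Tab-separated text with a header row.
    dialect : mapping, optional
        Maps canonical names (``peptide``, ``charge``, ``xcorr``,
        ``probability``, ``accession``) to the column names used in the file.

    Raises
    ------
    MissingColumnError
        If a declared column is absent from the header.
    RowParseError
        If charge/xcorr/probability cannot be parsed; cites the line number.
    """
    colmap = {k: k for k in PSM_COLUMNS}
    if dialect:
        colmap.update(dialect)
    fh, rows = _open_rows(path, delimiter)
    psms: list[PSM] = []
    with fh:
        try:
            header = next(rows)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        index: dict[str, int] = {}
        for key in PSM_COLUMNS:
            name = colmap[key]
            if name not in header:
                raise MissingColumnError(name, str(path))
            index[key] = header.index(name)
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                psms.append(
                    PSM(
                        peptide=row[index["peptide"]].strip().upper(),
                        charge=int(row[index["charge"]]),
                        xcorr=float(row[index["xcorr"]]),
                        probability=float(row[index["probability"]]),
                        protein_accession=row[index["accession"]].strip(),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise RowParseError(lineno, str(exc)) from exc
    return psms


def read_protein_list(
    path: str | Path,
    sample_id: str | None = None,
    condition: str = "",
    bio_replicate: int = 1,
    tech_replicate: int = 1,
    delimiter: str = "\t",
) -> RunIdentification:
    """Read a per-run protein list (accession, description, score, hits).

    Duplicate accession rows collapse to the row with the maximum score
    (a conservative presence call); a duplicate whose description conflicts
    with the first occurrence triggers a warning and the first is kept.
    Negative scores are a validation error.
    """
    fh, rows = _open_rows(path, delimiter)
    best: dict[str, ProteinEntry] = {}
    order: list[str] = []
    with fh:
        try:
            header = next(rows)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        index: dict[str, int] = {}
        for key in PROTEIN_COLUMNS:
            if key not in header:
                raise MissingColumnError(key, str(path))
            index[key] = header.index(key)
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                acc = row[index["accession"]].strip()
                desc = row[index["description"]].strip()
                score = float(row[index["score"]])
                hits = int(row[index["hits"]])
            except (ValueError, IndexError) as exc:
                raise RowParseError(lineno, str(exc)) from exc
            if score < 0:
                raise ValidationError(
                    f"{path} line {lineno}: negative score {score} for {acc}"
                )
            entry = ProteinEntry(accession=acc, description=desc, sc=score, hits=hits)
            if acc in best:
                prev = best[acc]
                if desc and prev.description and desc != prev.description:
                    warnings.warn(
                        f"{acc}: conflicting descriptions, keeping first "
                        f"({prev.description!r})",
                        stacklevel=2,
                    )
                if score > prev.sc:
                    best[acc] = replace(entry, description=prev.description or desc)
            else:
                best[acc] = entry
                order.append(acc)
    return RunIdentification(
        sample_id=sample_id or Path(path).stem,
        condition=condition,
        bio_replicate=bio_replicate,
        tech_replicate=tech_replicate,
        entries=[best[a] for a in order],
    )


def write_protein_list(
    run: RunIdentification, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a run's protein list; inverse of :func:`read_protein_list` on
    (accession, sc, hits)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(PROTEIN_COLUMNS)
        for e in run.entries:
            w.writerow([e.accession, e.description, repr(e.sc), e.hits])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into {accession: uppercased sequence}.

    The accession is the first whitespace-delimited header token.  Duplicate
    accessions and residues outside the 20-letter alphabet (plus X) are
    errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = record.id
        if acc in sequences:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - AMINO_ACIDS - {"X"}
        if bad:
            raise FormatError(
                f"{path}: record {acc!r} has invalid residues {sorted(bad)}"
            )
        sequences[acc] = seq
    return sequences


def filter_psms(psms: Iterable[PSM], config: AnalysisConfig) -> list[PSM]:
    """Apply the acceptance filters: Xcorr strictly above the charge tier
    (1+→1.5, 2+→2.0, ≥3+→2.5 by default) AND probability ≤ cap.

    Order-preserving and idempotent; empty input yields empty output.
    """
    return [
        p
        for p in psms
        if p.xcorr > config.xcorr_min(p.charge)
        and p.probability <= config.probability_max
    ]


def assemble_proteins(
    psms: Sequence[PSM],
    config: AnalysisConfig,
    descriptions: Mapping[str, str] | None = None,
) -> list[ProteinEntry]:
    """Assemble filtered PSMs into protein entries with consensus scores.

    Per accession: each distinct peptide sequence contributes its maximum
    Xcorr once; SC is the sum of those contributions and hits the number of
    distinct peptides.  Proteins with SC below ``config.consensus_min`` are
    dropped.  The result is sorted by descending SC (accession as tie-break)
    and independent of input PSM order.
    """
    by_protein: dict[str, dict[str, float]] = {}
    for p in psms:
        peptides = by_protein.setdefault(p.protein_accession, {})
        if p.xcorr > peptides.get(p.peptide, -1.0):
            peptides[p.peptide] = p.xcorr
    entries = []
    for acc, peptides in by_protein.items():
        sc = sum(peptides.values())
        if sc < config.consensus_min:
            continue
        entries.append(
            ProteinEntry(
                accession=acc,
                description=(descriptions or {}).get(acc, ""),
                sc=sc,
                hits=len(peptides),
            )
        )
    entries.sort(key=lambda e: (-e.sc, e.accession))
    return entries
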