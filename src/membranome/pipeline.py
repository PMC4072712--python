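"""End-to-end orchestration: filter → assemble → merge → align → DAve/DCI →
flag → Venn → virtual map → fractions, with TSV report rendering.

The pipeline is deterministic for fixed inputs and configuration; per-stage
counts (PSMs in/out, proteins retained, records flagged) are logged so the
narrative numbers of an analysis are auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from membranome.config import AnalysisConfig
from membranome.differential import (
    ConsensusList,
    DifferentialRecord,
    compare_conditions,
    merge_replicates,
)
from membranome.errors import ValidationError
from membranome.identification import RunIdentification
from membranome.seqprops import MapPoint, build_virtual_map
from membranome.sets_fractions import (
    CompositionSummary,
    VennPartition,
    localization_composition,
    select_him_proteins,
    venn_partition,
)

log = logging.getLogger(__name__)


@dataclass
class AnalysisResult:
    """Everything one comparison run produces, plus provenance."""

    consensus: dict[str, ConsensusList]
    records: list[DifferentialRecord]
    reference_condition: str
    test_condition: str
    venn: VennPartition | None = None
    map_points: list[MapPoint] = field(default_factory=list)
    him_proteins: set[str] = field(default_factory=set)
    him_composition: CompositionSummary | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_differential(self) -> int:
        return sum(1 for r in self.records if r.significant)


def run_pipeline(
    runs_by_condition: Mapping[str, Sequence[RunIdentification]],
    config: AnalysisConfig | None = None,
    reference: str | None = None,
    test: str | None = None,
    sequences: Mapping[str, str] | None = None,
    fraction_lists: Mapping[str, ConsensusList] | None = None,
    annotation: Mapping[str, str] | None = None,
) -> AnalysisResult:
    """Run the full comparison on per-condition replicate runs.

    ``reference``/``test`` default to the first and last condition in the
    mapping.  The virtual map requires ``sequences``; the hIM analysis
    requires ``fraction_lists`` (and composition additionally requires
    ``annotation``) — optional stages are skipped with a logged warning
    when their inputs are absent, never failing the run.
    """
    config = config or AnalysisConfig()
    conditions = list(runs_by_condition)
    if len(conditions) < 2:
        raise ValidationError("pipeline needs at least two conditions")
    reference = reference or conditions[0]
    test = test or conditions[-1]
    for name in (reference, test):
        if name not in runs_by_condition:
            raise ValidationError(f"condition {name!r} not in manifest")
        if not runs_by_condition[name]:
            raise ValidationError(f"condition {name!r} has no runs")

    consensus = {
        cond: merge_replicates(list(runs), config.merge_policy)
        for cond, runs in runs_by_condition.items()
    }
    for cond, cl in consensus.items():
        log.info("condition %s: %d proteins after merging %d runs",
                 cond, len(cl.scores), len(cl.provenance))

    records = compare_conditions(consensus[reference], consensus[test], config)
    log.info("aligned %d accessions; %d flagged differential",
             len(records), sum(r.significant for r in records))

    venn = None
    if 2 <= len(conditions) <= 3:
        venn = venn_partition({c: consensus[c] for c in conditions})

    map_points: list[MapPoint] = []
    if sequences:
        union_entries = []
        seen: set[str] = set()
        for cond in conditions:
            for acc, (sc, hits) in consensus[cond].scores.items():
                if acc not in seen:
                    seen.add(acc)
                    from membranome.identification import ProteinEntry

                    union_entries.append(
                        ProteinEntry(accession=acc, sc=sc, hits=hits)
                    )
        map_points = build_virtual_map(union_entries, sequences, config)
    else:
        log.warning("no sequences supplied: virtual map skipped")

    him: set[str] = set()
    composition = None
    if fraction_lists and "hIM" in fraction_lists:
        him = select_him_proteins(fraction_lists["hIM"], config)
        if him and annotation is not None:
            composition = localization_composition(him, annotation)
        elif him:
            log.warning("no annotation supplied: hIM composition skipped")

    provenance = {
        "config": config.model_dump(mode="json"),
        "conditions": conditions,
        "reference": reference,
        "test": test,
        "runs": {
            c: [r.sample_id for r in runs_by_condition[c]] for c in conditions
        },
    }
    return AnalysisResult(
        consensus=consensus,
        records=records,
        reference_condition=reference,
        test_condition=test,
        venn=venn,
        map_points=map_points,
        him_proteins=him,
        him_composition=composition,
        provenance=provenance,
    )


def _fmt(value: float, decimals: int, decimal_sep: str) -> str:
    s = f"{value:.{decimals}f}"
    return s.replace(".", decimal_sep) if decimal_sep != "." else s


def render_reports(
    result: AnalysisResult,
    out_dir: str | Path,
    locale: str = "point",
) -> dict[str, Path]:
    """Write TSV reports into ``out_dir``; returns {report name: path}.

    DAve is printed to 2 decimals; ``locale="comma"`` renders decimal
    commas (the style of the study's printed tables, e.g. "−2,00").
    """
    if locale not in ("point", "comma"):
        raise ValidationError(f"unknown locale {locale!r}")
    sep = "," if locale == "comma" else "."
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    path = out_dir / "differential.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "accession\tdescription\tsc_ref\tsc_test\tdave\tdci\tsignificant\n"
        )
        ordered = sorted(
            result.records, key=lambda r: (-abs(r.dci or 0), r.accession)
        )
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        r.accession,
                        r.description,
                        _fmt(r.sc_ref, 2, sep),
                        _fmt(r.sc_test, 2, sep),
                        _fmt(r.dave or 0.0, 2, sep),
                        _fmt(r.dci or 0.0, 1, sep),
                        "yes" if r.significant else "no",
                    ]
                )
                + "\n"
            )
    written["differential"] = path

    if result.venn is not None:
        path = out_dir / "venn.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("signature\tcount\taccessions\n")
            for sig in sorted(result.venn.regions, key=lambda s: (len(s), sorted(s))):
                accs = sorted(result.venn.regions[sig])
                fh.write(
                    f"{'+'.join(sorted(sig))}\t{len(accs)}\t{','.join(accs)}\n"
                )
        written["venn"] = path

    if result.map_points:
        from membranome.seqprops import write_map

        path = out_dir / "virtual_map.tsv"
        write_map(result.map_points, path)
        written["virtual_map"] = path

    if result.him_composition is not None:
        path = out_dir / "him_composition.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("compartment\tcount\tpercent\n")
            for comp, count in result.him_composition.counts.items():
                fh.write(
                    f"{comp}\t{count}\t{result.him_composition.percentages[comp]}\n"
                )
        written["him_composition"] = path

    path = out_dir / "provenance.json"
    path.write_text(
        json.dumps(result.provenance, indent=2, sort_keys=True), encoding="utf-8"
    )
    written["provenance"] = path
    return written


def report_digest(paths: Mapping[str, Path]) -> str:
    """SHA-256 over all rendered reports, for determinism checks."""
    h = hashlib.sha256()
    for name in sorted(paths):
        h.update(name.encode())
        h.update(Path(paths[name]).read_bytes())
    return h.hexdigest()
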