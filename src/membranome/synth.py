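"""Synthetic MudPIT-style datasets with known ground truth.

The generator emulates the statistical structure the score-based pipeline
assumes, at the study's replicate design (conditions × 2 biological × 2
technical replicates):

* protein consensus scores drawn from a log-normal family — nonnegative and
  heavy-tailed, spanning the low (≤15) to high (≥35) score classes;
* a configurable fraction of proteins carry a multiplicative fold effect in
  the test condition (direction random), the rest are null;
* per-run observed scores are the expected score times log-normal replicate
  noise at a configured coefficient of variation;
* presence/absence dropout: a protein is missing from a run with
  probability 1 − detection(expected score), where detection is a logistic
  curve in the expected score (midpoint well below typical scores, so
  dropout mostly affects weak identifications);
* random protein sequences (uniform over the 20 amino acids, lengths
  80–800) accompany the lists so MW/pI mapping is exercised.

Ground truth records, per protein, the expected reference score, the fold
effect and the noise-free DAve/DCI — a protein is labelled differential iff
those noise-free indexes clear the dual thresholds.

A PSM-level mode decomposes each run's protein scores into peptide-spectrum
matches (plus sub-threshold decoys) so the acceptance-filtering and
assembly stages are exercised end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from membranome.config import AnalysisConfig
from membranome.differential import (
    ConsensusList,
    DifferentialRecord,
    compute_dave,
    compute_dci,
)
from membranome.errors import ConfigError
from membranome.identification import PSM, ProteinEntry, RunIdentification

_AA = "ACDEFGHIKLMNPQRSTVWY"


class SynthConfig(BaseModel):
    """Parameters of the synthetic MudPIT experiment."""

    n_proteins: int = Field(300, ge=1)
    conditions: tuple[str, ...] = ("reference", "depleted")
    n_bio_replicates: int = Field(2, ge=1)
    n_tech_replicates: int = Field(2, ge=1)
    #: log-normal location/scale of the base consensus score (median ~20,
    #: populating both the <=15 and >=35 map classes)
    score_log_mean: float = 3.0
    score_log_sd: float = Field(0.8, gt=0)
    fraction_of_differential: float = Field(0.2, ge=0.0, le=1.0)
    #: multiplicative effect magnitudes for differential proteins; the
    #: direction (up/down in the test condition) is random
    fold_range: tuple[float, float] = (2.0, 8.0)
    #: logistic detection curve: P(detected) = 1/(1+exp(-(s-mid)/width));
    #: None disables dropout entirely
    dropout_midpoint: float | None = 5.0
    dropout_width: float = Field(2.0, gt=0)
    replicate_noise_cv: float = Field(0.1, ge=0.0)
    seq_length_range: tuple[int, int] = (80, 800)
    mode: Literal["protein", "psm"] = "protein"
    #: explicit fold effects by accession (e.g. {"SYN00000": 0.0} for a
    #: complete knockout); applied after random assignment
    fold_overrides: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        lo, hi = self.fold_range
        if not 0 < lo <= hi:
            raise ConfigError("fold_range must be positive and ordered")
        if lo <= 1.0 <= hi:
            raise ConfigError(
                "fold_range must exclude 1 (differential proteins must "
                "carry a real effect)"
            )
        if len(self.conditions) < 2:
            raise ConfigError("need at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be unique")
        a, b = self.seq_length_range
        if not 1 <= a <= b:
            raise ConfigError("seq_length_range must be ordered and >= 1")
        return self


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth for one synthetic protein."""

    accession: str
    base_score: float  # expected consensus score in the reference condition
    fold: float  # expected test score = base_score * fold
    is_differential: bool
    true_dave: float
    true_dci: float


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion summary of flagged vs truly differential proteins."""

    sensitivity: float
    fdp: float
    tp: int
    fp: int
    fn: int
    tn: int


def _detection_prob(expected: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    p = np.where(expected > 0, 1.0, 0.0)
    if cfg.dropout_midpoint is not None:
        logistic = 1.0 / (
            1.0 + np.exp(-(expected - cfg.dropout_midpoint) / cfg.dropout_width)
        )
        p = p * logistic
    return p


def _expected_score(base: float, fold: float, condition_idx: int, n_cond: int) -> float:
    # the fold effect applies in the final (test) condition; intermediate
    # conditions behave like the reference (the study's permissive control)
    return base * fold if condition_idx == n_cond - 1 else base


def generate_dataset(
    config: SynthConfig,
    analysis: AnalysisConfig | None = None,
) -> tuple[dict[str, list[RunIdentification]], dict[str, str], dict[str, SynthTruth]]:
    """Generate per-condition replicate runs, sequences, and ground truth.

    Deterministic for a fixed ``config.seed``.  Returns ``(runs, sequences,
    truth)`` where ``runs`` maps condition → list of
    :class:`RunIdentification` (one per bio × tech replicate).
    """
    analysis = analysis or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = [f"SYN{i:05d}" for i in range(n)]

    base = rng.lognormal(config.score_log_mean, config.score_log_sd, size=n)
    is_candidate = rng.random(n) < config.fraction_of_differential
    magnitude = rng.uniform(*config.fold_range, size=n)
    up = rng.random(n) < 0.5
    fold = np.where(is_candidate, np.where(up, magnitude, 1.0 / magnitude), 1.0)
    for acc, f in config.fold_overrides.items():
        if f < 0:
            raise ConfigError(f"fold override for {acc} must be >= 0")
        if acc in accessions:
            fold[accessions.index(acc)] = f

    truth: dict[str, SynthTruth] = {}
    for i, acc in enumerate(accessions):
        ref, test = base[i], base[i] * fold[i]
        dave = compute_dave(ref, test)
        dci = compute_dci(ref, test)
        truth[acc] = SynthTruth(
            accession=acc,
            base_score=float(ref),
            fold=float(fold[i]),
            is_differential=bool(
                abs(dave) > analysis.dave_threshold
                and abs(dci) > analysis.dci_threshold
            ),
            true_dave=float(dave),
            true_dci=float(dci),
        )

    sigma = float(np.sqrt(np.log1p(config.replicate_noise_cv**2)))
    n_cond = len(config.conditions)
    runs: dict[str, list[RunIdentification]] = {c: [] for c in config.conditions}
    for ci, condition in enumerate(config.conditions):
        expected = np.array(
            [_expected_score(base[i], fold[i], ci, n_cond) for i in range(n)]
        )
        detect_p = _detection_prob(expected, config)
        for bio in range(1, config.n_bio_replicates + 1):
            for tech in range(1, config.n_tech_replicates + 1):
                detected = rng.random(n) < detect_p
                noise = (
                    np.exp(rng.normal(0.0, sigma, size=n))
                    if sigma > 0
                    else np.ones(n)
                )
                observed = np.round(expected * noise, 2)
                entries = [
                    ProteinEntry(
                        accession=accessions[i],
                        description=f"synthetic protein {i}",
                        sc=float(observed[i]),
                        hits=max(1, round(float(observed[i]) / 6.0)),
                    )
                    for i in range(n)
                    if detected[i] and observed[i] > 0
                ]
                runs[condition].append(
                    RunIdentification(
                        sample_id=f"{condition}_b{bio}_t{tech}",
                        condition=condition,
                        bio_replicate=bio,
                        tech_replicate=tech,
                        entries=entries,
                    )
                )

    lengths = rng.integers(
        config.seq_length_range[0], config.seq_length_range[1] + 1, size=n
    )
    sequences = {
        accessions[i]: "".join(
            rng.choice(list(_AA), size=int(lengths[i]))
        )
        for i in range(n)
    }
    return runs, sequences, truth


def psms_for_run(
    run: RunIdentification,
    sequences: dict[str, str],
    seed: int = 0,
    decoy_rate: float = 0.3,
) -> list[PSM]:
    """Decompose a run's protein scores into synthetic peptide-spectrum
    matches that reconstruct the run under filtering + assembly.

    Each protein entry of score S is split into k = max(1, round(S/5))
    peptides of equal Xcorr S/k at charge 2 (above the 2.0 acceptance tier
    whenever S/k > 2, i.e. for any protein passing the consensus cut), with
    distinct peptide sequences cut from the protein sequence.  Duplicate
    PSMs with lower Xcorr and sub-threshold decoy PSMs are interleaved so
    the filters have real work to do.  Proteins whose score cannot clear
    the consensus minimum after filtering are faithfully lost downstream.
    """
    rng = np.random.default_rng(seed)
    psms: list[PSM] = []
    for entry in run.entries:
        seq = sequences.get(entry.accession)
        if seq is None or entry.sc <= 0:
            continue
        k = max(1, round(entry.sc / 5.0))
        while k > 1 and entry.sc / k <= 2.05:
            k -= 1
        xcorr = entry.sc / k
        step = max(1, (len(seq) - 12) // max(k, 1))
        for j in range(k):
            start = (j * step) % max(1, len(seq) - 8)
            peptide = seq[start : start + 8 + int(rng.integers(0, 5))]
            if not peptide:
                peptide = seq[:8]
            peptide = peptide.replace("X", "A") or "AAAAAAAA"
            psms.append(
                PSM(
                    peptide=peptide,
                    charge=2,
                    xcorr=xcorr,
                    probability=float(rng.uniform(1e-6, 1e-4)),
                    protein_accession=entry.accession,
                )
            )
            # duplicate identification of the same peptide at lower Xcorr:
            # assembly must keep the maximum, not the sum
            if rng.random() < 0.3:
                psms.append(
                    PSM(
                        peptide=peptide,
                        charge=2,
                        xcorr=max(2.1, xcorr * 0.7),
                        probability=float(rng.uniform(1e-6, 1e-4)),
                        protein_accession=entry.accession,
                    )
                )
        if rng.random() < decoy_rate:  # rejected by Xcorr or probability
            bad = "".join(rng.choice(list(_AA), size=9))
            if rng.random() < 0.5:
                psms.append(
                    PSM(bad, 2, float(rng.uniform(0.2, 1.9)), 1e-4, entry.accession)
                )
            else:
                psms.append(
                    PSM(bad, 2, float(rng.uniform(2.5, 5.0)), 0.05, entry.accession)
                )
    order = rng.permutation(len(psms))
    return [psms[i] for i in order]


def truth_recovery_report(
    truth: dict[str, SynthTruth],
    flagged,
) -> RecoveryReport:
    """Sensitivity, false-discovery proportion and confusion counts.

    ``flagged`` is a set of accessions or an iterable of
    :class:`DifferentialRecord` (significant ones are taken).
    """
    if not isinstance(flagged, (set, frozenset)):
        flagged = {
            r.accession if isinstance(r, DifferentialRecord) else r
            for r in flagged
            if not isinstance(r, DifferentialRecord) or r.significant
        }
    true_set = {acc for acc, t in truth.items() if t.is_differential}
    universe = set(truth)
    tp = len(flagged & true_set)
    fp = len(flagged - true_set)
    fn = len(true_set - flagged)
    tn = len(universe - true_set - flagged)
    sensitivity = tp / len(true_set) if true_set else 0.0
    fdp = fp / len(flagged) if flagged else 0.0
    return RecoveryReport(sensitivity=sensitivity, fdp=fdp, tp=tp, fp=fp, fn=fn, tn=tn)


def generate_fraction_lists(
    config: SynthConfig,
    analysis: AnalysisConfig | None = None,
) -> tuple[dict[str, ConsensusList], dict[str, str]]:
    """Emulate IM/hIM/OM sucrose-gradient fraction lists with a localization
    annotation.

    Each protein gets a compartment (IM/OM/cytoplasmic/periplasmic/unknown
    at roughly envelope-proteome proportions); its score in each fraction is
    the base score scaled by a compartment-specific enrichment profile
    (IM proteins concentrate in IM and hIM, OM proteins in OM, soluble
    proteins appear weakly everywhere), with dropout for weak signals.
    Returns ``(fraction_lists, annotation)``.
    """
    analysis = analysis or AnalysisConfig()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_proteins
    accessions = [f"SYN{i:05d}" for i in range(n)]
    base = rng.lognormal(config.score_log_mean, config.score_log_sd, size=n)

    compartments = ("IM", "OM", "cytoplasmic", "periplasmic", "unknown")
    probs = (0.40, 0.20, 0.25, 0.05, 0.10)
    assigned = rng.choice(compartments, size=n, p=probs)
    # fraction enrichment per compartment: (IM, hIM, OM) multipliers
    enrichment = {
        "IM": (1.0, 0.8, 0.15),
        "OM": (0.15, 0.5, 1.0),
        "cytoplasmic": (0.35, 0.45, 0.1),
        "periplasmic": (0.2, 0.3, 0.2),
        "unknown": (0.3, 0.4, 0.3),
    }
    lists: dict[str, ConsensusList] = {}
    for fi, frac in enumerate(("IM", "hIM", "OM")):
        scores: dict[str, tuple[float, int]] = {}
        for i in range(n):
            expected = base[i] * enrichment[assigned[i]][fi]
            p = _detection_prob(np.array([expected]), config)[0]
            if rng.random() < p:
                sc = round(float(expected), 2)
                if sc > 0:
                    scores[accessions[i]] = (sc, max(1, round(sc / 6.0)))
        lists[frac] = ConsensusList(condition=frac, scores=scores)
    annotation = {accessions[i]: str(assigned[i]) for i in range(n)}
    return lists, annotation
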