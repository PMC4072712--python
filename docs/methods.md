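# Methods

## Scope and model

`membranome` implements score-based label-free differential proteomics as
practised with MudPIT (2D LC-MS/MS) + SEQUEST identification output. The
quantitative signal is never an ion intensity: it is the protein
**consensus score** (SC), an identification-confidence statistic that
grows with the number and quality of a protein's accepted peptide-spectrum
matches and is used as a relative-abundance proxy between matched samples.
All downstream statistics (DAve, DCI, Venn membership, hIM selection) are
deterministic functions of SC values; there are no p-values and no
multiple-testing machinery in this workflow — stringency comes from the
dual-index threshold.

## Acceptance filtering and protein assembly

A PSM is accepted iff its Xcorr is **strictly greater** than the
charge-specific minimum — 1.5 (1+), 2.0 (2+), 2.5 (3+ and, by extension,
every higher charge) — and its peptide probability is **at most** 0.001.
The asymmetry (strict vs inclusive) follows the wording of the original
filter set and is preserved exactly.

SEQUEST's protein "consensus score" has no published closed form, so the
package defines it explicitly: **SC = Σ over distinct accepted peptide
sequences of that peptide's maximum Xcorr**, with `hits` = the number of
distinct peptides. This reproduces the right order of magnitude (tens for
confident identifications, matching scores like 40.25/7 or 50.30/7 seen in
fraction tables) and makes the protein-level cut SC ≥ 10 meaningful
(roughly "at least two to four good peptides"). It is a documented
stand-in, not a claim about SEQUEST internals; any monotone aggregate
would order proteins similarly.

## Replicate merging and alignment

Each condition is measured in 2 biological × 2 technical replicates. The
condition-level consensus list is the **union** of accessions over its
runs with the **maximum** score per accession (policies `mean` and `sum`
are available). Max-over-union is the default because presence/absence
carries signal in this workflow: a protein lost to technical dropout in
one run should not be averaged toward absence, and the ±2 DAve extremes
stay stable under dropout.

Two conditions are compared by full outer join on accession; a protein
missing from one side enters with score 0 (never stored as 0 inside a
list — absence is omission). DAve/DCI are then:

- `DAve = (R − T) / ((R + T)/2)` — the score difference normalised by the
  mean score, bounded in [−2, +2], scale-invariant, exactly ±2 for
  one-sided detection;
- `DCI = ((R + T)/2)(R − T)` — the same difference weighted by the mean
  score (quadratic under rescaling), so weakly identified proteins cannot
  produce large |DCI|.

These closed forms are the package's own statement of the two indices,
chosen because they reproduce the documented range, the ±2.00 entries for
presence/absence proteins and the described "relative ratio" / "absolute
variation" semantics. The significance rule is strict and two-sided:
`(DAve > 0.4 and DCI > 400) or (DAve < −0.4 and DCI < −400)`; both indices
must pass with agreeing signs. Positive means more abundant in the
reference condition.

## Sets, fractions, composition

- Venn partitioning assigns each accession of 2–3 named lists to the
  signature of exactly the lists containing it; regions are disjoint and
  sum to the universe.
- hIM membership uses score **strictly greater than 30** on the hIM
  fraction list.
- Compartment composition counts proteins per {IM, OM, cytoplasmic,
  periplasmic, unknown} (unannotated ⇒ unknown) and reports integer
  percentages rounded half-away-from-zero; they sum to 100 within ±1.
  (Note that published whole-number percentages are not always exactly
  reconstructible from their own totals under any rounding rule; the
  package's rule is fixed and tested.)
- Fraction profiles report (score, hits) per fraction with (0, 0) for not
  detected, rendered as "nd" in table output.

## Theoretical pI and MW

Net charge at pH x is the Henderson–Hasselbalch sum over the N-terminus
and K/R/H (positive terms `1/(1+10^(x−pKa))`) minus the C-terminus and
D/E/C/Y (negative terms `1/(1+10^(pKa−x))`). The curve is strictly
decreasing, so pI — its unique zero on [0, 14] — is found by bisection to
1e-3 pH (far below any plotting resolution). The pKa set is pinned: the
EMBOSS values (N-term 8.6, C-term 3.6; D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5,
K 10.8, R 12.5), registered under the id `"emboss"` and selectable via
`AnalysisConfig.pka_table_id` — theoretical pI is only reproducible
relative to a stated table. MW is the sum of residue masses plus one
water, **average masses by default** (monoisotopic selectable); `X`
contributes the mean of the 20 residue masses. No post-translational
modifications and no signal-peptide cleavage are applied. Map score
classes are inclusive outward: high iff SC ≥ 35, low iff SC ≤ 15.

## Synthetic data generator

The generator emulates what the analysis consumes — exported per-run
protein lists — not chromatography or spectra.

Defaults (the simulated study conditions, chosen once):

| parameter | default | rationale |
|---|---|---|
| conditions | reference, depleted | two-condition comparison; extra middle conditions behave like the reference |
| replicates | 2 bio × 2 tech | the study's design |
| n_proteins | 300 | ≈ the per-sample identification count of an envelope MudPIT run |
| SC distribution | log-normal, μ=3.0, σ=0.8 | nonnegative, heavy-tailed; median ≈ 20 with both ≤15 and ≥35 classes well populated |
| fraction_of_differential | 0.2 | ≈ 123 differential of ~500 aligned accessions in such comparisons |
| fold_range | 2–8 (direction random; must exclude 1) | clearly perturbed vs null; `fold_overrides` permits explicit effects incl. 0 (knockout) |
| replicate_noise_cv | 0.1 | typical technical CV of score-scale replicates |
| dropout | logistic in expected score, midpoint 5, width 2 | presence/absence failures concentrate on weak identifications; `None` disables |

Per run, the observed score is `expected × LogNormal(0, σ)` with
`σ = sqrt(ln(1+CV²))` (median-preserving), rounded to 2 decimals like an
exported list, and the protein is dropped with probability
`1 − detection(expected)`. A protein's truth label `is_differential` is
the dual-threshold rule evaluated on the *noise-free expected* scores, so
truth and pipeline are compared on identical terms. Bio and tech
replicates are treated identically (one noise level); the generator does
not model shared biological-replicate effects, peptide-level
between-protein score correlation, or abundance-dependent CV — passing
recovery tests therefore demonstrates correctness of the pipeline's
logic under the stated noise model, not performance on real instrument
data.

PSM-level mode (`psms_for_run`) decomposes a run's protein scores into
equal-Xcorr charge-2 peptides cut from the protein sequence (k ≈ SC/5,
keeping each Xcorr above the 2+ tier), plus duplicate PSMs at lower Xcorr
and sub-threshold decoys, so filtering and assembly are exercised
end-to-end and reconstruct the run's scores.

## Numerical and design choices

- All thresholds are strict/inclusive exactly as stated above; boundary
  values (DAve = 0.4, DCI = 400, SC = 30 for hIM) are **not** significant/
  members, and this is pinned by exhaustive grid tests.
- DAve/DCI are undefined (raised error) only for the 0/0 pair, which
  cannot arise from an alignment.
- Duplicate accessions in a protein-list file collapse to the
  maximum-score row (conservative presence call); conflicting descriptions
  warn and keep the first.
- Reports print DAve to 2 decimals; a comma-decimal locale is available to
  match European table formatting.
- Determinism: one `numpy` Generator seeded from `SynthConfig.seed` drives
  all randomness; identical config + inputs give byte-identical reports
  (hash-checked in tests).
- Problem sizes in the test suite (80–300 proteins, 10-seed stochastic
  checks, a 61×61 score grid) were chosen as the smallest sizes at which
  the tested properties are stable.

## Known limitations

- Score-based quantification saturates: SC correlates with abundance but
  is not linear in it, and the generator inherits this simplification by
  simulating directly on the score scale.
- The consensus-score composition rule is a stand-in (above); absolute SC
  values are comparable within this package, not across search engines.
- No FDR estimation beyond the printed filters; no XIC/intensity
  quantification; no localization prediction (annotations are supplied by
  the user); no modelling of the sucrose-gradient physics behind the
  IM/hIM/OM fractions — fraction lists are inputs.
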