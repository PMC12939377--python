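# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `hrvlit`. Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Evidence extraction and the MLRD

Each paper contributes one extraction table with columns
`parameter | High/Low | related outcome` over the closed seven-parameter set
{HF, LF/HF, VLF, LF, TP, SDNN, rMSSD}. Parsing accepts pipe-delimited tables
with or without markdown separator rows and outer pipes, because table
formatting from language-model output varies while the column semantics are
fixed. Direction vocabulary is normalised ({higher, increased, elevated} →
high; {lower, decreased, reduced} → low, case-insensitive); `N/A` cells mark
a row uninformative. A paper is *relevant* iff at least one row has both a
direction and a non-empty outcome; all-N/A tables are excluded — an empty
table is the extraction's signal that the abstract did not relate HRV
parameters to outcomes.

A counted record requires the outcome text to match a configurable
vascular-event lexicon (default: cardiovascular, cerebrovascular, stroke,
vascular event, mortality, myocardial infarction, cardiac event;
case-insensitive substring). The original evidence base was assembled from a
vascular-event literature query, so lexicon matching is this package's
explicit, auditable stand-in for that upstream filter.

**One tally per (parameter, direction) per paper.** A paper may report a
parameter in both directions (e.g. different sub-cohorts) and then
contributes one tally to each column. This is forced by arithmetic: the
bundled reference counts contain 222 HF records from 140 relevant papers,
impossible at one row per parameter per paper. Duplicate rows for the same
(parameter, direction) are a parse error.

Aggregation is order-independent (counts are sums; provenance lists are
sorted), and the generator⇄aggregator round trip is exact by construction:
`gen_literature_corpus` assigns each directional tally to a distinct relevant
paper (largest classes first, least-loaded paper first), which also
guarantees every relevant paper has at least one informative row. The
generator refuses targets that are unsatisfiable (a single count exceeding
the number of relevant papers, or fewer tallies than relevant papers).

## Three-phase prioritization

Selection over the anonymized (A–G) counts proceeds:

1. **Consistency** `max(pos, neg)/(pos+neg)`; undefined (excluded) when a
   parameter has no evidence.
2. **Retention** at threshold 2/3. The source procedure never states its
   cutoff, only its outcome; on the reference counts the consistencies are
   A 0.532, B 0.607, C 0.800, D 0.743, E 0.750, so any threshold in
   (0.607, 0.743] reproduces the retained set {C, D, E}. 2/3 sits in that
   interval with margin on both sides and is exposed as configuration.
3. **Document count**: the retained code with the largest pos+neg total
   wins (C 30, D 113, E 28 → D, i.e. LF). The dominant direction is the
   larger column (LF: 84 negative vs 29 positive → negative).

Ties are broken by higher consistency, then codebook order, and every phase
decision is recorded in a trace. Equal pos/neg counts for the winner default
the direction to negative (risk-conservative for HRV, where reduced
variability is the canonical danger sign) and are flagged in the trace.
The deterministic rules replace the original model-in-the-loop judgement,
whose outputs were reported stable across repeated runs; the three phase
prompts are still rendered (`render_prioritization_prompts`) for an optional
LLM replication, but are not executed. Selection provably commutes with
anonymization, and agrees with a literal brute-force enumeration of the
three rules on randomized databases (tested).

## Signal chain

**QRS detection.** Candidate peaks are local maxima above an adaptive
threshold (0.5 × rolling 2-s maximum, with an absolute floor at 0.25 × the
global maximum to fail cleanly on flat signals) separated by a 250 ms
refractory period. Per-candidate features are peak height and half-height
duration; the template is their mean ± σ over all candidates, and candidates
deviating more than 3σ in either feature are rejected (ventricular premature
complexes, noise). σ is floored at 1% of the feature mean so that noise-free
synthetic records (σ = 0) do not self-reject. With a 3σ cut, about 0.3% of
genuine beats are expected to be rejected under Gaussian feature noise;
rejected-beat gaps are flagged and excluded rather than interpolated.

**Windows.** RR intervals are grouped into non-overlapping 300 s windows on
a fixed grid inside the daytime span 08:00–16:00 (96 windows for a full
24-h record). A window is dropped when more than 5% of its intervals are
flagged invalid. This invalid-fraction rule, plus an optional variance
filter, replaces the original expert steady-state adjudication.

**Spectrum.** The tachogram (interval value anchored at its closing beat) is
resampled at 4 Hz by cubic spline. Linear interpolation was considered and
is retained as an option, but its chord error attenuates a modulation at
frequency ω by ≈ (ω·ΔRR)²/12 — measurably 2.1% in amplitude at 0.1 Hz and
tens of percent in power at 0.3 Hz for 0.8 s beats — which would bias HF
power; the spline makes the attenuation negligible for band-limited content.
The resampled series has its mean (DC) removed, a Hamming window applied,
and the one-sided squared-FFT density is divided by the window's noise-power
gain `mean(w²)`. This is the package's reading of "attenuation correction":
the integral of the corrected density equals the window-weighted variance of
the series *exactly* (machine precision, tested), and equals the plain
sample variance up to the sampling fluctuation of stochastic content
(O(√(Σw⁴)/Σw²) ≈ 3% of the noise power at 1200 samples — for deterministic
band-limited modulation the two agree well within 1%). Band powers integrate
the density over half-open bands VLF [0.003, 0.04), LF [0.04, 0.15),
HF [0.15, 0.4) Hz so shared edges are counted once; TP spans their union.
ln(LF) and ln(HF) are taken per window; zero band power yields a missing
(NaN) log and LF/HF, never ±inf.

**Per-subject reduction.** Subject features are means of per-window values
across eligible daytime windows, with log-domain fields averaged in the log
domain. The original study does not state its reduction; the log-domain mean
matches the distributional argument for the ln transform.

## Cohort stratification and evaluation

Reference statistics (sample mean, SD with ddof = 1) default to the
non-event controls — the less circular reading, matching the convention of
reporting "control-group mean ± SD" — with an all-subjects mode available.
Strata are strict: *above* iff value > mean + k·SD, *below* iff
value < mean − k·SD, boundary values fall *within* ("more than 1σ").
Prediction is positive only when the stratum matches the literature
direction. k defaults to 1.0.

Metrics follow the standard formulas (accuracy (TP+TN)/N, sensitivity
TP/(TP+FN), specificity TN/(TN+FP)), computed in full precision and rendered
half-up to one decimal percent (Python's banker's rounding would turn 81.25
into 81.2). Zero-denominator metrics are NaN. Two of the bundled published
summary percentages (LF accuracy 86.3 / specificity 87.1) and one
sensitivity (HF 43.8) are mutually inconsistent with the bundled four-cell
matrices ((13+85)/114 = 86.0, 85/98 = 86.7, 7/21 = 33.3); the package treats
the matrices as canonical and reproduces only the self-consistent set.

The ROC sweeps the raw feature threshold (the continuous-k limit of the
stratification rule; direction-aware sign flip), with (0,0)/(1,1) endpoints
and trapezoidal AUC — verified to 1e-9 against brute-force pairwise
concordance and against an independent library implementation. A coarse
k-grid mode evaluating the literal ±k·SD rule is also provided. Grouped
evaluation repeats confusion + metrics per group (e.g. sex) and overall.

## Synthetic-data models

* **RR generator**: intervals mean_rr + Σ aᵢ·sin(2π fᵢ t + φᵢ) + ε at
  cumulative beat times; parameter sets with Σaᵢ + 4·noise_sd ≥ mean_rr are
  rejected. Each modulation contributes aᵢ²/2 ms² of variance; noise adds
  noise_sd². Because beat *timing* carries the modulation, a small part of
  high-frequency line power spreads into FM sidebands — total variance is
  conserved (tested) but narrow-line oracles must demodulate at the
  generating times.
* **ECG generator**: Gaussian pulses (height 1 mV, FWHM 80 ms) at given R
  times; ectopics are height ×1.8 (and optionally width) outliers; overlap
  (gap < pulse width) rejected; ground-truth beat table returned.
* **Cohort generator**: ln(LF) ~ Normal(5.4, 1.1) (ln ms², typical daytime
  short-term values for middle-aged hypertensive adults), 114 subjects with
  16 events by default, sex assigned at the 90:49 male:female ratio of the
  reference cohort. Event models: *none* — exactly n_events subjects chosen
  uniformly (exact prevalence, null association); *threshold* — event
  subjects' values redrawn from the lower truncated tail below
  mean − (effect+1.25)·SD and nudged down until all sit strictly below
  mean − effect·SD under both empirical reference conventions, making
  perfect sensitivity a construction guarantee rather than a seed-dependent
  accident; *logistic* — P(event) = expit(α − effect·z) with α solved
  numerically so the expected event count equals n_events across effect
  sizes.
* **Corpus generator**: see above.

What the generators do **not** emulate: realistic QRS morphology and
arrhythmia, circadian/nonstationary HRV dynamics, skewed raw LF
distributions (ln(LF) is drawn Gaussian directly), correlated missingness,
and sex-specific effect differences. Passing tests therefore demonstrate
correctness of the mechanics under known ground truth, not clinical
performance on real Holter data.

## Problem sizes and determinism

Tests and the acceptance script use 5–30 min tachograms (1200-sample
windows), 375-beat ECGs at 250 Hz, 114-subject cohorts (10,000 for the null
calibration of the tail rate), 670-paper corpora, and 20–50 seed replicates
for stochastic rates — sizes at which every analytic target (sinusoid power,
Φ(−1) tail, null AUC) is resolved well inside its tolerance. All randomness
flows through explicit integer seeds; identical spec + seed gives
byte-identical outputs, and the full-pipeline report embeds the config and
input digests.

## Known limitations

* ECG input is single-lead CSV; no binary Holter formats.
* The detector handles upright QRS of roughly stereotyped morphology;
  inverted or biphasic complexes would need a polarity/feature extension.
* The lexicon stand-in for the upstream literature query is a substring
  match, not concept normalization.
* VLF from 5-min windows is reported but, as usual, of limited
  interpretability (the lowest VLF frequencies are barely resolved at 300 s).
* No confidence intervals on metrics or AUC.
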