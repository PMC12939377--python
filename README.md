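# hrvlit — literature-guided HRV risk stratification

`hrvlit` implements a transparent clinical-decision-support pipeline that
predicts cardiovascular/cerebrovascular events in a cohort from heart-rate
variability (HRV), with the predictive parameter chosen not by statistical
model fitting but by structured synthesis of the published literature.

The pipeline has two streams that meet at a simple classifier:

1. **Evidence stream.** Abstracts of HRV studies are reduced, one table per
   paper, to rows of `parameter | High/Low | related outcome` over the closed
   set {SDNN, rMSSD, VLF, LF, HF, LF/HF, TP}. Papers whose table is empty are
   excluded as irrelevant. Relevant tables are tallied into the *medical
   literature review database* (MLRD): for each parameter, the number of
   papers reporting it **higher** in event subjects (positive association)
   and the number reporting it **lower** (negative association).
2. **Signal stream.** 24-h ECG is processed to an RR tachogram
   (template-based QRS detection with ectopic rejection), daytime
   (08:00–16:00) 5-min windows are selected, and a Hamming-windowed FFT
   spectrum with attenuation correction yields band powers
   VLF (0.003–0.04 Hz), LF (0.04–0.15 Hz), HF (0.15–0.4 Hz), TP, plus SDNN
   and rMSSD; LF and HF are ln-transformed to near-normality.

The stratification parameter is selected from the MLRD by a deterministic
three-phase *least-to-most* procedure: per-parameter consistency
`max(pos, neg)/(pos + neg)` (parameters with no evidence are dropped),
retention of candidates with consistency ≥ 2/3, then selection by largest
total document count. With the bundled reference evidence counts this yields
LF with a **negative** dominant direction (lower LF ⇒ higher risk).

Subjects are then stratified against a reference mean ± k·SD (k = 1 by
default; reference statistics from the non-event controls by default):
a subject is predicted event-positive exactly when their value falls in the
stratum matching the literature direction (below −1σ for a negatively
associated parameter). Evaluation covers the confusion matrix, accuracy /
sensitivity / specificity, an ROC over the decision threshold, AUC, and
grouped (e.g. by-sex) metrics.

All external inputs can be synthesized with known ground truth: RR series
with sinusoidal band-limited modulations (a modulation of amplitude *a* ms
contributes *a*²/2 ms² of band power), ECG with stereotyped QRS pulses and
ectopic outliers, cohorts with null / low-tail-threshold / logistic event
models, and literature corpora whose aggregated counts reproduce a target
exactly.

## Worked example

```bash
hrvlit simulate-corpus --out demo_corpus --n-papers 200 --relevant-fraction 0.7 --seed 1
hrvlit simulate-cohort --out demo_cohort.csv --effect-model threshold --seed 4
hrvlit run --corpus demo_corpus --cohort demo_cohort.csv --out demo_out
```

prints the run report:

```
literature-guided HRV risk stratification — run report

corpus: 200 papers, 140 relevant, 60 excluded as irrelevant
evidence records aggregated: 538
prioritization: retained ['C', 'D', 'E'], selected LF (negative association with events)
cohort: 114 subjects, feature ln_lf (0 missing)
confusion: TP=16 FP=15 FN=0 TN=83
accuracy 86.8%  sensitivity 100.0%  specificity 84.7%
ROC AUC 1.000
```

Reading this: 538 directional parameter–outcome records were aggregated from
the 140 relevant papers; the consistency screen kept codes C, D, E (VLF, LF,
TP) and the document count selected LF, reported lower in event subjects.
On the synthetic cohort — 114 subjects, 16 events placed in the low tail of
ln(LF) — the −1σ rule recovers every event (sensitivity 100%) while flagging
15 of 98 non-events, and the ROC threshold sweep separates the classes
perfectly (AUC 1.000). The same
stages are available as library functions (`hrvlit.aggregate_mlrd`,
`hrvlit.prioritize`, `hrvlit.subject_features`, `hrvlit.classify_cohort`,
`hrvlit.roc_curve`, …) and as further subcommands (`extract`, `aggregate`,
`prioritize`, `hrv`, `stratify`, `evaluate`).

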