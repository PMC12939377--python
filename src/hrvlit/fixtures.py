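"""Bundled reference data from a published hypertensive-cohort HRV study.

Two small sets of published numbers ship with the package as inputs for
worked examples and regression checks:

* ``REFERENCE_EVIDENCE_COUNTS`` — directional literature counts (papers
  reporting each HRV parameter higher vs lower in subjects with a
  cardiovascular or cerebrovascular event), aggregated from 140 relevant
  abstracts; 538 directional records in total.  SDNN and rMSSD had no
  extractable evidence.
* ``REFERENCE_CONFUSION_MATRICES`` — the four-cell diagnostic outcomes
  (tp, fp, fn, tn) of the ±1σ classifier on a 114-subject hypertensive
  Holter cohort with 16 events, one matrix per candidate HRV parameter.

These are published tallies used as *inputs*; nothing in the package fits
to them.
"""

from __future__ import annotations

from .evaluation import ConfusionMatrix

#: parameter -> (positive count, negative count)
REFERENCE_EVIDENCE_COUNTS: dict[str, tuple[int, int]] = {
    "HF": (104, 118),
    "LF/HF": (57, 88),
    "VLF": (6, 24),
    "LF": (29, 84),
    "TP": (7, 21),
    "SDNN": (0, 0),
    "rMSSD": (0, 0),
}

#: parameter -> ConfusionMatrix(tp, fp, fn, tn); n = 114, 16 events each
REFERENCE_CONFUSION_MATRICES: dict[str, ConfusionMatrix] = {
    "HF": ConfusionMatrix(tp=7, fp=9, fn=14, tn=84),
    "LF/HF": ConfusionMatrix(tp=4, fp=12, fn=12, tn=86),
    "VLF": ConfusionMatrix(tp=6, fp=14, fn=10, tn=84),
    "LF": ConfusionMatrix(tp=13, fp=13, fn=3, tn=85),
    "TP": ConfusionMatrix(tp=10, fp=14, fn=6, tn=84),
}

#: Corpus scale of the reference literature search: 670 retrieved papers,
#: 140 of which were relevant (yielded a non-empty extraction table).
REFERENCE_N_PAPERS = 670
REFERENCE_N_RELEVANT = 140

#: Reference cohort composition.
REFERENCE_N_SUBJECTS = 114
REFERENCE_N_EVENTS = 16
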