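"""Synthetic data with known ground truth for every pipeline stage.

Four generators stand in for the study's external inputs:

* RR tachograms with sinusoidal autonomic modulation in defined bands plus
  Gaussian noise, so band powers are analytically known (a sinusoid of
  amplitude ``a`` ms contributes ``a²/2`` ms² of variance).
* Single-lead ECG waveforms built from stereotyped Gaussian QRS pulses at
  prescribed R times, with optional amplitude/duration-outlier ectopic beats
  and a ground-truth beat table.
* Cohorts of subjects with near-Gaussian ln(LF) values and event labels under
  a null, threshold (low-tail) or logistic effect model.
* Literature corpora of extraction-table texts whose aggregate directional
  counts reproduce a requested target exactly (round-trip property), mixed
  with irrelevant all-N/A papers.

All generators are deterministic under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .literature import PARAMETERS
from .signals import ECGRecord, RRSeries

#: Default study-scale cohort composition: 114 subjects, 16 with an event.
DEFAULT_N_SUBJECTS = 114
DEFAULT_N_EVENTS = 16
#: Default ln(LF) location/scale (ln ms²), typical of daytime short-term HRV
#: in middle-aged hypertensive adults.
DEFAULT_LF_MEAN = 5.4
DEFAULT_LF_SD = 1.1
#: Male fraction matching a 90/49 male/female Holter cohort.
DEFAULT_MALE_FRACTION = 90 / 139


@dataclass(frozen=True)
class ModulationSpec:
    """One sinusoidal RR modulation: frequency (Hz), amplitude (ms), phase (rad)."""

    freq: float
    amp: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not self.freq > 0:
            raise ValueError("modulation frequency must be positive")
        if not (math.isfinite(self.amp) and self.amp >= 0):
            raise ValueError("modulation amplitude must be finite and >= 0")


@dataclass
class CohortSpec:
    n_subjects: int = DEFAULT_N_SUBJECTS
    n_events: int = DEFAULT_N_EVENTS
    lf_mean: float = DEFAULT_LF_MEAN
    lf_sd: float = DEFAULT_LF_SD
    effect_model: str = "none"  # none | threshold | logistic
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_events <= self.n_subjects:
            raise ValueError("require 0 <= n_events <= n_subjects")
        if self.lf_sd <= 0:
            raise ValueError("lf_sd must be positive")
        if self.effect_model not in ("none", "threshold", "logistic"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")


@dataclass(frozen=True)
class QRSShape:
    """Stereotyped QRS pulse: peak height (mV) and half-height width (ms)."""

    height_mv: float = 1.0
    width_ms: float = 80.0


@dataclass(frozen=True)
class EctopicSpec:
    """Ectopic beats as feature outliers: n beats scaled in height/width."""

    n: int = 0
    height_factor: float = 1.8
    width_factor: float = 1.0


# ---------------------------------------------------------------------------
# RR series


def gen_rr_series(
    duration_s: float,
    mean_rr_ms: float,
    modulations: list[ModulationSpec] | tuple[ModulationSpec, ...] = (),
    noise_sd_ms: float = 0.0,
    seed: int = 0,
    start_clock_s: float = 8 * 3600.0,
) -> RRSeries:
    """RR tachogram with sinusoidal modulations evaluated at beat times.

    Each interval is ``mean_rr_ms + sum_j amp_j sin(2π f_j t + φ_j) + ε`` with
    the sinusoids evaluated at the cumulative beat time and ε Gaussian noise.
    Rejects parameter sets that could drive intervals non-positive
    (``sum(amp) + 4·noise_sd >= mean_rr_ms``).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if mean_rr_ms <= 0:
        raise ValueError("mean_rr_ms must be positive")
    if noise_sd_ms < 0:
        raise ValueError("noise_sd_ms must be >= 0")
    amp_sum = sum(m.amp for m in modulations)
    if amp_sum + 4.0 * noise_sd_ms >= mean_rr_ms:
        raise ValueError(
            "modulation amplitudes plus 4*noise_sd reach the mean RR; "
            "intervals could become non-positive"
        )
    rng = np.random.default_rng(seed)
    times_ms = [0.0]
    intervals: list[float] = []
    t = 0.0
    while t < duration_s * 1000.0:
        rr = mean_rr_ms
        for m in modulations:
            rr += m.amp * math.sin(2.0 * math.pi * m.freq * t / 1000.0 + m.phase)
        if noise_sd_ms > 0:
            rr += rng.normal(0.0, noise_sd_ms)
        intervals.append(rr)
        t += rr
        times_ms.append(t)
    return RRSeries(
        beat_times_ms=np.array(times_ms),
        intervals_ms=np.array(intervals),
        valid=np.ones(len(intervals), dtype=bool),
        start_clock_s=start_clock_s,
    )


# ---------------------------------------------------------------------------
# ECG


def gen_ecg(
    r_times_s,
    qrs: QRSShape = QRSShape(),
    fs: float = 250.0,
    noise_sd: float = 0.0,
    ectopic: EctopicSpec = EctopicSpec(),
    seed: int = 0,
) -> tuple[ECGRecord, pd.DataFrame]:
    """Synthesize an ECG as superposed Gaussian QRS pulses at given R times.

    ``ectopic.n`` beats (chosen at random) are scaled in height and width to
    act as template outliers.  Returns the record and a ground-truth table
    with columns ``r_time_s`` and ``is_ectopic``.  Overlapping pulses
    (inter-beat gap smaller than the pulse width) are rejected.
    """
    r_times = np.asarray(list(r_times_s), dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if r_times.size and np.any(np.diff(r_times) <= 0):
        raise ValueError("r_times must be strictly increasing")
    width_s = qrs.width_ms / 1000.0
    max_width_s = width_s * max(1.0, ectopic.width_factor)
    if r_times.size > 1 and np.min(np.diff(r_times)) < max_width_s:
        raise ValueError("inter-beat gap smaller than pulse width; pulses overlap")

    rng = np.random.default_rng(seed)
    duration = (r_times[-1] + 1.0) if r_times.size else 10.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    is_ectopic = np.zeros(r_times.size, dtype=bool)
    if ectopic.n > 0:
        if ectopic.n > r_times.size:
            raise ValueError("more ectopics requested than beats")
        idx = rng.choice(r_times.size, size=ectopic.n, replace=False)
        is_ectopic[idx] = True

    fwhm_to_sigma = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for rt, ect in zip(r_times, is_ectopic):
        h = qrs.height_mv * (ectopic.height_factor if ect else 1.0)
        sigma = width_s * (ectopic.width_factor if ect else 1.0) * fwhm_to_sigma
        lo = max(0, int((rt - 5 * sigma) * fs))
        hi = min(n, int((rt + 5 * sigma) * fs) + 1)
        x[lo:hi] += h * np.exp(-0.5 * ((t[lo:hi] - rt) / sigma) ** 2)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n)

    truth = pd.DataFrame({"r_time_s": r_times, "is_ectopic": is_ectopic})
    return ECGRecord(samples=x, fs=fs), truth


# ---------------------------------------------------------------------------
# cohort


def _solve_logistic_intercept(z: np.ndarray, effect_size: float, n_events: int) -> float:
    """Intercept α of P(event) = expit(α − effect·z) matching the expected count."""

    def expected(alpha: float) -> float:
        return float(np.sum(expit(alpha - effect_size * z))) - n_events

    return brentq(expected, -50.0, 50.0)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Cohort table: subject_id, sex, ln_lf, event.

    ln(LF) is Normal(lf_mean, lf_sd) per subject.  Event labels:

    * ``none`` — exactly ``n_events`` subjects chosen uniformly at random,
      independent of ln(LF) (null association, exact prevalence).
    * ``threshold`` — event subjects' ln(LF) is redrawn from the Gaussian
      truncated below ``lf_mean − (effect_size + 1.25)·lf_sd`` and nudged
      down if needed, guaranteeing every event sits strictly below
      mean − effect_size·SD of the realized cohort under either reference
      convention (all subjects or non-events only).
    * ``logistic`` — P(event) = expit(α − effect_size·z) with the intercept
      solved so the expected event count equals ``n_events``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    ln_lf = rng.normal(spec.lf_mean, spec.lf_sd, size=n)
    sex = np.where(rng.random(n) < DEFAULT_MALE_FRACTION, "male", "female")
    event = np.zeros(n, dtype=bool)

    if spec.effect_model == "none":
        if spec.n_events:
            event[rng.choice(n, size=spec.n_events, replace=False)] = True
    elif spec.effect_model == "logistic":
        z = (ln_lf - spec.lf_mean) / spec.lf_sd
        if 0 < spec.n_events < n:
            alpha = _solve_logistic_intercept(z, spec.effect_size, spec.n_events)
            event = rng.random(n) < expit(alpha - spec.effect_size * z)
        elif spec.n_events == n:
            event[:] = True
    else:  # threshold
        if spec.n_events >= n:
            raise ValueError("threshold model needs at least one non-event subject")
        if spec.n_events:
            idx = rng.choice(n, size=spec.n_events, replace=False)
            event[idx] = True
            cutoff = spec.lf_mean - (spec.effect_size + 1.25) * spec.lf_sd
            a = (cutoff - spec.lf_mean) / spec.lf_sd
            tail = truncnorm(-math.inf, a, loc=spec.lf_mean, scale=spec.lf_sd)
            ln_lf[idx] = tail.rvs(size=spec.n_events, random_state=rng)
            ln_lf = _enforce_low_tail(ln_lf, event, spec.effect_size, spec.lf_sd)

    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex": sex,
            "ln_lf": ln_lf,
            "event": event,
        }
    )


def _enforce_low_tail(
    ln_lf: np.ndarray, event: np.ndarray, effect_size: float, step: float
) -> np.ndarray:
    """Push event values down until all sit below mean − effect·SD under both
    the all-subject and the non-event-only empirical reference statistics."""
    values = ln_lf.copy()
    for _ in range(100):
        thr_all = values.mean() - effect_size * values.std(ddof=1)
        ne = values[~event]
        thr_ne = ne.mean() - effect_size * ne.std(ddof=1)
        thr = min(thr_all, thr_ne)
        violators = event & (values >= thr)
        if not violators.any():
            return values
        values[violators] -= 0.25 * step
    raise RuntimeError("could not place all events in the low tail")


# ---------------------------------------------------------------------------
# literature corpus


_HIGH_RENDER = ("Higher", "Increased", "Elevated", "higher")
_LOW_RENDER = ("Lower", "Decreased", "Reduced", "lower")
_OUTCOME_RENDER = (
    "cardiovascular event",
    "cerebrovascular event",
    "stroke",
    "all-cause mortality",
    "major vascular event",
)


@dataclass
class CorpusBundle:
    """Generated corpus: (paper_id, table text) pairs plus ground truth."""

    papers: list[tuple[str, str]]
    manifest: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for paper_id, text in self.papers:
            (directory / f"{paper_id}.txt").write_text(text)
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _render_table(rows: dict[str, list[tuple[str, str]]], rng: np.random.Generator) -> str:
    """Render one paper's extraction table in the pipe-delimited dialect."""
    lines = ["HRV Indicators | High/Low | Related Diseases/Symptoms"]
    for param in PARAMETERS:
        entries = rows.get(param, [])
        if not entries:
            lines.append(f"{param} | N/A | N/A")
        else:
            for direction_word, outcome in entries:
                lines.append(f"{param} | {direction_word} | {outcome}")
    return "\n".join(lines) + "\n"


def gen_literature_corpus(
    n_papers: int,
    relevant_fraction: float,
    count_targets: dict[str, tuple[int, int]],
    seed: int = 0,
) -> CorpusBundle:
    """Corpus of extraction-table texts whose aggregate equals count_targets.

    ``count_targets`` maps parameter -> (positive, negative) counts.  Exactly
    ``round(n_papers * relevant_fraction)`` papers are relevant; the remainder
    are all-N/A (irrelevant).  Each (parameter, direction) tally is assigned
    to a distinct relevant paper (least-loaded first), so a paper may report
    both directions of one parameter but never duplicates one.  Raises when
    the targets cannot be met: any single count exceeding the number of
    relevant papers, or fewer tallies than relevant papers (some relevant
    paper would be empty, i.e. irrelevant).
    """
    if not 0 <= relevant_fraction <= 1:
        raise ValueError("relevant_fraction must be in [0, 1]")
    unknown = set(count_targets) - set(PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameters in count_targets: {sorted(unknown)}")
    n_relevant = int(round(n_papers * relevant_fraction))
    total_units = sum(p + n for p, n in count_targets.values())
    if n_relevant > 0 and total_units == 0:
        raise ValueError("relevant papers requested but count_targets is all zero")
    if n_relevant == 0 and total_units > 0:
        raise ValueError("count_targets non-zero but no relevant papers")
    for param, (pos, neg) in count_targets.items():
        if pos < 0 or neg < 0:
            raise ValueError("count targets must be non-negative")
        if max(pos, neg) > n_relevant:
            raise ValueError(
                f"{param}: a directional count ({max(pos, neg)}) exceeds the "
                f"{n_relevant} relevant papers (one tally per paper per direction)"
            )
    if 0 < total_units < n_relevant:
        raise ValueError(
            f"only {total_units} tallies for {n_relevant} relevant papers; "
            "some relevant paper would have an empty table"
        )

    rng = np.random.default_rng(seed)
    # paper_rows[i]: parameter -> list of (direction_word, outcome) entries
    paper_rows: list[dict[str, list[tuple[str, str]]]] = [
        {} for _ in range(n_relevant)
    ]
    load = np.zeros(n_relevant, dtype=int)
    taken: list[set[tuple[str, str]]] = [set() for _ in range(n_relevant)]
    classes = []
    for param in PARAMETERS:
        pos, neg = count_targets.get(param, (0, 0))
        if pos:
            classes.append((param, "pos", pos))
        if neg:
            classes.append((param, "neg", neg))
    # distribute largest classes first so per-class distinctness stays feasible
    classes.sort(key=lambda c: -c[2])
    for param, dir_, count in classes:
        eligible = [i for i in range(n_relevant) if (param, dir_) not in taken[i]]
        eligible.sort(key=lambda i: (load[i], rng.random()))
        chosen = eligible[:count]
        for i in chosen:
            word_pool = _HIGH_RENDER if dir_ == "pos" else _LOW_RENDER
            word = word_pool[int(rng.integers(len(word_pool)))]
            outcome = _OUTCOME_RENDER[int(rng.integers(len(_OUTCOME_RENDER)))]
            paper_rows[i].setdefault(param, []).append((word, outcome))
            taken[i].add((param, dir_))
            load[i] += 1

    papers: list[tuple[str, str]] = []
    relevant_flags: dict[str, bool] = {}
    order = rng.permutation(n_papers)
    rel_iter = iter(range(n_relevant))
    for k, slot in enumerate(order):
        paper_id = f"paper_{k:04d}"
        if slot < n_relevant:
            text = _render_table(paper_rows[next(rel_iter)], rng)
            relevant_flags[paper_id] = True
        else:
            text = _render_table({}, rng)
            relevant_flags[paper_id] = False
        papers.append((paper_id, text))

    manifest = {
        "count_targets": {k: list(v) for k, v in count_targets.items()},
        "n_papers": n_papers,
        "n_relevant": n_relevant,
        "relevant": relevant_flags,
        "seed": seed,
    }
    return CorpusBundle(papers=papers, manifest=manifest)
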