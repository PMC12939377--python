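"""Least-to-most feature prioritization over the literature evidence database.

The selection of the single stratification parameter proceeds in three
deterministic phases, mirroring a structured literature-review progression:

1. **Consistency** — for each parameter with any evidence, the fraction of
   its directional reports that agree with its majority direction,
   ``max(pos, neg) / (pos + neg)``; parameters with no evidence are excluded.
2. **Candidate retention** — parameters whose consistency meets a threshold
   (default 2/3) are retained.
3. **Document count** — among retained candidates, the parameter backed by
   the largest total number of reports wins; its majority direction becomes
   the risk direction used by the classifier.

Ties in phase 3 are broken by higher consistency, then by codebook order;
every decision is recorded in the selection trace.  Prompt templates for an
optional LLM-in-the-loop replication of the three phases are also rendered,
but the deterministic rules are the package's selection mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .literature import MLRD, Codebook

DEFAULT_CONSISTENCY_THRESHOLD = 2.0 / 3.0


@dataclass
class SelectionResult:
    """Outcome of the three-phase prioritization with a full decision trace."""

    consistency: dict[str, float]  # only parameters with evidence
    retained: list[str]
    selected: str
    dominant_direction: str  # "positive" | "negative"
    trace: list[str] = field(default_factory=list)


def consistency_ratio(pos_count: int, neg_count: int) -> float | None:
    """Majority-direction fraction of reports; None when there is no evidence."""
    if pos_count < 0 or neg_count < 0:
        raise ValueError("counts must be non-negative")
    total = pos_count + neg_count
    if total == 0:
        return None
    return max(pos_count, neg_count) / total


def _ordered_keys(mlrd: MLRD, codebook: Codebook) -> list[str]:
    return sorted(mlrd.counts, key=codebook.code_order)


def retain_candidates(
    mlrd: MLRD,
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
    codebook: Codebook | None = None,
) -> list[str]:
    """Keys (parameters or codes) with defined consistency >= threshold.

    Returned in codebook order.  Parameters without evidence are excluded
    before the threshold is applied.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if codebook is None:
        codebook = Codebook()
    retained = []
    for key in _ordered_keys(mlrd, codebook):
        ratio = consistency_ratio(*mlrd.counts[key])
        if ratio is not None and ratio >= threshold:
            retained.append(key)
    return retained


def select_parameter(
    mlrd: MLRD,
    retained: list[str],
    codebook: Codebook | None = None,
) -> SelectionResult:
    """Phase-3 selection: highest total report count among retained candidates."""
    if not retained:
        raise ValueError("no candidates retained; cannot select a parameter")
    if codebook is None:
        codebook = Codebook()

    consistency = {
        k: r
        for k in mlrd.counts
        if (r := consistency_ratio(*mlrd.counts[k])) is not None
    }
    trace = [
        "phase1: consistency "
        + ", ".join(
            f"{k}={consistency[k]:.3f}" if k in consistency else f"{k}=excluded(no evidence)"
            for k in _ordered_keys(mlrd, codebook)
        ),
        f"phase2: retained {retained}",
    ]

    def sort_key(k: str) -> tuple[float, float, str]:
        pos, neg = mlrd.counts[k]
        # maximise total, then consistency; codebook order breaks exact ties
        return (-(pos + neg), -consistency[k], codebook.code_order(k))

    ranked = sorted(retained, key=sort_key)
    selected = ranked[0]
    totals = {k: sum(mlrd.counts[k]) for k in retained}
    trace.append(f"phase3: totals {totals}; ranked {ranked}")
    if len(ranked) > 1:
        runner = ranked[1]
        if totals[runner] == totals[selected]:
            if consistency[runner] == consistency[selected]:
                trace.append(
                    f"phase3: tie between {selected} and {runner} on total and "
                    f"consistency; codebook order selects {selected}"
                )
            else:
                trace.append(
                    f"phase3: tie between {selected} and {runner} on total; "
                    f"higher consistency selects {selected}"
                )
    pos, neg = mlrd.counts[selected]
    dominant = "positive" if pos > neg else "negative"
    if pos == neg:
        dominant = "negative"
        trace.append(
            f"phase3: {selected} has equal positive/negative counts; "
            "defaulting dominant direction to negative"
        )
    trace.append(f"selected {selected}, dominant direction {dominant}")
    return SelectionResult(
        consistency=consistency,
        retained=list(retained),
        selected=selected,
        dominant_direction=dominant,
        trace=trace,
    )


def prioritize(
    mlrd: MLRD,
    threshold: float = DEFAULT_CONSISTENCY_THRESHOLD,
    codebook: Codebook | None = None,
) -> SelectionResult:
    """Run all three phases on an MLRD (raw or anonymized keys)."""
    retained = retain_candidates(mlrd, threshold, codebook)
    return select_parameter(mlrd, retained, codebook)


PROMPT_PHASE1 = (
    "The following various parameters are substituted using the symbols: "
    "A B C D E F G. Please consider the consistency of the correlation and "
    "calculate the correlation between each parameter and the incidence rate.\n"
)
PROMPT_PHASE2 = (
    "What are the parameters to be left for further investigation in terms "
    "of the strength or weakness of the correlation?\n"
)
PROMPT_PHASE3 = (
    "Now that the number of documents is to be taken into account, choose "
    "the most relevant parameter from among these parameters, which one "
    "should be chosen?\n"
)


def render_prioritization_prompts(
    coded_mlrd: MLRD, n_repeats: int = 5
) -> list[str]:
    """Render the three phase prompts with the coded counts table appended.

    ``n_repeats`` documents how many identical prompting repetitions a
    replication should run when checking output stability (default 5).
    """
    if not coded_mlrd.counts or coded_mlrd.total() == 0:
        raise ValueError("cannot render prompts for an empty evidence database")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    table_lines = ["code | positive | negative"]
    for key in sorted(coded_mlrd.counts):
        pos, neg = coded_mlrd.counts[key]
        table_lines.append(f"{key} | {pos} | {neg}")
    table = "\n".join(table_lines)
    note = f"\n\n{table}\n\n(repeat this prompt sequence {n_repeats} times)\n"
    return [PROMPT_PHASE1 + note, PROMPT_PHASE2 + note, PROMPT_PHASE3 + note]
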