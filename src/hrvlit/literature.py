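"""Structured literature evidence: extraction tables and the directional-count database.

Abstracts of HRV studies are reduced, one table per paper, to rows of
``parameter | High/Low | related outcome``.  Relevant tables (at least one
informative row) are tallied into the medical literature review database
(MLRD): for each HRV parameter, the number of papers reporting the value
*higher* in subjects with a vascular event (a positive association) and the
number reporting it *lower* (a negative association).  The MLRD is the sole
input to downstream feature prioritization, so its construction must be
deterministic and order-independent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

logger = logging.getLogger("hrvlit.literature")

#: Closed set of HRV parameters tracked in extraction tables.
PARAMETERS: tuple[str, ...] = ("HF", "LF/HF", "VLF", "LF", "TP", "SDNN", "rMSSD")

#: Default single-letter anonymization codes, in codebook order.
DEFAULT_CODEBOOK_MAP: dict[str, str] = {
    "HF": "A",
    "LF/HF": "B",
    "VLF": "C",
    "LF": "D",
    "TP": "E",
    "SDNN": "F",
    "rMSSD": "G",
}

#: Default vascular-event outcome lexicon (case-insensitive substring match).
#: The study filtered papers by a vascular-event literature query; this term
#: list is the package's explicit, configurable stand-in for that filter.
DEFAULT_LEXICON: tuple[str, ...] = (
    "cardiovascular",
    "cerebrovascular",
    "stroke",
    "vascular event",
    "mortality",
    "myocardial infarction",
    "cardiac event",
)

# Direction vocabulary: extraction output phrasing varies, so a small synonym
# set is normalised to the two canonical directions.
_HIGH_WORDS = frozenset({"higher", "high", "increased", "elevated", "increase"})
_LOW_WORDS = frozenset({"lower", "low", "decreased", "reduced", "decrease"})

# Parameter-name normalisation (aliases seen in free-text tables).
_PARAM_ALIASES: dict[str, str] = {
    "HF": "HF",
    "HIGH FREQUENCY": "HF",
    "LF": "LF",
    "LOW FREQUENCY": "LF",
    "LF/HF": "LF/HF",
    "LF/HF RATIO": "LF/HF",
    "L/H": "LF/HF",
    "LF-HF": "LF/HF",
    "VLF": "VLF",
    "VERY LOW FREQUENCY": "VLF",
    "TP": "TP",
    "TOTAL POWER": "TP",
    "SDNN": "SDNN",
    "RMSSD": "rMSSD",
}

PROMPT_TEMPLATE = (
    "According to the article, please list LF, HF, LF/HF ratio, TP, VLF, "
    "SDNN, RMSSD which diseases/symptoms are related to each other? "
    "Does the value become higher or lower? If the item is not mentioned "
    "in the article, please write: N/A.\n"
    "\n"
    "Please present in a 3*8 table.\n"
    "\n"
    "notice:HF mean High frequency. NOT heart failure.\n"
    "\n"
    "Form header: HRV Indicators | High/Low | Related Diseases/Symptoms\n"
)


class Direction(str, Enum):
    HIGH = "high"
    LOW = "low"
    NA = "na"


class Association(str, Enum):
    """Directional association of a parameter with the outcome."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_COUNTED = "not_counted"


class TableParseError(ValueError):
    """Raised when a raw text blob contains no parseable extraction table."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One extraction-table row: a parameter, its direction in cases, the outcome."""

    paper_id: str
    parameter: str
    direction: Direction
    outcome_text: str

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {self.parameter!r}")


@dataclass
class ExtractionTable:
    """All evidence rows extracted from one paper.

    At most one row per (parameter, direction) pair: a paper contributes at
    most one tally to each of the positive and negative columns per parameter.
    """

    paper_id: str
    rows: list[EvidenceRecord] = field(default_factory=list)

    def informative_rows(self) -> list[EvidenceRecord]:
        return [
            r for r in self.rows
            if r.direction is not Direction.NA and r.outcome_text.strip()
        ]


@dataclass
class Codebook:
    """Bijective parameter <-> single-letter code mapping."""

    mapping: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CODEBOOK_MAP)
    )

    def __post_init__(self) -> None:
        codes = list(self.mapping.values())
        if len(set(codes)) != len(codes):
            raise ValueError("codebook codes are not unique")

    def encode(self, parameter: str) -> str:
        try:
            return self.mapping[parameter]
        except KeyError:
            raise KeyError(f"codebook has no code for parameter {parameter!r}")

    def decode(self, code: str) -> str:
        for param, c in self.mapping.items():
            if c == code:
                return param
        raise KeyError(f"codebook has no parameter for code {code!r}")

    def code_order(self, key: str) -> str:
        """Sort key: the code of *key* whether it is a parameter or a code."""
        if key in self.mapping:
            return self.mapping[key]
        if key in self.mapping.values():
            return key
        raise KeyError(f"{key!r} is neither a parameter nor a code")


@dataclass
class MLRD:
    """Medical literature review database: per-parameter directional counts.

    ``counts`` maps a key (parameter name, or code after :func:`encode_mlrd`)
    to ``(pos_count, neg_count)``; ``provenance`` maps the same key to the
    sorted list of contributing paper ids, one entry per counted record, so
    ``pos + neg == len(provenance[key])`` always holds.
    """

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def total(self) -> int:
        """Grand total of directional records over all parameters."""
        return sum(p + n for p, n in self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": {k: list(v) for k, v in self.counts.items()},
            "provenance": {k: list(v) for k, v in self.provenance.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLRD":
        return cls(
            counts={k: (int(v[0]), int(v[1])) for k, v in d["counts"].items()},
            provenance={k: list(v) for k, v in d.get("provenance", {}).items()},
        )


def normalize_parameter(raw: str) -> str | None:
    """Map a raw first-column cell to a canonical parameter, or None."""
    key = re.sub(r"\s+", " ", raw.strip()).upper()
    key = key.rstrip(":").strip()
    return _PARAM_ALIASES.get(key)


def normalize_direction(raw: str) -> Direction | None:
    """Map a raw High/Low cell to a Direction; None if unrecognised."""
    key = raw.strip().lower()
    if not key or key in {"n/a", "na", "none", "-"}:
        return Direction.NA
    if key in _HIGH_WORDS:
        return Direction.HIGH
    if key in _LOW_WORDS:
        return Direction.LOW
    return None


def render_extraction_prompt(abstract_text: str) -> str:
    """Return the fixed extraction-prompt template with the abstract appended."""
    if not abstract_text or not abstract_text.strip():
        raise ValueError("abstract text is empty")
    return PROMPT_TEMPLATE + "\n" + abstract_text.strip() + "\n"


def _is_separator_row(cells: list[str]) -> bool:
    return all(re.fullmatch(r":?-{2,}:?", c.strip()) for c in cells if c.strip())


def _is_header_row(cells: list[str]) -> bool:
    first = cells[0].strip().lower()
    return "hrv" in first or first in {"parameter", "indicator", "indicators"}


def parse_extraction_table(raw_text: str, paper_id: str) -> ExtractionTable:
    """Parse a pipe-delimited 3-column extraction table from raw text.

    Accepts tables with or without a markdown separator row and with optional
    leading/trailing pipes.  Cells equal to ``N/A`` (any case) mark a row as
    uninformative.  First-column names outside the parameter set are skipped
    with a logged warning.  Duplicate (parameter, direction) rows are an
    error; a paper may legitimately report both directions for one parameter.
    """
    rows: list[EvidenceRecord] = []
    seen: set[tuple[str, Direction]] = set()
    saw_table_line = False
    for line in raw_text.splitlines():
        if "|" not in line:
            continue
        stripped = line.strip()
        if stripped.startswith("|"):
            stripped = stripped[1:]
        if stripped.endswith("|"):
            stripped = stripped[:-1]
        cells = [c.strip() for c in stripped.split("|")]
        if not any(cells):
            continue
        if _is_separator_row(cells):
            continue
        if _is_header_row(cells):
            saw_table_line = True
            continue
        if len(cells) < 2:
            continue
        saw_table_line = True
        param = normalize_parameter(cells[0])
        if param is None:
            logger.warning(
                "paper %s: unknown parameter %r ignored", paper_id, cells[0]
            )
            continue
        direction = normalize_direction(cells[1])
        if direction is None:
            logger.warning(
                "paper %s: unrecognised direction %r for %s treated as N/A",
                paper_id, cells[1], param,
            )
            direction = Direction.NA
        outcome = cells[2] if len(cells) > 2 else ""
        if outcome.strip().lower() in {"n/a", "na"}:
            outcome = ""
        key = (param, direction)
        if key in seen and direction is not Direction.NA:
            raise TableParseError(
                f"paper {paper_id}: duplicate row for {param} / {direction.value}"
            )
        seen.add(key)
        rows.append(EvidenceRecord(paper_id, param, direction, outcome))
    if not saw_table_line:
        raise TableParseError(f"paper {paper_id}: no parseable table found")
    return ExtractionTable(paper_id=paper_id, rows=rows)


def is_relevant(table: ExtractionTable) -> bool:
    """A paper is relevant iff its table has at least one informative row.

    Empty (all-N/A) tables indicate the abstract did not discuss HRV
    parameters in relation to any outcome; such papers are excluded.
    """
    return len(table.informative_rows()) > 0


def classify_direction(
    record: EvidenceRecord,
    lexicon: tuple[str, ...] | list[str] | None = None,
) -> Association:
    """Classify one record as a positive/negative association or not counted.

    The outcome text must match the vascular-event lexicon (case-insensitive
    substring).  A matched outcome with the parameter *higher* in cases is a
    positive association; *lower* is a negative association.
    """
    if lexicon is None:
        lexicon = DEFAULT_LEXICON
    if record.direction is Direction.NA or not record.outcome_text.strip():
        return Association.NOT_COUNTED
    text = record.outcome_text.lower()
    if not any(term.lower() in text for term in lexicon):
        return Association.NOT_COUNTED
    if record.direction is Direction.HIGH:
        return Association.POSITIVE
    return Association.NEGATIVE


def aggregate_mlrd(
    tables: list[ExtractionTable],
    lexicon: tuple[str, ...] | list[str] | None = None,
) -> MLRD:
    """Aggregate relevant extraction tables into the MLRD.

    Irrelevant tables are skipped.  Each relevant table contributes at most
    one tally per (parameter, direction).  Counts and provenance are
    independent of table order.
    """
    pos: dict[str, int] = {p: 0 for p in PARAMETERS}
    neg: dict[str, int] = {p: 0 for p in PARAMETERS}
    prov: dict[str, list[str]] = {p: [] for p in PARAMETERS}
    n_skipped = 0
    for table in tables:
        if not is_relevant(table):
            n_skipped += 1
            continue
        contributions: set[tuple[str, Association]] = set()
        for record in table.rows:
            assoc = classify_direction(record, lexicon)
            if assoc is Association.NOT_COUNTED:
                continue
            contributions.add((record.parameter, assoc))
        for param, assoc in contributions:
            if assoc is Association.POSITIVE:
                pos[param] += 1
            else:
                neg[param] += 1
            prov[param].append(table.paper_id)
    if n_skipped:
        logger.info("aggregate_mlrd: %d irrelevant tables excluded", n_skipped)
    return MLRD(
        counts={p: (pos[p], neg[p]) for p in PARAMETERS},
        provenance={p: sorted(prov[p]) for p in PARAMETERS},
    )


def encode_mlrd(mlrd: MLRD, codebook: Codebook | None = None) -> MLRD:
    """Re-key an MLRD by anonymization codes; counts are unchanged."""
    if codebook is None:
        codebook = Codebook()
    missing = [k for k in mlrd.counts if k not in codebook.mapping]
    if missing:
        raise KeyError(f"codebook missing parameters: {missing}")
    return MLRD(
        counts={codebook.encode(k): v for k, v in mlrd.counts.items()},
        provenance={codebook.encode(k): list(v) for k, v in mlrd.provenance.items()},
    )


def decode_mlrd(mlrd: MLRD, codebook: Codebook | None = None) -> MLRD:
    """Inverse of :func:`encode_mlrd`."""
    if codebook is None:
        codebook = Codebook()
    return MLRD(
        counts={codebook.decode(k): v for k, v in mlrd.counts.items()},
        provenance={codebook.decode(k): list(v) for k, v in mlrd.provenance.items()},
    )
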