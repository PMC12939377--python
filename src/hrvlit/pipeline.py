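"""Configuration and the end-to-end pipeline.

``run_pipeline`` chains the stages: parse and filter a corpus of extraction
tables, aggregate the evidence database, prioritize the stratification
parameter, obtain per-subject HRV features (from a cohort CSV carrying the
feature, or computed from per-subject RR CSVs), stratify, and evaluate.
Every stage logs its input/output counts; the report embeds the full config
and input digests so each number is traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .evaluation import (
    UndefinedAUCError,
    confusion,
    evaluate_by_group,
    metrics,
    metrics_rounded,
    roc_curve,
)
from .literature import (
    DEFAULT_LEXICON,
    Codebook,
    TableParseError,
    aggregate_mlrd,
    encode_mlrd,
    is_relevant,
    parse_extraction_table,
)
from .prioritization import DEFAULT_CONSISTENCY_THRESHOLD, prioritize
from .signals import subject_features
from .stratification import classify_cohort

logger = logging.getLogger("hrvlit.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    corpus_dir: str | None = None
    cohort_csv: str | None = None
    rr_dir: str | None = None
    output_dir: str = "hrvlit_out"
    lexicon: tuple[str, ...] = DEFAULT_LEXICON
    consistency_threshold: float = DEFAULT_CONSISTENCY_THRESHOLD
    feature: str | None = None  # None: derived from the selected parameter
    k: float = 1.0
    reference_mode: str = "non_event_only"
    group_field: str | None = None
    window_s: float = 300.0
    day_start: str = "08:00"
    day_end: str = "16:00"
    max_invalid_fraction: float = 0.05
    fs_resample: float = 4.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lexicon" in raw:
            raw["lexicon"] = tuple(raw["lexicon"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lexicon"] = list(self.lexicon)
        return d


#: Feature column used for each selected parameter (log-domain for LF/HF
#: per the near-Gaussian distribution after the ln transform).
PARAMETER_FEATURE_COLUMN = {
    "LF": "ln_lf",
    "HF": "ln_hf",
    "LF/HF": "lf_hf",
    "VLF": "vlf",
    "TP": "tp",
    "SDNN": "sdnn",
    "rMSSD": "rmssd",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_corpus_tables(corpus_dir: str | Path, strict: bool = False):
    """Parse every ``*.txt`` in a corpus directory into extraction tables."""
    corpus_dir = Path(corpus_dir)
    tables = []
    n_failed = 0
    for path in sorted(corpus_dir.glob("*.txt")):
        try:
            tables.append(parse_extraction_table(path.read_text(), path.stem))
        except TableParseError as exc:
            n_failed += 1
            if strict:
                raise
            logger.warning("corpus: %s", exc)
    logger.info("corpus: parsed %d tables (%d failed)", len(tables), n_failed)
    return tables


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute extract -> aggregate -> prioritize -> features -> stratify ->
    evaluate and write all artifacts under ``config.output_dir``.

    Returns the report dictionary.  Raises :class:`PipelineError` naming the
    failing stage; partial outputs written before the failure are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "stages": {}, "inputs": {}}

    # -- extract + aggregate ------------------------------------------------
    if not config.corpus_dir:
        raise PipelineError("extract: no corpus directory configured")
    corpus_dir = Path(config.corpus_dir)
    if not corpus_dir.is_dir():
        raise PipelineError(f"extract: corpus directory {corpus_dir} not found")
    tables = load_corpus_tables(corpus_dir)
    if not tables:
        raise PipelineError("aggregate: corpus is empty, nothing to aggregate")
    relevant = [t for t in tables if is_relevant(t)]
    report["stages"]["extract"] = {
        "n_papers": len(tables),
        "n_relevant": len(relevant),
        "n_irrelevant": len(tables) - len(relevant),
    }
    mlrd = aggregate_mlrd(tables, config.lexicon)
    if mlrd.total() == 0:
        raise PipelineError("aggregate: no directional evidence in corpus")
    hio.write_mlrd_json(mlrd, out / "mlrd.json")
    report["stages"]["aggregate"] = {"total_records": mlrd.total()}

    # -- prioritize ---------------------------------------------------------
    codebook = Codebook()
    coded = encode_mlrd(mlrd, codebook)
    try:
        selection = prioritize(coded, config.consistency_threshold, codebook)
    except ValueError as exc:
        raise PipelineError(f"prioritize: {exc}") from exc
    selected_parameter = codebook.decode(selection.selected)
    hio.write_json(
        {
            "selected_code": selection.selected,
            "selected_parameter": selected_parameter,
            "dominant_direction": selection.dominant_direction,
            "retained": selection.retained,
            "consistency": selection.consistency,
            "trace": selection.trace,
        },
        out / "selection.json",
    )
    report["stages"]["prioritize"] = {
        "retained": selection.retained,
        "selected": selected_parameter,
        "dominant_direction": selection.dominant_direction,
    }

    # -- cohort features ----------------------------------------------------
    if not config.cohort_csv:
        raise PipelineError("features: no cohort CSV configured")
    cohort_path = Path(config.cohort_csv)
    if not cohort_path.is_file():
        raise PipelineError(f"features: cohort file {cohort_path} not found")
    cohort = hio.read_cohort_csv(cohort_path)
    report["inputs"]["cohort_csv"] = _sha256(cohort_path)

    feature = config.feature or PARAMETER_FEATURE_COLUMN[selected_parameter]
    if config.rr_dir:
        cohort = _attach_rr_features(cohort, config, out)
    if feature not in cohort.columns:
        raise PipelineError(
            f"features: cohort lacks column {feature!r} and no rr_dir given"
        )
    report["stages"]["features"] = {
        "feature": feature,
        "n_subjects": int(len(cohort)),
        "n_missing": int((~np.isfinite(cohort[feature].to_numpy(float))).sum()),
    }

    # -- stratify -----------------------------------------------------------
    try:
        predictions = classify_cohort(
            cohort, feature, selection.dominant_direction,
            config.reference_mode, config.k,
        )
    except ValueError as exc:
        raise PipelineError(f"stratify: {exc}") from exc
    predictions.to_csv(out / "predictions.csv", index=False)
    report["stages"]["stratify"] = {
        "n_predicted_positive": int(predictions["prediction"].sum()),
        "strata": predictions["stratum"].value_counts().to_dict(),
    }

    # -- evaluate -----------------------------------------------------------
    cm = confusion(predictions["prediction"], predictions["event"])
    evaluation = {
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "metrics": metrics(cm),
        "metrics_rounded": metrics_rounded(cm),
    }
    merged = predictions.merge(cohort[["subject_id", feature]], on="subject_id")
    try:
        roc = roc_curve(
            merged[feature].to_numpy(float),
            merged["event"].to_numpy(bool),
            selection.dominant_direction,
        )
        evaluation["auc"] = roc.auc
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            out / "roc.csv", index=False
        )
    except UndefinedAUCError as exc:
        evaluation["auc"] = None
        logger.warning("evaluate: %s", exc)
    if config.group_field:
        grouped = evaluate_by_group(cohort, predictions, config.group_field)
        evaluation["by_group"] = grouped.to_dict(orient="records")
    report["stages"]["evaluate"] = evaluation

    hio.write_json(report, out / "report.json")
    _write_text_report(report, out / "report.txt")
    return report


def _attach_rr_features(
    cohort: pd.DataFrame, config: PipelineConfig, out: Path
) -> pd.DataFrame:
    """Compute HRV features from per-subject RR CSVs (<subject_id>.csv)."""
    rr_dir = Path(config.rr_dir)
    feats = {}
    for sid in cohort["subject_id"]:
        path = rr_dir / f"{sid}.csv"
        if not path.is_file():
            logger.warning("features: no RR file for subject %s", sid)
            continue
        rr = hio.read_rr_csv(path)
        feats[sid], _ = subject_features(
            rr,
            window_s=config.window_s,
            day_start=config.day_start,
            day_end=config.day_end,
            max_invalid_fraction=config.max_invalid_fraction,
            fs_resample=config.fs_resample,
        )
    hio.write_features_csv(feats, out / "features.csv")
    feat_df = hio.read_features_csv(out / "features.csv")
    drop = [c for c in feat_df.columns if c != "subject_id" and c in cohort.columns]
    return cohort.drop(columns=drop).merge(feat_df, on="subject_id", how="left")


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["literature-guided HRV risk stratification — run report", ""]
    st = report["stages"]
    ex = st.get("extract", {})
    lines.append(
        f"corpus: {ex.get('n_papers', 0)} papers, "
        f"{ex.get('n_relevant', 0)} relevant, "
        f"{ex.get('n_irrelevant', 0)} excluded as irrelevant"
    )
    lines.append(f"evidence records aggregated: {st['aggregate']['total_records']}")
    pr = st["prioritize"]
    lines.append(
        f"prioritization: retained {pr['retained']}, selected {pr['selected']} "
        f"({pr['dominant_direction']} association with events)"
    )
    fe = st["features"]
    lines.append(
        f"cohort: {fe['n_subjects']} subjects, feature {fe['feature']} "
        f"({fe['n_missing']} missing)"
    )
    ev = st["evaluate"]
    cmx = ev["confusion"]
    lines.append(
        f"confusion: TP={cmx['tp']} FP={cmx['fp']} FN={cmx['fn']} TN={cmx['tn']}"
    )
    m = ev["metrics_rounded"]
    lines.append(
        f"accuracy {m['accuracy']}%  sensitivity {m['sensitivity']}%  "
        f"specificity {m['specificity']}%"
    )
    if ev.get("auc") is not None:
        lines.append(f"ROC AUC {ev['auc']:.3f}")
    path.write_text("\n".join(lines) + "\n")
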