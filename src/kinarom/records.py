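"""Participant/cohort records, persistence and the end-to-end pipeline.

A participant record carries demographics (chronological and mental age,
MACS/GMFCS levels for the hemiparesis group), optional per-limb skeleton
streams or a pre-computed FMA total, and — after the pipeline runs —
AROM results, the assembled sheet, the total and the capacity category.

``run_pipeline`` ties the chain together: skeleton streams -> angle
series -> AROM -> automated A-II scores -> sheet assembly -> total ->
capacity class, then cohort-level group comparisons and classification
shares. Records that lack inputs produce per-record failure entries; the
run continues. Persistence is plain CSV/JSON throughout.

The characteristics table of the validation cohort (18 control + 18
study children) ships as a packaged fixture; ``load_reference_cohort``
returns it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .angles import angle_series
from .arom import AromResult, extract_arom, summarize_rounded
from .errors import EmptyStreamError, KinaromError, SchemaError
from .fma import (
    DEFAULT_A2_THRESHOLDS,
    HYBRID_BANDS,
    A2Thresholds,
    CapacityBands,
    FmaItem,
    FmaSheet,
    assemble_sheet,
    classify,
    score_a2_item,
)
from .skeleton import SkeletonStream, read_skeleton_stream
from .stats import ComparisonRow, cohort_classification_shares, compare_groups

_LEVELS = ("I", "II", "III", "IV", "V")
_GROUPS = ("control", "study")

#: Streams expected per record for full automated scoring. Elbow
#: extension reuses the flexion trial's stream: the extension item is
#: scored from the same recording's extension-side excursion.
PIPELINE_MOVEMENTS = ("shoulder_abduction", "elbow_flexion")


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str
    chronological_age: float
    mental_age: float | None = None
    macs: str | None = None
    gmfcs: str | None = None
    fma_total: int | None = None
    stream_paths: dict = field(default_factory=dict)   # (movement, side) -> path
    streams: dict = field(default_factory=dict)        # (movement, side) -> SkeletonStream
    manual_items: list[FmaItem] | None = None
    truth: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.group not in _GROUPS:
            raise SchemaError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.chronological_age <= 0:
            raise SchemaError(f"chronological_age must be > 0, got {self.chronological_age}")
        for name in ("macs", "gmfcs"):
            level = getattr(self, name)
            if level is not None and level not in _LEVELS:
                raise SchemaError(f"invalid {name.upper()} level {level!r}; expected I-V")
            if level in ("III", "IV", "V"):
                self.warnings.append(
                    f"{name.upper()} {level} outside inclusion criteria (Level I-II)")
        if self.fma_total is not None and not (0 <= self.fma_total <= 66):
            raise SchemaError(f"fma_total {self.fma_total} outside [0, 66]")


@dataclass
class CohortTable:
    records: list[ParticipantRecord]
    label: str = "cohort"

    def __post_init__(self):
        ids = [r.participant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate participant id(s): {dupes}")

    def group(self, name: str) -> list[ParticipantRecord]:
        return [r for r in self.records if r.group == name]

    def __len__(self) -> int:
        return len(self.records)


_COHORT_COLUMNS = ["id", "group", "chronological_age", "mental_age", "macs", "gmfcs"]


def read_cohort(path: str | Path, label: str | None = None) -> CohortTable:
    """Read a cohort CSV.

    Required columns: id, group, chronological_age, mental_age, macs,
    gmfcs; optional: fma_total plus ``<movement>_<side>_stream`` path
    columns. A '-' or empty mental age means not assessed; MACS/GMFCS
    levels outside I-II are accepted with an eligibility warning on the
    record (the inclusion criteria require Level I-II).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"id": str, "macs": str, "gmfcs": str})
    missing = [c for c in _COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    def opt(value):
        if pd.isna(value) or str(value).strip() in ("", "-"):
            return None
        return value

    stream_cols = [c for c in table.columns if c.endswith("_stream")]
    records = []
    for row in table.itertuples():
        d = row._asdict()
        mental = opt(d["mental_age"])
        fma = opt(d.get("fma_total"))
        stream_paths = {}
        for col in stream_cols:
            p = opt(d[col])
            if p is not None:
                movement, side = col[:-len("_stream")].rsplit("_", 1)
                stream_paths[(movement, side)] = str(p)
        records.append(ParticipantRecord(
            participant_id=str(d["id"]), group=str(d["group"]),
            chronological_age=float(d["chronological_age"]),
            mental_age=None if mental is None else float(mental),
            macs=opt(d["macs"]), gmfcs=opt(d["gmfcs"]),
            fma_total=None if fma is None else int(fma),
            stream_paths=stream_paths))
    return CohortTable(records, label=label or path.stem)


def load_reference_cohort() -> CohortTable:
    """The packaged validation-cohort characteristics table (18 + 18 children)."""
    with resources.as_file(
            resources.files("kinarom.data") / "reference_cohort.csv") as p:
        return read_cohort(p, label="reference")


# --------------------------------------------------------------------------
# Pipeline

@dataclass
class PipelineConfig:
    thresholds: A2Thresholds = field(default_factory=lambda: DEFAULT_A2_THRESHOLDS)
    bands: CapacityBands = HYBRID_BANDS
    smoothing_window: int = 5
    sides: tuple[str, ...] = ("right", "left")
    #: which per-session statistic feeds the group comparisons
    compare_on: str = "mean"     # "mean" | "arom"


@dataclass
class ParticipantResult:
    participant_id: str
    group: str
    arom: dict = field(default_factory=dict)       # (movement, side) -> AromResult
    sheet: FmaSheet | None = None
    fma_total: int | None = None
    category: str | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class PipelineReport:
    results: list[ParticipantResult]
    comparisons: list[ComparisonRow]
    shares: dict[str, dict[str, tuple[int, int]]]   # group -> category -> (count, pct)
    failures: list[tuple[str, str]]                 # (participant_id, reason)

    def to_json(self, path: str | Path) -> None:
        def encode(result: ParticipantResult) -> dict:
            return {
                "participant_id": result.participant_id,
                "group": result.group,
                "arom": {f"{m}/{s}": summarize_rounded(a)
                         for (m, s), a in result.arom.items()},
                "fma_total": result.fma_total,
                "category": result.category,
                "warnings": result.warnings,
            }
        payload = {
            "results": [encode(r) for r in self.results],
            "comparisons": [
                {"label": c.label,
                 "a": asdict(c.a), "b": asdict(c.b),
                 "u": c.test.u_statistic, "p": c.test.p_two_sided,
                 "method": c.test.method, "h0_rejected": c.h0}
                for c in self.comparisons],
            "shares": {g: {k: {"count": v[0], "percent": v[1]}
                           for k, v in s.items()}
                       for g, s in self.shares.items()},
            "failures": [{"participant_id": p, "reason": r} for p, r in self.failures],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _score_record(record: ParticipantRecord, config: PipelineConfig,
                  base_dir: Path | None) -> ParticipantResult:
    result = ParticipantResult(record.participant_id, record.group,
                               warnings=list(record.warnings))
    streams: dict = dict(record.streams)
    for key, p in record.stream_paths.items():
        if key not in streams:
            path = Path(p)
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            streams[key] = read_skeleton_stream(path)

    for (movement, side), stream in streams.items():
        series = angle_series(stream, movement, side)
        result.arom[(movement, side)] = extract_arom(series, config.smoothing_window)

    if record.manual_items is not None and streams:
        side = _dominant_side(result.arom)
        automated = _automated_scores(result.arom, side, config.thresholds)
        result.sheet = assemble_sheet(record.manual_items, automated,
                                      participant_id=record.participant_id, side=side)
        result.fma_total = result.sheet.total
    elif record.fma_total is not None:
        result.fma_total = record.fma_total
    if result.fma_total is not None:
        result.category = classify(result.fma_total, config.bands)
    return result


def _dominant_side(arom: dict) -> str:
    sides = {s for _, s in arom}
    return "right" if "right" in sides else next(iter(sides))


def _automated_scores(arom: dict, side: str, thresholds: A2Thresholds) -> dict[str, int]:
    """Score the three automated movements from one side's sessions.

    Elbow extension is scored from the flexion trial's maximum included
    angle (its extension-side excursion): the AROM statistic is already
    the session max, which is exactly the extension reach.
    """
    scores: dict[str, int] = {}
    abd = arom.get(("shoulder_abduction", side))
    flex = arom.get(("elbow_flexion", side))
    if abd is None or flex is None:
        have = sorted(f"{m}/{s}" for m, s in arom)
        raise EmptyStreamError(
            f"need shoulder_abduction and elbow_flexion sessions for side "
            f"{side!r}; have {have}")
    scores["shoulder_abduction"] = score_a2_item(abd, thresholds)
    scores["elbow_flexion"] = score_a2_item(flex, thresholds)
    ext = AromResult(movement="elbow_extension", side=side, arom=flex.arom,
                     mean=flex.mean, sd=flex.sd,
                     n_used=flex.n_used, n_excluded=flex.n_excluded)
    scores["elbow_extension"] = score_a2_item(ext, thresholds)
    return scores


def run_pipeline(cohort: CohortTable, config: PipelineConfig | None = None,
                 base_dir: str | Path | None = None) -> PipelineReport:
    """Score every record and build the cohort-level comparison report.

    Deterministic: contains no randomness of its own (any stochasticity
    lives in the upstream simulator's seed). Records missing inputs are
    reported in ``failures`` and the run continues.
    """
    config = config or PipelineConfig()
    base = Path(base_dir) if base_dir is not None else None
    results: list[ParticipantResult] = []
    failures: list[tuple[str, str]] = []
    for record in cohort.records:
        try:
            results.append(_score_record(record, config, base))
        except (KinaromError, OSError) as exc:
            failures.append((record.participant_id, str(exc)))

    comparisons: list[ComparisonRow] = []
    control = [r for r in results if r.group == "control"]
    study = [r for r in results if r.group == "study"]
    if control and study:
        stat = config.compare_on
        for movement in PIPELINE_MOVEMENTS:
            a = [getattr(r.arom[(movement, s)], stat)
                 for r in control for (m, s) in r.arom if m == movement]
            b = [getattr(r.arom[(movement, s)], stat)
                 for r in study for (m, s) in r.arom if m == movement]
            if a and b:
                comparisons.append(compare_groups(a, b, movement))
        fa = [r.fma_total for r in control if r.fma_total is not None]
        fb = [r.fma_total for r in study if r.fma_total is not None]
        if fa and fb:
            comparisons.append(compare_groups(fa, fb, "fma_total", decimals=0))

    shares: dict[str, dict[str, tuple[int, int]]] = {}
    for group_name, group_results in (("control", control), ("study", study)):
        totals = [r.fma_total for r in group_results if r.fma_total is not None]
        if totals:
            shares[group_name] = cohort_classification_shares(totals, config.bands)
    return PipelineReport(results, comparisons, shares, failures)


def streams_from_record(record: ParticipantRecord) -> dict[tuple[str, str], SkeletonStream]:
    """In-memory streams of a (typically simulated) record."""
    return dict(record.streams)
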