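"""Semi-automated Fugl-Meyer upper-extremity (FMA-UE) motor scoring.

The FMA-UE motor domain has 33 ordinal items scored 0/1/2 (total 0-66;
66 = best motor function). In the semi-automated protocol the therapist
scores 30 items manually — movements such as rotation, pronation,
supination and retraction, plus grip and coordination observations,
which a skeleton sensor cannot resolve — while the three section A-II
items (voluntary movement within synergies: shoulder abduction, elbow
flexion, elbow extension) are scored automatically from the measured
AROM against configurable angle cutoffs.

Capacity classification of the total uses one of three band schemes:

* ``interface`` — the front-panel bands: 0-22 none, 23-31 low, 32-47
  limited, 53-66 total; totals 48-52 fall in a gap and classify as
  ``unclassified``.
* ``discussion`` — the cohort-share bands: 31-47 limited, 47-52 notable,
  52-66 total (overlapping endpoints; resolved top-down so 52 is total
  and 47 is notable).
* ``hybrid`` (default) — half-open intervals [0,23) none, [23,31) low,
  [31,47) limited, [47,52) notable, [52,67) total: the unique scheme
  consistent with both of the above that partitions the whole scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .arom import AromResult
from .errors import ConfigError, DomainError, IncompleteSheetError, SchemaError

SECTIONS = ("A-I", "A-II", "A-III", "A-IV", "A-V", "B", "C", "D")


@dataclass(frozen=True)
class FmaItem:
    """One ordinal assessment item (0/1/2; None = not yet scored)."""

    item_id: str
    section: str
    label: str
    mode: str = "manual"            # "manual" | "automated"
    score: int | None = None
    movement: str | None = None     # automated items: which AROM drives them

    def __post_init__(self):
        if self.section not in SECTIONS:
            raise SchemaError(f"unknown section {self.section!r}")
        if self.mode not in ("manual", "automated"):
            raise SchemaError(f"unknown mode {self.mode!r}")
        if self.score is not None and self.score not in (0, 1, 2):
            raise DomainError(f"score must be 0, 1 or 2, got {self.score!r}")


def _item(item_id, section, label, mode="manual", movement=None):
    return FmaItem(item_id, section, label, mode=mode, movement=movement)


#: The 33-item motor catalogue: 30 manual + 3 automated A-II items.
DEFAULT_ITEM_CATALOGUE: tuple[FmaItem, ...] = (
    _item("a1-flexor-reflex", "A-I", "Biceps/finger flexor reflex activity"),
    _item("a1-extensor-reflex", "A-I", "Triceps reflex activity"),
    _item("a2-shoulder-retraction", "A-II", "Flexor synergy: shoulder retraction"),
    _item("a2-shoulder-elevation", "A-II", "Flexor synergy: shoulder elevation"),
    _item("a2-shoulder-abduction", "A-II", "Flexor synergy: shoulder abduction",
          mode="automated", movement="shoulder_abduction"),
    _item("a2-shoulder-external-rotation", "A-II", "Flexor synergy: external rotation"),
    _item("a2-elbow-flexion", "A-II", "Flexor synergy: elbow flexion",
          mode="automated", movement="elbow_flexion"),
    _item("a2-forearm-supination", "A-II", "Flexor synergy: forearm supination"),
    _item("a2-shoulder-adduction-internal-rotation", "A-II",
          "Extensor synergy: shoulder adduction / internal rotation"),
    _item("a2-elbow-extension", "A-II", "Extensor synergy: elbow extension",
          mode="automated", movement="elbow_extension"),
    _item("a2-forearm-pronation", "A-II", "Extensor synergy: forearm pronation"),
    _item("a3-hand-to-lumbar-spine", "A-III", "Hand to lumbar spine"),
    _item("a3-shoulder-flexion-0-90", "A-III", "Shoulder flexion 0-90, elbow extended"),
    _item("a3-pronation-supination-elbow-90", "A-III",
          "Pronation/supination, elbow at 90"),
    _item("a4-shoulder-abduction-90", "A-IV", "Shoulder abduction to 90, elbow extended"),
    _item("a4-shoulder-flexion-90-180", "A-IV", "Shoulder flexion 90-180"),
    _item("a4-pronation-supination-elbow-0", "A-IV",
          "Pronation/supination, elbow extended"),
    _item("a5-normal-reflex-activity", "A-V", "Normal reflex activity"),
    _item("b-wrist-stable-elbow-90", "B", "Wrist stable, elbow at 90"),
    _item("b-wrist-flexion-extension-elbow-90", "B", "Wrist flexion/extension, elbow at 90"),
    _item("b-wrist-stable-elbow-0", "B", "Wrist stable, elbow extended"),
    _item("b-wrist-flexion-extension-elbow-0", "B", "Wrist flexion/extension, elbow extended"),
    _item("b-wrist-circumduction", "B", "Wrist circumduction"),
    _item("c-finger-mass-flexion", "C", "Finger mass flexion"),
    _item("c-finger-mass-extension", "C", "Finger mass extension"),
    _item("c-hook-grasp", "C", "Hook grasp"),
    _item("c-thumb-adduction", "C", "Thumb adduction grasp"),
    _item("c-pincer-grasp", "C", "Pincer grasp"),
    _item("c-cylinder-grasp", "C", "Cylindrical grasp"),
    _item("c-spherical-grasp", "C", "Spherical grasp"),
    _item("d-tremor", "D", "Coordination: tremor"),
    _item("d-dysmetria", "D", "Coordination: dysmetria"),
    _item("d-speed", "D", "Coordination: speed"),
)

AUTOMATED_MOVEMENTS = tuple(i.movement for i in DEFAULT_ITEM_CATALOGUE if i.mode == "automated")


@dataclass(frozen=True)
class A2Thresholds:
    """Angle cutoffs mapping a session AROM to the 0/1/2 ordinal.

    Score 2 at AROM >= full threshold, 1 at partial <= AROM < full,
    else 0. All angles in the included-angle convention. The defaults
    sit at clinically typical full/partial active ranges and are
    configuration, not measurement: the protocol publishes no cutoffs.
    """

    thresholds: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "shoulder_abduction": (150.0, 90.0),
        "elbow_flexion": (130.0, 60.0),
        "elbow_extension": (160.0, 120.0),
    })

    def __post_init__(self):
        for movement, (full, partial) in self.thresholds.items():
            if not (0.0 < partial < full <= 180.0):
                raise ConfigError(
                    f"{movement}: need 0 < partial < full <= 180, got "
                    f"partial={partial}, full={full}")

    def for_movement(self, movement: str) -> tuple[float, float]:
        try:
            return self.thresholds[movement]
        except KeyError:
            raise ConfigError(f"no thresholds configured for movement {movement!r}; "
                              f"configured: {sorted(self.thresholds)}") from None


DEFAULT_A2_THRESHOLDS = A2Thresholds()


def score_a2_item(arom: AromResult, thresholds: A2Thresholds = DEFAULT_A2_THRESHOLDS) -> int:
    """Ordinal 0/1/2 for one automated item from its session AROM."""
    full, partial = thresholds.for_movement(arom.movement)
    if arom.arom >= full:
        return 2
    if arom.arom >= partial:
        return 1
    return 0


@dataclass
class FmaSheet:
    """A complete 33-item sheet for one participant/side."""

    items: list[FmaItem]
    participant_id: str = ""
    side: str = ""

    def __post_init__(self):
        ids = [i.item_id for i in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item id(s): {dupes}")
        if len(self.items) != 33:
            raise SchemaError(f"sheet must have exactly 33 items, got {len(self.items)}")
        n_auto = sum(1 for i in self.items if i.mode == "automated")
        if n_auto != 3:
            raise SchemaError(f"sheet must have exactly 3 automated items, got {n_auto}")

    @property
    def total(self) -> int:
        return total_score(self)


def assemble_sheet(
    manual_items: list[FmaItem],
    automated_scores: dict[str, int],
    participant_id: str = "",
    side: str = "",
    catalogue: tuple[FmaItem, ...] = DEFAULT_ITEM_CATALOGUE,
) -> FmaSheet:
    """Merge 30 scored manual items with the 3 automated movement scores.

    Raises :class:`IncompleteSheetError` naming any manual item that is
    missing or unscored, and :class:`ConfigError` for a missing
    automated movement score.
    """
    by_id = {i.item_id: i for i in manual_items}
    if len(by_id) != len(manual_items):
        ids = [i.item_id for i in manual_items]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate manual item id(s): {dupes}")
    extra = set(by_id) - {i.item_id for i in catalogue}
    if extra:
        raise SchemaError(f"unknown manual item id(s): {sorted(extra)}")

    items: list[FmaItem] = []
    missing: list[str] = []
    for cat in catalogue:
        if cat.mode == "automated":
            if cat.movement not in automated_scores:
                raise ConfigError(f"no automated score for movement {cat.movement!r}")
            items.append(replace(cat, score=int(automated_scores[cat.movement])))
        else:
            item = by_id.get(cat.item_id)
            if item is None or item.score is None:
                missing.append(cat.item_id)
            else:
                items.append(replace(cat, score=item.score))
    if missing:
        raise IncompleteSheetError(
            f"{len(missing)} manual item(s) missing or unscored: {missing}", missing)
    return FmaSheet(items, participant_id=participant_id, side=side)


def total_score(sheet: FmaSheet) -> int:
    """Sum of the 33 ordinals (0-66)."""
    unset = [i.item_id for i in sheet.items if i.score is None]
    if unset:
        raise IncompleteSheetError(f"unscored item(s): {unset}", unset)
    return sum(i.score for i in sheet.items)


# --------------------------------------------------------------------------
# Capacity bands

@dataclass(frozen=True)
class CapacityBands:
    """Ordered score intervals -> capacity category.

    ``half_open`` intervals are [lo, hi); ``closed`` intervals are
    [lo, hi] and are checked in order, first match wins (this is how the
    overlapping 'discussion' endpoints resolve). Totals matched by no
    interval classify as ``unclassified``.
    """

    name: str
    intervals: tuple[tuple[int, int, str], ...]
    closed: bool = False

    def category(self, total: int) -> str:
        for lo, hi, label in self.intervals:
            if (lo <= total <= hi) if self.closed else (lo <= total < hi):
                return label
        return "unclassified"

    @property
    def labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, _, label in self.intervals:
            if label not in seen:
                seen.append(label)
        return tuple(seen)


HYBRID_BANDS = CapacityBands("hybrid", (
    (0, 23, "none"), (23, 31, "low"), (31, 47, "limited"),
    (47, 52, "notable"), (52, 67, "total")))

INTERFACE_BANDS = CapacityBands("interface", (
    (0, 22, "none"), (23, 31, "low"), (32, 47, "limited"), (53, 66, "total")),
    closed=True)

DISCUSSION_BANDS = CapacityBands("discussion", (
    (52, 66, "total"), (47, 52, "notable"), (31, 47, "limited"),
    (0, 22, "none"), (23, 31, "low")), closed=True)

BAND_SCHEMES = {b.name: b for b in (HYBRID_BANDS, INTERFACE_BANDS, DISCUSSION_BANDS)}


def classify(total: int, bands: CapacityBands = HYBRID_BANDS) -> str:
    """Capacity category of a total score under a band scheme."""
    if not (0 <= total <= 66):
        raise DomainError(f"total {total} outside [0, 66]")
    return bands.category(int(total))


# --------------------------------------------------------------------------
# Item-sheet CSV I/O

_SHEET_COLUMNS = ["item_id", "section", "label", "mode", "score"]


def read_item_sheet(path: str | Path) -> list[FmaItem]:
    """Read a (typically manual) item sheet CSV.

    Columns: item_id, section, label, mode, score; an empty score cell
    means not yet scored.
    """
    table = pd.read_csv(Path(path), dtype={"item_id": str})
    missing = [c for c in _SHEET_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    items = []
    for row in table.itertuples():
        score = None if pd.isna(row.score) else int(row.score)
        items.append(FmaItem(row.item_id, row.section, row.label,
                             mode=row.mode, score=score))
    return items


def write_item_sheet(items: list[FmaItem], path: str | Path) -> None:
    pd.DataFrame(
        [(i.item_id, i.section, i.label, i.mode,
          "" if i.score is None else i.score) for i in items],
        columns=_SHEET_COLUMNS).to_csv(Path(path), index=False)


def blank_manual_sheet() -> list[FmaItem]:
    """The 30 manual catalogue items, unscored — a template for therapists."""
    return [i for i in DEFAULT_ITEM_CATALOGUE if i.mode == "manual"]
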