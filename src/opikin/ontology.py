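"""Eight-step ontology of robotic Roux-en-Y gastric bypass.

Raw annotation labels (subtasks, segmented tasks) are mapped onto eight
canonical surgical steps ordered by when they occur in the procedure.  Rare
side tasks (leak test, concurrent hiatal hernia repair) are excluded, and
unmapped labels yield a distinct UNKNOWN outcome so downstream policy — not
the mapper — decides what to do with them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple, Union

import yaml

from . import intervals as iv
from .records import CaseRecord

logger = logging.getLogger(__name__)


class Step(str, Enum):
    """Canonical r-RYGB steps, in procedural order."""

    DISSECTION = "dissection"
    CREATION_OF_GASTRIC_POUCH = "creation_of_gastric_pouch"
    MEASUREMENT = "measurement"
    DIVISION_OF_MESENTERY = "division_of_mesentery"
    STAPLE_ANASTOMOSIS = "staple_anastomosis"
    ENTEROTOMY_CLOSURE = "enterotomy_closure"
    DEFECT_CLOSURE = "defect_closure"
    HAND_SEWN_ANASTOMOSIS = "hand_sewn_anastomosis"


STEP_ORDER: List[Step] = list(Step)
STEP_INDEX: Dict[Step, int] = {s: i for i, s in enumerate(STEP_ORDER)}


class _Sentinel(str):
    def __repr__(self) -> str:  # pragma: no cover
        return str(self)


EXCLUDED = _Sentinel("EXCLUDED")
UNKNOWN = _Sentinel("UNKNOWN")

MapResult = Union[Step, _Sentinel]

_DEFAULT_SYNONYMS: Dict[str, str] = {
    "dissection": "dissection",
    "adhesiolysis": "dissection",
    "omental dissection": "dissection",
    "creation of gastric pouch": "creation_of_gastric_pouch",
    "gastric pouch creation": "creation_of_gastric_pouch",
    "gastric pouch": "creation_of_gastric_pouch",
    "pouch creation": "creation_of_gastric_pouch",
    "measurement": "measurement",
    "limb measurement": "measurement",
    "measurement of limbs": "measurement",
    "bowel measurement": "measurement",
    "division of mesentery": "division_of_mesentery",
    "mesenteric division": "division_of_mesentery",
    "mesentery division": "division_of_mesentery",
    "staple anastomosis": "staple_anastomosis",
    "stapled anastomosis": "staple_anastomosis",
    "side to side stapled anastomosis": "staple_anastomosis",
    "enterotomy closure": "enterotomy_closure",
    "common channel enterotomy closure": "enterotomy_closure",
    "defect closure": "defect_closure",
    "mesenteric defect closure": "defect_closure",
    "hand sewn anastomosis": "hand_sewn_anastomosis",
    "handsewn anastomosis": "hand_sewn_anastomosis",
    "gastrojejunal anastomosis": "hand_sewn_anastomosis",
}

_DEFAULT_EXCLUSIONS = (
    "leak test",
    "hiatal hernia repair",
    "concurrent hiatal hernia repair",
)


def normalize_label(raw: str) -> str:
    """Case-fold and collapse punctuation/whitespace for lexicon matching."""
    s = re.sub(r"[_\-/,]+", " ", raw.strip().lower())
    return re.sub(r"\s+", " ", s)


@dataclass
class Lexicon:
    """User-extensible mapping from raw annotation labels to canonical steps.

    Ships seeded with the canonical names plus common synonym spellings; the
    raw subtask vocabulary of any given annotation effort is site-specific,
    so the map is loadable from an ``ontology.yaml`` config.
    """

    synonyms: Dict[str, Step] = field(
        default_factory=lambda: {k: Step(v) for k, v in _DEFAULT_SYNONYMS.items()}
    )
    exclusions: Tuple[str, ...] = _DEFAULT_EXCLUSIONS

    @classmethod
    def default(cls) -> "Lexicon":
        return cls()

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        syn = {normalize_label(k): Step(v) for k, v in d.get("synonyms", {}).items()}
        for s in d.get("steps", [v.value for v in STEP_ORDER]):
            syn.setdefault(normalize_label(s), Step(s))
        return cls(synonyms=syn, exclusions=tuple(normalize_label(x) for x in d.get("exclusions", [])))

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "steps": [s.value for s in STEP_ORDER],
            "synonyms": {k: v.value for k, v in self.synonyms.items()},
            "exclusions": list(self.exclusions),
        }

    def map(self, raw_label: str) -> MapResult:
        norm = normalize_label(raw_label)
        if norm in self.exclusions:
            return EXCLUDED
        return self.synonyms.get(norm, UNKNOWN)


def map_subtask(raw_label: str, lexicon: Optional[Lexicon] = None) -> MapResult:
    """Map one raw annotation label to a canonical :class:`Step`, EXCLUDED, or UNKNOWN."""
    return (lexicon or Lexicon.default()).map(raw_label)


@dataclass
class Window:
    start_s: float
    end_s: float
    operator_id: str
    role: str


@dataclass
class StepWindowSet:
    """All analysis windows of one canonical step within one case.

    Windows carry operator attribution and are never merged across operators,
    so per-operator OPIs stay computable (cohort comparisons are made within
    steps between operator roles).
    """

    case_id: str
    step: Step
    windows: List[Window]

    @property
    def total_duration(self) -> float:
        return iv.total([(w.start_s, w.end_s) for w in self.windows])

    def intervals(self, operator_id: Optional[str] = None) -> List[Tuple[float, float]]:
        return iv.normalize(
            (w.start_s, w.end_s)
            for w in self.windows
            if operator_id is None or w.operator_id == operator_id
        )

    def operators(self) -> List[str]:
        seen: List[str] = []
        for w in self.windows:
            if w.operator_id not in seen:
                seen.append(w.operator_id)
        return seen


def _has_kinematics(case: CaseRecord, windows: List[Window]) -> bool:
    spans = iv.normalize((w.start_s, w.end_s) for w in windows)
    ops = {w.operator_id for w in windows}
    for t in case.trajectories:
        if t.source != "instrument_tip" or t.operator_id not in ops:
            continue
        for s, e in spans:
            if ((t.time_s >= s) & (t.time_s < e)).any():
                return True
    return False


def build_step_windows(
    case: CaseRecord,
    lexicon: Optional[Lexicon] = None,
    *,
    require_kinematics: bool = True,
) -> List[StepWindowSet]:
    """Map a case's segments onto canonical steps and build analysis windows.

    UNKNOWN labels are dropped with a warning; excluded labels are dropped
    silently (by design).  Overlap between segments of *different* steps is
    resolved by delaying the later-starting segment to begin where the earlier
    one ends (the ontology is linear); overlapping same-step windows of the
    same operator are unioned.  A step is revisited-as-one-unit: all its
    windows within a case form a single :class:`StepWindowSet`.  Steps with no
    instrument-tip kinematics inside any window are omitted.
    """
    lex = lexicon or Lexicon.default()
    mapped = []
    for seg in case.segments:
        res = lex.map(seg.raw_label)
        if res is UNKNOWN:
            logger.warning("case %s: dropping unmapped segment label %r", case.case_id, seg.raw_label)
            continue
        if res is EXCLUDED:
            logger.debug("case %s: excluding segment %r", case.case_id, seg.raw_label)
            continue
        mapped.append((seg, res))

    if not mapped:
        logger.warning("case %s: no mappable segments", case.case_id)
        return []

    # resolve cross-step overlap with a linear sweep
    mapped.sort(key=lambda p: (p[0].start_s, p[0].end_s))
    resolved: List[Tuple[Step, Window]] = []
    cur_end = float("-inf")
    cur_step: Optional[Step] = None
    for seg, step in mapped:
        start, end = seg.start_s, seg.end_s
        if start < cur_end and step != cur_step:
            logger.warning(
                "case %s: segment %r overlaps a different step; start moved %g -> %g",
                case.case_id, seg.raw_label, start, cur_end,
            )
            start = cur_end
            if start >= end:
                continue
        resolved.append((step, Window(start, end, seg.operator_id, seg.role)))
        if end > cur_end:
            cur_end = end
            cur_step = step
        elif cur_step is None:
            cur_step = step

    by_step: Dict[Step, List[Window]] = {}
    for step, w in resolved:
        by_step.setdefault(step, []).append(w)

    out: List[StepWindowSet] = []
    for step in STEP_ORDER:
        if step not in by_step:
            continue
        # union same-operator overlapping windows, keep operators separate
        per_op: Dict[Tuple[str, str], List[Window]] = {}
        for w in by_step[step]:
            per_op.setdefault((w.operator_id, w.role), []).append(w)
        windows: List[Window] = []
        for (op, role), ws in per_op.items():
            for s, e in iv.normalize((w.start_s, w.end_s) for w in ws):
                windows.append(Window(s, e, op, role))
        windows.sort(key=lambda w: (w.start_s, w.operator_id))
        sws = StepWindowSet(case_id=case.case_id, step=step, windows=windows)
        if require_kinematics and case.trajectories and not _has_kinematics(case, windows):
            logger.warning(
                "case %s: step %s omitted (no console kinematics inside its windows)",
                case.case_id, step.value,
            )
            continue
        out.append(sws)
    return out
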