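"""Domain records for robotic-console kinematic case data.

A *case* is one recorded operation.  Its raw material is a set of kinematic
streams (timestamped 3-D positions of each hand's instrument tip and console
wrist), console-activity intervals (spans during which a hand / the console is
actively driving), annotated step segments, and a roster mapping operator ids
to roles (attending / fellow / resident) and prior robotic experience.

Coordinates live in an arbitrary fixed right-handed Cartesian frame in
centimeters; every metric computed downstream is translation- and
rotation-invariant, so no registration between cases is attempted.  Times are
seconds from case start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import intervals as iv

logger = logging.getLogger(__name__)

HANDS = ("dominant", "nondominant")
SOURCES = ("instrument_tip", "controller_wrist")
SCOPES = ("console", "dominant_hand", "nondominant_hand")
ROLES = ("attending", "fellow", "resident")
HANDEDNESS = ("right", "left")

#: gaps longer than this multiple of the nominal sample period are logged
GAP_FACTOR = 5.0


class ValidationError(ValueError):
    """A case bundle violates a structural invariant."""


@dataclass
class Trajectory:
    """One kinematic stream: ordered samples of a single (operator, hand, source).

    ``segment_id`` marks discontinuities: consecutive samples belong to a
    continuous recording only if their segment ids are equal.  Distance is
    never accumulated across a segment boundary (used by window clipping).
    """

    operator_id: str
    hand: str
    source: str
    time_s: np.ndarray
    xyz_cm: np.ndarray
    segment_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.xyz_cm = np.asarray(self.xyz_cm, dtype=float)
        if self.xyz_cm.ndim != 2 or self.xyz_cm.shape[1] != 3:
            raise ValidationError(
                f"trajectory {self.key}: xyz_cm must be (n, 3), got {self.xyz_cm.shape}"
            )
        if self.segment_id is None:
            self.segment_id = np.zeros(len(self.time_s), dtype=np.int64)
        else:
            self.segment_id = np.asarray(self.segment_id, dtype=np.int64)

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.operator_id, self.hand, self.source)

    @property
    def n(self) -> int:
        return int(len(self.time_s))


@dataclass
class ActivityInterval:
    """A half-open span [start_s, end_s) during which ``scope`` is actively driving."""

    operator_id: str
    scope: str
    start_s: float
    end_s: float


@dataclass
class StepSegment:
    """An annotated time span with its raw label and the operating surgeon."""

    raw_label: str
    operator_id: str
    role: str
    start_s: float
    end_s: float
    canonical_step: Optional[str] = None


@dataclass
class OperatorInfo:
    role: str
    prior_robotic_cases: int
    handedness: str = "right"


@dataclass
class CaseRecord:
    """A complete, validated case bundle held in memory."""

    case_id: str
    trajectories: List[Trajectory]
    activity: List[ActivityInterval]
    segments: List[StepSegment]
    roster: Dict[str, OperatorInfo]
    metadata: Dict[str, str] = field(default_factory=dict)
    sample_rate_hz: float = 50.0

    def trajectory(self, operator_id: str, hand: str, source: str) -> Optional[Trajectory]:
        for t in self.trajectories:
            if t.key == (operator_id, hand, source):
                return t
        return None

    def activity_for(self, operator_id: str, scope: str) -> List[Tuple[float, float]]:
        """Normalized activity intervals for one (operator, scope)."""
        return iv.normalize(
            (a.start_s, a.end_s)
            for a in self.activity
            if a.operator_id == operator_id and a.scope == scope
        )

    def equals(self, other: "CaseRecord", atol: float = 0.0) -> bool:
        """Field-for-field equality (trajectories compared as a keyed set)."""
        if (
            self.case_id != other.case_id
            or self.sample_rate_hz != other.sample_rate_hz
            or {k: str(v) for k, v in self.metadata.items()}
            != {k: str(v) for k, v in other.metadata.items()}
        ):
            return False
        if {k: (o.role, int(o.prior_robotic_cases), o.handedness) for k, o in self.roster.items()} != {
            k: (o.role, int(o.prior_robotic_cases), o.handedness) for k, o in other.roster.items()
        }:
            return False
        mine = {t.key: t for t in self.trajectories}
        theirs = {t.key: t for t in other.trajectories}
        if mine.keys() != theirs.keys():
            return False
        for k, a in mine.items():
            b = theirs[k]
            if a.n != b.n:
                return False
            if not (
                np.allclose(a.time_s, b.time_s, rtol=0, atol=atol)
                and np.allclose(a.xyz_cm, b.xyz_cm, rtol=0, atol=atol)
            ):
                return False
        def akey(a: ActivityInterval):
            return (a.operator_id, a.scope, a.start_s, a.end_s)

        if sorted(map(akey, self.activity)) != sorted(map(akey, other.activity)):
            return False

        def skey(s: StepSegment):
            return (s.start_s, s.end_s, s.operator_id, s.raw_label, s.role)

        return sorted(map(skey, self.segments)) == sorted(map(skey, other.segments))


def validate_case(case: CaseRecord) -> None:
    """Enforce every structural invariant of a :class:`CaseRecord`.

    Raises :class:`ValidationError` naming the offending stream / interval;
    sampling gaps are logged as warnings, never fatal (clinical recorders drop
    samples).
    """
    if not case.roster:
        raise ValidationError(f"case {case.case_id}: empty roster")
    for op, info in case.roster.items():
        if info.role not in ROLES:
            raise ValidationError(f"case {case.case_id}: operator {op!r} has unknown role {info.role!r}")
        if info.handedness not in HANDEDNESS:
            raise ValidationError(
                f"case {case.case_id}: operator {op!r} has unknown handedness {info.handedness!r}"
            )

    seen = set()
    period = 1.0 / case.sample_rate_hz if case.sample_rate_hz > 0 else None
    for t in case.trajectories:
        name = f"(operator={t.operator_id!r}, hand={t.hand!r}, source={t.source!r})"
        if t.operator_id not in case.roster:
            raise ValidationError(f"case {case.case_id}: unknown operator_id in stream {name}")
        if t.hand not in HANDS:
            raise ValidationError(f"case {case.case_id}: unknown hand in stream {name}")
        if t.source not in SOURCES:
            raise ValidationError(f"case {case.case_id}: unknown source in stream {name}")
        if t.key in seen:
            raise ValidationError(f"case {case.case_id}: duplicate stream {name}")
        seen.add(t.key)
        if t.n == 0:
            raise ValidationError(f"case {case.case_id}: empty stream {name}")
        if not np.all(np.isfinite(t.time_s)) or not np.all(np.isfinite(t.xyz_cm)):
            raise ValidationError(f"case {case.case_id}: non-finite values in stream {name}")
        if t.time_s[0] < 0:
            raise ValidationError(f"case {case.case_id}: negative timestamp in stream {name}")
        dt = np.diff(t.time_s)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise ValidationError(
                f"case {case.case_id}: non-monotone timestamps in stream {name} "
                f"at t={t.time_s[i + 1]:.6g}s"
            )
        if period is not None and t.n > 1:
            ngaps = int(np.sum(dt > GAP_FACTOR * period))
            if ngaps:
                logger.warning(
                    "case %s: stream %s has %d gap(s) > %gx nominal period",
                    case.case_id, name, ngaps, GAP_FACTOR,
                )

    for a in case.activity:
        if a.operator_id not in case.roster:
            raise ValidationError(
                f"case {case.case_id}: activity interval references unknown operator {a.operator_id!r}"
            )
        if a.scope not in SCOPES:
            raise ValidationError(f"case {case.case_id}: unknown activity scope {a.scope!r}")
        if not (a.end_s > a.start_s):
            raise ValidationError(
                f"case {case.case_id}: degenerate activity interval "
                f"[{a.start_s}, {a.end_s}) for {a.operator_id!r}/{a.scope}"
            )

    for s in case.segments:
        if s.operator_id not in case.roster:
            raise ValidationError(
                f"case {case.case_id}: segment {s.raw_label!r} references unknown operator {s.operator_id!r}"
            )
        if not (s.end_s > s.start_s):
            raise ValidationError(
                f"case {case.case_id}: degenerate segment {s.raw_label!r} [{s.start_s}, {s.end_s})"
            )
        if s.role != case.roster[s.operator_id].role:
            raise ValidationError(
                f"case {case.case_id}: segment {s.raw_label!r} role {s.role!r} disagrees with "
                f"roster role {case.roster[s.operator_id].role!r} for {s.operator_id!r}"
            )
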