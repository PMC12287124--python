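"""Objective performance indicators (OPIs) per (case, step, operator).

The eight core metrics:

* total task duration (s) — annotated step time attributed to the operator;
* active console time (s) and its percentage of the task duration;
* per-hand active time (s, %) — spans where each hand controller is driving;
* instrument path length (cm) — total tip travel during a hand's active time;
* instrument path-length speed (cm/s) — path length / active time;
* bimanual dexterity — dominant : non-dominant path-length ratio (> 1 means
  greater dominant-hand travel);
* workspace volume (cm^3) — convex hull of pooled both-hand tip positions
  within active windows — with two normalizations: per second of active
  console time (cm^3/s) and per cm of path length (cm^2);
* console-sensitivity ratio — instrument-tip path length over console-wrist
  path length, a per-case motion-scaling diagnostic.

Undefined metrics (zero denominators, no samples) propagate as ``None``,
never 0 or infinity, so downstream statistics can drop them per case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median as _median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from . import intervals as iv
from .ontology import Step, StepWindowSet
from .records import CaseRecord, Trajectory

logger = logging.getLogger(__name__)

Interval = Tuple[float, float]


@dataclass
class StepOPI:
    """The full OPI vector for one (case, step, operator)."""

    case_id: str
    step: Step
    operator_id: str
    role: str
    total_task_duration_s: float
    active_console_time_s: float
    pct_active_console: Optional[float]
    active_time_dom_s: float
    pct_active_dom: Optional[float]
    active_time_nondom_s: float
    pct_active_nondom: Optional[float]
    pathlength_dom_cm: Optional[float]
    pathlength_nondom_cm: Optional[float]
    speed_dom_cm_s: Optional[float]
    speed_nondom_cm_s: Optional[float]
    bimanual_dexterity: Optional[float]
    workspace_volume_cm3: Optional[float]
    workspace_rate_cm3_s: Optional[float]
    workspace_per_pathlength_cm2: Optional[float]
    sensitivity_ratio_dom: Optional[float] = None
    sensitivity_ratio_nondom: Optional[float] = None
    # full-window (activity-unrestricted) path lengths, kept for sensitivity
    # analyses of the active-time restriction
    window_pathlength_dom_cm: Optional[float] = None
    window_pathlength_nondom_cm: Optional[float] = None


def clip_stream(traj: Trajectory, windows: Sequence[Interval]) -> Trajectory:
    """Restrict a stream to samples strictly inside disjoint half-open windows.

    No interpolation is performed at window edges.  Samples from different
    windows receive different ``segment_id`` values so that no distance is
    accumulated across a window boundary.
    """
    windows = iv.normalize(windows)
    masks = []
    seg_ids = []
    base = (np.max(traj.segment_id) + 1) if traj.n else 1
    for j, (s, e) in enumerate(windows):
        m = (traj.time_s >= s) & (traj.time_s < e)
        masks.append(m)
        seg_ids.append(traj.segment_id[m] + base * j)
    if masks:
        keep = np.concatenate([np.flatnonzero(m) for m in masks])
        order = np.argsort(keep, kind="stable")
        keep = keep[order]
        seg = np.concatenate(seg_ids)[order] if len(seg_ids) else np.empty(0, dtype=np.int64)
    else:
        keep = np.empty(0, dtype=np.int64)
        seg = np.empty(0, dtype=np.int64)
    return Trajectory(
        operator_id=traj.operator_id,
        hand=traj.hand,
        source=traj.source,
        time_s=traj.time_s[keep],
        xyz_cm=traj.xyz_cm[keep],
        segment_id=seg,
    )


def path_length(traj: Trajectory) -> float:
    """Sum of Euclidean distances between consecutive same-segment samples (cm)."""
    if traj.n < 2:
        return 0.0
    d = np.linalg.norm(np.diff(traj.xyz_cm, axis=0), axis=1)
    same = traj.segment_id[1:] == traj.segment_id[:-1]
    return float(d[same].sum())


def active_time(
    activity: Iterable[Interval], windows: Iterable[Interval]
) -> float:
    """Total overlap (s) between a scope's activity intervals and step windows."""
    return iv.total(iv.intersect(activity, windows))


def pct_active(active_s: float, total_s: float) -> Optional[float]:
    """Active time as a percentage of task duration; ``None`` if duration is 0."""
    if total_s <= 0:
        return None
    return 100.0 * active_s / total_s


def instrument_speed(pathlength_cm: float, active_s: float) -> Optional[float]:
    """Mean tip speed during active console time (cm/s); ``None`` if no active time."""
    if active_s <= 0:
        if pathlength_cm > 0:
            logger.warning(
                "path length %.3g cm with zero active time: speed undefined", pathlength_cm
            )
        return None
    return pathlength_cm / active_s


def bimanual_dexterity(pl_dom_cm: float, pl_nondom_cm: float) -> Optional[float]:
    """Dominant over non-dominant path length; ``None`` on a zero denominator."""
    if pl_nondom_cm <= 0:
        return None
    return pl_dom_cm / pl_nondom_cm


def workspace_volume(points: np.ndarray) -> float:
    """Convex-hull volume (cm^3) of pooled instrument-tip positions.

    Fewer than 4 points, or coplanar/collinear clouds, yield 0 with a logged
    degeneracy note.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    if len(pts) < 4:
        logger.info("workspace volume degenerate: %d point(s) < 4", len(pts))
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        logger.info("workspace volume degenerate: coplanar/collinear point cloud")
        return 0.0


def normalize_workspace(
    volume_cm3: float, active_s: float, total_pathlength_cm: float
) -> Tuple[Optional[float], Optional[float]]:
    """Workspace volume per second of active time and per cm of path length."""
    rate = volume_cm3 / active_s if active_s > 0 else None
    per_pl = volume_cm3 / total_pathlength_cm if total_pathlength_cm > 0 else None
    return rate, per_pl


def console_sensitivity(instrument_pl_cm: float, wrist_pl_cm: float) -> Optional[float]:
    """Instrument-tip over console-wrist path length (the motion-scaling ratio)."""
    if wrist_pl_cm <= 0:
        return None
    return instrument_pl_cm / wrist_pl_cm


def flag_sensitivity_outliers(
    ratios: Sequence[Optional[float]], tolerance: float = 0.15
) -> List[bool]:
    """Flag sensitivity ratios deviating more than ``tolerance`` from the cohort median.

    Used as a per-case diagnostic for inconsistent master-slave motion scaling.
    """
    vals = [r for r in ratios if r is not None and r > 0]
    if not vals:
        return [False] * len(ratios)
    med = _median(vals)
    return [
        (r is not None and r > 0 and abs(r - med) > tolerance * med) for r in ratios
    ]


def derive_hand_activity(
    traj: Trajectory,
    console_intervals: Sequence[Interval],
    *,
    speed_threshold_cm_s: float = 0.05,
    smoothing_window_s: float = 0.1,
) -> List[Interval]:
    """Estimate one hand's active intervals from its controller motion.

    Used when a bundle records only console-scope activity: the hand is deemed
    active where its controller speed, smoothed over ``smoothing_window_s``,
    exceeds ``speed_threshold_cm_s``; the result is intersected with the
    console-active intervals.
    """
    if traj.n < 2:
        return []
    dt = np.diff(traj.time_s)
    v = np.linalg.norm(np.diff(traj.xyz_cm, axis=0), axis=1) / np.maximum(dt, 1e-12)
    # moving-average smoothing over the requested span
    med_dt = float(np.median(dt))
    k = max(int(round(smoothing_window_s / med_dt)), 1)
    if k > 1:
        kernel = np.ones(k) / k
        v = np.convolve(v, kernel, mode="same")
    active = v > speed_threshold_cm_s
    spans: List[Interval] = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = traj.time_s[i]
        elif not a and start is not None:
            spans.append((start, traj.time_s[i + 1]))
            start = None
    if start is not None:
        spans.append((start, traj.time_s[-1]))
    return iv.intersect(spans, console_intervals)


def _hand_activity(
    case: CaseRecord, operator_id: str, hand: str, console: Sequence[Interval],
    speed_threshold_cm_s: float, smoothing_window_s: float,
) -> List[Interval]:
    scope = f"{hand}_hand"
    recorded = case.activity_for(operator_id, scope)
    if recorded:
        return recorded
    src = case.trajectory(operator_id, hand, "controller_wrist") or case.trajectory(
        operator_id, hand, "instrument_tip"
    )
    if src is None:
        return []
    logger.info(
        "case %s: deriving %s activity for %r from controller motion",
        case.case_id, scope, operator_id,
    )
    return derive_hand_activity(
        src, console,
        speed_threshold_cm_s=speed_threshold_cm_s,
        smoothing_window_s=smoothing_window_s,
    )


def compute_step_opis(
    case: CaseRecord,
    window_sets: Sequence[StepWindowSet],
    *,
    speed_threshold_cm_s: float = 0.05,
    smoothing_window_s: float = 0.1,
) -> List[StepOPI]:
    """Compute the full OPI vector for every (step, operator) in a case.

    Path lengths (hence speeds) are restricted to samples inside each hand's
    active intervals, so that speed x active time equals path length exactly.
    The workspace hull pools both hands' tip positions within console-active
    spans of the step.  Steps with no tip kinematics for either hand are
    omitted, and every undefined metric is an explicit ``None``.
    """
    out: List[StepOPI] = []
    for sws in window_sets:
        for op in sws.operators():
            wins = sws.intervals(op)
            role = next(w.role for w in sws.windows if w.operator_id == op)
            total_dur = iv.total(wins)
            console = case.activity_for(op, "console")
            act_console = active_time(console, wins)

            per_hand: Dict[str, dict] = {}
            pooled_pts = []
            console_in_wins = iv.intersect(console, wins)
            for hand in ("dominant", "nondominant"):
                ivs = _hand_activity(
                    case, op, hand, console, speed_threshold_cm_s, smoothing_window_s
                )
                act_h = active_time(ivs, wins)
                tip = case.trajectory(op, hand, "instrument_tip")
                wrist = case.trajectory(op, hand, "controller_wrist")
                d = {"active_s": act_h, "pl": None, "speed": None, "sens": None, "win_pl": None}
                if tip is not None:
                    active_wins = iv.intersect(ivs, wins)
                    clipped = clip_stream(tip, active_wins)
                    pl = path_length(clipped)
                    d["pl"] = pl
                    d["speed"] = instrument_speed(pl, act_h)
                    d["win_pl"] = path_length(clip_stream(tip, wins))
                    if wrist is not None:
                        wpl = path_length(clip_stream(wrist, active_wins))
                        d["sens"] = console_sensitivity(pl, wpl)
                    pooled = clip_stream(tip, console_in_wins)
                    if pooled.n:
                        pooled_pts.append(pooled.xyz_cm)
                per_hand[hand] = d

            if all(per_hand[h]["pl"] is None for h in per_hand):
                logger.warning(
                    "case %s: step %s operator %r has no tip kinematics; omitted",
                    case.case_id, sws.step.value, op,
                )
                continue

            pl_dom = per_hand["dominant"]["pl"]
            pl_nondom = per_hand["nondominant"]["pl"]
            dex = (
                bimanual_dexterity(pl_dom, pl_nondom)
                if pl_dom is not None and pl_nondom is not None
                else None
            )
            if pooled_pts:
                vol = workspace_volume(np.vstack(pooled_pts))
            else:
                vol = None
            total_pl = sum(p for p in (pl_dom, pl_nondom) if p is not None)
            if vol is not None:
                rate, per_pl = normalize_workspace(vol, act_console, total_pl)
            else:
                rate, per_pl = None, None

            out.append(
                StepOPI(
                    case_id=case.case_id,
                    step=sws.step,
                    operator_id=op,
                    role=role,
                    total_task_duration_s=total_dur,
                    active_console_time_s=act_console,
                    pct_active_console=pct_active(act_console, total_dur),
                    active_time_dom_s=per_hand["dominant"]["active_s"],
                    pct_active_dom=pct_active(per_hand["dominant"]["active_s"], total_dur),
                    active_time_nondom_s=per_hand["nondominant"]["active_s"],
                    pct_active_nondom=pct_active(per_hand["nondominant"]["active_s"], total_dur),
                    pathlength_dom_cm=pl_dom,
                    pathlength_nondom_cm=pl_nondom,
                    speed_dom_cm_s=per_hand["dominant"]["speed"],
                    speed_nondom_cm_s=per_hand["nondominant"]["speed"],
                    bimanual_dexterity=dex,
                    workspace_volume_cm3=vol,
                    workspace_rate_cm3_s=rate,
                    workspace_per_pathlength_cm2=per_pl,
                    sensitivity_ratio_dom=per_hand["dominant"]["sens"],
                    sensitivity_ratio_nondom=per_hand["nondominant"]["sens"],
                    window_pathlength_dom_cm=per_hand["dominant"]["win_pl"],
                    window_pathlength_nondom_cm=per_hand["nondominant"]["win_pl"],
                )
            )
    return out
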