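"""Synthetic two-cohort case generator with known ground truth.

Clinical console recordings are proprietary, so this module fabricates
complete case bundles whose OPI-relevant properties are programmed:

* per-step duration (lognormal around a median);
* per-hand duty cycle, realized as alternating exponential active/idle bouts
  (mean active bout 8 s) so interval algebra is exercised on fragmented
  activity.  The bout process is console-level — the clutch engages and
  disengages both masters together — and each hand is active during a leading
  fraction of every console bout, so per-hand duty cycles are nested within
  the console duty cycle;
* per-hand target tip speed during active time;
* workspace spread (the spatial sd of the motion);
* a dominance scale multiplying dominant-hand travel (controls bimanual
  dexterity);
* a motion scale linking instrument tip to console wrist (the wrist stream is
  the tip stream shrunk by 1/motion_scale about its centroid).

Motion model: a two-timescale mean-reverting process.  A slow workspace
excursion (piecewise-linear interpolation of Gaussian knots with sd =
``workspace_sigma_cm``) sets the spatial spread while contributing little
path; a fast Ornstein-Uhlenbeck detail component (1 s reversion) supplies
path length, its amplitude solved and then exactly renormalized so that
realized path length during active intervals divided by active time equals
the target speed.  A single mean-reverting process cannot encode spread and
speed independently at a fixed sample rate — after an exact speed rescale its
spread is fully determined by the speed — hence the two timescales.  The tip
is frozen during idle bouts.

Between-case variability is multiplicative lognormal (speeds, dominance,
workspace sigma) and logit-normal (duty cycles); these case-level
distributions double as the null model for statistical calibration.

Seeding: every stream derives its generator from
``(master seed, cohort index, case index, step index, hand, purpose)``, so a
fixed seed yields byte-identical bundles and adding cases never perturbs
existing ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, logit

from . import intervals as iv
from .ontology import STEP_ORDER, Step, Lexicon, build_step_windows
from .opi import compute_step_opis
from .records import ActivityInterval, CaseRecord, OperatorInfo, StepSegment, Trajectory
from .stats import ComparisonRow, build_comparison_table

logger = logging.getLogger(__name__)

#: display labels written into segments.csv; all map onto the ontology via the
#: default lexicon
RAW_LABELS: Dict[Step, str] = {
    Step.DISSECTION: "Dissection",
    Step.CREATION_OF_GASTRIC_POUCH: "Creation of gastric pouch",
    Step.MEASUREMENT: "Limb measurement",
    Step.DIVISION_OF_MESENTERY: "Division of mesentery",
    Step.STAPLE_ANASTOMOSIS: "Stapled anastomosis",
    Step.ENTEROTOMY_CLOSURE: "Common channel enterotomy closure",
    Step.DEFECT_CLOSURE: "Mesenteric defect closure",
    Step.HAND_SEWN_ANASTOMOSIS: "Hand-sewn anastomosis",
}


@dataclass
class StepProfile:
    """Programmed per-step motion characteristics for one cohort."""

    duration_median_s: float = 30.0
    duration_log_sd: float = 0.2
    duty_cycle_dom: float = 0.5
    duty_cycle_nondom: float = 0.5
    speed_dom_cm_s: float = 4.0
    speed_nondom_cm_s: float = 3.7
    workspace_sigma_cm: float = 2.0
    dominance_scale: float = 1.0
    motion_scale: float = 1.8

    def __post_init__(self) -> None:
        for name in (
            "duration_median_s", "speed_dom_cm_s", "speed_nondom_cm_s",
            "workspace_sigma_cm", "dominance_scale", "motion_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StepProfile.{name} must be positive")
        for name in ("duty_cycle_dom", "duty_cycle_nondom"):
            d = getattr(self, name)
            if not (0 <= d <= 1):
                raise ValueError(f"StepProfile.{name} must be in [0, 1]")


@dataclass
class OperatorSpec:
    operator_id: str
    role: str
    prior_robotic_cases: int


@dataclass
class CohortSpec:
    label: str
    profiles: Dict[Step, StepProfile]
    n_cases: int
    operators: List[OperatorSpec]


@dataclass
class CaseJitter:
    """Between-case variability of the programmed parameters."""

    speed_cv: float = 0.08
    dominance_cv: float = 0.15
    sigma_cv: float = 0.10
    duty_logit_sd: float = 0.3


@dataclass
class GeneratorConfig:
    cohorts: List[CohortSpec]
    sample_rate_hz: float = 50.0
    seed: int = 0
    mean_active_bout_s: float = 8.0
    jitter: CaseJitter = field(default_factory=CaseJitter)
    slow_knot_spacing_s: float = 3.0
    fast_tau_s: float = 1.0
    inter_step_gap_s: float = 2.0

    def cohort(self, label: str) -> CohortSpec:
        for c in self.cohorts:
            if c.label == label:
                return c
        raise KeyError(f"no cohort labelled {label!r}")


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def _lognormal_mult(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative lognormal jitter with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(s * rng.standard_normal() - 0.5 * s * s))


def _shift_duty(duty: float, logit_shift: float) -> float:
    if duty <= 0 or duty >= 1:
        return duty
    return float(expit(logit(duty) + logit_shift))


def simulate_bouts(
    rng: np.random.Generator,
    duration_s: float,
    duty_cycle: float,
    mean_active_bout_s: float,
) -> List[Tuple[float, float]]:
    """Alternating exponential active/idle bouts over [0, duration) hitting ``duty_cycle``."""
    if duty_cycle <= 0 or duration_s <= 0:
        return []
    if duty_cycle >= 1:
        return [(0.0, duration_s)]
    mean_idle = mean_active_bout_s * (1.0 - duty_cycle) / duty_cycle
    out: List[Tuple[float, float]] = []
    t = 0.0
    active = bool(rng.random() < duty_cycle)
    while t < duration_s:
        length = float(rng.exponential(mean_active_bout_s if active else mean_idle))
        if active and length > 0:
            out.append((t, min(t + length, duration_s)))
        t += length
        active = not active
    return iv.normalize(out)


def _interval_ids(time_s: np.ndarray, intervals: Sequence[Tuple[float, float]]) -> np.ndarray:
    ids = np.full(len(time_s), -1, dtype=np.int64)
    for j, (s, e) in enumerate(intervals):
        ids[(time_s >= s) & (time_s < e)] = j
    return ids


def _within_interval_path(pos: np.ndarray, ids: np.ndarray) -> float:
    if len(pos) < 2:
        return 0.0
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    same = (ids[1:] == ids[:-1]) & (ids[1:] >= 0)
    return float(d[same].sum())


def simulate_trajectory(
    profile: StepProfile,
    hand: str,
    duration_s: float,
    active_intervals: Sequence[Tuple[float, float]],
    rng: np.random.Generator,
    *,
    sample_rate_hz: float = 50.0,
    t0: float = 0.0,
    operator_id: str = "op",
    slow_knot_spacing_s: float = 3.0,
    fast_tau_s: float = 1.0,
    target_speed_cm_s: Optional[float] = None,
    workspace_sigma_cm: Optional[float] = None,
) -> Trajectory:
    """Simulate one instrument-tip stream for one hand over one step.

    ``active_intervals`` are absolute times within ``[t0, t0 + duration_s)``;
    the tip is frozen outside them.  The realized path length inside the
    active intervals divided by their total length equals the hand's target
    speed (exactly, up to float rounding), and the spatial spread tracks
    ``workspace_sigma_cm``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if target_speed_cm_s is None:
        target_speed_cm_s = (
            profile.speed_dom_cm_s * profile.dominance_scale
            if hand == "dominant"
            else profile.speed_nondom_cm_s
        )
    sigma = workspace_sigma_cm if workspace_sigma_cm is not None else profile.workspace_sigma_cm

    dt = 1.0 / sample_rate_hz
    n = max(int(round(duration_s * sample_rate_hz)), 1)
    t = t0 + np.arange(n) * dt
    intervals = iv.intersect(active_intervals, [(t0, t0 + duration_s)])
    ids = _interval_ids(t, intervals)
    mask = ids >= 0
    m = int(mask.sum())

    pos = np.zeros((n, 3))
    if m >= 2:
        aid = ids[mask]
        # slow workspace excursion over active-ordinal time
        dur_active = m * dt
        n_knots = max(int(math.ceil(dur_active / slow_knot_spacing_s)) + 1, 2)
        knot_t = np.linspace(0.0, (m - 1) * dt, n_knots)
        knot_v = rng.normal(0.0, sigma, size=(n_knots, 3))
        ta = np.arange(m) * dt
        slow = np.column_stack([np.interp(ta, knot_t, knot_v[:, k]) for k in range(3)])
        # fast OU detail, unit stationary sd, reversion time fast_tau_s
        phi = math.exp(-dt / fast_tau_s)
        innov = rng.standard_normal((m, 3)) * math.sqrt(1.0 - phi * phi)
        innov[0] = rng.standard_normal(3)
        fast = lfilter([1.0], [1.0, -phi], innov, axis=0)

        active_total = iv.total(intervals)
        required = target_speed_cm_s * active_total
        slow_pl = _within_interval_path(slow, aid)
        fast_pl = _within_interval_path(fast, aid)
        g = (required - slow_pl) / fast_pl if fast_pl > 0 and required > slow_pl else 0.0
        act = slow + g * fast
        pl = _within_interval_path(act, aid)
        if pl > 0 and required > 0:
            c = act.mean(axis=0)
            act = c + (act - c) * (required / pl)
        active_idx = np.flatnonzero(mask)
        pos[active_idx] = act
        # hold position during idle bouts (frozen tip)
        filled = np.maximum.accumulate(np.where(mask, np.arange(n), -1))
        filled[filled < 0] = active_idx[0]
        pos = pos[filled]
    elif m == 1:
        pos[:] = rng.normal(0.0, sigma, size=3)

    return Trajectory(
        operator_id=operator_id, hand=hand, source="instrument_tip",
        time_s=t, xyz_cm=pos,
    )


def wrist_from_tip(tip: Trajectory, motion_scale: float) -> Trajectory:
    """Console-wrist stream: the tip stream scaled by 1/motion_scale about its centroid."""
    c = tip.xyz_cm.mean(axis=0) if tip.n else np.zeros(3)
    return Trajectory(
        operator_id=tip.operator_id, hand=tip.hand, source="controller_wrist",
        time_s=tip.time_s.copy(), xyz_cm=c + (tip.xyz_cm - c) / motion_scale,
        segment_id=tip.segment_id.copy(),
    )


def _simulate_case(
    config: GeneratorConfig, cohort: CohortSpec, case_index: int
) -> Tuple[CaseRecord, List[dict]]:
    ci = config.cohorts.index(cohort)
    op = cohort.operators[case_index % len(cohort.operators)]
    case_id = f"{cohort.label}_{case_index:03d}"
    jit = config.jitter

    trajectories: List[Trajectory] = []
    activity: List[ActivityInterval] = []
    segments: List[StepSegment] = []
    truth: List[dict] = []
    t0 = 0.0
    for step_idx, step in enumerate(STEP_ORDER):
        if step not in cohort.profiles:
            continue
        prof = cohort.profiles[step]
        r = _rng(config.seed, ci, case_index, step_idx, 0)
        dur = prof.duration_median_s * math.exp(prof.duration_log_sd * r.standard_normal())
        sp_d = (
            prof.speed_dom_cm_s
            * _lognormal_mult(r, jit.speed_cv)
            * prof.dominance_scale
            * _lognormal_mult(r, jit.dominance_cv)
        )
        sp_n = prof.speed_nondom_cm_s * _lognormal_mult(r, jit.speed_cv)
        sigma = prof.workspace_sigma_cm * _lognormal_mult(r, jit.sigma_cv)
        # one logit draw per (case, step) shifts both hands' duty cycles:
        # engagement is console-level (the clutch gates both masters)
        duty_shift = jit.duty_logit_sd * r.standard_normal()
        duty_d = _shift_duty(prof.duty_cycle_dom, duty_shift)
        duty_n = _shift_duty(prof.duty_cycle_nondom, duty_shift)
        duty_console = max(duty_d, duty_n)

        rb = _rng(config.seed, ci, case_index, step_idx, 0, 1)
        console = [
            (t0 + s, t0 + e)
            for s, e in simulate_bouts(rb, dur, duty_console, config.mean_active_bout_s)
        ]
        hand_ivs: Dict[str, List[Tuple[float, float]]] = {}
        for h_idx, (hand, speed, duty) in enumerate(
            (("dominant", sp_d, duty_d), ("nondominant", sp_n, duty_n))
        ):
            # each hand drives the leading fraction of every console bout
            frac = duty / duty_console if duty_console > 0 else 0.0
            if frac >= 1.0:
                bouts = list(console)
            else:
                bouts = [(s, s + (e - s) * frac) for s, e in console if frac > 0]
            hand_ivs[hand] = bouts
            rt = _rng(config.seed, ci, case_index, step_idx, h_idx + 1, 2)
            tip = simulate_trajectory(
                prof, hand, dur, bouts, rt,
                sample_rate_hz=config.sample_rate_hz, t0=t0, operator_id=op.operator_id,
                slow_knot_spacing_s=config.slow_knot_spacing_s,
                fast_tau_s=config.fast_tau_s,
                target_speed_cm_s=speed, workspace_sigma_cm=sigma,
            )
            trajectories.append(tip)
            trajectories.append(wrist_from_tip(tip, prof.motion_scale))
            for s, e in bouts:
                activity.append(ActivityInterval(op.operator_id, f"{hand}_hand", s, e))

        for s, e in console:
            activity.append(ActivityInterval(op.operator_id, "console", s, e))
        segments.append(
            StepSegment(
                raw_label=RAW_LABELS[step], operator_id=op.operator_id, role=op.role,
                start_s=t0, end_s=t0 + dur,
            )
        )
        truth.append(
            {
                "case_id": case_id, "cohort": cohort.label, "operator_id": op.operator_id,
                "step": step.value, "duration_s": dur,
                "speed_dom_cm_s": sp_d, "speed_nondom_cm_s": sp_n,
                "duty_dom": duty_d, "duty_nondom": duty_n,
                "realized_duty_dom": iv.total(hand_ivs["dominant"]) / dur,
                "realized_duty_nondom": iv.total(hand_ivs["nondominant"]) / dur,
                "workspace_sigma_cm": sigma,
                "dominance_scale": prof.dominance_scale,
                "motion_scale": prof.motion_scale,
            }
        )
        t0 += dur + config.inter_step_gap_s

    # merge per-stream trajectories that share a key (one trajectory per key
    # across steps)
    by_key: Dict[Tuple[str, str, str], List[Trajectory]] = {}
    for tr in trajectories:
        by_key.setdefault(tr.key, []).append(tr)
    merged: List[Trajectory] = []
    for key in sorted(by_key):
        parts = by_key[key]
        merged.append(
            Trajectory(
                operator_id=key[0], hand=key[1], source=key[2],
                time_s=np.concatenate([p.time_s for p in parts]),
                xyz_cm=np.vstack([p.xyz_cm for p in parts]),
            )
        )

    case = CaseRecord(
        case_id=case_id,
        trajectories=merged,
        activity=activity,
        segments=segments,
        roster={op.operator_id: OperatorInfo(op.role, op.prior_robotic_cases, "right")},
        metadata={"procedure": "initial", "cohort": cohort.label},
        sample_rate_hz=config.sample_rate_hz,
    )
    return case, truth


def simulate_case(
    config: GeneratorConfig, cohort: Union[str, CohortSpec], case_index: int
) -> CaseRecord:
    """Generate one complete synthetic :class:`CaseRecord`."""
    if isinstance(cohort, str):
        cohort = config.cohort(cohort)
    return _simulate_case(config, cohort, case_index)[0]


@dataclass
class SimulatedDataset:
    cases: List[CaseRecord]
    truth: pd.DataFrame


def simulate_cohorts(
    config: GeneratorConfig,
    out_dir: Optional[Union[str, Path]] = None,
    overwrite: bool = False,
) -> SimulatedDataset:
    """Generate all cohorts' cases; optionally write bundles and a truth manifest."""
    from .io import write_case_bundle  # local import to avoid a cycle

    cases: List[CaseRecord] = []
    rows: List[dict] = []
    for cohort in config.cohorts:
        for i in range(cohort.n_cases):
            case, truth = _simulate_case(config, cohort, i)
            cases.append(case)
            rows.extend(truth)
    truth_df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
        out.mkdir(parents=True, exist_ok=True)
        for case in cases:
            write_case_bundle(case, out / case.case_id)
        truth_df.to_csv(out / "manifest.csv", index=False)
    return SimulatedDataset(cases=cases, truth=truth_df)


# ---------------------------------------------------------------------------
# study preset: two cohorts with the six programmed step x metric effects
# ---------------------------------------------------------------------------

#: (step, OPI metric, sign of attending minus trainee) for the six programmed
#: effects; the remaining five steps have identical cohort profiles
PRESET_EFFECTS: Tuple[Tuple[Step, str, int], ...] = (
    (Step.DISSECTION, "bimanual_dexterity", +1),
    (Step.DISSECTION, "speed_nondom_cm_s", +1),
    (Step.CREATION_OF_GASTRIC_POUCH, "speed_nondom_cm_s", -1),
    (Step.CREATION_OF_GASTRIC_POUCH, "pct_active_console", +1),
    (Step.HAND_SEWN_ANASTOMOSIS, "pct_active_console", +1),
    (Step.HAND_SEWN_ANASTOMOSIS, "workspace_rate_cm3_s", -1),
)

PRESET_NULL_STEPS: Tuple[Step, ...] = (
    Step.MEASUREMENT,
    Step.DIVISION_OF_MESENTERY,
    Step.STAPLE_ANASTOMOSIS,
    Step.ENTEROTOMY_CLOSURE,
    Step.DEFECT_CLOSURE,
)

#: the metric families in which effects are programmed; null-step false-positive
#: rates are reported over these
EFFECT_METRICS: Tuple[str, ...] = (
    "pct_active_console",
    "speed_nondom_cm_s",
    "bimanual_dexterity",
    "workspace_rate_cm3_s",
)


def preset_study_effects(
    n_attending_cases: int = 20,
    n_trainee_cases: int = 20,
    seed: int = 0,
    duration_median_s: float = 120.0,
    sample_rate_hz: float = 25.0,
) -> GeneratorConfig:
    """A two-cohort config encoding the study's six effect *directions*.

    Attending vs trainee, per step: higher dissection dominance and
    non-dominant speed; lower pouch-creation non-dominant speed; higher
    pouch-creation and hand-sewn-anastomosis active time; smaller (hence
    lower-rate) hand-sewn-anastomosis workspace.  Directions only — the
    magnitudes are moderate programmed effects, not fits to any clinical
    table.  The five remaining steps have identical cohort profiles.

    The default problem size is a desk-scale analog of a clinical series:
    120 s median steps sampled at 25 Hz, 20 cases per cohort.
    """

    def base() -> StepProfile:
        return StepProfile(
            duration_median_s=duration_median_s, duration_log_sd=0.2,
            duty_cycle_dom=0.5, duty_cycle_nondom=0.5,
            speed_dom_cm_s=4.0, speed_nondom_cm_s=3.7,
            workspace_sigma_cm=2.0, dominance_scale=1.0, motion_scale=1.8,
        )

    att = {s: base() for s in STEP_ORDER}
    trn = {s: base() for s in STEP_ORDER}

    att[Step.DISSECTION] = replace(att[Step.DISSECTION], dominance_scale=1.4, speed_nondom_cm_s=3.74)
    trn[Step.DISSECTION] = replace(trn[Step.DISSECTION], dominance_scale=0.75, speed_nondom_cm_s=3.25)

    att[Step.CREATION_OF_GASTRIC_POUCH] = replace(
        att[Step.CREATION_OF_GASTRIC_POUCH],
        speed_nondom_cm_s=3.91, duty_cycle_dom=0.55, duty_cycle_nondom=0.55,
    )
    trn[Step.CREATION_OF_GASTRIC_POUCH] = replace(
        trn[Step.CREATION_OF_GASTRIC_POUCH],
        speed_nondom_cm_s=4.52, duty_cycle_dom=0.33, duty_cycle_nondom=0.33,
    )

    att[Step.HAND_SEWN_ANASTOMOSIS] = replace(
        att[Step.HAND_SEWN_ANASTOMOSIS],
        duty_cycle_dom=0.48, duty_cycle_nondom=0.48, workspace_sigma_cm=1.5,
    )
    trn[Step.HAND_SEWN_ANASTOMOSIS] = replace(
        trn[Step.HAND_SEWN_ANASTOMOSIS],
        duty_cycle_dom=0.23, duty_cycle_nondom=0.23, workspace_sigma_cm=2.2,
    )

    attending_ops = [
        OperatorSpec("att_a", "attending", 1300),
        OperatorSpec("att_b", "attending", 500),
    ]
    trainee_ops = [
        OperatorSpec("res_a", "resident", 5),
        OperatorSpec("res_b", "resident", 10),
        OperatorSpec("res_c", "resident", 20),
        OperatorSpec("res_d", "resident", 25),
        OperatorSpec("fel_a", "fellow", 100),
        OperatorSpec("fel_b", "fellow", 125),
    ]
    return GeneratorConfig(
        cohorts=[
            CohortSpec("attending", att, n_attending_cases, attending_ops),
            CohortSpec("trainee", trn, n_trainee_cases, trainee_ops),
        ],
        sample_rate_hz=sample_rate_hz,
        seed=seed,
    )


def null_config(
    n_a: int = 15, n_b: int = 15, seed: int = 0, **kwargs
) -> GeneratorConfig:
    """Two cohorts with *identical* profiles (the type-I-error generator)."""
    cfg = preset_study_effects(n_a, n_b, seed=seed, **kwargs)
    att = cfg.cohorts[0]
    trn = cfg.cohorts[1]
    trn.profiles = {s: replace(p) for s, p in att.profiles.items()}
    return cfg


# ---------------------------------------------------------------------------
# calibration / recovery harnesses
# ---------------------------------------------------------------------------


def draw_case_metric(
    rng: np.random.Generator, n: int, family: str, jitter: Optional[CaseJitter] = None
) -> np.ndarray:
    """Per-case OPI values under the generator's between-case null model.

    Families mirror the case-level distributions the kinematic generator
    induces: ``speed`` (lognormal, cv = speed_cv), ``dexterity`` (lognormal,
    dominance_cv on top of two speed jitters), ``pct_active`` (logit-normal
    duty), ``workspace_rate`` (cubed sigma lognormal over a duty draw).
    """
    jit = jitter or CaseJitter()

    def ln(cv: float, size: int) -> np.ndarray:
        s = math.sqrt(math.log1p(cv * cv))
        return np.exp(s * rng.standard_normal(size) - 0.5 * s * s)

    if family == "speed":
        return 3.7 * ln(jit.speed_cv, n)
    if family == "dexterity":
        return 1.0 * ln(jit.dominance_cv, n) * ln(jit.speed_cv, n) / ln(jit.speed_cv, n)
    if family == "pct_active":
        return 100.0 * expit(logit(0.5) + jit.duty_logit_sd * rng.standard_normal(n))
    if family == "workspace_rate":
        sigma = 2.0 * ln(jit.sigma_cv, n)
        duty = expit(logit(0.5) + jit.duty_logit_sd * rng.standard_normal(n))
        return sigma ** 3 / (duty * 30.0)
    raise ValueError(f"unknown metric family {family!r}")


NULL_FAMILIES = ("speed", "dexterity", "pct_active", "workspace_rate")


def null_rejection_rates(
    n_a: int = 15,
    n_b: int = 15,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    families: Sequence[str] = NULL_FAMILIES,
) -> Dict[str, float]:
    """Type-I error of the normality-gated comparison under the null generator.

    Both groups are drawn from the same case-level distribution for each
    metric family; returns the fraction of replicates rejecting at ``alpha``.
    """
    from .stats import compare_groups

    hits = {f: 0 for f in families}
    for rep in range(reps):
        rng = _rng(seed, rep)
        for f in families:
            a = draw_case_metric(rng, n_a, f)
            b = draw_case_metric(rng, n_b, f)
            row = compare_groups(a, b, alpha=alpha)
            hits[f] += int(row.significant)
    return {f: hits[f] / reps for f in families}


def run_study(config: GeneratorConfig) -> List[ComparisonRow]:
    """Simulate all cohorts, compute OPIs, and compare attending vs trainee roles."""
    ds = simulate_cohorts(config)
    lex = Lexicon.default()
    opis = []
    for case in ds.cases:
        windows = build_step_windows(case, lex)
        opis.extend(compute_step_opis(case, windows))
    return build_comparison_table(
        opis, ["attending"], ["resident", "fellow"],
        label_a="attending", label_b="trainee",
    )


def direction_recovery_study(
    reps: int = 100,
    n_per_cohort: int = 20,
    seed: int = 0,
    duration_median_s: float = 120.0,
) -> pd.DataFrame:
    """Replicate the preset study ``reps`` times; tabulate per-cell outcomes.

    Returns one row per (replicate, step, metric) with the p-value, the
    significance flag, and the sign of the attending-minus-trainee median
    difference — the raw material for direction-recovery and concordance
    summaries.
    """
    records = []
    for rep in range(reps):
        rep_seed = int(np.random.SeedSequence((seed, rep)).generate_state(1)[0] % (2**31))
        cfg = preset_study_effects(
            n_per_cohort, n_per_cohort, seed=rep_seed, duration_median_s=duration_median_s
        )
        for row in run_study(cfg):
            diff = row.summary_a.median - row.summary_b.median
            records.append(
                {
                    "rep": rep, "step": row.step.value, "metric": row.metric,
                    "p_value": row.p_value, "significant": row.significant,
                    "sign": int(np.sign(diff)), "test_used": row.test_used,
                }
            )
    return pd.DataFrame(records)


def summarize_direction_recovery(study: pd.DataFrame) -> Dict[str, float]:
    """Headline rates from a :func:`direction_recovery_study` table."""
    reps = study["rep"].nunique()
    per_effect = []
    joint = np.ones(reps, dtype=bool)
    for step, metric, sign in PRESET_EFFECTS:
        cell = study[(study["step"] == step.value) & (study["metric"] == metric)]
        ok = (cell["significant"] & (cell["sign"] == sign)).to_numpy()
        per_effect.append(ok.mean())
        hit = np.zeros(reps, dtype=bool)
        hit[cell["rep"].to_numpy()] = ok
        joint &= hit
    null_cells = study[
        study["step"].isin([s.value for s in PRESET_NULL_STEPS])
        & study["metric"].isin(EFFECT_METRICS)
    ]
    # per-metric false-positive rate pooled across the five null steps
    null_rate = (
        null_cells.groupby("metric")["significant"].mean().max()
        if len(null_cells) else float("nan")
    )
    hs = study[study["step"] == Step.HAND_SEWN_ANASTOMOSIS.value]
    rate = hs[hs["metric"] == "workspace_rate_cm3_s"].set_index("rep")["significant"]
    perpl = hs[hs["metric"] == "workspace_per_pathlength_cm2"].set_index("rep")["significant"]
    common = rate.index.intersection(perpl.index)
    concord = float((rate.loc[common] == perpl.loc[common]).mean()) if len(common) else float("nan")
    return {
        "min_effect_recovery_rate": float(min(per_effect)),
        "joint_effect_recovery_rate": float(joint.mean()),
        "max_null_rejection_rate": float(null_rate),
        "workspace_normalization_concordance": concord,
    }


def parameter_recovery(
    duration_s: float = 600.0,
    seed: int = 0,
    n_seeds: int = 16,
) -> Dict[str, float]:
    """Mean relative / absolute recovery error of generator parameters.

    A single-step, jitter-free case is simulated per seed and pushed through
    the full pipeline; programmed values are compared with the OPI estimates:
    per-hand speed (relative), duty cycle (percentage points, against the
    per-hand active-time percentages), dominance scale (relative, inverted
    from the speed ratio since base speeds are equal), and motion scale
    (relative, from the console-sensitivity ratio).
    """
    prof = StepProfile(
        duration_median_s=duration_s, duration_log_sd=0.0,
        duty_cycle_dom=0.6, duty_cycle_nondom=0.6,
        speed_dom_cm_s=3.0, speed_nondom_cm_s=3.0,
        workspace_sigma_cm=2.0, dominance_scale=1.3, motion_scale=1.8,
    )
    ops = [OperatorSpec("solo", "attending", 100)]
    errs: Dict[str, List[float]] = {
        "speed_dom_rel": [], "speed_nondom_rel": [],
        "duty_dom_pp": [], "duty_nondom_pp": [],
        "dominance_rel": [], "motion_scale_rel": [],
    }
    for k in range(n_seeds):
        s = int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31))
        cfg = GeneratorConfig(
            cohorts=[CohortSpec("solo", {Step.DISSECTION: prof}, 1, ops)],
            seed=s, jitter=CaseJitter(0.0, 0.0, 0.0, 0.0),
        )
        case = simulate_case(cfg, "solo", 0)
        windows = build_step_windows(case)
        (o,) = compute_step_opis(case, windows)
        target_dom = prof.speed_dom_cm_s * prof.dominance_scale
        errs["speed_dom_rel"].append(abs(o.speed_dom_cm_s - target_dom) / target_dom)
        errs["speed_nondom_rel"].append(
            abs(o.speed_nondom_cm_s - prof.speed_nondom_cm_s) / prof.speed_nondom_cm_s
        )
        errs["duty_dom_pp"].append(o.pct_active_dom - 100.0 * prof.duty_cycle_dom)
        errs["duty_nondom_pp"].append(o.pct_active_nondom - 100.0 * prof.duty_cycle_nondom)
        dom_hat = (o.speed_dom_cm_s / o.speed_nondom_cm_s) * (
            prof.speed_nondom_cm_s / prof.speed_dom_cm_s
        )
        errs["dominance_rel"].append(abs(dom_hat - prof.dominance_scale) / prof.dominance_scale)
        scale_hat = 0.5 * (o.sensitivity_ratio_dom + o.sensitivity_ratio_nondom)
        errs["motion_scale_rel"].append(abs(scale_hat - prof.motion_scale) / prof.motion_scale)
    out = {k: float(np.mean(v)) for k, v in errs.items()}
    out["duty_dom_pp"] = float(abs(np.mean(errs["duty_dom_pp"])))
    out["duty_nondom_pp"] = float(abs(np.mean(errs["duty_nondom_pp"])))
    return out
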