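"""On-disk case bundle format: plain delimited text plus a small YAML header.

A bundle directory contains::

    kinematics.csv  time_s, operator_id, hand, source, x_cm, y_cm, z_cm
    activity.csv    operator_id, scope, start_s, end_s
    segments.csv    raw_label, operator_id, role, start_s, end_s
    roster.csv      operator_id, role, prior_robotic_cases, handedness
    meta.yaml       case_id, sample_rate_hz, metadata

Everything is comma-separated with one header line; floats are written with
17 significant digits so a write/read round trip is bit-exact for doubles.
The source recorder's native format is proprietary, so this clean-room layout
is the package's interchange format.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd
import yaml

from .ontology import STEP_INDEX
from .opi import StepOPI
from .records import (
    ActivityInterval,
    CaseRecord,
    OperatorInfo,
    StepSegment,
    Trajectory,
    ValidationError,
    validate_case,
)
from .stats import ComparisonRow

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
REQUIRED_FILES = ("kinematics.csv", "activity.csv", "segments.csv", "roster.csv", "meta.yaml")

KINEMATICS_COLUMNS = ["time_s", "operator_id", "hand", "source", "x_cm", "y_cm", "z_cm"]
ACTIVITY_COLUMNS = ["operator_id", "scope", "start_s", "end_s"]
SEGMENTS_COLUMNS = ["raw_label", "operator_id", "role", "start_s", "end_s"]
ROSTER_COLUMNS = ["operator_id", "role", "prior_robotic_cases", "handedness"]

OPI_COLUMNS = [
    "case_id", "step", "operator_id", "role",
    "total_task_duration_s", "active_console_time_s", "pct_active_console",
    "active_time_dom_s", "pct_active_dom", "active_time_nondom_s", "pct_active_nondom",
    "pathlength_dom_cm", "pathlength_nondom_cm", "speed_dom_cm_s", "speed_nondom_cm_s",
    "bimanual_dexterity", "workspace_volume_cm3", "workspace_rate_cm3_s",
    "workspace_per_pathlength_cm2", "sensitivity_ratio_dom", "sensitivity_ratio_nondom",
    "window_pathlength_dom_cm", "window_pathlength_nondom_cm",
]

COMPARISON_COLUMNS = [
    "step", "metric",
    "group_a", "n_a", "mean_a", "ci_low_a", "ci_high_a", "median_a", "q1_a", "q3_a",
    "group_b", "n_b", "mean_b", "ci_low_b", "ci_high_b", "median_b", "q1_b", "q3_b",
    "test_used", "p_value", "significant",
]


class BundleError(IOError):
    """A bundle directory is missing required files or is unreadable."""


def read_case_bundle(path: Union[str, Path]) -> CaseRecord:
    """Load and validate a case bundle directory into a :class:`CaseRecord`."""
    path = Path(path)
    for name in REQUIRED_FILES:
        if not (path / name).exists():
            raise BundleError(f"bundle {path}: missing required file {name}")
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    case_id = str(meta.get("case_id", path.name))
    rate = float(meta.get("sample_rate_hz", 50.0))
    metadata = {str(k): str(v) for k, v in (meta.get("metadata") or {}).items()}

    kin = pd.read_csv(path / "kinematics.csv", dtype={"operator_id": str}, float_precision="round_trip")
    trajectories: List[Trajectory] = []
    if len(kin):
        for (op, hand, source), grp in kin.groupby(
            ["operator_id", "hand", "source"], sort=True
        ):
            trajectories.append(
                Trajectory(
                    operator_id=str(op), hand=str(hand), source=str(source),
                    time_s=grp["time_s"].to_numpy(dtype=float),
                    xyz_cm=grp[["x_cm", "y_cm", "z_cm"]].to_numpy(dtype=float),
                )
            )

    act = pd.read_csv(path / "activity.csv", dtype={"operator_id": str}, float_precision="round_trip")
    activity = [
        ActivityInterval(str(r.operator_id), str(r.scope), float(r.start_s), float(r.end_s))
        for r in act.itertuples()
    ]
    seg = pd.read_csv(path / "segments.csv", dtype={"operator_id": str, "raw_label": str}, float_precision="round_trip")
    segments = [
        StepSegment(
            raw_label=str(r.raw_label), operator_id=str(r.operator_id),
            role=str(r.role), start_s=float(r.start_s), end_s=float(r.end_s),
        )
        for r in seg.itertuples()
    ]
    ros = pd.read_csv(path / "roster.csv", dtype={"operator_id": str})
    roster = {
        str(r.operator_id): OperatorInfo(
            role=str(r.role),
            prior_robotic_cases=int(r.prior_robotic_cases),
            handedness=str(r.handedness),
        )
        for r in ros.itertuples()
    }
    case = CaseRecord(
        case_id=case_id, trajectories=trajectories, activity=activity,
        segments=segments, roster=roster, metadata=metadata, sample_rate_hz=rate,
    )
    validate_case(case)
    return case


def write_case_bundle(case: CaseRecord, path: Union[str, Path]) -> None:
    """Serialize a validated case so that :func:`read_case_bundle` inverts it exactly."""
    if not case.trajectories:
        raise ValidationError(f"case {case.case_id}: nothing to analyze (no trajectories)")
    validate_case(case)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    frames = []
    for t in sorted(case.trajectories, key=lambda t: t.key):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": t.time_s,
                    "operator_id": t.operator_id,
                    "hand": t.hand,
                    "source": t.source,
                    "x_cm": t.xyz_cm[:, 0],
                    "y_cm": t.xyz_cm[:, 1],
                    "z_cm": t.xyz_cm[:, 2],
                }
            )
        )
    kin = pd.concat(frames, ignore_index=True)[KINEMATICS_COLUMNS]
    kin.to_csv(path / "kinematics.csv", index=False, float_format=_FLOAT_FMT)

    pd.DataFrame(
        [(a.operator_id, a.scope, a.start_s, a.end_s) for a in case.activity],
        columns=ACTIVITY_COLUMNS,
    ).to_csv(path / "activity.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [(s.raw_label, s.operator_id, s.role, s.start_s, s.end_s) for s in case.segments],
        columns=SEGMENTS_COLUMNS,
    ).to_csv(path / "segments.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        [
            (op, info.role, info.prior_robotic_cases, info.handedness)
            for op, info in sorted(case.roster.items())
        ],
        columns=ROSTER_COLUMNS,
    ).to_csv(path / "roster.csv", index=False)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "case_id": case.case_id,
                "sample_rate_hz": case.sample_rate_hz,
                "metadata": dict(case.metadata),
            },
            fh,
            sort_keys=True,
        )


def format_p(p: float) -> str:
    """Render a p-value to 3 decimals, '<0.001' below that threshold."""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


def write_opi_table(
    rows: Sequence[Union[StepOPI, ComparisonRow]], path: Union[str, Path]
) -> None:
    """Write StepOPI or ComparisonRow rows as delimited text with a fixed column order.

    StepOPI rows are ordered by (case_id, ontology step index); ComparisonRow
    order is preserved (the table builder already orders by step then metric).
    Mixed row types are a usage error; an empty list yields a header-only
    StepOPI file.
    """
    kinds = {type(r) for r in rows}
    if len(kinds) > 1:
        raise ValueError(f"mixed row types: {sorted(k.__name__ for k in kinds)}")
    path = Path(path)
    if not rows or kinds == {StepOPI}:
        lines = [",".join(OPI_COLUMNS)]
        for r in sorted(rows, key=lambda r: (r.case_id, STEP_INDEX[r.step])):
            vals = []
            for col in OPI_COLUMNS:
                v = getattr(r, col)
                vals.append(v.value if hasattr(v, "value") else _fmt(v))
            lines.append(",".join(vals))
    else:
        lines = [",".join(COMPARISON_COLUMNS)]
        for r in rows:
            sa, sb = r.summary_a, r.summary_b
            vals = [
                r.step.value if r.step is not None else "",
                r.metric or "",
                sa.group_label, str(sa.n), _fmt(sa.mean), _fmt(sa.ci_low), _fmt(sa.ci_high),
                _fmt(sa.median), _fmt(sa.q1), _fmt(sa.q3),
                sb.group_label, str(sb.n), _fmt(sb.mean), _fmt(sb.ci_low), _fmt(sb.ci_high),
                _fmt(sb.median), _fmt(sb.q1), _fmt(sb.q3),
                r.test_used, format_p(r.p_value), str(bool(r.significant)),
            ]
            lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")


def read_opi_table(path: Union[str, Path]) -> List[StepOPI]:
    """Load a StepOPI table written by :func:`write_opi_table`."""
    from .ontology import Step

    df = pd.read_csv(path, dtype={"case_id": str, "operator_id": str})
    rows: List[StepOPI] = []
    for r in df.itertuples(index=False):
        kw = {}
        for col in OPI_COLUMNS:
            v = getattr(r, col)
            if col == "step":
                kw[col] = Step(v)
            elif col in ("case_id", "operator_id", "role"):
                kw[col] = str(v)
            else:
                kw[col] = None if pd.isna(v) else float(v)
        rows.append(StepOPI(**kw))
    return rows
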