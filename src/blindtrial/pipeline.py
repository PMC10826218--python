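"""End-to-end blinding analysis of respondent-level trial data.

The pipeline ingests a long-format CSV (one row per respondent-role:
the participant's own guess plus one guess per outcome assessor), validates
it, and produces a report mirroring a trial's primary/secondary outcome
table: per-arm Bang blinding indices with Wald CIs, the summed study-level
Bang index, James indices with bootstrap CIs, adequacy classifications,
range-of-motion contrasts (Welch intervals) when raw ROM values are present,
and optional subgroup estimates. Blinding is analysed by intention to treat:
every randomised respondent is analysed as allocated, and the report records
that the analysed count equals the randomised count.

CSV schema (UTF-8, header required)::

    participant_id:str, role:{participant,assessor_1,assessor_2,assessor_3},
    arm:{active,control}, stratum:{0,1} (optional),
    response:{strongly_active,somewhat_active,dont_know,
              somewhat_control,strongly_control},
    rom_pre_flexion, rom_post_flexion, rom_pre_extension, rom_post_extension
    (floats, degrees, optional)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .blinding import (
    ARMS,
    ArmResponseTable,
    BlindingEstimate,
    GuessCategory,
    bang_estimate,
    classify_blinding,
    james_estimate,
    round_half_away,
    summed_bang,
)
from .reconstruction import ROLES, ROM_COLUMNS
from .summaries import GroupSummary, welch_mean_diff

__all__ = [
    "BlindingDataError",
    "REQUIRED_COLUMNS",
    "read_responses_csv",
    "write_responses_csv",
    "validate_dataset",
    "run_analysis",
    "render_report",
    "AnalysisReport",
]

REQUIRED_COLUMNS = ("participant_id", "role", "arm", "response")
ASSESSOR_ROLES = tuple(r for r in ROLES if r.startswith("assessor"))
_VALID_RESPONSES = {c.value for c in GuessCategory}

try:
    __version__ = _pkg_version("blindtrial")
except PackageNotFoundError:  # pragma: no cover - source tree without install
    __version__ = "0.0.0"


class BlindingDataError(ValueError):
    """Input validation failure, with machine-readable details."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}

    def to_json(self) -> str:
        return json.dumps({"error": str(self), **self.details}, sort_keys=True)


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a respondent-level table.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise BlindingDataError(f"missing required columns: {missing}",
                                {"missing_columns": missing})
    df = df.copy().reset_index(drop=True)
    df["participant_id"] = df["participant_id"].astype(str)
    for col in ("role", "arm", "response"):
        df[col] = df[col].astype(str).str.strip()

    def _bad_rows(mask: pd.Series) -> list[int]:
        return [int(i) + 1 for i in df.index[mask]]

    bad = ~df["arm"].isin(ARMS)
    if bad.any():
        rows = _bad_rows(bad)
        raise BlindingDataError(f"invalid arm token at rows {rows}",
                                {"rows": rows, "column": "arm"})
    bad = ~df["role"].isin(ROLES)
    if bad.any():
        rows = _bad_rows(bad)
        raise BlindingDataError(f"invalid role token at rows {rows}",
                                {"rows": rows, "column": "role"})
    bad = ~df["response"].isin(_VALID_RESPONSES)
    if bad.any():
        rows = _bad_rows(bad)
        raise BlindingDataError(
            f"invalid response token at rows {rows}: "
            f"{sorted(df.loc[bad, 'response'].unique())}",
            {"rows": rows, "column": "response"})
    dup = df.duplicated(subset=["participant_id", "role"], keep=False)
    if dup.any():
        rows = _bad_rows(dup)
        raise BlindingDataError(f"duplicate (participant_id, role) pairs at rows {rows}",
                                {"rows": rows})
    arms_per_pid = df.groupby("participant_id")["arm"].nunique()
    conflicted = arms_per_pid[arms_per_pid > 1].index.tolist()
    if conflicted:
        raise BlindingDataError(
            f"participants with conflicting arm across roles: {conflicted}",
            {"participants": conflicted})
    if "stratum" in df.columns:
        df["stratum"] = pd.to_numeric(df["stratum"], errors="coerce")
    for col in ROM_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_responses_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a respondent-level CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    return validate_dataset(df)


def write_responses_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a respondent-level table with a stable column order."""
    cols = [c for c in ("participant_id", "role", "arm", "stratum", "response",
                        *ROM_COLUMNS) if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def _table_for(df: pd.DataFrame, roles: Iterable[str], arm: str) -> ArmResponseTable:
    sub = df[df["role"].isin(list(roles)) & (df["arm"] == arm)]
    return ArmResponseTable.from_responses(arm, sub["response"].tolist())


def _estimate_dict(e: BlindingEstimate, role: str, arm: str | None) -> dict:
    return {
        "role": role,
        "arm": arm,
        "index_type": e.index_type,
        "point": e.point,
        "variance": e.variance,
        "ci_lower": e.ci_lower,
        "ci_upper": e.ci_upper,
        "level": e.level,
        "n": e.n,
        "undefined": e.undefined,
        "classification": classify_blinding(e),
        "display": format_estimate(e),
    }


def format_estimate(e: BlindingEstimate, ndigits: int = 2) -> str:
    """Render an estimate the way outcome tables print it; NaN when undefinable."""
    if e.undefined:
        return "NaN"
    fmt = f"{{:.{ndigits}f}}"
    p = fmt.format(round_half_away(e.point, ndigits))
    lo = fmt.format(round_half_away(e.ci_lower, ndigits))
    hi = fmt.format(round_half_away(e.ci_upper, ndigits))
    return f"{p} ({lo} to {hi})"


def _blinding_block(df: pd.DataFrame, roles: Iterable[str], label: str,
                    level: float, n_resamples: int,
                    rng: np.random.Generator) -> dict:
    roles = list(roles)
    sub = df[df["role"].isin(roles)]
    if sub.empty:
        return {"role": label, "available": False}
    active = _table_for(df, roles, "active")
    control = _table_for(df, roles, "control")
    est_a = bang_estimate(active, level)
    est_c = bang_estimate(control, level)
    est_sum = summed_bang(est_a, est_c)
    est_james = james_estimate(active, control, level=level,
                               n_resamples=n_resamples, seed=rng)
    return {
        "role": label,
        "available": True,
        "bang_active": _estimate_dict(est_a, label, "active"),
        "bang_control": _estimate_dict(est_c, label, "control"),
        "bang_summed": _estimate_dict(est_sum, label, None),
        "james": _estimate_dict(est_james, label, None),
    }


def _rom_contrasts(df: pd.DataFrame, level: float) -> list[dict] | None:
    part = df[df["role"] == "participant"]
    if part.empty or not all(c in part.columns for c in ROM_COLUMNS):
        return None
    if part[list(ROM_COLUMNS)].isna().all().all():
        return None
    derived = pd.DataFrame({
        "arm": part["arm"].to_numpy(),
        "post_flexion": part["rom_post_flexion"].to_numpy(),
        "post_extension": part["rom_post_extension"].to_numpy(),
        "post_total": (part["rom_post_flexion"] + part["rom_post_extension"]).to_numpy(),
        "change_flexion": (part["rom_post_flexion"] - part["rom_pre_flexion"]).to_numpy(),
        "change_extension": (part["rom_post_extension"] - part["rom_pre_extension"]).to_numpy(),
        "change_total": (
            part["rom_post_flexion"] + part["rom_post_extension"]
            - part["rom_pre_flexion"] - part["rom_pre_extension"]).to_numpy(),
    })
    out = []
    for outcome in ("post_flexion", "post_extension", "post_total",
                    "change_flexion", "change_extension", "change_total"):
        groups = {}
        for arm in ARMS:
            vals = derived.loc[derived["arm"] == arm, outcome].dropna()
            if len(vals) < 2:
                groups = None
                break
            groups[arm] = GroupSummary.from_values(vals)
        if groups is None:
            continue
        md = welch_mean_diff(groups["active"], groups["control"], level)
        out.append({
            "outcome": outcome,
            "active": dataclasses.asdict(groups["active"]),
            "control": dataclasses.asdict(groups["control"]),
            "md": md.md,
            "ci_lower": md.ci_lower,
            "ci_upper": md.ci_upper,
            "df": md.df,
            "display": (f"MD, {round_half_away(md.md, 1):.1f} "
                        f"({round_half_away(md.ci_lower, 1):.1f} to "
                        f"{round_half_away(md.ci_upper, 1):.1f})"),
        })
    return out or None


@dataclass
class AnalysisReport:
    """Structured result of :func:`run_analysis` (Table-2-style content)."""

    n_randomised: int
    n_analysed: int
    level: float
    groups: dict = field(default_factory=dict)
    rom_contrasts: list | None = None
    subgroups: dict | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonify(dataclasses.asdict(self))


def _jsonify(obj):
    """Recursively replace NaN by None so the JSON rendering is strict."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def _input_hash(df: pd.DataFrame) -> str:
    canonical = df.sort_values(["participant_id", "role"], kind="stable")
    payload = canonical.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def run_analysis(df: pd.DataFrame, level: float = 0.95, by: str | None = None,
                 seed: int | None = 0, n_resamples: int = 10_000) -> AnalysisReport:
    """Compute the full blinding report from a respondent-level table.

    ``by`` names a column (e.g. ``stratum``) for additional per-level
    participant Bang estimates. ``seed`` drives the James bootstrap CIs.
    """
    df = validate_dataset(df)
    if df.empty:
        raise BlindingDataError("empty dataset: nothing to analyse")
    rng = np.random.default_rng(seed)
    n_part = int(df["participant_id"].nunique())

    groups: dict[str, dict] = {}
    groups["participant"] = _blinding_block(df, ["participant"], "participant",
                                            level, n_resamples, rng)
    for role in ASSESSOR_ROLES:
        groups[role] = _blinding_block(df, [role], role, level, n_resamples, rng)
    present_assessors = [r for r in ASSESSOR_ROLES if groups[r].get("available")]
    if present_assessors:
        groups["assessors_pooled"] = _blinding_block(
            df, present_assessors, "assessors_pooled", level, n_resamples, rng)
    else:
        groups["assessors_pooled"] = {"role": "assessors_pooled", "available": False}

    subgroups = None
    if by is not None:
        if by not in df.columns:
            raise BlindingDataError(f"unknown grouping column {by!r}", {"column": by})
        subgroups = {}
        part = df[df["role"] == "participant"]
        for value in sorted(part[by].dropna().unique(), key=str):
            sub = df[df[by] == value]
            subgroups[str(value)] = _blinding_block(
                sub, ["participant"], f"participant[{by}={value}]",
                level, n_resamples, rng)

    report = AnalysisReport(
        n_randomised=n_part,
        n_analysed=n_part,  # intention to treat: all randomised are analysed
        level=level,
        groups=groups,
        rom_contrasts=_rom_contrasts(df, level),
        subgroups=subgroups,
        metadata={
            "software": "blindtrial",
            "version": __version__,
            "seed": seed,
            "n_resamples": n_resamples,
            "input_hash": _input_hash(df),
        },
    )
    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_GROUP_TITLES = {
    "participant": "Participants",
    "assessor_1": "Assessor 1",
    "assessor_2": "Assessor 2",
    "assessor_3": "Assessor 3",
    "assessors_pooled": "Outcome assessors (pooled)",
}


def _text_lines(report: AnalysisReport) -> list[str]:
    pct = f"{report.level * 100:g}%"
    lines = [
        "Blinding analysis report",
        f"Randomised: {report.n_randomised}; analysed (intention to treat): "
        f"{report.n_analysed}; {pct} confidence intervals",
        "",
    ]
    for key, block in report.groups.items():
        title = _GROUP_TITLES.get(key, key)
        lines.append(title)
        if not block.get("available"):
            lines.append("  (no responses recorded for this role)")
            lines.append("")
            continue
        for slot, label in (("bang_active", "Bang BI, active arm "),
                            ("bang_control", "Bang BI, control arm"),
                            ("bang_summed", "Summed Bang BI      "),
                            ("james", "James BI            ")):
            e = block[slot]
            lines.append(f"  {label}: {e['display']}  [{e['classification']}]")
        lines.append("")
    if report.rom_contrasts:
        lines.append("Range of motion (degrees), active vs control")
        for c in report.rom_contrasts:
            lines.append(f"  {c['outcome']:<17}: {c['display']}")
        lines.append("")
    if report.subgroups:
        lines.append("Participant subgroups")
        for value, block in report.subgroups.items():
            lines.append(f"  level {value}:")
            if not block.get("available"):
                lines.append("    (no responses)")
                continue
            for slot in ("bang_active", "bang_control", "bang_summed"):
                e = block[slot]
                lines.append(f"    {e['index_type']} {e['arm'] or ''}: {e['display']}")
        lines.append("")
    return lines


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialise a report: deterministic ``json``, or ``text``/``markdown``."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True, allow_nan=False)
    if format in ("text", "markdown"):
        lines = _text_lines(report)
        if format == "markdown":
            lines = [f"# {lines[0]}", *lines[1:]]
        return "\n".join(lines).rstrip() + "\n"
    raise ValueError(f"unknown report format {format!r}")
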