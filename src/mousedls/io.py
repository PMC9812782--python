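"""File formats: tidy measurement CSV, YAML configuration, report JSON/CSV.

The single measurement format is a long/tidy, comma-separated, UTF-8 file
with a mandatory header ``animal_id,group,sex,readout,session_day,value``
— one row per animal x read-out x session.  Unknown columns are preserved;
group labels are matched case-insensitively against interest/control.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .types import (
    CohortDataset,
    ConfigError,
    Direction,
    DLSError,
    DLSReport,
    Group,
    MEASUREMENT_COLUMNS,
    MESPConfig,
    RDoCDomain,
    ReadoutCriterion,
    ReadoutSpec,
    Sex,
)

__all__ = [
    "MeasurementFileError",
    "read_measurements",
    "write_measurements",
    "read_config",
    "write_config",
    "load_cohort",
    "write_report",
    "read_report",
]


class MeasurementFileError(DLSError):
    """Aggregated per-line diagnostics for a malformed measurement file."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        super().__init__(
            f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )


_GROUP_ALIASES = {g.value: g for g in Group}
_SEX_ALIASES = {s.value: s for s in Sex}
_SEX_ALIASES.update({"f": Sex.FEMALE, "m": Sex.MALE, "": Sex.UNSPECIFIED, "na": Sex.UNSPECIFIED})


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Parse a tidy measurement CSV into a typed frame.

    Group and sex strings are matched case-insensitively; rows with a
    non-finite or unparsable value, an unknown group, or a negative session
    day are collected and reported together in one ``MeasurementFileError``
    naming each offending line (1-based, header = line 1).
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise MeasurementFileError(
            path, [f"missing mandatory column(s): {', '.join(missing)}"]
        )
    problems: list[str] = []
    n = len(raw)
    groups = np.empty(n, dtype=object)
    sexes = np.empty(n, dtype=object)
    days = np.empty(n, dtype=float)
    values = np.empty(n, dtype=float)
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # 1-based file line, after the header
        g = str(getattr(row, "group")).strip().lower()
        if g in _GROUP_ALIASES:
            groups[i] = _GROUP_ALIASES[g].value
        else:
            problems.append(f"line {line}: unknown group {getattr(row, 'group')!r}")
            groups[i] = Group.CONTROL.value
        s = str(getattr(row, "sex")).strip().lower()
        if s in _SEX_ALIASES:
            sexes[i] = _SEX_ALIASES[s].value
        else:
            problems.append(f"line {line}: unknown sex {getattr(row, 'sex')!r}")
            sexes[i] = Sex.UNSPECIFIED.value
        try:
            days[i] = float(getattr(row, "session_day"))
        except ValueError:
            problems.append(
                f"line {line}: unparsable session_day {getattr(row, 'session_day')!r}"
            )
            days[i] = np.nan
        else:
            if days[i] < 0:
                problems.append(f"line {line}: negative session_day {days[i]:g}")
        try:
            values[i] = float(getattr(row, "value"))
        except ValueError:
            problems.append(f"line {line}: unparsable value {getattr(row, 'value')!r}")
            values[i] = np.nan
        else:
            if not np.isfinite(values[i]):
                problems.append(f"line {line}: non-finite value {getattr(row, 'value')!r}")
    if problems:
        raise MeasurementFileError(path, problems)
    frame = pd.DataFrame(
        {
            "animal_id": raw["animal_id"].astype(str),
            "group": groups,
            "sex": sexes,
            "readout": raw["readout"].astype(str),
            "session_day": days,
            "value": values,
        }
    )
    for extra in raw.columns:
        if extra not in MEASUREMENT_COLUMNS:
            frame[extra] = raw[extra]
    return frame


def write_measurements(dataset: CohortDataset | pd.DataFrame, path: str | Path) -> None:
    """Write measurements as the tidy CSV dialect."""
    frame = dataset.frame if isinstance(dataset, CohortDataset) else dataset
    frame.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _parse_spec(entry: dict[str, Any]) -> ReadoutSpec:
    try:
        name = entry["name"]
    except KeyError:
        raise ConfigError(f"read-out entry without a name: {entry!r}") from None
    try:
        criterion = ReadoutCriterion(str(entry["criterion"]).lower())
    except (KeyError, ValueError):
        raise ConfigError(
            f"read-out {name!r}: missing or unknown criterion {entry.get('criterion')!r}"
        ) from None
    try:
        direction = Direction(str(entry["direction"]).lower())
    except (KeyError, ValueError):
        raise ConfigError(
            f"read-out {name!r}: missing or unknown direction {entry.get('direction')!r}"
        ) from None
    try:
        domain = RDoCDomain(str(entry.get("rdoc_domain", "negative_valence")).lower())
    except ValueError:
        raise ConfigError(
            f"read-out {name!r}: unknown rdoc_domain {entry.get('rdoc_domain')!r}"
        ) from None
    return ReadoutSpec(
        readout=str(name),
        criterion=criterion,
        direction=direction,
        rdoc_domain=domain,
        symptom_label=str(entry.get("symptom", entry.get("symptom_label", ""))),
        longitudinal=bool(entry.get("longitudinal", False)),
    )


def read_config(path: str | Path) -> tuple[list[ReadoutSpec], MESPConfig]:
    """Read the YAML configuration: read-out specs plus MESP thresholds.

    Unspecified thresholds take the framework defaults (0.05, 0.5, 0.0625,
    7, 3, 4).  Exactly one anhedonia symptom label is required — it is the
    mandatory core symptom.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        mesp = MESPConfig(**(doc.get("mesp") or {}))
    except TypeError as exc:
        raise ConfigError(f"{path}: invalid mesp section: {exc}") from None
    entries = doc.get("readouts") or []
    if not entries:
        raise ConfigError(f"{path}: no read-outs configured")
    specs = [_parse_spec(e) for e in entries]
    names = [s.readout for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError(f"{path}: duplicate read-out names")
    anhedonia = {s.symptom_label for s in specs if s.criterion is ReadoutCriterion.ANHEDONIA}
    if len(anhedonia) == 0:
        raise ConfigError(
            f"{path}: no anhedonia read-out configured (anhedonia is the core symptom)"
        )
    if len(anhedonia) > 1:
        raise ConfigError(
            f"{path}: multiple anhedonia symptom labels: {sorted(anhedonia)}"
        )
    return specs, mesp


def write_config(
    specs: list[ReadoutSpec], config: MESPConfig, path: str | Path
) -> None:
    """Write a configuration YAML matching ``read_config``."""
    doc = {
        "mesp": config.to_dict(),
        "readouts": [
            {
                "name": s.readout,
                "criterion": s.criterion.value,
                "direction": s.direction.value,
                "rdoc_domain": s.rdoc_domain.value,
                "symptom": s.symptom_label,
                "longitudinal": s.longitudinal,
            }
            for s in specs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_cohort(
    measurements_path: str | Path, config_path: str | Path
) -> tuple[CohortDataset, MESPConfig]:
    """Read measurements and configuration into a ready-to-classify pair."""
    frame = read_measurements(measurements_path)
    specs, config = read_config(config_path)
    return CohortDataset(frame, specs), config


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(report: DLSReport, path: str | Path, format: str = "json") -> None:
    """Serialize a report as structured JSON (round-trippable) or flat CSV
    (one row per evidence item)."""
    path = Path(path)
    if format == "json":
        path.write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=False), encoding="utf-8"
        )
        return
    if format == "csv":
        rows = []
        for c in report.criteria:
            base = {
                "verdict": report.verdict.value,
                "criterion": c.criterion.value,
                "status": c.status.value,
            }
            if not c.evidence:
                rows.append({**base})
            for e in c.evidence:
                rows.append(
                    {
                        **base,
                        "readout": e.readout,
                        "p_value": e.p_value,
                        "effect_size": e.effect_size,
                        "effect_kind": e.effect_kind.value,
                        "direction_consistent": e.direction_consistent,
                        "passes": e.passes,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")
        return
    raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> DLSReport:
    """Read back a JSON report written by ``write_report``."""
    with open(path, encoding="utf-8") as fh:
        return DLSReport.from_dict(json.load(fh))
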