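"""Domain types and dataset validation for DLS assessment.

The depression-like syndrome (DLS) framework assesses a group of interest
against a healthy control group on four criteria — minimum duration,
sociofunctional impairment, biological features, and depressive-like
symptoms — each decided by the MESP rule (minimum effect size plus p value).
This module holds the shared vocabulary: measurement rows, read-out
configuration, the MESP thresholds, and the report structures produced by
the classifier.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Sex",
    "Direction",
    "ReadoutCriterion",
    "RDoCDomain",
    "DLSCriterion",
    "Status",
    "Verdict",
    "Severity",
    "EffectKind",
    "MultipleTesting",
    "Measurement",
    "ControlReference",
    "ReadoutSpec",
    "MESPConfig",
    "MESPResult",
    "CriterionResult",
    "DLSReport",
    "CohortDataset",
    "ValidationFinding",
    "validate_dataset",
    "DLSError",
    "ConfigError",
    "DegenerateControlError",
    "UnbalancedPanelError",
    "DatasetValidationError",
    "MEASUREMENT_COLUMNS",
]

MEASUREMENT_COLUMNS = ("animal_id", "group", "sex", "readout", "session_day", "value")


class DLSError(Exception):
    """Base class for all package errors."""


class ConfigError(DLSError):
    """Invalid read-out specification or threshold configuration."""


class DegenerateControlError(DLSError):
    """Control group variance is (numerically) zero for a read-out."""


class UnbalancedPanelError(DLSError):
    """A longitudinal read-out is missing animal x session cells."""


class DatasetValidationError(DLSError):
    """Raised when classification is attempted on an invalid dataset."""

    def __init__(self, findings: list["ValidationFinding"]):
        self.findings = findings
        super().__init__(
            "dataset failed validation: " + "; ".join(f.message for f in findings)
        )


class Group(str, enum.Enum):
    INTEREST = "interest"
    CONTROL = "control"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNSPECIFIED = "unspecified"


class Direction(str, enum.Enum):
    """Impairment direction of a read-out.

    Sucrose preference falls with anhedonia (LOWER_IS_IMPAIRED); plasma
    corticosterone rises under chronic stress (HIGHER_IS_IMPAIRED).
    """

    HIGHER_IS_IMPAIRED = "higher_is_impaired"
    LOWER_IS_IMPAIRED = "lower_is_impaired"


class ReadoutCriterion(str, enum.Enum):
    """Which DLS criterion a read-out contributes evidence to."""

    DURATION_PROXY = "duration_proxy"
    SOCIOFUNCTIONAL = "sociofunctional"
    BIOLOGICAL = "biological"
    ANHEDONIA = "anhedonia"
    ADDITIONAL_SYMPTOM = "additional_symptom"


class RDoCDomain(str, enum.Enum):
    """Research Domain Criteria domain tag (pass-through metadata)."""

    POSITIVE_VALENCE = "positive_valence"
    NEGATIVE_VALENCE = "negative_valence"
    AROUSAL_REGULATION = "arousal_regulation"
    SOCIAL_PROCESSES = "social_processes"
    COGNITION = "cognition"
    SENSORIMOTOR = "sensorimotor"


class DLSCriterion(str, enum.Enum):
    """The four syndrome criteria assessed by the classifier."""

    DURATION = "duration"
    SOCIOFUNCTIONAL = "sociofunctional"
    BIOLOGICAL = "biological"
    SYMPTOMS = "symptoms"


class Status(str, enum.Enum):
    PRESENT = "present"
    INCONSISTENT = "inconsistent"
    ABSENT = "absent"
    NOT_ASSESSED = "not_assessed"


class Verdict(str, enum.Enum):
    PRESENT = "present"
    INCOMPLETE = "incomplete"
    ABSENT = "absent"


class Severity(str, enum.Enum):
    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class EffectKind(str, enum.Enum):
    COHENS_D = "cohens_d"
    COHENS_F2 = "cohens_f2"


class MultipleTesting(str, enum.Enum):
    NONE = "none"
    HOLM_WITHIN_CRITERION = "holm_within_criterion"


@dataclass(frozen=True)
class Measurement:
    """One observation of one animal on one read-out at one session."""

    animal_id: str
    group: Group
    sex: Sex
    readout: str
    session_day: float
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"measurement value must be finite, got {self.value!r}")
        if self.session_day < 0:
            raise ValueError(f"session_day must be >= 0, got {self.session_day!r}")


@dataclass(frozen=True)
class ControlReference:
    """Control-group mean and SD anchoring the z-test for one read-out/session."""

    readout: str
    session_day: float
    mu: float
    sigma: float
    n_control: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateControlError(
                f"control SD for read-out {self.readout!r} at day "
                f"{self.session_day} must be > 0, got {self.sigma!r}"
            )
        if self.n_control < 2:
            raise ValueError("a control reference needs at least 2 animals")


@dataclass(frozen=True)
class ReadoutSpec:
    """Configuration of one read-out: criterion, direction, RDoC tag.

    ``symptom_label`` groups read-outs measuring the same depressive-like
    symptom (e.g. sucrose preference and the urine sniffing test both probe
    anhedonia). ``longitudinal`` marks read-outs sampled repeatedly that
    feed the minimum-duration criterion.
    """

    readout: str
    criterion: ReadoutCriterion
    direction: Direction
    rdoc_domain: RDoCDomain
    symptom_label: str = ""
    longitudinal: bool = False

    def __post_init__(self) -> None:
        if self.criterion is ReadoutCriterion.DURATION_PROXY and not self.longitudinal:
            raise ConfigError(
                f"duration-proxy read-out {self.readout!r} must be longitudinal"
            )


@dataclass(frozen=True)
class MESPConfig:
    """Decision thresholds of the DLS algorithm.

    Defaults are the framework's recommended constants: alpha 0.05, Cohen's
    d >= 0.5, Cohen's f^2 >= 0.0625 (0.25 squared, taken literally; override
    to 0.15 for the conventional "moderate" f^2), a 7-day minimum phenotype
    duration, anhedonia plus 3 additional symptoms, and 4 criteria required
    for a syndrome verdict.
    """

    alpha: float = 0.05
    d_threshold: float = 0.5
    f2_threshold: float = 0.0625
    min_duration_days: float = 7.0
    n_additional_symptoms: int = 3
    n_criteria_required: int = 4
    multiple_testing: MultipleTesting = MultipleTesting.NONE
    allow_augmentation: bool = False
    sd_tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("d_threshold", "f2_threshold", "min_duration_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_additional_symptoms < 0:
            raise ConfigError("n_additional_symptoms must be >= 0")
        if self.n_criteria_required < 1:
            raise ConfigError("n_criteria_required must be >= 1")
        if isinstance(self.multiple_testing, str) and not isinstance(
            self.multiple_testing, MultipleTesting
        ):
            object.__setattr__(
                self, "multiple_testing", MultipleTesting(self.multiple_testing)
            )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["multiple_testing"] = self.multiple_testing.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MESPConfig":
        d = dict(d)
        if "multiple_testing" in d:
            d["multiple_testing"] = MultipleTesting(d["multiple_testing"])
        return cls(**d)


@dataclass(frozen=True)
class MESPResult:
    """Outcome of one MESP comparison (one read-out or one composite z).

    ``passes`` is true only when the p value clears alpha, the effect
    magnitude clears its threshold, and the effect points toward impairment.
    """

    readout: str
    p_value: float
    effect_size: float
    effect_kind: EffectKind
    direction_consistent: bool
    passes: bool

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["effect_kind"] = self.effect_kind.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MESPResult":
        d = dict(d)
        d["effect_kind"] = EffectKind(d["effect_kind"])
        return cls(**d)


@dataclass(frozen=True)
class CriterionResult:
    """Status of one DLS criterion with its MESP evidence and disclosures."""

    criterion: DLSCriterion
    status: Status
    evidence: tuple[MESPResult, ...] = ()
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        return {
            "criterion": self.criterion.value,
            "status": self.status.value,
            "evidence": [e.to_dict() for e in self.evidence],
            "notes": list(self.notes),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CriterionResult":
        return cls(
            criterion=DLSCriterion(d["criterion"]),
            status=Status(d["status"]),
            evidence=tuple(MESPResult.from_dict(e) for e in d["evidence"]),
            notes=tuple(d["notes"]),
        )


SCHEMA_VERSION = "1.0"


@dataclass(frozen=True)
class DLSReport:
    """Full classification report for one cohort.

    ``per_animal_severity`` grades every group-of-interest animal by its
    composite z (control-SD units): none / mild (0,1] / moderate (1,2] /
    severe (>2). ``severity_if_present`` repeats the map only when the
    group-level verdict is PRESENT, for users who read severity as
    conditional on the syndrome.
    """

    verdict: Verdict
    criteria: tuple[CriterionResult, ...]
    per_animal_severity: Mapping[str, Severity]
    per_animal_composite_z: Mapping[str, float]
    severity_if_present: Mapping[str, Severity]
    config: MESPConfig
    disclosures: tuple[str, ...] = ()
    metadata: Mapping[str, Any] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def criterion(self, which: DLSCriterion | str) -> CriterionResult:
        which = DLSCriterion(which)
        for c in self.criteria:
            if c.criterion is which:
                return c
        raise KeyError(which)

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "verdict": self.verdict.value,
            "criteria": [c.to_dict() for c in self.criteria],
            "per_animal_severity": {
                k: v.value for k, v in self.per_animal_severity.items()
            },
            "per_animal_composite_z": dict(self.per_animal_composite_z),
            "severity_if_present": {
                k: v.value for k, v in self.severity_if_present.items()
            },
            "config": self.config.to_dict(),
            "disclosures": list(self.disclosures),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DLSReport":
        return cls(
            verdict=Verdict(d["verdict"]),
            criteria=tuple(CriterionResult.from_dict(c) for c in d["criteria"]),
            per_animal_severity={
                k: Severity(v) for k, v in d["per_animal_severity"].items()
            },
            per_animal_composite_z=dict(d["per_animal_composite_z"]),
            severity_if_present={
                k: Severity(v) for k, v in d["severity_if_present"].items()
            },
            config=MESPConfig.from_dict(d["config"]),
            disclosures=tuple(d["disclosures"]),
            metadata=dict(d["metadata"]),
            schema_version=d.get("schema_version", SCHEMA_VERSION),
        )


class CohortDataset:
    """Long-format measurements for one interest group vs one control group.

    Parameters
    ----------
    frame : pandas.DataFrame
        Tidy table with columns ``animal_id, group, sex, readout,
        session_day, value`` — one row per animal x read-out x session.
    specs : iterable of ReadoutSpec
        Configuration of every read-out appearing in ``frame``.
    metadata : dict, optional
        Free-form study metadata (e.g. the induction protocol applied),
        echoed into reports.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        specs: Iterable[ReadoutSpec],
        metadata: Mapping[str, Any] | None = None,
    ):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement frame is missing columns: {missing}")
        frame = frame.copy()
        frame["animal_id"] = frame["animal_id"].astype(str)
        # validate/normalize categorical columns via their unique values only
        for col, enum_cls in (("group", Group), ("sex", Sex)):
            mapping = {raw: enum_cls(raw).value for raw in frame[col].unique()}
            frame[col] = frame[col].map(mapping)
        frame["readout"] = frame["readout"].astype(str)
        frame["session_day"] = frame["session_day"].astype(float)
        frame["value"] = frame["value"].astype(float)
        self.frame = frame.reset_index(drop=True)
        self.specs: dict[str, ReadoutSpec] = {s.readout: s for s in specs}
        self.metadata: dict[str, Any] = dict(metadata or {})

    @classmethod
    def from_measurements(
        cls,
        measurements: Iterable[Measurement],
        specs: Iterable[ReadoutSpec],
        metadata: Mapping[str, Any] | None = None,
    ) -> "CohortDataset":
        rows = [
            (m.animal_id, m.group.value, m.sex.value, m.readout, m.session_day, m.value)
            for m in measurements
        ]
        frame = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
        return cls(frame, specs, metadata)

    def measurements(self) -> list[Measurement]:
        return [
            Measurement(
                animal_id=r.animal_id,
                group=Group(r.group),
                sex=Sex(r.sex),
                readout=r.readout,
                session_day=r.session_day,
                value=r.value,
            )
            for r in self.frame.itertuples(index=False)
        ]

    def animals(self, group: Group | str | None = None) -> list[str]:
        f = self.frame
        if group is not None:
            f = f[f["group"] == Group(group).value]
        return sorted(f["animal_id"].unique())

    def longitudinal_readouts(self) -> list[str]:
        return sorted(r for r, s in self.specs.items() if s.longitudinal)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortDataset({len(self.frame)} measurements, "
            f"{len(self.specs)} read-outs, "
            f"{len(self.animals(Group.INTEREST))} interest / "
            f"{len(self.animals(Group.CONTROL))} control animals)"
        )


@dataclass(frozen=True)
class ValidationFinding:
    """One violated dataset invariant; ``level`` is 'error' or 'warning'."""

    invariant: str
    message: str
    level: str = "error"
    rows: tuple[int, ...] = ()


def validate_dataset(dataset: CohortDataset) -> list[ValidationFinding]:
    """Check every dataset invariant; return findings (empty = valid).

    Errors block classification; warnings (e.g. a symptom backed by a single
    read-out, where two are recommended) are carried into the report as
    disclosures.
    """
    findings: list[ValidationFinding] = []
    f = dataset.frame

    bad = f.index[~np.isfinite(f["value"])]
    if len(bad):
        findings.append(
            ValidationFinding(
                "finite_values",
                f"{len(bad)} measurement(s) with non-finite value",
                rows=tuple(int(i) for i in bad),
            )
        )
    bad = f.index[f["session_day"] < 0]
    if len(bad):
        findings.append(
            ValidationFinding(
                "nonnegative_session_day",
                f"{len(bad)} measurement(s) with negative session_day",
                rows=tuple(int(i) for i in bad),
            )
        )

    unknown = sorted(set(f["readout"]) - set(dataset.specs))
    for r in unknown:
        rows = tuple(int(i) for i in f.index[f["readout"] == r])
        findings.append(
            ValidationFinding(
                "readout_in_specs",
                f"read-out {r!r} has measurements but no ReadoutSpec",
                rows=rows,
            )
        )

    for g in Group:
        n = len(dataset.animals(g))
        if n == 0:
            findings.append(
                ValidationFinding("both_groups_nonempty", f"group {g.value!r} is empty")
            )
        elif n < 2:
            findings.append(
                ValidationFinding(
                    "min_group_size",
                    f"group {g.value!r} has {n} animal(s); at least 2 required",
                )
            )

    dup = f.duplicated(subset=["animal_id", "readout", "session_day"], keep=False)
    if dup.any():
        findings.append(
            ValidationFinding(
                "unique_cells",
                f"{int(dup.sum())} duplicated animal x read-out x session row(s)",
                rows=tuple(int(i) for i in f.index[dup]),
            )
        )

    # Balanced panel: every animal of a group observed exactly once at every
    # session of a longitudinal read-out (the RM-ANOVA assumes balance).
    for r in dataset.longitudinal_readouts():
        sub = f[f["readout"] == r]
        if sub.empty:
            continue
        counts = (
            sub.groupby(["group", "animal_id", "session_day"])
            .size()
            .unstack("session_day")
        )
        bad = counts.isna().any(axis=1) | (counts != 1).any(axis=1)
        if bad.any():
            offenders = [f"{g}/{a}" for g, a in counts.index[bad]]
            findings.append(
                ValidationFinding(
                    "balanced_panel",
                    f"unbalanced panel for read-out {r!r}: animals not measured "
                    f"exactly once at every session: {offenders}",
                )
            )

    anhedonia_labels = {
        s.symptom_label
        for s in dataset.specs.values()
        if s.criterion is ReadoutCriterion.ANHEDONIA
    }
    if len(anhedonia_labels) == 0:
        findings.append(
            ValidationFinding(
                "single_anhedonia_label",
                "no read-out is configured for the anhedonia core symptom",
            )
        )
    elif len(anhedonia_labels) > 1:
        findings.append(
            ValidationFinding(
                "single_anhedonia_label",
                f"multiple anhedonia symptom labels: {sorted(anhedonia_labels)}",
            )
        )

    symptom_counts: dict[str, int] = {}
    for s in dataset.specs.values():
        if s.criterion in (ReadoutCriterion.ANHEDONIA, ReadoutCriterion.ADDITIONAL_SYMPTOM):
            symptom_counts[s.symptom_label] = symptom_counts.get(s.symptom_label, 0) + 1
    for label, n in sorted(symptom_counts.items()):
        if n < 2:
            findings.append(
                ValidationFinding(
                    "two_readouts_per_symptom",
                    f"symptom {label!r} is backed by a single read-out; "
                    "two are recommended",
                    level="warning",
                )
            )

    return findings
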