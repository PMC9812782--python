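"""Statistical primitives of the DLS algorithm.

Control-referenced z-tests with directionality correction, composite
z-scores, the Welch two-sample test, Cohen's d, the balanced mixed-design
(group x session) repeated-measures group effect with partial eta squared,
the eta^2 -> f^2 bridge, and the MESP (minimum effect size plus p value)
decision rule.

The z-test expresses how many control SDs a single observation X deviates
from the control mean:  z = (X - mu) / sigma.  Directional correction flips
the sign for read-outs where lower values mean more impairment, so a
positive z always reflects impairment.  Composite z-scores are plain
arithmetic means of directional z values and therefore stay in control-SD
units.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .types import (
    ControlReference,
    DegenerateControlError,
    Direction,
    EffectKind,
    Group,
    MESPConfig,
    MESPResult,
    ReadoutSpec,
    UnbalancedPanelError,
)

__all__ = [
    "z_test",
    "directional",
    "composite_z",
    "welch_test",
    "cohens_d",
    "rm_group_effect",
    "eta2_to_f2",
    "mesp_check",
    "holm_adjust",
    "build_references",
    "ControlZScorer",
]

_SD_TOL = 1e-12


def z_test(value: float, reference: ControlReference, sd_tolerance: float = _SD_TOL) -> float:
    """Control-referenced z-test: (X - mu) / sigma."""
    if reference.sigma < sd_tolerance:
        raise DegenerateControlError(
            f"control SD for read-out {reference.readout!r} is below tolerance"
        )
    return (value - reference.mu) / reference.sigma


def directional(z_raw: float, direction: Direction) -> float:
    """Sign-correct a raw z so that positive always means impairment."""
    return z_raw if direction is Direction.HIGHER_IS_IMPAIRED else -z_raw


def composite_z(components: Sequence[float]) -> float:
    """Composite z-score: arithmetic mean of directional z components."""
    components = list(components)
    if not components:
        raise ValueError("composite_z requires at least one component")
    return float(sum(components)) / len(components)


def welch_test(
    interest_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """Two-sided p of the unequal-variance two-sample t test.

    Two constant, equal groups return p = 1 by convention (no evidence of a
    difference); constant, unequal groups return p = 0.
    """
    a = np.asarray(interest_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires at least 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("welch_test requires finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va < _SD_TOL**2 and vb < _SD_TOL**2:
        return 1.0 if abs(a.mean() - b.mean()) < _SD_TOL else 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2.0 * sps.t.sf(abs(t), df))


def cohens_d(
    interest_values: Sequence[float],
    control_values: Sequence[float],
    sd: str = "pooled",
    hedges: bool = False,
    sd_tolerance: float = _SD_TOL,
) -> float:
    """Signed standardized mean difference (interest minus control).

    ``sd='pooled'`` uses the pooled (n-1)-weighted SD (Cohen's d proper);
    ``sd='control'`` uses the control SD alone (Glass's delta). ``hedges``
    applies the small-sample bias correction factor 1 - 3/(4*df - 1).
    """
    a = np.asarray(interest_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires at least 2 values per group")
    if sd == "pooled":
        df = a.size + b.size - 2
        pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        denom = np.sqrt(pooled_var)
    elif sd == "control":
        df = b.size - 1
        denom = b.std(ddof=1)
    else:
        raise ValueError(f"unknown sd variant {sd!r}")
    if denom < sd_tolerance:
        raise DegenerateControlError("pooled/control SD below tolerance in cohens_d")
    d = float((a.mean() - b.mean()) / denom)
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (a.size + b.size) - 9.0)
    return d


def rm_group_effect(
    interest_panel: np.ndarray,
    control_panel: np.ndarray,
    sd_tolerance: float = _SD_TOL,
) -> tuple[float, float]:
    """Between-group main effect of a balanced mixed (group x session) design.

    Parameters are complete ``animals x sessions`` matrices (one per group,
    same session columns; NaN cells mean an unbalanced panel and raise).
    The group main effect is tested against the subject-within-group error:

        F = (SS_group / (g-1)) / (SS_subj / (N-g)),
        partial eta^2 = SS_group / (SS_group + SS_subj).

    Returns ``(p_value, partial_eta_squared)``.  In the degenerate limit of
    zero subject-level error, p -> 0 and eta^2 -> 1 unless the group effect
    is itself zero (then p = 1, eta^2 = 0).
    """
    a = np.asarray(interest_panel, dtype=float)
    b = np.asarray(control_panel, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("panels must be 2-D with matching session columns")
    if a.shape[1] < 2:
        raise ValueError("rm_group_effect requires at least 2 sessions")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("rm_group_effect requires at least 2 animals per group")
    if np.isnan(a).any() or np.isnan(b).any():
        raise UnbalancedPanelError("panel contains missing animal x session cells")

    k = a.shape[1]
    n_a, n_b = a.shape[0], b.shape[0]
    subj_means = np.concatenate([a.mean(axis=1), b.mean(axis=1)])
    grand = (a.sum() + b.sum()) / ((n_a + n_b) * k)
    ss_group = k * (
        n_a * (a.mean() - grand) ** 2 + n_b * (b.mean() - grand) ** 2
    )
    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_subj = ss_between_subj - ss_group
    ss_subj = max(ss_subj, 0.0)  # guard tiny negative rounding

    df1 = 1  # two groups
    df2 = n_a + n_b - 2
    if ss_subj < sd_tolerance:
        if ss_group < sd_tolerance:
            return 1.0, 0.0
        return 0.0, 1.0
    f_stat = (ss_group / df1) / (ss_subj / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    eta_p2 = float(ss_group / (ss_group + ss_subj))
    return p, eta_p2


def eta2_to_f2(partial_eta_squared: float) -> float:
    """Cohen's f^2 from partial eta^2: f^2 = eta^2 / (1 - eta^2)."""
    if not 0 <= partial_eta_squared < 1:
        raise ValueError("partial eta^2 must lie in [0, 1)")
    return partial_eta_squared / (1.0 - partial_eta_squared)


def mesp_check(
    p_value: float,
    effect: float,
    effect_kind: EffectKind,
    direction_consistent: bool,
    config: MESPConfig,
    readout: str = "",
) -> MESPResult:
    """Apply the MESP rule: significant AND at least a moderate effect AND
    pointing toward impairment.

    Cohen's d is compared by magnitude (|d| >= d_threshold); f^2 is already
    non-negative and compared directly (f^2 >= f2_threshold).
    """
    if not 0 <= p_value <= 1:
        raise ValueError(f"p value must lie in [0, 1], got {p_value}")
    effect_kind = EffectKind(effect_kind)
    if effect_kind is EffectKind.COHENS_D:
        big_enough = abs(effect) >= config.d_threshold
    else:
        big_enough = effect >= config.f2_threshold
    passes = (p_value <= config.alpha) and big_enough and bool(direction_consistent)
    return MESPResult(
        readout=readout,
        p_value=float(p_value),
        effect_size=float(effect),
        effect_kind=effect_kind,
        direction_consistent=bool(direction_consistent),
        passes=passes,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values (family = one DLS criterion)."""
    p = list(p_values)
    if not p:
        return []
    return [float(x) for x in multipletests(p, method="holm")[1]]


def build_references(
    frame: pd.DataFrame, sd_tolerance: float = _SD_TOL
) -> dict[tuple[str, float], ControlReference]:
    """Control references (mu, sigma, n) per read-out x session from the
    control rows of a tidy measurement frame."""
    ctrl = frame[frame["group"] == Group.CONTROL.value]
    refs: dict[tuple[str, float], ControlReference] = {}
    grouped = ctrl.groupby(["readout", "session_day"], sort=True)["value"]
    for (readout, day), values in grouped:
        v = values.to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(
                f"control reference for {readout!r} at day {day} needs >= 2 animals"
            )
        sigma = float(v.std(ddof=1))
        if sigma < sd_tolerance:
            raise DegenerateControlError(
                f"degenerate control variance for read-out {readout!r} at day {day}"
            )
        refs[(str(readout), float(day))] = ControlReference(
            readout=str(readout),
            session_day=float(day),
            mu=float(v.mean()),
            sigma=sigma,
            n_control=int(v.size),
        )
    return refs


class ControlZScorer(BaseEstimator):
    """Transformer that z-scores measurements against control references.

    ``fit`` learns per-(read-out, session) control means and SDs from the
    control rows of a tidy frame; ``transform`` appends ``z_raw`` (control-
    referenced z) and ``z`` (directionality-corrected, positive =
    impairment) columns.  Follows the scikit-learn fit/transform contract
    on tidy DataFrames rather than 2-D arrays.

    Parameters
    ----------
    specs : dict mapping read-out name -> ReadoutSpec
        Provides the impairment direction per read-out.
    sd_tolerance : float
        Control SDs below this raise ``DegenerateControlError``.
    """

    def __init__(self, specs: dict[str, ReadoutSpec] | None = None, sd_tolerance: float = _SD_TOL):
        self.specs = specs
        self.sd_tolerance = sd_tolerance

    def fit(self, frame: pd.DataFrame, y=None) -> "ControlZScorer":
        self.references_ = build_references(frame, self.sd_tolerance)
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "references_"):
            raise RuntimeError("ControlZScorer must be fitted before transform")
        specs = self.specs or {}
        out = frame.copy()
        # vectorized lookup: session days are exact keys (they originate from
        # the same frame the references were fitted on)
        keys = pd.MultiIndex.from_arrays(
            [out["readout"], out["session_day"].astype(float)]
        )
        mu_map = {k: r.mu for k, r in self.references_.items()}
        sd_map = {k: r.sigma for k, r in self.references_.items()}
        missing = [k for k in set(keys) if k not in mu_map]
        if missing:
            raise KeyError(
                f"no control reference for read-out/session cell(s): {sorted(missing)[:5]}"
            )
        mu = keys.map(mu_map.get).to_numpy(dtype=float)
        sigma = keys.map(sd_map.get).to_numpy(dtype=float)
        sign_map = {
            name: (-1.0 if s.direction is Direction.LOWER_IS_IMPAIRED else 1.0)
            for name, s in specs.items()
        }
        sign = out["readout"].map(lambda r: sign_map.get(r, 1.0)).to_numpy(dtype=float)
        out["z_raw"] = (out["value"].to_numpy(dtype=float) - mu) / sigma
        out["z"] = sign * out["z_raw"]
        return out

    def fit_transform(self, frame: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(frame).transform(frame)
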