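"""CFU-based survival analysis and inactivation dose-response fitting.

Plate counts become per-replicate log10 survival values against the
replicate's own unirradiated control, are aggregated to mean +/- SEM survival
curves, and are fitted with the two models the wavelength-sensitivity ratios
consume: a first-order (log-linear) rate constant over the linear portion of
the curve, and a through-origin quadratic -log10 S = b1*F + b2*F^2 in the
dose F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateObservation",
    "SurvivalPoint",
    "SurvivalCurve",
    "FirstOrderFit",
    "QuadraticFit",
    "DoseRequirement",
    "TTestResult",
    "COUNT_COLUMNS",
    "cfu_per_ml",
    "log_survival",
    "aggregate",
    "survival_curve",
    "survival_curves",
    "fit_first_order",
    "fit_quadratic",
    "dose_for_log_reduction",
    "compare_conditions",
]

#: Canonical plate-count table columns (CSV header and DataFrame schema).
COUNT_COLUMNS = (
    "condition_id",
    "wavelength_nm",
    "dose_mj_cm2",
    "replicate",
    "dilution_factor",
    "plated_volume_ml",
    "colony_count",
)

#: Zero-colony plates are censored at this many colonies for log transforms.
CENSOR_COLONIES = 0.5

#: Default linear-portion rule: doses whose mean log survival is above this.
LINEAR_RANGE_FLOOR = -4.0


@dataclass(frozen=True)
class PlateObservation:
    """One plated dilution of one irradiated (or control) sample.

    ``colony_count`` admits non-negative floats so that deterministic
    (expectation-valued) simulations round-trip exactly; real plate counts
    are integers.
    """

    condition_id: str
    wavelength_nm: float
    dose_mj_cm2: float
    replicate: int
    dilution_factor: float
    plated_volume_ml: float
    colony_count: float

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.plated_volume_ml <= 0:
            raise ValueError("plated volume must be > 0")
        if self.colony_count < 0:
            raise ValueError("colony count must be >= 0")
        if self.dose_mj_cm2 < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class SurvivalPoint:
    dose_mj_cm2: float
    log_survival_mean: float
    sem: float
    n: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")
        if self.dose_mj_cm2 < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class SurvivalCurve:
    """Per-wavelength (dose, log survival) points with replicate statistics."""

    wavelength_nm: float
    points: tuple[SurvivalPoint, ...]

    def __post_init__(self) -> None:
        doses = self.doses
        if doses.size == 0 or doses[0] != 0.0:
            raise ValueError("curve must start at dose 0")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.dose_mj_cm2 for p in self.points])

    @property
    def mean_log_survival(self) -> np.ndarray:
        return np.array([p.log_survival_mean for p in self.points])

    @property
    def sems(self) -> np.ndarray:
        return np.array([p.sem for p in self.points])

    def mean_at(self, dose: float) -> float:
        """Mean log survival at a dose, linearly interpolated on the mean curve."""
        doses = self.doses
        if dose < doses[0] or dose > doses[-1]:
            raise ValueError(
                f"dose {dose} outside measured range [{doses[0]}, {doses[-1]}]"
            )
        return float(np.interp(dose, doses, self.mean_log_survival))


@dataclass(frozen=True)
class FirstOrderFit:
    """Through-origin slope of -log10 S vs dose over the linear portion."""

    k_f0: float
    linear_range: tuple[float, float]
    r_squared: float
    doses: tuple[float, ...]
    residuals: tuple[float, ...]
    wavelength_nm: float | None = None


@dataclass(frozen=True)
class QuadraticFit:
    """Through-origin quadratic -log10 S = b1*F + b2*F^2."""

    b1: float
    b2: float
    wavelength_nm: float | None = None

    def predict_neg_log(self, dose: float | np.ndarray) -> float | np.ndarray:
        return self.b1 * np.asarray(dose) + self.b2 * np.asarray(dose) ** 2

    def invert(self, target_logs: float) -> float:
        """Dose achieving ``target_logs`` of reduction (positive root)."""
        if target_logs <= 0:
            raise ValueError("target log reduction must be > 0")
        if abs(self.b2) < 1e-15:
            if self.b1 <= 0:
                raise ValueError("non-inactivating fit cannot reach the target")
            return target_logs / self.b1
        disc = self.b1**2 + 4.0 * self.b2 * target_logs
        if disc < 0:
            raise ValueError("target unreachable under the fitted quadratic")
        root = (-self.b1 + math.sqrt(disc)) / (2.0 * self.b2)
        if root <= 0:
            raise ValueError("target unreachable under the fitted quadratic")
        return root


@dataclass(frozen=True)
class DoseRequirement:
    wavelength_nm: float | None
    target_logs: float
    required_dose_mj_cm2: float

    def __post_init__(self) -> None:
        if self.target_logs <= 0:
            raise ValueError("target log reduction must be > 0")
        if self.required_dose_mj_cm2 <= 0:
            raise ValueError("required dose must be > 0")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    significant_05: bool
    significant_01: bool
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# counts -> survival
# ---------------------------------------------------------------------------

def cfu_per_ml(obs: PlateObservation) -> float:
    """Viable concentration: colonies / plated volume x dilution factor."""
    return obs.colony_count / obs.plated_volume_ml * obs.dilution_factor


def log_survival(n_t: float, n_0: float, detection_limit: float | None = None) -> float:
    """log10(Nt/N0): 0 for no inactivation, negative for kill.

    A sterile plate (``n_t == 0``) has no finite log survival; pass the
    assay's ``detection_limit`` (CFU/mL) to censor it there instead of
    getting an error.
    """
    if n_0 <= 0:
        raise ValueError("N0 must be > 0")
    if n_t < 0:
        raise ValueError("Nt must be >= 0")
    if n_t == 0:
        if detection_limit is None:
            raise ValueError(
                "zero survivors: supply detection_limit to censor instead of -inf"
            )
        n_t = detection_limit
    return math.log10(n_t / n_0)


def aggregate(log_survivals: Sequence[float], dose_mj_cm2: float) -> SurvivalPoint:
    """Mean and SEM (SD/sqrt(n), sample SD) of per-replicate log survival."""
    vals = np.asarray(log_survivals, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one replicate")
    flags: tuple[str, ...] = ()
    if vals.size == 1:
        sem = 0.0
        flags = ("single_replicate",)
    else:
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return SurvivalPoint(
        dose_mj_cm2=dose_mj_cm2,
        log_survival_mean=float(vals.mean()),
        sem=sem,
        n=int(vals.size),
        flags=flags,
    )


def _replicate_log_survivals(
    group: pd.DataFrame,
) -> tuple[dict[float, list[float]], set[float]]:
    """Per-dose log survival values, pairing each replicate with its own
    dose-0 control; also returns the doses where zero-colony plates were
    censored at the detection limit."""
    controls: dict[int, float] = {}
    for _, row in group[group["dose_mj_cm2"] == 0].iterrows():
        rep = int(row["replicate"])
        if rep in controls:
            raise ValueError(f"replicate {rep} has more than one unirradiated control")
        controls[rep] = (
            row["colony_count"] / row["plated_volume_ml"] * row["dilution_factor"]
        )
    if not controls:
        raise ValueError("no unirradiated control (dose-0 rows missing)")

    by_dose: dict[float, list[float]] = {}
    censored: set[float] = set()
    for _, row in group[group["dose_mj_cm2"] > 0].iterrows():
        rep = int(row["replicate"])
        if rep not in controls:
            raise ValueError(f"replicate {rep} has no unirradiated control")
        n0 = controls[rep]
        count = row["colony_count"]
        if count == 0:
            count = CENSOR_COLONIES  # detection limit
            censored.add(float(row["dose_mj_cm2"]))
        nt = count / row["plated_volume_ml"] * row["dilution_factor"]
        by_dose.setdefault(float(row["dose_mj_cm2"]), []).append(log_survival(nt, n0))
    return by_dose, censored


def survival_curve(counts: pd.DataFrame, wavelength_nm: float) -> SurvivalCurve:
    """Build the mean +/- SEM survival curve for one wavelength.

    ``counts`` follows the plate-count schema (:data:`COUNT_COLUMNS`); the
    dose-0 rows of each replicate serve as its N0.  Zero-colony plates are
    censored at 0.5 colonies.
    """
    group = counts[counts["wavelength_nm"] == wavelength_nm]
    if group.empty:
        raise ValueError(f"no observations at wavelength {wavelength_nm} nm")
    by_dose, censored = _replicate_log_survivals(group)
    points = [SurvivalPoint(0.0, 0.0, 0.0, n=max(len(v) for v in by_dose.values()))]
    for dose in sorted(by_dose):
        point = aggregate(by_dose[dose], dose)
        if dose in censored:
            point = SurvivalPoint(
                point.dose_mj_cm2, point.log_survival_mean, point.sem, point.n,
                flags=point.flags + ("censored_at_detection_limit",),
            )
        points.append(point)
    return SurvivalCurve(wavelength_nm=wavelength_nm, points=tuple(points))


def survival_curves(counts: pd.DataFrame) -> dict[float, SurvivalCurve]:
    """Survival curves for every wavelength present in a plate-count table."""
    return {
        float(wl): survival_curve(counts, float(wl))
        for wl in sorted(counts["wavelength_nm"].unique())
    }


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def _linear_portion(
    curve: SurvivalCurve, dose_range: tuple[float, float] | None
) -> np.ndarray:
    doses = curve.doses
    means = curve.mean_log_survival
    if dose_range is not None:
        sel = (doses > 0) & (doses >= dose_range[0]) & (doses <= dose_range[1])
    else:
        # explicit, reproducible stand-in for "reading" the linear portion:
        # keep doses not yet saturated below -4 logs
        sel = (doses > 0) & (means >= LINEAR_RANGE_FLOOR)
    return sel


def fit_first_order(
    curve: SurvivalCurve,
    dose_range: tuple[float, float] | None = None,
    free_intercept: bool = False,
) -> FirstOrderFit:
    """Least-squares through-origin slope k_F0 of -log10 S vs dose.

    The linear portion defaults to all nonzero doses with mean log survival
    >= -4; pass ``dose_range=(lo, hi)`` to override.  ``free_intercept=True``
    fits an unconstrained line instead (a nonzero intercept indicates a
    shoulder); the reported k is still the slope.
    """
    sel = _linear_portion(curve, dose_range)
    F = curve.doses[sel]
    y = -curve.mean_log_survival[sel]
    if F.size < 2:
        raise ValueError("need at least 2 nonzero-dose points in the linear range")
    if free_intercept:
        k, intercept = np.polyfit(F, y, 1)
        k = float(k)
        resid = y - (k * F + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        k = float(np.dot(F, y) / np.dot(F, F))
        resid = y - k * F
        ss_tot = float(np.dot(y, y))  # uncentered: model is constrained through 0
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    return FirstOrderFit(
        k_f0=k,
        linear_range=(float(F.min()), float(F.max())),
        r_squared=r2,
        doses=tuple(F),
        residuals=tuple(resid),
        wavelength_nm=curve.wavelength_nm,
    )


def fit_quadratic(curve: SurvivalCurve) -> QuadraticFit:
    """Least squares for -log10 S = b1*F + b2*F^2, constrained through (0, 0)."""
    sel = curve.doses > 0
    F = curve.doses[sel]
    y = -curve.mean_log_survival[sel]
    if F.size < 2 or np.unique(F).size < 2:
        raise ValueError("need at least 2 distinct nonzero doses")
    X = np.column_stack([F, F**2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("degenerate dose design: quadratic fit is not identifiable")
    return QuadraticFit(b1=float(coef[0]), b2=float(coef[1]), wavelength_nm=curve.wavelength_nm)


def dose_for_log_reduction(
    curve_model: SurvivalCurve | FirstOrderFit | QuadraticFit,
    target_logs: float,
    extrapolate: bool = False,
) -> DoseRequirement:
    """Dose achieving a target log10 reduction.

    Survival-curve input is inverted by monotone piecewise-linear
    interpolation on the mean curve; fit objects are inverted analytically.
    Targets beyond the measured range raise unless ``extrapolate=True``, in
    which case the quadratic fit of the curve is used (and the result should
    be treated as an extrapolation).
    """
    if target_logs <= 0:
        raise ValueError("target log reduction must be > 0")

    if isinstance(curve_model, FirstOrderFit):
        if curve_model.k_f0 <= 0:
            raise ValueError("non-inactivating fit cannot reach the target")
        return DoseRequirement(
            curve_model.wavelength_nm, target_logs, target_logs / curve_model.k_f0
        )
    if isinstance(curve_model, QuadraticFit):
        return DoseRequirement(
            curve_model.wavelength_nm, target_logs, curve_model.invert(target_logs)
        )

    curve = curve_model
    doses = curve.doses
    neg_log = -curve.mean_log_survival
    if np.any(np.diff(neg_log) < -1e-12):
        raise ValueError(
            "mean survival curve is not monotone; invert a fitted model instead"
        )
    if target_logs > neg_log[-1] + 1e-12:
        if extrapolate:
            return dose_for_log_reduction(fit_quadratic(curve), target_logs)
        raise ValueError(
            f"target {target_logs} logs exceeds the measured maximum "
            f"{neg_log[-1]:.3f}; pass extrapolate=True to invert the quadratic fit"
        )
    required = float(np.interp(target_logs, neg_log, doses))
    if required <= 0:
        raise ValueError("target reached at zero dose; curve degenerate near origin")
    return DoseRequirement(curve.wavelength_nm, target_logs, required)


def compare_conditions(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    Both groups are per-replicate log survival values with n >= 2.  If both
    groups are constant and equal the comparison is degenerate and reported
    as p = 1 with a flag.  ``welch=True`` drops the equal-variance
    assumption (Welch's t).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, False, False, flags=("degenerate",))
        return TTestResult(math.inf, 0.0, True, True, flags=("zero_variance",))
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(float(t), float(p), p < 0.05, p < 0.01)
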