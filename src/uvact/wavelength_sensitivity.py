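"""Wavelength-sensitivity ratios and the inactivation action spectrum.

Four ratio methods express how effective a test LED wavelength is relative
to a reference LED (280 nm by default):

* GF1 -- ratio of first-order rate constants, k(lambda) / k(ref);
* GF2 -- inverse ratio of the doses required for the same log reduction,
  F_ref(n logs) / F_lambda(n logs), evaluated per target level;
* GF3 -- the dose-axis scale factor epsilon that best maps the reference
  quadratic dose-response onto the test curve, by least squares;
* GF4 -- the constant-dose method: observe the log survival the test LED
  produces at a fixed dose d0, read off the reference dose that produces
  the same log survival, and take reference dose / d0.

All four collapse to k(lambda)/k(ref) under pure first-order kinetics.
Values above 1 mean the test wavelength inactivates more per unit dose than
the reference.  Ordering GF4 over the LED set gives the relative
inactivation action spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .kinetics import (
    FirstOrderFit,
    QuadraticFit,
    SurvivalCurve,
    dose_for_log_reduction,
    fit_first_order,
    fit_quadratic,
)

__all__ = [
    "GfRow",
    "GfTable",
    "ActionSpectrum",
    "gf1",
    "gf2",
    "gf3",
    "gf4",
    "build_gf_table",
    "action_spectrum",
]

GF3_BOUNDS = (0.01, 100.0)


@dataclass(frozen=True)
class GfRow:
    """Sensitivity ratios of one wavelength relative to the reference.

    Ratios that cannot be established from the measured curves (target log
    reduction unreachable, or no admissible dose-axis mapping) are NaN with
    an entry in ``flags``.
    """

    wavelength_nm: float
    gf1: float
    gf2: Mapping[float, float]  # target log level -> ratio
    gf3: float
    gf4: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GfTable:
    reference_wavelength_nm: float
    d0_mj_cm2: float
    rows: tuple[GfRow, ...]

    def row(self, wavelength_nm: float) -> GfRow:
        for r in self.rows:
            if r.wavelength_nm == wavelength_nm:
                return r
        raise KeyError(f"no row for {wavelength_nm} nm")

    def to_frame(self):
        import pandas as pd

        records = []
        for r in self.rows:
            rec = {"wavelength_nm": r.wavelength_nm, "gf1": r.gf1}
            for level, v in sorted(r.gf2.items()):
                rec[f"gf2_{level:g}logs"] = v
            rec["gf3"] = r.gf3
            rec["gf4"] = r.gf4
            records.append(rec)
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class ActionSpectrum:
    """Relative inactivation effectiveness by wavelength (GF4-based)."""

    wavelength_nm: tuple[float, ...]
    relative_effectiveness: tuple[float, ...]
    peak_wavelength_nm: float
    flags: tuple[str, ...] = ()


def gf1(k_lambda: float, k_ref: float) -> float:
    """Rate-constant ratio k(lambda) / k(reference)."""
    if k_lambda <= 0 or k_ref <= 0:
        raise ValueError("rate constants must be > 0")
    return k_lambda / k_ref


def gf2(
    curve_lambda: SurvivalCurve | FirstOrderFit | QuadraticFit,
    curve_ref: SurvivalCurve | FirstOrderFit | QuadraticFit,
    target_logs: float,
) -> float:
    """Equal-log-reduction dose ratio F_ref(target) / F_lambda(target)."""
    d_lambda = dose_for_log_reduction(curve_lambda, target_logs).required_dose_mj_cm2
    d_ref = dose_for_log_reduction(curve_ref, target_logs).required_dose_mj_cm2
    return d_ref / d_lambda


def _gf3_objective(
    eps: float, fit_ref: QuadraticFit, fit_lambda: QuadraticFit, doses: np.ndarray
) -> float:
    diff = fit_ref.predict_neg_log(eps * doses) - fit_lambda.predict_neg_log(doses)
    return float(np.dot(diff, diff))


def gf3(curve_lambda: SurvivalCurve, curve_ref: SurvivalCurve) -> float:
    """Dose-axis scale factor mapping the reference curve onto the test curve.

    Both curves are approximated by through-origin quadratics; epsilon
    minimizes the sum of squared differences between the rescaled reference
    prediction and the test prediction, evaluated at the test curve's
    measured (nonzero) doses.  Search is bounded to [0.01, 100].
    """
    fit_l = fit_quadratic(curve_lambda)
    fit_r = fit_quadratic(curve_ref)
    doses = curve_lambda.doses[curve_lambda.doses > 0]
    # the objective can be multimodal when a noisy fit turns concave, so
    # bracket the global minimum on a log-spaced grid before refining
    grid = np.geomspace(GF3_BOUNDS[0], GF3_BOUNDS[1], 400)
    values = [_gf3_objective(e, fit_r, fit_l, doses) for e in grid]
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _gf3_objective,
        bounds=(lo, hi),
        method="bounded",
        args=(fit_r, fit_l, doses),
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"gf3 scale search did not converge: {res.message}")
    eps = float(res.x)
    if eps <= GF3_BOUNDS[0] * 1.01 or eps >= GF3_BOUNDS[1] * 0.99:
        raise RuntimeError(
            f"gf3 scale {eps:.4g} pinned at the search bound {GF3_BOUNDS}; "
            "curves are too dissimilar for a dose-axis mapping"
        )
    return eps


def gf4(
    log_survival_at_d0: float,
    curve_ref: SurvivalCurve | QuadraticFit,
    d0: float,
    extrapolate: bool = False,
) -> float:
    """Constant-dose equivalent-dose ratio.

    ``log_survival_at_d0`` is the (negative) log survival the test LED
    produced at dose ``d0``; the return value is the reference dose needed
    for that same log survival divided by ``d0``.  Values > 1 mean the test
    wavelength is more effective than the reference.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    target = -log_survival_at_d0
    if target <= 0:
        raise ValueError("observed log survival must indicate inactivation")
    if isinstance(curve_ref, QuadraticFit):
        d_ref = curve_ref.invert(target)
    else:
        d_ref = dose_for_log_reduction(
            curve_ref, target, extrapolate=extrapolate
        ).required_dose_mj_cm2
    return d_ref / d0


def build_gf_table(
    curves: Mapping[float, SurvivalCurve],
    reference: float = 280.0,
    d0: float = 4.0,
    target_logs: Sequence[float] = (1.0, 2.0, 3.0),
    extrapolate: bool = False,
) -> GfTable:
    """Compute all four GF families for every wavelength against a reference.

    Reference-column entries are identically 1 (a curve's ratio to itself).
    GF2 entries whose target is unreachable on either curve without
    extrapolation are reported as NaN.
    """
    if reference not in curves:
        raise ValueError(f"reference wavelength {reference} nm missing from curves")
    curve_ref = curves[reference]
    fit_ref_k = fit_first_order(curve_ref)

    rows = []
    for wl in sorted(curves):
        curve = curves[wl]
        if wl == reference:
            rows.append(
                GfRow(wl, 1.0, {t: 1.0 for t in target_logs}, 1.0, 1.0)
            )
            continue
        flags: list[str] = []
        g1 = gf1(fit_first_order(curve).k_f0, fit_ref_k.k_f0)
        g2 = {}
        for t in target_logs:
            try:
                g2[t] = gf2(curve, curve_ref, t)
            except ValueError:
                g2[t] = math.nan
                flags.append(f"gf2_{t:g}logs_unreachable")
        try:
            g3 = gf3(curve, curve_ref)
        except RuntimeError:
            g3 = math.nan
            flags.append("gf3_no_mapping")
        try:
            g4 = gf4(curve.mean_at(d0), curve_ref, d0, extrapolate=extrapolate)
        except ValueError:
            g4 = math.nan
            flags.append("gf4_unreachable")
        rows.append(GfRow(wl, g1, g2, g3, g4, flags=tuple(flags)))
    return GfTable(reference_wavelength_nm=reference, d0_mj_cm2=d0, rows=tuple(rows))


def action_spectrum(table: GfTable) -> ActionSpectrum:
    """Order the GF4 ratios by wavelength and locate the sensitivity peak.

    Ties at the maximum report the lowest wavelength as the peak and flag
    the tie; a peak at the first or last wavelength is flagged as a
    boundary, since the true maximum may lie outside the measured range.
    """
    rows = sorted(table.rows, key=lambda r: r.wavelength_nm)
    flags: list[str] = []
    dropped = [r.wavelength_nm for r in rows if math.isnan(r.gf4)]
    if dropped:
        flags.append("gf4_missing:" + ",".join(f"{w:g}" for w in dropped))
        rows = [r for r in rows if not math.isnan(r.gf4)]
    if len(rows) < 2:
        raise ValueError("action spectrum needs at least 2 wavelengths")
    wl = tuple(r.wavelength_nm for r in rows)
    eff = tuple(r.gf4 for r in rows)
    peak_val = max(eff)
    peaks = [w for w, e in zip(wl, eff) if e == peak_val]
    if len(peaks) > 1:
        flags.append("tied_maximum:" + ",".join(f"{p:g}" for p in peaks))
    if peaks[0] in (wl[0], wl[-1]):
        flags.append("peak_at_boundary")
    return ActionSpectrum(
        wavelength_nm=wl,
        relative_effectiveness=eff,
        peak_wavelength_nm=peaks[0],
        flags=tuple(flags),
    )
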