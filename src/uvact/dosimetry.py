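"""Dose accounting and correction factors for collimated UV-LED exposure.

Bench protocols for UV sensitivity testing quantify how faithfully the dose
delivered to a bacterial suspension in a Petri dish matches the nominal
irradiance x time product.  Four dimensionless factors and one dispersion
statistic do that job:

* water factor (WF) -- depth-averaged fraction of incident UV transmitted
  through the absorbing liquid column (Beer-Lambert),
* divergence factor (DF) -- geometric correction L/(L+l) for beam divergence
  between the liquid surface and the bottom of the column,
* Petri factor (PF) -- mean/center (or mean/max) irradiance over the dish,
  a uniformity measure,
* reflection factor (RF) -- fraction of the beam entering the sample after
  Fresnel reflection at the air/liquid interface, weighted over the beam's
  angular distribution,
* coefficient of variation (CV) -- SD/mean of the irradiance field, in %.

The factors are used here as validity gates (WF >= 0.9, DF >= 0.94,
CV <= 6.7 %) rather than as dose multipliers; an optional corrected-dose
mode multiplies them in for cross-protocol comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SampleOptics",
    "LedSpec",
    "IrradianceField",
    "AngularDistribution",
    "CorrectionFactors",
    "ExposureRecord",
    "GateReport",
    "dose",
    "effective_exposure_time",
    "overshoot_corrected_dose",
    "water_factor",
    "water_factor_weighted",
    "divergence_factor",
    "depth_from_volume",
    "petri_factor",
    "coefficient_of_variation",
    "fresnel_reflectance",
    "reflection_factor",
    "beam_fraction_within",
    "validate_exposure",
    "corrected_dose",
    "transmittance_to_absorbance",
]

LN10 = math.log(10.0)

#: Validity gate thresholds (inclusive).
WF_GATE = 0.9
DF_GATE = 0.94
CV_GATE_PERCENT = 6.7


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleOptics:
    """Optical description of the bacterial suspension in its dish.

    Parameters
    ----------
    decadic_absorbance_per_cm
        Decadic absorption coefficient at the evaluation wavelength (1/cm).
    depth_cm
        Liquid column depth (cm).
    dish_inner_diameter_mm
        Inner diameter of the Petri dish (mm).
    volume_ml
        Sample volume (mL); checked for consistency with depth and dish
        area within `volume_rtol` (the protocol rounds depths to 0.1 cm).
    refractive_index
        Refractive index of the suspension (water-like, ~1.33).
    refractive_index_air
        Refractive index of the incident medium, default 1.0.
    """

    decadic_absorbance_per_cm: float
    depth_cm: float
    dish_inner_diameter_mm: float = 35.0
    volume_ml: float | None = None
    refractive_index: float = 1.33
    refractive_index_air: float = 1.0
    volume_rtol: float = 0.1

    def __post_init__(self) -> None:
        if self.decadic_absorbance_per_cm < 0:
            raise ValueError("absorbance must be >= 0")
        if self.depth_cm <= 0:
            raise ValueError("depth must be > 0")
        if self.dish_inner_diameter_mm <= 0:
            raise ValueError("dish diameter must be > 0")
        if self.refractive_index < 1 or self.refractive_index_air < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.volume_ml is not None:
            implied = depth_from_volume(self.volume_ml, self.dish_inner_diameter_mm)
            if not math.isclose(implied, self.depth_cm, rel_tol=self.volume_rtol):
                raise ValueError(
                    f"volume {self.volume_ml} mL implies depth {implied:.4f} cm, "
                    f"inconsistent with declared depth {self.depth_cm} cm"
                )


@dataclass(frozen=True)
class LedSpec:
    """One UV-LED rank: emission, drive and power-supply timing behaviour.

    ``time_lag_s`` is either a constant lag in seconds or a piecewise-linear
    table ``[(current_a, lag_s), ...]`` mapping drive current to the power
    supply's turn-on delay; the lag at ``drive_current_a`` is added to the
    timer setting when computing the delivered dose.
    """

    rank_label: str
    peak_wavelength_nm: float
    fwhm_nm: float = 10.0
    irradiance_setpoint_mw_cm2: float = 1.0
    drive_current_a: float = 2.4
    time_lag_s: float | Sequence[tuple[float, float]] = 0.0
    overshoot_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 200.0 <= self.peak_wavelength_nm <= 400.0:
            raise ValueError("peak wavelength must lie in [200, 400] nm")
        if self.irradiance_setpoint_mw_cm2 <= 0:
            raise ValueError("irradiance setpoint must be > 0")
        if not 0.0 <= self.overshoot_fraction <= 0.1:
            raise ValueError("overshoot fraction must lie in [0, 0.1]")
        if isinstance(self.time_lag_s, (int, float)):
            if self.time_lag_s < 0:
                raise ValueError("time lag must be >= 0")
        else:
            table = sorted(self.time_lag_s)
            if any(lag < 0 for _, lag in table):
                raise ValueError("time lag must be >= 0")
            object.__setattr__(self, "time_lag_s", tuple(table))

    def lag_at(self, current_a: float) -> float:
        """Power-supply time lag (s) at a drive current, by linear interpolation.

        Extrapolation outside the tabulated current range is refused.
        """
        if isinstance(self.time_lag_s, (int, float)):
            return float(self.time_lag_s)
        currents = np.array([c for c, _ in self.time_lag_s])
        lags = np.array([l for _, l in self.time_lag_s])
        if current_a < currents[0] or current_a > currents[-1]:
            raise ValueError(
                f"current {current_a} A outside lag table range "
                f"[{currents[0]}, {currents[-1]}] A"
            )
        return float(np.interp(current_a, currents, lags))


@dataclass
class IrradianceField:
    """Irradiance sampled on a uniform x/y grid over the dish plane.

    Node arrays are flat and parallel; ``dish_mask`` marks the nodes inside
    the dish area over which PF and CV are evaluated.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    irradiance_mw_cm2: np.ndarray
    dish_mask: np.ndarray

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.irradiance_mw_cm2 = np.asarray(self.irradiance_mw_cm2, dtype=float)
        self.dish_mask = np.asarray(self.dish_mask, dtype=bool)
        n = self.x_mm.size
        if not (self.y_mm.size == self.irradiance_mw_cm2.size == self.dish_mask.size == n):
            raise ValueError("field arrays must have equal length")
        if np.any(self.irradiance_mw_cm2 < 0):
            raise ValueError("irradiance must be >= 0 everywhere")

    @classmethod
    def from_grid(
        cls,
        x_mm: np.ndarray,
        y_mm: np.ndarray,
        irradiance_mw_cm2: np.ndarray,
        dish_diameter_mm: float = 35.0,
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "IrradianceField":
        """Build a field from flat coordinate/irradiance arrays, masking the
        disc of the given diameter around ``center``."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        r2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
        mask = r2 <= (dish_diameter_mm / 2.0) ** 2
        return cls(x, y, np.asarray(irradiance_mw_cm2, dtype=float), mask)

    def center_index(self) -> int:
        """Index of the masked node nearest the dish center.

        Ties are broken toward smaller coordinates so that even-sized grids
        resolve deterministically.
        """
        idx = np.flatnonzero(self.dish_mask)
        if idx.size == 0:
            raise ValueError("dish mask covers no grid node")
        d2 = self.x_mm[idx] ** 2 + self.y_mm[idx] ** 2
        order = np.lexsort((self.y_mm[idx], self.x_mm[idx], np.round(d2, 12)))
        return int(idx[order[0]])


@dataclass(frozen=True)
class AngularDistribution:
    """Radiant power fractions binned by incidence angle at the dish plane."""

    angle_deg: tuple[float, ...]
    power_fraction: tuple[float, ...]

    def __post_init__(self) -> None:
        angles = np.asarray(self.angle_deg, dtype=float)
        fractions = np.asarray(self.power_fraction, dtype=float)
        if angles.size != fractions.size or angles.size == 0:
            raise ValueError("angles and fractions must have equal nonzero length")
        if np.any(np.diff(angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(angles < 0) or np.any(angles >= 90):
            raise ValueError("angles must lie in [0, 90) degrees")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("power fractions must sum to 1 within 1e-9")
        object.__setattr__(self, "angle_deg", tuple(angles))
        object.__setattr__(self, "power_fraction", tuple(fractions))


@dataclass(frozen=True)
class CorrectionFactors:
    """The five exposure-validity factors for one device configuration."""

    wf: float
    df: float
    pf_center: float
    pf_max: float
    rf: float
    cv_percent: float

    def __post_init__(self) -> None:
        for name in ("wf", "df", "pf_max", "rf"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.pf_center <= 0:
            raise ValueError("pf_center must be > 0")
        if self.cv_percent < 0:
            raise ValueError("cv_percent must be >= 0")


@dataclass(frozen=True)
class GateReport:
    """Per-gate pass/fail flags for a set of correction factors."""

    wf_pass: bool
    df_pass: bool
    cv_pass: bool
    factors: CorrectionFactors

    @property
    def all_pass(self) -> bool:
        return self.wf_pass and self.df_pass and self.cv_pass

    def lines(self) -> list[str]:
        def fmt(name: str, ok: bool, detail: str) -> str:
            return f"{name}: {'PASS' if ok else 'FAIL'} ({detail})"

        return [
            fmt("WF", self.wf_pass, f"{self.factors.wf:.3f} >= {WF_GATE}"),
            fmt("DF", self.df_pass, f"{self.factors.df:.3f} >= {DF_GATE}"),
            fmt("CV", self.cv_pass, f"{self.factors.cv_percent:.2f}% <= {CV_GATE_PERCENT}%"),
            f"overall: {'PASS' if self.all_pass else 'FAIL'}",
        ]


@dataclass(frozen=True)
class ExposureRecord:
    """One irradiation event with its timing correction and delivered dose."""

    led: LedSpec
    timer_time_s: float
    effective_time_s: float
    surface_irradiance_mw_cm2: float
    dose_mj_cm2: float

    def __post_init__(self) -> None:
        if self.effective_time_s < self.timer_time_s:
            raise ValueError("effective time cannot be shorter than the timer setting")
        expected = self.surface_irradiance_mw_cm2 * self.effective_time_s
        if abs(expected - self.dose_mj_cm2) > 1e-9:
            raise ValueError("dose must equal irradiance x effective time")

    @classmethod
    def from_timer(
        cls, led: LedSpec, timer_time_s: float, surface_irradiance_mw_cm2: float
    ) -> "ExposureRecord":
        t_eff = effective_exposure_time(timer_time_s, led)
        return cls(
            led=led,
            timer_time_s=timer_time_s,
            effective_time_s=t_eff,
            surface_irradiance_mw_cm2=surface_irradiance_mw_cm2,
            dose_mj_cm2=dose(surface_irradiance_mw_cm2, t_eff),
        )


# ---------------------------------------------------------------------------
# dose accounting
# ---------------------------------------------------------------------------

def dose(irradiance_mw_cm2: float, exposure_time_s: float) -> float:
    """UV dose (fluence) in mJ/cm^2: irradiance (mW/cm^2) x time (s)."""
    if irradiance_mw_cm2 < 0 or exposure_time_s < 0:
        raise ValueError("irradiance and exposure time must be >= 0")
    return irradiance_mw_cm2 * exposure_time_s


def effective_exposure_time(timer_time_s: float, led: LedSpec) -> float:
    """Timer setting plus the power-supply turn-on lag at the LED's drive current.

    DC supplies need a current-dependent time to reach the setpoint after
    switch-on; adding that lag to the timer reading gives the time base the
    delivered dose actually accumulated over.
    """
    if timer_time_s < 0:
        raise ValueError("timer time must be >= 0")
    return timer_time_s + led.lag_at(led.drive_current_a)


def overshoot_corrected_dose(
    dose_mj_cm2: float,
    overshoot_fraction: float,
    exposure_time_s: float,
    reference_time_s: float,
) -> float:
    """Add the power-supply startup overshoot as a fixed per-exposure surplus.

    Overshoot is a transient at switch-on, so its absolute energy excess is
    what the fraction measured over ``reference_time_s`` implies, and it does
    not grow with longer exposures: surplus = fraction x (dose delivered over
    the reference interval at this exposure's dose rate).
    """
    if not 0.0 <= overshoot_fraction <= 0.1:
        raise ValueError("overshoot fraction must lie in [0, 0.1]")
    if exposure_time_s <= 0 or reference_time_s <= 0:
        raise ValueError("times must be > 0")
    surplus = overshoot_fraction * dose_mj_cm2 * reference_time_s / exposure_time_s
    return dose_mj_cm2 + surplus


# ---------------------------------------------------------------------------
# correction factors
# ---------------------------------------------------------------------------

def water_factor(absorbance_per_cm: float, depth_cm: float) -> float:
    """Depth-averaged decadic transmission of the liquid column.

    WF = (1 - 10^(-a*l)) / (a*l*ln 10), the mean of 10^(-a*z) over
    z in [0, l]; 1 in the transparent limit a -> 0.
    """
    if absorbance_per_cm < 0:
        raise ValueError("absorbance must be >= 0")
    if depth_cm <= 0:
        raise ValueError("depth must be > 0")
    al = absorbance_per_cm * depth_cm
    if al < 1e-12:
        return 1.0
    return -math.expm1(-al * LN10) / (al * LN10)


def water_factor_weighted(
    absorbances_per_cm: Sequence[float],
    weights: Sequence[float],
    depth_cm: float,
) -> float:
    """Emission-spectrum-weighted water factor.

    Averages the single-wavelength WF over an LED emission spectrum sampled
    at several wavelengths (``weights`` are the spectral power fractions).
    Optional; the single-wavelength factor at the LED peak is the default
    reporting convention.
    """
    a = np.asarray(absorbances_per_cm, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.size != w.size or a.size == 0:
        raise ValueError("absorbances and weights must have equal nonzero length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(sum(wi * water_factor(ai, depth_cm) for ai, wi in zip(a, w)))


def divergence_factor(working_distance_cm: float, depth_cm: float) -> float:
    """Beam-divergence correction L/(L + l) for a source at distance L."""
    if working_distance_cm <= 0:
        raise ValueError("working distance must be > 0")
    if depth_cm < 0:
        raise ValueError("depth must be >= 0")
    return working_distance_cm / (working_distance_cm + depth_cm)


def depth_from_volume(volume_ml: float, dish_inner_diameter_mm: float) -> float:
    """Liquid depth (cm) of a volume (mL) in a cylindrical dish."""
    if volume_ml <= 0 or dish_inner_diameter_mm <= 0:
        raise ValueError("volume and diameter must be > 0")
    radius_cm = dish_inner_diameter_mm / 20.0
    return volume_ml / (math.pi * radius_cm**2)


def petri_factor(field: IrradianceField, mode: str = "center") -> float:
    """Mean irradiance over the dish divided by the center (or maximum) value.

    With a multi-LED surface source the center node need not carry the
    maximum irradiance, hence the two modes; ``mode="max"`` is bounded by 1.
    """
    masked = field.irradiance_mw_cm2[field.dish_mask]
    if masked.size == 0:
        raise ValueError("dish mask covers no grid node")
    mean = float(masked.mean())
    if mode == "center":
        denom = float(field.irradiance_mw_cm2[field.center_index()])
    elif mode == "max":
        denom = float(masked.max())
    else:
        raise ValueError("mode must be 'center' or 'max'")
    if denom <= 0:
        raise ValueError("denominator irradiance is zero")
    return mean / denom


def coefficient_of_variation(field: IrradianceField) -> float:
    """Irradiance nonuniformity over the dish: 100 x sample SD / mean, in %."""
    masked = field.irradiance_mw_cm2[field.dish_mask]
    if masked.size < 2:
        raise ValueError("CV needs at least 2 masked nodes")
    mean = float(masked.mean())
    if mean <= 0:
        raise ValueError("mean irradiance must be > 0")
    return 100.0 * float(masked.std(ddof=1)) / mean


def fresnel_reflectance(
    n_incident: float, n_transmitted: float, angle_deg: float
) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Mean of the s- and p-polarized intensity reflection coefficients for a
    beam hitting the interface at ``angle_deg`` from the normal.  Beyond the
    critical angle (only possible for n_incident > n_transmitted) all power
    is reflected and 1 is returned.
    """
    if n_incident < 1 or n_transmitted < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 <= angle_deg < 90.0:
        raise ValueError("angle must lie in [0, 90) degrees")
    theta_i = math.radians(angle_deg)
    sin_t = n_incident * math.sin(theta_i) / n_transmitted
    if sin_t >= 1.0:
        return 1.0
    cos_i = math.cos(theta_i)
    cos_t = math.sqrt(1.0 - sin_t**2)
    rs = (n_incident * cos_i - n_transmitted * cos_t) / (
        n_incident * cos_i + n_transmitted * cos_t
    )
    rp = (n_transmitted * cos_i - n_incident * cos_t) / (
        n_transmitted * cos_i + n_incident * cos_t
    )
    return 0.5 * (rs**2 + rp**2)


def reflection_factor(dist: AngularDistribution, optics: SampleOptics) -> float:
    """Fraction of beam power entering the sample after surface reflection.

    1 minus the angular-distribution-weighted unpolarized Fresnel
    reflectance at the air/suspension interface.
    """
    loss = sum(
        f * fresnel_reflectance(optics.refractive_index_air, optics.refractive_index, a)
        for a, f in zip(dist.angle_deg, dist.power_fraction)
    )
    return 1.0 - loss


def beam_fraction_within(dist: AngularDistribution, cone_angle_deg: float) -> float:
    """Cumulative power fraction at incidence angles <= ``cone_angle_deg``."""
    if not 0.0 < cone_angle_deg <= 90.0:
        raise ValueError("cone angle must lie in (0, 90] degrees")
    return float(
        sum(f for a, f in zip(dist.angle_deg, dist.power_fraction) if a <= cone_angle_deg)
    )


def transmittance_to_absorbance(
    transmittance_percent: float, path_length_cm: float
) -> float:
    """Decadic absorption coefficient (1/cm) from percent transmittance."""
    if not 0.0 < transmittance_percent <= 100.0:
        raise ValueError("transmittance must lie in (0, 100] percent")
    if path_length_cm <= 0:
        raise ValueError("path length must be > 0")
    return -math.log10(transmittance_percent / 100.0) / path_length_cm


def validate_exposure(factors: CorrectionFactors) -> GateReport:
    """Apply the protocol validity gates; never raises on failing gates.

    Gates (inclusive): WF >= 0.9, DF >= 0.94, CV <= 6.7 %.
    """
    return GateReport(
        wf_pass=factors.wf >= WF_GATE,
        df_pass=factors.df >= DF_GATE,
        cv_pass=factors.cv_percent <= CV_GATE_PERCENT,
        factors=factors,
    )


def corrected_dose(dose_mj_cm2: float, factors: CorrectionFactors) -> float:
    """Dose rescaled by WF x DF x PF_max x RF, for cross-protocol comparison.

    The default workflow treats the factors as validity gates only; this
    multiplicative mode is provided for comparison with protocols that fold
    them into the reported fluence.
    """
    if dose_mj_cm2 < 0:
        raise ValueError("dose must be >= 0")
    return dose_mj_cm2 * factors.wf * factors.df * factors.pf_max * factors.rf
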