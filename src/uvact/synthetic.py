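"""Synthetic bench data with the statistical structure the analysis assumes.

The generator emulates a collimated multi-LED exposure bench running a
CFU-based dose-response assay on *E. coli* ATCC 25922:

* a dose-scaled quadratic inactivation model
  -log10 S(lambda, F) = b1*(eps_lambda*F) + b2*(eps_lambda*F)^2,
  where eps_lambda is the wavelength's dose-scale (relative effectiveness)
  and (b1, b2) describe the reference (280 nm) curve.  The reference
  coefficients are solved at run time from two calibration anchors:
  0.95 logs at 4 mJ/cm2 on the reference LED and 5.96 logs at 10 mJ/cm2 on
  the 254 nm LED (eps = 1.25);
* Poisson plate counts after auto-dilution into the 30-300 colony countable
  window, with a Normal replicate effect in log10 space;
* a parametric multi-LED irradiance field (Lambertian-like cos^m point
  emitters on a board) for uniformity and beam-angle studies;
* Gaussian LED emission spectra (~10 nm FWHM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .dosimetry import AngularDistribution, IrradianceField, LedSpec

__all__ = [
    "NOMINAL_WAVELENGTHS",
    "KineticsModel",
    "SimulationConfig",
    "EmissionSpectrum",
    "led_catalog",
    "default_kinetics",
    "simulate_counts",
    "default_board_layout",
    "simulate_irradiance_field",
    "make_led_spectrum",
]

#: Nominal rank wavelengths of the 13-LED set (nm).
NOMINAL_WAVELENGTHS = (
    250.0, 254.0, 257.0, 260.0, 263.0, 267.0, 270.0,
    275.0, 280.0, 290.0, 300.0, 308.0, 365.0,
)

#: Measured emission peaks of the 13 ranks (nm), keyed by nominal wavelength.
_PEAK_WAVELENGTHS = {
    250.0: 250.8, 254.0: 253.3, 257.0: 255.7, 260.0: 260.3, 263.0: 263.0,
    267.0: 266.8, 270.0: 269.3, 275.0: 274.0, 280.0: 281.3, 290.0: 289.7,
    300.0: 300.2, 308.0: 307.5, 365.0: 367.0,
}

#: Surface-irradiance setpoints (mW/cm2): 1.0 except the weak/strong ranks.
_SETPOINTS = {250.0: 0.5, 290.0: 1.5, 365.0: 18.0}

REFERENCE_WAVELENGTH = 280.0

#: Calibration anchors: (wavelength, dose mJ/cm2, -log10 survival).
_ANCHOR_REF = (280.0, 4.0, 0.95)
_ANCHOR_254 = (254.0, 10.0, 5.96)

#: Dose-scale anchors relative to the 280 nm reference.
_EPSILON_ANCHORS = {254.0: 1.25, 267.0: 1.56, 270.0: 1.52, 280.0: 1.0}

# Shape knots for interpolating eps at wavelengths without an anchor: a
# germicidal-spectrum-like peak at 267 nm, falling steeply above 290 nm and
# nearly flat far into the UVA.  Values away from the four anchors are
# plausible-shape choices, not measurements.
_EPSILON_KNOTS = {
    250.0: 1.12,
    254.0: 1.25,
    267.0: 1.56,
    270.0: 1.52,
    280.0: 1.0,
    290.0: 0.40,
    300.0: 0.08,
    308.0: 0.02,
    365.0: 0.001,
}

COUNTABLE_RANGE = (30.0, 300.0)


def led_catalog() -> dict[float, LedSpec]:
    """The 13-LED bench set, keyed by nominal rank wavelength."""
    return {
        wl: LedSpec(
            rank_label=f"U{int(wl)}",
            peak_wavelength_nm=_PEAK_WAVELENGTHS[wl],
            fwhm_nm=10.0,
            irradiance_setpoint_mw_cm2=_SETPOINTS.get(wl, 1.0),
        )
        for wl in NOMINAL_WAVELENGTHS
    }


@dataclass(frozen=True)
class KineticsModel:
    """Dose-scaled quadratic inactivation model across wavelengths."""

    b1: float
    b2: float
    epsilon: Mapping[float, float]
    reference_wavelength_nm: float = REFERENCE_WAVELENGTH

    def __post_init__(self) -> None:
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        ref = self.epsilon.get(self.reference_wavelength_nm)
        if ref is None or abs(ref - 1.0) > 1e-12:
            raise ValueError("epsilon at the reference wavelength must be 1")
        if any(e <= 0 for e in self.epsilon.values()):
            raise ValueError("epsilon values must be > 0")

    def neg_log_survival(self, wavelength_nm: float, dose_mj_cm2: float) -> float:
        """-log10 survival at a wavelength and dose (monotone in dose)."""
        if dose_mj_cm2 < 0:
            raise ValueError("dose must be >= 0")
        eff = self.epsilon[wavelength_nm] * dose_mj_cm2
        return self.b1 * eff + self.b2 * eff**2

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.epsilon))


@dataclass(frozen=True)
class SimulationConfig:
    """Assay layout: wavelengths, dose grid, replication, titer and noise."""

    wavelengths: Sequence[float] = NOMINAL_WAVELENGTHS
    doses_mj_cm2: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    replicates: int = 4
    n0_cfu_ml: float = 1e7
    noise_sd_log: float = 0.2
    plated_volume_ml: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in tuple(self.doses_mj_cm2):
            raise ValueError("dose grid must include 0 (the unirradiated control)")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.n0_cfu_ml <= 0 or self.plated_volume_ml <= 0:
            raise ValueError("titer and plated volume must be > 0")
        if self.noise_sd_log < 0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class EmissionSpectrum:
    wavelength_nm: np.ndarray
    intensity_per_nm: np.ndarray


def default_kinetics() -> KineticsModel:
    """The calibrated 13-wavelength model.

    (b1, b2) solve the 2x2 linear system pinning the reference curve to the
    two calibration anchors; eps at wavelengths without a printed anchor is
    PCHIP-interpolated in log10 space through the shape knots, so the
    spectrum rises monotonically to its 267 nm peak and falls monotonically
    above it.
    """
    _, f_ref, y_ref = _ANCHOR_REF
    wl254, f_254, y_254 = _ANCHOR_254
    eps254 = _EPSILON_ANCHORS[wl254]
    a = np.array(
        [
            [f_ref, f_ref**2],
            [eps254 * f_254, (eps254 * f_254) ** 2],
        ]
    )
    b1, b2 = np.linalg.solve(a, np.array([y_ref, y_254]))

    knots_wl = np.array(sorted(_EPSILON_KNOTS))
    knots_log_eps = np.log10([_EPSILON_KNOTS[w] for w in knots_wl])
    interp = PchipInterpolator(knots_wl, knots_log_eps)
    epsilon = {wl: float(10.0 ** interp(wl)) for wl in NOMINAL_WAVELENGTHS}
    epsilon.update(_EPSILON_ANCHORS)  # anchors exact, not interpolated
    return KineticsModel(b1=float(b1), b2=float(b2), epsilon=epsilon)


def _auto_dilution(concentration_cfu_ml: float, plated_volume_ml: float) -> float:
    """Smallest decimal dilution that brings the expected plate count into
    the countable window; dilution 1 when even the neat plate is sparse."""
    expected_neat = concentration_cfu_ml * plated_volume_ml
    if expected_neat <= COUNTABLE_RANGE[1]:
        return 1.0
    decades = math.ceil(math.log10(expected_neat / COUNTABLE_RANGE[1]))
    return 10.0**decades


def simulate_counts(
    model: KineticsModel,
    config: SimulationConfig,
    deterministic: bool = False,
) -> pd.DataFrame:
    """Simulate a plate-count table for the configured assay.

    Per (wavelength, dose, replicate): the model's survival, perturbed by a
    Normal(0, noise_sd_log) replicate effect in log10 space, sets the true
    concentration; an auto-chosen decimal dilution targets the 30-300 colony
    window; the plate count is Poisson.  Dose-0 rows are each replicate's N0
    control.  ``deterministic=True`` switches off both noise sources and
    emits expectation-valued (fractional) counts, so the analysis pipeline
    recovers the model exactly; the same seed always yields the same table.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for wl in config.wavelengths:
        if wl not in model.epsilon:
            raise ValueError(f"model has no dose scale for {wl} nm")
        for rep in range(1, config.replicates + 1):
            for dose in config.doses_mj_cm2:
                if dose == 0.0:
                    conc = config.n0_cfu_ml
                else:
                    neg_log = model.neg_log_survival(wl, dose)
                    if not deterministic and config.noise_sd_log > 0:
                        neg_log -= rng.normal(0.0, config.noise_sd_log)
                    conc = config.n0_cfu_ml * 10.0 ** (-neg_log)
                dilution = _auto_dilution(conc, config.plated_volume_ml)
                expected = conc * config.plated_volume_ml / dilution
                if deterministic:
                    count = expected
                else:
                    count = float(rng.poisson(expected))
                records.append(
                    {
                        "condition_id": f"U{int(wl)}",
                        "wavelength_nm": wl,
                        "dose_mj_cm2": float(dose),
                        "replicate": rep,
                        "dilution_factor": dilution,
                        "plated_volume_ml": config.plated_volume_ml,
                        "colony_count": count,
                    }
                )
    return pd.DataFrame.from_records(records)


def default_board_layout(n_leds: int = 36, pitch_mm: float = 6.0) -> np.ndarray:
    """Centered near-square grid of LED positions (mm) on the circuit board."""
    if n_leds < 1:
        raise ValueError("need at least one LED")
    side = math.ceil(math.sqrt(n_leds))
    coords = (np.arange(side) - (side - 1) / 2.0) * pitch_mm
    xx, yy = np.meshgrid(coords, coords)
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    # drop corners first so partial boards stay roughly round
    order = np.argsort(pos[:, 0] ** 2 + pos[:, 1] ** 2, kind="stable")
    return pos[order[:n_leds]]


def simulate_irradiance_field(
    board_layout_mm: np.ndarray | None = None,
    working_distance_mm: float = 100.0,
    lambertian_exponent: float = 1.0,
    grid_spacing_mm: float = 1.0,
    dish_diameter_mm: float = 35.0,
    angle_bin_deg: float = 1.0,
) -> tuple[IrradianceField, AngularDistribution]:
    """Irradiance field and incidence-angle distribution of a multi-LED board.

    Each LED is a point emitter with intensity proportional to
    cos^m(theta)/d^2 (m = ``lambertian_exponent``); contributions are summed
    on a uniform grid at the dish plane, and arriving power is binned by
    incidence angle over the dish area.
    """
    if working_distance_mm <= 0:
        raise ValueError("working distance must be > 0")
    if board_layout_mm is None:
        board_layout_mm = default_board_layout()
    leds = np.atleast_2d(np.asarray(board_layout_mm, dtype=float))
    if leds.shape[0] < 1:
        raise ValueError("need at least one LED")

    half = dish_diameter_mm / 2.0
    coords = np.arange(-half, half + grid_spacing_mm / 2, grid_spacing_mm)
    gx, gy = np.meshgrid(coords, coords)
    gx, gy = gx.ravel(), gy.ravel()

    dx = gx[:, None] - leds[None, :, 0]
    dy = gy[:, None] - leds[None, :, 1]
    d2 = dx**2 + dy**2 + working_distance_mm**2
    cos_theta = working_distance_mm / np.sqrt(d2)
    contrib = cos_theta**lambertian_exponent / d2  # (nodes, leds)
    irradiance = contrib.sum(axis=1)

    field = IrradianceField.from_grid(gx, gy, irradiance, dish_diameter_mm)

    mask = field.dish_mask
    theta = np.degrees(np.arccos(np.clip(cos_theta[mask], -1.0, 1.0)))
    power = contrib[mask]
    edges = np.arange(0.0, 90.0 + angle_bin_deg, angle_bin_deg)
    hist, _ = np.histogram(theta.ravel(), bins=edges, weights=power.ravel())
    nonzero = hist > 0
    centers = (edges[:-1] + edges[1:]) / 2.0
    fractions = hist[nonzero] / hist.sum()
    fractions = fractions / fractions.sum()  # guard rounding
    dist = AngularDistribution(tuple(centers[nonzero]), tuple(fractions))
    return field, dist


def make_led_spectrum(peak_nm: float, fwhm_nm: float = 10.0) -> EmissionSpectrum:
    """Unit-area Gaussian emission spectrum on a 0.5 nm grid."""
    if fwhm_nm <= 0:
        raise ValueError("FWHM must be > 0")
    sigma = fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    wl = np.arange(peak_nm - 5 * fwhm_nm, peak_nm + 5 * fwhm_nm + 0.25, 0.5)
    intensity = np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)
    intensity /= np.trapezoid(intensity, wl)
    return EmissionSpectrum(wavelength_nm=wl, intensity_per_nm=intensity)
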