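"""End-to-end convenience: synthetic counts -> curves -> GF table -> spectrum."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .kinetics import SurvivalCurve, survival_curves
from .synthetic import KineticsModel, SimulationConfig, default_kinetics, simulate_counts
from .wavelength_sensitivity import ActionSpectrum, GfTable, action_spectrum, build_gf_table

__all__ = ["PipelineResult", "run_action_spectrum"]


@dataclass(frozen=True)
class PipelineResult:
    counts: pd.DataFrame
    curves: dict[float, SurvivalCurve]
    gf_table: GfTable
    spectrum: ActionSpectrum


def run_action_spectrum(
    model: KineticsModel | None = None,
    config: SimulationConfig | None = None,
    deterministic: bool = False,
    reference: float = 280.0,
    d0: float = 4.0,
    target_logs: Sequence[float] = (1.0, 2.0, 3.0),
) -> PipelineResult:
    """Simulate the full assay and assemble the GF table and action spectrum."""
    model = model if model is not None else default_kinetics()
    config = config if config is not None else SimulationConfig()
    counts = simulate_counts(model, config, deterministic=deterministic)
    curves = survival_curves(counts)
    table = build_gf_table(curves, reference=reference, d0=d0, target_logs=target_logs)
    return PipelineResult(
        counts=counts,
        curves=curves,
        gf_table=table,
        spectrum=action_spectrum(table),
    )
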