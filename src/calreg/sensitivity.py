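"""Protein-type sensitivity of the average cytosolic calcium concentration.

With regulation disabled (fixed ``n``), the density of one protein type is
increased (default +20 %) at t = 0 from the default limit cycle, the model
is integrated for an equilibration period (default 1000 s), and cytosolic
calcium is averaged over the following 10 s. The percent change relative to
the matching average of the unperturbed model quantifies how that protein
type moves the calcium level: depolarising/influx pathways (CaL, Na, f)
raise it, repolarising currents and SR uptake (Kr, K1, SERCA) lower it —
which is why a single calcium setpoint cannot regulate all densities with
the same feedback sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cell_model import (
    CellModel,
    DrugBlock,
    SolverOptions,
    cycle_average_calcium,
    limit_cycle_init,
    run_fixed_n,
)
from .errors import InvalidParameterError

__all__ = ["SensitivityResult", "perturb_and_measure", "sensitivity_panel"]


@dataclass
class SensitivityResult:
    """Effect of scaling one protein type on average cytosolic calcium."""

    protein: str
    scale: float
    percent_change: float
    quiescent: bool = False
    error: str | None = None


def _averaged_calcium_after(
    model: CellModel,
    scales: dict[str, float] | None,
    init_state: np.ndarray,
    equilibration_ms: float,
    window_ms: float,
    solver: SolverOptions,
) -> tuple[float, bool]:
    if equilibration_ms > 0:
        settle = run_fixed_n(
            model, 1.0, DrugBlock.none(), equilibration_ms, init_state,
            scales=scales, solver=solver, dt_sample_ms=equilibration_ms / 2,
        )
        state = settle.metadata["final_state"]
    else:
        state = init_state
    trace = run_fixed_n(
        model, 1.0, DrugBlock.none(), window_ms, state, scales=scales, solver=solver
    )
    return cycle_average_calcium(trace)


def perturb_and_measure(
    model: CellModel,
    protein: str,
    scale: float = 1.2,
    *,
    equilibration_ms: float = 1_000_000.0,
    window_ms: float = 10_000.0,
    solver: SolverOptions | None = None,
    _baseline: float | None = None,
    _init_state: np.ndarray | None = None,
) -> SensitivityResult:
    """Percent change in average cytosolic calcium from scaling one protein.

    The scale is applied at t = 0 from the default limit cycle; the model
    runs ``equilibration_ms`` (fixed ``n``, no regulation) and calcium is
    averaged by quadrature over the next ``window_ms``, against the default
    model's matching average. ``_baseline``/``_init_state`` let a panel
    reuse the comparator run.
    """
    if protein not in model.protein_types:
        raise InvalidParameterError(
            f"unknown protein type {protein!r}; supported: {model.protein_types}"
        )
    solver = solver or SolverOptions()
    if _init_state is None:
        _init_state = limit_cycle_init(model, 1.0, solver=solver).state
    if _baseline is None:
        _baseline, _ = _averaged_calcium_after(
            model, None, _init_state, equilibration_ms, window_ms, solver
        )
    c_pert, quiescent = _averaged_calcium_after(
        model, {protein: scale}, _init_state, equilibration_ms, window_ms, solver
    )
    pct = 100.0 * (c_pert - _baseline) / _baseline
    return SensitivityResult(
        protein=protein, scale=scale, percent_change=pct, quiescent=quiescent
    )


def sensitivity_panel(
    model: CellModel,
    proteins: Sequence[str] | None = None,
    scale: float = 1.2,
    *,
    equilibration_ms: float = 1_000_000.0,
    window_ms: float = 10_000.0,
    solver: SolverOptions | None = None,
) -> list[SensitivityResult]:
    """Sensitivity of average calcium to a density increase per protein type.

    Each protein is scaled separately with all others at their defaults.
    The unperturbed comparator is computed once and shared. Per-protein
    failures are reported in the result rows; the panel always completes.
    """
    if proteins is None:
        proteins = list(model.protein_types)
    results: list[SensitivityResult] = []
    if not proteins:
        return results
    solver = solver or SolverOptions()
    init_state = limit_cycle_init(model, 1.0, solver=solver).state
    baseline, _ = _averaged_calcium_after(
        model, None, init_state, equilibration_ms, window_ms, solver
    )
    for protein in proteins:
        try:
            results.append(
                perturb_and_measure(
                    model,
                    protein,
                    scale,
                    equilibration_ms=equilibration_ms,
                    window_ms=window_ms,
                    solver=solver,
                    _baseline=baseline,
                    _init_state=init_state,
                )
            )
        except Exception as exc:  # panel completes; row carries the error
            results.append(
                SensitivityResult(
                    protein=protein,
                    scale=scale,
                    percent_change=float("nan"),
                    error=str(exc),
                )
            )
    return results
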