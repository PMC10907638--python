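"""Spontaneously beating cardiomyocyte model with a scalable L-type current.

The package treats the action-potential model as a pluggable contract
(:class:`CellModel`): any ODE system exposing membrane voltage, cytosolic
calcium, and per-protein-type density scale factors can drive the expression
regulation. One reference implementation is provided,
:class:`MinimalHiPSCCM`, a compact pacemaking formulation in the
Hodgkin–Huxley tradition with the currents that dominate the spontaneous
hiPSC-CM action potential:

* ``I_Na`` — fast sodium current (instantaneous activation, gated
  inactivation ``h``) carrying the upstroke,
* ``I_NaL`` — late/persistent sodium current with slow inactivation,
  sustaining the plateau,
* ``I_CaL`` — L-type calcium current (``d``/``f`` gating) sustaining the
  plateau and triggering sarcoplasmic-reticulum release,
* ``I_Kr`` — rapid delayed-rectifier potassium current repolarising the
  plateau,
* ``I_K1`` — inward-rectifier potassium current setting the maximum
  diastolic potential,
* ``I_f`` — hyperpolarisation-activated "funny" current driving diastolic
  depolarisation (the pacemaker),

plus a calcium subsystem with SERCA uptake, graded SR release proportional
to the instantaneous L-type influx and saturating in SR load, SR leak, and
saturating sarcolemmal extrusion.

The whole-cell L-type current is written as a default maximal conductance
multiplied by ``n * b(D)``: the relative channel count ``n`` from the
regulation model times the single-channel block factor ``b`` of a calcium
channel blocker. The two enter only through their product, so a 90 % block
compensated by a ten-fold channel-count increase reproduces the control
model exactly — an identity the tests exploit.

Units package-wide: mV, ms, mM; currents in A/F with a unit membrane
capacitance.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    IntegrationError,
    InvalidParameterError,
    NumericalStateError,
)

__all__ = [
    "DrugBlock",
    "Trace",
    "SolverOptions",
    "CellModel",
    "MinimalHiPSCCM",
    "ical_scaling",
    "run_fixed_n",
    "limit_cycle_init",
    "LimitCycleInit",
    "compute_target_calcium",
    "cycle_average_calcium",
]

#: Protein types every compliant cell model must expose.
REQUIRED_PROTEIN_TYPES = ("CaL", "Na", "f", "Kr", "K1", "SERCA")


@dataclass(frozen=True)
class DrugBlock:
    """Calcium-channel-blocker effect as a single-channel scaling factor.

    ``block_factor`` is the fraction of single-channel current remaining:
    1 means no drug, 0.12 means an 88 % block (the 1 uM nifedipine case).
    """

    dose_uM: float = 0.0
    block_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.block_factor <= 1.0:
            raise InvalidParameterError("block_factor must lie in (0, 1]")
        if self.dose_uM < 0:
            raise InvalidParameterError("dose_uM must be non-negative")
        if self.dose_uM == 0 and self.block_factor != 1.0:
            raise InvalidParameterError("zero dose requires block_factor == 1")

    @classmethod
    def none(cls) -> "DrugBlock":
        return cls(0.0, 1.0)


@dataclass
class Trace:
    """Uniformly or non-uniformly sampled voltage (and calcium) time series."""

    time_ms: np.ndarray
    voltage: np.ndarray
    calcium: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.calcium is not None:
            self.calcium = np.asarray(self.calcium, dtype=float)
        if self.time_ms.shape != self.voltage.shape:
            raise InvalidParameterError("time and voltage must have equal length")
        if self.calcium is not None and self.calcium.shape != self.time_ms.shape:
            raise InvalidParameterError("calcium must match time length")
        if self.time_ms.size >= 2 and not np.all(np.diff(self.time_ms) > 0):
            raise InvalidParameterError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time_ms.size


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-solver settings used by every simulation in the package.

    LSODA switches automatically between non-stiff and BDF-type stiff
    multistep methods; ``atol_calcium`` is tighter than the voltage-scale
    tolerance because concentrations are four orders of magnitude smaller.
    """

    method: str = "LSODA"
    rtol: float = 1e-6
    atol_voltage: float = 1e-8
    atol_calcium: float = 1e-10
    max_step_ms: float = math.inf

    def atol_vector(self, model: "CellModel") -> np.ndarray:
        atol = np.full(len(model.state_names), self.atol_voltage)
        for i, name in enumerate(model.state_names):
            if name in ("c", "c_sr"):
                atol[i] = self.atol_calcium
        return atol


def ical_scaling(n: float, drug: DrugBlock) -> float:
    """Multiplicative factor ``n * b(D)`` on the default whole-cell I_CaL.

    The relative channel count and the single-channel block enter the
    current only through this product.
    """
    if not n > 0:
        raise InvalidParameterError("relative channel count n must be positive")
    return n * drug.block_factor


class CellModel(ABC):
    """Contract for a spontaneously beating cardiomyocyte ODE model.

    Implementations expose ordered state names (including membrane voltage
    ``V`` in mV and cytosolic calcium ``c`` in mM), per-protein-type density
    scale factors, and a derivative evaluator in which the whole-cell
    L-type conductance is multiplied by ``ical_scaling(n, drug)``.
    """

    #: ordered state labels; must contain "V" and "c"
    state_names: tuple[str, ...]
    #: protein-type labels whose densities can be scaled; superset of
    #: REQUIRED_PROTEIN_TYPES
    protein_types: tuple[str, ...]

    @abstractmethod
    def default_state(self) -> np.ndarray:
        """A reasonable starting state (not necessarily on the limit cycle)."""

    @abstractmethod
    def derivatives(
        self,
        state: np.ndarray,
        t: float,
        scales: Mapping[str, float] | None = None,
        drug: DrugBlock | None = None,
        n: float = 1.0,
    ) -> np.ndarray:
        """Full right-hand side of the cell ODE system."""

    @property
    def voltage_index(self) -> int:
        return self.state_names.index("V")

    @property
    def calcium_index(self) -> int:
        return self.state_names.index("c")

    def validate_scales(self, scales: Mapping[str, float] | None) -> dict[str, float]:
        full = {p: 1.0 for p in self.protein_types}
        if scales:
            for key, value in scales.items():
                if key not in full:
                    raise InvalidParameterError(
                        f"unknown protein type {key!r}; supported: {self.protein_types}"
                    )
                if value < 0:
                    raise InvalidParameterError("scale factors must be non-negative")
                full[key] = float(value)
        return full


# Default parameters of the minimal model. Conductances in A/F per unit
# driving force (mS/uF), fluxes in mM/ms, calibrated so the default limit
# cycle beats at ~1.6 Hz with APD50 near 180 ms and a cytosolic calcium
# transient in the 1e-4 mM range.
_MINIMAL_PARAMS: dict[str, float] = {
    # maximal conductances (mS/uF) and reversal potentials (mV)
    "g_Na": 8.0,
    "g_NaL": 0.02,  # late/persistent sodium component
    "g_CaL": 0.30,
    "g_Kr": 0.25,
    "g_K1": 0.25,
    "g_f": 0.12,
    "E_Na": 70.0,
    "E_K": -86.0,
    "E_CaL": 60.0,
    "E_f": -15.0,
    # gate midpoints (mV), slopes (mV) and time constants (ms)
    "V_m": -36.0, "k_m": 5.0,
    "V_h": -64.0, "k_h": 6.0, "tau_h_base": 3.0, "tau_h_amp": 22.0,
    "V_d": -25.0, "k_d": 5.5, "tau_d": 2.0,
    "V_f": -28.0, "k_f": 4.5, "tau_f": 250.0,
    "V_xr": -24.0, "k_xr": 6.0, "tau_xr": 300.0,
    "V_k1": -68.0, "k_k1": 7.0,
    "V_y": -68.0, "k_y": 6.0, "tau_y": 400.0,
    "V_mL": -50.0, "k_mL": 6.0,
    "V_hL": -55.0, "k_hL": 6.0, "tau_hL": 600.0,
    # calcium handling
    "k_flux_CaL": 5.0e-8,  # A/F -> mM/ms conversion for L-type influx
    "v_up": 5.0e-7,  # SERCA maximal uptake, mM/ms
    "K_up": 6.25e-5,  # SERCA half-saturation, mM
    "k_rel": 200.0,  # graded-release gain on the SR-load factor
    "K_sr": 0.0125,  # SR-load half-saturation of release, mM
    "k_leak": 1.0e-6,  # SR leak rate, 1/ms
    "v_out": 1.6e-6,  # lumped extrusion (NCX/PMCA) max rate, mM/ms
    "K_out": 3.0e-4,  # extrusion half-saturation, mM (Hill 2)
    "vol_ratio": 45.0,  # cytosol/SR volume ratio
}


class MinimalHiPSCCM(CellModel):
    """Compact spontaneously beating hiPSC-CM-like action potential model.

    Nine states: membrane voltage ``V``; gates ``h`` (Na inactivation),
    ``d``/``f`` (CaL activation/inactivation), ``xr`` (Kr activation),
    ``y`` (funny-current activation), ``hL`` (late-Na inactivation);
    cytosolic calcium ``c`` and SR calcium ``c_sr``. Sodium activation is
    taken at its voltage-dependent steady state, which removes the
    sub-millisecond gating time scale without losing the upstroke.

    Parameters may be overridden per instance; scale factors multiply the
    density parameter of the matching protein type (``CaL`` additionally
    carries the regulation/drug product ``n * b``).
    """

    state_names = ("V", "h", "d", "f", "xr", "y", "hL", "c", "c_sr")
    protein_types = ("CaL", "Na", "f", "Kr", "K1", "SERCA", "NCX")

    def __init__(self, params: Mapping[str, float] | None = None):
        self.params = dict(_MINIMAL_PARAMS)
        if params:
            unknown = set(params) - set(self.params)
            if unknown:
                raise InvalidParameterError(f"unknown model parameters: {sorted(unknown)}")
            self.params.update(params)

    def default_state(self) -> np.ndarray:
        # diastolic guess; run limit_cycle_init for an on-cycle state
        return np.array([-75.0, 0.8, 0.0, 0.9, 0.05, 0.1, 0.9, 2.5e-5, 0.02])

    # gate steady states and time constants -------------------------------

    def _gates(self, V: float) -> tuple[float, ...]:
        p = self.params
        m_inf = 1.0 / (1.0 + math.exp(-(V - p["V_m"]) / p["k_m"]))
        h_inf = 1.0 / (1.0 + math.exp((V - p["V_h"]) / p["k_h"]))
        tau_h = p["tau_h_base"] + p["tau_h_amp"] / (1.0 + math.exp((V + 50.0) / 8.0))
        d_inf = 1.0 / (1.0 + math.exp(-(V - p["V_d"]) / p["k_d"]))
        tau_d = p["tau_d"]
        f_inf = 1.0 / (1.0 + math.exp((V - p["V_f"]) / p["k_f"]))
        tau_f = p["tau_f"]
        xr_inf = 1.0 / (1.0 + math.exp(-(V - p["V_xr"]) / p["k_xr"]))
        tau_xr = p["tau_xr"]
        k1_inf = 1.0 / (1.0 + math.exp((V - p["V_k1"]) / p["k_k1"]))
        y_inf = 1.0 / (1.0 + math.exp((V - p["V_y"]) / p["k_y"]))
        tau_y = p["tau_y"]
        hL_inf = 1.0 / (1.0 + math.exp((V - p["V_hL"]) / p["k_hL"]))
        tau_hL = p["tau_hL"]
        return (m_inf, h_inf, tau_h, d_inf, tau_d, f_inf, tau_f,
                xr_inf, tau_xr, k1_inf, y_inf, tau_y, hL_inf, tau_hL)

    def derivatives(
        self,
        state: np.ndarray,
        t: float = 0.0,
        scales: Mapping[str, float] | None = None,
        drug: DrugBlock | None = None,
        n: float = 1.0,
    ) -> np.ndarray:
        s = self.validate_scales(scales)
        drug = drug or DrugBlock.none()
        V, h, d, f, xr, y, hL, c, c_sr = (float(v) for v in state)
        if not all(map(math.isfinite, (V, h, d, f, xr, y, hL, c, c_sr))):
            bad = [nm for nm, v in zip(self.state_names, state) if not math.isfinite(v)]
            raise NumericalStateError(f"non-finite state component(s): {bad}")

        p = self.params
        (m_inf, h_inf, tau_h, d_inf, tau_d, f_inf, tau_f,
         xr_inf, tau_xr, k1_inf, y_inf, tau_y, hL_inf, tau_hL) = self._gates(V)

        cal_factor = ical_scaling(n, drug) * s["CaL"]
        mL_inf = 1.0 / (1.0 + math.exp(-(V - p["V_mL"]) / p["k_mL"]))
        I_Na = p["g_Na"] * s["Na"] * m_inf ** 3 * h * (V - p["E_Na"])
        I_NaL = p["g_NaL"] * s["Na"] * mL_inf * hL * (V - p["E_Na"])
        I_CaL = p["g_CaL"] * cal_factor * d * f * (V - p["E_CaL"])
        I_Kr = p["g_Kr"] * s["Kr"] * xr * (V - p["E_K"])
        I_K1 = p["g_K1"] * s["K1"] * k1_inf * (V - p["E_K"])
        I_f = p["g_f"] * s["f"] * y * (V - p["E_f"])

        dV = -(I_Na + I_NaL + I_CaL + I_Kr + I_K1 + I_f)

        # calcium subsystem: L-type influx, graded SR release (saturating in
        # SR load), SERCA uptake, SR leak and lumped extrusion (NCX/PMCA)
        j_cal = max(-p["k_flux_CaL"] * I_CaL, 0.0)  # inward current -> influx
        j_up = p["v_up"] * s["SERCA"] * c * c / (c * c + p["K_up"] ** 2)
        j_rel = p["k_rel"] * c_sr / (1.0 + c_sr / p["K_sr"]) * j_cal
        j_leak = p["k_leak"] * (c_sr - c)
        # saturating Hill-2 extrusion: cooperativity makes the cycle mean
        # sensitive to transient shape, not just to total influx
        j_out = p["v_out"] * s["NCX"] * c * c / (c * c + p["K_out"] ** 2)
        dc = j_cal + j_rel + j_leak - j_up - j_out
        dc_sr = (j_up - j_rel - j_leak) * p["vol_ratio"]

        return np.array(
            [
                dV,
                (h_inf - h) / tau_h,
                (d_inf - d) / tau_d,
                (f_inf - f) / tau_f,
                (xr_inf - xr) / tau_xr,
                (y_inf - y) / tau_y,
                (hL_inf - hL) / tau_hL,
                dc,
                dc_sr,
            ]
        )


def _integrate(
    model: CellModel,
    state0: np.ndarray,
    t_span: tuple[float, float],
    *,
    scales: Mapping[str, float] | None,
    drug: DrugBlock,
    n: float,
    solver: SolverOptions,
    t_eval: np.ndarray | None = None,
    dense_output: bool = False,
):
    full_scales = model.validate_scales(scales)

    def rhs(t, y):
        return model.derivatives(y, t, full_scales, drug, n)

    sol = solve_ivp(
        rhs,
        t_span,
        np.asarray(state0, dtype=float),
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol_vector(model),
        max_step=solver.max_step_ms,
        t_eval=t_eval,
        dense_output=dense_output,
    )
    if not sol.success:
        raise IntegrationError(
            f"cell-model integration failed: {sol.message}",
            t_fail=float(sol.t[-1]) if sol.t.size else t_span[0],
        )
    return sol


def run_fixed_n(
    model: CellModel,
    n: float = 1.0,
    drug: DrugBlock | None = None,
    duration_ms: float = 10_000.0,
    initial_state: np.ndarray | None = None,
    *,
    scales: Mapping[str, float] | None = None,
    solver: SolverOptions | None = None,
    dt_sample_ms: float = 1.0,
    t0_ms: float = 0.0,
) -> Trace:
    """Integrate the cell model at a frozen channel count; return a Trace.

    Deterministic for fixed inputs and solver tolerances. The trace is
    sampled on a uniform grid of ``dt_sample_ms`` and carries the final full
    state vector in ``metadata["final_state"]`` so runs can be chained.
    """
    if not duration_ms > 0:
        raise InvalidParameterError("duration_ms must be positive")
    drug = drug or DrugBlock.none()
    solver = solver or SolverOptions()
    state0 = model.default_state() if initial_state is None else initial_state
    t_eval = np.arange(t0_ms, t0_ms + duration_ms + 0.5 * dt_sample_ms, dt_sample_ms)
    sol = _integrate(
        model,
        state0,
        (t0_ms, float(t_eval[-1])),
        scales=scales,
        drug=drug,
        n=n,
        solver=solver,
        t_eval=t_eval,
    )
    iv, ic = model.voltage_index, model.calcium_index
    return Trace(
        time_ms=sol.t,
        voltage=sol.y[iv],
        calcium=sol.y[ic],
        metadata={
            "sampling": "uniform",
            "dt_ms": dt_sample_ms,
            "units": {"time": "ms", "voltage": "mV", "calcium": "mM"},
            "n": n,
            "block_factor": drug.block_factor,
            "solver": {"method": solver.method, "rtol": solver.rtol},
            "final_state": sol.y[:, -1].copy(),
        },
    )


def _upstroke_times_from_arrays(
    t: np.ndarray, v: np.ndarray, min_amplitude_mV: float = 20.0
) -> np.ndarray:
    """Upstroke times on a model voltage trace (50 %-amplitude crossings).

    Lightweight internal detector for phase alignment and cycle averaging;
    the biomarkers module has the full configurable pipeline.
    """
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmax - vmin < min_amplitude_mV:
        return np.empty(0)
    thr = 0.5 * (vmin + vmax)
    above = v >= thr
    rising = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -math.inf
    for i in rising:
        # linear interpolation of the crossing time
        tc = t[i] + (thr - v[i]) * (t[i + 1] - t[i]) / (v[i + 1] - v[i])
        if tc - last >= 200.0:  # refractory guard
            times.append(tc)
            last = tc
    return np.asarray(times)


@dataclass
class LimitCycleInit:
    """Result of limit-cycle equilibration: a state plus a quiescence flag."""

    state: np.ndarray
    quiescent: bool
    upstroke_time_ms: float | None = None


def limit_cycle_init(
    model: CellModel,
    n_fixed: float = 1.0,
    drug: DrugBlock | None = None,
    *,
    scales: Mapping[str, float] | None = None,
    equilibration_ms: float = 480_000.0,
    solver: SolverOptions | None = None,
) -> LimitCycleInit:
    """Equilibrate onto the limit cycle at fixed ``n``; upstroke-aligned.

    Runs ``equilibration_ms`` of model time from the default state (the
    default 480 s covers the slow loading of the sarcoplasmic reticulum,
    whose content relaxes with a tens-of-seconds time constant), detects
    upstrokes in the final 10 s, and returns the state at the last upstroke.
    A quiescent model (no beats in the final window) is legal: the end state
    is returned with ``quiescent=True``.
    """
    drug = drug or DrugBlock.none()
    solver = solver or SolverOptions()
    settle = max(equilibration_ms - 10_000.0, 0.0)
    state = model.default_state()
    if settle > 0:
        sol = _integrate(
            model, state, (0.0, settle),
            scales=scales, drug=drug, n=n_fixed, solver=solver,
            t_eval=np.array([settle]),
        )
        state = sol.y[:, -1]
    sol = _integrate(
        model, state, (settle, equilibration_ms),
        scales=scales, drug=drug, n=n_fixed, solver=solver,
        dense_output=True,
    )
    iv = model.voltage_index
    t_grid = np.arange(settle, equilibration_ms, 1.0)
    v_grid = sol.sol(t_grid)[iv]
    ups = _upstroke_times_from_arrays(t_grid, v_grid)
    if ups.size == 0:
        return LimitCycleInit(state=sol.y[:, -1].copy(), quiescent=True)
    t_up = float(ups[-1])
    return LimitCycleInit(
        state=np.asarray(sol.sol(t_up), dtype=float),
        quiescent=False,
        upstroke_time_ms=t_up,
    )


def cycle_average_calcium(trace: Trace) -> tuple[float, bool]:
    """Time-averaged cytosolic calcium over complete AP cycles.

    Averages by trapezoidal quadrature between the first and last detected
    upstroke (complete upstroke-delimited cycles). A quiescent trace falls
    back to the plain window mean; the second return value flags that case.
    """
    if trace.calcium is None:
        raise InvalidParameterError("trace carries no calcium channel")
    ups = _upstroke_times_from_arrays(trace.time_ms, trace.voltage)
    if ups.size < 2:
        mean = float(
            np.trapezoid(trace.calcium, trace.time_ms)
            / (trace.time_ms[-1] - trace.time_ms[0])
        )
        return mean, True
    t0, t1 = ups[0], ups[-1]
    mask = (trace.time_ms >= t0) & (trace.time_ms <= t1)
    tt, cc = trace.time_ms[mask], trace.calcium[mask]
    return float(np.trapezoid(cc, tt) / (tt[-1] - tt[0])), False


def compute_target_calcium(
    model: CellModel,
    *,
    solver: SolverOptions | None = None,
    equilibration_ms: float = 480_000.0,
    window_ms: float = 10_000.0,
) -> float:
    """Target concentration ``c*``: cycle-averaged calcium of the default model.

    Equilibrates the default model (all scales 1, no drug, ``n = 1``) and
    averages cytosolic calcium over complete upstroke-delimited cycles in
    the final ``window_ms``. A quiescent default model is a configuration
    error — the regulation setpoint would be undefined.
    """
    solver = solver or SolverOptions()
    init = limit_cycle_init(
        model, 1.0, DrugBlock.none(), equilibration_ms=equilibration_ms, solver=solver
    )
    trace = run_fixed_n(
        model, 1.0, DrugBlock.none(), window_ms, init.state, solver=solver
    )
    cstar, quiescent = cycle_average_calcium(trace)
    if quiescent or init.quiescent:
        raise ConfigurationError(
            "default cell model is quiescent; target calcium undefined"
        )
    return cstar
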