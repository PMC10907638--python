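"""Expression-regulation dynamics for L-type calcium channel density.

Two model variants are provided:

* the original two-ODE model, in which the relative mRNA count ``m`` tracks
  the deviation of cytosolic calcium ``c`` from its target ``c*`` and the
  relative channel count ``n`` relaxes toward ``m``::

      tau_m dm/dt = c* - c        (tau_m in mM*ms)
      tau_n dn/dt = m - n         (tau_n in ms)

* the bounded scalar refinement, which collapses the system to one equation
  in ``n`` and multiplies the drive by a smooth gate ``H(c, n)`` that shuts
  off growth above ``n_plus`` and decay below ``n_minus``::

      tau dn/dt = (c* - c) * H(c, n)     (tau in mM*ms)

The gate is built from tanh switches ``h(a, b, eps) = (1 + tanh((a-b)/eps))/2``
and equals 1 everywhere except in the two corner regimes (n above the upper
bound while calcium is below target, and n below the lower bound while
calcium is above target), where it vanishes.

Because the two usages of the protein time constant carry different units
(ms in the two-ODE model, mM*ms in the scalar model) the parameter container
keeps them as separate fields, ``tau_n_traffic_ms`` and ``tau_scalar_mM_ms``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidParameterError

__all__ = [
    "RegulationParams",
    "RegulationState",
    "sigmoid_gate",
    "expression_gate",
    "two_ode_rhs",
    "bounded_scalar_rhs",
    "gronwall_bound",
    "predicted_equilibrium_n",
]


@dataclass(frozen=True)
class RegulationParams:
    """Parameters of the expression-regulation models.

    Attributes
    ----------
    tau_m_mM_ms:
        Time scale of the mRNA equation (mM*ms). Default 400.
    tau_n_traffic_ms:
        Time scale of protein trafficking in the two-ODE model (ms).
        Default 1000.
    tau_scalar_mM_ms:
        Time scale of the bounded scalar model (mM*ms). Default 400.
    c_target_mM:
        Target cytosolic calcium concentration ``c*`` (mM). Must be set from
        the coupled cell model (cycle-averaged calcium of the default limit
        cycle); no universal default exists, so it is required.
    n_minus, n_plus:
        Lower and upper bounds on the relative channel count (dimensionless).
        Defaults 0.1 and 3.
    eps_n:
        Gate steepness in ``n`` (dimensionless). Default 0.01.
    eps_c_mM:
        Gate steepness in ``c`` (mM). Default 1e-7.
    """

    c_target_mM: float
    tau_m_mM_ms: float = 400.0
    tau_n_traffic_ms: float = 1000.0
    tau_scalar_mM_ms: float = 400.0
    n_minus: float = 0.1
    n_plus: float = 3.0
    eps_n: float = 0.01
    eps_c_mM: float = 1e-7

    def __post_init__(self) -> None:
        for name in ("tau_m_mM_ms", "tau_n_traffic_ms", "tau_scalar_mM_ms"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not self.eps_n > 0:
            raise InvalidParameterError("eps_n must be strictly positive")
        if not self.eps_c_mM > 0:
            raise InvalidParameterError("eps_c_mM must be strictly positive")
        if not (0 < self.n_minus < self.n_plus):
            raise InvalidParameterError("bounds must satisfy 0 < n_minus < n_plus")
        if not self.c_target_mM > 0:
            raise InvalidParameterError("c_target_mM must be strictly positive")


@dataclass
class RegulationState:
    """State of the regulation ODEs: relative mRNA and channel counts.

    The scalar model carries ``n`` only; ``m`` is then ignored. Absolute
    counts ``M = m*M0`` and ``N = n*N0`` never appear — the cell model
    consumes the relative count through a multiplicative conductance scaling.
    """

    m: float = 1.0
    n: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.m) and math.isfinite(self.n)):
            raise InvalidParameterError("regulation state must be finite")
        if not self.n > 0:
            raise InvalidParameterError("relative channel count n must be positive")


def sigmoid_gate(a: float, b: float, eps: float) -> float:
    """Smooth switch ``h(a, b, eps) = (1 + tanh((a - b)/eps)) / 2``.

    Rises from 0 to 1 as ``a`` crosses ``b``, over a width set by ``eps``.
    Satisfies the complement identity ``h(a,b,e) + h(b,a,e) == 1`` exactly
    (tanh is odd).
    """
    if not eps > 0:
        raise InvalidParameterError("gate steepness eps must be strictly positive")
    return 0.5 * (1.0 + math.tanh((a - b) / eps))


def expression_gate(c: float, n: float, params: RegulationParams) -> float:
    """Expression gate ``H(c, n)`` bounding channel-count growth.

    ``H = h(n, n-, eps_n) h(c, c*, eps_c) + h(n+, n, eps_n) h(c*, c, eps_c)``.

    Equals 1 whenever ``n`` lies well inside ``(n_minus, n_plus)`` (the two
    c-gates are complementary and each n-gate saturates at 1), and drops to 0
    in the two corner regimes where growth past a bound would otherwise
    continue.
    """
    hn_lo = sigmoid_gate(n, params.n_minus, params.eps_n)
    hn_hi = sigmoid_gate(params.n_plus, n, params.eps_n)
    hc_hi = sigmoid_gate(c, params.c_target_mM, params.eps_c_mM)
    return hn_lo * hc_hi + hn_hi * (1.0 - hc_hi)


def two_ode_rhs(
    state: RegulationState, c: float, params: RegulationParams
) -> tuple[float, float]:
    """Right-hand side of the original two-ODE model.

    Returns ``(dm/dt, dn/dt)`` in 1/ms:
    ``dm/dt = (c* - c)/tau_m`` and ``dn/dt = (m - n)/tau_n``.
    """
    dm = (params.c_target_mM - c) / params.tau_m_mM_ms
    dn = (state.m - state.n) / params.tau_n_traffic_ms
    return dm, dn


def bounded_scalar_rhs(n: float, c: float, params: RegulationParams) -> float:
    """Right-hand side of the bounded scalar model, ``dn/dt`` in 1/ms.

    ``dn/dt = (c* - c) H(c, n) / tau``. Vanishes at ``c = c*`` for every
    ``n``; elsewhere its sign is that of ``c* - c`` wherever the gate is
    open.
    """
    return (
        (params.c_target_mM - c)
        * expression_gate(c, n, params)
        / params.tau_scalar_mM_ms
    )


def gronwall_bound(
    t: float, p0: float, cdev_sup: float, params: RegulationParams
) -> float:
    """Gronwall envelope for the mRNA/protein deviation ``p = |m - n|``.

    ``p(t) <= exp(-t/tau_n) (p0 - (tau_n/tau_m) sup|c*-c|)
              + (tau_n/tau_m) sup|c*-c|``

    with ``tau_n`` the trafficking time scale and ``sup|c*-c|`` the largest
    calcium deviation along the trajectory. As ``t → ∞`` the bound tends to
    ``(tau_n/tau_m) sup|c*-c|``, which is why the two-ODE system collapses
    onto a scalar model: the deviation is of order 1e-3 for the default
    parameters.
    """
    if t < 0:
        raise InvalidParameterError("time t must be non-negative")
    if cdev_sup < 0:
        raise InvalidParameterError("cdev_sup must be non-negative")
    asymptote = (params.tau_n_traffic_ms / params.tau_m_mM_ms) * cdev_sup
    return math.exp(-t / params.tau_n_traffic_ms) * (p0 - asymptote) + asymptote


def predicted_equilibrium_n(block_factor: float, n_plus: float = math.inf) -> float:
    """Equilibrium relative channel count under a single-channel block.

    The whole-cell L-type current scales with the product ``n * b``; average
    cytosolic calcium reattains its target exactly when that product returns
    to 1, so the unbounded model equilibrates at ``n = 1/b``. The bounded
    model halts at ``n_plus`` if compensation would require more:
    ``n_eq = min(1/b, n_plus)``.
    """
    if not 0 < block_factor <= 1:
        raise InvalidParameterError("block_factor must lie in (0, 1]")
    return min(1.0 / block_factor, n_plus)
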