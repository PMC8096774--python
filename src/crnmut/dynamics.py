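"""Stiff integration of the mass-action ODEs to an asymptotic steady state.

The steady state is defined operationally as the solution value at the end
of a long integration window (default t_end = 2.5e7 time units), obtained
with a variable-order implicit multistep solver suited to the stiff,
widely-separated timescales of signaling networks.  The default is LSODA,
which switches itself onto BDF multistep formulas in stiff regions; scipy's
plain ``BDF`` stepper is available via ``method`` but its step-size control
can freeze (steps stop growing near equilibrium) on some rate-constant
draws, so it is not the default.  ``||dx/dt||_inf`` along
the trajectory is the convergence diagnostic; moiety conservation drift is
the correctness oracle tying the integration back to the conservation
analysis.

Numerical choices
-----------------
* rtol 1e-6, atol 1e-12 nM by default, both exposed.
* Negative concentrations are never clipped.  Terminal entries below
  ``-atol`` abort with an integrity error (a signal of a bug or of
  tolerances too loose); entries in ``[-atol, 0)`` are reported as 0.
* An optional early exit fires when ``||dx/dt||_inf`` stays below the
  steady tolerance; it is off by default so the fixed-window protocol is
  reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .conservation import ConservationSet
from .errors import ContractError, IntegrityError
from .network import ReactionNetwork, _raw_fluxes, ode_jacobian

__all__ = [
    "SteadyStateResult",
    "integrate_to_steady",
    "relative_difference",
    "derivative_infnorm_series",
]

T_END_DEFAULT = 2.5e7


@dataclass
class SteadyStateResult:
    x_e: np.ndarray
    t_end: float
    times: np.ndarray
    trajectory: np.ndarray              # n x len(times)
    dxdt_infnorm_series: np.ndarray
    converged: bool
    max_drift: float | None             # relative, None if no CS given
    solver_stats: dict = field(default_factory=dict)


def integrate_to_steady(net: ReactionNetwork, x0: np.ndarray,
                        t_end: float = T_END_DEFAULT,
                        rtol: float = 1e-6, atol: float = 1e-12,
                        method: str = "LSODA",
                        steady_tol: float = 1e-6,
                        conservation: ConservationSet | None = None,
                        drift_tol: float = 1e-6,
                        early_exit: bool = False,
                        ) -> SteadyStateResult:
    """Integrate dx/dt = S v(x, k) on [0, t_end] and return the endpoint.

    When a :class:`ConservationSet` is supplied, the relative drift of every
    conserved total over the solver's output points is checked against
    ``drift_tol``; exceeding it raises :class:`IntegrityError`.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n,):
        raise ContractError(f"expected initial state of length {net.n}")
    if np.any(x0 < 0):
        raise ContractError("initial state must be non-negative")

    def rhs(t, x):
        return net.S @ _raw_fluxes(net, x)

    def jac(t, x):
        return ode_jacobian(net, x)

    events = None
    if early_exit:
        scale0 = 1.0 + float(np.max(np.abs(x0)))

        def ev(t, x):
            return float(np.max(np.abs(rhs(t, x)))) - steady_tol * scale0
        ev.terminal = True
        ev.direction = -1
        events = ev

    sol = solve_ivp(rhs, (0.0, t_end), x0, method=method, jac=jac,
                    rtol=rtol, atol=atol, events=events)
    if not sol.success:
        raise IntegrityError(f"solver failed at t = {sol.t[-1]:.6g}: "
                             f"{sol.message}")
    times, traj = sol.t, sol.y
    x_e = traj[:, -1].copy()
    if np.any(x_e < -atol):
        bad = [net.species[i].name for i in np.nonzero(x_e < -atol)[0]]
        raise IntegrityError(
            f"terminal concentrations below -atol for species {bad}")
    x_e[(x_e < 0)] = 0.0

    norms = derivative_infnorm_series(net, times, traj)
    scale = 1.0 + float(np.max(np.abs(x_e)))
    converged = bool(norms[-1] <= steady_tol * scale)

    max_drift = None
    if conservation is not None and conservation.p:
        totals = conservation.N @ traj
        ref = totals[:, [0]]
        drift = np.abs(totals - ref) / (1.0 + np.abs(ref))
        max_drift = float(np.max(drift))
        if max_drift > drift_tol:
            raise IntegrityError(
                f"conservation drift {max_drift:.3e} exceeds tolerance "
                f"{drift_tol:.1e}: integration is not trustworthy")

    stats = {"n_steps": int(sol.t.size), "nfev": int(sol.nfev),
             "njev": int(getattr(sol, "njev", 0)),
             "rtol": rtol, "atol": atol, "method": method,
             "early_exit": bool(early_exit and sol.status == 1)}
    if stats["early_exit"]:
        stats["t_exit"] = float(times[-1])
    return SteadyStateResult(x_e=x_e, t_end=float(times[-1]), times=times,
                             trajectory=traj,
                             dxdt_infnorm_series=norms,
                             converged=converged, max_drift=max_drift,
                             solver_stats=stats)


def relative_difference(x_mut: np.ndarray, x_phys: np.ndarray) -> np.ndarray:
    """Per-species relative steady-state change d_i = (x^m_i - x_i) / x_i.

    ``d_i = -1`` means species i is fully suppressed in the mutated cell;
    ``d_i > 0`` means it increased.  Entries with a zero physiological
    denominator are undefined and returned as NaN (never +-inf).
    """
    x_mut = np.asarray(x_mut, dtype=float)
    x_phys = np.asarray(x_phys, dtype=float)
    if x_mut.shape != x_phys.shape:
        raise ContractError("shape mismatch in relative_difference")
    d = np.full_like(x_phys, np.nan)
    nz = x_phys != 0
    d[nz] = (x_mut[nz] - x_phys[nz]) / x_phys[nz]
    return d


def derivative_infnorm_series(net: ReactionNetwork, times: np.ndarray,
                              states: np.ndarray) -> np.ndarray:
    """||S v(x(t), k)||_inf at each output time (convergence diagnostic)."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] != net.n:
        states = states.T
    out = np.empty(states.shape[1])
    for t in range(states.shape[1]):
        out[t] = np.max(np.abs(net.S @ _raw_fluxes(net, states[:, t])))
    return out
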