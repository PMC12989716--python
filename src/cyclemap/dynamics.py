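"""Integration of the tissue ODE model and therapy-scenario analysis.

A :class:`Scenario` bundles parameters, an initial state, a time window and a
``blocking_efficacy`` — the fraction of endocycle entries a hypothetical
endocycle-blocking therapy prevents.  Therapy scales the success probability
``eta`` (normal cells still *attempt* whole-genome duplication and leave the
normal pool at rate ``phi_N``, but a blocked attempt produces no endocycle
cell); a flag switches to scaling the attempt rate ``phi_N`` itself instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (
    ModelParameters,
    TissueState,
    _rhs_raw,
    immune_killing_rate,
)

__all__ = [
    "Scenario",
    "Trajectory",
    "integrate",
    "prestress_equilibrium",
    "cancer_invasion_fitness",
    "summarize",
]

logger = logging.getLogger(__name__)

#: solver tolerance below which tiny negative populations are clamped to 0
_CLAMP_TOL = 1e-6


@dataclass(frozen=True)
class Scenario:
    """One simulation run: window, initial state, therapy strength, parameters.

    ``blocking_efficacy`` in [0, 1]: 0 is the untreated baseline, 1 blocks
    every endocycle entry.  ``initial_state=None`` starts from the pre-stress
    tissue equilibrium.
    """

    t_start: float = 0.0
    t_end: float = 400.0
    dt_report: float = 0.5
    initial_state: Optional[TissueState] = None
    blocking_efficacy: float = 0.0
    block_attempts: bool = False  # scale phi_N instead of eta
    params: ModelParameters = field(default_factory=ModelParameters)

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not 0.0 <= self.blocking_efficacy <= 1.0:
            raise ValueError("blocking_efficacy must be in [0, 1]")
        if self.dt_report <= 0:
            raise ValueError("dt_report must be positive")


@dataclass
class Trajectory:
    """Solution reported on a regular time grid.

    ``states`` has one row per time point with columns [N, E, C].
    """

    times: np.ndarray
    states: np.ndarray
    scenario: Scenario
    solver: dict

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 3):
            raise ValueError("states must have shape (len(times), 3)")

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 2]

    def endocycle_fraction(self) -> np.ndarray:
        """Percent endocycle cells over time (0 where the tissue is empty)."""
        total = self.states.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, 100.0 * self.E / total, 0.0)
        return frac

    def to_frame(self) -> pd.DataFrame:
        from .model import mutation_rate

        rows = pd.DataFrame(
            {"time": self.times, "N": self.N, "E": self.E, "C": self.C}
        )
        rows["endocycle_fraction"] = self.endocycle_fraction()
        params = self.scenario.params
        states = [TissueState(*np.maximum(s, 0.0)) for s in self.states]
        rows["mu"] = [mutation_rate(s, params) for s in states]
        rows["kappa"] = [immune_killing_rate(s, params) for s in states]
        return rows


def integrate(scenario: Scenario, method: str = "RK45", rtol: float = 1e-8,
              atol: float = 1e-8) -> Trajectory:
    """Integrate the scenario adaptively; report states on the dt_report grid.

    Therapy enters as an effective success probability
    ``eta' = eta * (1 - blocking_efficacy)`` (or as a scaled ``phi_N`` when
    ``block_attempts`` is set).  Negative values within solver tolerance are
    clamped to zero and logged.
    """
    params = scenario.params
    if scenario.block_attempts:
        params = replace(params, phiN_max=params.phiN_max * (1.0 - scenario.blocking_efficacy))
        eta_eff = params.eta
    else:
        eta_eff = params.eta * (1.0 - scenario.blocking_efficacy)

    x0 = scenario.initial_state
    if x0 is None:
        x0 = prestress_equilibrium(params)
    n_pts = int(round((scenario.t_end - scenario.t_start) / scenario.dt_report)) + 1
    t_eval = np.linspace(scenario.t_start, scenario.t_end, n_pts)

    if method == "RK4":
        states = _rk4(params, eta_eff, x0.as_array(), t_eval, dt=0.01)
        meta = {"method": "RK4", "dt": 0.01}
    else:
        sol = solve_ivp(
            lambda t, y: _rhs_raw(t, y, params, eta_eff),
            (scenario.t_start, scenario.t_end),
            x0.as_array(),
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE integration failed at t={sol.t[-1] if sol.t.size else scenario.t_start}: "
                f"{sol.message}"
            )
        states = sol.y.T
        meta = {"method": method, "rtol": rtol, "atol": atol}

    neg = states < 0
    if neg.any():
        worst = states[neg].min()
        if worst < -_CLAMP_TOL:
            logger.warning("negative populations beyond tolerance (min %.3g); clamping", worst)
        else:
            logger.debug("clamped tiny negative populations (min %.3g)", worst)
        states = np.maximum(states, 0.0)
    return Trajectory(times=t_eval, states=states, scenario=scenario, solver=meta)


def _rk4(params: ModelParameters, eta: float, y0: np.ndarray,
         t_eval: np.ndarray, dt: float) -> np.ndarray:
    """Fixed-step classical Runge-Kutta, used as a solver-independence check."""
    out = np.empty((t_eval.size, 3))
    out[0] = y0
    y = y0.copy()
    t = t_eval[0]
    for i in range(1, t_eval.size):
        target = t_eval[i]
        while t < target - 1e-12:
            h = min(dt, target - t)
            k1 = _rhs_raw(t, y, params, eta)
            k2 = _rhs_raw(t + h / 2, y + h / 2 * k1, params, eta)
            k3 = _rhs_raw(t + h / 2, y + h / 2 * k2, params, eta)
            k4 = _rhs_raw(t + h, y + h * k3, params, eta)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = y
    return out


def prestress_equilibrium(params: ModelParameters = ModelParameters()) -> TissueState:
    """Tissue equilibrium before chronic stress (``phi_N`` forced to 0).

    With no endocycle influx E decays to 0, leaving a 2-D balance in (N, C):
    logistic growth of N against death, and a small cancer pool sustained by
    the baseline mutation influx ``alpha*mu(0)*N*L`` against immune killing.
    Used as the default initial condition.
    """
    # with phi_N = 0 the E equation is dE/dt = -(phi_E + delta) E -> E* = 0
    no_stress = replace(params, phiN_max=0.0)

    growth0 = params.alpha * (1.0 - _mu_at_zero(params))
    if params.delta >= growth0:
        return TissueState(0.0, 0.0, 0.0)  # super-critical death: extinction

    def f(y: np.ndarray) -> np.ndarray:
        d = _rhs_raw(0.0, np.array([y[0], 0.0, y[1]]), no_stress)
        return np.array([d[0], d[2]])

    n_guess = params.K * (1.0 - params.delta / growth0)
    sol = root(f, np.array([n_guess, 1.0]), tol=1e-12)
    n_star, c_star = sol.x
    if not sol.success or not (0 < n_star < params.K) or c_star < -1e-9 or c_star > params.K:
        raise RuntimeError(f"no pre-stress equilibrium found in (0, K): {sol.message}")
    return TissueState(n_star, 0.0, max(c_star, 0.0))


def _mu_at_zero(params: ModelParameters) -> float:
    return params.mu_max / (1.0 + np.exp(params.mu_slope * params.mu_mid))


def cancer_invasion_fitness(state: TissueState, params: ModelParameters = ModelParameters()) -> float:
    """Per-capita growth rate (/day) of a rare cancer clone at a resident state.

    ``beta*(K-N-E-C)/K - delta - kappa(X)``: positive iff cancer can invade.
    Endocycling raises this fitness by suppressing ``kappa``.
    """
    L = (params.K - state.total) / params.K
    return params.beta * L - params.delta - immune_killing_rate(state, params)


def summarize(traj: Trajectory, invasion_threshold_frac: float = 0.01) -> dict:
    """Endpoint metrics of a trajectory.

    Returns final N/E/C, the peak endocycle fraction, the first time C
    exceeds ``invasion_threshold_frac * K`` (None if never), and the
    trapezoidal area under C.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    K = traj.scenario.params.K
    thresh = invasion_threshold_frac * K
    above = np.nonzero(traj.C > thresh)[0]
    invasion_time = float(traj.times[above[0]]) if above.size else None
    return {
        "final_N": float(traj.N[-1]),
        "final_E": float(traj.E[-1]),
        "final_C": float(traj.C[-1]),
        "peak_endocycle_fraction": float(traj.endocycle_fraction().max()),
        "invasion_time": invasion_time,
        "auc_C": float(np.trapezoid(traj.C, traj.times)),
    }
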