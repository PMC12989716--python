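"""Three-compartment ODE model of endocycle-mediated liver carcinogenesis.

The model tracks normal hepatocytes (N), endocycling (whole-genome-duplicated,
mitosis-skipping) hepatocytes (E) and cancer cells (C) in a tissue of carrying
capacity K.  Normal and cancer cells grow logistically; normal cells enter the
endocycle at a time-dependent rate ``phi_N(t)`` once chronic stress begins at
time ``psi``, and endocycle cells return to the normal pool by reductive
mitosis (one polyploid cell -> two normal cells) at rate ``phi_E(t)``.
Endocycling degrades the tissue microenvironment: the per-division mutation
rate ``mu`` increases, and the immune killing rate of cancer cells ``kappa``
decreases, as sigmoid functions of the endocycle *frequency*
``100*E/(N+E+C)`` (in percent).

All rates are per day; populations are cell counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "TissueState",
    "endocycle_fraction",
    "mutation_rate",
    "endocycle_entry_rate",
    "ploidy_reduction_rate",
    "immune_killing_rate",
    "rhs",
]


@dataclass(frozen=True)
class ModelParameters:
    """Model constants and sigmoid shape coefficients.

    Defaults are the baseline simulation values.  Each of the four nonlinear
    rate functions is a logistic sigmoid parameterized by (ceiling or
    base+amplitude, slope, midpoint), exposed here so therapy and sensitivity
    sweeps can retune them.

    Attributes
    ----------
    alpha, beta : float
        Intrinsic growth rates of normal and cancer cells (/day).
    K : float
        Tissue carrying capacity (cells).
    delta : float
        Background death rate shared by all compartments (/day).
    eta : float
        Probability that an attempted endocycle entry succeeds, in [0, 1].
    psi : float
        Onset time of chronic stress (days); ``phi_N`` is 0 before ``psi``.
    mu_max, mu_slope, mu_mid : float
        Mutation-rate sigmoid: ceiling (/division), slope (per percent) and
        midpoint (percent endocycle frequency).
    phiN_max, phiN_slope, phiN_mid : float
        Endocycle entry-rate sigmoid in time (/day, /day, days).
    phiE_base, phiE_amp, phiE_slope, phiE_mid : float
        Ploidy-reduction (reductive mitosis) rate: base + decreasing sigmoid
        in time (/day, /day, /day, days).
    kappa_base, kappa_amp, kappa_slope, kappa_mid : float
        Immune killing of cancer cells: base + decreasing sigmoid in
        endocycle frequency (/day, /day, per percent, percent).
    literal_phie : bool
        If True, use the ploidy-reduction terms as constant fluxes
        (``+2*phi_E`` and ``-phi_E``) instead of per-capita rates
        (``+2*phi_E*E`` and ``-phi_E*E``).  Default False: reductive mitosis
        is an event of individual endocycle cells, and the per-capita form is
        the only one under which the empty tissue is a fixed point.
    """

    alpha: float = 0.3
    beta: float = 0.45
    K: float = 10_000.0
    delta: float = 0.1
    eta: float = 1.0
    psi: float = 50.0
    mu_max: float = 0.01
    mu_slope: float = 0.4
    mu_mid: float = 5.0
    phiN_max: float = 0.02
    phiN_slope: float = 0.06
    phiN_mid: float = 125.0
    phiE_base: float = 0.01
    phiE_amp: float = 0.04
    phiE_slope: float = 0.06
    phiE_mid: float = 125.0
    kappa_base: float = 0.01
    kappa_amp: float = 0.15
    kappa_slope: float = 0.4
    kappa_mid: float = 5.0
    literal_phie: bool = False

    def __post_init__(self) -> None:
        nonneg = (
            "alpha", "beta", "delta", "mu_max", "phiN_max",
            "phiE_base", "phiE_amp", "kappa_base", "kappa_amp",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ModelParameters":
        """Load parameters from a YAML (or JSON) mapping of field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"parameter file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TissueState:
    """Tissue composition: normal (N), endocycle (E) and cancer (C) cell counts."""

    N: float
    E: float
    C: float

    def __post_init__(self) -> None:
        for name in ("N", "E", "C"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.N, self.E, self.C], dtype=float)

    @property
    def total(self) -> float:
        return self.N + self.E + self.C


def endocycle_fraction(state: TissueState) -> float:
    """Percent of cells in the endocycle compartment, ``100*E/(N+E+C)``.

    Returns 0 for an empty tissue (convention: avoids 0/0 and makes
    extinction a fixed point of the dynamics).
    """
    total = state.total
    if total == 0:
        return 0.0
    return 100.0 * state.E / total


def _sigmoid(x: float) -> float:
    # numerically-safe logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def mutation_rate(state: TissueState, params: ModelParameters = ModelParameters()) -> float:
    """Per-division mutation rate mu(X), increasing in endocycle frequency.

    ``mu = mu_max / (1 + exp(-mu_slope * (frac - mu_mid)))`` with ``frac`` the
    endocycle frequency in percent; bounded in (0, mu_max).
    """
    frac = endocycle_fraction(state)
    return params.mu_max * _sigmoid(params.mu_slope * (frac - params.mu_mid))


def endocycle_entry_rate(t: float, params: ModelParameters = ModelParameters()) -> float:
    """Normal -> endocycle transition rate phi_N(t) (/day).

    Zero before the stress-onset time ``psi``; afterwards a rising sigmoid
    ``phiN_max / (1 + exp(-phiN_slope * (t - phiN_mid)))`` bounded in
    [0, phiN_max).
    """
    if t < params.psi:
        return 0.0
    return params.phiN_max * _sigmoid(params.phiN_slope * (t - params.phiN_mid))


def ploidy_reduction_rate(t: float, params: ModelParameters = ModelParameters()) -> float:
    """Endocycle -> normal reductive-mitosis rate phi_E(t) (/day).

    ``phiE_base + phiE_amp / (1 + exp(phiE_slope * (t - phiE_mid)))``:
    monotone non-increasing from phiE_base+phiE_amp toward phiE_base.
    """
    return params.phiE_base + params.phiE_amp * _sigmoid(-params.phiE_slope * (t - params.phiE_mid))


def immune_killing_rate(state: TissueState, params: ModelParameters = ModelParameters()) -> float:
    """Immune-mediated cancer cell death rate kappa(X) (/day).

    ``kappa_base + kappa_amp / (1 + exp(kappa_slope * (frac - kappa_mid)))``,
    decreasing in endocycle frequency (endocycling cells suppress immune
    infiltration); bounded in (kappa_base, kappa_base + kappa_amp).
    """
    frac = endocycle_fraction(state)
    return params.kappa_base + params.kappa_amp * _sigmoid(-params.kappa_slope * (frac - params.kappa_mid))


def rhs(t: float, state: TissueState, params: ModelParameters = ModelParameters()) -> np.ndarray:
    """Right-hand side (dN/dt, dE/dt, dC/dt) of the ODE system, in cells/day.

    With ``L = (K - N - E - C)/K`` (logistic free-space factor):

    - dN/dt = alpha*(1-mu)*N*L - delta*N - phi_N*N + 2*phi_E*E
    - dE/dt = eta*phi_N*N - phi_E*E - delta*E
    - dC/dt = beta*C*L - delta*C - kappa*C + alpha*mu*N*L

    Divisions of normal cells occur at total rate ``alpha*N*L``; a fraction
    ``mu`` of them produce a cancer cell (the C influx) and the rest stay
    normal, so the two fluxes sum to ``alpha*N*L`` identically.
    """
    return _rhs_raw(t, state.as_array(), params)


def _rhs_raw(t: float, y: np.ndarray, params: ModelParameters, eta: float | None = None) -> np.ndarray:
    """rhs on a raw [N, E, C] array, without non-negativity validation.

    Used by the integrator, which may probe slightly-negative trial states.
    ``eta`` overrides the parameter value (therapy scales it).
    """
    N, E, C = float(y[0]), float(y[1]), float(y[2])
    if eta is None:
        eta = params.eta
    total = N + E + C
    frac = 100.0 * E / total if total != 0 else 0.0
    L = (params.K - total) / params.K
    mu = params.mu_max * _sigmoid(params.mu_slope * (frac - params.mu_mid))
    phi_n = endocycle_entry_rate(t, params)
    phi_e = ploidy_reduction_rate(t, params)
    kappa = params.kappa_base + params.kappa_amp * _sigmoid(
        -params.kappa_slope * (frac - params.kappa_mid)
    )
    phi_e_flux = phi_e if params.literal_phie else phi_e * E
    dN = params.alpha * (1.0 - mu) * N * L - params.delta * N - phi_n * N + 2.0 * phi_e_flux
    dE = eta * phi_n * N - phi_e_flux - params.delta * E
    dC = params.beta * C * L - params.delta * C - kappa * C + params.alpha * mu * N * L
    return np.array([dN, dE, dC])
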