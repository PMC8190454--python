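"""Six-cell-type model of plasmid-borne versus chromosomal gene carriage.

A well-mixed bacterial population is partitioned by chromosome genotype
(antibiotic-resistant ``R`` or sensitive ``S``) and plasmid state (no plasmid
``0``, resistant plasmid ``R``, sensitive plasmid ``S``), giving six cell
types.  Cells replicate logistically (density-dependent death ``gamma*T``),
plasmids transfer by mass-action conjugation at rate ``beta`` with
single-plasmid exclusion, are lost at replication with probability ``s``
(segregation loss), and antibiotic pressure adds a death rate ``A`` to the
two fully susceptible types.  Carrying the resistance gene costs a fraction
``cR`` of the replication rate per copy, plasmid carriage costs ``cP``;
a cell with the gene on both replicons pays ``(1-cR)**2`` but gains no extra
protection.

The canonical state ordering, shared by every module, is::

    (S0, SS, SR, R0, RS, RR)

first letter chromosome, second plasmid (``0`` = plasmid-free).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

__all__ = [
    "STATE_LABELS",
    "IDX",
    "ModelParameters",
    "DerivedRates",
    "state_vector",
    "derived_rates",
    "rhs",
]

#: Canonical ordering of the six cell-type densities.
STATE_LABELS: tuple[str, ...] = ("S0", "SS", "SR", "R0", "RS", "RR")

#: Map from cell-type label to index in the state vector.
IDX: dict[str, int] = {lab: i for i, lab in enumerate(STATE_LABELS)}


@dataclass(frozen=True)
class ModelParameters:
    """Rate and cost parameters of the six-type competition model.

    Defaults are the main illustrative parameter set used throughout the
    analysis; they place the system in the bistable regime where either
    chromosomal or plasmid-borne resistance can establish.

    Attributes
    ----------
    lam:
        Replication rate λ (1/time).
    gamma:
        Density-dependent death coefficient γ (volume·cells⁻¹·time⁻¹).
    A:
        Antibiotic-associated death rate (1/time), applied to the two
        fully susceptible types S0 and SS only.
    cR:
        Fitness cost of carrying one copy of the resistance gene
        (dimensionless fraction of λ).
    cP:
        Fitness cost of plasmid carriage (dimensionless).
    beta:
        Plasmid conjugation (mass-action transmission) rate β
        (volume·cells⁻¹·time⁻¹).
    s:
        Probability that a daughter cell fails to inherit the plasmid at
        replication (segregation loss, dimensionless).
    """

    lam: float = 1.0
    gamma: float = 1.0
    A: float = 1.0
    cR: float = 0.05
    cP: float = 0.075
    beta: float = 0.2
    s: float = 0.005

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.A < 0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not 0 <= self.cR < 1:
            raise ValueError(f"cR must be in [0, 1), got {self.cR}")
        if not 0 <= self.cP < 1:
            raise ValueError(f"cP must be in [0, 1), got {self.cP}")
        if not 0 <= self.s <= 1:
            raise ValueError(f"s must be in [0, 1], got {self.s}")

    # -- derived replication rates ------------------------------------
    @property
    def lamR(self) -> float:
        """Replication rate of chromosomally resistant, plasmid-free cells."""
        return (1.0 - self.cR) * self.lam

    @property
    def lamP(self) -> float:
        """Replication rate of cells carrying a sensitive plasmid only."""
        return (1.0 - self.cP) * self.lam

    @property
    def lamRP(self) -> float:
        """Replication rate with one resistance copy plus a plasmid (SR, RS)."""
        return (1.0 - self.cR) * (1.0 - self.cP) * self.lam

    @property
    def lamRRP(self) -> float:
        """Replication rate of dually resistant cells (RR): dual cost (1-cR)²."""
        return (1.0 - self.cR) ** 2 * (1.0 - self.cP) * self.lam

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {
            "lam": self.lam, "gamma": self.gamma, "A": self.A,
            "cR": self.cR, "cP": self.cP, "beta": self.beta, "s": self.s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class DerivedRates:
    """Modified replication rates and aggregate densities at a given state."""

    lamR: float
    lamP: float
    lamRP: float
    lamRRP: float
    T: float      #: total cell density
    TPR: float    #: total density of cells carrying a resistant plasmid
    TPS: float    #: total density of cells carrying a sensitive plasmid


def state_vector(S0: float = 0.0, SS: float = 0.0, SR: float = 0.0,
                 R0: float = 0.0, RS: float = 0.0, RR: float = 0.0,
                 ) -> np.ndarray:
    """Build a state vector in the canonical ordering from named densities."""
    n = np.array([S0, SS, SR, R0, RS, RR], dtype=float)
    _check_state(n)
    return n


def _check_state(n: np.ndarray) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.shape != (6,):
        raise ValueError(f"state must have shape (6,), got {n.shape}")
    if np.any(n < 0):
        raise ValueError(f"negative cell density in state {n}")
    return n


def derived_rates(params: ModelParameters, state: Iterable[float]) -> DerivedRates:
    """Compute the cost-discounted replication rates and aggregate densities."""
    n = _check_state(np.asarray(state, dtype=float))
    S0, SS, SR, R0, RS, RR = n
    return DerivedRates(
        lamR=params.lamR,
        lamP=params.lamP,
        lamRP=params.lamRP,
        lamRRP=params.lamRRP,
        T=float(n.sum()),
        TPR=float(SR + RR),
        TPS=float(SS + RS),
    )


def _rhs_raw(n: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Time-derivative of the six densities; no input validation.

    Replication of plasmid-bearing types is discounted by (1-s); the matching
    segregation flux s·λ_•·N_• enters the plasmid-free type with the same
    chromosome, so segregation changes plasmid state but never cell count.
    Conjugation is mass-action between plasmid-free and plasmid-bearing cells
    with single-plasmid exclusion (plasmid-bearing cells cannot be reinfected).
    """
    S0, SS, SR, R0, RS, RR = n
    lam, gamma, A, beta, s = p.lam, p.gamma, p.A, p.beta, p.s
    lamR, lamP, lamRP, lamRRP = p.lamR, p.lamP, p.lamRP, p.lamRRP

    T = S0 + SS + SR + R0 + RS + RR
    TPS = SS + RS          # sensitive-plasmid carriers
    TPR = SR + RR          # resistant-plasmid carriers
    P = TPS + TPR          # all plasmid-bearing cells

    dS0 = S0 * (lam - beta * P - gamma * T - A) + s * (lamP * SS + lamRP * SR)
    dSS = SS * ((1 - s) * lamP - gamma * T - A) + beta * TPS * S0
    dSR = SR * ((1 - s) * lamRP - gamma * T) + beta * TPR * S0
    dR0 = R0 * (lamR - beta * P - gamma * T) + s * (lamRP * RS + lamRRP * RR)
    dRS = RS * ((1 - s) * lamRP - gamma * T) + beta * TPS * R0
    dRR = RR * ((1 - s) * lamRRP - gamma * T) + beta * TPR * R0

    return np.array([dS0, dSS, dSR, dR0, dRS, dRR])


def rhs(t: float, state: Iterable[float], params: ModelParameters) -> np.ndarray:
    """Right-hand side of the six-type ODE system.

    Parameters
    ----------
    t:
        Time.  The autonomous model ignores it; the argument is kept so
        time-dependent variants (fluctuating antibiotic pressure) share the
        same integration path.
    state:
        Densities in the canonical ``(S0, SS, SR, R0, RS, RR)`` ordering.
        Negative densities are rejected.
    params:
        Model parameters.

    Returns
    -------
    numpy.ndarray
        The six time-derivatives.
    """
    n = _check_state(np.asarray(state, dtype=float))
    return _rhs_raw(n, params)
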