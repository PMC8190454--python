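"""Equilibria of the six-type model and linear stability analysis.

Competitive exclusion (no coexistence-promoting mechanism between the
sensitive and resistant variant of either replicon) and the strict inferiority
of dually resistant cells narrow the biologically relevant equilibria to five
candidates, each supported on one or two cell types:

``sensitive_no_plasmid``        S0 > 0
``sensitive_with_plasmid``      S0 > 0, SS > 0  (parasitic sensitive plasmid)
``chromosomal_no_plasmid``      R0 > 0
``chromosomal_with_plasmid``    R0 > 0, RS > 0
``plasmid_borne``               S0 > 0, SR > 0

Each candidate is the steady state of the reduced system obtained by setting
the remaining densities to zero; its evolutionary stability is then judged in
the *full* model from the six eigenvalues of the analytic Jacobian evaluated
at the candidate.  An equilibrium is evolutionarily stable when all six real
parts are negative: no rare type, in particular the alternative location of
the resistance gene, can invade.

Both two-type reduced systems reduce to a single quadratic: the steady-state
condition of the plasmid-bearing type is linear in total density, which turns
the plasmid-free type's condition into a quadratic with at most one admissible
root.  Closed forms are therefore used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParameters, _rhs_raw, state_vector

__all__ = [
    "EQUILIBRIUM_LABELS",
    "EquilibriumPoint",
    "StabilityResult",
    "RegimeResult",
    "EquilibriumError",
    "reduced_equilibrium",
    "jacobian",
    "stability",
    "classify_regime",
    "phase_sweep",
    "parasite_persistence",
    "find_parasite_paradox_point",
]

EQUILIBRIUM_LABELS: tuple[str, ...] = (
    "sensitive_no_plasmid",
    "sensitive_with_plasmid",
    "chromosomal_no_plasmid",
    "chromosomal_with_plasmid",
    "plasmid_borne",
)

#: Support (strictly positive cell types) required by each candidate label.
_SUPPORT: dict[str, tuple[str, ...]] = {
    "sensitive_no_plasmid": ("S0",),
    "sensitive_with_plasmid": ("S0", "SS"),
    "chromosomal_no_plasmid": ("R0",),
    "chromosomal_with_plasmid": ("R0", "RS"),
    "plasmid_borne": ("S0", "SR"),
}

#: Residual tolerance on the full rhs at a reported equilibrium.
RESIDUAL_TOL = 1e-10

#: Eigenvalue margin: stable iff max Re < -MARGIN; |Re| <= MARGIN is marginal.
STABILITY_MARGIN = 1e-9

#: Densities below this are treated as non-existent when checking support.
_EXIST_TOL = 1e-12


class EquilibriumError(RuntimeError):
    """A candidate steady state could not be computed to tolerance."""


@dataclass(frozen=True)
class EquilibriumPoint:
    """A candidate equilibrium of a reduced subsystem.

    ``exists`` is True when every required component is strictly positive
    (and all others zero); the residual is the inf-norm of the full-model
    rhs at ``state``.
    """

    label: str
    state: np.ndarray
    exists: bool
    residual: float


@dataclass(frozen=True)
class StabilityResult:
    """Six Jacobian eigenvalues and the stability verdict for one candidate.

    ``applicable`` is False when the candidate does not exist at these
    parameters (the verdict then carries no information).  ``marginal``
    flags a leading real part within the numerical margin of zero; marginal
    points are excluded from the stable count.
    """

    label: str
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    applicable: bool
    equilibrium: EquilibriumPoint

    @property
    def max_real(self) -> float:
        return float(np.max(self.eigenvalues.real)) if self.applicable else np.nan


def _single_type_density(params: ModelParameters, label: str) -> float:
    """Steady-state density of a lone cell type (logistic fixed point)."""
    if label == "sensitive_no_plasmid":
        return (params.lam - params.A) / params.gamma
    if label == "chromosomal_no_plasmid":
        return params.lamR / params.gamma
    raise ValueError(f"not a single-type equilibrium: {label}")


def _two_type_equilibrium(g_free: float, lam_pb: float, A_pb: float,
                          params: ModelParameters) -> tuple[float, float] | None:
    """Coexistence steady state of one plasmid-free and one plasmid-bearing type.

    The reduced system, with x the plasmid-free and y the plasmid-bearing
    density, is::

        dx/dt = x*(g_free - beta*y - gamma*(x+y)) + s*lam_pb*y
        dy/dt = y*((1-s)*lam_pb - A_pb - gamma*(x+y)) + beta*x*y

    ``g_free`` is the net linear growth rate of the plasmid-free type
    (lam - A, lamR, or lam), ``lam_pb`` the costed replication rate of the
    plasmid-bearing type, ``A_pb`` its antibiotic death rate (nonzero only
    for SS).  Setting dy/dt = 0 with y > 0 fixes gamma*(x+y) linearly in x;
    substituting into dx/dt = 0 yields a quadratic in x.  Returns (x, y) with
    both strictly positive, or None when no such root exists.
    """
    gamma, beta, s = params.gamma, params.beta, params.s
    sL = s * lam_pb
    a = ((1 - s) * lam_pb - A_pb) / gamma        # y-intercept of y(x)
    b = (beta - gamma) / gamma                   # slope of y(x): y = a + b*x
    c0 = g_free - (1 - s) * lam_pb + A_pb
    # quadratic q2*x**2 + q1*x + q0 = 0
    q2 = -beta ** 2 / gamma                      # = -beta*(1+b)
    q1 = c0 - beta * a + sL * b
    q0 = sL * a

    if abs(q2) < 1e-300:                         # beta == 0: linear case
        if abs(q1) < 1e-14:
            return None
        roots = [-q0 / q1]
    else:
        disc = q1 ** 2 - 4 * q2 * q0
        if disc < 0:
            return None
        sq = np.sqrt(disc)
        roots = [(-q1 + sq) / (2 * q2), (-q1 - sq) / (2 * q2)]

    best = None
    for x in roots:
        y = a + b * x
        if x > _EXIST_TOL and y > _EXIST_TOL:
            if best is None or x + y > sum(best):
                best = (float(x), float(y))
    return best


def reduced_equilibrium(params: ModelParameters, label: str) -> EquilibriumPoint:
    """Steady state of the reduced system named by ``label``.

    Single-type candidates use the logistic closed form; two-type candidates
    the quadratic closed form.  ``exists`` is False when no steady state with
    the required strictly positive support is admissible at these parameters.
    A state that is found but fails the full-model residual check raises
    :class:`EquilibriumError` (distinct from non-existence).
    """
    if label not in _SUPPORT:
        raise ValueError(f"unknown equilibrium label {label!r}; "
                         f"choose from {EQUILIBRIUM_LABELS}")

    densities: dict[str, float] = {}
    if label in ("sensitive_no_plasmid", "chromosomal_no_plasmid"):
        d = _single_type_density(params, label)
        if d > _EXIST_TOL:
            densities[_SUPPORT[label][0]] = d
    elif label == "sensitive_with_plasmid":
        xy = _two_type_equilibrium(params.lam - params.A, params.lamP,
                                   params.A, params)
        if xy is not None:
            densities["S0"], densities["SS"] = xy
    elif label == "chromosomal_with_plasmid":
        xy = _two_type_equilibrium(params.lamR, params.lamRP, 0.0, params)
        if xy is not None:
            densities["R0"], densities["RS"] = xy
    elif label == "plasmid_borne":
        xy = _two_type_equilibrium(params.lam - params.A, params.lamRP,
                                   0.0, params)
        if xy is not None:
            densities["S0"], densities["SR"] = xy

    state = state_vector(**densities) if densities else np.zeros(6)
    exists = len(densities) == len(_SUPPORT[label])
    residual = float(np.max(np.abs(_rhs_raw(state, params))))
    if exists and residual > RESIDUAL_TOL * max(1.0, float(state.max())):
        raise EquilibriumError(
            f"{label} steady state residual {residual:.3e} exceeds tolerance "
            f"at params {params}")
    return EquilibriumPoint(label=label, state=state, exists=exists,
                            residual=residual)


def jacobian(state: np.ndarray, params: ModelParameters,
             lamRRP: float | None = None) -> np.ndarray:
    """Analytic 6×6 Jacobian of the full model at ``state``.

    Hand-coded partial derivatives of the rhs in the canonical ordering
    (S0, SS, SR, R0, RS, RR); cross-checked against central finite
    differences in the test suite.  ``lamRRP`` optionally overrides the
    dual-resistant replication rate, which is how the dual-cost variant
    (whose candidate equilibria all have RR = 0 and are therefore unchanged)
    evaluates its stability exactly.
    """
    n = np.asarray(state, dtype=float)
    S0, SS, SR, R0, RS, RR = n
    lam, gamma, A, beta, s = params.lam, params.gamma, params.A, params.beta, params.s
    lamR, lamP, lamRP = params.lamR, params.lamP, params.lamRP
    lamRRP = params.lamRRP if lamRRP is None else lamRRP

    T = n.sum()
    TPS = SS + RS
    TPR = SR + RR
    P = TPS + TPR

    J = np.empty((6, 6))
    # dS0/dt = S0*(lam - beta*P - gamma*T - A) + s*(lamP*SS + lamRP*SR)
    J[0] = [lam - beta * P - gamma * T - A - gamma * S0,
            S0 * (-beta - gamma) + s * lamP,
            S0 * (-beta - gamma) + s * lamRP,
            -gamma * S0,
            S0 * (-beta - gamma),
            S0 * (-beta - gamma)]
    # dSS/dt = SS*((1-s)*lamP - gamma*T - A) + beta*TPS*S0
    J[1] = [-gamma * SS + beta * TPS,
            (1 - s) * lamP - gamma * T - A - gamma * SS + beta * S0,
            -gamma * SS,
            -gamma * SS,
            -gamma * SS + beta * S0,
            -gamma * SS]
    # dSR/dt = SR*((1-s)*lamRP - gamma*T) + beta*TPR*S0
    J[2] = [-gamma * SR + beta * TPR,
            -gamma * SR,
            (1 - s) * lamRP - gamma * T - gamma * SR + beta * S0,
            -gamma * SR,
            -gamma * SR,
            -gamma * SR + beta * S0]
    # dR0/dt = R0*(lamR - beta*P - gamma*T) + s*(lamRP*RS + lamRRP*RR)
    J[3] = [-gamma * R0,
            R0 * (-beta - gamma),
            R0 * (-beta - gamma),
            lamR - beta * P - gamma * T - gamma * R0,
            R0 * (-beta - gamma) + s * lamRP,
            R0 * (-beta - gamma) + s * lamRRP]
    # dRS/dt = RS*((1-s)*lamRP - gamma*T) + beta*TPS*R0
    J[4] = [-gamma * RS,
            -gamma * RS + beta * R0,
            -gamma * RS,
            -gamma * RS + beta * TPS,
            (1 - s) * lamRP - gamma * T - gamma * RS + beta * R0,
            -gamma * RS]
    # dRR/dt = RR*((1-s)*lamRRP - gamma*T) + beta*TPR*R0
    J[5] = [-gamma * RR,
            -gamma * RR,
            -gamma * RR + beta * R0,
            -gamma * RR + beta * TPR,
            -gamma * RR,
            (1 - s) * lamRRP - gamma * T - gamma * RR + beta * R0]
    return J


def stability(params: ModelParameters, label: str,
              margin: float = STABILITY_MARGIN) -> StabilityResult:
    """Full-model eigenvalues and stability verdict for a candidate.

    A non-existent candidate yields ``applicable=False`` (and ``stable=False``);
    a leading real part within ``margin`` of zero is ``marginal`` and excluded
    from the stable count.
    """
    eq = reduced_equilibrium(params, label)
    if not eq.exists:
        return StabilityResult(label=label, eigenvalues=np.full(6, np.nan,
                               dtype=complex), stable=False, marginal=False,
                               applicable=False, equilibrium=eq)
    eig = np.linalg.eigvals(jacobian(eq.state, params))
    max_re = float(np.max(eig.real))
    marginal = abs(max_re) <= margin
    stable = max_re < -margin
    return StabilityResult(label=label, eigenvalues=eig, stable=stable,
                           marginal=marginal, applicable=True, equilibrium=eq)


@dataclass(frozen=True)
class RegimeResult:
    """Evolutionary regime at one parameter point.

    ``regime`` is one of ``no_resistance``, ``chromosomal_only``,
    ``plasmid_only``, ``bistable``.  For regimes with a stable chromosomal
    equilibrium, ``plasmid_presence`` records whether the sensitive plasmid
    circulates there (``with_plasmid``/``without_plasmid``).  ``review``
    flags points where no candidate (including the sensitive ones) is stable,
    i.e. the attractor is outside the candidate menu and the point deserves a
    simulation look.
    """

    regime: str
    plasmid_presence: str | None
    results: dict[str, StabilityResult]
    review: bool

    def max_real(self, label: str) -> float:
        return self.results[label].max_real


def classify_regime(params: ModelParameters) -> RegimeResult:
    """Classify the evolutionary regime from the candidate stability results.

    ``bistable`` iff a chromosomal equilibrium and the plasmid-borne
    equilibrium are simultaneously stable; ``chromosomal_only`` /
    ``plasmid_only`` when one side alone is stable; ``no_resistance``
    otherwise.
    """
    results = {lab: stability(params, lab) for lab in EQUILIBRIUM_LABELS}
    chrom_with = results["chromosomal_with_plasmid"].stable
    chrom_without = results["chromosomal_no_plasmid"].stable
    chrom = chrom_with or chrom_without
    plasmid = results["plasmid_borne"].stable

    if chrom and plasmid:
        regime = "bistable"
    elif chrom:
        regime = "chromosomal_only"
    elif plasmid:
        regime = "plasmid_only"
    else:
        regime = "no_resistance"

    presence = None
    if chrom_with:
        presence = "with_plasmid"
    elif chrom_without:
        presence = "without_plasmid"

    review = not any(r.stable for r in results.values())
    return RegimeResult(regime=regime, plasmid_presence=presence,
                        results=results, review=review)


def phase_sweep(base: ModelParameters,
                axis1: tuple[str, np.ndarray],
                axis2: tuple[str, np.ndarray]) -> pd.DataFrame:
    """Regime classification over a 2-D parameter grid.

    Parameters
    ----------
    base:
        Parameters held fixed off the axes.
    axis1, axis2:
        ``(parameter_name, grid_values)`` pairs naming two distinct
        :class:`ModelParameters` fields.

    Returns
    -------
    pandas.DataFrame
        Tidy table with one row per grid point: the two axis values, the
        regime, plasmid presence, the leading real part of each candidate's
        spectrum, the review flag, and any per-point error message.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    if name1 == name2:
        raise ValueError("axes must name two distinct parameters")
    rows = []
    for v1 in np.asarray(vals1, dtype=float):
        for v2 in np.asarray(vals2, dtype=float):
            row: dict = {name1: v1, name2: v2}
            try:
                res = classify_regime(base.replace(**{name1: v1, name2: v2}))
                row.update(regime=res.regime,
                           plasmid_presence=res.plasmid_presence,
                           review=res.review, error="")
                for lab in EQUILIBRIUM_LABELS:
                    row[f"max_re_{lab}"] = res.max_real(lab)
            except Exception as exc:  # per-point failures recorded, not fatal
                row.update(regime="error", plasmid_presence=None,
                           review=True, error=str(exc))
                for lab in EQUILIBRIUM_LABELS:
                    row[f"max_re_{lab}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def parasite_persistence(params: ModelParameters) -> bool | None:
    """Can a sensitive (gene-free) plasmid persist in a sensitive population?

    Evaluates the invasion eigenvalue of the SS direction at the
    plasmid-free sensitive equilibrium S0* = (lam-A)/gamma::

        (1-s)*lamP - (lam - A) - A + beta*(lam - A)/gamma

    Returns True when positive (the plasmid spreads parasitically), False
    when negative, and None when sensitive cells are not viable on their own
    (A >= lam), in which case the question does not apply.
    """
    if params.A >= params.lam:
        return None
    S0_star = (params.lam - params.A) / params.gamma
    eig = ((1 - params.s) * params.lamP - (params.lam - params.A)
           - params.A + params.beta * S0_star)
    return bool(eig > 0)


def find_parasite_paradox_point(base: ModelParameters | None = None,
                                A_grid: np.ndarray | None = None,
                                beta_grid: np.ndarray | None = None,
                                ) -> ModelParameters | None:
    """Search for parameters where plasmid-borne resistance is stable although
    the plasmid cannot persist as a parasite.

    Scans an (A, beta) grid around the default parameter set (sensitive cells
    viable, A < lam) and returns the first point with
    ``parasite_persistence`` False but a stable plasmid-borne equilibrium,
    or None if the grid contains no such point.  Such points show that low
    transmissibility plasmids can be maintained purely by the benefit they
    confer on the host.
    """
    base = base or ModelParameters()
    if A_grid is None:
        A_grid = np.linspace(0.80, 0.99, 12)
    if beta_grid is None:
        beta_grid = np.linspace(0.12, 0.25, 12)
    for A in A_grid:
        for beta in beta_grid:
            p = base.replace(A=float(A), beta=float(beta))
            if parasite_persistence(p) is False:
                if stability(p, "plasmid_borne").stable:
                    return p
    return None
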