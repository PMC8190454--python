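"""Forward integration, outcome classification, basin maps and invasion tests.

The initial-condition experiments ask which attractor the system reaches:
a population where the resistance gene sits on the plasmid (S0 + SR), on the
chromosome (R0, with or without a circulating sensitive plasmid RS), or
nowhere.  Because the model is bistable over a wide parameter range, the
answer depends on the starting frequencies — mapping that dependence over a
grid of initial conditions produces the basin-of-attraction maps, and seeding
a resident equilibrium with a rare alternative type gives the invasion
(priority-effect) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import IDX, ModelParameters, _rhs_raw, state_vector
from . import equilibria as eqm

__all__ = [
    "SimulationSettings",
    "IntegrationResult",
    "integrate",
    "classify_outcome",
    "basin_map",
    "invasion_test",
    "stability_agrees_with_simulation",
]


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings for forward integration.

    The integration horizon defaults to 1e7 time units, long enough for every
    transient in the default parameter regime (slowest rate ~ s*lam) to decay;
    an early-stop event ends the run as soon as the dynamics have flattened to
    ``‖rhs‖∞ < early_stop``.  Densities below ``rounding_threshold`` in the
    *final* state are set to zero, so that a type's presence/absence is
    well-defined despite roundoff; no rounding is applied mid-integration.

    Because a losing lineage decays exponentially at a rate that can be small
    (its derivative falls below ``early_stop`` while its density is still
    above the rounding threshold), the early stop additionally refuses to
    fire while any density sits in the ambiguous band
    ``(rounding_threshold, decay_band_upper)`` — every type must be either
    clearly established or already below the rounding threshold.
    """

    horizon: float = 1e7
    rounding_threshold: float = 1e-10
    rtol: float = 1e-8
    atol: float = 1e-14
    early_stop: float | None = 1e-12
    decay_band_upper: float = 1e-6
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not self.horizon > 0:
            raise ValueError("horizon must be > 0")
        if not self.rounding_threshold > 0:
            raise ValueError("rounding_threshold must be > 0")

    def replace(self, **changes) -> "SimulationSettings":
        from dataclasses import replace as _replace
        return _replace(self, **changes)


@dataclass(frozen=True)
class IntegrationResult:
    """Final state (rounded) plus solver diagnostics."""

    state: np.ndarray          #: final state, after rounding
    raw_state: np.ndarray      #: final state before rounding
    t_end: float               #: time actually reached
    early_stopped: bool
    success: bool
    message: str


def _round_state(y: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out densities below threshold; clip (and warn on) negatives."""
    y = np.asarray(y, dtype=float).copy()
    if np.any(y < -1e-8):
        warnings.warn(f"clipping negative densities {y[y < -1e-8]} to zero",
                      RuntimeWarning, stacklevel=2)
    y[y < threshold] = 0.0
    return y


def integrate(state0: np.ndarray, params: ModelParameters,
              settings: SimulationSettings | None = None,
              rhs: Callable[[float, np.ndarray], np.ndarray] | None = None,
              jac: Callable[[float, np.ndarray], np.ndarray] | None = None,
              dense: bool = False,
              ) -> IntegrationResult:
    """Integrate the model (or a variant) until the horizon or equilibrium.

    Parameters
    ----------
    state0:
        Initial densities, canonical ordering.
    params:
        Model parameters (used for the default rhs/Jacobian).
    settings:
        Numerical settings; defaults to :class:`SimulationSettings()`.
    rhs, jac:
        Optional replacement right-hand side / Jacobian with solve_ivp
        signature ``f(t, y)``; variants and migration pass their own.
        When ``rhs`` is given without ``jac``, the solver falls back to
        finite-difference Jacobians.
    dense:
        Keep the full solution object (attached as ``.sol`` attribute of the
        returned result's ``raw_state``; trajectories are otherwise dropped).

    Notes
    -----
    The solver state is clipped at zero inside the rhs evaluation, which
    prevents tiny negative excursions from feeding back into the dynamics;
    genuine negative excursions beyond 1e-8 trigger a warning at rounding.
    """
    settings = settings or SimulationSettings()
    y0 = np.asarray(state0, dtype=float)
    if y0.shape != (6,):
        raise ValueError("state0 must have shape (6,)")
    if np.any(y0 < 0):
        raise ValueError("negative initial densities")

    if rhs is None:
        def rhs(t, y, _p=params):
            return _rhs_raw(np.maximum(y, 0.0), _p)

        def jac(t, y, _p=params):
            return eqm.jacobian(np.maximum(y, 0.0), _p)

    def _settle_metric(t, y):
        # negative once the dynamics are flat AND no density is stuck in the
        # ambiguous band between "absent" and "established"
        resid = float(np.max(np.abs(rhs(t, y)))) - settings.early_stop
        # lower band edge at half the rounding threshold: the event root sits
        # on the band boundary, which must land strictly below the threshold
        band = float(np.max(np.minimum(
            y - 0.5 * settings.rounding_threshold,
            settings.decay_band_upper - y)))
        return max(resid, band)

    # already at (numerical) equilibrium: nothing to integrate
    if settings.early_stop is not None and _settle_metric(0.0, y0) < 0:
        return IntegrationResult(
            state=_round_state(y0, settings.rounding_threshold),
            raw_state=y0.copy(), t_end=0.0, early_stopped=True,
            success=True, message="initial state already at equilibrium")

    events = None
    if settings.early_stop is not None:
        def settled(t, y):
            return _settle_metric(t, y)
        settled.terminal = True
        settled.direction = -1
        events = settled

    sol = solve_ivp(rhs, (0.0, settings.horizon), y0,
                    method=settings.method, jac=jac,
                    rtol=settings.rtol, atol=settings.atol,
                    events=events, dense_output=dense)
    if not sol.success:
        raise RuntimeError(
            f"solver failed: {sol.message}; params={params}, state0={y0}")
    raw = sol.y[:, -1]
    early = bool(events is not None and sol.t_events[0].size > 0)
    result = IntegrationResult(
        state=_round_state(raw, settings.rounding_threshold),
        raw_state=raw, t_end=float(sol.t[-1]), early_stopped=early,
        success=True, message=sol.message)
    if dense:
        object.__setattr__(result, "sol", sol)
    return result


def classify_outcome(final: np.ndarray) -> str:
    """Label the resistance location in a (rounded) final state.

    ``plasmid_borne``  resistant plasmid present, resistant chromosome absent
    ``chromosomal``    resistant chromosome present, resistant plasmid absent
    ``sensitive``      cells present but no resistance in the population
    ``extinct``        all densities zero
    ``mixed``          both locations present (not expected at equilibrium
                       under the default dual-cost assumptions — flag for
                       inspection)
    """
    n = np.asarray(final, dtype=float)
    TPR = n[IDX["SR"]] + n[IDX["RR"]]
    chrom = n[IDX["R0"]] + n[IDX["RS"]] + n[IDX["RR"]]
    if TPR > 0 and chrom == 0:
        return "plasmid_borne"
    if chrom > 0 and TPR == 0:
        return "chromosomal"
    if TPR == 0 and chrom == 0:
        return "extinct" if np.all(n == 0) else "sensitive"
    return "mixed"


def initial_state(panel: str, x: float, y: float,
                  sensitive_total: float = 1.0,
                  resistant_total: float = 1.0) -> np.ndarray:
    """Initial densities for the basin-map experiments.

    ``x`` is the frequency of the sensitive plasmid in the initial sensitive
    population, SS/(S0+SS).  ``y`` is the frequency of plasmid-borne
    resistance in the initial resistant population: panel ``A`` splits the
    resistant total between SR and RS (chromosomally resistant cells carry
    the sensitive plasmid), panel ``B`` between SR and R0 (they do not).
    """
    if panel not in ("A", "B"):
        raise ValueError("panel must be 'A' or 'B'")
    if not (0 <= x <= 1 and 0 <= y <= 1):
        raise ValueError("frequencies must lie in [0, 1]")
    kw = {"SS": x * sensitive_total, "S0": (1 - x) * sensitive_total,
          "SR": y * resistant_total}
    other = "RS" if panel == "A" else "R0"
    kw[other] = (1 - y) * resistant_total
    return state_vector(**kw)


def basin_map(panel: str, params: ModelParameters,
              grid: int = 41,
              totals: tuple[float, float] = (1.0, 1.0),
              settings: SimulationSettings | None = None,
              rhs: Callable | None = None,
              jac: Callable | None = None) -> pd.DataFrame:
    """Outcome of the dynamics over a grid of initial frequencies.

    Returns a tidy DataFrame with columns ``x`` (initial sensitive-plasmid
    frequency), ``y`` (initial plasmid-borne-resistance frequency),
    ``outcome`` and ``error`` (empty on success); per-cell failures are
    recorded rather than raised.
    """
    settings = settings or SimulationSettings()
    xs = np.linspace(0.0, 1.0, grid)
    ys = np.linspace(0.0, 1.0, grid)
    rows = []
    for x in xs:
        for y in ys:
            try:
                n0 = initial_state(panel, x, y, *totals)
                res = integrate(n0, params, settings, rhs=rhs, jac=jac)
                rows.append({"x": x, "y": y,
                             "outcome": classify_outcome(res.state),
                             "error": ""})
            except Exception as exc:
                rows.append({"x": x, "y": y, "outcome": "error",
                             "error": str(exc)})
    return pd.DataFrame(rows)


#: Lineage classes used to score invasion: densities summed per gene location.
_LINEAGE = {
    "chromosomal": ("R0", "RS", "RR"),
    "plasmid_borne": ("SR", "RR"),
}


def _lineage_of(cell_type: str) -> str:
    if cell_type in ("R0", "RS"):
        return "chromosomal"
    if cell_type in ("SR", "RR"):
        return "plasmid_borne"
    raise ValueError(f"invader {cell_type!r} carries no resistance gene")


def _lineage_density(state: np.ndarray, lineage: str) -> float:
    return float(sum(state[IDX[t]] for t in _LINEAGE[lineage]))


def invasion_test(resident: str, invader: str, params: ModelParameters,
                  inoculum: float = 1e-6,
                  settings: SimulationSettings | None = None) -> bool | None:
    """Can a rare invader displace an established resident equilibrium?

    The resident equilibrium (label as in :mod:`plasmidfate.equilibria`) is
    seeded with ``inoculum`` of the invading cell type and integrated
    forward.  Returns True when the system leaves the resident's outcome
    class (invasion succeeded), False when the invader lineage decayed by at
    least a factor of 10, and None when neither happened within the horizon
    (inconclusive).
    """
    eq = eqm.reduced_equilibrium(params, resident)
    if not eq.exists:
        raise ValueError(f"resident equilibrium {resident!r} does not exist "
                         f"at these parameters")
    lineage = _lineage_of(invader)
    n0 = eq.state.copy()
    n0[IDX[invader]] += inoculum
    res = integrate(n0, params, settings)
    if classify_outcome(res.state) != classify_outcome(
            _round_state(eq.state, (settings or SimulationSettings()).rounding_threshold)):
        return True
    final_density = _lineage_density(res.raw_state, lineage)
    if final_density < inoculum / 10:
        return False
    return None


def stability_agrees_with_simulation(params: ModelParameters, label: str,
                                     inoculum: float = 1e-6,
                                     settings: SimulationSettings | None = None,
                                     escape_distance: float = 1e-3,
                                     ) -> bool | None:
    """Cross-check the eigenvalue verdict for one candidate by simulation.

    A candidate judged stable must repel the complementary rare invader
    (resistant plasmid SR against a chromosomal resident, resistant
    chromosome R0 against a plasmid-borne resident); a candidate judged
    unstable must be escaped by a trajectory nudged ``inoculum`` along the
    leading unstable eigenvector.  Returns True when simulation agrees with
    the eigenvalues, False when it contradicts them, None when the candidate
    does not exist or is numerically marginal (no verdict to check).
    """
    st = eqm.stability(params, label)
    if not st.applicable or st.marginal:
        return None
    n_star = st.equilibrium.state
    if st.stable:
        invader = "SR" if label.startswith("chromosomal") else "R0"
        return invasion_test(label, invader, params, inoculum, settings) is False
    # unstable: nudge along the leading eigenvector, oriented and clipped so
    # the perturbed state stays non-negative
    J = eqm.jacobian(n_star, params)
    w, V = np.linalg.eig(J)
    v = np.real(V[:, np.argmax(w.real)])
    v = v / np.max(np.abs(v))
    zero = n_star < 1e-12
    if np.sum(v[zero]) < 0:
        v = -v
    n0 = np.maximum(n_star + inoculum * v, 0.0)
    res = integrate(n0, params, settings)
    return bool(np.max(np.abs(res.raw_state - n_star)) > escape_distance)
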