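"""Structural variants of the six-type model.

Each variant perturbs one assumption of the core model:

* **Migration / local adaptation** — a constant influx of sensitive cells,
  a fraction ``f_imm`` of which carry the sensitive plasmid.  This frames the
  modeled habitat as a local niche where the gene is beneficial, embedded in
  an outside world where it is not.
* **Gene flow (transposition)** — the resistance gene relocates between
  plasmid and chromosome within a cell (SR ↔ RS) at a small per-cell rate.
* **Fluctuating antibiotic pressure** — A(t) becomes a square wave,
  so stability must be probed by simulation rather than eigenvalues.
* **Dual-resistance cost/benefit** — the cost of the second gene copy and
  the completeness of single-copy protection become tunable; positive
  frequency dependence hinges on dual carriage being disadvantageous.
* **Alternative formulations** — segregation loss as a standalone rate
  rather than a replication failure; the antibiotic slowing growth rather
  than killing; fitness costs as added death rather than reduced growth.

With every knob at its default the variant rhs *is* the core rhs (it
delegates), so the reduction invariant holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .model import IDX, ModelParameters, _rhs_raw, state_vector
from . import equilibria as eqm
from .dynamics import SimulationSettings, classify_outcome, integrate

__all__ = [
    "MigrationParameters",
    "FluctuationConfig",
    "VariantConfig",
    "rhs_migration",
    "rhs_variant",
    "make_rhs",
    "dual_cost_regime",
    "migration_outcome_map",
    "fluctuation_experiment",
]


@dataclass(frozen=True)
class MigrationParameters:
    """Constant influx of sensitive cells into the local niche.

    ``mu`` is the influx rate (cells·volume⁻¹·time⁻¹); ``f_imm`` the fraction
    of immigrants carrying the sensitive plasmid (the rest are plasmid-free).
    """

    mu: float = 0.0
    f_imm: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0 <= self.f_imm <= 1:
            raise ValueError("f_imm must lie in [0, 1]")


@dataclass(frozen=True)
class FluctuationConfig:
    """Square-wave antibiotic pressure.

    A(t) = ``A_on`` for the first ``duty`` fraction of each period and
    ``A_off`` for the remainder.
    """

    period: float
    duty: float = 0.5
    A_on: float = 1.0
    A_off: float = 0.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if not 0 <= self.duty <= 1:
            raise ValueError("duty must lie in [0, 1]")
        if self.A_on < 0 or self.A_off < 0:
            raise ValueError("antibiotic levels must be >= 0")

    def value(self, t: float) -> float:
        return self.A_on if (t % self.period) < self.duty * self.period \
            else self.A_off


@dataclass(frozen=True)
class VariantConfig:
    """Knobs for the structural sensitivity variants.

    Attributes
    ----------
    transposition_rate:
        Per-cell rate of the gene relocating between replicons (SR ↔ RS,
        equal both ways).  Default 0 (off).
    fluctuation:
        Square-wave antibiotic schedule replacing constant A; None = off.
    dual_cost_second_copy:
        Cost factor of the *second* resistance copy; None means "same as the
        first" (cR), recovering the dual cost (1-cR)².  Zero removes the
        extra cost entirely.
    single_copy_protection:
        Fraction of antibiotic-associated death prevented by one gene copy.
        Default 1 (full protection).  Below 1, single-resistant types suffer
        residual death (1-π)·A and dual-resistant types (1-π)²·A, so dual
        carriage gains a real benefit.
    segregation_mode:
        ``at_replication`` (default): replication of plasmid-bearing types is
        discounted by (1-s) with the matching flux into the plasmid-free
        type.  ``independent_rate``: replication is undiscounted and the
        plasmid is lost at a standalone per-cell rate (``independent_seg_rate``
        if set, else s times the type's replication rate, which matches the
        default to first order in s).
    antibiotic_mode:
        ``death`` (default) adds A to the death rate of exposed types;
        ``growth_slowing`` multiplies their replication rate by
        max(0, 1 - A_eff/lam) instead, calibrated so a lone susceptible
        population equilibrates at the same density as under death mode
        whenever A < lam.
    cost_mode:
        ``growth`` (default) discounts replication rates by the cost factors;
        ``death`` replicates every type at the uncosted rate and adds the
        forgone growth (lam_full - lam_costed) to the death rate instead.
    """

    transposition_rate: float = 0.0
    fluctuation: FluctuationConfig | None = None
    dual_cost_second_copy: float | None = None
    single_copy_protection: float = 1.0
    segregation_mode: str = "at_replication"
    independent_seg_rate: float | None = None
    antibiotic_mode: str = "death"
    cost_mode: str = "growth"

    def __post_init__(self) -> None:
        if self.transposition_rate < 0:
            raise ValueError("transposition_rate must be >= 0")
        if self.dual_cost_second_copy is not None and not \
                0 <= self.dual_cost_second_copy < 1:
            raise ValueError("dual_cost_second_copy must lie in [0, 1)")
        if not 0 <= self.single_copy_protection <= 1:
            raise ValueError("single_copy_protection must lie in [0, 1]")
        if self.segregation_mode not in ("at_replication", "independent_rate"):
            raise ValueError("segregation_mode must be 'at_replication' or "
                             "'independent_rate'")
        if self.antibiotic_mode not in ("death", "growth_slowing"):
            raise ValueError("antibiotic_mode must be 'death' or "
                             "'growth_slowing'")
        if self.cost_mode not in ("growth", "death"):
            raise ValueError("cost_mode must be 'growth' or 'death'")

    @property
    def is_default(self) -> bool:
        return (self.transposition_rate == 0.0 and self.fluctuation is None
                and self.dual_cost_second_copy is None
                and self.single_copy_protection == 1.0
                and self.segregation_mode == "at_replication"
                and self.independent_seg_rate is None
                and self.antibiotic_mode == "death"
                and self.cost_mode == "growth")


def rhs_migration(t: float, n: np.ndarray, params: ModelParameters,
                  migration: MigrationParameters) -> np.ndarray:
    """Core rhs plus a constant influx of sensitive cells.

    Immigrants are chromosomally sensitive; a fraction ``f_imm`` carry the
    sensitive plasmid (into SS), the rest are plasmid-free (into S0).
    """
    d = _rhs_raw(np.maximum(np.asarray(n, dtype=float), 0.0), params)
    if migration.mu > 0:
        d = d.copy()
        d[IDX["S0"]] += migration.mu * (1.0 - migration.f_imm)
        d[IDX["SS"]] += migration.mu * migration.f_imm
    return d


def _variant_rates(params: ModelParameters, variant: VariantConfig,
                   A_t: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-type effective replication rates and added death rates.

    Order (S0, SS, SR, R0, RS, RR).  Returns (rep, death_extra) where
    ``rep`` excludes the segregation discount (applied by the caller) and
    ``death_extra`` covers antibiotic death and death-mode fitness costs.
    """
    lam = params.lam
    cR, cP = params.cR, params.cP
    d2 = cR if variant.dual_cost_second_copy is None \
        else variant.dual_cost_second_copy
    # costed replication rates per type
    costed = np.array([
        lam,
        (1 - cP) * lam,
        (1 - cR) * (1 - cP) * lam,
        (1 - cR) * lam,
        (1 - cR) * (1 - cP) * lam,
        (1 - cR) * (1 - d2) * (1 - cP) * lam,
    ])
    # effective antibiotic exposure per type
    pi = variant.single_copy_protection
    exposure = A_t * np.array([1.0, 1.0, 1 - pi, 1 - pi, 1 - pi,
                               (1 - pi) ** 2])

    if variant.cost_mode == "growth":
        rep = costed.copy()
        death = np.zeros(6)
    else:  # costs as added death: everyone replicates at full lam
        rep = np.full(6, lam)
        death = lam - costed

    if variant.antibiotic_mode == "death":
        death = death + exposure
    else:  # growth slowing, calibrated to match death-mode lone equilibrium
        rep = rep * np.maximum(0.0, 1.0 - exposure / lam)
    return rep, death


def rhs_variant(t: float, n: np.ndarray, params: ModelParameters,
                variant: VariantConfig) -> np.ndarray:
    """Right-hand side with the configured structural modifications.

    With every knob at its default this delegates to the core rhs and is
    bitwise identical to it.
    """
    n = np.maximum(np.asarray(n, dtype=float), 0.0)
    if variant.is_default:
        return _rhs_raw(n, params)

    S0, SS, SR, R0, RS, RR = n
    gamma, beta, s = params.gamma, params.beta, params.s
    T = n.sum()
    TPS = SS + RS
    TPR = SR + RR
    P = TPS + TPR

    A_t = variant.fluctuation.value(t) if variant.fluctuation is not None \
        else params.A
    rep, death = _variant_rates(params, variant, A_t)

    if variant.segregation_mode == "at_replication":
        seg_discount = np.array([1.0, 1 - s, 1 - s, 1.0, 1 - s, 1 - s])
        seg_loss = np.zeros(6)            # no standalone loss rate
        seg_flux = s * rep                # flux into plasmid-free partner
    else:
        seg_discount = np.ones(6)
        sig = variant.independent_seg_rate
        seg_loss = np.array([0.0,
                             sig if sig is not None else s * rep[1],
                             sig if sig is not None else s * rep[2],
                             0.0,
                             sig if sig is not None else s * rep[4],
                             sig if sig is not None else s * rep[5]])
        seg_flux = seg_loss

    growth = rep * seg_discount

    dS0 = (S0 * (growth[0] - beta * P - gamma * T - death[0])
           + (seg_flux[1] * SS + seg_flux[2] * SR
              if variant.segregation_mode == "independent_rate"
              else s * (rep[1] * SS + rep[2] * SR)))
    dSS = SS * (growth[1] - gamma * T - death[1] - seg_loss[1]) \
        + beta * TPS * S0
    dSR = SR * (growth[2] - gamma * T - death[2] - seg_loss[2]) \
        + beta * TPR * S0
    dR0 = (R0 * (growth[3] - beta * P - gamma * T - death[3])
           + (seg_flux[4] * RS + seg_flux[5] * RR
              if variant.segregation_mode == "independent_rate"
              else s * (rep[4] * RS + rep[5] * RR)))
    dRS = RS * (growth[4] - gamma * T - death[4] - seg_loss[4]) \
        + beta * TPS * R0
    dRR = RR * (growth[5] - gamma * T - death[5] - seg_loss[5]) \
        + beta * TPR * R0

    d = np.array([dS0, dSS, dSR, dR0, dRS, dRR])

    tau = variant.transposition_rate
    if tau > 0:  # within-cell gene relocation between replicons
        flow = tau * (RS - SR)
        d[IDX["SR"]] += flow
        d[IDX["RS"]] -= flow
    return d


def dual_cost_regime(params: ModelParameters,
                     dual_cost_second_copy: float,
                     margin: float = eqm.STABILITY_MARGIN) -> str:
    """Evolutionary regime when the second resistance copy costs
    ``dual_cost_second_copy`` instead of cR.

    The candidate equilibria are unchanged (they all have RR = 0 and λRRP
    enters the rhs only through RR), so only the Jacobian's RR entries move;
    stability is re-evaluated with the overridden dual-resistant replication
    rate.  With the second copy free, the chromosomal-with-plasmid
    equilibrium becomes exactly marginal in the RR direction and the
    plasmid-borne one loses stability to joint chromosome-plus-resistant-
    plasmid invasion, so bistability disappears and dual resistance takes
    over in simulation.
    """
    lamRRP = ((1 - params.cR) * (1 - dual_cost_second_copy)
              * (1 - params.cP) * params.lam)
    verdicts: dict[str, bool] = {}
    for lab in eqm.EQUILIBRIUM_LABELS:
        eq = eqm.reduced_equilibrium(params, lab)
        if not eq.exists:
            verdicts[lab] = False
            continue
        eig = np.linalg.eigvals(eqm.jacobian(eq.state, params, lamRRP=lamRRP))
        verdicts[lab] = bool(np.max(eig.real) < -margin)
    chrom = verdicts["chromosomal_with_plasmid"] or \
        verdicts["chromosomal_no_plasmid"]
    plasmid = verdicts["plasmid_borne"]
    if chrom and plasmid:
        return "bistable"
    if chrom:
        return "chromosomal_only"
    if plasmid:
        return "plasmid_only"
    return "no_resistance"


def make_rhs(params: ModelParameters,
             variant: VariantConfig | None = None,
             migration: MigrationParameters | None = None,
             ) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind a solve_ivp-style rhs closure for the requested modifications."""
    if variant is None and migration is None:
        return lambda t, n: _rhs_raw(np.maximum(np.asarray(n, float), 0.0),
                                     params)

    def f(t, n):
        if variant is not None:
            d = rhs_variant(t, n, params, variant)
        else:
            d = _rhs_raw(np.maximum(np.asarray(n, float), 0.0), params)
        if migration is not None and migration.mu > 0:
            d = d.copy()
            d[IDX["S0"]] += migration.mu * (1.0 - migration.f_imm)
            d[IDX["SS"]] += migration.mu * migration.f_imm
        return d

    return f


def migration_outcome_map(params: ModelParameters, mu: float,
                          grid: int = 41,
                          settings: SimulationSettings | None = None,
                          resistant_total: float = 1.0) -> pd.DataFrame:
    """Equilibrium gene location under sensitive-cell influx.

    The initial population is fully resistant with total density 1, split
    between plasmid-borne (SR) and chromosomal resistance with the sensitive
    plasmid (RS) by the initial frequency ``y = SR/(SR+RS)``.  The x-axis is
    the sensitive-plasmid frequency ``f_imm`` among immigrants arriving at
    rate ``mu``.  Returns a tidy DataFrame (f_imm, y, mu, outcome, error).
    """
    settings = settings or SimulationSettings()
    fs = np.linspace(0.0, 1.0, grid)
    ys = np.linspace(0.0, 1.0, grid)
    rows = []
    for f_imm in fs:
        mig = MigrationParameters(mu=mu, f_imm=float(f_imm))
        rhs = make_rhs(params, migration=mig)
        for y in ys:
            n0 = state_vector(SR=y * resistant_total,
                              RS=(1 - y) * resistant_total)
            try:
                res = integrate(n0, params, settings, rhs=rhs)
                rows.append({"f_imm": f_imm, "y": y, "mu": mu,
                             "outcome": classify_outcome(res.state),
                             "error": ""})
            except Exception as exc:
                rows.append({"f_imm": f_imm, "y": y, "mu": mu,
                             "outcome": "error", "error": str(exc)})
    return pd.DataFrame(rows)


def _established_start(params: ModelParameters, form: str, A_ref: float,
                       sensitive_inoculum: float = 1e-3) -> np.ndarray:
    """Starting state with one resistance form established.

    Uses the constant-A equilibrium at the reference antibiotic level when it
    exists, otherwise a generic established state of total density ~1.
    A small plasmid-free sensitive inoculum is always present so that
    persistence is judged against the sensitive challenger that antibiotic-free
    phases can amplify (an all-resistant population would otherwise persist
    trivially for lack of a competitor).
    """
    label = "plasmid_borne" if form == "plasmid_borne" \
        else "chromosomal_with_plasmid"
    eq = eqm.reduced_equilibrium(params.replace(A=A_ref), label)
    if eq.exists:
        state = eq.state.copy()
    elif form == "plasmid_borne":
        state = state_vector(S0=0.1, SR=0.9)
    else:
        state = state_vector(R0=0.1, RS=0.9)
    state[IDX["S0"]] = max(state[IDX["S0"]], sensitive_inoculum)
    return state


def fluctuation_experiment(params: ModelParameters,
                           periods: np.ndarray,
                           duty: float = 0.5,
                           A_on: float | None = None,
                           A_off: float = 0.0,
                           n_periods: int = 50,
                           min_horizon: float = 2000.0,
                           settings: SimulationSettings | None = None,
                           persistence_threshold: float = 1e-6,
                           ) -> pd.DataFrame:
    """Persistence of each established resistance form under square-wave A(t).

    For each period, both resistance forms are started from their established
    (constant-A) state and integrated over many antibiotic cycles; a form
    persists when its lineage density stays above ``persistence_threshold``
    at the end.  Because the forcing never switches off, runs use a fixed
    horizon (max of ``n_periods`` cycles and ``min_horizon``) with the
    equilibrium early-stop disabled.

    Returns a tidy DataFrame (period, form, persists, final_density).
    """
    A_on = params.A if A_on is None else A_on
    base_settings = settings or SimulationSettings()
    A_mean_ref = duty * A_on + (1 - duty) * A_off
    rows = []
    for period in np.asarray(periods, dtype=float):
        fluct = FluctuationConfig(period=period, duty=duty,
                                  A_on=A_on, A_off=A_off)
        variant = VariantConfig(fluctuation=fluct)
        rhs = make_rhs(params, variant=variant)
        horizon = max(n_periods * period, min_horizon)
        run_settings = base_settings.replace(horizon=horizon, early_stop=None)
        for form, lineage in (("plasmid_borne", ("SR", "RR")),
                              ("chromosomal", ("R0", "RS", "RR"))):
            n0 = _established_start(params, form, A_mean_ref)
            res = integrate(n0, params, run_settings, rhs=rhs)
            dens = float(sum(res.raw_state[IDX[t]] for t in lineage))
            rows.append({"period": period, "form": form,
                         "persists": bool(dens > persistence_threshold),
                         "final_density": dens})
    return pd.DataFrame(rows)
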