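"""Stochastic multispecies model of resistance-gene acquisition.

Each of ``n`` species is in one of three states: susceptible ``S``,
chromosomally resistant ``RC``, or plasmid-borne resistant ``RP``.  Positive
frequency-dependent selection within each species (the priority effect
established by the within-species dynamics) makes ``RC`` and ``RP``
absorbing: whichever form a species acquires first is kept.

A susceptible species acquires resistance with per-time hazards::

    hazard_RC = m + c*N_RC + c*t*N_RP
    hazard_RP = p*N_RP + p*t*N_RC

where ``m`` is the de-novo chromosomal mutation rate, ``c`` and ``p`` the
interspecies transfer rates of chromosomal and plasmid-borne resistance, and
``t`` the frequency of the low-frequency alternative form maintained by
plasmid–chromosome gene flow within donor species (so an ``RC`` donor also
transmits plasmid-borne resistance at rate ``p*t``, and vice versa).

Since resistance can only arise de novo on the chromosome, the first
transition is always ``S → RC`` and the plasmid-borne proportion is capped at
``(n-1)/n``.

The model is simulated as a continuous-time Markov chain (competing
exponential hazards; the embedded jump chain suffices for absorption
statistics).  A discrete-time Bernoulli scheme with explicit timestep is
provided as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MultiSpeciesParameters",
    "MultiSpeciesState",
    "EnsembleSummary",
    "transition_hazards",
    "run_realization",
    "ensemble",
    "acquisition_sweep",
    "two_species_rp_probability",
]


@dataclass(frozen=True)
class MultiSpeciesParameters:
    """Rates of the multispecies acquisition model.

    Defaults follow the reference parameterization m=1e-6, c=1e-5, t=0.1,
    with p=1e-4 (plasmid-to-chromosome transfer-rate ratio p/c = 10).
    """

    n: int = 10
    m: float = 1e-6
    c: float = 1e-5
    p: float = 1e-4
    t_freq: float = 0.1

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"n must be an integer >= 1, got {self.n}")
        for name in ("m", "c", "p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.t_freq <= 1:
            raise ValueError("t_freq must lie in [0, 1]")

    def replace(self, **changes) -> "MultiSpeciesParameters":
        from dataclasses import replace as _replace
        return _replace(self, **changes)


@dataclass(frozen=True)
class MultiSpeciesState:
    """Counts of species per state; n_S = n - n_RC - n_RP."""

    n: int
    n_RC: int
    n_RP: int

    def __post_init__(self) -> None:
        if self.n_RC < 0 or self.n_RP < 0 or self.n_RC + self.n_RP > self.n:
            raise ValueError("invalid species counts")

    @property
    def n_S(self) -> int:
        return self.n - self.n_RC - self.n_RP

    @property
    def absorbed(self) -> bool:
        return self.n_S == 0

    @property
    def proportion_plasmid(self) -> float:
        return self.n_RP / self.n


def transition_hazards(state: MultiSpeciesState,
                       params: MultiSpeciesParameters) -> tuple[float, float]:
    """Per-susceptible-species hazards (hazard_RC, hazard_RP).

    Identical for every susceptible species; zero applies trivially to the
    absorbed ones.
    """
    h_rc = params.m + params.c * state.n_RC \
        + params.c * params.t_freq * state.n_RP
    h_rp = params.p * state.n_RP + params.p * params.t_freq * state.n_RC
    return h_rc, h_rp


def run_realization(params: MultiSpeciesParameters,
                    rng: np.random.Generator,
                    mode: str = "ctmc",
                    dt: float | None = None) -> MultiSpeciesState:
    """One stochastic realization, run until every species is resistant.

    ``mode='ctmc'`` samples the embedded jump chain of the continuous-time
    model (each event is S→RC with probability hazard_RC/(hazard_RC+hazard_RP),
    identically for all susceptible species).  ``mode='discrete'`` steps time
    by ``dt`` and draws a categorical outcome per susceptible species per
    step; it requires dt small enough that (hazard_RC+hazard_RP)*dt <= 1.
    """
    if params.m <= 0:
        raise ValueError("m must be > 0: with m = 0 and no resistant species "
                         "absorption is unreachable")
    state = MultiSpeciesState(n=params.n, n_RC=0, n_RP=0)
    if mode == "ctmc":
        while not state.absorbed:
            h_rc, h_rp = transition_hazards(state, params)
            total = h_rc + h_rp
            if rng.random() < h_rc / total:
                state = MultiSpeciesState(state.n, state.n_RC + 1, state.n_RP)
            else:
                state = MultiSpeciesState(state.n, state.n_RC, state.n_RP + 1)
        return state
    if mode == "discrete":
        if dt is None:
            raise ValueError("discrete mode requires an explicit dt")
        while not state.absorbed:
            h_rc, h_rp = transition_hazards(state, params)
            p_rc, p_rp = h_rc * dt, h_rp * dt
            if p_rc + p_rp > 1:
                raise ValueError("dt too large: per-step probability > 1")
            u = rng.random(state.n_S)
            new_rc = int(np.count_nonzero(u < p_rc))
            new_rp = int(np.count_nonzero((u >= p_rc) & (u < p_rc + p_rp)))
            state = MultiSpeciesState(state.n, state.n_RC + new_rc,
                                      state.n_RP + new_rp)
        return state
    raise ValueError("mode must be 'ctmc' or 'discrete'")


@dataclass(frozen=True)
class EnsembleSummary:
    """Monte-Carlo summary of the final plasmid-borne proportion N_RP/n."""

    proportions: np.ndarray
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n_realizations: int
    seed: int | None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def ensemble(params: MultiSpeciesParameters,
             n_realizations: int = 1000,
             seed: int | None = None,
             rng: np.random.Generator | None = None,
             mode: str = "ctmc",
             dt: float | None = None) -> EnsembleSummary:
    """Independent realizations with a seeded RNG.

    The 95% confidence interval is the normal approximation
    mean ± 1.96·SE over realizations.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    props = np.array([
        run_realization(params, rng, mode=mode, dt=dt).proportion_plasmid
        for _ in range(n_realizations)])
    mean = float(props.mean())
    se = float(props.std(ddof=1) / np.sqrt(n_realizations)) \
        if n_realizations > 1 else 0.0
    return EnsembleSummary(proportions=props, mean=mean, se=se,
                           ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se,
                           n_realizations=n_realizations, seed=seed)


def acquisition_sweep(n_values: list[int],
                      ratios: list[float],
                      base: MultiSpeciesParameters | None = None,
                      n_realizations: int = 1000,
                      seed: int | None = None) -> pd.DataFrame:
    """Ensemble mean and CI over species counts and p/c transfer-rate ratios.

    ``p`` is set to ``ratio * c`` for each cell, matching the convention of
    sweeping the plasmid/chromosomal transfer-rate ratio.  Returns a tidy
    DataFrame (n, ratio, mean, se, ci_low, ci_high, n_realizations, max_prop).
    Per-cell failures are recorded in an ``error`` column rather than raised.
    """
    base = base or MultiSpeciesParameters()
    seed_seq = np.random.SeedSequence(seed)
    rows = []
    for n in n_values:
        for ratio in ratios:
            child = np.random.default_rng(seed_seq.spawn(1)[0])
            row: dict = {"n": n, "ratio": ratio}
            try:
                p = base.replace(n=int(n), p=float(ratio) * base.c)
                summ = ensemble(p, n_realizations=n_realizations, rng=child)
                row.update(mean=summ.mean, se=summ.se, ci_low=summ.ci_low,
                           ci_high=summ.ci_high,
                           n_realizations=n_realizations,
                           max_prop=float(summ.proportions.max()), error="")
            except Exception as exc:
                row.update(mean=np.nan, se=np.nan, ci_low=np.nan,
                           ci_high=np.nan, n_realizations=0,
                           max_prop=np.nan, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)


def two_species_rp_probability(params: MultiSpeciesParameters) -> float:
    """Exact probability the second of two species fixes plasmid-borne
    resistance.

    With n=2 the first acquisition is always chromosomal (both plasmid
    hazards vanish while no species is resistant); the second species then
    faces competing hazards m + c (chromosomal) versus p·t (plasmid), so::

        P(RP) = p*t / (p*t + m + c)

    This is the analytic oracle used to validate the simulation.
    """
    pt = params.p * params.t_freq
    return pt / (pt + params.m + params.c)
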