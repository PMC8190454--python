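# Methods

## Model and assumptions

The core model is a six-compartment ODE system for the densities of cell
types indexed by chromosome genotype (R/S) and plasmid state (∅/R/S); see
the README for the equations. The structural assumptions are:

* **Well-mixed, density-dependent competition.** All cell types compete
  through a single crowding death term γT; there is no spatial structure or
  resource dynamics.
* **Single plasmid per cell.** A plasmid-bearing cell cannot be infected by
  a second plasmid (complete surface/entry exclusion). Relaxing this is out
  of scope here.
* **Equal gene effect on either replicon.** The resistance gene has the
  same cost c_R and gives the same (complete) protection whether
  chromosomal or plasmid-borne; a second copy doubles the cost,
  (1−c_R)², and adds no benefit. This penalty on dual carriage is what
  generates positive frequency-dependent selection; the `variants` module
  exposes it as a knob precisely because the headline behavior hinges on it.
* **Segregation loss at replication.** Plasmid-bearing types replicate at
  (1−s) of their rate and the missing fraction appears as plasmid-free
  daughters of the same chromosome, so segregation conserves cell number.
* **Antibiotic as added death.** Pressure A falls only on the two fully
  susceptible types. With A ≥ λ susceptible cells are non-viable even
  without competition (resistance "essential"); nothing in the machinery
  depends on this distinction.

Time and density units are arbitrary: parameters are chosen to explore the
qualitative behavior of a generic system, not to fit a specific organism.

## Parameters

| symbol | meaning | default | role |
|---|---|---|---|
| λ | replication rate (1/time) | 1 | sets the timescale |
| γ | crowding death (vol·cell⁻¹·time⁻¹) | 1 | sets carrying capacity λ/γ |
| A | antibiotic death rate (1/time) | 1 | benefit of resistance |
| c_R | resistance cost (–) | 0.05 | penalizes each gene copy |
| c_P | plasmid carriage cost (–) | 0.075 | plasmid fitness |
| β | conjugation rate (vol·cell⁻¹·time⁻¹) | 0.2 | plasmid fitness |
| s | segregation-loss probability (–) | 0.005 | plasmid inheritance failure |

The defaults are the reference illustrative set: they sit inside the
bistable regime so that every qualitative behavior (both stable gene
locations, the priority effect, the basin structure) is visible at one
parameter point.

## Equilibria and stability

Competitive exclusion between the sensitive and resistant variant of each
replicon, plus the strict inferiority of dual carriers, narrows the
candidate equilibria to five, supported on one or two cell types. Single-
type candidates have logistic closed forms ((λ−A)/γ and (1−c_R)λ/γ). For
the two-type candidates the steady-state condition of the plasmid-bearing
type is linear in total density, which reduces the plasmid-free condition
to a scalar quadratic; both roots are checked for strict positivity, so
the computation is closed-form and cannot fail to converge. Every reported
equilibrium is verified against the full rhs at inf-norm residual 1e−10.

Stability is judged in the **full** six-dimensional model: the analytic
Jacobian (hand-coded, finite-difference-validated to 1e−6) is evaluated at
the candidate and an equilibrium is stable iff max Re(eig) < −1e−9.
Leading real parts within ±1e−9 of zero are flagged *marginal* and excluded
from stable counts — this margin matters because two structural
degeneracies (c_R = 0, and the dual-cost knockout) make the RR direction
exactly neutral, and those points must not be counted as stable. The
regime at a parameter point combines the verdicts: bistable iff a
chromosomal candidate and the plasmid-borne candidate are simultaneously
stable. Points where no candidate at all is stable are flagged for review
(`RegimeResult.review`); the candidate menu is an argument, not a theorem,
and the flag is the guard against an overlooked attractor. None of the
sweeps exercised by the tests trips it except the structurally degenerate
cases above.

Parasitic persistence of a gene-free plasmid is decided by the sign of the
SS-invasion eigenvalue at the plasmid-free sensitive equilibrium,
(1−s)λ_P − (λ−A) − A + β(λ−A)/γ; it is reported as not-applicable when
A ≥ λ (no sensitive host population to invade).

## Numerical integration

Forward simulations use scipy's LSODA with rtol 1e−8 and atol 1e−14 and an
integration horizon of 1e7 time units, read as "until equilibrium": a
terminal event stops the run once ‖rhs‖∞ < 1e−12 **and** no density lies in
the ambiguous band (1e−10, 1e−6). The band condition exists because a
losing lineage decays exponentially at a possibly small rate (≈ βN_S∅* ~
7e−4 at the reference parameters), so the derivative criterion alone is met
while the lineage is still above the rounding threshold; requiring every
component to be clearly established (> 1e−6) or effectively absent
(< 1e−10) makes the final zero-pattern well defined. Final states are
rounded: densities below 1e−10 are set to zero, and only then is the
outcome classified (plasmid-borne / chromosomal / sensitive / extinct /
mixed) from the zero pattern. Rounding is never applied mid-integration.
Tiny negative excursions are clipped inside the rhs; excursions beyond
1e−8 trigger a warning. Outcomes are checked to be invariant under halving
the solver tolerances on sampled grid cells.

One boundary case is worth noting: a lone susceptible population at
exactly A = λ decays algebraically (dN/dt = −γN²), so at the 1e7 horizon
its density is ≈ 1e−7 — above the rounding threshold. Such states classify
as "sensitive" rather than "extinct"; the two labels are deliberately
equivalent for every structural claim (both mean "no resistance").

Default grids: 61×61 for parameter sweeps, 41×41 for basin maps; the tests
and the acceptance script run 21×21 (and coarser for property spot-checks),
which resolves every qualitative feature while keeping a full run in
minutes on one core.

## Variants

All variants reduce exactly to the core model at default knob settings
(the default-config rhs *is* the core rhs). Where an alternative
formulation was not pinned down externally, the choice made here is:

* **Migration**: constant influx μ of chromosomally sensitive cells, a
  fraction f_imm carrying the sensitive plasmid; influx only, no
  emigration.
* **Gene flow**: within-cell relocation of the gene between replicons,
  SR ↔ RS at equal rate τ; dual carriers are untouched (they already have
  both copies). This is the minimal flow that lets the excluded form
  persist at mutation-selection-balance-like frequencies.
* **Fluctuating antibiotic**: square wave (A_on for a duty fraction of each
  period, else A_off), the simplest periodic forcing. Persistence is probed
  by simulation over many cycles from an established state seeded with a
  small (1e−3) sensitive inoculum — without a challenger, an all-resistant
  population would "persist" trivially even with the antibiotic off.
* **Independent segregation**: a standalone loss rate σ per plasmid-bearing
  cell replacing the replication discount; with the default σ = s·λ_type
  the two formulations are algebraically identical, and σ is exposed for
  formulations that are not.
* **Growth-slowing antibiotic**: susceptible replication is multiplied by
  max(0, 1 − A/λ), calibrated so a lone susceptible population equilibrates
  at the same density as under death-mode whenever A < λ.
* **Death-mode costs**: every type replicates at the uncosted rate and the
  forgone growth λ − λ_type moves into the death rate, preserving lone-type
  equilibria.
* **Dual-resistance knobs**: the second-copy cost (default c_R) and the
  single-copy protection fraction (default 1). Because every candidate
  equilibrium has RR = 0, changing only the second-copy cost leaves the
  candidates themselves untouched and stability is re-evaluated exactly via
  a λ_RRP override of the analytic Jacobian. With the second copy free the
  chromosomal-with-plasmid equilibrium becomes exactly marginal and the
  plasmid-borne one is destabilized through joint R∅+RR invasion:
  bistability disappears and simulations end in dual-resistant (mixed)
  states.

## Multispecies acquisition model

Species are S / RC / RP with RC and RP absorbing (the within-species
priority effect, imported as an assumption). Per-susceptible-species
hazards are h_RC = m + c·N_RC + c·t·N_RP and h_RP = p·N_RP + p·t·N_RC.
The reference rates are m = 1e−6, c = 1e−5, t = 0.1, with p swept via the
ratio p/c. The published description is in per-timestep probabilities with
no stated timestep; here the model is a continuous-time Markov chain with
those hazards, simulated by its embedded jump chain (event probabilities
h/(h_RC+h_RP), identical for all susceptible species) — this avoids
timestep artifacts and simultaneous-event tie-breaks and coincides with
any discrete-time scheme in the small-rate limit that all reference rates
occupy. A discrete-time Bernoulli mode with explicit Δt is provided as a
cross-check. Since h_RP = 0 while nothing is resistant, the first
acquisition is always chromosomal, capping the plasmid-borne proportion at
(n−1)/n. For n = 2 the plasmid probability of the second species is exactly
p·t/(p·t + m + c), used as the analytic oracle. Ensembles are 1000 seeded
realizations; the 95% CI is the normal approximation mean ± 1.96·SE (the CI
method is a convention choice).

## What the scenario generator does and does not emulate

The built-in scenarios are the analysis's experimental designs themselves
(parameter-plane sweeps, initial-frequency grids with unit total densities,
immigration contrasts, the species/ratio sweep) — the study is entirely
model-based, so there is no external data to stand in for. Passing tests
therefore demonstrate internal correctness and reproducibility of the
modeling claims, not agreement with any measured system: parameters are
illustrative, units arbitrary, and real plasmid biology (spatial structure,
multi-copy plasmids, compensatory evolution, co-infection) is outside the
model class.

## Known limitations

* The candidate-equilibrium menu rests on a verbal competitive-exclusion
  argument; the review flag and the simulation cross-checks mitigate but
  cannot prove completeness.
* `classify_outcome` trusts the zero pattern after rounding; a genuine
  attractor with a component permanently inside (1e−10, 1e−6) would forfeit
  the early stop and run to the full horizon (correct but slow).
* The fluctuating-antibiotic analysis is simulation-only (Floquet analysis
  is not implemented), and the transposition variant models relocation, not
  copy-and-paste duplication.
* The multispecies model does not feed back into the within-species ODE;
  absorption is absolute, so very long-timescale displacement is excluded
  by construction.
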