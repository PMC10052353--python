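# Methods

`reedsnet` implements the replica-exchange enveloping distribution sampling
(RE-EDS) machinery for combinatorial replacement of hydration-site waters by
apolar probes, exercised on one-dimensional site-network models that admit
exact partition-function references. This note records the model, the
estimators, the numerical choices, and what the toy systems do and do not
show about real protein/water systems.

## The site-network model

A system has `n` hydration sites, each a single 1-D coordinate `x_i` (nm).
An end state is the subset of sites occupied by an apolar probe (labels
`apo`, `(1)`, `(1,3)`, ... by probe-occupied site id); the remaining sites
hold waters. The potential of end state `m` is

    V_m(x) = sum_i [ 0.5 k_char(m,i) (x_i - c_char(m,i))^2        (character well)
                   + 0.5 k_r,i (x_i - c_r,i)^2 ]                  (position restraint)
            - sum_(i,j) eps_char(m,ij) exp(-(x_i-x_j)^2 / 2 sigma_ij^2)   (coupling)

* The **character well** (water or probe) is the only thing the alchemical
  perturbation changes; the probe carries no charge term, mimicking a single
  uncharged united-atom particle standing in for a methyl substituent.
* The **restraint** localizes the alchemical particle to its site. It is
  identical in the pocket and bulk variants of a system, so its contribution
  cancels in the thermodynamic cycle.
* The **Gaussian coupling well** is active only when both sites of a pair
  host the character named by its channel (water–water by default). It is
  the surrogate for hydrogen-bond-network stabilization: replacing either
  partner water by a probe switches the term off, which is precisely the
  cooperativity signature the analyses measure.
* **Bulk partner** = identical sites and states with all couplings removed.
  This isolates network correlation as the only pocket/bulk difference, so
  on toy systems every replacement free energy is a pure network effect.

Units are kJ/mol, nm, K; default temperature 298.15 K (kT = 2.479 kJ/mol).

### Benchmark suite

Three fixed pocket/bulk pairs drive every stochastic test:

| name | sites | couplings | purpose |
|---|---|---|---|
| `uncoupled-3site` | 3 | none | null system: zero replacement signal, exact additivity |
| `coupled-3site` | 3 | one water–water well, eps = 4.0 kJ/mol, sigma = 0.3 nm, sites 1–2 | known nonadditivity and exactly one correlation edge |
| `chain-5site` | 5 | water–water chain, eps = 2.0 | 32-state scale tests (no quadrature) |

All sites use water wells k = 25 kJ/mol/nm² at 0, probe wells k = 100 at
0.3 nm, restraints k = 10 at 0. The probe well is displaced far enough that
end-state basins are geometrically distinct — dominance cells then track
basins and the offset-rebalancing map is contractive, as it must be for a
system the pipeline is expected to converge on — yet close enough that the
smoothed (s < 1) replicas restore transitions. The coupling strength
(~1.6 kT) produces a cooperativity signal (~2.8 kJ/mol through the cycle)
that desk-scale sampling resolves at several sigma.

## Exact references

For systems of up to 4 sites, per-state partition functions are computed by
tensor-product Gauss–Hermite quadrature: the per-site quadratic part
(character well + restraint, completed to a single Gaussian) supplies the
nodes, and the bounded coupling factor is averaged at those nodes (40/dim
by default). Every coupled result is recomputed on a denser node set and
must agree to 1e-7 relative, otherwise a quadrature error is raised. For
uncoupled systems this reduces to the closed-form harmonic result
`0.5 kT sum ln(k_eff,j / k_eff,i)` plus well-offset terms, which the tests
verify, and an independent fine-grid trapezoid integration agrees to
better than 1e-6 kJ/mol on the coupled two-site case.

A deterministic thermodynamic-integration oracle provides a second
independent route: linear mixing `V_lambda = (1-lambda) V_i + lambda V_j`
(no soft-core — the toy potentials are bounded), configurational averages
of `V_j - V_i` by the same quadrature, trapezoid over an even lambda grid.
At 11 windows the discretization error is below 0.05 kJ/mol on harmonic
transformations and below 0.1 kJ/mol on the coupled 3-site benchmark,
shrinking roughly quadratically with window count.

## Reference state, sampling and exchange

The enveloping reference potential at smoothing parameter `s` with
per-state energy offsets `E_i` is

    V_R(x) = -(beta s)^-1 ln sum_i exp[-beta s (V_i(x) - E_i)].

All log-sum evaluations are shifted by the extreme exponent. `V_R` is
bounded between `min_i(V_i - E_i) - (beta s)^-1 ln N` and `min_i(V_i - E_i)`.

Sampling is derivative-free Metropolis Monte Carlo rather than MD: one
site perturbed per step with a Gaussian proposal (default width
`0.5 sqrt(kT / k_max)`), acceptance `min(1, exp(-beta dV_R))`. The
stationary law is the exact reference-state Boltzmann distribution — no
integrator timestep bias — so quadrature oracles apply without correction.
Replicas sit at fixed rungs of a log-uniform s-ladder (default 4 rungs,
s_min = 0.05); after each propagation phase, neighboring rungs attempt a
configuration swap with the Hamiltonian replica-exchange criterion,
alternating even/odd pairs. One RNG stream per replica plus one for
exchanges, all spawned from the master seed, makes runs bitwise
reproducible. Roundtrip statistics track configuration lineages (walkers)
through the rung history; a roundtrip is one full bottom-top-bottom (or
top-bottom-top) traversal, with disjoint trips sharing endpoints so counts
are additive under history concatenation.

## Offset estimation and rebalancing

Initial offsets are `E_i = n_probes(i) x increment`, with the increment
defaulting to the closed-form harmonic cost of one water-to-probe switch.
The rebalancing loop then alternates short RE-EDS runs with the damped
multiplicative-log update

    E_i <- E_i - (intensity / beta) ln( max(f_i, floor) / (1/N) ),

re-centred so the apo offset stays zero, where `f_i` are dominant-state
(maximal-weight, ties to the lowest index) sampling fractions of the s = 1
trajectory. Equal sampling is the rule's fixed point; unsampled states are
lifted by the finite floor term (default floor 1/(10N)). The loop stops
when the deviation from ideal sampling `max_i |f_i - 1/N|` drops below the
stop threshold (default 0.05). Offsets are estimation-neutral: they shift
`V_R` but cancel exactly out of every free-energy difference, which the
tests verify both algebraically and on sampled data.

Two numerical facts shape the defaults:

* **Iteration ensemble size.** The max-deviation statistic carries a
  positive sampling bias of roughly 1.8x the per-fraction standard error
  on an 8-state system. The default iteration ensemble (30 exchange
  phases x 800 steps, stride 2, ~12k frames) keeps that bias near 0.015,
  comfortably below the 0.05 threshold; with ~2k-frame iterations the loop
  can hover at the threshold for noise reasons alone.
* **Intensity.** The triplicate default intensities are (0.5, 0.75, 1.0).
  The undamped update (intensity 1.0) amplifies fraction noise at unit
  gain and in practice oscillates without converging on the coupled
  benchmark; 0.5 and 0.75 converge in 2–4 iterations. This mirrors why a
  damping knob exists at all, and the triplicate design means distinct
  state-sampling distributions across replicates are expected and useful.

## Estimation

Free energies come only from the physical s = 1 replica, by applying
Zwanzig's perturbation formula twice:

    g_i = -kT ln < exp(-beta (V_i - V_R)) >_R,    dG_ji = g_j - g_i.

Since all entries derive from the per-state scalars `g_i`, antisymmetry
and cycle closure of the matrix hold exactly by construction (and are
asserted anyway). A state whose exponent underflows on every frame raises
an error naming the state and advising rebalancing. Single-trajectory
uncertainties use a circular block bootstrap (block length = ceil of twice
the integrated autocorrelation time of the reference-energy series, 200
resamples, fixed seed); replicate spread is the n-1 standard deviation
over the triplicate, and pocket/bulk uncertainties combine in quadrature.

## Network analyses

The thermodynamic cycle gives `ddG_repl(j,i) = dG_ji(pocket) - dG_ji(bulk)`.
On top of the replacement matrix:

* **Conditional replacement**: `ddG` of replacing one site given a context
  of already-replaced sites; path sums close the cycle exactly.
* **Additivity gap**: sum of single-site apo replacements minus the
  concomitant multi-site replacement. Positive gap = cooperative network
  (simultaneous replacement cheaper than the additive estimate).
* **Correlation graph**: `dddG(a|b) = conditional(a,{b}) - conditional(a,{})`
  per ordered pair; unordered edges keep both directions plus the
  symmetrized mean. Negative delta = positive (cooperative) solvation
  correlation. An edge is significant when |delta| exceeds 3x its
  propagated uncertainty; entries with replicate sd above 2.5 kJ/mol are
  flagged low-confidence in outputs.
* **Spearman profile comparison** with a two-sided permutation test
  (5000 permutations by default, seeded, average ranks on ties).
* **Cost accounting** for pairwise protocols: minimal (N-1) or all-pairs
  perturbation counts x lambda windows x per-window times, plus cumulative
  stage-time sums for multistate protocols.

## What the toys show — and what they do not

The toy systems validate the statistical machinery: that the enveloping
reference with rebalanced offsets samples all 2^n states, that
double-Zwanzig recovers exact free energies within its stated errors, that
the cycle isolates network effects, and that implanted cooperativity is
recovered quantitatively with the right sign. They do not emulate
explicit-solvent physics: there are no protein degrees of freedom, no
rotational water entropy, no long-range electrostatics, and the coupling
is a smooth pairwise surrogate for a hydrogen-bond network. Quantitative
agreement here therefore demonstrates correctness of the method's
implementation, not accuracy of any force field or the magnitude of real
protein hydration-site free energies.

## Problem sizes used

Default study: 4 s-replicas, 3 replicates per environment at rebalancing
intensities (0.5, 0.75, 1.0), ~12k-frame rebalancing iterations (max 15),
production 30 phases x 600 steps (18k frames at s = 1), 200 bootstrap
resamples. The acceptance script runs a 3-replicate dual-environment study
on the coupled 3-site benchmark at 10k production frames per replicate.
These sizes resolve the implanted ~2.8 kJ/mol signal at several sigma on a
single CPU in minutes.
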