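# Methods

## The problem

Condensation polymers — nucleic acids, peptides — are thermodynamically
unstable in bulk water: with reversible bond making and breaking, the
equilibrium in solution is mostly monomers. Drying makes bond formation
favourable, but a dry phase also suppresses diffusion, so only molecules
that happen to sit together can react. `polysim` implements a minimal
kinetic theory of this interplay: an exactly solvable dimer model, a
well-mixed polymer equilibrium/kinetics layer, and a stochastic lattice
simulator of the full polymer model under wet–dry cycling and monomer
influx. The point of the model is kinetic, not thermodynamic: cycling wins
because wet phases reposition molecules, not because it changes the
equilibrium.

## Dimer mean-field model (`dimer_meanfield`)

Sites of a 2-d lattice hold 0, 1 or 2 monomers or 1 dimer, with fractions
`P0, P1, P2, PD`. Monomer density relative to maximum occupancy is
`phi = M_tot / 2N`. Dimerization occurs on two-monomer sites at rate `k+`,
breakup at rate `k-`, with `K = k+/k-`. Monomer hopping at rate `h` is
treated in mean field (neighbouring sites independent); the only relevant
exchange is `2 + 0 <-> 1 + 1`, and the dimer hopping rate drops out of the
theory entirely, which is why it is not a parameter.

Closed forms implemented and cross-checked against the ODE system:

* **Diffusion equilibrium** — simultaneous vacancy, occupancy, reaction
  (`PD = K P2`) and diffusion (`4 P0 P2 = P1^2`) balance. The quadratic
  root is evaluated in conjugate form,
  `PD = 2 K phi^2 / (2 K phi + 1 + sqrt(1 + 4 K phi (1 - phi)))`,
  which is exact in both the `K -> 0` (initial conditions) and `K -> inf`
  (`PD -> phi`) limits and avoids cancellation.
* **No-diffusion local equilibrium** — `PD = K phi^2 / (1 + K)`: dimers
  only form where two monomers started, so `P2 + PD = phi^2` is conserved
  and `PD` relaxes linearly at rate `k+ + k-`. The relaxation has a closed
  form; no integrator is used for dry segments of the cycling trajectory,
  because the four ODEs reduce exactly to this scalar relaxation at `h = 0`
  (verified against `solve_ivp` in the tests).
* **Cycling map and fixed point** — each cycle composes local dry
  equilibration (or finite-time relaxation), wet decay `exp(-w t_wet)`,
  and random repositioning, which resets the two-monomer fraction to
  `(phi - PD)^2 / (1 - PD)`. The fixed point solves a quadratic in `PD`;
  again the conjugate root form is used. At `w t_wet = 0` the fixed point
  coincides algebraically with the diffusion equilibrium — the code paths
  agree to 1e-10 over a parameter grid, and the strict ordering
  `local equilibrium < cycling limit < diffusion equilibrium` holds for
  every `0 < w t_wet < inf`.

ODE integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-9,
atol 1e-12); the conservation laws (normalization, vacancy and occupancy
fractions) are identities of the right-hand side and are asserted along
trajectories to 1e-8.

## Well-mixed polymer theory (`wellmixed_polymer`)

With a single monomer type and one bond free energy, the equilibrium
length distribution is geometric (Flory's most probable distribution):
`C_m = a x^{m-1}` with `a = x/K`, where `x` solves
`(1 - x)^2 = x / (K mu)`. The quadratic is solved in the conjugate form
`x = 1 / (1 + q + sqrt(q(2 + q)))`, `q = 1/(2 K mu)`, plus one Newton
polish step, so the residual stays below 1e-12 even for `K mu ~ 1e8`.
Mean length is `1/(1 - x) = mu / lambda`; the strand concentration
`lambda` equivalently solves `K lambda^2 = mu - lambda`, and the two
routes agree to 1e-8 by test. Out of equilibrium the strand concentration
obeys `dC_tot/dt = -k+ C_tot^2 + k- (mu - C_tot)`; only this closed
equation is implemented (the full per-length kinetic hierarchy only holds
well-mixed and is out of scope). The length-distribution cutoff defaults
to the smallest `m` whose analytic tail mass is below `1e-9 mu`; the
truncated mass is reported, never silently dropped.

## Lattice simulator (`lattice_sim`)

Strands (length >= 1) live on a periodic `L x L` lattice with unbounded
per-site occupancy. Per fixed step `dt`, in order: one bond per site with
probability `k+ n(n-1) dt` (two distinct strands chosen uniformly), one
break per strand with probability `k- (m-1) dt` at a uniform bond (both
fragments stay on the site; fragments created in a step are not revisited
within it, but strands merged in the bond pass are eligible), one hop per
strand with probability `h dt` to a uniform Moore neighbour, always
accepted. Probabilities are clamped at 1 and every clamp is counted; a
nonzero count in the run metadata flags discretization bias. Default
`dt = 0.01` for the canonical parameter sets; halving `dt` leaves ensemble
trajectories unchanged within sampling error. Wet phases run
hydrolysis-only steps at rate `w` then scramble every strand to a uniform
random site; scrambling every step realizes the well-mixed limit.
Monomer influx adds a Poisson-distributed count with mean
`N b (1 - mu/mu_max) dt` (the model fixes only the mean; independent
arrivals make Poisson the natural choice), placed uniformly; freshly added
monomers count in the mean length immediately.

Design choices where the model statement is open: periodic boundaries
(removes edge effects so mean-field comparisons are clean);
length-independent hopping; break fragments stay on the parent site;
strands carry no identity beyond length. One seeded
`numpy.random.Generator` per run drives every draw — scramble, influx and
kernel events — so identical seed and parameters give byte-identical
outputs. The inner loop is compiled with numba; the compiled step is the
only implementation (tests exercise it directly against exact Bernoulli,
uniform, Poisson and Markov-chain oracles, including the 1-site
3-monomer partition chain solved by linear algebra).

## Scenarios (`protocols`) and study conditions

Six presets pin the canonical parameter sets: dimer cycling
(`phi = 0.2, K = e^2, k+ = 1, w = 1, t_dry = 8, t_wet = 0.5`) and the
polymer scenarios (`mu = 2, k+ = 1, K = e^4`, diffusion `h = 1`, cycling
`w = 0.2, t_dry = 8, t_wet = 0.5`, influx `b = 5, mu_max = 20`). Influx
is applied during wet steps in the cycling variant and during dry steps in
the diffusion variant. The default lattice is `100^2` (so `mu = 2` means
20,000 monomers); the statistical checks in the test suite and the
acceptance script use `50^2` with 10 replicate seeds, which keeps every
relative fluctuation below ~1% while running in seconds. "Long-run" values
average the last quarter of a run; horizons (t = 300 for diffusion, 150
for no diffusion, 50 cycles = 400 time units for cycling, 200 for influx)
are at least ten times the observed relaxation time of the `C_tot`
overlay, since the model states no stopping rule. Trajectory agreement
with the well-mixed equation is checked at 10 log-spaced checkpoints
spanning `t = 0.5` to the end of the run (the relaxation spans decades, so
a log grid weights the transient and the plateau evenly).

## What the generator does and does not emulate

The simulator realizes exactly the idealized model: one monomer type, one
bond free energy, instantaneous wet/dry switching, length-independent
diffusion and hydrolysis, no templating, no surfaces. Passing tests
therefore demonstrate internal consistency of theory and simulation and
the qualitative mechanism (cycling substitutes for diffusion), not
quantitative agreement with any particular experimental chemistry, where
sequence effects, structure-dependent hydrolysis and gradual drying all
matter.

## Known limitations

* The fixed-step scheme allows at most one bond per site and one break
  per strand per step; at high occupancy (e.g. early in influx runs) some
  site probabilities can clamp. The clamp counter makes this visible; at
  the canonical parameters it stays at zero.
* Mean-field dimer theory ignores spatial correlations; it is exact only
  for fast or global hopping. No stochastic dimer simulator is provided.
* `integrate_ctot` is quantitatively wrong when diffusion is slow — that
  is the scientific point, and the simulator is the tool for that regime.
* The cycling trajectory reports `NaN` site fractions other than `PD`
  during wet phases, where lattice site classes are undefined.
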