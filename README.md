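# polysim

Reversible condensation polymerization under limited diffusion and wet–dry
cycling: exact dimer theory, well-mixed polymer equilibrium, and a
stochastic lattice Monte Carlo simulator.

## The problem

Polymers like RNA and peptides form by condensation reactions that are
unfavourable in water: left alone, a reversible system relaxes to mostly
monomers. Dry conditions make bond formation favourable (`K = k+/k- =
exp(-ΔG/RT) > 1`) but suppress diffusion, so only molecules that end up
close together after drying can react — a single dry phase gets stuck far
short of equilibrium. Alternating wet and dry phases repositions molecules
(at the price of some wet-phase hydrolysis at rate `w`) and ratchets the
system toward the equilibrium that free dry-phase diffusion would reach.
`polysim` is for modellers who want this mechanism quantitatively: every
analytic limit is a closed form, every simulated scenario is one command,
and each simulation ships with its theory overlay.

## Models

**Dimer model (exactly solvable).** Lattice sites hold 0–2 monomers or a
dimer, with site fractions `P0, P1, P2, PD` and monomer density `φ`. In
mean field, the dry-phase equilibrium with diffusion satisfies
`PD = K·P2` and `4·P0·P2 = P1²`; without diffusion the system stops at the
local equilibrium `PD = Kφ²/(1+K)`. Under cycling (dry relaxation, wet
decay `e^{-w·t_wet}`, random repositioning) `PD` converges geometrically
to the root of a quadratic, and for any `w·t_wet > 0`:

    local equilibrium  <  cycling limit  <  diffusion equilibrium

with equality to the diffusion equilibrium as `w·t_wet → 0`.

**Polymer model.** Strands of any length on a lattice with unbounded site
occupancy; two strands on a site join at rate `k+`, each bond hydrolyzes
at `k-` (dry) or `w` (wet), strands hop at rate `h`. Well-mixed
equilibrium is the Flory geometric distribution `C_m = a·x^{m-1}`,
`a = x/K`, with `(1-x)² = x/(Kμ)` and mean length `1/(1-x) = μ/λ`,
`Kλ² = μ - λ`. Kinetics of the strand concentration follow
`dC_tot/dt = -k⁺C_tot² + k⁻(μ - C_tot)`. The simulator reproduces this
when scrambled every step, reaches the same equilibrium for any `h > 0`,
stalls for `h = 0`, and recovers the equilibrium under cycling with
`t_wet = 0`. Monomer influx `dμ/dt = b(1 - μ/μ_max)` raises the ceiling
to the equilibrium at `μ_max`.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Closed-form cycling limits for the dimer model at `φ = 0.2`, `K = e²`,
`w = 1`, `t_wet = 0.5`:

```sh
$ polysim theory cycling-limit
{
  "K": 7.38905609893065,
  "PD_dry_limit": 0.05450450962059047,
  "PD_wet_limit": 0.03305865617749031,
  "phi": 0.2,
  "t_wet": 0.5,
  "w": 1.0
}
```

Repeated cycling holds the dimer fraction between 0.033 (end of wet) and
0.055 (end of dry) — well above the no-diffusion local equilibrium
`Kφ²/(1+K) = 0.0352`, and below the diffusion equilibrium 0.0931 that
it would match if the wet phase did no hydrolysis. The map gets within
0.5% of these limits in six cycles.

A stochastic polymer run with diffusion (`h = 1`, `K = e⁴`, `μ = 2`) on a
50×50 lattice:

```python
from polysim.protocols import run_scenario, long_run_mean

r = run_scenario("polymer-diffusion", seed=1, side=50, t_dry=300.0)
print(long_run_mean(r.timeseries))          # 11.248
print(r.overlay["equilibrium_mean_length"]) # 10.962
print(r.timeseries.tail(1).to_string(index=False))
#  time phase  mean_length  total_strands  total_monomers  clamp_count
# 300.0   dry    11.709602            427            5000            0
```

The long-run mean length (last quarter of the run) fluctuates around the
theoretical `1/(1-x) = 10.96` — with only ~430 strands on the lattice a
single seed wobbles by a few percent; averaging 10 seeds lands within one
standard error of theory. The same command with `h=0.0` plateaus near 2.3
and never approaches equilibrium, while
`run_scenario("polymer-cycling-nohydrolysis", ...)` climbs back to ~10.9:
cycling substitutes for diffusion.

Every scenario is also available from the shell, writing deterministic
CSVs plus a JSON metadata sidecar:

```sh
polysim run polymer-cycling --seed 1 --out out/ -p side=50 -p n_cycles=50
polysim defaults polymer-influx    # show a scenario's canonical parameters
```

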