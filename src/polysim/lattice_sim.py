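"""Stochastic lattice model of reversible polymerization.

Strands (unbranched chains of identical monomers, characterized only by
length) live on a periodic square lattice with no cap on per-site occupancy.
In each fixed time step of length ``dt``:

1. every site holding ``n >= 2`` strands forms one bond with probability
   ``k+ n(n-1) dt``, joining two distinct uniformly chosen strands;
2. every strand of length ``m >= 2`` breaks with probability
   ``k- (m-1) dt`` at a uniformly chosen bond, both fragments staying on
   the site (fragments are not revisited within the step);
3. every strand hops with probability ``h dt`` to one of its 8 Moore
   neighbours, always accepted.

Wet phases hydrolyze at rate ``w`` per bond with no bond formation or
hopping, and end with a global scramble (every strand to a uniform random
site) — the well-mixed limit is recovered by scrambling every step.
Monomer influx adds Poisson-distributed monomers at mean rate
``N b (1 - mu/mu_max)`` per unit time.

Event probabilities that exceed 1 are clamped and counted; a nonzero clamp
count signals that ``dt`` is too coarse for the current configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import run_kernel, step_kernel

__all__ = [
    "LatticeConfig",
    "SimParams",
    "PolymerState",
    "init_random",
    "dry_step",
    "run_dry",
    "scramble",
    "wet_phase",
    "apply_influx",
    "measure_mean_length",
    "measure_length_distribution",
    "site_occupancy_distribution",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Periodic square lattice of ``side x side`` sites."""

    side: int

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("side must be >= 2")

    @property
    def n_sites(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class SimParams:
    """Dry-phase rates, time step and seed for the stochastic dynamics."""

    k_plus: float
    k_minus: float
    h: float
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if min(self.k_plus, self.k_minus, self.h) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class PolymerState:
    """Strand lengths and positions on the lattice, with cached totals.

    ``lengths`` and ``sites`` expose the active strands as views; internal
    arrays are over-allocated to the maximum possible strand count (the
    total monomer count) so steps never reallocate.  The attached
    ``rng`` is the single source of randomness for the whole run.
    """

    config: LatticeConfig
    rng: np.random.Generator
    _lengths: np.ndarray = field(repr=False)
    _sites: np.ndarray = field(repr=False)
    n_strands: int
    time: float = 0.0
    clamp_count: int = 0

    @property
    def lengths(self) -> np.ndarray:
        return self._lengths[: self.n_strands]

    @property
    def sites(self) -> np.ndarray:
        return self._sites[: self.n_strands]

    @property
    def total_strands(self) -> int:
        return self.n_strands

    @property
    def total_monomers(self) -> int:
        return int(self.lengths.sum())

    @property
    def mu(self) -> float:
        """Monomers per lattice site."""
        return self.total_monomers / self.config.n_sites

    def site_lengths(self, site: int) -> list[int]:
        """Multiset of strand lengths on one site (diagnostic accessor)."""
        return sorted(self.lengths[self.sites == site].tolist())

    def validate(self) -> None:
        if self.n_strands and self.lengths.min() < 1:
            raise AssertionError("stored strand length < 1")
        if self.n_strands:
            if self.sites.min() < 0 or self.sites.max() >= self.config.n_sites:
                raise AssertionError("strand site index out of range")

    def _ensure_capacity(self, cap: int) -> None:
        if self._lengths.shape[0] < cap:
            new_cap = max(cap, 2 * self._lengths.shape[0])
            grown_l = np.zeros(new_cap, dtype=np.int64)
            grown_s = np.zeros(new_cap, dtype=np.int64)
            grown_l[: self.n_strands] = self.lengths
            grown_s[: self.n_strands] = self.sites
            self._lengths = grown_l
            self._sites = grown_s


def init_random(
    config: LatticeConfig, m_tot: int, seed: int | np.random.Generator
) -> PolymerState:
    """Place ``m_tot`` monomers independently and uniformly over the sites."""
    if m_tot < 0:
        raise ValueError("m_tot must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = np.ones(max(m_tot, 1), dtype=np.int64)
    sites = np.zeros(max(m_tot, 1), dtype=np.int64)
    sites[:m_tot] = rng.integers(0, config.n_sites, size=m_tot)
    if m_tot == 0:
        lengths[:] = 0
    return PolymerState(
        config=config, rng=rng, _lengths=lengths, _sites=sites, n_strands=m_tot
    )


def dry_step(state: PolymerState, params: SimParams) -> PolymerState:
    """One dry-phase step (bond formation, hydrolysis, hopping), in place."""
    n, clamp = step_kernel(
        state._lengths,
        state._sites,
        state.n_strands,
        state.config.n_sites,
        state.config.side,
        params.k_plus,
        params.k_minus,
        params.h,
        params.dt,
        state.rng,
    )
    state.n_strands = int(n)
    state.clamp_count += int(clamp)
    state.time += params.dt
    return state


def run_dry(
    state: PolymerState, params: SimParams, n_steps: int,
    record_strands: bool = False,
) -> np.ndarray | None:
    """Advance ``n_steps`` dry steps inside the compiled loop.

    With ``record_strands`` the strand count after every step is returned,
    giving the mean-length trajectory at no cost (monomers are conserved).
    """
    record = np.empty(n_steps, dtype=np.int64)
    n, clamp = run_kernel(
        state._lengths, state._sites, state.n_strands,
        state.config.n_sites, state.config.side,
        params.k_plus, params.k_minus, params.h, params.dt,
        state.rng, n_steps, record,
    )
    state.n_strands = int(n)
    state.clamp_count += int(clamp)
    state.time += n_steps * params.dt
    return record if record_strands else None


def scramble(state: PolymerState, rng: np.random.Generator | None = None) -> PolymerState:
    """Move every strand to an independent uniform random site."""
    rng = rng if rng is not None else state.rng
    state._sites[: state.n_strands] = rng.integers(
        0, state.config.n_sites, size=state.n_strands
    )
    return state


def wet_phase(
    state: PolymerState,
    w: float,
    t_wet: float,
    dt: float,
    rng: np.random.Generator | None = None,
    influx: tuple[float, float] | None = None,
) -> PolymerState:
    """Hydrolysis-only steps for a duration ``t_wet``, then one scramble.

    Each step breaks each strand with probability ``w (m-1) dt``; with
    ``influx=(b, mu_max)`` fresh monomers are also added every step.  With
    ``t_wet = 0`` the strands are only repositioned.
    """
    if w < 0 or t_wet < 0:
        raise ValueError("w and t_wet must be >= 0")
    rng = rng if rng is not None else state.rng
    hydro = SimParams(k_plus=0.0, k_minus=w, h=0.0, dt=dt)
    for _ in range(math.ceil(t_wet / dt - 1e-12)):
        dry_step(state, hydro)
        if influx is not None:
            apply_influx(state, influx[0], influx[1], dt, rng)
    return scramble(state, rng)


def apply_influx(
    state: PolymerState,
    b: float,
    mu_max: float,
    dt: float,
    rng: np.random.Generator | None = None,
) -> PolymerState:
    """Add Poisson-many monomers with mean N b (1 - mu/mu_max) dt."""
    if b < 0:
        raise ValueError("b must be >= 0")
    if mu_max <= 0:
        raise ValueError("mu_max must be > 0")
    rng = rng if rng is not None else state.rng
    mean = state.config.n_sites * b * (1.0 - state.mu / mu_max) * dt
    if mean <= 0.0:
        return state
    k = int(rng.poisson(mean))
    if k == 0:
        return state
    state._ensure_capacity(state.n_strands + k)
    sl = slice(state.n_strands, state.n_strands + k)
    state._lengths[sl] = 1
    state._sites[sl] = rng.integers(0, state.config.n_sites, size=k)
    state.n_strands += k
    return state


def measure_mean_length(state: PolymerState) -> float:
    """Total monomers / total strands; NaN for an empty lattice."""
    if state.n_strands == 0:
        return math.nan
    return state.total_monomers / state.n_strands


def measure_length_distribution(state: PolymerState) -> dict[str, np.ndarray]:
    """Counts and per-site concentrations by strand length.

    Returns arrays ``length``, ``count``, ``concentration`` covering
    1..max(length); the mass identity sum(m * count) == total_monomers is
    exact by construction.
    """
    if state.n_strands == 0:
        return {
            "length": np.array([], dtype=np.int64),
            "count": np.array([], dtype=np.int64),
            "concentration": np.array([]),
        }
    counts = np.bincount(state.lengths)[1:]
    lengths = np.arange(1, counts.size + 1)
    return {
        "length": lengths,
        "count": counts,
        "concentration": counts / state.config.n_sites,
    }


def site_occupancy_distribution(state: PolymerState) -> dict[str, np.ndarray]:
    """Number of sites holding n strands, n = 0..max occupancy."""
    per_site = np.bincount(state.sites, minlength=state.config.n_sites)
    occ = np.bincount(per_site)
    return {"n_strands": np.arange(occ.size), "n_sites": occ}
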