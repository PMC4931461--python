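"""Exactly solvable dimer-formation model on a lattice.

Each lattice site holds 0, 1 or 2 monomers or a single dimer.  Two monomers
on one site dimerize at rate ``k_plus``; a dimer breaks at rate ``k_minus``;
the equilibrium constant is ``K = k_plus / k_minus``.  Monomers hop between
neighbouring sites at rate ``h``; in the mean-field approximation (sites
statistically independent) only the exchange 2 + 0 <-> 1 + 1 matters and the
dimer hopping rate drops out entirely.

Three regimes are treated:

* a dry phase with diffusion, which relaxes to a closed-form equilibrium
  with dimer fraction well above the no-diffusion value;
* a dry phase without diffusion, which is stuck at a local per-site
  equilibrium ``PD = K phi^2 / (1 + K)``;
* alternating dry/wet cycles — dry phases without diffusion, wet phases
  that hydrolyze dimers at rate ``w`` and randomly reposition molecules —
  which converge geometrically to a fixed point between the two.

All fractions are per lattice site; ``phi`` is the monomer density relative
to the maximum occupancy of two monomers per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DimerParams",
    "SiteProbs",
    "CycleSchedule",
    "CyclingTrajectory",
    "initial_probs",
    "integrate_meanfield",
    "equilibrium_diffusion",
    "local_equilibrium_no_diffusion",
    "relax_no_diffusion",
    "cycle_start_state",
    "cycle_start_probs",
    "iterate_cycles",
    "cycling_limit",
    "dimer_cycling_trajectory",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DimerParams:
    """Rates and density for the dimer model.

    ``K`` is derived as ``k_plus / k_minus`` (``inf`` when ``k_minus == 0``).
    The dimer hopping rate has no effect in mean field and is not a field.
    """

    phi: float
    k_plus: float
    k_minus: float
    h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        for name in ("k_plus", "k_minus", "h"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def K(self) -> float:
        if self.k_minus == 0.0:
            return math.inf
        return self.k_plus / self.k_minus

    @classmethod
    def from_K(cls, phi: float, K: float, k_plus: float = 1.0, h: float = 0.0) -> "DimerParams":
        """Build params fixing ``K`` and ``k_plus``; ``k_minus = k_plus / K``."""
        if K <= 0.0:
            raise ValueError("K must be > 0")
        return cls(phi=phi, k_plus=k_plus, k_minus=k_plus / K, h=h)


@dataclass(frozen=True)
class SiteProbs:
    """Fractions of sites holding 0 monomers, 1 monomer, 2 monomers, 1 dimer."""

    P0: float
    P1: float
    P2: float
    PD: float

    def as_array(self) -> np.ndarray:
        return np.array([self.P0, self.P1, self.P2, self.PD])

    def validate(self) -> None:
        a = self.as_array()
        if np.any(a < -_SUM_TOL) or np.any(a > 1.0 + _SUM_TOL):
            raise ValueError(f"site probabilities out of [0, 1]: {self}")
        if abs(a.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"site probabilities do not sum to 1: {self}")

    @property
    def occupancy(self) -> float:
        """Monomer density phi implied by the state: P1/2 + P2 + PD."""
        return 0.5 * self.P1 + self.P2 + self.PD


@dataclass(frozen=True)
class CycleSchedule:
    """Wet-dry cycling protocol: phase durations, wet hydrolysis rate, count."""

    t_dry: float
    t_wet: float
    w: float
    n_cycles: int

    def __post_init__(self) -> None:
        if self.t_dry < 0 or self.t_wet < 0 or self.w < 0:
            raise ValueError("durations and rates must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def initial_probs(phi: float) -> SiteProbs:
    """Random monomer placement with no dimers: binomial site occupancy."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    return SiteProbs((1.0 - phi) ** 2, 2.0 * phi * (1.0 - phi), phi**2, 0.0)


def _rhs(t: float, y: np.ndarray, k_plus: float, k_minus: float, h: float) -> np.ndarray:
    p0, p1, p2, pd = y
    hop = -2.0 * h * p0 * p2 + 0.5 * h * p1 * p1
    react = -k_plus * p2 + k_minus * pd
    return np.array([hop, -2.0 * hop, hop + react, -react])


def integrate_meanfield(
    params: DimerParams,
    init: SiteProbs,
    t_end: float,
    report_dt: float,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the four mean-field site-fraction ODEs.

    Returns a frame with columns ``time, P0, P1, P2, PD``.  Normalization and
    the vacancy/occupancy conservation laws are preserved to integrator
    tolerance (the right-hand side conserves them exactly).
    """
    init.validate()
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    t_eval = np.arange(0.0, t_end + 0.5 * report_dt, report_dt)
    t_eval = t_eval[t_eval <= t_end]
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_end)),
        init.as_array(),
        t_eval=t_eval,
        args=(params.k_plus, params.k_minus, params.h),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"mean-field integration failed near t={sol.t[-1]}: {sol.message}")
    return pd.DataFrame(
        {"time": sol.t, "P0": sol.y[0], "P1": sol.y[1], "P2": sol.y[2], "PD": sol.y[3]}
    )


def equilibrium_diffusion(phi: float, K: float) -> SiteProbs:
    """Closed-form dry-phase equilibrium when monomer hopping is allowed.

    Solves the simultaneous vacancy, occupancy, reaction-balance
    (``PD = K P2``) and diffusion-balance (``4 P0 P2 = P1^2``) conditions.
    Cancellation-safe root forms are used so the large-``K`` and small-``K``
    limits are exact.
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if K <= 0.0:
        raise ValueError("K must be > 0")
    if math.isinf(K):
        return SiteProbs(1.0 - phi, 0.0, 0.0, phi)
    r = math.sqrt(1.0 + 4.0 * K * phi * (1.0 - phi))
    p1 = 4.0 * phi * (1.0 - phi) / (1.0 + r)
    pd = 2.0 * K * phi * phi / (2.0 * K * phi + 1.0 + r)
    p2 = pd / K
    p0 = 1.0 - p1 - p2 - pd
    return SiteProbs(p0, p1, p2, pd)


def local_equilibrium_no_diffusion(phi: float, K: float) -> float:
    """Dimer fraction at per-site equilibrium without diffusion: K phi^2/(1+K)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    if K <= 0.0:
        raise ValueError("K must be > 0")
    if math.isinf(K):
        return phi * phi
    return K * phi * phi / (1.0 + K)


def relax_no_diffusion(pd0: float, S: float, k_plus: float, k_minus: float, t: float) -> float:
    """Exact first-order relaxation of the dimer fraction at fixed P2 + PD = S.

    Solves dPD/dt = k+ (S - PD) - k- PD from PD(0) = pd0.
    """
    if not 0.0 <= pd0 <= S <= 1.0:
        raise ValueError(f"need 0 <= pd0 <= S <= 1, got pd0={pd0}, S={S}")
    if t < 0:
        raise ValueError("t must be >= 0")
    rate = k_plus + k_minus
    if rate == 0.0 or t == 0.0:
        return pd0
    pd_eq = k_plus * S / rate
    return pd_eq + (pd0 - pd_eq) * math.exp(-rate * t)


def cycle_start_state(pd_init: float, phi: float) -> float:
    """Fraction of two-monomer sites after random repositioning.

    ``pd_init`` dimer-occupied sites are placed first; the remaining monomers
    are distributed over the other sites at concentration
    ``(phi - pd_init) / (1 - pd_init)``, giving two-monomer fraction
    ``(phi - pd_init)^2 / (1 - pd_init)``.
    """
    if not 0.0 <= pd_init <= phi:
        raise ValueError(f"need 0 <= pd_init <= phi, got pd_init={pd_init}, phi={phi}")
    if phi >= 1.0:
        raise ValueError("phi must be < 1")
    return (phi - pd_init) ** 2 / (1.0 - pd_init)


def cycle_start_probs(pd_init: float, phi: float) -> SiteProbs:
    """Full site-fraction state at the start of a dry phase."""
    p2 = cycle_start_state(pd_init, phi)
    xi = (phi - pd_init) / (1.0 - pd_init)
    p1 = (1.0 - pd_init) * 2.0 * xi * (1.0 - xi)
    p0 = (1.0 - pd_init) * (1.0 - xi) ** 2
    return SiteProbs(p0, p1, p2, pd_init)


Mode = Literal["local-equilibrium", "finite-t_dry"]


@dataclass(frozen=True)
class CyclingTrajectory:
    """Per-cycle dimer fractions plus convergence metadata."""

    cycles: pd.DataFrame  # columns cycle, PD_dry, PD_wet
    converged: bool
    n_cycles_run: int


def iterate_cycles(
    phi: float,
    K: float,
    schedule: CycleSchedule,
    mode: Mode = "local-equilibrium",
    k_plus: float | None = None,
    k_minus: float | None = None,
    pd_init: float = 0.0,
    rel_tol: float = 1e-12,
) -> CyclingTrajectory:
    """Iterate the wet-dry cycling map for the dimer model.

    In ``local-equilibrium`` mode each dry phase is assumed long enough to
    equilibrate: ``PD_dry = K/(1+K) * (pd + P2_start)``.  In ``finite-t_dry``
    mode the dry phase relaxes for ``schedule.t_dry`` with the supplied rate
    constants.  Each wet phase multiplies PD by ``exp(-w t_wet)`` and
    repositions the molecules (which is what the start-state formula
    encodes).  Iteration stops at ``schedule.n_cycles`` or when the relative
    change in end-of-wet PD drops below ``rel_tol``.
    """
    if mode == "finite-t_dry":
        if k_plus is None or k_minus is None:
            raise ValueError("finite-t_dry mode requires k_plus and k_minus")
    decay = math.exp(-schedule.w * schedule.t_wet)
    f_dry = K / (1.0 + K) if not math.isinf(K) else 1.0
    pd_cur = pd_init
    rows = []
    converged = False
    for n in range(1, schedule.n_cycles + 1):
        s = pd_cur + cycle_start_state(pd_cur, phi)
        if mode == "local-equilibrium":
            pd_dry = f_dry * s
        else:
            pd_dry = relax_no_diffusion(pd_cur, s, k_plus, k_minus, schedule.t_dry)
        pd_wet = pd_dry * decay
        rows.append((n, pd_dry, pd_wet))
        if pd_cur > 0 and abs(pd_wet - pd_cur) <= rel_tol * pd_cur:
            pd_cur = pd_wet
            converged = True
            break
        pd_cur = pd_wet
    frame = pd.DataFrame(rows, columns=["cycle", "PD_dry", "PD_wet"])
    return CyclingTrajectory(cycles=frame, converged=converged, n_cycles_run=len(rows))


def cycling_limit(phi: float, K: float, w: float, t_wet: float) -> tuple[float, float]:
    """Fixed point of the cycling map: (end-of-wet, end-of-dry) dimer fractions.

    With ``f = K exp(-w t_wet) / (1 + K)`` the limit satisfies a quadratic;
    the root in [0, 1] is evaluated in the conjugate form
    ``2 f phi^2 / (b + sqrt(b^2 - 4 f phi^2))``, ``b = 1 - f + 2 f phi``,
    which is stable when the discriminant approaches ``b^2``.
    """
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    if K <= 0.0:
        raise ValueError("K must be > 0")
    wt = w * t_wet
    if wt < 0:
        raise ValueError("w * t_wet must be >= 0")
    decay = math.exp(-wt)
    f = decay if math.isinf(K) else K * decay / (1.0 + K)
    b = 1.0 - f + 2.0 * f * phi
    disc = b * b - 4.0 * f * phi * phi
    pd_wet = 2.0 * f * phi * phi / (b + math.sqrt(max(disc, 0.0)))
    return pd_wet, pd_wet / decay if decay > 0 else math.inf


def dimer_cycling_trajectory(
    params: DimerParams,
    schedule: CycleSchedule,
    report_dt: float = 0.05,
    pd_init: float = 0.0,
) -> pd.DataFrame:
    """Time-resolved PD(t) under cycling with no dry-phase diffusion.

    Dry segments follow the exact scalar relaxation at fixed P2 + PD (the
    no-diffusion mean-field ODEs reduce to it); wet segments decay PD
    exponentially at rate ``w``.  Returns columns
    ``time, cycle, phase, P0, P1, P2, PD``.
    """
    phi = params.phi
    rows: list[tuple[float, int, str, float, float, float, float]] = []
    t0 = 0.0
    pd_cur = pd_init
    for n in range(1, schedule.n_cycles + 1):
        start = cycle_start_probs(pd_cur, phi)
        s = pd_cur + start.P2
        # vacancy split P0/P1 is frozen during a no-diffusion dry phase
        occ0, occ1 = start.P0, start.P1
        n_pts = max(int(round(schedule.t_dry / report_dt)), 1)
        for tau in np.linspace(0.0, schedule.t_dry, n_pts + 1):
            pdt = relax_no_diffusion(pd_cur, s, params.k_plus, params.k_minus, tau)
            rows.append((t0 + tau, n, "dry", occ0, occ1, s - pdt, pdt))
        t0 += schedule.t_dry
        pd_dry = relax_no_diffusion(pd_cur, s, params.k_plus, params.k_minus, schedule.t_dry)
        if schedule.t_wet > 0:
            n_pts = max(int(round(schedule.t_wet / report_dt)), 1)
            for tau in np.linspace(0.0, schedule.t_wet, n_pts + 1):
                pdt = pd_dry * math.exp(-schedule.w * tau)
                # during the wet phase only PD is meaningful on the lattice scale
                rows.append((t0 + tau, n, "wet", math.nan, math.nan, math.nan, pdt))
            t0 += schedule.t_wet
            pd_cur = pd_dry * math.exp(-schedule.w * schedule.t_wet)
        else:
            pd_cur = pd_dry
    return pd.DataFrame(
        rows, columns=["time", "cycle", "phase", "P0", "P1", "P2", "PD"]
    )
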