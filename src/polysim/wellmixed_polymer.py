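"""Well-mixed reversible polymerization: equilibrium theory and C_tot kinetics.

At equilibrium the concentration of strands of length ``m`` is geometric
(Flory-type), ``C_m = a x^{m-1}`` with ``a = x / K``, where the decay ratio
``x`` solves ``(1 - x)^2 = x / (K mu)`` for total monomer concentration
``mu``.  The mean strand length is ``1 / (1 - x) = mu / lambda`` with
``lambda = a / (1 - x)`` the total strand concentration, which equivalently
solves ``K lambda^2 = mu - lambda``.  Out of equilibrium the total strand
concentration obeys the closed kinetics ``dC_tot/dt = -k+ C_tot^2 +
k- (mu - C_tot)``.

The same formulas describe the lattice model with fast diffusion, where the
number of strands per site is Poisson(lambda); the helpers here serve as the
analytic cross-check for the stochastic simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import poisson

__all__ = [
    "PolymerParams",
    "EquilibriumSolution",
    "LengthDistribution",
    "equilibrium_x",
    "equilibrium_lambda",
    "equilibrium_solution",
    "equilibrium_length_distribution",
    "mean_length_equilibrium",
    "integrate_ctot",
    "poisson_occupancy",
    "default_m_max",
]


@dataclass(frozen=True)
class PolymerParams:
    """Bond formation/hydrolysis rates and total monomer concentration."""

    k_plus: float
    k_minus: float
    mu: float

    def __post_init__(self) -> None:
        if self.k_plus < 0 or self.k_minus < 0:
            raise ValueError("rates must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def K(self) -> float:
        if self.k_minus == 0.0:
            return math.inf
        return self.k_plus / self.k_minus

    @classmethod
    def from_K(cls, K: float, mu: float, k_plus: float = 1.0) -> "PolymerParams":
        if K <= 0.0:
            raise ValueError("K must be > 0")
        return cls(k_plus=k_plus, k_minus=k_plus / K, mu=mu)


@dataclass(frozen=True)
class EquilibriumSolution:
    x: float  # geometric decay ratio of the length distribution
    a: float  # free-monomer concentration C_1 = x / K
    lambda_: float  # total strand concentration a / (1 - x)
    mean_length: float  # 1 / (1 - x) = mu / lambda


@dataclass(frozen=True)
class LengthDistribution:
    """Equilibrium concentrations C_1..C_{m_max} and the truncated tail mass."""

    lengths: np.ndarray
    concentration: np.ndarray
    truncation_mass_error: float


def _check_pos(K: float, mu: float) -> None:
    if K <= 0.0:
        raise ValueError("K must be > 0")
    if mu <= 0.0:
        raise ValueError("mu must be > 0")


def equilibrium_x(K: float, mu: float) -> float:
    """Decay ratio x in (0, 1) solving (1 - x)^2 = x / (K mu).

    Uses the conjugate form ``x = 1 / (1 + q + sqrt(q (2 + q)))`` with
    ``q = 1 / (2 K mu)`` (exact rearrangement of the quadratic root, stable
    for large ``K mu``), followed by one Newton polish step.
    """
    _check_pos(K, mu)
    q = 1.0 / (2.0 * K * mu)
    x = 1.0 / (1.0 + q + math.sqrt(q * (2.0 + q)))
    # Newton polish on g(x) = (1-x)^2 - x/(K mu)
    g = (1.0 - x) ** 2 - x / (K * mu)
    gp = -2.0 * (1.0 - x) - 1.0 / (K * mu)
    x -= g / gp
    return min(max(x, 0.0), 1.0 - 1e-300)


def equilibrium_lambda(K: float, mu: float) -> float:
    """Total strand concentration: positive root of K lambda^2 = mu - lambda."""
    _check_pos(K, mu)
    return 2.0 * mu / (1.0 + math.sqrt(1.0 + 4.0 * K * mu))


def equilibrium_solution(K: float, mu: float) -> EquilibriumSolution:
    x = equilibrium_x(K, mu)
    a = x / K
    lam = a / (1.0 - x)
    return EquilibriumSolution(x=x, a=a, lambda_=lam, mean_length=1.0 / (1.0 - x))


def mean_length_equilibrium(K: float, mu: float) -> float:
    """Equilibrium mean strand length 1 / (1 - x)."""
    return 1.0 / (1.0 - equilibrium_x(K, mu))


def default_m_max(K: float, mu: float, mass_tol: float = 1e-9) -> int:
    """Smallest cutoff M whose tail monomer mass is below ``mass_tol * mu``."""
    sol = equilibrium_solution(K, mu)
    x, a = sol.x, sol.a

    def tail(m: int) -> float:
        return a * x**m * (m + 1 - m * x) / (1.0 - x) ** 2

    hi = max(int(sol.mean_length), 1)
    while tail(hi) > mass_tol * mu:
        hi *= 2
    lo = 1
    while lo < hi:  # smallest m with tail(m) <= tol (tail is decreasing)
        mid = (lo + hi) // 2
        if tail(mid) <= mass_tol * mu:
            hi = mid
        else:
            lo = mid + 1
    return hi


def equilibrium_length_distribution(
    K: float, mu: float, m_max: int | None = None
) -> LengthDistribution:
    """Geometric equilibrium distribution C_m = a x^{m-1}, m = 1..m_max.

    Satisfies detailed balance ``k+ C_n C_m = k- C_{n+m}`` for every split.
    The monomer mass beyond the cutoff is reported, not silently dropped.
    """
    if m_max is None:
        m_max = default_m_max(K, mu)
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    sol = equilibrium_solution(K, mu)
    m = np.arange(1, m_max + 1)
    conc = sol.a * sol.x ** (m - 1)
    tail = sol.a * sol.x**m_max * (m_max + 1 - m_max * sol.x) / (1.0 - sol.x) ** 2
    return LengthDistribution(lengths=m, concentration=conc, truncation_mass_error=tail)


def integrate_ctot(
    params: PolymerParams,
    c0: float,
    t_end: float,
    report_dt: float | None = None,
    n_points: int = 200,
    log_spaced: bool = False,
    t_start: float = 1e-3,
) -> pd.DataFrame:
    """Integrate dC_tot/dt = -k+ C_tot^2 + k- (mu - C_tot).

    Returns columns ``time, C_tot, mean_length`` with
    ``mean_length = mu / C_tot``.  With ``log_spaced`` the reporting grid is
    geometric from ``t_start`` to ``t_end`` (the relaxation spans decades).
    """
    if not 0.0 < c0 <= params.mu:
        raise ValueError(f"need 0 < c0 <= mu, got c0={c0}, mu={params.mu}")
    if log_spaced:
        t_eval = np.geomspace(t_start, t_end, n_points)
        t_eval = np.concatenate(([0.0], t_eval))
    elif report_dt is not None:
        t_eval = np.arange(0.0, t_end + 0.5 * report_dt, report_dt)
        t_eval = t_eval[t_eval <= t_end]
    else:
        t_eval = np.linspace(0.0, t_end, n_points)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = y[0]
        return np.array([-params.k_plus * c * c + params.k_minus * (params.mu - c)])

    sol = solve_ivp(rhs, (0.0, float(t_end)), [c0], t_eval=t_eval, method="LSODA",
                    rtol=1e-10, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"C_tot integration failed: {sol.message}")
    c = sol.y[0]
    return pd.DataFrame({"time": sol.t, "C_tot": c, "mean_length": params.mu / c})


def poisson_occupancy(lambda_: float, n_max: int) -> np.ndarray:
    """P(n strands on a site) = Poisson(lambda), n = 0..n_max."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    return poisson.pmf(np.arange(n_max + 1), lambda_)
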