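"""Named simulation scenarios composing dry phases, wet phases and influx.

The six scenarios reproduce the model's canonical numerical experiments:

* ``dimer-cycling`` — analytic wet-dry cycling of the dimer model with the
  closed-form limits as overlay (no stochastic simulation involved);
* ``polymer-diffusion`` — a single dry phase with hopping at rate ``h``;
* ``polymer-nodiffusion`` — a single dry phase with ``h = 0``;
* ``polymer-cycling`` — dry phases with ``h = 0`` alternating with
  hydrolyzing wet phases (``w``, ``t_wet``) that reposition all strands;
* ``polymer-cycling-nohydrolysis`` — cycling with ``t_wet = 0``: strands
  are repositioned between dry phases but no wet hydrolysis occurs;
* ``polymer-influx`` — monomer influx up to a ceiling ``mu_max``, either
  during dry steps (diffusion variant) or during wet steps (cycling
  variant), selected by the protocol's influx phase.

Defaults pin the canonical parameter sets (k+ = 1, K = e^4, mu = 2 for the
polymer scenarios; phi = 0.2, K = e^2 for the dimer scenario) so each run
is reproducible from a single call; every field can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from . import dimer_meanfield as dm
from . import lattice_sim as ls
from . import wellmixed_polymer as wp

__all__ = [
    "InfluxSettings",
    "CycleProtocol",
    "ScenarioResult",
    "SCENARIO_NAMES",
    "scenario_defaults",
    "run_scenario",
    "run_replicates",
    "long_run_mean",
]

SCENARIO_NAMES = (
    "dimer-cycling",
    "polymer-diffusion",
    "polymer-nodiffusion",
    "polymer-cycling",
    "polymer-cycling-nohydrolysis",
    "polymer-influx",
)


@dataclass(frozen=True)
class InfluxSettings:
    """Monomer influx at rate b (1 - mu/mu_max), applied in one phase."""

    b: float
    mu_max: float
    phase: str = "wet"  # "wet" or "dry"

    def __post_init__(self) -> None:
        if self.b < 0 or self.mu_max <= 0:
            raise ValueError("need b >= 0 and mu_max > 0")
        if self.phase not in ("wet", "dry"):
            raise ValueError("influx phase must be 'wet' or 'dry'")


@dataclass(frozen=True)
class CycleProtocol:
    """Scheduling of dry/wet phases, scrambling and influx for one run."""

    t_dry: float
    t_wet: float = 0.0
    w: float = 0.0
    n_cycles: int = 1
    scramble_every_step: bool = False
    influx: InfluxSettings | None = None
    h_dry: float = 0.0

    def __post_init__(self) -> None:
        if self.t_dry < 0 or self.t_wet < 0 or self.w < 0:
            raise ValueError("durations and rates must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.scramble_every_step and self.n_cycles > 1:
            raise ValueError("scramble_every_step is a single-phase (well-mixed) mode")

    @property
    def total_time(self) -> float:
        return self.n_cycles * (self.t_dry + self.t_wet)


@dataclass
class ScenarioResult:
    """Time series, final length histogram/occupancy, overlay and metadata."""

    name: str
    timeseries: pd.DataFrame
    length_distribution: pd.DataFrame
    occupancy: pd.DataFrame
    overlay: dict[str, Any]
    metadata: dict[str, Any]


_POLYMER_DEFAULTS = dict(mu=2.0, k_plus=1.0, k_minus=math.exp(-4.0), side=100, dt=0.01)


def scenario_defaults(name: str) -> dict[str, Any]:
    """Canonical parameter set for a named scenario (all overridable)."""
    if name == "dimer-cycling":
        return dict(
            phi=0.2, k_plus=1.0, k_minus=math.exp(-2.0), w=1.0,
            t_dry=8.0, t_wet=0.5, n_cycles=20,
        )
    base = dict(_POLYMER_DEFAULTS)
    if name == "polymer-diffusion":
        base.update(h=1.0, t_dry=400.0)
    elif name == "polymer-nodiffusion":
        base.update(h=0.0, t_dry=400.0)
    elif name == "polymer-cycling":
        base.update(h=0.0, w=0.2, t_dry=8.0, t_wet=0.5, n_cycles=50)
    elif name == "polymer-cycling-nohydrolysis":
        base.update(h=0.0, w=0.0, t_dry=8.0, t_wet=0.0, n_cycles=50)
    elif name == "polymer-influx":
        base.update(h=1.0, t_dry=400.0, b=5.0, mu_max=20.0, influx_phase="dry")
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return base


def _polymer_protocol(name: str, p: dict[str, Any]) -> CycleProtocol:
    influx = None
    if "b" in p and p.get("b") is not None:
        influx = InfluxSettings(b=p["b"], mu_max=p["mu_max"], phase=p.get("influx_phase", "dry"))
    return CycleProtocol(
        t_dry=p["t_dry"],
        t_wet=p.get("t_wet", 0.0),
        w=p.get("w", 0.0),
        n_cycles=int(p.get("n_cycles", 1)),
        scramble_every_step=bool(p.get("scramble_every_step", False)),
        influx=influx,
        h_dry=p.get("h", 0.0),
    )


def run_scenario(
    name: str,
    seed: int = 0,
    record_every: int = 50,
    **overrides: Any,
) -> ScenarioResult:
    """Run one named scenario and return its outputs with theory overlay.

    ``record_every`` is the sampling stride in steps for the stochastic
    scenarios.  Missing required parameters raise ``KeyError`` naming the
    field; unknown overrides raise ``ValueError``.
    """
    params = scenario_defaults(name)
    unknown = set(overrides) - set(params) - {
        "n_cycles", "t_wet", "w", "scramble_every_step", "influx_phase", "b", "mu_max"
    }
    if unknown:
        raise ValueError(f"unknown parameter(s) for scenario {name!r}: {sorted(unknown)}")
    params.update(overrides)

    if name == "dimer-cycling":
        return _run_dimer_cycling(params, seed)
    return _run_polymer(name, params, seed, record_every)


def _run_dimer_cycling(p: dict[str, Any], seed: int) -> ScenarioResult:
    dp = dm.DimerParams(phi=p["phi"], k_plus=p["k_plus"], k_minus=p["k_minus"])
    sched = dm.CycleSchedule(
        t_dry=p["t_dry"], t_wet=p["t_wet"], w=p["w"], n_cycles=int(p["n_cycles"])
    )
    traj = dm.dimer_cycling_trajectory(dp, sched)
    cyc = dm.iterate_cycles(dp.phi, dp.K, sched, mode="finite-t_dry",
                            k_plus=dp.k_plus, k_minus=dp.k_minus)
    pd_wet_lim, pd_dry_lim = dm.cycling_limit(dp.phi, dp.K, sched.w, sched.t_wet)
    eq = dm.equilibrium_diffusion(dp.phi, dp.K)
    overlay = {
        "PD_wet_limit": pd_wet_lim,
        "PD_dry_limit": pd_dry_lim,
        "PD_equilibrium_diffusion": eq.PD,
        "PD_local_equilibrium": dm.local_equilibrium_no_diffusion(dp.phi, dp.K),
        "per_cycle": cyc.cycles,
    }
    meta = {"scenario": "dimer-cycling", "seed": seed, "converged": cyc.converged,
            "n_cycles_run": cyc.n_cycles_run, **{k: p[k] for k in
            ("phi", "k_plus", "k_minus", "w", "t_dry", "t_wet", "n_cycles")}}
    empty = pd.DataFrame()
    return ScenarioResult("dimer-cycling", traj, empty, empty, overlay, meta)


def _run_polymer(
    name: str, p: dict[str, Any], seed: int, record_every: int
) -> ScenarioResult:
    proto = _polymer_protocol(name, p)
    cfg = ls.LatticeConfig(int(p["side"]))
    m_tot = int(round(p["mu"] * cfg.n_sites))
    sim = ls.SimParams(k_plus=p["k_plus"], k_minus=p["k_minus"],
                       h=proto.h_dry, dt=p["dt"], seed=seed)
    state = ls.init_random(cfg, m_tot, seed)
    if proto.influx is not None:
        state._ensure_capacity(int(proto.influx.mu_max * cfg.n_sites * 1.2) + m_tot)

    rows: list[tuple[float, str, float, int, int, int]] = []

    def record(phase: str) -> None:
        rows.append((state.time, phase, ls.measure_mean_length(state),
                     state.total_strands, state.total_monomers, state.clamp_count))

    record("dry")
    dry_steps = int(round(proto.t_dry / sim.dt))
    influx_dry = proto.influx if (proto.influx and proto.influx.phase == "dry") else None
    influx_wet = proto.influx if (proto.influx and proto.influx.phase == "wet") else None
    for _ in range(proto.n_cycles):
        for step_i in range(dry_steps):
            ls.dry_step(state, sim)
            if influx_dry is not None:
                ls.apply_influx(state, influx_dry.b, influx_dry.mu_max, sim.dt)
            if proto.scramble_every_step:
                ls.scramble(state)
            if (step_i + 1) % record_every == 0:
                record("dry")
        if proto.n_cycles > 1 or proto.t_wet > 0:
            influx = (influx_wet.b, influx_wet.mu_max) if influx_wet else None
            ls.wet_phase(state, proto.w, proto.t_wet, sim.dt, influx=influx)
            record("wet")

    ts = pd.DataFrame(rows, columns=[
        "time", "phase", "mean_length", "total_strands", "total_monomers", "clamp_count"
    ])
    dist = pd.DataFrame(ls.measure_length_distribution(state))
    occ_d = ls.site_occupancy_distribution(state)
    occ = pd.DataFrame(occ_d)

    mu_eq = proto.influx.mu_max if proto.influx else p["mu"]
    K = p["k_plus"] / p["k_minus"]
    sol = wp.equilibrium_solution(K, mu_eq)
    overlay: dict[str, Any] = {
        "equilibrium_mean_length": sol.mean_length,
        "equilibrium_x": sol.x,
        "equilibrium_lambda": sol.lambda_,
    }
    if proto.scramble_every_step or proto.h_dry > 0:
        wm = wp.integrate_ctot(
            wp.PolymerParams(p["k_plus"], p["k_minus"], p["mu"]),
            c0=p["mu"], t_end=max(proto.total_time, p["dt"]), log_spaced=True,
        )
        overlay["wellmixed_trajectory"] = wm
    meta = {
        "scenario": name, "seed": seed, "side": cfg.side, "m_tot": m_tot,
        "dt": p["dt"], "k_plus": p["k_plus"], "k_minus": p["k_minus"],
        "h": proto.h_dry, "mu": p["mu"], "record_every": record_every,
        "t_dry": proto.t_dry, "t_wet": proto.t_wet, "w": proto.w,
        "n_cycles": proto.n_cycles, "scramble_every_step": proto.scramble_every_step,
        "influx_b": proto.influx.b if proto.influx else None,
        "influx_mu_max": proto.influx.mu_max if proto.influx else None,
        "influx_phase": proto.influx.phase if proto.influx else None,
        "clamp_count": state.clamp_count,
    }
    return ScenarioResult(name, ts, dist, occ, overlay, meta)


def run_replicates(
    name: str, seeds: list[int] | np.ndarray, record_every: int = 50, **overrides: Any
) -> list[ScenarioResult]:
    """Run the same scenario over several seeds (for CI-based checks)."""
    return [run_scenario(name, seed=int(s), record_every=record_every, **overrides)
            for s in seeds]


def long_run_mean(timeseries: pd.DataFrame, frac: float = 0.25) -> float:
    """Mean of mean_length over the last ``frac`` of the recorded run."""
    t = timeseries["time"]
    cut = t.iloc[-1] - frac * (t.iloc[-1] - t.iloc[0])
    return float(timeseries.loc[t >= cut, "mean_length"].mean())
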