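"""Stochastic lattice simulator: event rules, conservation and distributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polysim import lattice_sim as ls


def chi_square_pvalue(observed: np.ndarray, expected: np.ndarray) -> float:
    """Pool bins with expected count < 5 into the last bin before testing."""
    keep = expected >= 5
    obs = np.append(observed[keep], observed[~keep].sum())
    exp = np.append(expected[keep], expected[~keep].sum())
    if exp[-1] == 0:
        obs, exp = obs[:-1], exp[:-1]
    exp = exp * obs.sum() / exp.sum()
    return stats.chisquare(obs, exp).pvalue


class TestInitRandom:
    def test_density_and_composition(self):
        cfg = ls.LatticeConfig(100)
        state = ls.init_random(cfg, 20000, seed=1)
        assert state.total_monomers == 20000
        assert state.mu == pytest.approx(2.0)
        assert np.all(state.lengths == 1)
        state.validate()

    def test_empty_lattice(self):
        state = ls.init_random(ls.LatticeConfig(5), 0, seed=1)
        assert state.total_strands == 0
        assert math.isnan(ls.measure_mean_length(state))

    def test_per_site_counts_poissonian(self):
        """Pooled over seeds, site occupancy matches Poisson(mu)."""
        cfg = ls.LatticeConfig(20)
        mu = 2.0
        pooled = np.zeros(30)
        for seed in range(20):
            state = ls.init_random(cfg, int(mu * cfg.n_sites), seed=seed)
            occ = ls.site_occupancy_distribution(state)["n_sites"]
            pooled[: occ.size] += occ
        n_sites_total = pooled.sum()
        expected = stats.poisson.pmf(np.arange(30), mu) * n_sites_total
        assert chi_square_pvalue(pooled, expected) > 0.01


class TestDryStep:
    def test_no_eligible_events_leaves_state_unchanged(self, build_state):
        state = build_state(5, [1, 1, 1], [0, 7, 13])
        params = ls.SimParams(k_plus=1.0, k_minus=0.0, h=0.0, dt=0.01)
        ls.dry_step(state, params)
        # singleton sites cannot form bonds; nothing else is enabled
        assert state.lengths.tolist() == [1, 1, 1]
        assert sorted(state.sites.tolist()) == [0, 7, 13]

    def test_pair_site_bond_frequency_matches_bernoulli(self, build_state):
        """A site holding two monomers forms a bond with probability 2 k+ dt."""
        n_sites_used, reps, dt = 400, 60, 0.01
        p = 2.0 * 1.0 * dt
        fired = 0
        for seed in range(reps):
            lengths = np.ones(2 * n_sites_used, dtype=np.int64)
            sites = np.repeat(np.arange(n_sites_used), 2)
            state = build_state(20, lengths, sites, seed=seed)
            ls.dry_step(state, ls.SimParams(k_plus=1.0, k_minus=0.0, h=0.0, dt=dt))
            fired += 2 * n_sites_used - state.total_strands
        trials = n_sites_used * reps
        se = math.sqrt(p * (1 - p) * trials)
        assert abs(fired - p * trials) < 3 * se

    def test_hydrolysis_break_point_uniform(self, build_state):
        """Break points of an 11-mer are uniform over its 10 bonds."""
        frag_counts = np.zeros(12)
        for seed in range(40):
            lengths = np.full(2000, 11, dtype=np.int64)
            sites = np.arange(2000) % 400
            state = build_state(20, lengths, sites, seed=seed)
            ls.dry_step(state, ls.SimParams(k_plus=0.0, k_minus=0.5, h=0.0, dt=0.02))
            kept = state.lengths[:2000]  # broken strands keep the left fragment in place
            left = kept[kept != 11]
            frag_counts[:] += np.bincount(left, minlength=12)[:12]
        observed = frag_counts[1:11]
        expected = np.full(10, observed.sum() / 10.0)
        assert chi_square_pvalue(observed, expected) > 0.01

    def test_hopping_disabled_freezes_positions(self, build_state):
        state = build_state(10, [3, 2, 5], [1, 1, 42])
        before = state.sites.copy()
        params = ls.SimParams(k_plus=0.0, k_minus=0.0, h=0.0, dt=0.01)
        for _ in range(50):
            ls.dry_step(state, params)
        assert np.array_equal(np.sort(state.sites), np.sort(before))

    def test_hop_moves_to_moore_neighbour(self, build_state):
        side = 9
        state = build_state(side, [1], [4 * side + 4])  # centre of the lattice
        params = ls.SimParams(k_plus=0.0, k_minus=0.0, h=150.0, dt=0.01)
        ls.dry_step(state, params)  # hop probability clamps to 1
        x, y = state.sites[0] % side, state.sites[0] // side
        assert max(abs(x - 4), abs(y - 4)) == 1
        assert state.clamp_count == 1

    def test_mass_conserved_with_all_processes(self):
        state = ls.init_random(ls.LatticeConfig(10), 300, seed=3)
        params = ls.SimParams(k_plus=1.0, k_minus=0.1, h=1.0, dt=0.01)
        for _ in range(200):
            ls.dry_step(state, params)
            assert state.total_monomers == 300
        state.validate()

    def test_determinism_same_seed(self):
        params = ls.SimParams(k_plus=1.0, k_minus=0.05, h=1.0, dt=0.01)
        runs = []
        for _ in range(2):
            state = ls.init_random(ls.LatticeConfig(10), 200, seed=11)
            ls.run_dry(state, params, 100)
            runs.append((state.lengths.copy(), state.sites.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])


class TestScramble:
    def test_length_multiset_exactly_preserved(self, build_state):
        state = build_state(10, [4, 1, 1, 7], [0, 0, 5, 99])
        before = sorted(state.lengths.tolist())
        ls.scramble(state)
        assert sorted(state.lengths.tolist()) == before

    def test_destination_uniform(self, build_state):
        counts = np.zeros(16)
        for seed in range(4000):
            state = build_state(4, [1], [0], seed=seed)
            ls.scramble(state)
            counts[state.sites[0]] += 1
        expected = np.full(16, 4000 / 16.0)
        assert chi_square_pvalue(counts, expected) > 0.01

    def test_empty_state(self):
        state = ls.init_random(ls.LatticeConfig(4), 0, seed=0)
        ls.scramble(state)
        assert state.total_strands == 0


class TestWetPhase:
    def test_zero_duration_only_scrambles(self, build_state):
        state = build_state(10, [5, 5, 2], [3, 3, 3], seed=7)
        ls.wet_phase(state, w=2.0, t_wet=0.0, dt=0.01)
        assert sorted(state.lengths.tolist()) == [2, 5, 5]

    def test_long_hydrolysis_reduces_to_monomers(self, build_state):
        lengths = np.full(50, 11, dtype=np.int64)
        state = build_state(10, lengths, np.arange(50), seed=2)
        ls.wet_phase(state, w=1.0, t_wet=50.0, dt=0.01)
        assert ls.measure_mean_length(state) < 1.1

    def test_bond_survival_exponential(self, build_state):
        """Ensemble bond survival after the phase tracks exp(-w t_wet)."""
        w, t_wet, dt = 1.0, 0.5, 0.001
        survived, total = 0, 0
        for seed in range(10):
            lengths = np.full(1000, 11, dtype=np.int64)
            state = build_state(40, lengths, np.arange(1000), seed=seed)
            ls.wet_phase(state, w=w, t_wet=t_wet, dt=dt)
            survived += state.total_monomers - state.total_strands
            total += 10 * 1000
        p = math.exp(-w * t_wet)
        se = math.sqrt(p * (1 - p) * total)
        assert abs(survived - p * total) < 3 * se


class TestInflux:
    def test_no_addition_at_ceiling(self, build_state):
        state = build_state(5, np.ones(50, dtype=np.int64), np.zeros(50), seed=0)
        ls.apply_influx(state, b=5.0, mu_max=2.0, dt=0.01)  # mu = 2 = mu_max
        assert state.total_monomers == 50

    def test_mean_addition_rate(self):
        """From an empty lattice the mean additions per step is N b dt."""
        cfg = ls.LatticeConfig(100)
        added = []
        for seed in range(50):
            state = ls.init_random(cfg, 0, seed=seed)
            ls.apply_influx(state, b=5.0, mu_max=20.0, dt=0.01)
            added.append(state.total_monomers)
        mean = 10000 * 5.0 * 0.01
        se = math.sqrt(mean / 50)  # Poisson variance = mean
        assert abs(np.mean(added) - mean) < 3 * se

    def test_influx_only_trajectory_matches_logistic_relaxation(self):
        """mu(t) solves dmu/dt = b (1 - mu/mu_max) when nothing reacts."""
        cfg = ls.LatticeConfig(30)
        b, mu_max, dt, t_end = 5.0, 20.0, 0.01, 20.0
        times = np.arange(0.0, t_end, 1.0)
        trajs = []
        for seed in range(5):
            state = ls.init_random(cfg, int(2.0 * cfg.n_sites), seed=seed)
            mus = []
            for step in range(int(t_end / dt)):
                if step % 100 == 0:
                    mus.append(state.mu)
                ls.apply_influx(state, b, mu_max, dt)
            trajs.append(mus)
        mean_mu = np.mean(trajs, axis=0)
        theory = mu_max + (2.0 - mu_max) * np.exp(-b * times / mu_max)
        se = np.std(trajs, axis=0, ddof=1) / math.sqrt(5)
        assert np.all(np.abs(mean_mu - theory) < 3 * se + 0.05)


class TestMeasurements:
    def test_mean_length_direct_count(self, build_state):
        state = build_state(10, [10] + [1] * 10, np.arange(11))
        assert ls.measure_mean_length(state) == pytest.approx(20.0 / 11.0)

    def test_length_histogram_and_mass_identity(self, build_state):
        state = build_state(10, [2, 2, 2, 2, 2], np.arange(5))
        dist = ls.measure_length_distribution(state)
        assert dist["count"].tolist() == [0, 5]
        assert int((dist["length"] * dist["count"]).sum()) == state.total_monomers

    def test_occupancy_strand_identity(self):
        state = ls.init_random(ls.LatticeConfig(15), 500, seed=4)
        occ = ls.site_occupancy_distribution(state)
        assert int((occ["n_strands"] * occ["n_sites"]).sum()) == state.total_strands
        assert int(occ["n_sites"].sum()) == state.config.n_sites

    def test_occupancy_poisson_after_scramble(self):
        """Scrambling S strands gives Poisson(S/N) site occupancy (pooled)."""
        cfg = ls.LatticeConfig(20)
        pooled = np.zeros(20)
        s_count = 300
        for seed in range(30):
            state = ls.init_random(cfg, s_count, seed=seed)
            ls.scramble(state)
            occ = ls.site_occupancy_distribution(state)["n_sites"]
            pooled[: occ.size] += occ
        lam = s_count / cfg.n_sites
        expected = stats.poisson.pmf(np.arange(20), lam) * pooled.sum()
        assert chi_square_pvalue(pooled, expected) > 0.01


@given(seed=st.integers(0, 2**20), n_steps=st.integers(1, 30))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_mass_invariant_under_arbitrary_dynamics(seed, n_steps):
    """Total monomer count is exactly conserved by dry, wet and scramble ops."""
    state = ls.init_random(ls.LatticeConfig(8), 150, seed=seed)
    params = ls.SimParams(k_plus=2.0, k_minus=0.5, h=2.0, dt=0.05)
    rng = np.random.default_rng(seed + 1)
    for _ in range(n_steps):
        op = rng.integers(0, 3)
        if op == 0:
            ls.dry_step(state, params)
        elif op == 1:
            ls.wet_phase(state, w=1.0, t_wet=0.1, dt=0.05)
        else:
            ls.scramble(state)
        assert state.total_monomers == 150
        state.validate()
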