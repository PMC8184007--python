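"""Monte Carlo engine: initial conditions, the two-phase growth pmf,
single-iteration semantics, termination, and population summaries."""

import numpy as np
import pytest
from scipy.stats import chisquare

from polkadots.simulate import (
    InitDistributions,
    SimCell,
    SimParams,
    growth_pmf,
    run_cell,
    run_population,
    sample_initial_conditions,
    sample_population,
    step,
)


class TestInitialConditions:
    def test_fixed_seed_identical(self):
        d = InitDistributions()
        a = sample_initial_conditions(d, seed=42)
        b = sample_initial_conditions(d, seed=42)
        assert (a.n_sites, a.synapse_fraction, a.n_autophagosomes,
                a.initial_monomers) == \
            (b.n_sites, b.synapse_fraction, b.n_autophagosomes,
             b.initial_monomers)

    def test_sample_moments_match_distributions(self):
        d = InitDistributions()
        rng = np.random.default_rng(7)
        n = 100_000
        cells = [sample_initial_conditions(d, seed=rng) for _ in range(n)]
        sites = np.array([c.n_sites for c in cells], dtype=float)
        mono = np.array([c.initial_monomers for c in cells], dtype=float)
        # gamma(1.59, 15.92): mean alpha*beta, var alpha*beta^2
        mu_s = d.sites_alpha * d.sites_beta
        se_s = np.sqrt(d.sites_alpha * d.sites_beta**2 / n)
        assert abs(sites.mean() - mu_s) < 3 * se_s + 0.5  # +0.5 for rounding
        se_m = d.monomers_sigma / np.sqrt(n)
        assert abs(mono.mean() - d.monomers_mu) < 3 * se_m + 0.5

    def test_negative_draws_truncated(self):
        d = InitDistributions(monomers_mu=0.0, monomers_sigma=1.0)
        rng = np.random.default_rng(0)
        cells = [sample_initial_conditions(d, seed=rng) for _ in range(200)]
        assert all(c.initial_monomers >= 0 for c in cells)


class TestGrowthPmf:
    def test_prebarrier_reduces_to_binomial(self):
        # below the barrier the pmf is Binomial(n, p_attach)
        assert growth_pmf(10, 3, 50, 0.3, 0.8) == pytest.approx(0.2668, abs=5e-5)

    def test_beyond_iterations_zero(self):
        assert growth_pmf(10, 11, 5, 0.3, 0.8) == 0.0

    @pytest.mark.parametrize("n", [1, 5, 20, 80, 200])
    def test_normalized_up_to_n_200(self, n):
        x = np.arange(n + 1)
        total = growth_pmf(n, x, 5, 0.3, 0.8).sum()
        assert abs(total - 1.0) < 1e-9

    def test_matches_brute_force_two_phase_process(self):
        # oracle: direct simulation of the two-phase Bernoulli growth
        n, L0, pa, pg = 20, 5, 0.3, 0.8
        reps = 1_000_000
        rng = np.random.default_rng(123)
        u = rng.random((reps, n))
        lengths = np.zeros(reps, dtype=np.int64)
        for t in range(n):
            p = np.where(lengths < L0, pa, pg)
            lengths += u[:, t] < p
        counts = np.bincount(lengths, minlength=n + 1)
        x = np.arange(n + 1)
        pmf = growth_pmf(n, x, L0, pa, pg)
        se = np.sqrt(np.maximum(pmf * (1 - pmf) / reps, 1e-300))
        assert np.all(np.abs(counts / reps - pmf) <= 3 * se + 1e-9)

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError):
            growth_pmf(10, 3, 5, 1.3, 0.5)


def _small_cell(n_sites=5, n_auto=0, monomers=2000, synapse=0.4):
    return SimCell(n_sites=n_sites, synapse_fraction=synapse,
                   n_autophagosomes=n_auto, initial_monomers=monomers)


class TestStep:
    def test_no_activation_means_no_growth(self):
        cell = _small_cell()
        params = SimParams(p_activate=0.0)
        for t in range(200):
            step(cell, params, rng_seed=t)
        assert cell.free_monomers == cell.initial_monomers
        assert cell.filamentous_monomers == 0

    def test_no_degradation_never_shortens(self):
        cell = _small_cell(n_auto=10, monomers=5000)
        params = SimParams(p_activate=1.0, p_degrade=0.0)
        prev = 0
        for t in range(300):
            step(cell, params, rng_seed=t)
            fil = cell.filamentous_monomers
            assert fil >= prev
            prev = fil
        assert cell.degraded_monomers == 0

    def test_ledger_exact_every_iteration(self):
        cell = _small_cell(n_sites=8, n_auto=12, monomers=3000)
        params = SimParams(p_activate=0.8, p_attach=0.2, p_degrade=0.3)
        for t in range(500):
            step(cell, params, rng_seed=t)
            cell.check_ledger()  # raises on violation


class TestRunCell:
    def test_growth_only_terminates_at_zero_monomers(self):
        cell = _small_cell(monomers=1000)
        trace = run_cell(cell, SimParams(), seed=1, growth_only=True,
                         record=False, max_iter=200_000)
        assert cell.free_monomers == 0
        assert trace.terminated_early

    def test_forced_decay_exhausts_pool_before_cap(self):
        cell = _small_cell(n_sites=3, n_auto=30, monomers=300)
        params = SimParams(p_activate=1.0, p_degrade=1.0,
                           p_collide_auto=1.0, p_attach_auto=1.0)
        trace = run_cell(cell, params, seed=3)
        assert trace.terminated_early
        assert trace.n_iter < params.max_iter
        assert cell.free_monomers + cell.filamentous_monomers == 0

    def test_max_iter_reached_trace_length(self):
        cell = _small_cell(n_sites=2, monomers=10**6)
        params = SimParams(max_iter=50)
        trace = run_cell(cell, params, seed=5)
        assert trace.n_iter == 50
        assert len(trace.filamentous) == 51

    def test_deterministic_in_seed(self):
        p = SimParams(p_degrade=0.1)
        traces = []
        for _ in range(2):
            cell = _small_cell(n_sites=6, n_auto=8, monomers=2000)
            traces.append(run_cell(cell, p, seed=9))
        np.testing.assert_array_equal(traces[0].filamentous,
                                      traces[1].filamentous)

    def test_conservation_along_trace(self):
        cell = _small_cell(n_sites=6, n_auto=8, monomers=2000)
        trace = run_cell(cell, SimParams(p_degrade=0.2), seed=4)
        total = trace.free + trace.filamentous + trace.degraded
        assert (total == cell.initial_monomers).all()


class TestEngineMatchesPmf:
    def test_single_site_nondepleting_pool_matches_growth_pmf(self):
        # engine vs analytic two-phase pmf: one site, effectively infinite
        # monomers, unit collision and activation probabilities
        n, L0, pa, pg = 30, 5, 0.3, 0.4
        params = SimParams(
            p_activate=1.0, p_collide_carma=1.0, p_attach=pa, p_grow=pg,
            n_barrier=L0, max_iter=n, collision_model="monomer_scaled",
            activation_model="per_site")
        lengths = []
        for rep in range(3000):
            cell = SimCell(n_sites=1, synapse_fraction=1.0,
                           n_autophagosomes=0, initial_monomers=10**7)
            run_cell(cell, params, seed=rep, record=False, max_iter=n)
            lengths.append(int(cell.fil_len[cell.fil_alive].sum()))
        counts = np.bincount(lengths, minlength=n + 1)
        pmf = growth_pmf(n, np.arange(n + 1), L0, pa, pg)
        # merge sparse bins for the chi-square
        keep = pmf * len(lengths) >= 5
        obs = np.r_[counts[keep], counts[~keep].sum()]
        exp = np.r_[pmf[keep], pmf[~keep].sum()] * len(lengths)
        _, p = chisquare(obs, exp)
        assert p > 0.01


class TestRunPopulation:
    def test_undefined_rho_sentinel_when_no_puncta(self):
        params = SimParams(p_activate=0.0, max_iter=50)
        res = run_population(params, n_cells=4, n_trials=1, seed=0,
                             growth_only=False)
        assert np.isnan(res.rho_end)

    def test_n_half_after_n_max(self):
        params = SimParams(p_activate=0.5, p_attach=0.1, p_degrade=0.2,
                           max_iter=3000)
        res = run_population(params, n_cells=6, n_trials=2, seed=3,
                             growth_only=False)
        ok = np.isfinite(res.n_half) & np.isfinite(res.n_max)
        assert ok.any()
        assert (res.n_half[ok] > res.n_max[ok]).all()

    def test_higher_degradation_not_higher_peak(self):
        dists = InitDistributions()
        cells = sample_population(dists, 10, seed=21)
        peaks = []
        for pd in (0.05, 0.3):
            params = SimParams(p_activate=0.5, p_attach=0.1, p_degrade=pd,
                               max_iter=4000)
            res = run_population(params, dists, n_cells=10, n_trials=2,
                                 seed=21, cells=cells)
            peaks.append(res.peak_concentration)
        assert peaks[1] <= peaks[0]

    def test_same_cells_reused_across_configs(self):
        dists = InitDistributions()
        cells = sample_population(dists, 5, seed=8)
        r1 = run_population(SimParams(p_degrade=0.05, max_iter=200), dists,
                            n_cells=5, n_trials=1, seed=8, cells=cells)
        r2 = run_population(SimParams(p_degrade=0.20, max_iter=200), dists,
                            n_cells=5, n_trials=1, seed=8, cells=cells)
        np.testing.assert_array_equal(r1.n_sites, r2.n_sites)
        np.testing.assert_array_equal(r1.n_autophagosomes, r2.n_autophagosomes)
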