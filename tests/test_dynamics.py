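"""Monte Carlo engine: update semantics, determinism, and rate oracles."""

import numpy as np
import pytest
from numba import njit
from scipy import stats

from epifate import _kernels
from epifate.dynamics import (
    ModelConfig,
    micro_update,
    monte_carlo_step,
    run_simulation,
    run_to_absorption,
    single_site_rates,
)
from epifate.interactions import InteractionSpec, fate_probability_A
from epifate.lattice import make_grid, pair_neighbor_field
from epifate.observables import order_parameter


def config(variant="R", form="logistic", J=0.0, q=0.5, L=8, mcs=10, seed=0):
    if variant == "C":
        q = 1.0
    return ModelConfig(
        variant=variant,
        interaction=InteractionSpec(form, J),
        L=L,
        runtime_mcs=mcs,
        seed=seed,
        q=q,
    )


@njit(cache=False)
def _tagged_plus_fraction(base, q, variant, form, J, trials, rng, sk, sl):
    """Fraction of single random updates (from a frozen grid) leaving
    the tagged site at +1."""
    hits = 0
    for _ in range(trials):
        cells = base.copy()
        _kernels.micro_update(cells, q, variant, form, J, rng, -1, -1)
        if cells[sk, sl] == 1:
            hits += 1
    return hits / trials


@njit(cache=False)
def _forced_pair_aa_fraction(base, q, variant, form, J, trials, rng, fi, fdir):
    hits = 0
    L = base.shape[0]
    for _ in range(trials):
        cells = base.copy()
        code, _, _ = _kernels.micro_update(cells, q, variant, form, J, rng, fi, fdir)
        if code == _kernels.DIVISION_AA:
            hits += 1
    return hits / trials


class TestModelConfig:
    def test_variant_c_forces_q_one(self):
        with pytest.raises(ValueError, match="q = 1"):
            ModelConfig("C", InteractionSpec("logistic", 0.0), 8, 10, 0, q=0.5)

    def test_invalid_parameters_rejected(self):
        spec = InteractionSpec("logistic", 0.0)
        with pytest.raises(ValueError, match="variant"):
            ModelConfig("X", spec, 8, 10, 0)
        with pytest.raises(ValueError, match="even"):
            ModelConfig("R", spec, 7, 10, 0, q=0.5)
        with pytest.raises(ValueError, match="q"):
            ModelConfig("R", spec, 8, 10, 0, q=1.5)


class TestMicroUpdate:
    def test_uniform_grid_is_absorbing_for_variant_c(self, rng):
        grid = make_grid(6, "all_A")
        cfg = config(variant="C", L=6)
        tags = {micro_update(grid, cfg, rng) for _ in range(500)}
        assert tags == {"division_blocked"}
        assert (grid == 1).all()

    def test_saturated_induction_forces_division_aa(self, rng):
        cfg = config(variant="C", form="logistic", J=50.0, L=6)
        for _ in range(200):
            grid = make_grid(6, "all_A")
            grid[2, 2] = -1  # lone B; pair field of ((2,1),(2,2)) is +6
            tag = micro_update(grid, cfg, rng, i=(2, 2), j_direction=2)
            assert tag == "division_AA"
            assert grid[2, 2] == 1 and grid[2, 1] == 1

    def test_division_outcome_follows_six_site_pair_field(self, rng):
        """The division fate probability uses the pair's 6 exterior
        neighbours, not just the 4 neighbours of the primary site."""
        grid = make_grid(6, "all_B")
        grid[1, 1] = 1  # A at i; j = (1, 2) stays B
        for site in ((0, 1), (2, 1), (1, 0), (0, 2), (2, 2), (1, 3)):
            grid[site] = 1  # all 6 exterior neighbours A
        n6 = pair_neighbor_field(grid, (1, 1), (1, 2))
        assert n6 == 6
        spec = InteractionSpec("hill", 0.5)
        trials = 10**4
        frac = _forced_pair_aa_fraction(
            grid, 1.0, _kernels.VARIANT_C, _kernels.FORM_HILL, 0.5, trials, rng, 7, 3
        )
        p6 = fate_probability_A(spec, 6)  # 0.875
        p4 = fate_probability_A(spec, 2)  # 0.75, the 4-neighbour value at i
        se = np.sqrt(p6 * (1 - p6) / trials)
        assert abs(frac - p6) < 3 * se
        assert abs(frac - p4) > 10 * se

    @pytest.mark.parametrize(
        "variant,form,q,J,n4",
        [
            ("R", "logistic", 0.5, 0.0, 0),
            ("R", "logistic", 0.3, 0.7, 2),
            ("R", "hill", 0.0, -0.5, -2),
            ("R", "logistic", 1.0, 0.0, 4),
            ("C", "logistic", 1.0, 0.0, 2),
        ],
    )
    def test_update_frequency_matches_analytic_rate(self, rng, variant, form, q, J, n4):
        """N times the per-update probability that a frozen B site ends up
        +1 equals the analytic per-site rate gamma_A(n)."""
        L = 4
        grid = make_grid(L, "all_B")
        n_a = (n4 + 4) // 2
        neighbours = [(0, 1), (2, 1), (1, 0), (1, 2)]
        for site in neighbours[:n_a]:
            grid[site] = 1
        cfg = config(variant=variant, form=form, J=J, q=q, L=L)
        gamma_a, _ = single_site_rates(n4, cfg)
        trials = 10**5
        frac = _tagged_plus_fraction(
            grid,
            cfg.q,
            _kernels.VARIANT_C if variant == "C" else _kernels.VARIANT_R,
            _kernels.FORM_HILL if form == "hill" else _kernels.FORM_LOGISTIC,
            J,
            trials,
            rng,
            1,
            1,
        )
        expected = gamma_a / (L * L)
        se = np.sqrt(max(expected * (1 - expected), 1e-12) / trials)
        assert abs(frac - expected) < 3 * se


class TestSingleSiteRates:
    def test_balanced_neighbourhood_gives_half_half(self):
        for q in (0.0, 0.3, 1.0):
            cfg = config(variant="R", q=q)
            assert single_site_rates(0, cfg) == pytest.approx((0.5, 0.5))

    @pytest.mark.parametrize("q", [0.0, 0.25, 0.8, 1.0])
    @pytest.mark.parametrize("n4", [-4, -2, 0, 2, 4])
    def test_variant_r_rates_sum_to_total_rate(self, q, n4):
        gamma_a, gamma_b = single_site_rates(n4, config(variant="R", q=q, J=0.6))
        assert gamma_a + gamma_b == pytest.approx(1.0)

    def test_variant_c_neutral_fully_aligned(self):
        gamma_a, gamma_b = single_site_rates(4, config(variant="C", J=0.0))
        assert (gamma_a, gamma_b) == pytest.approx((1.0, 0.0))

    @pytest.mark.parametrize("n4", [1, 3, -5, 6])
    def test_invalid_field_rejected(self, n4):
        with pytest.raises(ValueError, match="n4"):
            single_site_rates(n4, config())


class TestTrajectories:
    def test_monte_carlo_step_is_L_squared_micro_updates(self):
        for variant, form, J, q in [("R", "hill", -0.5, 0.3), ("C", "logistic", 0.8, 1.0)]:
            cfg = config(variant=variant, form=form, J=J, q=q, L=8)
            g1 = make_grid(8, "random", seed=5)
            g2 = g1.copy()
            r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
            for _ in range(64):
                micro_update(g1, cfg, r1)
            monte_carlo_step(g2, cfg, r2)
            assert (g1 == g2).all()

    def test_same_seed_reproduces_trajectory(self):
        cfg = config(variant="R", J=0.4, q=0.6, L=10, mcs=30, seed=42)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert (a.grid == b.grid).all()
        assert a.elapsed_mcs == b.elapsed_mcs == 30

    def test_neighbouring_seeds_decorrelate(self):
        base = dict(variant="R", J=0.4, q=0.6, L=10, mcs=30)
        a = run_simulation(config(seed=1, **base))
        b = run_simulation(config(seed=2, **base))
        assert not (a.grid == b.grid).all()

    def test_zero_runtime_returns_initial_random_grid(self):
        cfg = config(variant="C", L=4, mcs=0, seed=9)
        result = run_simulation(cfg)
        rng = np.random.default_rng(9)
        expected = (2 * rng.integers(0, 2, size=(4, 4)) - 1).astype(np.int8)
        assert (result.grid == expected).all()
        assert result.elapsed_mcs == 0 and not result.absorbed

    def test_uniform_grid_fixed_under_variant_c(self):
        cfg = config(variant="C", J=0.3, L=4, mcs=50)
        result = run_simulation(cfg, initial=make_grid(4, "all_A"))
        assert (result.grid == 1).all()

    def test_early_exit_rejected_for_reversible_dynamics(self):
        with pytest.raises(ValueError, match="early_exit"):
            run_simulation(config(variant="R", q=0.5, mcs=5), early_exit=True)

    def test_voter_runs_absorb_to_full_order(self):
        for seed in range(5):
            cfg = config(variant="C", J=0.0, L=10, seed=seed)
            result = run_to_absorption(cfg, max_mcs=10**6)
            assert result.absorbed
            assert order_parameter(result.grid) == 1.0

    def test_time_series_sampling(self):
        cfg = config(variant="R", J=0.2, q=0.2, L=8, mcs=20, seed=3)
        result = run_simulation(cfg, sample_stride=5)
        times = [t for t, _, _ in result.time_series]
        assert times == [0, 5, 10, 15, 20]
        assert result.time_series[-1][1] == order_parameter(result.grid)

    def test_phi_distribution_invariant_under_global_flip(self):
        """A<->B exchange symmetry: starting ensembles from g and -g give
        statistically indistinguishable order parameters."""
        initial = make_grid(10, "random", seed=77)
        phis, phis_flipped = [], []
        for r in range(80):
            cfg = config(variant="R", form="hill", J=0.4, q=0.3, L=10, mcs=40, seed=1000 + r)
            phis.append(order_parameter(run_simulation(cfg, initial=initial).grid))
            phis_flipped.append(
                order_parameter(run_simulation(cfg, initial=-initial).grid)
            )
        m1, m2 = np.mean(phis), np.mean(phis_flipped)
        pooled = np.sqrt(
            np.var(phis, ddof=1) / 80 + np.var(phis_flipped, ddof=1) / 80
        )
        assert abs(m1 - m2) < 3 * pooled

    def test_reversible_neutral_limit_is_iid_coin_flips(self):
        """Variant R with q=0, J=0 redraws every site i.i.d.; the mean order
        parameter matches the exact binomial closed form."""
        L, reps = 20, 200
        N = L * L
        k = np.arange(N + 1)
        exact = float(np.sum(np.abs(2 * k - N) * stats.binom.pmf(k, N, 0.5))) / N
        phis = []
        for r in range(reps):
            cfg = config(variant="R", J=0.0, q=0.0, L=L, mcs=20, seed=5000 + r)
            phis.append(order_parameter(run_simulation(cfg).grid))
        sem = np.std(phis, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(phis) - exact) < 3 * sem
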