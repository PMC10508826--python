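import numpy as np
import pytest

from spibmetad import (BiasPotential, FrozenBiasError, IdentityOP,
                       LangevinConfig, MetadConfig, StopCondition, ToyEngine,
                       deposit, evaluate_bias, freeze, make_potential,
                       run_baoab, run_biased_walker, run_shared_bias_walkers,
                       static_bias_transfer)
from spibmetad.structure_cv import DunbrackState


def _random_bias(rng, n, dim=2):
    bias = BiasPotential(dim=dim)
    for k in range(n):
        bias.append(rng.normal(size=dim), rng.uniform(0.05, 0.5, size=dim),
                    rng.uniform(0, 1.5), k)
    return bias


class TestEvaluate:
    def test_empty_bias_is_zero(self):
        bias = BiasPotential(dim=2)
        assert evaluate_bias(bias, np.array([0.3, -1.0])) == 0.0

    def test_center_value_equals_height(self):
        bias = BiasPotential(dim=2)
        bias.append([1.0, 2.0], [0.2, 0.3], 0.8, 0)
        assert evaluate_bias(bias, np.array([1.0, 2.0])) == pytest.approx(0.8)

    def test_matches_brute_force_double_loop(self):
        """1000 kernels at random query points vs an independent
        double-loop summation oracle."""
        rng = np.random.default_rng(0)
        bias = _random_bias(rng, 1000)
        pts = rng.normal(size=(50, 2))
        kernels = bias.kernels
        for p in pts:
            expected = 0.0
            for k in kernels:
                expo = sum((p[d] - k.center[d])**2 / (2 * k.widths[d]**2)
                           for d in range(2))
                expected += k.height * np.exp(-expo)
            assert evaluate_bias(bias, p) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_total_height_and_nonnegative(self):
        rng = np.random.default_rng(1)
        bias = _random_bias(rng, 200)
        v = bias.value(rng.normal(size=(500, 2)))
        assert np.all(v >= 0)
        assert np.all(v <= bias.total_height)

    def test_grid_cache_matches_exact(self):
        rng = np.random.default_rng(2)
        exact = _random_bias(rng, 300)
        cached = BiasPotential(dim=2)
        cached.enable_grid([-5, -5], [5, 5], spacing=0.015)
        for k in exact.kernels:
            cached.append(k.center, k.widths, k.height, k.deposit_time)
        pts = rng.uniform(-4, 4, size=(200, 2))
        v_exact, g_exact = exact._exact_value_and_grad(pts)
        v_grid, g_grid = cached.value_and_grad_many(pts)
        assert np.max(np.abs(v_exact - v_grid)) < 1e-2
        # gradients are steep where kernels are narrow; a few % relative
        assert np.all(np.abs(g_exact - g_grid) <= 0.01 + 0.03 * np.abs(g_exact))


class TestDeposit:
    def test_first_deposit_has_initial_height(self):
        bias = BiasPotential(dim=1)
        cfg = MetadConfig(w0=1.2, widths=(0.1,), bias_factor=10.0, kbt=1.0)
        k = deposit(bias, [0.0], cfg)
        assert k.height == pytest.approx(1.2)

    def test_second_deposit_well_tempered_scaling(self):
        bias = BiasPotential(dim=1)
        cfg = MetadConfig(w0=1.2, widths=(0.1,), bias_factor=10.0, kbt=1.0)
        deposit(bias, [0.0], cfg)
        k2 = deposit(bias, [0.0], cfg)
        assert k2.height == pytest.approx(1.2 * np.exp(-1.2 / 9.0))

    def test_repeated_deposits_decay_like_well_tempered_recursion(self):
        """Heights at a single point strictly decrease and the accumulated
        bias follows the closed-form well-tempered recursion
        V_{n+1} = V_n + w0 exp(−V_n/(γ−1)), whose late growth is the slow
        logarithmic (γ−1)·ln(n) law."""
        bias = BiasPotential(dim=1)
        cfg = MetadConfig(w0=1.0, widths=(0.1,), bias_factor=5.0, kbt=1.0)
        heights = [deposit(bias, [0.0], cfg).height for _ in range(200)]
        assert all(b < a for a, b in zip(heights, heights[1:]))
        assert heights[-1] < 0.02 * heights[0]
        v_ref = 0.0
        for h in heights:
            assert h == pytest.approx(1.0 * np.exp(-v_ref / 4.0), rel=1e-12)
            v_ref += h
        # doubling the deposit count adds ~ (γ−1) ln 2 once decayed
        growth = sum(heights) - sum(heights[:100])
        assert growth == pytest.approx(4.0 * np.log(2), rel=0.1)

    def test_deposit_on_frozen_bias_errors(self):
        bias = BiasPotential(dim=1)
        cfg = MetadConfig(widths=(0.1,))
        deposit(bias, [0.0], cfg)
        freeze(bias)
        with pytest.raises(FrozenBiasError, match="frozen-bias"):
            deposit(bias, [0.5], cfg)


class TestFreezeSerialize:
    def test_freeze_empty_is_static_zero(self):
        bias = freeze(BiasPotential(dim=2))
        assert bias.frozen and evaluate_bias(bias, np.zeros(2)) == 0.0

    def test_hills_round_trip_evaluates_identically(self, tmp_path):
        rng = np.random.default_rng(3)
        bias = freeze(_random_bias(rng, 150))
        bias.to_hills(tmp_path / "HILLS")
        loaded = BiasPotential.from_hills(tmp_path / "HILLS")
        assert loaded.frozen
        pts = rng.normal(size=(100, 2))
        np.testing.assert_allclose(loaded.value(pts), bias.value(pts),
                                   atol=1e-9)


class TestStopCondition:
    def test_hand_built_sequence(self):
        stop = StopCondition(target_state="B", stability_window=3)
        assert stop.first_hit(["A", "A", "B", "B", "B"]) == 4

    def test_interrupted_run_resets(self):
        stop = StopCondition(target_state="B", stability_window=3)
        assert stop.first_hit(["B", "B", "A", "B", "B", "B"]) == 5

    def test_set_target(self):
        stop = StopCondition(target_state=frozenset({"A", "B"}),
                             stability_window=2)
        assert stop.first_hit(["C", "A", "B"]) == 2


class TestWalkers:
    @pytest.fixture(scope="class")
    def barrier8(self):
        return make_potential("double_well_1d", barrier=8.0)

    def test_bias_enables_transition_unbiased_does_not(self, barrier8):
        """At desk length an 8 kBT barrier is never crossed unbiased, but a
        well-tempered walker escapes within the cap."""
        lang = LangevinConfig(dt=0.02, friction=2.0, kbt=1.0, n_steps=5000,
                              seed=10)
        unbiased = run_baoab(barrier8, lang, x0=[-1.0], record_every=5)
        assert np.all(unbiased["positions"][:, 0] < 0)

        op = IdentityOP(1)
        eng = ToyEngine(barrier8, LangevinConfig(dt=0.02, friction=2.0,
                                                 kbt=1.0, n_steps=0, seed=0),
                        np.array([-1.0]), op)
        bias = BiasPotential(dim=1)
        cfg = MetadConfig(w0=1.2, widths=(0.1,), pace=100, bias_factor=10.0,
                          kbt=1.0, max_steps=50000)
        stop = StopCondition(target_state=DunbrackState.OUT,
                             stability_window=200)
        res = run_biased_walker(eng, bias, cfg, stop, record_every=5, seed=10)
        assert res.converged and res.stopped_at is not None

    def test_unconverged_flag_without_exception(self, barrier8):
        op = IdentityOP(1)
        eng = ToyEngine(barrier8, LangevinConfig(dt=0.02, friction=2.0,
                                                 kbt=1.0, n_steps=0, seed=0),
                        np.array([-1.0]), op)
        static_zero = freeze(BiasPotential(dim=1))
        stop = StopCondition(target_state=DunbrackState.OUT,
                             stability_window=100)
        res = static_bias_transfer(static_zero, [eng],
                                   MetadConfig(widths=(0.1,), max_steps=3000),
                                   [stop], seed=4)[0]
        assert not res.converged and res.stopped_at is None

    def test_two_walkers_fill_well_faster_than_one(self, barrier8):
        """Shared bias: with two walkers depositing jointly, the first
        escape from the starting well happens in fewer integrator steps
        (median over 10 seeds)."""
        op = IdentityOP(1)
        lang = LangevinConfig(dt=0.02, friction=2.0, kbt=1.0, n_steps=0,
                              seed=0)
        cfg = MetadConfig(w0=1.2, widths=(0.1,), pace=100, bias_factor=10.0,
                          kbt=1.0, max_steps=60000)

        def steps_to_first_escape(n_walkers, seed):
            engines = [ToyEngine(barrier8, lang, np.array([-1.0]), op)
                       for _ in range(n_walkers)]
            bias = BiasPotential(dim=1)
            stops = [StopCondition(DunbrackState.OUT, 100)
                     for _ in range(n_walkers)]
            res = run_shared_bias_walkers(engines, bias, cfg, stops,
                                          record_every=50, seed=seed)
            hits = [r.stopped_at for r in res if r.stopped_at is not None]
            return min(hits) if hits else cfg.max_steps

        singles = [steps_to_first_escape(1, s) for s in range(10)]
        pairs = [steps_to_first_escape(2, s) for s in range(10)]
        assert np.median(pairs) < np.median(singles)

    def test_shared_mode_single_walker_bit_identical(self, barrier8):
        op = IdentityOP(1)
        lang = LangevinConfig(dt=0.02, friction=1.0, kbt=1.0, n_steps=0,
                              seed=0)
        cfg = MetadConfig(w0=1.0, widths=(0.1,), pace=100, bias_factor=8.0,
                          kbt=1.0, max_steps=5000)
        outs = []
        for _ in range(2):
            eng = ToyEngine(barrier8, lang, np.array([-1.0]), op)
            bias = BiasPotential(dim=1)
            outs.append(run_biased_walker(eng, bias, cfg, None,
                                          record_every=10, seed=9))
        assert np.array_equal(outs[0].positions, outs[1].positions)

    def test_transfer_requires_frozen_bias(self, barrier8):
        op = IdentityOP(1)
        eng = ToyEngine(barrier8, LangevinConfig(n_steps=0), np.array([-1.0]),
                        op)
        with pytest.raises(ValueError, match="frozen"):
            static_bias_transfer(BiasPotential(dim=1), [eng],
                                 MetadConfig(widths=(0.1,)),
                                 [StopCondition("x", 1)])
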