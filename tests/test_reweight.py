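import numpy as np
import pytest
from scipy import integrate

from spibmetad import (BiasPotential, LangevinConfig, WeightedTrajectory,
                       compute_weights, make_potential, pmf_2d, run_baoab,
                       state_thermo)
from spibmetad.structure_cv import DunbrackState
from spibmetad.toy_models import KINASE_MIMIC_CENTERS


def classify_sign(frames):
    x = np.atleast_2d(frames)[:, 0]
    out = np.full(x.shape, DunbrackState.OUT, dtype=object)
    out[x < 0] = DunbrackState.IN
    return out


def classify_d12(frames):
    from spibmetad.structure_cv import classify_dfg_array
    f = np.atleast_2d(frames)
    return classify_dfg_array(f[:, 0], f[:, 1])


class TestWeights:
    def test_zero_bias_gives_unit_weights(self):
        frames = np.zeros((10, 2))
        wt = compute_weights(frames, np.zeros(10))
        np.testing.assert_allclose(wt.weights, 1.0)
        assert wt.ess == pytest.approx(10.0)

    def test_constant_bias_shift_invariance(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(50, 2))
        v = rng.uniform(0, 5, size=50)
        w1 = compute_weights(frames, v).weights
        w2 = compute_weights(frames, v + 123.4).weights
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_large_bias_does_not_overflow(self):
        wt = compute_weights(np.zeros((3, 1)), np.array([1e4, 1e4 - 1, 1e4 - 2]))
        assert np.all(np.isfinite(wt.weights))

    def test_static_negative_f_bias_recovers_boltzmann(self):
        """A kernel bias fitted to −F inside the wells flattens the
        surface; reweighting the biased run must restore the Boltzmann
        density from quadrature to < 0.05 total variation."""
        from scipy.optimize import nnls

        pot = make_potential("double_well_1d", barrier=5.0)
        centers = np.arange(-1.6, 1.61, 0.1)
        width = 0.15
        xfit = np.linspace(-1.6, 1.6, 400)
        target = pot.energy(np.array(1.8)) - pot.energy(xfit)
        design = np.exp(-(xfit[:, None] - centers[None])**2 / (2 * width**2))
        heights, _ = nnls(design, np.clip(target, 0, None))
        bias = BiasPotential(dim=1)
        for c, h in zip(centers, heights):
            if h > 0:
                bias.append([c], [width], h, 0)
        bias.freeze()

        def bias_force(x):
            _, dvds = bias.value_and_grad_many(x[None, :])
            return -dvds[0]

        tr = run_baoab(pot, LangevinConfig(dt=0.02, friction=1.0, kbt=1.0,
                                           n_steps=200000, seed=2),
                       x0=[-1.0], record_every=5, bias_force=bias_force)
        x = tr["positions"][:, 0]
        # the flattened walker must actually cross between wells
        assert (x < 0).any() and (x > 0).any()
        wt = compute_weights(x[:, None], bias.value(x[:, None]))
        edges = np.linspace(-1.6, 1.6, 33)
        hist, _ = np.histogram(x, bins=edges, weights=wt.weights)
        hist = hist / hist.sum()
        z = np.array([integrate.quad(lambda t: np.exp(-pot.energy(np.array(t))),
                                     a, b)[0]
                      for a, b in zip(edges[:-1], edges[1:])])
        z = z / z.sum()
        assert 0.5 * np.abs(hist - z).sum() < 0.05


class TestPMF:
    def test_uniform_weights_flat_pmf(self):
        rng = np.random.default_rng(1)
        frames = rng.uniform(8, 12, size=(200000, 2))
        wt = WeightedTrajectory(frames, np.ones(len(frames)))
        edges = (np.arange(8, 12.5, 0.5), np.arange(8, 12.5, 0.5))
        grid = pmf_2d(wt, edges=edges)
        assert np.nanmax(grid.free_energy) < 0.1

    def test_two_bin_weight_ratio_is_one_kbt(self):
        frames = np.array([[6.1, 6.1], [6.6, 6.1]])
        wt = WeightedTrajectory(frames, np.array([np.e, 1.0]))
        edges = (np.array([6.0, 6.5, 7.0]), np.array([6.0, 6.5]))
        grid = pmf_2d(wt, edges=edges)
        assert grid.free_energy[0, 0] == pytest.approx(0.0)
        assert grid.free_energy[1, 0] == pytest.approx(1.0)

    def test_unsampled_bins_flagged_not_zero(self):
        wt = WeightedTrajectory(np.array([[6.1, 6.1]]), np.array([1.0]))
        edges = (np.array([6.0, 6.5, 7.0]), np.array([6.0, 6.5]))
        grid = pmf_2d(wt, edges=edges)
        assert not grid.sampled[1, 0] and np.isnan(grid.free_energy[1, 0])

    def test_empty_sampling_errors(self):
        wt = WeightedTrajectory(np.array([[100.0, 100.0]]), np.array([1.0]))
        with pytest.raises(ValueError, match="sampled"):
            pmf_2d(wt)

    def test_minima_match_generator_basins(self):
        """Weighted samples from the kinase-mimic Boltzmann density put the
        PMF minima within one bin of the generator's basin centers."""
        pot = make_potential("kinase_mimic_2d", delta_g_in_out=0.5)
        rng = np.random.default_rng(3)
        # the surface is built as −ln of a Gaussian mixture, so its exact
        # Boltzmann density can be sampled directly
        weights = pot.params["weights"]
        states = [DunbrackState.IN, DunbrackState.OUT, DunbrackState.INTER]
        pis = np.array([weights[s.value] for s in states])
        modes = rng.choice(3, size=200000, p=pis / pis.sum())
        centers = np.stack([KINASE_MIMIC_CENTERS[s] for s in states])
        pts = centers[modes] + rng.normal(0, pot.params["width"],
                                          size=(200000, 2))
        wt = WeightedTrajectory(pts, np.ones(len(pts)))
        grid = pmf_2d(wt)
        f = np.where(np.isfinite(grid.free_energy), grid.free_energy, np.inf)
        c1 = 0.5 * (grid.edges1[:-1] + grid.edges1[1:])
        c2 = 0.5 * (grid.edges2[:-1] + grid.edges2[1:])
        i, j = np.unravel_index(np.argmin(f), f.shape)
        glob = np.array([c1[i], c2[j]])
        out_center = KINASE_MIMIC_CENTERS[DunbrackState.OUT]
        assert np.all(np.abs(glob - out_center) <= 0.25)


class TestStateThermo:
    def test_equal_populations_zero_dg(self):
        frames = np.array([[-1.0, 0.0], [1.0, 0.0]])
        wt = WeightedTrajectory(frames, np.ones(2))
        th = state_thermo([wt], classify_sign)
        assert th.delta_g == pytest.approx(0.0)

    def test_closed_form_ratio(self):
        frames = np.concatenate([np.full((62, 2), -1.0), np.full((38, 2), 1.0)])
        wt = WeightedTrajectory(frames, np.ones(100))
        th = state_thermo([wt], classify_sign)
        assert th.delta_g == pytest.approx(-np.log(0.62 / 0.38), abs=1e-12)
        assert th.delta_g == pytest.approx(-0.490, abs=1e-3)

    def test_one_sided_trajectory_excluded_with_warning(self):
        both = WeightedTrajectory(np.array([[-1.0, 0], [1.0, 0]]), np.ones(2))
        one = WeightedTrajectory(np.array([[-1.0, 0]]), np.ones(1))
        with pytest.warns(UserWarning, match="one-sided"):
            th = state_thermo([both, one], classify_sign)
        assert th.n_traj == 1
        assert th.per_trajectory[1]["one_sided"]

    def test_gap_mass_reported_separately(self):
        frames = np.array([[9.0, 16.0], [13.0, 10.0], [10.0, 12.5]])
        wt = WeightedTrajectory(frames, np.ones(3))
        th = state_thermo([wt], classify_d12)
        assert th.p_in + th.p_out == pytest.approx(1.0)
        assert th.gap_mass == pytest.approx(1 / 3)

    def test_spread_is_sample_sd_over_trajectories(self):
        def traj(p_in):
            n = 1000
            k = int(p_in * n)
            frames = np.concatenate([np.full((k, 2), -1.0),
                                     np.full((n - k, 2), 1.0)])
            return WeightedTrajectory(frames, np.ones(n))

        th = state_thermo([traj(0.4), traj(0.5), traj(0.6)], classify_sign)
        dgs = [t["delta_g_kbt"] for t in th.per_trajectory]
        assert th.n_traj == 3
        assert th.spread == pytest.approx(np.std(dgs, ddof=1))

    def test_self_consistency_with_pmf_integration(self):
        """ΔG from state populations equals ΔG from integrating
        exp(−F/kBT) over the PMF regions on a fine grid."""
        pot = make_potential("kinase_mimic_2d", delta_g_in_out=0.5)
        rng = np.random.default_rng(5)
        pts = rng.uniform(6, 20, size=(500000, 2))
        w = np.exp(-pot.energy(pts))
        wt = WeightedTrajectory(pts, w / w.mean())
        th = state_thermo([wt], classify_d12)

        edges = (np.arange(6, 20.1, 0.1), np.arange(6, 20.1, 0.1))
        grid = pmf_2d(wt, edges=edges)
        c1 = 0.5 * (grid.edges1[:-1] + grid.edges1[1:])
        c2 = 0.5 * (grid.edges2[:-1] + grid.edges2[1:])
        C1, C2 = np.meshgrid(c1, c2, indexing="ij")
        labels = classify_d12(np.column_stack([C1.ravel(), C2.ravel()])
                              ).reshape(C1.shape)
        p = np.where(np.isfinite(grid.free_energy),
                     np.exp(-np.nan_to_num(grid.free_energy, nan=np.inf)), 0.0)
        p_in = p[labels == DunbrackState.IN].sum()
        p_out = p[labels == DunbrackState.OUT].sum()
        dg_pmf = -np.log(p_in / p_out)
        assert abs(dg_pmf - th.delta_g) < 0.05


def test_weights_validation():
    with pytest.raises(ValueError, match="finite"):
        WeightedTrajectory(np.zeros((2, 1)), np.array([1.0, np.inf]))
    with pytest.raises(ValueError, match="mismatch"):
        WeightedTrajectory(np.zeros((2, 1)), np.array([1.0]))
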