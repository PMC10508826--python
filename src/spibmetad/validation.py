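"""Closed-loop validation experiments on the analytic toy systems.

Each function runs one self-contained benchmark of the sampling machinery
against ground truth that is computed independently of the sampler
(quadrature, closed forms, generator bookkeeping), and returns a summary
dict.  These are the desk-scale analogs of the full protocol's convergence
checks; problem sizes are chosen so each experiment finishes in minutes on
one CPU while leaving clear statistical margin to its expected outcome.
"""

from __future__ import annotations

import numpy as np

from .bias_engine import (BiasPotential, IdentityOP, MetadConfig,
                          StopCondition, ToyEngine, fes_from_bias,
                          run_biased_walker, run_shared_bias_walkers,
                          static_bias_transfer)
from .reweight import compute_weights, state_thermo
from .spib import SPIBConfig, label_accuracy, spib_refine_loop
from .structure_cv import DunbrackState, classify_dfg_array
from .toy_models import (KINASE_MIMIC_CENTERS, LangevinConfig, make_potential,
                         run_baoab)

__all__ = ["wt_metad_fes_rmse", "tilted_dg_recovery", "sign_flip_transfer",
           "spib_two_state_benchmark"]


def _classify_d12(frames):
    f = np.atleast_2d(frames)
    return classify_dfg_array(f[:, 0], f[:, 1])


def _classify_sign(frames):
    x = np.atleast_2d(frames)[:, 0]
    out = np.full(x.shape, DunbrackState.OUT, dtype=object)
    out[x < 0] = DunbrackState.IN
    return out


def wt_metad_fes_rmse(seed: int = 42, barrier: float = 8.0,
                      n_steps: int = 600_000) -> dict:
    """Well-tempered convergence: −(γ/(γ−1))·V vs the analytic double-well
    free energy over the sampled range (central 99% of visited positions),
    after aligning the irrelevant constant offset."""
    pot = make_potential("double_well_1d", barrier=barrier)
    op = IdentityOP(1)
    eng = ToyEngine(pot, LangevinConfig(dt=0.02, friction=1.0, kbt=1.0,
                                        n_steps=0, seed=0),
                    np.array([-1.0]), op)
    gamma = 8.0
    cfg = MetadConfig(w0=0.5, widths=(0.1,), pace=200, bias_factor=gamma,
                      kbt=1.0, max_steps=n_steps)
    bias = BiasPotential(dim=1)
    bias.enable_grid([-2.5], [2.5], spacing=0.02)
    res = run_biased_walker(eng, bias, cfg, stop=None, record_every=20,
                            seed=seed)
    xs = res.positions[:, 0]
    lo, hi = np.quantile(xs, [0.005, 0.995])
    grid = np.linspace(lo, hi, 200)[:, None]
    fhat = fes_from_bias(bias, grid, gamma)
    f = pot.energy(grid[:, 0])
    f -= f.min()
    resid = fhat - f
    rmse = float(np.sqrt(np.mean((resid - resid.mean())**2)))
    return {"rmse_kbt": rmse, "n_steps": n_steps, "n_kernels": len(bias),
            "sampled_range": (float(lo), float(hi))}


def _learn_static_bias_1d(seed: int, barrier: float = 8.0,
                          n_steps: int = 300_000) -> BiasPotential:
    pot = make_potential("double_well_1d", barrier=barrier)
    op = IdentityOP(1)
    eng = ToyEngine(pot, LangevinConfig(dt=0.02, friction=1.0, kbt=1.0,
                                        n_steps=0, seed=0),
                    np.array([-1.0]), op)
    cfg = MetadConfig(w0=0.5, widths=(0.1,), pace=200, bias_factor=8.0,
                      kbt=1.0, max_steps=n_steps)
    bias = BiasPotential(dim=1)
    bias.enable_grid([-2.5], [2.5], spacing=0.02)
    run_biased_walker(eng, bias, cfg, stop=None, record_every=20, seed=seed)
    return bias.freeze()


def tilted_dg_recovery(seed: int = 21,
                       targets=(-1.0, -0.5, 0.0, 0.5, 1.0)) -> dict:
    """Static-bias reweighting across a family of tilted double wells; the
    oracle ΔG comes from quadrature of each member."""
    ss = np.random.SeedSequence(seed)
    learn_seed, run_seed = [int(c.generate_state(1)[0] % 2**31)
                            for c in ss.spawn(2)]
    bias = _learn_static_bias_1d(learn_seed)
    op = IdentityOP(1)
    lang = LangevinConfig(dt=0.02, friction=1.0, kbt=1.0, n_steps=0, seed=0)
    results = []
    for dg in targets:
        pot = make_potential("tilted_double_well_1d", barrier=8.0,
                             target_dg=dg)
        engines = [ToyEngine(pot, lang,
                             np.array([-1.0 if i % 2 == 0 else 1.0]), op)
                   for i in range(5)]
        stops = [StopCondition(DunbrackState.OUT if i % 2 == 0
                               else DunbrackState.IN, 3000)
                 for i in range(5)]
        tres = static_bias_transfer(bias, engines,
                                    MetadConfig(widths=(0.1,), kbt=1.0,
                                                max_steps=100_000),
                                    stops, record_every=10, seed=run_seed)
        wtrajs = [compute_weights(r.positions, bias.value(r.ib), 1.0)
                  for r in tres]
        th = state_thermo(wtrajs, _classify_sign, 1.0)
        results.append({"target": dg, "analytic": pot.delta_g(),
                        "estimate": th.delta_g, "spread": th.spread,
                        "error": abs(th.delta_g - pot.delta_g())})
    mae = float(np.mean([r["error"] for r in results]))
    return {"mae_kbt": mae, "per_target": results}


def _learn_kinase_bias(seed: int, delta_g: float = 0.5,
                       max_steps: int = 150_000):
    pot = make_potential("kinase_mimic_2d", delta_g_in_out=delta_g)
    op = IdentityOP(2)
    lang = LangevinConfig(dt=0.05, friction=1.0, kbt=1.0, n_steps=0, seed=0)
    C = KINASE_MIMIC_CENTERS
    starts = [C[DunbrackState.IN], C[DunbrackState.OUT],
              C[DunbrackState.INTER], C[DunbrackState.IN],
              C[DunbrackState.OUT]]
    targets = [DunbrackState.OUT, DunbrackState.IN,
               frozenset({DunbrackState.IN, DunbrackState.OUT}),
               DunbrackState.OUT, DunbrackState.IN]
    engines = [ToyEngine(pot, lang, np.array(s, float), op) for s in starts]
    stops = [StopCondition(t, 2000) for t in targets]
    cfg = MetadConfig(w0=1.2, widths=(0.35, 0.35), pace=250, bias_factor=10.0,
                      kbt=1.0, max_steps=max_steps)
    bias = BiasPotential(dim=2)
    bias.enable_grid([5, 5], [21, 21], spacing=0.1)
    run_shared_bias_walkers(engines, bias, cfg, stops, record_every=10,
                            seed=seed)
    return bias.freeze(), pot, op, lang


def _transfer_dg(bias, pot, op, lang, seed: int,
                 max_steps: int = 100_000, window: int = 4000):
    C = KINASE_MIMIC_CENTERS
    engines = [ToyEngine(pot, lang,
                         C[DunbrackState.IN if i % 2 == 0
                           else DunbrackState.OUT].copy(), op)
               for i in range(5)]
    stops = [StopCondition(DunbrackState.OUT if i % 2 == 0
                           else DunbrackState.IN, window)
             for i in range(5)]
    tres = static_bias_transfer(bias, engines,
                                MetadConfig(widths=(0.35, 0.35), kbt=1.0,
                                            max_steps=max_steps),
                                stops, record_every=10, seed=seed)
    wtrajs = [compute_weights(r.positions, bias.value(r.ib), 1.0)
              for r in tres]
    return state_thermo(wtrajs, _classify_d12, 1.0)


def sign_flip_transfer(seed: int = 1, n_seeds: int = 10,
                       wt_dg: float = 0.5, mutant_dg: float = -0.4) -> dict:
    """Headline transfer behavior: one bias learned on the reference
    surface (ΔG = +0.5 kBT, DFG-out more stable), frozen, then applied
    statically to a perturbed surface with the stability flipped
    (ΔG = −0.4 kBT).  Success per seed = the reweighted ΔG recovers the
    flipped sign."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n_seeds + 2)]
    bias, wt_pot, op, lang = _learn_kinase_bias(seeds[0], delta_g=wt_dg)
    mut_pot = make_potential("kinase_mimic_2d", delta_g_in_out=mutant_dg)

    wt_thermo = _transfer_dg(bias, wt_pot, op, lang, seeds[1])
    estimates = []
    for s in seeds[2:]:
        th = _transfer_dg(bias, mut_pot, op, lang, s)
        estimates.append({"delta_g_kbt": th.delta_g,
                          "spread_kbt": th.spread,
                          "sign_correct": bool(th.delta_g < 0)})
    n_success = sum(e["sign_correct"] for e in estimates)
    return {"success_rate": n_success / n_seeds, "n_seeds": n_seeds,
            "n_success": n_success,
            "wt": {"analytic": wt_pot.delta_g(),
                   "delta_g_kbt": wt_thermo.delta_g,
                   "spread_kbt": wt_thermo.spread},
            "mutant_analytic": mut_pot.delta_g(),
            "mutant_estimates": estimates,
            "n_kernels": len(bias)}


def spib_two_state_benchmark(seed: int = 0, n_informative: int = 3,
                             n_noise: int = 17) -> dict:
    """SPIB on a two-well Langevin trajectory with known state sequence:
    label-recovery accuracy plus the 3-round prune loop's behavior on
    informative-vs-noise CV channels."""
    pot = make_potential("double_well_1d", barrier=5.0)
    tr = run_baoab(pot, LangevinConfig(dt=0.02, n_steps=40_000,
                                       seed=seed + 3, friction=1.0),
                   x0=[-1.0], record_every=10)
    x = tr["positions"][:, 0]
    truth = np.where(x < 0, "L", "R")
    rng = np.random.default_rng(seed)
    informative = [x] + [np.sign(c) * x + 0.1 * rng.standard_normal(x.size)
                         for c in np.linspace(-1, 1, n_informative - 1)]
    noise = [rng.standard_normal(x.size) for _ in range(n_noise)]
    X = np.column_stack(informative + noise)

    cfg = SPIBConfig(lag=5, seed=seed)
    model, retained = spib_refine_loop(X, truth, cfg)
    acc = label_accuracy(truth, model.state_labels)
    imp = model.feature_importance()
    return {
        "accuracy": float(acc),
        "n_frames": int(x.size),
        "retained": retained.tolist(),
        "informative_retained": bool(set(range(n_informative))
                                     <= set(retained.tolist())),
        "noise_retained": int(sum(1 for i in retained if i >= n_informative)),
        "prune_rule_satisfied": bool(np.all(imp >= cfg.prune_fraction
                                            * imp.max())),
    }
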