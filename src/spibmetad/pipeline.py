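"""End-to-end protocol orchestration on the shipped toy systems.

The pipeline mirrors the full enhanced-sampling protocol at desk scale:

1. ``ensemble``  — synthetic structure-prediction ensemble (CV mixture),
   unphysical-structure filtering, standardization;
2. ``cluster``   — regular-space clustering, seed selection;
3. ``unbiased``  — Langevin trajectories seeded at the cluster centers;
4. ``spib``      — SPIB order-parameter learning with the prune loop;
5. ``metad``     — shared-bias well-tempered metadynamics on the IB plane,
   stop conditions, bias freeze + HILLS export;
6. ``transfer``  — static-bias walkers from both basins, for the reference
   ("wt") surface and each perturbed ("mutant") surface;
7. ``reweight``  — importance weights, PMFs, DFG-state ΔG ± sd.

Every stage writes its artifacts plus a manifest (seeds, parameter block,
input checksums) under the run directory, and appends structured JSON-line
events to ``events.jsonl``; a completed stage is skipped on resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import colvar
from .bias_engine import (BiasPotential, LinearOP, MetadConfig, StopCondition,
                          ToyEngine, run_shared_bias_walkers,
                          static_bias_transfer)
from .reweight import WeightedTrajectory, compute_weights, pmf_2d, state_thermo
from .seed_select import ClusterConfig, regular_space_cluster, select_seeds
from .spib import SPIBConfig, IBModel, export_plumed, project, spib_refine_loop
from .structure_cv import (DunbrackState, classify_dfg_array,
                           filter_unphysical, standardize)
from .toy_models import (KINASE_MIMIC_CENTERS, LangevinConfig,
                         SyntheticEnsembleConfig, make_potential,
                         synth_ensemble)

__all__ = ["ProtocolConfig", "run_protocol", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["ensemble", "cluster", "unbiased", "spib", "metad", "transfer",
          "reweight"]


@dataclass
class ProtocolConfig:
    """Single config for the whole run; every block is a plain dict so YAML
    round-trips losslessly.  Defaults define the shipped kinase-mimic demo;
    parameters with no counterpart in the reference protocol are marked
    ``paper-unstated`` in the template emitted by :meth:`template_yaml`."""

    run_dir: str = "runs/demo"
    seed: int = 1
    kbt: float = 1.0
    stages: list = field(default_factory=lambda: list(STAGES))
    resume: bool = False

    potential: dict = field(default_factory=lambda: {
        "name": "kinase_mimic_2d", "delta_g_in_out": 0.5,
        "p_inter": 0.08, "width": 0.7})
    mutants: dict = field(default_factory=lambda: {"mutant": -0.4})
    ensemble: dict = field(default_factory=lambda: {
        "n_structures": 1280, "weights": [0.55, 0.30, 0.15],
        "sigma": 0.35, "n_aux": 4, "unphysical_fraction": 0.05})
    cluster: dict = field(default_factory=lambda: {"dmin": 2.0})
    unbiased: dict = field(default_factory=lambda: {
        "n_steps": 20000, "dt": 0.05, "friction": 1.0, "record_every": 10,
        "n_noise_cvs": 2, "max_seeds": 6})
    spib: dict = field(default_factory=lambda: {
        "lag": 5, "epochs_per_iter": 60, "max_relabel_iters": 6,
        "prune_rounds": 3, "learning_rate": 0.05, "beta": 0.01})
    metad: dict = field(default_factory=lambda: {
        "w0": 1.2, "pace": 250, "bias_factor": 10.0, "n_walkers": 5,
        "max_steps": 150000, "stability_window": 2000,
        "width_fraction": 0.1, "dt": 0.05, "friction": 1.0,
        "record_every": 10})
    transfer: dict = field(default_factory=lambda: {
        "n_walkers": 5, "max_steps": 100000, "stability_window": 4000,
        "record_every": 10})
    reweight: dict = field(default_factory=lambda: {
        "bin_width": 0.25, "range": [6.0, 20.0]})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


class _RunLog:
    """JSON-lines event log; one object per line."""

    def __init__(self, path: Path):
        self.path = path

    def event(self, kind: str, **fields) -> None:
        rec = {"t": _time.time(), "event": kind, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, stage: str, seed: int, params: dict,
                    inputs: list[Path], outputs: list[Path]) -> None:
    stage_dir.joinpath("manifest.json").write_text(json.dumps({
        "stage": stage, "seed": int(seed), "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
    }, indent=2))


def _stage_done(stage_dir: Path) -> bool:
    return (stage_dir / "manifest.json").exists()


def _stage_seeds(global_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(global_seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % 2**31)
            for stage, c in zip(STAGES, children)}


def _classify_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.atleast_2d(frames)
    return classify_dfg_array(frames[:, 0], frames[:, 1])


def run_protocol(cfg: ProtocolConfig) -> dict:
    """Execute the enabled stages in order; returns the run report."""
    run_dir = Path(cfg.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _RunLog(run_dir / "events.jsonl")
    seeds = _stage_seeds(cfg.seed)
    cfg.to_yaml(run_dir / "config.yaml")
    report: dict = {"run_dir": str(run_dir), "seed": cfg.seed, "stages": {}}

    wt_potential = make_potential(cfg.potential["name"],
                                  **{k: v for k, v in cfg.potential.items()
                                     if k != "name"})

    for stage in cfg.stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    enabled = [s for s in STAGES if s in cfg.stages]

    for stage in enabled:
        stage_dir = run_dir / stage
        if cfg.resume and _stage_done(stage_dir):
            log.event("stage_skipped", stage=stage)
            report["stages"][stage] = {"skipped": True}
            continue
        stage_dir.mkdir(parents=True, exist_ok=True)
        log.event("stage_start", stage=stage, seed=seeds[stage])
        try:
            fn = globals()[f"_stage_{stage}"]
            summary = fn(cfg, run_dir, stage_dir, seeds[stage], log,
                         wt_potential)
        except Exception as exc:
            log.event("stage_failed", stage=stage, error=str(exc))
            raise RuntimeError(
                f"stage {stage!r} failed ({exc}); completed stages remain in "
                f"{run_dir} and the run can be resumed with resume=True") from exc
        report["stages"][stage] = summary
        log.event("stage_end", stage=stage, **{k: v for k, v in summary.items()
                                               if isinstance(v, (int, float, str))})

    (run_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_ensemble(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    e = cfg.ensemble
    syn = synth_ensemble(SyntheticEnsembleConfig(
        n_structures=e["n_structures"], weights=tuple(e["weights"]),
        sigma=e["sigma"], n_aux=e["n_aux"],
        unphysical_fraction=e["unphysical_fraction"], seed=seed))
    retained, rejections = filter_unphysical(syn["ca_traces"])
    values = syn["values"][retained]
    out = stage_dir / "colvar.tsv"
    colvar.write_colvar(out, syn["names"], values)
    truth = stage_dir / "truth.json"
    truth.write_text(json.dumps({
        "labels": [s.value for s in syn["labels"][retained]],
        "n_injected_breaks": syn["n_injected_breaks"],
        "n_rejected": len(rejections),
        "retained_indices": retained,
    }))
    log.event("ensemble_filtered", n_total=e["n_structures"],
              n_rejected=len(rejections))
    _write_manifest(stage_dir, "ensemble", seed, e, [], [out, truth])
    return {"n_structures": len(retained), "n_rejected": len(rejections)}


def _stage_cluster(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    data = colvar.read_colvar(run_dir / "ensemble" / "colvar.tsv")
    std, mean, sd = standardize(data.values)
    result = regular_space_cluster(std, ClusterConfig(dmin=cfg.cluster["dmin"]))
    states = _classify_frames(data.values[:, :2])
    seeds_list = select_seeds(result, data.values, states=list(states))
    result.to_json(stage_dir / "centers.json")
    colvar.write_colvar(stage_dir / "seeds.tsv", data.names,
                        np.array([s["values"] for s in seeds_list]))
    (stage_dir / "seed_states.json").write_text(json.dumps(
        [s["state"].value for s in seeds_list]))
    log.event("clustered", n_centers=len(result.center_indices))
    _write_manifest(stage_dir, "cluster", seed, cfg.cluster,
                    [run_dir / "ensemble" / "colvar.tsv"],
                    [stage_dir / "centers.json", stage_dir / "seeds.tsv"])
    return {"n_centers": len(result.center_indices),
            "seed_states": [s["state"].value for s in seeds_list]}


def _stage_unbiased(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    from .toy_models import run_baoab
    u = cfg.unbiased
    seeds_tsv = colvar.read_colvar(run_dir / "cluster" / "seeds.tsv")
    starts = seeds_tsv.values[:, :2]
    if len(starts) > u["max_seeds"]:
        starts = starts[:u["max_seeds"]]
    rng = np.random.default_rng(seed)
    names = ["d1", "d2"] + [f"noise{j + 1}" for j in range(u["n_noise_cvs"])]
    outputs = []
    for i, x0 in enumerate(starts):
        traj = run_baoab(potential,
                         LangevinConfig(friction=u["friction"], kbt=cfg.kbt,
                                        dt=u["dt"], n_steps=u["n_steps"],
                                        seed=int(rng.integers(2**31))),
                         x0, record_every=u["record_every"])
        pos = traj["positions"]
        noise = 12.0 + 0.5 * rng.standard_normal((pos.shape[0],
                                                  u["n_noise_cvs"]))
        out = stage_dir / f"traj_{i}.tsv"
        colvar.write_colvar(out, names, np.column_stack([pos, noise]))
        outputs.append(out)
    log.event("unbiased_runs", n_traj=len(outputs))
    _write_manifest(stage_dir, "unbiased", seed, u,
                    [run_dir / "cluster" / "seeds.tsv"], outputs)
    return {"n_traj": len(outputs), "frames_per_traj": int(pos.shape[0])}


def _stage_spib(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    s = cfg.spib
    trajs = sorted((run_dir / "unbiased").glob("traj_*.tsv"))
    datas = [colvar.read_colvar(t) for t in trajs]
    names = datas[0].names
    # fit on the concatenation; lag pairs crossing trajectory joins are a
    # negligible fraction at these lengths
    X = np.vstack([d.values for d in datas])
    labels = []
    for st in _classify_frames(X[:, :2]):
        labels.append(None if st == DunbrackState.GAP else st.value)
    spib_cfg = SPIBConfig(lag=s["lag"], epochs_per_iter=s["epochs_per_iter"],
                          max_relabel_iters=s["max_relabel_iters"],
                          prune_rounds=s["prune_rounds"],
                          learning_rate=s["learning_rate"], beta=s["beta"],
                          seed=seed)
    model, retained = spib_refine_loop(X, np.array(labels, dtype=object),
                                       spib_cfg, cv_names=names)
    model.save(stage_dir / "model.json")
    (stage_dir / "retained.json").write_text(json.dumps(
        {"indices": retained.tolist(),
         "names": [names[i] for i in retained]}))
    (stage_dir / "plumed.dat").write_text(export_plumed(model))
    for it, ch in enumerate(model.history.get("relabel_changes", [])):
        log.event("relabel", iteration=it, changed_fraction=ch)
    log.event("pruned", retained=[names[i] for i in retained])
    _write_manifest(stage_dir, "spib", seed, s, trajs,
                    [stage_dir / "model.json", stage_dir / "retained.json"])
    return {"retained_cvs": [names[i] for i in retained],
            "n_states": model.n_states}


def _load_op(run_dir) -> LinearOP:
    model = IBModel.load(run_dir / "spib" / "model.json")
    coord_map = {}
    for cv_i, name in enumerate(model.cv_names):
        if name == "d1":
            coord_map[cv_i] = 0
        elif name == "d2":
            coord_map[cv_i] = 1
    if not coord_map:
        raise RuntimeError("learned OP contains no dynamical CVs (d1/d2)")
    return LinearOP(model, coord_map=coord_map, n_coords=2)


def _opposite(state: DunbrackState):
    if state == DunbrackState.IN:
        return DunbrackState.OUT
    if state == DunbrackState.OUT:
        return DunbrackState.IN
    return frozenset({DunbrackState.IN, DunbrackState.OUT})


def _stage_metad(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    m = cfg.metad
    op = _load_op(run_dir)
    seeds_tsv = colvar.read_colvar(run_dir / "cluster" / "seeds.tsv")
    seed_states = [DunbrackState(v) for v in json.loads(
        (run_dir / "cluster" / "seed_states.json").read_text())]
    # walker starts: prefer one per state, then cycle
    order = []
    for want in (DunbrackState.IN, DunbrackState.OUT, DunbrackState.INTER):
        order += [i for i, st in enumerate(seed_states) if st == want]
    order += [i for i in range(len(seed_states)) if i not in order]
    picks = [order[i % len(order)] for i in range(m["n_walkers"])]

    # Gaussian widths from the latent spread of the unbiased ensemble
    unb = [colvar.read_colvar(t) for t in
           sorted((run_dir / "unbiased").glob("traj_*.tsv"))]
    cols = [unb[0].names.index(n) for n in op.model.cv_names]
    ib_all = np.vstack([project(op.model, d.values[:, cols]) for d in unb])
    widths = tuple(m["width_fraction"] * (ib_all.max(axis=0) - ib_all.min(axis=0)))

    mcfg = MetadConfig(w0=m["w0"], widths=widths, pace=m["pace"],
                       bias_factor=m["bias_factor"], n_walkers=m["n_walkers"],
                       kbt=cfg.kbt, max_steps=m["max_steps"])
    bias = BiasPotential(dim=op.dim)
    # grid cache over the unbiased IB range with generous margin
    span = ib_all.max(axis=0) - ib_all.min(axis=0)
    bias.enable_grid(ib_all.min(axis=0) - 1.5 * span,
                     ib_all.max(axis=0) + 1.5 * span,
                     spacing=float(0.3 * min(widths)))
    engines, stops = [], []
    for w, pick in enumerate(picks):
        x0 = seeds_tsv.values[pick, :2]
        engines.append(ToyEngine(potential=potential,
                                 langevin=LangevinConfig(
                                     friction=m["friction"], kbt=cfg.kbt,
                                     dt=m["dt"], n_steps=0, seed=0),
                                 x0=x0, op=op))
        stops.append(StopCondition(target_state=_opposite(seed_states[pick]),
                                   stability_window=m["stability_window"]))
    results = run_shared_bias_walkers(engines, bias, mcfg, stops,
                                      record_every=m["record_every"],
                                      seed=seed)
    for i, r in enumerate(results):
        log.event("walker_done", walker=i, converged=r.converged,
                  stopped_at=r.stopped_at, n_steps=r.n_steps)
        colvar.write_colvar(stage_dir / f"walker_{i}.tsv",
                            ["d1", "d2", "ib1", "ib2"],
                            np.column_stack([r.positions, r.ib]))
    log.event("deposits_total", count=len(bias))
    bias.freeze()
    bias.to_hills(stage_dir / "HILLS", bias_factor=m["bias_factor"])
    (stage_dir / "metad_report.json").write_text(json.dumps({
        "n_kernels": len(bias), "widths": list(widths),
        "converged": [r.converged for r in results]}))
    _write_manifest(stage_dir, "metad", seed, m,
                    [run_dir / "spib" / "model.json"],
                    [stage_dir / "HILLS"])
    return {"n_kernels": len(bias),
            "n_converged": sum(r.converged for r in results)}


def _transfer_one(cfg, run_dir, out_dir, seed, log, potential, tag) -> list:
    t = cfg.transfer
    op = _load_op(run_dir)
    bias = BiasPotential.from_hills(run_dir / "metad" / "HILLS", frozen=True)
    if len(bias):
        lo = bias._centers.min(axis=0) - 6 * bias._widths.max(axis=0)
        hi = bias._centers.max(axis=0) + 6 * bias._widths.max(axis=0)
        bias.enable_grid(lo, hi, spacing=float(0.3 * bias._widths.min()))
    n_before = len(bias)
    starts, stops = [], []
    basins = [DunbrackState.IN, DunbrackState.OUT]
    for w in range(t["n_walkers"]):
        basin = basins[w % 2]
        starts.append(KINASE_MIMIC_CENTERS[basin].copy())
        stops.append(StopCondition(target_state=_opposite(basin),
                                   stability_window=t["stability_window"]))
    engines = [ToyEngine(potential=potential,
                         langevin=LangevinConfig(friction=cfg.metad["friction"],
                                                 kbt=cfg.kbt,
                                                 dt=cfg.metad["dt"],
                                                 n_steps=0, seed=0),
                         x0=x0, op=op) for x0 in starts]
    results = static_bias_transfer(bias, engines,
                                   MetadConfig(widths=(1.0,) * op.dim,
                                               kbt=cfg.kbt,
                                               pace=cfg.metad["pace"],
                                               bias_factor=cfg.metad["bias_factor"],
                                               max_steps=t["max_steps"]),
                                   stops, record_every=t["record_every"],
                                   seed=seed)
    assert len(bias) == n_before  # frozen contract: no deposits
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, r in enumerate(results):
        log.event("transfer_walker_done", system=tag, walker=i,
                  converged=r.converged, n_steps=r.n_steps)
        colvar.write_colvar(out_dir / f"walker_{i}.tsv",
                            ["d1", "d2", "ib1", "ib2"],
                            np.column_stack([r.positions, r.ib]))
    log.event("deposits_total", system=tag, count=len(bias) - n_before)
    return results


def _stage_transfer(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    systems = {"wt": potential}
    for name, dg in cfg.mutants.items():
        systems[name] = make_potential(cfg.potential["name"],
                                       **{**{k: v for k, v in
                                             cfg.potential.items()
                                             if k != "name"},
                                          "delta_g_in_out": dg})
    summary = {}
    rng = np.random.default_rng(seed)
    for tag, pot in systems.items():
        results = _transfer_one(cfg, run_dir, stage_dir / tag,
                                int(rng.integers(2**31)), log, pot, tag)
        summary[tag] = {"n_converged": sum(r.converged for r in results),
                        "analytic_delta_g": pot.delta_g()}
    _write_manifest(stage_dir, "transfer", seed, cfg.transfer,
                    [run_dir / "metad" / "HILLS"],
                    sorted(stage_dir.glob("*/walker_*.tsv")))
    return summary


def _stage_reweight(cfg, run_dir, stage_dir, seed, log, potential) -> dict:
    bias = BiasPotential.from_hills(run_dir / "metad" / "HILLS", frozen=True)
    r = cfg.reweight
    lo, hi = r["range"]
    edges = (np.arange(lo, hi + r["bin_width"], r["bin_width"]),) * 2
    summary = {}
    for sys_dir in sorted((run_dir / "transfer").iterdir()):
        if not sys_dir.is_dir():
            continue
        wtrajs = []
        for tsv in sorted(sys_dir.glob("walker_*.tsv")):
            d = colvar.read_colvar(tsv)
            frames = d.values[:, :2]
            ib = d.values[:, 2:4]
            wtrajs.append(compute_weights(frames, bias.value(ib), kbt=cfg.kbt))
        thermo = state_thermo(wtrajs, _classify_frames, kbt=cfg.kbt)
        allw = np.concatenate([w.weights for w in wtrajs])
        pooled = WeightedTrajectory(np.vstack([w.frames for w in wtrajs]),
                                    allw / allw.mean())
        pmf = pmf_2d(pooled, edges=edges, kbt=cfg.kbt)
        out = stage_dir / sys_dir.name
        out.mkdir(parents=True, exist_ok=True)
        thermo.to_json(out / "thermo.json")
        pmf.to_tsv(out / "pmf.tsv")
        summary[sys_dir.name] = {"delta_g_kbt": thermo.delta_g,
                                 "spread_kbt": thermo.spread,
                                 "n_traj": thermo.n_traj}
        log.event("reweighted", system=sys_dir.name,
                  delta_g=thermo.delta_g, spread=thermo.spread)
    _write_manifest(stage_dir, "reweight", seed, r,
                    [run_dir / "metad" / "HILLS"],
                    sorted(stage_dir.glob("*/thermo.json")))
    return summary
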