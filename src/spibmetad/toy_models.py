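"""Analytic toy systems with known thermodynamics.

These stand in for the expensive stages of the real protocol — structure
prediction and all-atom MD — so the sampling machinery can be exercised and
validated end-to-end on a desk.  Everything here exports its ground truth
(state labels, quadrature free energies, injected defects) so downstream
estimates can be checked closed-loop.

Energies are in kBT (kBT = 1 internally); coordinates of the kinase-mimic
surface live directly on the Dunbrack (d1, d2) plane in Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import integrate, optimize

from .structure_cv import DunbrackState, classify_dfg_array

__all__ = [
    "ToyPotential", "LangevinConfig", "SyntheticEnsembleConfig",
    "make_potential", "run_baoab", "synth_ensemble", "write_fixture_pdb",
    "KINASE_MIMIC_CENTERS",
]

#: Default kinase-mimic basin centers on the (d1, d2) plane in Å, placed
#: inside the Dunbrack rule regions (IN: d1<11, d2>14; OUT: d1>11, d2<14;
#: INTER: d1<11, d2<11).
KINASE_MIMIC_CENTERS = {
    DunbrackState.IN: np.array([9.5, 15.5]),
    DunbrackState.OUT: np.array([13.0, 10.0]),
    DunbrackState.INTER: np.array([9.5, 9.5]),
}


@dataclass
class ToyPotential:
    """Analytic energy surface with quadrature-derived state free energies.

    ``energy`` and ``grad`` are vectorized over leading axes; ``classify``
    maps configurations to discrete state labels; ``free_energies`` holds
    −ln Z_state per state from numerical quadrature (kBT units, unnormalized
    but mutually comparable).
    """

    name: str
    dim: int
    energy: Callable[[np.ndarray], np.ndarray]
    grad: Callable[[np.ndarray], np.ndarray]
    classify: Callable[[np.ndarray], np.ndarray]
    bounds: tuple
    free_energies: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def delta_g(self, state_a=DunbrackState.IN, state_b=DunbrackState.OUT) -> float:
        """G(state_a) − G(state_b) in kBT."""
        return self.free_energies[state_a] - self.free_energies[state_b]


@dataclass
class LangevinConfig:
    friction: float = 1.0
    kbt: float = 1.0
    dt: float = 0.01
    n_steps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("step size must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")


@dataclass
class SyntheticEnsembleConfig:
    """Emulates a reduced-MSA structure-prediction ensemble as CV vectors
    drawn from a mixture over the three DFG reference geometries.

    The default count of 1280 mirrors a typical prediction campaign (128
    random seeds x 5 structures x 2 MSA depths); the emulator makes no claim
    of matching real predictor statistics — it exists to exercise filtering,
    classification, clustering and seeding.
    """

    weights: tuple[float, float, float] = (0.55, 0.30, 0.15)  # IN, OUT, INTER
    centers: dict = field(default_factory=lambda: {k: v.copy() for k, v in
                                                   KINASE_MIMIC_CENTERS.items()})
    sigma: float = 0.35
    n_structures: int = 1280
    n_aux: int = 4
    aux_sigma: float = 0.5
    unphysical_fraction: float = 0.05
    chain_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1, got {self.weights}")
        if self.sigma <= 0 or self.aux_sigma <= 0:
            raise ValueError("mode covariances must be positive definite")


# ---------------------------------------------------------------------------
# potential constructors


def _quadrature_1d(energy, classify, bounds, states) -> dict:
    free = {}
    lo, hi = bounds
    for s in states:
        def integrand(x, s=s):
            lab = classify(np.array([x]))[0]
            return float(np.exp(-energy(np.array(x)))) if lab == s else 0.0
        z, _ = integrate.quad(integrand, lo, hi, limit=400)
        free[s] = -np.log(z) if z > 0 else np.inf
    return free


def _quadrature_2d(energy, classify, bounds, states, n: int = 600) -> dict:
    (x0, x1), (y0, y1) = bounds
    gx = np.linspace(x0, x1, n)
    gy = np.linspace(y0, y1, n)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    w = np.exp(-energy(pts))
    labels = classify(pts)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    free = {}
    for s in states:
        z = float(w[labels == s].sum()) * cell
        free[s] = -np.log(z) if z > 0 else np.inf
    return free


def _double_well_1d(barrier: float, tilt: float, name: str) -> ToyPotential:
    def energy(x):
        x = np.asarray(x, float)
        return barrier * (x**2 - 1.0) ** 2 + tilt * x

    def grad(x):
        x = np.asarray(x, float)
        return 4.0 * barrier * x * (x**2 - 1.0) + tilt

    def classify(x):
        x = np.asarray(x, float).reshape(-1)
        out = np.full(x.shape, DunbrackState.OUT, dtype=object)
        out[x < 0] = DunbrackState.IN
        return out

    free = _quadrature_1d(energy, classify, (-2.5, 2.5),
                          [DunbrackState.IN, DunbrackState.OUT])
    return ToyPotential(name=name, dim=1, energy=energy, grad=grad,
                        classify=classify, bounds=(-2.5, 2.5),
                        free_energies=free,
                        params={"barrier": barrier, "tilt": tilt})


def _kinase_mimic_2d(weights: dict, width: float) -> ToyPotential:
    """Gaussian-mixture surface U = −ln Σ_k π_k N(x; c_k, width² I).

    The Boltzmann density is then exactly the mixture, so the state
    populations are the mixture weights up to negligible tail leakage across
    the Dunbrack region boundaries; quadrature confirms this to ~1e-3 kBT.
    """
    states = list(KINASE_MIMIC_CENTERS)
    centers = np.stack([KINASE_MIMIC_CENTERS[s] for s in states])
    pis = np.array([weights[s] for s in states], float)
    pis = pis / pis.sum()
    inv2w2 = 1.0 / (2.0 * width**2)

    def _comps(x):
        x = np.asarray(x, float)
        diff = x[..., None, :] - centers          # (..., k, 2)
        q = (diff**2).sum(axis=-1) * inv2w2       # (..., k)
        qmin = q.min(axis=-1, keepdims=True)
        return diff, q, qmin

    def energy(x):
        _, q, qmin = _comps(x)
        return (qmin[..., 0]
                - np.log((pis * np.exp(-(q - qmin))).sum(axis=-1)))

    def grad(x):
        diff, q, qmin = _comps(x)
        w = pis * np.exp(-(q - qmin))             # (..., k)
        w = w / w.sum(axis=-1, keepdims=True)
        return (w[..., None] * diff * (1.0 / width**2)).sum(axis=-2)

    def classify(x):
        x = np.atleast_2d(np.asarray(x, float))
        return classify_dfg_array(x[:, 0], x[:, 1])

    bounds = ((6.0, 20.0), (6.0, 20.0))
    free = _quadrature_2d(energy, classify, bounds, states)
    return ToyPotential(name="kinase_mimic_2d", dim=2, energy=energy,
                        grad=grad, classify=classify, bounds=bounds,
                        free_energies=free,
                        params={"weights": {s.value: float(p) for s, p in
                                            zip(states, pis)},
                                "width": width})


def _mueller_like_2d() -> ToyPotential:
    A = np.array([-8.0, -4.0, -6.8, 0.6])
    a = np.array([-1, -1, -6.5, 0.7])
    b = np.array([0, 0, 11, 0.6])
    c = np.array([-10, -10, -6.5, 0.7])
    xc = np.array([1, 0, -0.5, -1])
    yc = np.array([0, 0.5, 1.5, 1])

    def _terms(x):
        x = np.asarray(x, float)
        dx = x[..., 0:1] - xc
        dy = x[..., 1:2] - yc
        return dx, dy, A * np.exp(a * dx**2 + b * dx * dy + c * dy**2)

    def energy(x):
        _, _, t = _terms(x)
        return t.sum(axis=-1)

    def grad(x):
        dx, dy, t = _terms(x)
        gx = (t * (2 * a * dx + b * dy)).sum(axis=-1)
        gy = (t * (b * dx + 2 * c * dy)).sum(axis=-1)
        return np.stack([gx, gy], axis=-1)

    def classify(x):
        x = np.atleast_2d(np.asarray(x, float))
        out = np.full(x.shape[0], DunbrackState.OUT, dtype=object)
        out[x[:, 1] > 0.75] = DunbrackState.IN
        return out

    bounds = ((-1.8, 1.2), (-0.5, 2.2))
    free = _quadrature_2d(energy, classify, bounds,
                          [DunbrackState.IN, DunbrackState.OUT])
    return ToyPotential(name="mueller_like_2d", dim=2, energy=energy,
                        grad=grad, classify=classify, bounds=bounds,
                        free_energies=free)


def make_potential(name: str, **params) -> ToyPotential:
    """Build a named analytic potential.

    Names: ``double_well_1d`` (barrier, default 8 kBT),
    ``tilted_double_well_1d`` (barrier + either ``tilt`` or ``target_dg``,
    the latter solved numerically so the quadrature ΔG(left−right) hits the
    requested value), ``mueller_like_2d``, and ``kinase_mimic_2d``
    (``delta_g_in_out``, ``p_inter``, ``width``) whose three basins sit at
    the Dunbrack reference geometries.
    """
    if name == "double_well_1d":
        return _double_well_1d(params.get("barrier", 8.0), 0.0, name)
    if name == "tilted_double_well_1d":
        barrier = params.get("barrier", 8.0)
        if "target_dg" in params:
            target = params["target_dg"]

            def gap(tilt):
                p = _double_well_1d(barrier, tilt, name)
                return p.delta_g() - target

            tilt = optimize.brentq(gap, -3.0, 3.0, xtol=1e-10) if target != 0 else 0.0
        else:
            tilt = params.get("tilt", 0.5)
        return _double_well_1d(barrier, tilt, name)
    if name == "kinase_mimic_2d":
        dg = params.get("delta_g_in_out", 0.5)
        p_inter = params.get("p_inter", 0.08)
        width = params.get("width", 0.7)

        def build(dg_param):
            # pi_in/pi_out = exp(−ΔG'); inter gets a fixed small share
            r = np.exp(-dg_param)
            p_out = (1.0 - p_inter) / (1.0 + r)
            weights = {DunbrackState.IN: r * p_out, DunbrackState.OUT: p_out,
                       DunbrackState.INTER: p_inter}
            return _kinase_mimic_2d(weights, width)

        # mixture weights give the in/out ratio only up to Gaussian tail
        # leakage across the Dunbrack boundaries; solve the internal weight
        # ratio so the quadrature ΔG hits the requested value
        f = lambda dgp: build(dgp).delta_g() - dg
        lo, hi = dg - 0.5, dg + 0.5
        dg_param = optimize.brentq(f, lo, hi, xtol=1e-4)
        return build(dg_param)
    if name == "mueller_like_2d":
        return _mueller_like_2d()
    raise ValueError(f"unknown potential {name!r}")


# ---------------------------------------------------------------------------
# BAOAB Langevin integration


class TrajectoryDivergedError(RuntimeError):
    pass


def run_baoab(potential: ToyPotential, cfg: LangevinConfig, x0,
              bias_force: Callable[[np.ndarray], np.ndarray] | None = None,
              record_every: int = 1, guard: float = 1e3) -> dict:
    """Integrate Langevin dynamics with the BAOAB splitting (unit mass).

    B: half kick, A: half drift, O: Ornstein–Uhlenbeck thermostat, then A, B.
    ``bias_force`` (if given) is added to the systematic force.  Returns
    positions, velocities and potential energies recorded every
    ``record_every`` steps (the initial point included).
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    if not np.all(np.isfinite(x)):
        raise ValueError("x0 must be finite")
    rng = np.random.default_rng(cfg.seed)
    v = rng.normal(0.0, np.sqrt(cfg.kbt) if cfg.kbt > 0 else 0.0, size=x.shape)
    c1 = np.exp(-cfg.friction * cfg.dt)
    c2 = np.sqrt(cfg.kbt * (1.0 - c1**2))
    h = cfg.dt

    def force(pos):
        f = -potential.grad(pos)
        if bias_force is not None:
            f = f + bias_force(pos)
        return f

    def _u(pos):
        return float(np.squeeze(potential.energy(pos)))

    f = force(x)
    xs, vs, us = [x.copy()], [v.copy()], [_u(x)]
    for step in range(1, cfg.n_steps + 1):
        v = v + 0.5 * h * f
        x = x + 0.5 * h * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x = x + 0.5 * h * v
        f = force(x)
        v = v + 0.5 * h * f
        if np.any(np.abs(x) > guard):
            raise TrajectoryDivergedError(f"trajectory diverged at step {step}")
        if step % record_every == 0:
            xs.append(x.copy())
            vs.append(v.copy())
            us.append(_u(x))
    return {"positions": np.array(xs), "velocities": np.array(vs),
            "energies": np.array(us)}


# ---------------------------------------------------------------------------
# synthetic structure ensembles


def synth_ensemble(cfg: SyntheticEnsembleConfig) -> dict:
    """Draw an AF2-like conformational ensemble as CV vectors.

    (d1, d2) come from an isotropic Gaussian mixture over the IN/OUT/INTER
    reference geometries; each mode also has its own centers for the
    auxiliary CVs so clustering sees the modes across the full CV set.  A
    fraction of structures get a broken Cα backbone injected (one 9 Å gap);
    the returned dict records every piece of ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    states = [DunbrackState.IN, DunbrackState.OUT, DunbrackState.INTER]
    modes = rng.choice(3, size=cfg.n_structures, p=np.asarray(cfg.weights))
    centers = np.stack([cfg.centers[s] for s in states])
    d12 = centers[modes] + rng.normal(0.0, cfg.sigma, size=(cfg.n_structures, 2))
    d12 = np.abs(d12)  # CV invariant: distances strictly positive

    # deterministic per-mode auxiliary centers, spread over a plausible Å range
    aux_centers = 10.0 + 2.0 * np.arange(3)[:, None] + 0.7 * np.arange(cfg.n_aux)[None, :]
    aux = aux_centers[modes] + rng.normal(0.0, cfg.aux_sigma,
                                          size=(cfg.n_structures, cfg.n_aux))
    values = np.column_stack([d12, np.abs(aux)])
    names = ["d1", "d2"] + [f"aux{j+1}" for j in range(cfg.n_aux)]

    n_broken = int(round(cfg.unphysical_fraction * cfg.n_structures))
    broken = np.zeros(cfg.n_structures, dtype=bool)
    broken[rng.choice(cfg.n_structures, size=n_broken, replace=False)] = True

    traces = []
    base = np.zeros((cfg.chain_length, 3))
    base[:, 0] = 3.8 * np.arange(cfg.chain_length)
    for i in range(cfg.n_structures):
        t = base.copy()
        if broken[i]:
            j = int(rng.integers(0, cfg.chain_length - 1))
            t[j + 1:, 0] += 9.0 - 3.8  # widen one Cα–Cα gap to 9 Å
        traces.append(t)

    return {"names": names, "values": values,
            "labels": np.array([states[m] for m in modes], dtype=object),
            "broken": broken, "ca_traces": traces,
            "n_injected_breaks": n_broken}


# ---------------------------------------------------------------------------
# PDB fixtures


def write_fixture_pdb(atoms: list[dict], path: str | Path) -> None:
    """Write a minimal single-model PDB from explicit atom records.

    Each record: ``{"res_id": int, "res_name": str, "atom_name": str,
    "coord": (x, y, z)}``.  Coordinates survive the PDB round trip to the
    format's 1e-3 Å precision.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not atoms:
        raise ValueError("empty atom spec")
    arr = struc.AtomArray(len(atoms))
    for i, a in enumerate(atoms):
        try:
            arr.coord[i] = np.asarray(a["coord"], float)
            arr.res_id[i] = int(a["res_id"])
            arr.res_name[i] = a["res_name"]
            arr.atom_name[i] = a["atom_name"]
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed atom spec at index {i}: {a!r}") from exc
        arr.chain_id[i] = "A"
        arr.element[i] = a["atom_name"][0]
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
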