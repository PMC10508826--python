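"""Boltzmann reweighting of static-bias trajectories and state thermodynamics.

A trajectory sampled under a *frozen* bias V(s) samples the tilted density
p_V(x) ∝ exp(−(U(x) + V(s(x)))/kBT); unbiased expectations are recovered
with the fixed-bias importance weights w_t ∝ exp(+V(s_t)/kBT).  Because the
bias never changes during these runs, no time-dependent rewinding (with its
normalization pitfalls) is needed.

From the weighted frames this module builds potentials of mean force on the
Dunbrack (d1, d2) plane and integrates state probabilities over the DFG
regions, yielding ΔG = G(in) − G(out) = −kBT ln(P_in / P_out).  With this
sign convention a system whose inactive (DFG-out) state is more stable — the
wild-type-like case — has positive ΔG.  ΔG is computed per trajectory and
reported as mean ± sample sd over the trajectories (5 in the reference
protocol).  GAP-labelled frames are excluded from the state normalization
and reported as separate mass.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .structure_cv import DunbrackState

__all__ = ["WeightedTrajectory", "PMFGrid", "StateThermo",
           "compute_weights", "pmf_2d", "state_thermo", "DEFAULT_PMF_EDGES"]

#: Default Dunbrack-plane binning: 0.25 Å bins over [6, 20] Å per axis.
DEFAULT_PMF_EDGES = (np.arange(6.0, 20.0 + 0.25, 0.25),
                     np.arange(6.0, 20.0 + 0.25, 0.25))


@dataclass
class WeightedTrajectory:
    """Frames (in Dunbrack or IB coordinates) with importance weights
    normalized to mean 1, plus the Kish effective sample size."""

    frames: np.ndarray
    weights: np.ndarray
    ess: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, float))
        self.weights = np.asarray(self.weights, float)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and non-negative")
        if self.weights.size != self.frames.shape[0]:
            raise ValueError("weights/frames length mismatch")


@dataclass
class PMFGrid:
    edges1: np.ndarray
    edges2: np.ndarray
    free_energy: np.ndarray   # kBT; NaN where unsampled
    sampled: np.ndarray       # bool mask

    def to_tsv(self, path: str | Path) -> None:
        c1 = 0.5 * (self.edges1[:-1] + self.edges1[1:])
        c2 = 0.5 * (self.edges2[:-1] + self.edges2[1:])
        lines = ["#! FIELDS d1 d2 free_energy"]
        for i, a in enumerate(c1):
            for j, b in enumerate(c2):
                f = self.free_energy[i, j]
                lines.append(f"{a:.6g} {b:.6g} {f if np.isfinite(f) else 'nan'}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class StateThermo:
    """Reweighted DFG-state populations and ΔG = G_in − G_out (kBT)."""

    p_in: float
    p_out: float
    p_inter: float
    p_unassigned: float
    gap_mass: float
    delta_g: float
    spread: float
    n_traj: int
    per_trajectory: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "P_in": self.p_in, "P_out": self.p_out, "P_inter": self.p_inter,
            "P_unassigned": self.p_unassigned, "gap_mass": self.gap_mass,
            "delta_g_kbt": self.delta_g, "spread_kbt": self.spread,
            "n_traj": self.n_traj, "per_trajectory": self.per_trajectory,
        }, indent=2))


def compute_weights(frames: np.ndarray, bias_values: np.ndarray,
                    kbt: float = 1.0) -> WeightedTrajectory:
    """Fixed-bias importance weights w ∝ exp(+V/kBT), mean-normalized.

    The maximum bias value is subtracted before exponentiation so large
    static biases cannot overflow; the shift cancels in the normalization.
    """
    v = np.asarray(bias_values, float)
    w = np.exp((v - v.max()) / kbt)
    w = w / w.mean()
    ess = float(w.sum()**2 / (w**2).sum())
    return WeightedTrajectory(frames=frames, weights=w, ess=ess)


def pmf_2d(wtraj: WeightedTrajectory,
           edges: tuple[np.ndarray, np.ndarray] = DEFAULT_PMF_EDGES,
           kbt: float = 1.0) -> PMFGrid:
    """Weighted 2-D histogram turned into a free-energy surface.

    F_bin = −kBT ln(Σ weights in bin), referenced to 0 at the sampled
    minimum; empty bins are flagged unsampled (NaN), never zero energy.
    """
    e1, e2 = edges
    h, _, _ = np.histogram2d(wtraj.frames[:, 0], wtraj.frames[:, 1],
                             bins=(e1, e2), weights=wtraj.weights)
    sampled = h > 0
    if not sampled.any():
        raise ValueError("no sampled bins inside the PMF grid")
    f = np.full(h.shape, np.nan)
    with np.errstate(divide="ignore"):
        f[sampled] = -kbt * np.log(h[sampled])
    f[sampled] -= np.nanmin(f[sampled])
    return PMFGrid(edges1=e1, edges2=e2, free_energy=f, sampled=sampled)


def state_thermo(wtrajs: list[WeightedTrajectory],
                 classifier: Callable[[np.ndarray], np.ndarray],
                 kbt: float = 1.0) -> StateThermo:
    """Integrate reweighted state probabilities and the in/out ΔG.

    ``classifier`` maps the frame array of one trajectory to DunbrackState
    labels.  Each trajectory yields its own ΔG; trajectories where either
    basin carries zero weight are flagged one-sided and excluded (with a
    warning) from the ΔG mean/spread, though they still count toward the
    pooled populations.
    """
    pooled = {s: 0.0 for s in DunbrackState}
    per_traj = []
    dgs = []
    total_w = 0.0
    for ti, wt in enumerate(wtrajs):
        labels = classifier(wt.frames)
        masses = {s: float(wt.weights[labels == s].sum()) for s in DunbrackState}
        for s, m in masses.items():
            pooled[s] += m
        total_w += float(wt.weights.sum())
        if masses[DunbrackState.IN] == 0 or masses[DunbrackState.OUT] == 0:
            warnings.warn(f"trajectory {ti} is one-sided (P_in or P_out = 0); "
                          "excluded from delta-G statistics", stacklevel=2)
            per_traj.append({"index": ti, "one_sided": True})
            continue
        dg = -kbt * np.log(masses[DunbrackState.IN] / masses[DunbrackState.OUT])
        dgs.append(dg)
        per_traj.append({"index": ti, "one_sided": False,
                         "delta_g_kbt": float(dg), "ess": wt.ess})

    assigned = sum(pooled[s] for s in (DunbrackState.IN, DunbrackState.OUT,
                                       DunbrackState.INTER,
                                       DunbrackState.UNASSIGNED))
    norm = assigned if assigned > 0 else 1.0
    dgs = np.asarray(dgs)
    return StateThermo(
        p_in=pooled[DunbrackState.IN] / norm,
        p_out=pooled[DunbrackState.OUT] / norm,
        p_inter=pooled[DunbrackState.INTER] / norm,
        p_unassigned=pooled[DunbrackState.UNASSIGNED] / norm,
        gap_mass=pooled[DunbrackState.GAP] / total_w if total_w else 0.0,
        delta_g=float(dgs.mean()) if dgs.size else float("nan"),
        spread=float(dgs.std(ddof=1)) if dgs.size > 1 else 0.0,
        n_traj=len(dgs),
        per_trajectory=per_traj,
    )
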