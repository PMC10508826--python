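"""State-predictive information bottleneck (SPIB) order-parameter learning.

Given a CV trajectory x_t and per-frame state labels, SPIB learns a
low-dimensional stochastic encoder z = mu(x_t) + sigma*eps together with a
decoder that predicts the state label of the frame a time lag Delta-t
*later*.  Compressing the present while predicting the future state forces
the latent coordinates onto the slow degrees of freedom — exactly what one
wants as metadynamics order parameters.  The state labels themselves are
refined during training: every few epochs each frame is relabelled with the
decoder's own most-probable state, so kinetically indistinct initial states
merge (states may merge, never split).

The model here is deliberately small and fully deterministic:

* linear encoder ``mu = W x_std + b`` on standardized inputs (so the learned
  order parameter can be exported as a plain linear combination of CVs and
  biased by any metadynamics engine), with a learnable state-independent
  diagonal log-variance;
* linear-softmax decoder over the occupied states;
* a learnable Gaussian-mixture prior over the latent, giving the variational
  information-bottleneck regularizer its multi-basin shape;
* full-batch Adam on hand-derived gradients (float64, seeded — runs are
  bit-reproducible).

Feature pruning follows the refinement rule used with linear encoders: a
CV's importance is the largest |encoder weight| it carries across the latent
dimensions (weights act on standardized inputs, so scales are comparable),
and CVs below 0.25 of the maximum importance are discarded; fit + prune is
repeated, three rounds by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["SPIBConfig", "IBModel", "spib_fit", "prune_features",
           "spib_refine_loop", "project", "label_accuracy", "export_plumed"]

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """All frames carry a single state label; nothing to predict."""


@dataclass
class SPIBConfig:
    """Training configuration.

    ``lag`` is in trajectory steps.  ``prune_fraction`` is the importance
    threshold relative to the strongest CV; ``prune_rounds`` the number of
    fit+prune repetitions.  ``beta`` weighs the variational compression term
    against state-prediction cross-entropy.
    """

    lag: int = 1
    latent_dim: int = 2
    prune_fraction: float = 0.25
    prune_rounds: int = 3
    epochs_per_iter: int = 60
    max_relabel_iters: int = 8
    relabel_tol: float = 0.01
    learning_rate: float = 0.05
    beta: float = 0.01
    batch_size: int = 0  # 0 = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0 < self.prune_fraction < 1:
            raise ValueError("prune_fraction must be in (0, 1)")
        if self.prune_rounds < 1:
            raise ValueError("prune_rounds must be >= 1")


@dataclass
class IBModel:
    """A trained information-bottleneck encoder/decoder.

    ``enc_w`` acts on standardized CVs: mu = enc_w @ (x - mean)/sd + enc_b.
    ``state_labels`` are the converged per-frame labels (internal ids into
    ``label_values``, the surviving original label values).
    """

    cv_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    enc_w: np.ndarray          # (latent_dim, n_cv)
    enc_b: np.ndarray          # (latent_dim,)
    log_sigma: np.ndarray      # (latent_dim,)
    dec_w: np.ndarray          # (n_states, latent_dim)
    dec_b: np.ndarray          # (n_states,)
    prior_centers: np.ndarray  # (n_states, latent_dim)
    state_labels: np.ndarray   # per-frame internal ids
    label_values: list         # internal id -> original label value
    history: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.label_values)

    @property
    def latent_dim(self) -> int:
        return self.enc_w.shape[0]

    def feature_importance(self) -> np.ndarray:
        """Per-CV importance: max over latent dims of |standardized weight|."""
        return np.max(np.abs(self.enc_w), axis=0)

    def save(self, path: str | Path) -> None:
        payload = {
            "cv_names": self.cv_names,
            "mean": self.mean.tolist(), "sd": self.sd.tolist(),
            "enc_w": self.enc_w.tolist(), "enc_b": self.enc_b.tolist(),
            "log_sigma": self.log_sigma.tolist(),
            "dec_w": self.dec_w.tolist(), "dec_b": self.dec_b.tolist(),
            "prior_centers": self.prior_centers.tolist(),
            "state_labels": np.asarray(self.state_labels).tolist(),
            "label_values": [str(v) for v in self.label_values],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "IBModel":
        p = json.loads(Path(path).read_text())
        return cls(cv_names=p["cv_names"], mean=np.array(p["mean"]),
                   sd=np.array(p["sd"]), enc_w=np.array(p["enc_w"]),
                   enc_b=np.array(p["enc_b"]), log_sigma=np.array(p["log_sigma"]),
                   dec_w=np.array(p["dec_w"]), dec_b=np.array(p["dec_b"]),
                   prior_centers=np.array(p["prior_centers"]),
                   state_labels=np.array(p["state_labels"], dtype=int),
                   label_values=p["label_values"])


# ---------------------------------------------------------------------------
# numerics


def _softmax(a: np.ndarray) -> np.ndarray:
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _loss_and_grads(params: dict, x: np.ndarray, y_onehot: np.ndarray,
                    beta: float, rng: np.random.Generator) -> tuple[float, float, dict]:
    """One stochastic forward/backward pass; returns (CE, KL, grads)."""
    W, b_e, logs = params["W"], params["b_e"], params["logs"]
    A, b_d, U = params["A"], params["b_d"], params["U"]
    B = x.shape[0]

    mu = x @ W.T + b_e                      # (B, L)
    s = np.exp(logs)
    eps = rng.standard_normal(mu.shape)
    z = mu + s * eps
    logits = z @ A.T + b_d
    p = _softmax(logits)
    ce = -np.mean(np.sum(y_onehot * np.log(p + 1e-300), axis=1))

    # mixture-prior KL, single-sample estimate
    # log q(z|x) = sum_d [-0.5 log 2pi - logs_d - 0.5 eps_d^2]
    L = mu.shape[1]
    lq = -0.5 * L * np.log(2 * np.pi) - logs.sum() - 0.5 * (eps**2).sum(axis=1)
    diff = z[:, None, :] - U[None, :, :]    # (B, M, L)
    g = -0.5 * (diff**2).sum(axis=2)        # (B, M)
    gmax = g.max(axis=1, keepdims=True)
    lr_ = (gmax[:, 0] + np.log(np.exp(g - gmax).sum(axis=1))
           - 0.5 * L * np.log(2 * np.pi) - np.log(U.shape[0]))
    kl = float(np.mean(lq - lr_))

    # backward
    dlogits = (p - y_onehot) / B
    gA = dlogits.T @ z
    gb_d = dlogits.sum(axis=0)
    dz = dlogits @ A

    r = _softmax(g)                          # (B, M) responsibilities
    # d(-lr)/dz = z - sum_k r_k u_k
    dz = dz + beta / B * (z - r @ U)
    gU = -beta / B * np.einsum("bm,bml->ml", r, diff)

    gW = dz.T @ x
    gb_e = dz.sum(axis=0)
    glogs = (dz * eps).sum(axis=0) * s - beta  # chain z=mu+s*eps, + d(lq)/dlogs
    loss_grads = {"W": gW, "b_e": gb_e, "logs": glogs,
                  "A": gA, "b_d": gb_d, "U": gU}
    return ce, kl, loss_grads


def _predict_states(params: dict, x: np.ndarray) -> np.ndarray:
    mu = x @ params["W"].T + params["b_e"]
    logits = mu @ params["A"].T + params["b_d"]
    return np.argmax(logits, axis=1)


# ---------------------------------------------------------------------------
# operations


def spib_fit(traj: np.ndarray, labels: np.ndarray, cfg: SPIBConfig,
             cv_names: list[str] | None = None) -> IBModel:
    """Train one SPIB model on a CV trajectory.

    ``traj``: (T, D) raw CV values, time-ordered.  ``labels``: length-T
    initial per-frame state labels (any hashable values; frames labelled
    ``None`` — e.g. Dunbrack GAP frames — contribute as encoder inputs but
    never as prediction targets).  Relabeling iterates until fewer than
    ``relabel_tol`` of frames change or ``max_relabel_iters`` is reached.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    T, D = traj.shape
    if T <= cfg.lag:
        raise ValueError(f"trajectory length {T} must exceed lag {cfg.lag}")
    if cv_names is None:
        cv_names = [f"cv{i}" for i in range(D)]

    labels = np.asarray(labels, dtype=object)
    valid_values = sorted({v for v in labels if v is not None}, key=str)
    if len(valid_values) < 2:
        raise DegenerateLabelsError(
            f"degenerate-labels: need >= 2 states, got {valid_values}")
    value_to_id = {v: i for i, v in enumerate(valid_values)}
    ids = np.array([value_to_id.get(v, -1) for v in labels], dtype=int)
    K = len(valid_values)

    mean = traj.mean(axis=0)
    sd = traj.std(axis=0)
    sd[sd == 0] = 1.0
    xstd = (traj - mean) / sd

    rng = np.random.default_rng(cfg.seed)
    L = cfg.latent_dim
    params = {
        "W": rng.normal(0, 0.1, size=(L, D)),
        "b_e": np.zeros(L),
        "logs": np.full(L, -1.0),
        "A": rng.normal(0, 0.1, size=(K, L)),
        "b_d": np.zeros(K),
        "U": rng.normal(0, 1.0, size=(K, L)),
    }
    opt = _Adam(params, cfg.learning_rate)

    cur = ids.copy()
    occupied = np.unique(cur[cur >= 0])
    history = {"relabel_changes": [], "occupied_states": [int(occupied.size)],
               "ce": [], "kl": []}

    for it in range(cfg.max_relabel_iters):
        # training pairs: input frame t, target = current label of t+lag
        tgt = cur[cfg.lag:]
        keep = tgt >= 0
        x_in = xstd[:-cfg.lag][keep]
        y_ids = tgt[keep]
        y_onehot = np.zeros((y_ids.size, K))
        y_onehot[np.arange(y_ids.size), y_ids] = 1.0

        n = x_in.shape[0]
        bs = n if cfg.batch_size in (0, None) or cfg.batch_size >= n else cfg.batch_size
        for _ in range(cfg.epochs_per_iter):
            if bs == n:
                ce, kl, grads = _loss_and_grads(params, x_in, y_onehot, cfg.beta, rng)
                opt.step(params, grads)
            else:
                perm = rng.permutation(n)
                for start in range(0, n, bs):
                    sl = perm[start:start + bs]
                    ce, kl, grads = _loss_and_grads(params, x_in[sl],
                                                    y_onehot[sl], cfg.beta, rng)
                    opt.step(params, grads)
        history["ce"].append(float(ce))
        history["kl"].append(float(kl))

        # relabel with the deterministic (mean) encoder, restricted to the
        # currently occupied states so states can merge but never split
        mu = xstd @ params["W"].T + params["b_e"]
        logits = mu @ params["A"].T + params["b_d"]
        masked = np.full_like(logits, -np.inf)
        masked[:, occupied] = logits[:, occupied]
        new = np.argmax(masked, axis=1)
        changed = float(np.mean(new != np.where(cur >= 0, cur, new)))
        history["relabel_changes"].append(changed)
        cur = new
        occupied = np.unique(cur)
        history["occupied_states"].append(int(occupied.size))
        logger.debug("relabel iter %d: %.3f%% changed, %d states occupied",
                     it, 100 * changed, occupied.size)
        if changed < cfg.relabel_tol:
            break

    # compact to surviving states
    surviving = np.unique(cur)
    remap = {int(old): i for i, old in enumerate(surviving)}
    final_labels = np.array([remap[int(v)] for v in cur], dtype=int)
    model = IBModel(
        cv_names=list(cv_names), mean=mean, sd=sd,
        enc_w=params["W"].copy(), enc_b=params["b_e"].copy(),
        log_sigma=params["logs"].copy(),
        dec_w=params["A"][surviving].copy(), dec_b=params["b_d"][surviving].copy(),
        prior_centers=params["U"][surviving].copy(),
        state_labels=final_labels,
        label_values=[valid_values[int(v)] for v in surviving],
        history=history,
    )
    return model


def prune_features(model: IBModel, cfg: SPIBConfig) -> np.ndarray:
    """Indices of CVs whose importance is >= prune_fraction x the maximum.

    The strongest CV always survives, so the retained set is never empty.
    """
    imp = model.feature_importance()
    return np.where(imp >= cfg.prune_fraction * imp.max())[0]


def spib_refine_loop(traj: np.ndarray, labels: np.ndarray, cfg: SPIBConfig,
                     cv_names: list[str] | None = None,
                     ) -> tuple[IBModel, np.ndarray]:
    """Fit + prune for ``cfg.prune_rounds`` rounds.

    Returns the final model (trained on the surviving CVs) and the indices
    of those CVs into the original CV set.  The CV count is non-increasing
    across rounds, and by construction every surviving importance in the
    final model is >= prune_fraction x max.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if cv_names is None:
        cv_names = [f"cv{i}" for i in range(traj.shape[1])]
    retained = np.arange(traj.shape[1])
    model = None
    for round_i in range(cfg.prune_rounds):
        round_cfg = replace(cfg, seed=cfg.seed + round_i)
        model = spib_fit(traj[:, retained], labels, round_cfg,
                         cv_names=[cv_names[i] for i in retained])
        keep = prune_features(model, cfg)
        logger.info("refine round %d: %d -> %d CVs", round_i + 1,
                    retained.size, keep.size)
        if keep.size == retained.size:
            retained = retained[keep]
            continue
        retained = retained[keep]
    # refit on the final CV set only if the last prune removed something
    if model is not None and len(model.cv_names) != retained.size:
        model = spib_fit(traj[:, retained], labels,
                         replace(cfg, seed=cfg.seed + cfg.prune_rounds),
                         cv_names=[cv_names[i] for i in retained])
    return model, retained


def project(model: IBModel, frames: np.ndarray) -> np.ndarray:
    """Deterministic mean-encoder projection of raw CV frames to IB space."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if frames.shape[1] != len(model.cv_names):
        raise ValueError(f"cv-set mismatch: model expects {len(model.cv_names)} "
                         f"CVs {model.cv_names}, got {frames.shape[1]}")
    xstd = (frames - model.mean) / model.sd
    return xstd @ model.enc_w.T + model.enc_b


def ib_jacobian(model: IBModel) -> np.ndarray:
    """d(IB)/d(raw CV): constant (latent_dim, n_cv) matrix for the linear
    encoder, enc_w scaled by the inverse standardization sd."""
    return model.enc_w / model.sd[None, :]


def label_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    """Best-permutation (Hungarian) agreement between two label sequences;
    state ids are arbitrary so labels are matched before scoring."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    t_vals = {v: i for i, v in enumerate(np.unique(truth))}
    p_vals = {v: i for i, v in enumerate(np.unique(pred))}
    conf = np.zeros((len(t_vals), len(p_vals)))
    for t, p in zip(truth, pred):
        conf[t_vals[t], p_vals[p]] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / truth.size)


def export_plumed(model: IBModel, label: str = "ib") -> str:
    """Render the learned linear OP as PLUMED COMBINE lines.

    The standardization is folded into the coefficients; the constant
    encoder offset only shifts the OP and is irrelevant for biasing, so the
    PARAMETERS recentre each CV at its training mean.
    """
    jac = ib_jacobian(model)
    lines = []
    args = ",".join(model.cv_names)
    params = ",".join(f"{m:.10g}" for m in model.mean)
    for d in range(model.latent_dim):
        coeffs = ",".join(f"{c:.10g}" for c in jac[d])
        lines.append(f"{label}{d + 1}: COMBINE ARG={args} COEFFICIENTS={coeffs} "
                     f"PARAMETERS={params} PERIODIC=NO")
    return "\n".join(lines) + "\n"
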