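# Methods

This note documents the models, numerical choices and limitations behind
`spibmetad`. Energies are in units of kBT throughout (kBT = 1 internally;
temperatures in Kelvin appear only as config metadata).

## Collective variables and DFG classification

CVs are inter-residue atom-pair distances in Å, defined by a user-supplied
schema (YAML) with 1-based residue numbering. Cβ requests on glycine fall
back to Cα with a logged note, the standard structural-biology convention.
The two Dunbrack distances must be present under the names `d1` and `d2`.

The DFG rule is implemented as four open quadrants plus an explicit `GAP`
label. The published quadrant thresholds (11 Å / 14 Å, units taken as Å —
Dunbrack-style Cβ distances are always reported in Å) leave the band
d₁ < 11, 11 ≤ d₂ ≤ 14 uncovered, and the printed definitions of DFG-out
and unassigned overlap for d₁ > 11, 11 < d₂ < 14; we resolve the overlap by
requiring d₂ > 14 for unassigned and route the remaining band and all exact
boundary equalities to `GAP`. Auditable is better than silently merged:
`GAP` frames are excluded from state-population normalization and reported
as separate mass.

The broken-bond filter rejects a structure iff any consecutive Cα–Cα
distance leaves [2.5, 4.5] Å — a window bracketing the 3.8 Å trans spacing.
Standardization uses the population (1/N) standard deviation; the (mean, sd)
pair is retained so the identical affine map can be applied to other
sequences and inverted exactly.

## Regular-space clustering

Single pass in frame order; the first frame is a center and a frame becomes
a new center iff its distance to every existing center is ≥ dmin (closed
rule, so results are bit-reproducible). Assignment is to the nearest center
with ties to the lower index. The pass is order-sensitive by construction;
a seeded shuffle flag exists for sensitivity analysis, and the
post-conditions (center separation, coverage) hold under any order. The
default dmin = 9 applies to full standardized kinase CV sets (tens of
dimensions); the shipped demo, with 6 CVs, uses dmin = 2 in its config.

## SPIB

The trainable model is deliberately small:

* **Encoder** — linear on standardized CVs, mu = W x_std + b, latent
  dimension 2, with a learnable state-independent diagonal log-variance.
  Linearity is a design choice, not a limitation of the idea: it makes the
  learned order parameter a plain linear combination of CVs, exportable to
  any biasing engine (PLUMED COMBINE) and differentiable for bias forces.
* **Decoder** — linear-softmax over the occupied states, predicting the
  state label at t + Δt from the latent at t.
* **Prior** — a learnable Gaussian-mixture over the latent (one unit-width
  component per initial state); the single-sample KL estimate against this
  mixture is the compression term, weighted by β = 0.01.

Training is full-batch Adam (lr 0.05) on hand-derived gradients in float64
with a seeded generator — runs are bit-reproducible. Every
`epochs_per_iter` (60) epochs, frames are relabelled with the deterministic
encoder's most probable state, restricted to currently occupied states so
the state count is non-increasing (merge, never split); iteration stops when
under 1% of frames change. Initial labels default to Dunbrack states
(`GAP` frames carry no prediction target but still serve as encoder inputs).

The lag Δt is a config parameter (demo: 5 recorded frames). Feature
importance is max over the two latent dimensions of |weight| on
standardized inputs (so scales are comparable); a CV survives a prune round
iff its importance is ≥ 0.25 × the maximum, and fit + prune runs 3 rounds.
Accuracy metrics use best-permutation (Hungarian) label matching since
state ids are arbitrary.

## Well-tempered metadynamics and the static bias

The bias is an ordered Gaussian-kernel sum (exact serialization to a
HILLS-dialect table at full float64 precision, `%.17g`). Deposits scale as
w₀·exp(−V/( (γ−1) kBT )); the free-energy estimator is
F̂ = −(γ/(γ−1))·V + const. Defaults: w₀ = 1.2 kBT, γ = 10, pace 500
steps, widths 0.1 × the latent range of the unbiased ensemble, 5 walkers —
all config-exposed, none prescribed by the transfer idea itself. Walkers
advance in lockstep as one vectorized batch over a shared kernel list and
deposit in walker order, so one shared-bias walker is bit-identical to the
single-walker path.

Stop rules are per walker: the target state (the opposite DFG basin, or
either main basin for walkers started in DFG-inter) must hold for
`stability_window` consecutive steps — the desk-scale analog of requiring a
transition that stays stable for a fixed physical time. Hitting the step
cap flags the walker `unconverged`, never raises.

An optional **grid cache** stores V and ∇V on a regular grid (exact at
nodes, multilinear between). With node spacing ≤ 0.3 of the smallest kernel
width the value error is well under 1% of a kernel height and the force
error a few percent relative — negligible against the thermal noise — while
per-step cost becomes independent of the kernel count. The kernel list
remains authoritative: deposit heights and serialization always use exact
summation. No wall potentials are applied by default.

Freezing sets an immutability flag; deposits on a frozen bias raise.
Transfer runs start walkers in both main basins of the (possibly perturbed)
system under the frozen bias and run to opposite-basin stability or cap.

## Reweighting

Under a frozen bias the importance weights are w_t = exp(+V(s_t)/kBT),
max-shifted before exponentiation and normalized to mean 1; the Kish
effective sample size is logged. Time-dependent-bias rewinding is
deliberately out of scope — the frozen bias makes it unnecessary and avoids
its normalization pitfalls. PMFs on the Dunbrack plane use 0.25 Å bins over
[6, 20] Å by default; empty bins are flagged unsampled (NaN), not zero.
ΔG = G(in) − G(out) = −kBT·ln(P_in/P_out), computed per trajectory and
reported as mean ± sample sd (n−1) over trajectories; with this sign a
system whose inactive state is more stable has ΔG > 0. Trajectories with
an empty basin are flagged one-sided and excluded from ΔG statistics with a
warning.

## Toy systems and what they do (not) show

* `double_well_1d` / `tilted_double_well_1d`: U = a(x²−1)² (+ εx), barrier
  a in kBT; the tilt is solved numerically so the quadrature ΔG between
  half-lines hits a requested value.
* `kinase_mimic_2d`: U = −ln Σ πₖ N(x; cₖ, w²I) on the (d₁, d₂) plane with
  basins at IN (9.5, 15.5), OUT (13, 10) and INTER (9.5, 9.5) Å — inside
  the classification regions — so the Boltzmann density is exactly the
  mixture; the internal weight ratio is solved so the quadrature
  ΔG(in−out) over the Dunbrack regions matches the target to ~1e-3 kBT
  (Gaussian tails leak across region boundaries, so weights alone are not
  exact). Default width 0.7 Å puts inter-basin barriers near 8 kBT.
* `mueller_like_2d`: a scaled Müller-Brown-type surface for rough-landscape
  experiments.

State free energies come from quadrature (adaptive in 1-D, a 600² grid in
2-D). The BAOAB integrator (unit mass, friction γf, step h) uses the
standard B-A-O-A-B splitting with exact OU coefficients; a divergence guard
names the offending step.

The synthetic ensemble generator draws (d₁, d₂) plus auxiliary CVs from a
three-mode Gaussian mixture (default 1280 structures, mirroring a
128-seed × 5-structure × 2-depth prediction campaign; mode weights
0.55/0.30/0.15 for in/out/inter — a prediction-biased, not Boltzmann,
composition) and injects a configurable fraction (5%) of broken backbones.
It emulates only what downstream stages consume — multimodal CV vectors
with defects — and makes no claim of reproducing real predictor statistics:
passing tests demonstrate the machinery (filtering, classification,
clustering, OP learning, biasing, reweighting) is correct on a system whose
answer is known, not that any particular protein's ensemble is predicted.

## Validation experiments and problem sizes

The closed-loop experiments in `spibmetad.validation` use sizes chosen for
clear statistical margin at desk scale:

* FES convergence: one walker, 6×10⁵ steps (w₀ 0.5, γ 8, pace 200) on the
  8 kBT double well; RMSE against the analytic F over the central 99% of
  visited positions, offset-aligned.
* ΔG recovery: one static bias learned on the symmetric well (3×10⁵
  steps), transferred to tilts ΔG ∈ {−1…+1} kBT; 5 walkers × 10⁵ steps
  each; oracle by quadrature.
* Sign-flip transfer: one bias learned on the +0.5 kBT kinase mimic
  (5 shared walkers, 1.5×10⁵ steps), frozen, applied to the −0.4 kBT
  variant for 10 transfer seeds (5 walkers × 10⁵ steps each).
* SPIB: 4×10³-frame two-well trajectory, 3 informative + 17 noise CVs,
  3 prune rounds.

## Known limitations

* The linear encoder cannot represent order parameters that are genuinely
  nonlinear functions of the CV basis; the intended remedy is a richer CV
  basis, not a deeper encoder.
* Lag-pair construction concatenates trajectories, so a lag-sized sliver of
  cross-trajectory pairs exists (negligible at shipped lengths).
* Single-trajectory ΔG estimates on flattened surfaces have kBT-scale
  spread at desk lengths; conclusions should use the multi-trajectory mean
  ± sd, as the protocol does.
* The pipeline biases only CVs that are dynamical coordinates of the toy
  engine; non-dynamical CVs surviving pruning are held at their training
  mean and exert no force (warned about in logs).
* No replica exchange, no wall potentials, no time-dependent-bias
  reweighting, no all-atom MD: file-level interoperation with PLUMED is
  supported, runtime linkage is not.
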