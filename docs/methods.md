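# Methods

## The method in brief

Neural potentials map a molecular geometry (element numbers `Z`, Cartesian
coordinates `X` in Å) to a potential energy (kcal/mol). Labeled energies are
expensive, so `denopot` implements denoise pretraining on unlabeled
nonequilibrium conformations: every atomic coordinate of a sampled
conformation is perturbed with i.i.d. Gaussian noise ε ~ N(0, σ²I), and a
message-passing network is trained to predict ε from the perturbed geometry
X̂ = X + ε by minimizing the mean squared error over all 3N coordinate
components. If the conformation distribution around X is approximated as a
Gaussian with scale σ, the Bayes-optimal predictor of the noise is
proportional to −∇ log p(X̂) — a pseudoforce field pointing back toward
lower-energy geometry — so denoising teaches the network local potential
structure without a single energy label. The pretrained message-passing
layers are then transferred, a fresh MLP energy head is attached, and the
whole model is fine-tuned on labeled energies.

## Backbones

Two message-passing architectures are implemented over a radius graph
(default cutoff 5.0 Å, strict `d < d_cut`; the graph is rebuilt from the
perturbed coordinates during pretraining since noise can change the
neighbor set):

* **invariant_conv** — continuous-filter convolutions in the SchNet family:
  messages are `(linear map of neighbor features) ⊙ (filter MLP of a
  Gaussian radial basis)`. The radial basis has evenly spaced centers on
  `[0, d_cut]`, width equal to the spacing, and a cosine envelope
  `½(cos(πd/d_cut)+1)` so every filter (and its derivative) vanishes
  smoothly at the cutoff — important because the noise head differentiates
  the energy with respect to coordinates. All geometry enters through
  distances, so scalar outputs are E(3)-invariant.
* **equivariant_egnn** — an EGNN-style network: messages are an MLP of both
  endpoint features and the squared distance; coordinates are updated each
  layer by a neighbor-normalized (`C = 1/|N(i)|`) linear combination of unit
  direction vectors, and a per-atom vector feature channel accumulates the
  same way. Only scaling and linear combination touch vectors, preserving
  rotation equivariance exactly (verified to float64 round-off in tests).

Feature updates are residual (`h ← h + MLP(h, Σm)`); per-conformation
energies are an MLP of the sum-pooled final features. Element embeddings
are a lookup table over atomic number (size 100).

Noise heads: the invariant model predicts ε̂ = −∂Ê/∂X̂ by automatic
differentiation (the predicted field is conservative by construction and
sums to zero per conformation — a structural mismatch with i.i.d. noise,
whose sum is almost surely nonzero, that we note and do not correct); the
equivariant model uses either the coordinate displacement accumulated
across layers (default) or a gated equivariant readout of the vector
features. The final linear layers of all vector/coordinate pathways are
zero-initialized so an untrained model predicts exactly zero noise.

Everything runs on an in-package reverse-mode automatic-differentiation
engine over float64 numpy arrays. Its backward pass emits graph operations,
so gradients of gradients work — training through −∂Ê/∂X̂ requires exactly
that. The engine is validated against central finite differences at first
and second order.

## Synthetic benchmark

The generator stands in for quantum-chemistry conformer datasets: random
chain-topology molecules (5–9 atoms from {H, C, N, O}; chains guarantee a
connected graph) with harmonic bonds (k_b ∈ [50, 500] kcal/mol/Å²,
r₀ ∈ [0.9, 1.6] Å), harmonic angles (k_a ∈ [20, 100] kcal/mol/rad²,
θ₀ ∈ [1.6, 2.2] rad), and Lennard-Jones terms (ε ∈ [0.05, 0.3] kcal/mol,
σ_LJ ∈ [2.5, 3.5] Å) on all pairs not sharing a bond or angle. Each
molecule is minimized (L-BFGS on the analytic gradient), then
nonequilibrium conformations are sampled:

* **normal-mode sampling** (default): displacements along Hessian
  eigenvectors with coefficients ~ N(0, scale²/λ_q); the six smallest-|λ|
  (rigid-body) modes are excluded. Modes are mass-free (identity mass
  matrix) — labels only need diverse low-energy conformations, not correct
  vibrational dynamics. Default scale 0.1 gives a median energy excess of
  ~0.1–1 kcal/mol over the minimum with tails to a few tens.
* **overdamped Langevin chain** as the dynamics-based alternative:
  `x ← x + (step/γ)F + √(2·step·kT/γ)ξ`.

Large draws along soft modes can land on Lennard-Jones near-clashes with
energies many orders of magnitude above the minimum; curated conformer
datasets contain no such geometries, so draws more than 25 kcal/mol above
the minimum are rejected and redrawn (with the amplitude softened by 0.7
every ten consecutive rejections). The Hessian is a central finite
difference of the analytic forces (step 1e-4 Å), symmetrized.

What the generator does *not* emulate: real electronic-structure energies
(no bond breaking, charge effects, or many-body polarization), torsional
multi-minimum landscapes, element-specific interactions beyond the random
constants, and dataset curation artifacts. Passing results show the
pretraining mechanism works on a smooth physical surface with exact labels;
they do not certify accuracy on DFT data.

## Training protocol

Pretraining splits each molecule's conformations 95/5 into train/validation,
draws fresh noise every epoch, and minimizes the denoising MSE with AdamW
(zero weight decay) under a linear-warmup + cosine-decay schedule; the
best-validation parameter set is kept. Defaults on `PretrainConfig` (σ = 0.2
Å, 5 epochs, batch 256, peak LR 2e-4) reflect the regime of multi-million-
conformation corpora, where 5 epochs mean hundreds of thousands of updates.
On the 10⁴-sample synthetic suite the same settings yield only ~190 updates,
so the *experiment drivers* scale the optimization budget — 10 pretraining
epochs at peak LR 1e-3, 20 fine-tuning epochs at LR 1e-3 with 10% warmup,
gradient-norm clipping at 5 — while σ, the data sizes, and the paired-seed
protocol stay fixed.

Fine-tuning splits conformations per molecule 80/10/10 (seeded shuffle,
largest-remainder rounding), fits a per-element linear energy baseline
`E ≈ Σ_e n_e c_e + b` on the training split only (total energies are
dominated by composition; the model learns the conformational residual; if
the composition design is singular the baseline falls back to the training
mean), transfers the message-passing parameters exactly, attaches a freshly
initialized head, and fine-tunes everything (nothing frozen) with MSE loss.
Model selection uses validation MAE; the test set is untouched until the
final evaluation. Metrics are RMSE, MAE, and per-atom MAE in kcal/mol on
baseline-inverted (raw) energies.

The desk-scale benchmark is 20 pretraining molecules × 500 conformations
and 8 disjoint fine-tuning molecules × 300 conformations, with ≥3 paired
seeds: the scratch arm shares every setting and seed with the pretrained
arm except the initial backbone weights.

## Numerical choices

* Data layer float64 throughout; symmetry checks asserted at 1e-5
  (model-scale tolerance), data-layer identities at 1e-9.
* Strict inequality at the cutoff; matches the cosine envelope vanishing
  at `d_cut`, so the boundary pair contributes nothing either way.
* Bayes denoiser for Gaussian data N(μ, σ_d²) + noise N(0, σ_n²):
  E[ε|x̂] = σ_n²(x̂−μ)/(σ_d²+σ_n²); a `standardized` flag divides by σ_n
  for the ε/σ convention. The pretraining target is the raw noise ε.
* Normal-mode sampling eigenvalue floor 1e-6; fewer than 7 degrees of
  freedom falls back to Langevin sampling with a warning.
* The gated equivariant readout adds 1e-12 inside the vector-norm square
  root; at zero vector features the gradient is exactly zero, so the
  regularization never biases training.
* Largest-remainder rounding makes 10 conformations at 0.8/0.1/0.1 split
  exactly 8/1/1; a single conformation lands in train with a warning.

## Known limitations

* The toy potential is easy enough that a from-scratch invariant network
  converges fully given ~2× more fine-tuning epochs, after which the
  pretraining advantage disappears — the benefit of transfer lives in the
  limited-data / limited-budget regime, consistent with the data-efficiency
  picture. The equivariant network's advantage is robust across budgets
  (its zero-initialized coordinate pathway must bootstrap from scratch
  otherwise).
* For the same reason the invariant comparison depends on the benchmark
  draw: on suite draws whose fine-tune task is easy enough that the scratch
  model reaches its error floor (test MAE ≈ 0.3 kcal/mol), pretrained and
  scratch tie to within ±1% and the sign of the difference is noise. The
  default benchmark suite avoids this saturation; the equivariant
  improvement is large on every draw we generated.
* The gradient noise head constrains predictions to sum to zero per
  conformation, while the true noise does not; at desk scale this ceiling
  is visible in the pretraining loss.
* Single-noise-scale pretraining only; no diffusion-style σ schedules.
* No periodic boundary conditions, no charges/spin, no force-matching
  fine-tuning.
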