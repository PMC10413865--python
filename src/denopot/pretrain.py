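"""Denoise pretraining: perturb conformations, predict the noise.

Gaussian noise ε ~ N(0, σ²I) is added to every atomic coordinate of a
sampled nonequilibrium conformation; the network is trained to predict ε
from the perturbed geometry X̂ by minimizing the mean squared error over
all 3N coordinate components.  Under a Gaussian approximation of the
conformation distribution around X, the optimal predictor is proportional
to the pseudoforce −∇ log p(X̂), so denoising amounts to learning a score
function that points back toward lower-energy geometries.

Two noise heads are provided:

``gradient``
    For scalar (invariant) backbones: ε̂ = −∂Ê/∂X̂ via automatic
    differentiation.  The predicted field is conservative by construction
    and sums to zero over each conformation.

``displacement`` / ``gated``
    For equivariant backbones: ε̂ is the coordinate displacement X^(T) − X̂
    accumulated across layers, or the output of the gated equivariant
    readout of the final vector features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grad
from .backbones import (
    GNNModel,
    UnsupportedArchitectureError,
    gated_equivariant_readout,
)
from .nn import AdamW, Parameters, warmup_cosine_lr
from .systems import AtomicConformation, ConformationBatch, batch_conformations

__all__ = [
    "PerturbedSample",
    "PretrainConfig",
    "PretrainResult",
    "perturb",
    "perturb_batch",
    "denoise_loss",
    "gradient_noise_head",
    "vector_noise_head",
    "pretrain",
    "closed_form_denoiser",
    "fit_point_denoiser",
]


@dataclass
class PerturbedSample:
    """A conformation, its Gaussian-perturbed copy, and the exact noise."""

    original: AtomicConformation
    perturbed_coordinates: np.ndarray
    noise: np.ndarray
    sigma: float


def perturb(
    conformation: AtomicConformation, sigma: float, rng: np.random.Generator
) -> PerturbedSample:
    """Add i.i.d. N(0, σ²) noise to every coordinate component."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    eps = (
        rng.normal(0.0, sigma, size=conformation.coordinates.shape)
        if sigma > 0
        else np.zeros_like(conformation.coordinates)
    )
    perturbed = conformation.coordinates + eps
    return PerturbedSample(
        original=conformation,
        perturbed_coordinates=perturbed,
        # store the realized difference so X̂ − X == ε bit-exactly
        noise=perturbed - conformation.coordinates,
        sigma=float(sigma),
    )


def perturb_batch(
    conformations: list[AtomicConformation], sigma: float, rng: np.random.Generator
) -> tuple[ConformationBatch, np.ndarray]:
    """Batch the conformations with perturbed coordinates; return the noise."""
    batch = batch_conformations(conformations)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    eps = (
        rng.normal(0.0, sigma, size=batch.coordinates.shape)
        if sigma > 0
        else np.zeros_like(batch.coordinates)
    )
    coords = batch.coordinates + eps
    eps = coords - batch.coordinates  # realized noise, bit-exact difference
    perturbed = ConformationBatch(
        atomic_numbers=batch.atomic_numbers,
        coordinates=coords,
        segment_index=batch.segment_index,
        counts=batch.counts,
        energies=batch.energies,
        molecule_ids=batch.molecule_ids,
        conformation_ids=batch.conformation_ids,
    )
    return perturbed, eps


def denoise_loss(predicted_noise: Tensor, true_noise) -> Tensor:
    """Mean squared difference over all 3N coordinate components."""
    true_noise = ad.astensor(true_noise)
    if predicted_noise.shape != true_noise.shape:
        raise ValueError(
            f"shape mismatch: {predicted_noise.shape} vs {true_noise.shape}"
        )
    diff = predicted_noise - true_noise
    return ad.tmean(diff * diff)


def gradient_noise_head(
    model: GNNModel, perturbed: ConformationBatch
) -> tuple[Tensor, Tensor]:
    """ε̂ = −∂Ê/∂X̂, differentiable a second time for training.

    Returns (predicted noise, coordinate tensor used) so callers can reuse
    the graph.
    """
    if model.config.architecture != "invariant_conv":
        # the gradient head is defined for any scalar-energy model; we route
        # equivariant nets to their native vector heads instead
        raise UnsupportedArchitectureError(
            "gradient noise head is used with the invariant backbone; "
            "use vector_noise_head for equivariant models"
        )
    x_hat = Tensor(perturbed.coordinates)
    x_hat.requires_grad = True
    energies = model.energy(perturbed, coordinates=x_hat)
    (g,) = grad(ad.tsum(energies), [x_hat], create_graph=True)
    return -g, x_hat


def vector_noise_head(
    model: GNNModel, perturbed: ConformationBatch, mode: str = "displacement"
) -> Tensor:
    """Equivariant noise prediction: layer displacement or gated readout."""
    if model.config.architecture != "equivariant_egnn":
        raise UnsupportedArchitectureError(
            "vector noise head needs the equivariant backbone"
        )
    if mode == "displacement":
        state = model.features(perturbed, need_vectors=False)
        return state.x - state.x_input
    if mode == "gated":
        state = model.features(perturbed)
        return gated_equivariant_readout(
            state, model.gated_head, model.config.n_gated_blocks
        )
    raise ValueError(f"unknown vector head mode {mode!r}")


@dataclass
class PretrainConfig:
    sigma: float = 0.2          # Å; noise standard deviation
    epochs: int = 5
    batch_size: int = 256
    max_lr: float = 2e-4
    weight_decay: float = 0.0
    warmup_fraction: float = 0.05
    seed: int = 0
    head: str = "auto"          # gradient | displacement | gated | auto
    scale_by_sigma: bool = False  # predict eps/sigma instead of eps
    val_fraction: float = 0.05  # conformation-level split per molecule
    clip_norm: float | None = 5.0  # global gradient-norm clip

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.epochs < 1 or self.batch_size < 1 or self.max_lr <= 0:
            raise ValueError("epochs, batch_size, max_lr must be positive")


@dataclass
class PretrainResult:
    model: GNNModel
    history: list          # per-epoch dicts: epoch, train_loss, val_loss, lr
    best_val_loss: float
    best_params: dict      # parameter arrays at the best validation epoch
    config: PretrainConfig


def _resolve_head(model: GNNModel, head: str) -> str:
    if head != "auto":
        return head
    return (
        "gradient"
        if model.config.architecture == "invariant_conv"
        else "displacement"
    )


def _predict_noise(model: GNNModel, perturbed: ConformationBatch, head: str) -> Tensor:
    if head == "gradient":
        eps_hat, _ = gradient_noise_head(model, perturbed)
        return eps_hat
    return vector_noise_head(model, perturbed, mode=head)


def _trainable(model: GNNModel, head: str) -> Parameters:
    p = Parameters()
    for k, v in model.backbone.items():
        p[f"backbone.{k}"] = v
    if head == "gradient":
        for k, v in model.energy_head.items():
            p[f"energy_head.{k}"] = v
    elif head == "gated":
        for k, v in model.gated_head.items():
            p[f"gated_head.{k}"] = v
    return p


def pretrain(
    model: GNNModel,
    dataset: dict[str, list[AtomicConformation]],
    config: PretrainConfig,
) -> PretrainResult:
    """Denoise-pretrain ``model`` in place on a molecule → conformations map.

    Conformations of every molecule are split 95/5 (by ``val_fraction``)
    into train/validation; fresh noise is drawn every epoch; AdamW with a
    linear-warmup + cosine-decay schedule minimizes the denoising MSE.  The
    parameter set with the best validation loss is recorded.
    """
    if not dataset or all(len(v) == 0 for v in dataset.values()):
        raise ValueError("empty pretraining dataset")
    head = _resolve_head(model, config.head)
    rng = np.random.default_rng(config.seed)
    train, val = [], []
    for mid in sorted(dataset):
        confs = list(dataset[mid])
        order = rng.permutation(len(confs))
        n_val = int(round(config.val_fraction * len(confs)))
        val.extend(confs[i] for i in order[:n_val])
        train.extend(confs[i] for i in order[n_val:])
    if not train:
        raise ValueError("training split is empty")

    params = _trainable(model, head)
    opt = AdamW(params, weight_decay=config.weight_decay, clip_norm=config.clip_norm)
    steps_per_epoch = max(1, int(np.ceil(len(train) / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs
    step = 0
    history = []
    best_val = np.inf
    best_params = params.as_arrays()

    def batch_loss(confs):
        perturbed, eps = perturb_batch(confs, config.sigma, rng)
        target = eps / config.sigma if config.scale_by_sigma and config.sigma > 0 else eps
        eps_hat = _predict_noise(model, perturbed, head)
        return denoise_loss(eps_hat, target)

    # optimization runs in single precision for speed; parameters are
    # restored to float64 afterwards for evaluation
    params.astype(np.float32)
    try:
        with ad.compute_dtype(np.float32):
            for epoch in range(config.epochs):
                order = rng.permutation(len(train))
                train_losses = []
                for s in range(steps_per_epoch):
                    idx = order[s * config.batch_size : (s + 1) * config.batch_size]
                    if idx.size == 0:
                        continue
                    loss = batch_loss([train[i] for i in idx])
                    opt.lr = warmup_cosine_lr(
                        step, total_steps, config.max_lr, config.warmup_fraction
                    )
                    grads = grad(loss, params.tensors())
                    opt.step({k: g.data for k, g in zip(params, grads)})
                    train_losses.append(loss.item() * idx.size)
                    step += 1
                train_loss = float(np.sum(train_losses) / len(train))
                if val:
                    val_losses = [
                        batch_loss(val[i : i + config.batch_size]).item()
                        * len(val[i : i + config.batch_size])
                        for i in range(0, len(val), config.batch_size)
                    ]
                    val_loss = float(np.sum(val_losses) / len(val))
                else:
                    val_loss = train_loss
                if val_loss < best_val:
                    best_val = val_loss
                    best_params = params.as_arrays()
                history.append(
                    {
                        "epoch": epoch,
                        "train_loss": train_loss,
                        "val_loss": val_loss,
                        "lr": opt.lr,
                    }
                )
    finally:
        params.astype(np.float64)
    best_params = {k: a.astype(np.float64) for k, a in best_params.items()}
    return PretrainResult(
        model=model,
        history=history,
        best_val_loss=float(best_val),
        best_params=best_params,
        config=config,
    )


def closed_form_denoiser(
    mu, sigma_data: float, sigma_noise: float, x_hat, standardized: bool = False
) -> np.ndarray:
    """Bayes-optimal noise prediction for Gaussian data + Gaussian noise.

    For x ~ N(μ, σ_d² I) and ε ~ N(0, σ_n² I) observed as x̂ = x + ε,

        E[ε | x̂] = σ_n² (x̂ − μ) / (σ_d² + σ_n²).

    With ``standardized=True`` the prediction is divided by σ_n, i.e. the
    optimal predictor of the standardized noise ε/σ_n.
    """
    if sigma_noise <= 0:
        raise ValueError("sigma_noise must be positive")
    if sigma_data < 0:
        raise ValueError("sigma_data must be >= 0")
    x_hat = np.asarray(x_hat, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    coef = sigma_noise**2 / (sigma_data**2 + sigma_noise**2)
    out = coef * (x_hat - mu)
    return out / sigma_noise if standardized else out


def fit_point_denoiser(
    mu,
    sigma_data: float,
    sigma_noise: float,
    n_train: int,
    seed: int,
    hidden: int = 32,
    epochs: int = 200,
    lr: float = 1e-2,
) -> "callable":
    """Train a small MLP x̂ → ε̂ on single-point Gaussian data.

    This is the minimal score-matching testbed: with enough data the MLP
    must converge to :func:`closed_form_denoiser`.  Returns a predictor
    mapping an (n, d)-array of x̂ to predicted noise.
    """
    from .nn import init_mlp, mlp_forward

    rng = np.random.default_rng(seed)
    mu = np.atleast_1d(np.asarray(mu, dtype=np.float64))
    d = mu.shape[0]
    x = mu + rng.normal(0.0, sigma_data, size=(n_train, d))
    eps = rng.normal(0.0, sigma_noise, size=(n_train, d))
    x_hat = x + eps

    params = Parameters()
    init_mlp(params, "net", [d, hidden, hidden, d], rng)
    opt = AdamW(params, weight_decay=0.0)
    n_batch = min(512, n_train)
    total = epochs * max(1, n_train // n_batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_train)
        for s in range(0, n_train, n_batch):
            idx = order[s : s + n_batch]
            xb = Tensor(x_hat[idx])
            pred = mlp_forward(params, "net", xb, 3, activation=ad.tanh)
            loss = denoise_loss(pred, eps[idx])
            opt.lr = warmup_cosine_lr(step, total, lr, 0.05)
            grads = grad(loss, params.tensors())
            opt.step({k: g.data for k, g in zip(params, grads)})
            step += 1

    def predict(xq: np.ndarray) -> np.ndarray:
        out = mlp_forward(
            params, "net", Tensor(np.atleast_2d(xq)), 3, activation=ad.tanh
        )
        return out.data

    return predict
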