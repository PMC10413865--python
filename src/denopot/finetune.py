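"""Transfer pretrained message-passing weights and fine-tune for energies.

The pretrained backbone parameters are copied into a fresh model, a new
randomly initialized MLP energy head is attached, and everything is trained
(nothing frozen by default) to predict per-conformation potential energies.
Total energies are dominated by composition, so a per-element linear
baseline fitted on the training split is removed before training and added
back at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, grad
from .backbones import (
    BackboneConfig,
    GNNModel,
    IncompatibleCheckpointError,
    init_energy_head,
    init_gated_head,
)
from .nn import AdamW, Parameters, warmup_cosine_lr
from .systems import AtomicConformation, batch_conformations

__all__ = [
    "FinetuneConfig",
    "EnergyBaseline",
    "EvalReport",
    "split_by_conformation",
    "fit_energy_baseline",
    "transfer_weights",
    "finetune",
    "predict_energies",
]


@dataclass
class FinetuneConfig:
    epochs: int = 10
    batch_size: int = 64
    max_lr: float = 1e-3
    weight_decay: float = 0.0
    warmup_fraction: float = 0.05
    split_ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    baseline_mode: str = "per_element_linear"  # | mean | none
    loss: str = "mse"  # | mae
    clip_norm: float | None = 5.0  # global gradient-norm clip

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.max_lr <= 0:
            raise ValueError("epochs, batch_size, max_lr must be positive")
        if any(r < 0 for r in self.split_ratios) or abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must be non-negative and sum to 1")
        if self.baseline_mode not in ("per_element_linear", "mean", "none"):
            raise ValueError(f"unknown baseline mode {self.baseline_mode!r}")


@dataclass
class EvalReport:
    rmse: float
    mae: float
    per_atom_mae: float
    n_test: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("metrics must be non-negative")
        # root-mean-square >= mean absolute (power-mean inequality)
        if self.n_test >= 1 and np.isfinite(self.rmse) and self.rmse < self.mae - 1e-12:
            raise ValueError("rmse < mae is impossible for a common sample")


def _largest_remainder_sizes(n: int, ratios) -> list[int]:
    raw = [n * r for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - x for s, x in zip(sizes, raw)])  # most negative first
    for k in range(rem):
        sizes[order[k]] += 1
    return sizes


def split_by_conformation(
    dataset: dict[str, list[AtomicConformation]], ratios, seed: int
) -> tuple[list, list, list]:
    """Shuffle each molecule's conformations and partition by ``ratios``
    with largest-remainder rounding.  Parts are disjoint; union = dataset."""
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    rng = np.random.default_rng(seed)
    parts: tuple[list, ...] = tuple([] for _ in ratios)
    for mid in sorted(dataset):
        confs = list(dataset[mid])
        order = rng.permutation(len(confs))
        sizes = _largest_remainder_sizes(len(confs), ratios)
        if len(confs) < len([r for r in ratios if r > 0]):
            warnings.warn(
                f"molecule {mid}: only {len(confs)} conformations; "
                "some splits are empty"
            )
        pos = 0
        for part, size in zip(parts, sizes):
            part.extend(confs[i] for i in order[pos : pos + size])
            pos += size
    return parts


@dataclass
class EnergyBaseline:
    """Composition-linear energy reference: E ≈ Σ_e n_e·c_e + offset."""

    mode: str
    coefficients: dict = field(default_factory=dict)  # element -> kcal/mol
    offset: float = 0.0

    def transform(self, conformations) -> np.ndarray:
        """Baseline-subtracted (residual) energies."""
        return np.array([c.energy - self.reference(c) for c in conformations])

    def reference(self, c: AtomicConformation) -> float:
        ref = self.offset
        for z in c.atomic_numbers:
            ref += self.coefficients.get(int(z), 0.0)
        return ref

    def invert(self, residuals: np.ndarray, conformations) -> np.ndarray:
        return np.asarray(residuals) + np.array(
            [self.reference(c) for c in conformations]
        )


def fit_energy_baseline(train_split, mode: str = "per_element_linear") -> EnergyBaseline:
    """Least-squares per-element baseline (or mean / identity) on train data."""
    if mode == "none":
        return EnergyBaseline(mode="none")
    confs = list(train_split)
    if not confs or any(c.energy is None for c in confs):
        raise ValueError("baseline fitting needs labeled energies")
    energies = np.array([c.energy for c in confs])
    if mode == "mean":
        return EnergyBaseline(mode="mean", offset=float(energies.mean()))
    elements = sorted({int(z) for c in confs for z in c.atomic_numbers})
    design = np.zeros((len(confs), len(elements) + 1))
    for i, c in enumerate(confs):
        for j, e in enumerate(elements):
            design[i, j] = np.sum(c.atomic_numbers == e)
        design[i, -1] = 1.0
    # rank-deficient design (e.g. identical compositions) → mean fallback
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "singular composition design; falling back to mean baseline"
        )
        return EnergyBaseline(mode="mean", offset=float(energies.mean()))
    coef, *_ = np.linalg.lstsq(design, energies, rcond=None)
    return EnergyBaseline(
        mode="per_element_linear",
        coefficients={e: float(c) for e, c in zip(elements, coef[:-1])},
        offset=float(coef[-1]),
    )


def transfer_weights(
    source: GNNModel,
    config: BackboneConfig,
    head_seed: int,
    freeze: bool = False,
) -> GNNModel:
    """Copy message-passing parameters; attach a freshly initialized head.

    By default nothing is frozen: both the transferred layers and the new
    head are fine-tuned.
    """
    if source.config != config:
        from dataclasses import asdict

        diffs = [
            k for k in asdict(config) if asdict(config)[k] != asdict(source.config)[k]
        ]
        raise IncompatibleCheckpointError(
            f"checkpoint config differs in fields: {diffs}"
        )
    rng = np.random.default_rng(head_seed)
    backbone = source.backbone.copy_values()
    if freeze:
        for t in backbone.values():
            t.requires_grad = False
    energy_head = init_energy_head(config, rng)
    gated_head = (
        init_gated_head(config, rng)
        if config.architecture == "equivariant_egnn"
        else None
    )
    return GNNModel(config, backbone, energy_head, gated_head)


def predict_energies(model: GNNModel, conformations, batch_size: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(conformations), batch_size):
        batch = batch_conformations(conformations[i : i + batch_size])
        out.append(model.energy(batch).data)
    return np.concatenate(out)


def finetune(
    model: GNNModel,
    dataset: dict[str, list[AtomicConformation]],
    config: FinetuneConfig,
) -> tuple[GNNModel, EvalReport, dict]:
    """Train on baseline-adjusted energies; report test metrics in kcal/mol.

    The dataset is split per molecule by ``config.split_ratios``; the
    baseline is fitted on the training split only; model selection uses
    validation MAE; the best-validation parameters are restored before the
    test evaluation.  Returns (model, report, extras) where extras carries
    the splits, baseline, and history.
    """
    from .evaluation import rmse_mae, per_atom_mae

    train, val, test = split_by_conformation(dataset, config.split_ratios, config.seed)
    if not train:
        raise ValueError("empty training split")
    if any(c.energy is None for c in train):
        raise ValueError("fine-tuning needs labeled energies")
    baseline = fit_energy_baseline(train, config.baseline_mode)
    y_train = baseline.transform(train)

    params = Parameters()
    for k, v in model.backbone.items():
        if v.requires_grad:
            params[f"backbone.{k}"] = v
    for k, v in model.energy_head.items():
        params[f"energy_head.{k}"] = v
    opt = AdamW(params, weight_decay=config.weight_decay, clip_norm=config.clip_norm)
    rng = np.random.default_rng(config.seed + 1)
    steps_per_epoch = max(1, int(np.ceil(len(train) / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs
    step = 0
    history = []
    best_val = np.inf
    best_params = params.as_arrays()

    def eval_mae(confs, baseline):
        if not confs:
            return np.nan
        pred = baseline.invert(predict_energies(model, confs), confs)
        target = np.array([c.energy for c in confs])
        return float(np.abs(pred - target).mean())

    # single-precision optimization; evaluation below runs in float64
    params.astype(np.float32)
    try:
        with ad.compute_dtype(np.float32):
            for epoch in range(config.epochs):
                order = rng.permutation(len(train))
                losses = []
                for s in range(steps_per_epoch):
                    idx = order[s * config.batch_size : (s + 1) * config.batch_size]
                    if idx.size == 0:
                        continue
                    batch = batch_conformations([train[i] for i in idx])
                    pred = model.energy(batch)
                    target = Tensor(y_train[idx])
                    diff = pred - target
                    if config.loss == "mae":
                        loss = ad.tmean(ad.sqrt(diff * diff + 1e-12))
                    else:
                        loss = ad.tmean(diff * diff)
                    opt.lr = warmup_cosine_lr(
                        step, total_steps, config.max_lr, config.warmup_fraction
                    )
                    grads = grad(loss, params.tensors())
                    opt.step({k: g.data for k, g in zip(params, grads)})
                    losses.append(loss.item() * idx.size)
                    step += 1
                val_mae = eval_mae(val, baseline)
                history.append(
                    {
                        "epoch": epoch,
                        "train_loss": float(np.sum(losses) / len(train)),
                        "val_mae": val_mae,
                        "lr": opt.lr,
                    }
                )
                if np.isnan(val_mae):
                    # no validation data: keep the final parameters
                    best_params = params.as_arrays()
                elif val_mae < best_val:
                    best_val = val_mae
                    best_params = params.as_arrays()
    finally:
        params.astype(np.float64)
    params.load_arrays({k: a.astype(np.float64) for k, a in best_params.items()})

    if test:
        pred = baseline.invert(predict_energies(model, test), test)
        target = np.array([c.energy for c in test])
        rmse, mae = rmse_mae(pred, target)
        pam = per_atom_mae(pred, target, np.array([c.n_atoms for c in test]))
    else:
        rmse = mae = pam = float("nan")
    report = EvalReport(
        rmse=rmse,
        mae=mae,
        per_atom_mae=pam,
        n_test=len(test),
        seed=config.seed,
        config={
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "max_lr": config.max_lr,
            "baseline_mode": config.baseline_mode,
            "split_ratios": list(config.split_ratios),
        },
    )
    extras = {
        "train": train,
        "val": val,
        "test": test,
        "baseline": baseline,
        "history": history,
        "best_val_mae": float(best_val),
    }
    return model, report, extras
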