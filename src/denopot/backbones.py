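"""Invariant and equivariant message-passing backbones.

Two architectures are provided:

``invariant_conv``
    A continuous-filter convolution network in the SchNet family.  Messages
    are an elementwise product between a linear map of the neighbor's scalar
    features and a learned filter of the interatomic distance (Gaussian
    radial basis × cosine cutoff envelope).  All geometric information
    enters through distances only, so every scalar output is E(3)-invariant.

``equivariant_egnn``
    An EGNN-style network.  Messages are an MLP of both endpoint features
    and the squared distance; atom coordinates are updated each layer by a
    neighbor-normalized linear combination of unit direction vectors, and a
    per-atom vectorial feature channel is accumulated the same way.  Only
    scaling and linear combination ever touch vectors, which keeps
    coordinate/vector outputs rotation-equivariant and scalar outputs
    invariant.

Per-conformation energies come from sum-pooling the final scalar features
and applying an MLP; equivariant per-atom vectors come either from the
coordinate displacement accumulated across layers or from a gated
equivariant readout of the vector features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Parameters, init_linear, init_mlp, linear_forward, mlp_forward
from .systems import ConformationBatch, NeighborList, build_neighbor_list

__all__ = [
    "BackboneConfig",
    "BackboneState",
    "GNNModel",
    "UnsupportedArchitectureError",
    "UnknownElementError",
    "IncompatibleCheckpointError",
    "radial_basis",
    "forward_backbone",
    "energy_readout",
    "gated_equivariant_readout",
    "init_model",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


class UnsupportedArchitectureError(TypeError):
    pass


class UnknownElementError(ValueError):
    pass


class IncompatibleCheckpointError(ValueError):
    pass


@dataclass(frozen=True)
class BackboneConfig:
    architecture: str = "equivariant_egnn"  # or "invariant_conv"
    feature_dim: int = 64
    num_layers: int = 4
    d_cut: float = 5.0
    num_radial_basis: int = 50
    max_atomic_number: int = 100
    n_gated_blocks: int = 2

    def __post_init__(self):
        if self.architecture not in ("invariant_conv", "equivariant_egnn"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.feature_dim < 1 or self.num_layers < 1 or self.num_radial_basis < 1:
            raise ValueError("feature_dim, num_layers, num_radial_basis must be >= 1")
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")


@dataclass
class BackboneState:
    """Per-atom features after message passing."""

    h: Tensor  # N×F scalar features
    x: Tensor  # N×3 coordinates (updated by the equivariant net)
    v: Tensor | None  # N×3×F vector features (equivariant only)
    x_input: Tensor  # N×3 coordinates the forward pass started from
    segment_index: np.ndarray
    n_conformations: int
    architecture: str


def radial_basis(distances: Tensor, d_cut: float, num_basis: int) -> Tensor:
    """Gaussian radial basis on [0, d_cut] times the cosine cutoff envelope.

    Centers are evenly spaced, the Gaussian width equals the center spacing,
    and the envelope ½(cos(πd/d_cut)+1) sends every basis value smoothly to
    zero at the cutoff.
    """
    centers = np.linspace(0.0, d_cut, num_basis)
    width = d_cut / max(num_basis - 1, 1)
    d = ad.reshape(distances, (-1, 1))
    delta = d - Tensor(centers[None, :])
    gauss = ad.exp(delta * delta * (-0.5 / width**2))
    envelope = 0.5 * (ad.cos(d * (np.pi / d_cut)) + 1.0)
    return gauss * envelope


def _init_backbone_params(config: BackboneConfig, rng: np.random.Generator) -> Parameters:
    p = Parameters()
    F = config.feature_dim
    emb = rng.normal(0.0, 1.0, size=(config.max_atomic_number + 1, F))
    t = Tensor(emb)
    t.requires_grad = True
    p["embedding"] = t
    for layer in range(config.num_layers):
        base = f"layer{layer}"
        if config.architecture == "invariant_conv":
            init_mlp(p, f"{base}.filter", [config.num_radial_basis, F, F], rng)
            init_linear(p, f"{base}.pre", F, F, rng)
            init_mlp(p, f"{base}.update", [2 * F, F, F], rng)
        else:
            init_mlp(p, f"{base}.message", [2 * F + 1, F, F], rng)
            init_mlp(p, f"{base}.coord", [F, F, 1], rng, zero_last=True)
            init_mlp(p, f"{base}.vec", [F, F, F], rng, zero_last=True)
            init_mlp(p, f"{base}.update", [2 * F, F, F], rng)
    return p


def _invariant_layer(
    p: Parameters, base: str, h: Tensor, rbf: Tensor, nl: NeighborList, n_atoms: int
) -> Tensor:
    filt = mlp_forward(p, f"{base}.filter", rbf, 2, activation=ad.softplus)
    hj = ad.gather(linear_forward(p, f"{base}.pre", h), nl.index_j)
    messages = hj * filt
    agg = ad.segment_sum(messages, nl.index_i, n_atoms)
    return h + mlp_forward(
        p, f"{base}.update", ad.concat([h, agg], axis=1), 2, activation=ad.softplus
    )


def _egnn_layer(
    p: Parameters,
    base: str,
    h: Tensor,
    x: Tensor,
    v: Tensor | None,
    nl: NeighborList,
    n_atoms: int,
) -> tuple[Tensor, Tensor, Tensor | None]:
    xi = ad.gather(x, nl.index_i)
    xj = ad.gather(x, nl.index_j)
    rij = xi - xj
    d2 = ad.tsum(rij * rij, axis=1, keepdims=True)
    d = ad.sqrt(d2)
    rhat = rij / d
    hi = ad.gather(h, nl.index_i)
    hj = ad.gather(h, nl.index_j)
    m = mlp_forward(p, f"{base}.message", ad.concat([hi, hj, d2], axis=1), 2)
    # neighbor-count normalization keeps coordinate updates bounded
    deg_arr = np.zeros((n_atoms, 1))
    np.add.at(deg_arr, nl.index_i, np.ones((nl.n_pairs, 1)))
    inv_deg = Tensor(1.0 / np.maximum(deg_arr, 1.0))
    coord_w = mlp_forward(p, f"{base}.coord", m, 2)  # pairs×1
    dx = ad.segment_sum(rhat * coord_w, nl.index_i, n_atoms) * inv_deg
    if v is not None:
        # vector features feed only the gated readout; skipped when unused
        vec_w = mlp_forward(p, f"{base}.vec", m, 2)  # pairs×F
        dv = (
            ad.segment_sum(
                ad.reshape(rhat, (-1, 3, 1))
                * ad.reshape(vec_w, (-1, 1, vec_w.shape[1])),
                nl.index_i,
                n_atoms,
            )
            * ad.reshape(inv_deg, (-1, 1, 1))
        )
        v = v + dv
    agg = ad.segment_sum(m, nl.index_i, n_atoms)
    h_new = h + mlp_forward(p, f"{base}.update", ad.concat([h, agg], axis=1), 2)
    return h_new, x + dx, v


def forward_backbone(
    config: BackboneConfig,
    params: Parameters,
    batch: ConformationBatch,
    coordinates: Tensor | None = None,
    neighbor_list: NeighborList | None = None,
    need_vectors: bool = True,
) -> BackboneState:
    """Run T message-passing layers and return the final per-atom state.

    ``coordinates`` may be a graph-connected Tensor (for gradient heads);
    otherwise the batch's numpy coordinates are used.  The neighbor list is
    built from the supplied coordinates' values unless given explicitly.
    ``need_vectors=False`` skips the equivariant vector-feature channel
    (used only by the gated readout); scalar features and coordinate
    updates are unaffected.
    """
    if batch.n_atoms == 0:
        raise ValueError("empty batch")
    z = batch.atomic_numbers
    if np.any(z > config.max_atomic_number):
        bad = int(z[z > config.max_atomic_number][0])
        raise UnknownElementError(
            f"atomic number {bad} exceeds embedding table size "
            f"{config.max_atomic_number}"
        )
    x = coordinates if coordinates is not None else Tensor(batch.coordinates)
    if neighbor_list is None:
        geom = ConformationBatch(
            atomic_numbers=batch.atomic_numbers,
            coordinates=np.asarray(x.data),
            segment_index=batch.segment_index,
            counts=batch.counts,
            energies=batch.energies,
        )
        neighbor_list = build_neighbor_list(geom, config.d_cut)
    nl = neighbor_list
    n_atoms = batch.n_atoms
    h = ad.gather(params["embedding"], z)
    if config.architecture == "invariant_conv":
        xi = ad.gather(x, nl.index_i)
        xj = ad.gather(x, nl.index_j)
        rij = xi - xj
        d = ad.sqrt(ad.tsum(rij * rij, axis=1, keepdims=False))
        rbf = radial_basis(d, config.d_cut, config.num_radial_basis)
        for layer in range(config.num_layers):
            h = _invariant_layer(params, f"layer{layer}", h, rbf, nl, n_atoms)
        v = None
        x_out = x
    else:
        v = Tensor(np.zeros((n_atoms, 3, config.feature_dim))) if need_vectors else None
        x_out = x
        for layer in range(config.num_layers):
            h, x_out, v = _egnn_layer(
                params, f"layer{layer}", h, x_out, v, nl, n_atoms
            )
    return BackboneState(
        h=h,
        x=x_out,
        v=v,
        x_input=x,
        segment_index=batch.segment_index,
        n_conformations=batch.n_conformations,
        architecture=config.architecture,
    )


# ---------------------------------------------------------------------------
# readout heads
# ---------------------------------------------------------------------------

def init_energy_head(
    config: BackboneConfig, rng: np.random.Generator, zero_last: bool = False
) -> Parameters:
    F = config.feature_dim
    p = Parameters()
    init_mlp(p, "energy", [F, F, 1], rng, zero_last=zero_last)
    return p


def energy_readout(state: BackboneState, head_params: Parameters) -> Tensor:
    """Sum-pool scalar features per conformation, then an MLP → energy."""
    pooled = ad.segment_sum(state.h, state.segment_index, state.n_conformations)
    e = mlp_forward(head_params, "energy", pooled, 2)
    return ad.reshape(e, (-1,))


def init_gated_head(config: BackboneConfig, rng: np.random.Generator) -> Parameters:
    F = config.feature_dim
    p = Parameters()
    dims = [F] * config.n_gated_blocks + [1]
    for b in range(config.n_gated_blocks):
        fin, fout = dims[b], dims[b + 1]
        last = b == config.n_gated_blocks - 1
        init_linear(p, f"gated{b}.v1", fin, fout, rng, zero=last)
        init_linear(p, f"gated{b}.v2", fin, fout, rng)
        init_mlp(p, f"gated{b}.gate", [fin + fout, F, fout], rng)
    return p


def gated_equivariant_readout(
    state: BackboneState, head_params: Parameters, n_blocks: int = 2
) -> Tensor:
    """Stack of gated equivariant blocks mapping (v, h) → one 3-vector/atom.

    Each block forms two linear channels of the vector features; the norm of
    one channel joins the scalar features in an MLP that gates the other
    channel.  Gates are scalars, so outputs rotate with the input.
    """
    if state.v is None:
        raise UnsupportedArchitectureError(
            "gated equivariant readout needs an equivariant backbone state"
        )
    v, h = state.v, state.h
    for b in range(n_blocks):
        w1 = head_params[f"gated{b}.v1.w"]
        w2 = head_params[f"gated{b}.v2.w"]
        v1 = v @ w1  # N×3×fout
        v2 = v @ w2
        norm = ad.sqrt(ad.tsum(v2 * v2, axis=1) + 1e-12)  # N×fout
        gate_in = ad.concat([h, norm], axis=1)
        gate = mlp_forward(head_params, f"gated{b}.gate", gate_in, 2)
        v = v1 * ad.reshape(gate, (gate.shape[0], 1, gate.shape[1]))
        h = gate  # pass gated scalars forward
    return ad.reshape(v, (-1, 3))


# ---------------------------------------------------------------------------
# model container and checkpoints
# ---------------------------------------------------------------------------

@dataclass
class GNNModel:
    """Backbone + energy head (+ gated head for equivariant nets)."""

    config: BackboneConfig
    backbone: Parameters
    energy_head: Parameters
    gated_head: Parameters | None = None

    def all_params(self) -> Parameters:
        p = Parameters()
        for k, v in self.backbone.items():
            p[f"backbone.{k}"] = v
        for k, v in self.energy_head.items():
            p[f"energy_head.{k}"] = v
        if self.gated_head is not None:
            for k, v in self.gated_head.items():
                p[f"gated_head.{k}"] = v
        return p

    def features(
        self, batch: ConformationBatch, coordinates: Tensor | None = None,
        neighbor_list=None, need_vectors: bool = True,
    ) -> BackboneState:
        return forward_backbone(
            self.config, self.backbone, batch, coordinates, neighbor_list,
            need_vectors=need_vectors,
        )

    def energy(
        self, batch: ConformationBatch, coordinates: Tensor | None = None,
        neighbor_list=None,
    ) -> Tensor:
        state = self.features(batch, coordinates, neighbor_list,
                              need_vectors=False)
        return energy_readout(state, self.energy_head)


def init_model(config: BackboneConfig, seed: int, zero_head: bool = False) -> GNNModel:
    """Fresh model; ``zero_head=True`` zero-initializes the last energy-head
    layer so noise heads start at exactly zero prediction (pretraining)."""
    rng = np.random.default_rng(seed)
    backbone = _init_backbone_params(config, rng)
    energy_head = init_energy_head(config, rng, zero_last=zero_head)
    gated_head = (
        init_gated_head(config, rng)
        if config.architecture == "equivariant_egnn"
        else None
    )
    return GNNModel(config, backbone, energy_head, gated_head)


def save_checkpoint(model: GNNModel, path) -> None:
    """Single-file archive: config echo + named parameter arrays + version."""
    path = Path(path)
    arrays = {}
    for k, v in model.all_params().items():
        arrays[k] = v.data
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": asdict(model.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expected_config: BackboneConfig | None = None) -> GNNModel:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        arrays = {k: f[k] for k in f.files if k != "__meta__"}
    config = BackboneConfig(**meta["config"])
    if expected_config is not None and config != expected_config:
        diffs = [
            k
            for k in asdict(config)
            if asdict(config)[k] != asdict(expected_config)[k]
        ]
        raise IncompatibleCheckpointError(
            f"checkpoint config differs in fields: {diffs}"
        )
    model = init_model(config, seed=0)
    model.all_params().load_arrays(arrays)
    return model
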