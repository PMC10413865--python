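import numpy as np
import pytest

from denopot.autodiff import Tensor
from denopot.backbones import (
    BackboneConfig,
    IncompatibleCheckpointError,
    UnknownElementError,
    UnsupportedArchitectureError,
    gated_equivariant_readout,
    init_model,
    load_checkpoint,
    radial_basis,
    save_checkpoint,
)
from denopot.evaluation import random_rotation
from denopot.systems import AtomicConformation, batch_conformations


def _random_batch(seed=0, n_confs=2, lo=4, hi=8):
    rng = np.random.default_rng(seed)
    confs = [
        AtomicConformation(
            rng.choice([1, 6, 7, 8], size=n),
            rng.uniform(-2.5, 2.5, size=(n, 3)),
        )
        for n in rng.integers(lo, hi, size=n_confs)
    ]
    return confs, batch_conformations(confs)


class TestBackboneConfig:
    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            BackboneConfig(architecture="se3_transformer")
        with pytest.raises(ValueError):
            BackboneConfig(num_layers=0)
        with pytest.raises(ValueError):
            BackboneConfig(d_cut=-1.0)


class TestRadialBasis:
    def test_envelope_vanishes_at_cutoff(self):
        out = radial_basis(Tensor(np.array([5.0 - 1e-12])), 5.0, 10)
        assert np.abs(out.data).max() < 1e-10

    def test_envelope_is_one_at_zero_distance(self):
        d = Tensor(np.array([1e-15]))
        out = radial_basis(d, 5.0, 10).data
        # first basis center sits at d=0, so its value ≈ envelope = 1
        assert out[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.1, 4.9, size=20)
        d_cut, nb = 5.0, 16
        out = radial_basis(Tensor(d), d_cut, nb).data
        centers = np.linspace(0, d_cut, nb)
        width = d_cut / (nb - 1)
        expected = np.exp(-((d[:, None] - centers) ** 2) / (2 * width**2)) * (
            0.5 * (np.cos(np.pi * d[:, None] / d_cut) + 1)
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestForwardBackbone:
    def test_isolated_atom_gets_self_update_only(self, small_model):
        c = AtomicConformation([6], [[0.0, 0.0, 0.0]])
        batch = batch_conformations([c])
        state = small_model.features(batch)
        assert state.h.shape == (1, small_model.config.feature_dim)
        assert np.all(np.isfinite(state.h.data))

    def test_permuting_atoms_permutes_features(self, small_model):
        confs, batch = _random_batch(seed=1, n_confs=1)
        state = small_model.features(batch)
        rng = np.random.default_rng(5)
        perm = rng.permutation(confs[0].n_atoms)
        permuted = batch_conformations(
            [
                AtomicConformation(
                    confs[0].atomic_numbers[perm], confs[0].coordinates[perm]
                )
            ]
        )
        state_p = small_model.features(permuted)
        np.testing.assert_allclose(
            state_p.h.data, state.h.data[perm], atol=1e-10
        )

    def test_scalar_features_invariant_under_rigid_motion(self, small_model):
        confs, batch = _random_batch(seed=2, n_confs=1)
        state = small_model.features(batch)
        rng = np.random.default_rng(6)
        R = random_rotation(rng)
        t = rng.uniform(-10, 10, 3)
        moved = batch_conformations(
            [AtomicConformation(confs[0].atomic_numbers, confs[0].coordinates @ R.T + t)]
        )
        state_m = small_model.features(moved)
        assert np.abs(state_m.h.data - state.h.data).max() < 1e-5

    def test_batch_independence(self, small_model):
        confs, _ = _random_batch(seed=3, n_confs=2)
        together = small_model.features(batch_conformations(confs))
        separate = [
            small_model.features(batch_conformations([c])) for c in confs
        ]
        split = np.split(together.h.data, [confs[0].n_atoms])
        for part, st in zip(split, separate):
            np.testing.assert_allclose(part, st.h.data, atol=1e-12)

    def test_unknown_element_rejected(self):
        cfg = BackboneConfig(feature_dim=8, num_layers=1, max_atomic_number=10)
        model = init_model(cfg, seed=0)
        c = AtomicConformation([99], [[0.0, 0.0, 0.0]])
        with pytest.raises(UnknownElementError):
            model.features(batch_conformations([c]))


class TestEgnnLayerGeometry:
    def test_symmetric_diatomic_updates_cancel(self):
        cfg = BackboneConfig(
            architecture="equivariant_egnn", feature_dim=8, num_layers=1
        )
        model = init_model(cfg, seed=1)
        # make the coordinate head non-trivial (it is zero-initialized)
        for k, v in model.backbone.items():
            if ".coord." in k and k.endswith(".w"):
                v.data = np.random.default_rng(0).normal(0, 0.5, v.data.shape)
        c = AtomicConformation([6, 6], [[0, 0, 0], [1.2, 0, 0]])
        state = model.features(batch_conformations([c]))
        disp = state.x.data - state.x_input.data
        np.testing.assert_allclose(disp[0], -disp[1], atol=1e-12)
        np.testing.assert_allclose(disp.sum(axis=0), 0.0, atol=1e-12)

    def test_rotation_commutes_with_layer(self):
        cfg = BackboneConfig(
            architecture="equivariant_egnn", feature_dim=8, num_layers=2
        )
        model = init_model(cfg, seed=2)
        for k, v in model.backbone.items():
            if (".coord." in k or ".vec." in k) and k.endswith(".w"):
                v.data = np.random.default_rng(1).normal(0, 0.3, v.data.shape)
        confs, batch = _random_batch(seed=7, n_confs=1)
        state = model.features(batch)
        R = random_rotation(np.random.default_rng(8))
        rotated = batch_conformations(
            [AtomicConformation(confs[0].atomic_numbers, confs[0].coordinates @ R.T)]
        )
        state_r = model.features(rotated)
        np.testing.assert_allclose(
            state_r.x.data, state.x.data @ R.T, atol=1e-5
        )
        np.testing.assert_allclose(state_r.h.data, state.h.data, atol=1e-5)

    def test_translation_acts_additively_on_coordinates(self):
        cfg = BackboneConfig(
            architecture="equivariant_egnn", feature_dim=8, num_layers=2
        )
        model = init_model(cfg, seed=3)
        confs, batch = _random_batch(seed=9, n_confs=1)
        state = model.features(batch)
        t = np.array([3.0, -2.0, 7.0])
        moved = batch_conformations(
            [AtomicConformation(confs[0].atomic_numbers, confs[0].coordinates + t)]
        )
        state_t = model.features(moved)
        np.testing.assert_allclose(state_t.x.data, state.x.data + t, atol=1e-10)
        np.testing.assert_allclose(state_t.h.data, state.h.data, atol=1e-10)


class TestEnergyReadout:
    def test_permutation_invariance(self, small_model):
        confs, batch = _random_batch(seed=4, n_confs=1)
        e = small_model.energy(batch).data
        perm = np.random.default_rng(0).permutation(confs[0].n_atoms)
        batch_p = batch_conformations(
            [AtomicConformation(confs[0].atomic_numbers[perm], confs[0].coordinates[perm])]
        )
        assert small_model.energy(batch_p).data[0] == pytest.approx(e[0], abs=1e-10)

    def test_batched_equals_individual(self, small_model):
        confs, batch = _random_batch(seed=5, n_confs=3, lo=3, hi=7)
        together = small_model.energy(batch).data
        separate = [
            small_model.energy(batch_conformations([c])).data[0] for c in confs
        ]
        np.testing.assert_allclose(together, separate, atol=1e-6)

    def test_rigid_transform_invariance(self, small_model):
        confs, batch = _random_batch(seed=6, n_confs=1)
        e = small_model.energy(batch).data[0]
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        moved = batch_conformations(
            [
                AtomicConformation(
                    confs[0].atomic_numbers,
                    confs[0].coordinates @ R.T + rng.uniform(-10, 10, 3),
                )
            ]
        )
        assert abs(small_model.energy(moved).data[0] - e) < 1e-5


class TestGatedEquivariantReadout:
    def _equivariant_model(self, seed=0):
        cfg = BackboneConfig(
            architecture="equivariant_egnn", feature_dim=8, num_layers=2
        )
        model = init_model(cfg, seed=seed)
        for k, v in model.backbone.items():
            if ".vec." in k and k.endswith(".w"):
                v.data = np.random.default_rng(seed).normal(0, 0.3, v.data.shape)
        for k, v in model.gated_head.items():
            if "v1" in k and k.endswith(".w"):
                v.data = np.random.default_rng(seed + 1).normal(0, 0.3, v.data.shape)
        return model

    def test_zero_vector_features_give_zero_output(self):
        model = self._equivariant_model()
        confs, batch = _random_batch(seed=10, n_confs=1)
        state = model.features(batch)
        state.v = Tensor(np.zeros_like(state.v.data))
        out = gated_equivariant_readout(state, model.gated_head)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_rotation_equivariance(self):
        model = self._equivariant_model(seed=3)
        confs, batch = _random_batch(seed=11, n_confs=1)
        out = gated_equivariant_readout(model.features(batch), model.gated_head).data
        R = random_rotation(np.random.default_rng(12))
        rotated = batch_conformations(
            [AtomicConformation(confs[0].atomic_numbers, confs[0].coordinates @ R.T)]
        )
        out_r = gated_equivariant_readout(
            model.features(rotated), model.gated_head
        ).data
        np.testing.assert_allclose(out_r, out @ R.T, atol=1e-5)

    def test_invariant_state_rejected(self):
        cfg = BackboneConfig(architecture="invariant_conv", feature_dim=8, num_layers=1)
        model = init_model(cfg, seed=0)
        _, batch = _random_batch(seed=13, n_confs=1)
        state = model.features(batch)
        with pytest.raises(UnsupportedArchitectureError):
            gated_equivariant_readout(state, {})


class TestCheckpoints:
    def test_round_trip_preserves_parameters_and_config(self, tmp_path, small_model):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(small_model, path)
        loaded = load_checkpoint(path)
        assert loaded.config == small_model.config
        for k, v in small_model.all_params().items():
            np.testing.assert_array_equal(loaded.all_params()[k].data, v.data)

    def test_config_mismatch_rejected(self, tmp_path, small_model):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(small_model, path)
        other = BackboneConfig(
            architecture=small_model.config.architecture,
            feature_dim=small_model.config.feature_dim * 2,
            num_layers=small_model.config.num_layers,
            num_radial_basis=small_model.config.num_radial_basis,
        )
        with pytest.raises(IncompatibleCheckpointError, match="feature_dim"):
            load_checkpoint(path, expected_config=other)
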