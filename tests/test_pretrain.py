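import numpy as np
import pytest

from denopot.autodiff import Tensor
from denopot.backbones import BackboneConfig, UnsupportedArchitectureError, init_model
from denopot.evaluation import random_rotation
from denopot.pretrain import (
    PretrainConfig,
    closed_form_denoiser,
    denoise_loss,
    gradient_noise_head,
    perturb,
    perturb_batch,
    pretrain,
    vector_noise_head,
)
from denopot.systems import AtomicConformation, ConformationBatch, batch_conformations


def _conf(seed=0, n=6):
    rng = np.random.default_rng(seed)
    return AtomicConformation(
        rng.choice([1, 6, 7, 8], size=n), rng.uniform(-2, 2, size=(n, 3))
    )


class TestPerturb:
    def test_zero_sigma_is_identity(self):
        c = _conf()
        s = perturb(c, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(s.perturbed_coordinates, c.coordinates)
        np.testing.assert_array_equal(s.noise, 0.0)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            perturb(_conf(), -0.1, np.random.default_rng(0))

    def test_default_sigma_is_point_two(self):
        assert PretrainConfig().sigma == 0.2

    def test_noise_variance_matches_sigma(self):
        sigma = 0.3
        c = _conf(n=8)
        rng = np.random.default_rng(1)
        sq = []
        for _ in range(1250):  # 10,000 atoms total
            sq.append(perturb(c, sigma, rng).noise**2)
        assert np.mean(sq) == pytest.approx(sigma**2, rel=0.05)

    def test_original_untouched_and_exact_difference(self):
        c = _conf()
        before = c.coordinates.copy()
        s = perturb(c, 0.5, np.random.default_rng(2))
        np.testing.assert_array_equal(c.coordinates, before)
        np.testing.assert_array_equal(
            s.perturbed_coordinates - c.coordinates, s.noise
        )


class TestDenoiseLoss:
    def test_perfect_prediction_is_zero(self):
        x = Tensor(np.random.default_rng(0).normal(size=(5, 3)))
        assert denoise_loss(x, x.data).item() == 0.0

    def test_constant_error_gives_c_squared(self):
        c = 0.7
        pred = Tensor(np.zeros((4, 3)))
        assert denoise_loss(pred, np.full((4, 3), c)).item() == pytest.approx(c**2)

    def test_matches_brute_force_reduction(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
        expected = np.sum((a - b) ** 2) / a.size
        assert denoise_loss(Tensor(a), b).item() == pytest.approx(expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            denoise_loss(Tensor(np.zeros((3, 3))), np.zeros((4, 3)))

    def test_batch_loss_is_atom_weighted_mean(self):
        rng = np.random.default_rng(2)
        pred = rng.normal(size=(10, 3))
        true = rng.normal(size=(10, 3))
        whole = denoise_loss(Tensor(pred), true).item()
        n1 = 4  # first conformation's atoms
        parts = [
            denoise_loss(Tensor(pred[:n1]), true[:n1]).item(),
            denoise_loss(Tensor(pred[n1:]), true[n1:]).item(),
        ]
        weighted = (parts[0] * n1 + parts[1] * (10 - n1)) / 10
        assert whole == pytest.approx(weighted)


@pytest.fixture
def invariant_model():
    cfg = BackboneConfig(
        architecture="invariant_conv", feature_dim=16, num_layers=2, num_radial_basis=8
    )
    return init_model(cfg, seed=4)


@pytest.fixture
def equivariant_model():
    cfg = BackboneConfig(
        architecture="equivariant_egnn", feature_dim=16, num_layers=2
    )
    model = init_model(cfg, seed=4)
    for k, v in model.backbone.items():
        if (".coord." in k or ".vec." in k) and k.endswith(".w"):
            v.data = np.random.default_rng(3).normal(0, 0.3, v.data.shape)
    return model


class TestGradientNoiseHead:
    def test_matches_finite_differences(self, invariant_model):
        rng = np.random.default_rng(5)
        batch = batch_conformations([_conf(5), _conf(6)])
        eps_hat, _ = gradient_noise_head(invariant_model, batch)
        step = 1e-4
        for i, j in [(0, 0), (3, 1), (8, 2)]:
            xp = batch.coordinates.copy()
            xp[i, j] += step
            xm = batch.coordinates.copy()
            xm[i, j] -= step
            bp = ConformationBatch(
                batch.atomic_numbers, xp, batch.segment_index, batch.counts,
                batch.energies,
            )
            bm = ConformationBatch(
                batch.atomic_numbers, xm, batch.segment_index, batch.counts,
                batch.energies,
            )
            fd = -(
                invariant_model.energy(bp).data.sum()
                - invariant_model.energy(bm).data.sum()
            ) / (2 * step)
            assert eps_hat.data[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_per_conformation_sum_is_zero(self, invariant_model):
        batch = batch_conformations([_conf(7, n=5), _conf(8, n=7)])
        eps_hat, _ = gradient_noise_head(invariant_model, batch)
        for b in range(2):
            seg = batch.segment_index == b
            np.testing.assert_allclose(
                eps_hat.data[seg].sum(axis=0), 0.0, atol=1e-6
            )

    def test_rotation_equivariance(self, invariant_model):
        c = _conf(9)
        batch = batch_conformations([c])
        eps_hat, _ = gradient_noise_head(invariant_model, batch)
        R = random_rotation(np.random.default_rng(10))
        batch_r = batch_conformations(
            [AtomicConformation(c.atomic_numbers, c.coordinates @ R.T)]
        )
        eps_r, _ = gradient_noise_head(invariant_model, batch_r)
        np.testing.assert_allclose(eps_r.data, eps_hat.data @ R.T, atol=1e-5)

    def test_conservative_field_along_closed_loops(self, invariant_model):
        # line integral of a gradient field along a closed 4-point loop ≈ 0
        rng = np.random.default_rng(11)
        c = _conf(12, n=5)
        base = c.coordinates
        deltas = [rng.normal(0, 0.05, base.shape) for _ in range(3)]
        loop = [base, base + deltas[0], base + deltas[1], base + deltas[2], base]
        integral = 0.0
        for a, b in zip(loop[:-1], loop[1:]):
            mid = 0.5 * (a + b)
            batch = batch_conformations([AtomicConformation(c.atomic_numbers, mid)])
            eps_hat, _ = gradient_noise_head(invariant_model, batch)
            integral += np.sum(-eps_hat.data * (b - a))  # field = -eps_hat = dE/dx
        assert abs(integral) < 1e-4 * max(
            1.0, float(np.abs(eps_hat.data).max())
        )

    def test_equivariant_model_rejected(self, equivariant_model):
        batch = batch_conformations([_conf(13)])
        with pytest.raises(UnsupportedArchitectureError):
            gradient_noise_head(equivariant_model, batch)


class TestVectorNoiseHead:
    def test_zero_initialized_heads_predict_zero(self):
        cfg = BackboneConfig(architecture="equivariant_egnn", feature_dim=16, num_layers=2)
        model = init_model(cfg, seed=0)  # coord/vec/gated last layers zero-init
        batch = batch_conformations([_conf(14)])
        for mode in ("displacement", "gated"):
            out = vector_noise_head(model, batch, mode=mode)
            np.testing.assert_array_equal(out.data, 0.0)

    def test_rotation_equivariance(self, equivariant_model):
        c = _conf(15)
        batch = batch_conformations([c])
        R = random_rotation(np.random.default_rng(16))
        batch_r = batch_conformations(
            [AtomicConformation(c.atomic_numbers, c.coordinates @ R.T)]
        )
        for mode in ("displacement", "gated"):
            out = vector_noise_head(equivariant_model, batch, mode=mode)
            out_r = vector_noise_head(equivariant_model, batch_r, mode=mode)
            np.testing.assert_allclose(out_r.data, out.data @ R.T, atol=1e-5)

    def test_translation_invariance(self, equivariant_model):
        c = _conf(17)
        batch = batch_conformations([c])
        out = vector_noise_head(equivariant_model, batch)
        moved = batch_conformations(
            [AtomicConformation(c.atomic_numbers, c.coordinates + np.array([5.0, -3.0, 2.0]))]
        )
        out_t = vector_noise_head(equivariant_model, moved)
        np.testing.assert_allclose(out_t.data, out.data, atol=1e-10)

    def test_invariant_model_rejected(self, invariant_model):
        batch = batch_conformations([_conf(18)])
        with pytest.raises(UnsupportedArchitectureError):
            vector_noise_head(invariant_model, batch)


class TestPretrainLoop:
    def _tiny_data(self):
        rng = np.random.default_rng(20)
        data = {}
        for m in range(2):
            base = _conf(seed=30 + m, n=5)
            confs = []
            for k in range(50):
                confs.append(
                    AtomicConformation(
                        base.atomic_numbers,
                        base.coordinates + rng.normal(0, 0.05, (5, 3)),
                        molecule_id=f"m{m}",
                        conformation_id=str(k),
                    )
                )
            data[f"m{m}"] = confs
        return data

    @pytest.mark.parametrize("arch", ["invariant_conv", "equivariant_egnn"])
    def test_loss_decreases_on_tiny_run(self, arch):
        cfg = BackboneConfig(architecture=arch, feature_dim=16, num_layers=2,
                             num_radial_basis=8)
        model = init_model(cfg, seed=0, zero_head=True)
        result = pretrain(
            model,
            self._tiny_data(),
            PretrainConfig(sigma=0.2, epochs=3, batch_size=32, max_lr=2e-3, seed=1),
        )
        assert result.history[-1]["train_loss"] < result.history[0]["train_loss"]

    def test_sigma_zero_with_zero_init_head_starts_at_zero_loss(self):
        cfg = BackboneConfig(architecture="equivariant_egnn", feature_dim=16,
                             num_layers=2)
        model = init_model(cfg, seed=0, zero_head=True)
        result = pretrain(
            model,
            self._tiny_data(),
            PretrainConfig(sigma=0.0, epochs=1, batch_size=32, max_lr=1e-9, seed=1),
        )
        assert result.history[0]["train_loss"] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_history(self):
        cfg = BackboneConfig(architecture="equivariant_egnn", feature_dim=16,
                             num_layers=2)
        histories = []
        for _ in range(2):
            model = init_model(cfg, seed=0, zero_head=True)
            r = pretrain(
                model,
                self._tiny_data(),
                PretrainConfig(sigma=0.2, epochs=2, batch_size=32, seed=5),
            )
            histories.append(r.history)
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self):
        cfg = BackboneConfig(architecture="equivariant_egnn", feature_dim=8,
                             num_layers=1)
        model = init_model(cfg, seed=0)
        with pytest.raises(ValueError):
            pretrain(model, {}, PretrainConfig())


class TestClosedFormDenoiser:
    def test_at_mean_prediction_is_zero(self):
        out = closed_form_denoiser(np.zeros(3), 1.0, 0.5, np.zeros(3))
        np.testing.assert_array_equal(out, 0.0)

    def test_point_mass_data_limit_returns_full_displacement(self):
        x_hat = np.array([0.3, -0.2, 0.5])
        out = closed_form_denoiser(np.zeros(3), 0.0, 0.5, x_hat)
        np.testing.assert_allclose(out, x_hat)
        out_std = closed_form_denoiser(np.zeros(3), 0.0, 0.5, x_hat, standardized=True)
        np.testing.assert_allclose(out_std, x_hat / 0.5)

    def test_zero_sigma_noise_rejected(self):
        with pytest.raises(ValueError):
            closed_form_denoiser(np.zeros(3), 1.0, 0.0, np.zeros(3))

    def test_monte_carlo_conditional_expectation(self):
        # bin x_hat near a fixed value; E[eps | bin] must match the formula
        mu, sd, sn = 0.0, 0.8, 0.4
        rng = np.random.default_rng(0)
        x = rng.normal(mu, sd, size=1_000_000)
        eps = rng.normal(0, sn, size=1_000_000)
        x_hat = x + eps
        target = 0.7
        sel = np.abs(x_hat - target) < 0.02
        mc = eps[sel].mean()
        formula = closed_form_denoiser(mu, sd, sn, np.array([target]))[0]
        assert mc == pytest.approx(formula, rel=0.02)


class TestPerturbBatch:
    def test_consistency_with_batch(self):
        confs = [_conf(40, n=4), _conf(41, n=6)]
        perturbed, eps = perturb_batch(confs, 0.3, np.random.default_rng(0))
        orig = batch_conformations(confs)
        np.testing.assert_array_equal(
            perturbed.coordinates - orig.coordinates, eps
        )
        np.testing.assert_array_equal(perturbed.segment_index, orig.segment_index)
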