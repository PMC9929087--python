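import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh, hadamard

from saeibs.ibs import degree, ibs_matrix
from saeibs.matrix import GenotypeMatrix, normalize_unit
from saeibs.neural import (
    NetConfig,
    fit_ae,
    fit_d_sae_ibs,
    fit_d_sae_ibs_l,
    fit_dae,
    fit_sae_ibs,
    latent_scores,
    load_model,
    project_ae,
    project_target,
    projection_loss,
    reconstruct,
    save_model,
    svd_bottleneck,
)
from saeibs.simulate import PerturbationSpec, SimConfig, simulate_populations
from .conftest import make_genotypes, make_variants


def hadamard_genotypes(n=12, m=16):
    """Samples with exactly equal pairwise IBS (hence equal degrees)."""
    h = hadamard(m)[:n].astype(np.int8)
    return GenotypeMatrix(h, [f"i{i}" for i in range(n)], make_variants(m))


def tiny_cfg(**kw):
    base = dict(hidden_sizes=(8,), k=2, seed=0, pretrain_epochs=30,
                max_epochs=30, patience=10, batch_size=16)
    base.update(kw)
    return NetConfig(**base)


class TestSvdBottleneck:
    def test_diagonal_matrix(self):
        z, v, s = svd_bottleneck(np.diag([3.0, 2.0]), 2)
        np.testing.assert_allclose(s, [3.0, 2.0])
        np.testing.assert_allclose(np.abs(z), np.diag([3.0, 2.0]), atol=1e-12)

    def test_score_gram_is_sigma_squared(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(15, 8))
        z, v, s = svd_bottleneck(g, 3)
        np.testing.assert_allclose(z.T @ z, np.diag(s**2), atol=1e-10)
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-10)

    def test_matches_eigendecomposition_oracle(self):
        # independent route: eigenvectors of G^T G give the best rank-k
        # reconstruction
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, h = rng.integers(5, 30, size=2)
            k = int(rng.integers(1, min(n, h)))
            g = rng.normal(size=(n, h))
            z, v, s = svd_bottleneck(g, k)
            evals, evecs = eigh(g.T @ g)
            vk = evecs[:, np.argsort(evals)[::-1][:k]]
            oracle = g @ vk @ vk.T
            np.testing.assert_allclose(z @ v.T, oracle, atol=1e-8)

    def test_rank_deficit_strict_flag(self):
        g = np.ones((3, 2))
        with pytest.raises(ValueError):
            svd_bottleneck(g, 3)
        z, v, s = svd_bottleneck(g, 3, strict=False)
        assert z.shape == (3, 2)


class TestProjectionLoss:
    def test_identical_zero(self):
        z = np.ones((4, 2))
        assert projection_loss(z, z) == 0.0

    def test_unit_difference(self):
        z = np.zeros((4, 2))
        assert projection_loss(z, z + 1.0) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            projection_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestTraining:
    def test_deterministic_given_seed(self, small_pop):
        cfg = tiny_cfg()
        a = fit_sae_ibs(small_pop, cfg)
        b = fit_sae_ibs(small_pop, cfg)
        assert pd.DataFrame(a.training_log).equals(pd.DataFrame(b.training_log))
        np.testing.assert_array_equal(a.training_scores.values, b.training_scores.values)

    def test_zero_noise_dae_equals_ae(self, small_pop):
        spec = PerturbationSpec(miss_rate=0.0, error_rate=0.0, mode="both", seed=0)
        ae = fit_ae(small_pop, tiny_cfg(max_epochs=15))
        dae = fit_dae(small_pop, tiny_cfg(max_epochs=15, denoise=spec))
        a = pd.DataFrame(ae.training_log)[["train_loss", "val_loss"]]
        d = pd.DataFrame(dae.training_log)[["train_loss", "val_loss"]]
        pd.testing.assert_frame_equal(a, d)

    def test_beta_zero_reduces_lsae_to_dsae(self, small_pop):
        spec = PerturbationSpec(miss_rate=0.05, error_rate=0.05, mode="both", seed=0)
        plain = fit_d_sae_ibs(small_pop, tiny_cfg(denoise=spec, max_epochs=10))
        with_l = fit_d_sae_ibs_l(small_pop, tiny_cfg(denoise=spec, max_epochs=10, beta=0.0))
        np.testing.assert_array_equal(plain.training_scores.values,
                                      with_l.training_scores.values)

    def test_ae_fits_rank_one_manifold(self):
        # samples alternate along a 1-D affine family of genotype profiles
        rng = np.random.default_rng(3)
        pattern = rng.integers(-1, 2, size=60).astype(np.int8)
        rows = [pattern, np.roll(pattern, 1)]
        values = np.array([rows[i % 2] for i in range(40)])
        g = make_genotypes(values)
        cfg = tiny_cfg(k=1, max_epochs=500, patience=150, batch_size=8,
                       weight_decay=0.0, learning_rate=1e-2)
        model = fit_ae(g, cfg)
        recon = reconstruct(model, g).values
        mse = np.mean((recon - normalize_unit(g).values) ** 2)
        assert mse < 0.01

    def test_reconstruction_not_below_rank_k_floor(self, small_pop):
        # with identity (slope-1) activations the whole network is affine and
        # all reconstructions live in a k-dim affine subspace, so the
        # training error can never beat the rank-k PCA optimum
        cfg = tiny_cfg(activation=1.0, k=2, drop_trivial_axis=False,
                       max_epochs=60, pretrain_epochs=60)
        model = fit_sae_ibs(small_pop, cfg)
        x = normalize_unit(small_pop).values
        recon = reconstruct(model, small_pop).values
        mse = np.mean((recon - x) ** 2)
        xc = x - x.mean(axis=0)
        sv = np.linalg.svd(xc, compute_uv=False)
        floor = np.sum(sv[2:] ** 2) / x.size
        assert mse >= floor - 1e-9

    def test_divergence_guard_message(self, small_pop):
        from saeibs.neural import DivergenceError

        # one Adam step of ~1e200 overflows the next forward pass to inf
        cfg = tiny_cfg(learning_rate=1e200, max_epochs=5, pretrain_epochs=5)
        with pytest.raises((DivergenceError, FloatingPointError)):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_sae_ibs(small_pop, cfg)


@pytest.fixture(scope="module")
def trained(small_pop):
    return fit_sae_ibs(small_pop, tiny_cfg(max_epochs=60, pretrain_epochs=120))


class TestScoresAndProjection:

    def test_latent_dimensions_and_gram(self, small_pop, trained):
        z = latent_scores(trained, small_pop)
        assert z.k == trained.config.k
        gram = z.values.T @ z.values
        off = np.abs(gram - np.diag(np.diag(gram))).max()
        assert off < 1e-8 * gram[0, 0]
        # axis "variances" (uncentered) follow the singular-value order
        assert (np.diff(np.diag(gram)) <= 1e-9 * gram[0, 0]).all()

    def test_training_scores_equal_latent_scores(self, small_pop, trained):
        np.testing.assert_allclose(latent_scores(trained, small_pop).values,
                                   trained.training_scores.values, atol=1e-10)

    def test_duplicated_target_duplicates_scores(self, small_pop, trained):
        tgt = GenotypeMatrix(small_pop.values[[3, 3, 7]], ["a", "b", "c"],
                             small_pop.variants)
        z = project_target(trained, tgt, small_pop)
        np.testing.assert_allclose(z.values[0], z.values[1])

    def test_self_projection_identity_equal_degrees(self):
        g = hadamard_genotypes()
        d = degree(ibs_matrix(g)).degrees
        assert np.allclose(d, d[0])
        model = fit_sae_ibs(g, tiny_cfg(batch_size=4))
        proj = project_target(model, g, g).values
        train = model.training_scores.values
        np.testing.assert_allclose(proj, train / np.sqrt(d[0]), atol=1e-8)

    def test_held_out_sample_projects_into_own_population(self):
        hits = 0
        for seed in range(5):
            g = simulate_populations(SimConfig(n_pops=2, n_per_pop=40, m_snps=400,
                                               fst=0.3, seed=100 + seed))
            ref = g.take_samples(list(range(0, 39)) + list(range(40, 79)))
            held = g.take_samples([39])  # last POP1 sample
            model = fit_sae_ibs(ref, tiny_cfg(k=1, seed=seed, max_epochs=120,
                                              pretrain_epochs=200))
            z_ref = model.training_scores.values[:, 0]
            z_held = project_target(model, held, ref).values[0, 0]
            pop1 = z_ref[:39] / np.sqrt(degree(ibs_matrix(ref)).degrees[:39])
            lo, hi = pop1.min(), pop1.max()
            hits += lo <= z_held <= hi
        assert hits >= 4

    def test_reconstruct_shape_and_signal(self, small_pop, trained):
        recon = reconstruct(trained, small_pop).values
        assert recon.shape == small_pop.shape
        x = normalize_unit(small_pop).values
        mse_real = np.mean((recon - x) ** 2)
        # scrambling the sample structure must reconstruct worse
        rng = np.random.default_rng(0)
        scrambled = np.column_stack([rng.permutation(col) for col in x.T])
        mse_scrambled = np.mean((reconstruct(trained,
                                 small_pop.with_values(
                                     np.rint(scrambled * 2 - 1).astype(np.int8))).values
                                 - scrambled) ** 2)
        assert np.isfinite(mse_real)
        assert mse_real < mse_scrambled

    def test_checkpoint_roundtrip(self, tmp_path, small_pop, trained):
        save_model(trained, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(latent_scores(back, small_pop).values,
                                   latent_scores(trained, small_pop).values)
        ae = fit_ae(small_pop, tiny_cfg(max_epochs=5))
        save_model(ae, tmp_path / "ae.npz")
        ae_back = load_model(tmp_path / "ae.npz")
        np.testing.assert_allclose(project_ae(ae_back, small_pop).values,
                                   project_ae(ae, small_pop).values)


def test_mae_training_more_robust_to_relatives_than_mse():
    """Relatives pull MSE-trained latents harder than MAE-trained ones."""
    from saeibs.evaluate import mean_mahalanobis

    diffs = []
    for seed in range(3):
        g = simulate_populations(SimConfig(n_pops=2, n_per_pop=80, m_snps=600,
                                           fst=0.1, seed=200 + seed,
                                           families=[(5, 0), (4, 0)]))
        lab = np.asarray(g.labels, dtype=str)
        rel = np.flatnonzero(np.char.startswith(lab, "REL"))
        pop1 = np.flatnonzero(lab == "POP1")
        mmd = {}
        for loss in ("mae", "mse"):
            model = fit_sae_ibs(g, NetConfig(hidden_sizes=(16,), k=4, loss=loss,
                                             seed=seed, pretrain_epochs=400,
                                             max_epochs=300, patience=40))
            mmd[loss] = mean_mahalanobis(model.training_scores, pop1, rel)
        diffs.append(mmd["mse"] - mmd["mae"])
    assert np.mean(diffs) > 0
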