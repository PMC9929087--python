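"""Autoencoder family for ancestry inference: AE, DAE, DAE-L and the hybrid
SAE-IBS with its denoising variants (D-SAE-IBS, D-SAE-IBS-L).

The hybrid model replaces the fully connected bottleneck of a plain
autoencoder with a low-rank SVD of the IBS-generalized encoder features

    G = D^{-1/2} f(W X + b),      G = U~ S~ V~^T  (top-k),

so the latent representation Z~ = U~ S~ is orthogonal by construction and the
decoder reconstructs from Z~ V~^T.  The training objective is

    J = sum_x L(x, g(D^{-1/2} f(x) V~ V~^T)),

optimized by mini-batch gradient descent through the encoder and decoder
while V~ is held constant within an epoch and refreshed from a full-data SVD
after each epoch.  Unseen targets project as D~^{-1} f(W Y + b) V~ where D~
holds the target-to-reference cross-IBS degrees; this per-sample degree
correction is what absorbs genotyping errors and missing calls in the target.

Denoising variants corrupt the network input each epoch while reconstructing
the clean data; the "-L" variants add beta times a projection loss, the mean
squared difference between the latent representations of the clean and
corrupted inputs, so that robustness is imposed on the latent space itself
and not only on the reconstruction.

Everything runs on a compact double-precision numpy MLP (leaky-ReLU layers,
Adam with decoupled-style L2 weight decay, early stopping on a stratified
validation split), which keeps training exactly reproducible for a given
seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from . import ibs as ibs_mod
from .linear import AncestryScores, _fix_signs
from .matrix import GenotypeMatrix, NormalizedMatrix, normalize_unit
from .simulate import PerturbationSpec, perturb

NEURAL_METHODS = ("ae", "dae", "dae_l", "sae_ibs", "d_sae_ibs", "d_sae_ibs_l")


class DivergenceError(RuntimeError):
    pass


@dataclass
class NetConfig:
    """Architecture and training settings shared by the autoencoder family."""

    hidden_sizes: tuple[int, ...] = (32,)
    k: int = 2
    activation: float = 0.01  # leaky-ReLU negative slope
    loss: str = "mse"  # mse | mae
    weight_decay: float = 1e-4
    beta: float = 0.0  # projection-loss weight (the -L variants)
    denoise: Optional[PerturbationSpec] = None
    batch_size: int = 64
    max_epochs: int = 500
    pretrain_epochs: int = 1000
    patience: int = 50
    val_fraction: float = 0.10
    learning_rate: float = 1e-3
    drop_trivial_axis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes or min(self.hidden_sizes) < 1:
            raise ValueError("hidden_sizes must be positive")
        if not 1 <= self.k + int(self.drop_trivial_axis) <= self.hidden_sizes[-1]:
            raise ValueError("k (+1 for the trivial axis) must fit the last hidden size")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")

    @property
    def h(self) -> int:
        return self.hidden_sizes[-1]


# ---------------------------------------------------------------------------
# numpy MLP primitives


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _dleaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def _init_layers(sizes: list[int], rng: np.random.Generator) -> list[list[np.ndarray]]:
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        layers.append([w, np.zeros(fan_out)])
    return layers


def _zeros_like_layers(layers) -> list[list[np.ndarray]]:
    return [[np.zeros_like(w), np.zeros_like(b)] for w, b in layers]


def _mlp_forward(layers, x, slope):
    caches, a = [], x
    for w, b in layers:
        z = a @ w + b
        caches.append((a, z))
        a = _leaky(z, slope)
    return a, caches


def _mlp_backward(layers, caches, grad_out, slope, grads):
    """Accumulate parameter gradients; return the gradient wrt the input."""
    da = grad_out
    for (w, _b), (a_prev, z), g in zip(reversed(layers), reversed(caches), reversed(grads)):
        dz = da * _dleaky(z, slope)
        g[0] += a_prev.T @ dz
        g[1] += dz.sum(axis=0)
        da = dz @ w.T
    return da


def _linear_forward(layer, x):
    w, b = layer
    return x @ w + b


def _linear_backward(layer, x, grad_out, grad):
    w, _b = layer
    grad[0] += x.T @ grad_out
    grad[1] += grad_out.sum(axis=0)
    return grad_out @ w.T


class _Adam:
    """Adam over a flat list of arrays; L2 decay applied to weights only."""

    def __init__(self, params, decay_flags, lr, weight_decay,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.decay_flags = decay_flags
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v, decay in zip(self.params, grads, self.m, self.v, self.decay_flags):
            if decay and self.wd:
                g = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten(*layer_lists):
    params, flags = [], []
    for layers in layer_lists:
        for w, b in layers:
            params += [w, b]
            flags += [True, False]
    return params, flags


def _loss_and_grad(xhat, target, loss):
    diff = xhat - target
    if loss == "mse":
        return float(np.mean(diff**2)), 2.0 * diff / diff.size
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def _loss_value(xhat, target, loss):
    diff = xhat - target
    return float(np.mean(diff**2)) if loss == "mse" else float(np.mean(np.abs(diff)))


# ---------------------------------------------------------------------------
# models


@dataclass
class AEModel:
    """Plain or denoising autoencoder with a linear k-bottleneck."""

    encoder: list
    bottleneck: list  # [h->k, k->h] linear layers
    decoder: list
    config: NetConfig
    method: str = "ae"
    training_log: list = field(default_factory=list, repr=False)

    def encode(self, x: np.ndarray) -> np.ndarray:
        a, _ = _mlp_forward(self.encoder, x, self.config.activation)
        return _linear_forward(self.bottleneck[0], a)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = self.encode(x)
        h = _linear_forward(self.bottleneck[1], z)
        out, _ = _mlp_forward(self.decoder, h, self.config.activation)
        return out


@dataclass
class SAEIBSModel:
    """Hybrid autoencoder with the IBS-generalized SVD bottleneck."""

    encoder: list
    decoder: list
    loadings: np.ndarray  # V~ ancestry axes: h x k, semi-orthogonal
    singular_values: np.ndarray  # descending positive, ancestry axes
    degrees: np.ndarray  # reference similarity degrees d_ii
    config: NetConfig
    loadings_full: Optional[np.ndarray] = None  # incl. the trivial mean axis
    method: str = "sae_ibs"
    training_log: list = field(default_factory=list, repr=False)
    training_scores: Optional[AncestryScores] = None

    def __post_init__(self) -> None:
        if self.loadings_full is None:
            self.loadings_full = self.loadings

    def features(self, x: np.ndarray) -> np.ndarray:
        """Encoder activations f(Wx + b)."""
        a, _ = _mlp_forward(self.encoder, x, self.config.activation)
        return a

    def generalized_features(self, x: np.ndarray) -> np.ndarray:
        """G = D^{-1/2} f(x) for the training reference."""
        return self.features(x) * self.degrees[:, None] ** -0.5


def svd_bottleneck(
    g_features: np.ndarray, k: int, strict: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k SVD of the generalized features: G = U~ S~ V~^T.

    Returns (scores Z~ = U~ S~, loadings V~, singular values).  When ``k``
    exceeds the available rank, ``strict`` raises; otherwise the available
    rank is retained.
    """
    g_features = np.asarray(g_features, dtype=float)
    max_rank = min(g_features.shape)
    if k > max_rank:
        if strict:
            raise ValueError(f"k={k} exceeds max rank {max_rank}")
        k = max_rank
    u, s, vt = np.linalg.svd(g_features, full_matrices=False)
    v, u = _fix_signs(vt[:k].T, u[:, :k])
    return u * s[:k], v, s[:k]


def projection_loss(clean_latent: np.ndarray, noisy_latent: np.ndarray) -> float:
    """Mean squared difference between clean and corrupted latents."""
    if clean_latent.shape != noisy_latent.shape:
        raise ValueError("latent shapes differ")
    return float(np.mean((clean_latent - noisy_latent) ** 2))


# ---------------------------------------------------------------------------
# training machinery


def _val_split(n: int, cfg: NetConfig, labels) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise validation split, stratified by label where possible."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]).generate_state(1)[0])
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training samples")
    if labels is not None:
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() >= 2:
            val_idx = []
            for lab in np.unique(labels):
                members = np.flatnonzero(labels == lab)
                take = max(1, int(round(cfg.val_fraction * members.size)))
                val_idx.append(rng.choice(members, size=min(take, members.size - 1),
                                          replace=False))
            val = np.sort(np.concatenate(val_idx))
            train = np.setdiff1d(np.arange(n), val)
            return train, val
    val = np.sort(rng.choice(n, size=n_val, replace=False))
    return np.setdiff1d(np.arange(n), val), val


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0
        self.best_state = None

    def update(self, val_loss: float, snapshot: Callable) -> bool:
        """Record; return True when training should stop."""
        if val_loss < self.best - 1e-12:
            self.best = val_loss
            self.bad_epochs = 0
            self.best_state = snapshot()
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _epoch_corruption(g: GenotypeMatrix, spec: PerturbationSpec,
                      epoch_seed: int) -> np.ndarray:
    sub = replace(spec, seed=epoch_seed)
    return normalize_unit(perturb(g, sub)).values


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _check_finite(loss: float, epoch: int) -> None:
    if not np.isfinite(loss):
        raise DivergenceError(f"non-finite loss at epoch {epoch}")


# -- plain / denoising AE ----------------------------------------------------


def fit_ae(x: GenotypeMatrix, cfg: NetConfig) -> AEModel:
    """Train a plain autoencoder (linear k-bottleneck, mirrored decoder)."""
    return _fit_ae_family(x, cfg, method="ae")


def fit_dae(x: GenotypeMatrix, cfg: NetConfig) -> AEModel:
    """Denoising AE: corrupted input, clean reconstruction target."""
    if cfg.denoise is None:
        raise ValueError("fit_dae requires cfg.denoise")
    return _fit_ae_family(x, cfg, method="dae")


def fit_dae_l(x: GenotypeMatrix, cfg: NetConfig) -> AEModel:
    """DAE with the latent projection loss weighted by cfg.beta."""
    if cfg.denoise is None:
        raise ValueError("fit_dae_l requires cfg.denoise")
    return _fit_ae_family(x, cfg, method="dae_l")


def _fit_ae_family(x: GenotypeMatrix, cfg: NetConfig, method: str) -> AEModel:
    slope = cfg.activation
    clean = normalize_unit(x).values
    n, m = clean.shape
    denoise = method in ("dae", "dae_l")
    use_proj = method == "dae_l" and cfg.beta > 0

    rng = np.random.default_rng(cfg.seed)
    enc_sizes = [m, *cfg.hidden_sizes]
    dec_sizes = [cfg.h, *cfg.hidden_sizes[-2::-1], m]
    encoder = _init_layers(enc_sizes, rng)
    bottleneck = _init_layers([cfg.h, cfg.k], rng) + _init_layers([cfg.k, cfg.h], rng)
    decoder = _init_layers(dec_sizes, rng)
    params, flags = _flatten(encoder, bottleneck, decoder)
    opt = _Adam(params, flags, cfg.learning_rate, cfg.weight_decay)

    train_idx, val_idx = _val_split(n, cfg, x.labels)
    batch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]).generate_state(1)[0])
    corrupt_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]).generate_state(1)[0])

    def forward_all(xin):
        a, enc_caches = _mlp_forward(encoder, xin, slope)
        z = _linear_forward(bottleneck[0], a)
        h = _linear_forward(bottleneck[1], z)
        out, dec_caches = _mlp_forward(decoder, h, slope)
        return out, (xin, a, z, h, enc_caches, dec_caches)

    def backward_all(cache, grad_out, grads_enc, grads_bn, grads_dec, grad_latent=None):
        _xin, a, z, _h, enc_caches, dec_caches = cache
        dh = _mlp_backward(decoder, dec_caches, grad_out, slope, grads_dec)
        dz = _linear_backward(bottleneck[1], z, dh, grads_bn[1])
        if grad_latent is not None:
            dz = dz + grad_latent
        da = _linear_backward(bottleneck[0], a, dz, grads_bn[0])
        _mlp_backward(encoder, enc_caches, da, slope, grads_enc)

    def val_loss_fn(epoch_seed):
        out, cache = forward_all(clean[val_idx])
        loss = _loss_value(out, clean[val_idx], cfg.loss)
        if use_proj:
            noisy = _epoch_corruption(x.take_samples(val_idx), cfg.denoise, epoch_seed)
            z_clean = cache[2]
            a_n, _ = _mlp_forward(encoder, noisy, slope)
            z_noisy = _linear_forward(bottleneck[0], a_n)
            loss += cfg.beta * projection_loss(z_clean, z_noisy)
        return loss

    log: list[dict] = []
    stopper = _EarlyStopper(cfg.patience)
    snapshot = lambda: copy.deepcopy((encoder, bottleneck, decoder))

    for epoch in range(cfg.max_epochs):
        if denoise:
            epoch_seed = int(corrupt_rng.integers(2**31))
            noisy_full = _epoch_corruption(x, cfg.denoise, epoch_seed)
        else:
            epoch_seed = 0
            noisy_full = clean
        epoch_loss, n_batches = 0.0, 0
        for batch in _batches(train_idx.size, cfg.batch_size, batch_rng):
            idx = train_idx[batch]
            target = clean[idx]
            out, cache = forward_all(noisy_full[idx])
            loss, grad = _loss_and_grad(out, target, cfg.loss)
            grads_enc = _zeros_like_layers(encoder)
            grads_bn = _zeros_like_layers(bottleneck)
            grads_dec = _zeros_like_layers(decoder)
            grad_latent = None
            if use_proj:
                a_c, enc_caches_c = _mlp_forward(encoder, target, slope)
                z_clean = _linear_forward(bottleneck[0], a_c)
                z_noisy = cache[2]
                loss += cfg.beta * projection_loss(z_clean, z_noisy)
                dproj = 2.0 * (z_noisy - z_clean) / z_noisy.size
                grad_latent = cfg.beta * dproj
                # clean pass gradient (encoder + first bottleneck layer only)
                da_c = _linear_backward(bottleneck[0], a_c, -cfg.beta * dproj, grads_bn[0])
                _mlp_backward(encoder, enc_caches_c, da_c, slope, grads_enc)
            backward_all(cache, grad, grads_enc, grads_bn, grads_dec, grad_latent)
            flat_grads, _ = _flatten(grads_enc, grads_bn, grads_dec)
            opt.step(flat_grads)
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= max(n_batches, 1)
        _check_finite(epoch_loss, epoch)
        vloss = val_loss_fn(epoch_seed)
        log.append({"epoch": epoch, "phase": method, "train_loss": epoch_loss,
                    "val_loss": vloss})
        if stopper.update(vloss, snapshot):
            break
    if stopper.best_state is not None:
        encoder, bottleneck, decoder = stopper.best_state
    return AEModel(encoder=encoder, bottleneck=bottleneck, decoder=decoder,
                   config=cfg, method=method, training_log=log)


# -- SAE-IBS family ----------------------------------------------------------


def fit_sae_ibs(x: GenotypeMatrix, cfg: NetConfig) -> SAEIBSModel:
    """Train the hybrid SAE-IBS model (see module docstring for the scheme)."""
    return _fit_sae_family(x, cfg, method="sae_ibs")


def fit_d_sae_ibs(x: GenotypeMatrix, cfg: NetConfig) -> SAEIBSModel:
    """Denoising SAE-IBS: corrupted inputs, clean reconstruction targets."""
    if cfg.denoise is None:
        raise ValueError("fit_d_sae_ibs requires cfg.denoise")
    return _fit_sae_family(x, cfg, method="d_sae_ibs")


def fit_d_sae_ibs_l(x: GenotypeMatrix, cfg: NetConfig) -> SAEIBSModel:
    """Denoising SAE-IBS with the beta-weighted latent projection loss."""
    if cfg.denoise is None:
        raise ValueError("fit_d_sae_ibs_l requires cfg.denoise")
    return _fit_sae_family(x, cfg, method="d_sae_ibs_l")


def _fit_sae_family(x: GenotypeMatrix, cfg: NetConfig, method: str) -> SAEIBSModel:
    slope = cfg.activation
    clean = normalize_unit(x).values
    n, m = clean.shape
    denoise = method in ("d_sae_ibs", "d_sae_ibs_l")
    use_proj = method == "d_sae_ibs_l" and cfg.beta > 0
    # bottleneck rank: the requested ancestry axes plus, by default, the
    # trivial grand-mean axis the decoder needs for reconstruction
    skip = 1 if cfg.drop_trivial_axis else 0
    rank = cfg.k + skip

    # IBS similarity and degrees computed once on the full reference
    d = ibs_mod.degree(ibs_mod.ibs_matrix(x)).degrees
    inv_sqrt_d = d**-0.5

    rng = np.random.default_rng(cfg.seed)
    encoder = _init_layers([m, *cfg.hidden_sizes], rng)
    decoder = _init_layers([cfg.h, *cfg.hidden_sizes[-2::-1], m], rng)
    params, flags = _flatten(encoder, decoder)
    opt = _Adam(params, flags, cfg.learning_rate, cfg.weight_decay)

    train_idx, val_idx = _val_split(n, cfg, x.labels)
    batch_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]).generate_state(1)[0])
    corrupt_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]).generate_state(1)[0])
    log: list[dict] = []

    snapshot = lambda: copy.deepcopy((encoder, decoder))

    # ---- phase 1: plain AE pre-training (direct h -> decoder path) -------
    stopper = _EarlyStopper(cfg.patience)
    for epoch in range(cfg.pretrain_epochs):
        epoch_loss, n_batches = 0.0, 0
        for batch in _batches(train_idx.size, cfg.batch_size, batch_rng):
            idx = train_idx[batch]
            xb = clean[idx]
            a, enc_caches = _mlp_forward(encoder, xb, slope)
            out, dec_caches = _mlp_forward(decoder, a, slope)
            loss, grad = _loss_and_grad(out, xb, cfg.loss)
            grads_enc = _zeros_like_layers(encoder)
            grads_dec = _zeros_like_layers(decoder)
            da = _mlp_backward(decoder, dec_caches, grad, slope, grads_dec)
            _mlp_backward(encoder, enc_caches, da, slope, grads_enc)
            flat_grads, _ = _flatten(grads_enc, grads_dec)
            opt.step(flat_grads)
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= max(n_batches, 1)
        _check_finite(epoch_loss, epoch)
        a_val, _ = _mlp_forward(encoder, clean[val_idx], slope)
        out_val, _ = _mlp_forward(decoder, a_val, slope)
        vloss = _loss_value(out_val, clean[val_idx], cfg.loss)
        log.append({"epoch": epoch, "phase": "pretrain", "train_loss": epoch_loss,
                    "val_loss": vloss})
        if stopper.update(vloss, snapshot):
            break
    if stopper.best_state is not None:
        enc_state, dec_state = stopper.best_state
        for layer, best in zip(encoder, enc_state):
            layer[0][:], layer[1][:] = best[0], best[1]
        for layer, best in zip(decoder, dec_state):
            layer[0][:], layer[1][:] = best[0], best[1]

    def full_svd_update():
        feats, _ = _mlp_forward(encoder, clean, slope)
        g_full = feats * inv_sqrt_d[:, None]
        return svd_bottleneck(g_full, rank)

    _, v_mat, sing = full_svd_update()

    def val_loss_fn(epoch_seed):
        a, _ = _mlp_forward(encoder, clean[val_idx], slope)
        g_val = a * inv_sqrt_d[val_idx, None]
        out, _ = _mlp_forward(decoder, g_val @ v_mat @ v_mat.T, slope)
        loss = _loss_value(out, clean[val_idx], cfg.loss)
        if use_proj:
            noisy = _epoch_corruption(x.take_samples(val_idx), cfg.denoise, epoch_seed)
            a_n, _ = _mlp_forward(encoder, noisy, slope)
            v_anc = v_mat[:, skip:]
            loss += cfg.beta * projection_loss(g_val @ v_anc,
                                               (a_n * inv_sqrt_d[val_idx, None]) @ v_anc)
        return loss

    # ---- phase 2: SVD-bottleneck training ---------------------------------
    stopper = _EarlyStopper(cfg.patience)
    sae_snapshot = lambda: (copy.deepcopy((encoder, decoder)), v_mat.copy(), sing.copy())
    for epoch in range(cfg.max_epochs):
        if denoise:
            epoch_seed = int(corrupt_rng.integers(2**31))
            noisy_full = _epoch_corruption(x, cfg.denoise, epoch_seed)
        else:
            epoch_seed = 0
            noisy_full = clean
        proj = v_mat @ v_mat.T  # constant within the epoch
        epoch_loss, n_batches = 0.0, 0
        for batch in _batches(train_idx.size, cfg.batch_size, batch_rng):
            idx = train_idx[batch]
            target = clean[idx]
            scale = inv_sqrt_d[idx, None]
            a, enc_caches = _mlp_forward(encoder, noisy_full[idx], slope)
            g_b = a * scale
            out, dec_caches = _mlp_forward(decoder, g_b @ proj, slope)
            loss, grad = _loss_and_grad(out, target, cfg.loss)
            grads_enc = _zeros_like_layers(encoder)
            grads_dec = _zeros_like_layers(decoder)
            dh = _mlp_backward(decoder, dec_caches, grad, slope, grads_dec)
            dg = dh @ proj  # proj is symmetric
            if use_proj:
                v_anc = v_mat[:, skip:]
                a_c, enc_caches_c = _mlp_forward(encoder, target, slope)
                z_clean = (a_c * scale) @ v_anc
                z_noisy = g_b @ v_anc
                loss += cfg.beta * projection_loss(z_clean, z_noisy)
                dproj = 2.0 * (z_noisy - z_clean) / z_noisy.size
                dg = dg + cfg.beta * dproj @ v_anc.T
                da_c = (-cfg.beta * dproj @ v_anc.T) * scale
                _mlp_backward(encoder, enc_caches_c, da_c, slope, grads_enc)
            _mlp_backward(encoder, enc_caches, dg * scale, slope, grads_enc)
            flat_grads, _ = _flatten(grads_enc, grads_dec)
            opt.step(flat_grads)
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= max(n_batches, 1)
        _check_finite(epoch_loss, epoch)
        # refresh the SVD layer from the embeddings of the complete dataset
        _, v_mat, sing = full_svd_update()
        vloss = val_loss_fn(epoch_seed)
        log.append({"epoch": epoch, "phase": method, "train_loss": epoch_loss,
                    "val_loss": vloss})
        if stopper.update(vloss, sae_snapshot):
            break
    if stopper.best_state is not None:
        (enc_state, dec_state), v_mat, sing = stopper.best_state
        for layer, best in zip(encoder, enc_state):
            layer[0][:], layer[1][:] = best[0], best[1]
        for layer, best in zip(decoder, dec_state):
            layer[0][:], layer[1][:] = best[0], best[1]
        scores_z, v_mat, sing = full_svd_update()
    else:
        scores_z, v_mat, sing = full_svd_update()

    model = SAEIBSModel(
        encoder=encoder, decoder=decoder,
        loadings=v_mat[:, skip:], singular_values=sing[skip:],
        degrees=d, config=cfg, loadings_full=v_mat, method=method, training_log=log,
        training_scores=AncestryScores(values=scores_z[:, skip:],
                                       sample_ids=list(x.sample_ids)),
    )
    return model


# ---------------------------------------------------------------------------
# inference


def fit(method: str, x: GenotypeMatrix, cfg: NetConfig):
    """Dispatch to the trainer for any of the six autoencoder variants."""
    table = {
        "ae": fit_ae, "dae": fit_dae, "dae_l": fit_dae_l,
        "sae_ibs": fit_sae_ibs, "d_sae_ibs": fit_d_sae_ibs,
        "d_sae_ibs_l": fit_d_sae_ibs_l,
    }
    if method not in table:
        raise ValueError(f"unknown neural method {method!r}")
    return table[method](x, cfg)


def latent_scores(model, x: GenotypeMatrix) -> AncestryScores:
    """Latent coordinates of ``x`` under a trained model.

    For SAE-IBS variants ``x`` must be the training reference (the stored
    degrees apply sample-wise): Z~ = D^{-1/2} f(x) V~ = U~ S~.  For AE
    variants any allele-matched data works; the bottleneck activations are
    returned.
    """
    xin = normalize_unit(x).values
    if isinstance(model, SAEIBSModel):
        if xin.shape[0] != model.degrees.size:
            raise ValueError("sample count does not match the stored reference degrees")
        z = (model.features(xin) * model.degrees[:, None] ** -0.5) @ model.loadings
    else:
        z = model.encode(xin)
    return AncestryScores(values=z, sample_ids=list(x.sample_ids))


def project_target(model: SAEIBSModel, y: GenotypeMatrix,
                   x_ref: GenotypeMatrix) -> AncestryScores:
    """Project unseen targets onto the reference space: D~^{-1} f(Y) V~."""
    d_t = ibs_mod.degree(ibs_mod.cross_ibs(y, x_ref)).degrees
    yin = normalize_unit(y).values
    z = (model.features(yin) * d_t[:, None] ** -1.0) @ model.loadings
    return AncestryScores(values=z, sample_ids=list(y.sample_ids))


def project_ae(model: AEModel, y: GenotypeMatrix) -> AncestryScores:
    """Bottleneck coordinates of new data under an AE-family model."""
    return AncestryScores(values=model.encode(normalize_unit(y).values),
                          sample_ids=list(y.sample_ids))


def save_model(model, path) -> None:
    """Serialize an AE-family or SAE-IBS model to a single .npz checkpoint."""
    import json

    cfg = dict(model.config.__dict__)
    if cfg.get("denoise") is not None:
        cfg["denoise"] = dict(cfg["denoise"].__dict__)
    arrays = {
        "format_version": np.array(1),
        "method": np.array(model.method),
        "config_json": np.array(json.dumps(cfg)),
    }
    for name, layers in (("encoder", model.encoder), ("decoder", model.decoder)):
        for i, (w, b) in enumerate(layers):
            arrays[f"{name}_{i}_w"], arrays[f"{name}_{i}_b"] = w, b
    if isinstance(model, SAEIBSModel):
        arrays["loadings"] = model.loadings
        arrays["loadings_full"] = model.loadings_full
        arrays["singular_values"] = model.singular_values
        arrays["degrees"] = model.degrees
    else:
        for i, (w, b) in enumerate(model.bottleneck):
            arrays[f"bottleneck_{i}_w"], arrays[f"bottleneck_{i}_b"] = w, b
    np.savez(path, **arrays)


def load_model(path):
    import json

    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config_json"]))
        if cfg_dict.get("denoise") is not None:
            cfg_dict["denoise"] = PerturbationSpec(**cfg_dict["denoise"])
        cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
        cfg = NetConfig(**cfg_dict)
        method = str(data["method"])

        def read_layers(name):
            layers = []
            i = 0
            while f"{name}_{i}_w" in data:
                layers.append([data[f"{name}_{i}_w"], data[f"{name}_{i}_b"]])
                i += 1
            return layers

        encoder, decoder = read_layers("encoder"), read_layers("decoder")
        if method in ("sae_ibs", "d_sae_ibs", "d_sae_ibs_l"):
            return SAEIBSModel(
                encoder=encoder, decoder=decoder, loadings=data["loadings"],
                singular_values=data["singular_values"], degrees=data["degrees"],
                config=cfg, loadings_full=data["loadings_full"], method=method,
            )
        return AEModel(encoder=encoder, bottleneck=read_layers("bottleneck"),
                       decoder=decoder, config=cfg, method=method)


def training_log_frame(model):
    """The per-epoch training curve as a tidy table."""
    import pandas as pd

    return pd.DataFrame(model.training_log)


def reconstruct(model, x: GenotypeMatrix) -> NormalizedMatrix:
    """Decoder output for ``x`` (unit-interval scale, same shape as input)."""
    xin = normalize_unit(x).values
    if isinstance(model, SAEIBSModel):
        g_feat = model.generalized_features(xin)
        v_full = model.loadings_full
        out, _ = _mlp_forward(model.decoder, g_feat @ v_full @ v_full.T,
                              model.config.activation)
    else:
        out = model.forward(xin)
    return NormalizedMatrix(values=out, source=x)
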