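"""Gated-convolution variational protein encoder and deconvolutional decoder.

The encoder stacks three 1-D gated convolutions (channel counts W_en,
2*W_en, 3*W_en), keeps the pre-pooling position-wise feature map for the
interaction module, global-max-pools, and emits (mu, log_var) heads. The
decoder resizes the latent with a fully connected layer, applies three
stride-1 transposed convolutions with ReLU, and projects each position to
a scalar, giving a reconstruction profile of exactly the configured
protein length. A saliency rule over the reconstruction yields the
"original binding area" profile s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .featurize import ProteinKmerMatrix, kmer_vocab_size
from .nn import Tensor
from .nn.layers import masked_max

__all__ = [
    "VAEConfig", "ProteinEncoding", "ProteinVAE",
    "vae_encode", "vae_decode", "reconstruction_binding_profile",
    "kl_divergence", "reconstruction_target",
]


@dataclass
class VAEConfig:
    n_filters: int = 32        # W_en (doubled / tripled in layers 2, 3)
    kernel_en: int = 7         # K_en
    n_filters_de: int = 16     # W_de
    kernel_de: int = 7         # K_de
    latent_dim: int = 64       # L_p
    embed_dim: int = 64        # D_p, 3-mer embedding width
    max_positions: int = 1000  # theta_p

    def __post_init__(self):
        for name in ("n_filters", "kernel_en", "n_filters_de", "kernel_de",
                     "latent_dim", "embed_dim", "max_positions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class ProteinEncoding:
    mu: np.ndarray
    log_var: np.ndarray
    z: np.ndarray                       # sampled latent (X_en)
    eps: np.ndarray                     # recorded reparameterization noise
    feature_map: np.ndarray             # (positions, 3*W_en), pre-pooling
    reconstruction: np.ndarray | None = None  # (theta_p,)
    mask: np.ndarray = field(default=None)


class _GatedConv(nn.Module):
    """out = conv_a(x) * sigmoid(conv_b(x))"""

    def __init__(self, in_ch, out_ch, kernel, rng):
        super().__init__()
        self.conv_a = nn.Conv1d(in_ch, out_ch, kernel, rng)
        self.conv_b = nn.Conv1d(in_ch, out_ch, kernel, rng)

    def forward(self, x):
        return self.conv_a(x) * self.conv_b(x).sigmoid()


class ProteinVAE(nn.Module):
    def __init__(self, cfg: VAEConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w, k = cfg.n_filters, cfg.kernel_en
        self.embedding = nn.Embedding(kmer_vocab_size() + 1, cfg.embed_dim, rng)
        self.gated = [
            _GatedConv(cfg.embed_dim, w, k, rng),
            _GatedConv(w, 2 * w, k, rng),
            _GatedConv(2 * w, 3 * w, k, rng),
        ]
        self.fc_mu = nn.Linear(3 * w, cfg.latent_dim, rng)
        self.fc_logvar = nn.Linear(3 * w, cfg.latent_dim, rng)
        wd = cfg.n_filters_de
        self.fc_resize = nn.Linear(cfg.latent_dim, cfg.max_positions * wd, rng)
        self.deconvs = [nn.ConvTranspose1d(wd, wd, cfg.kernel_de, rng)
                        for _ in range(3)]
        self.fc_recon = nn.Linear(wd, 1, rng)

    @property
    def feature_dim(self) -> int:
        return 3 * self.cfg.n_filters

    def encode_features(self, x, mask):
        """x: (B, T, D_p) embedded k-mers; mask (B, T).

        Returns (mu, log_var, feature_map) as Tensors. Two ReLUs follow
        the first two gated layers; a (global) max-pool follows the third.
        """
        h = self.gated[0](x if isinstance(x, Tensor) else Tensor(x)).relu()
        h = self.gated[1](h).relu()
        feature_map = self.gated[2](h)
        pooled = masked_max(feature_map, mask, axis=1)
        return self.fc_mu(pooled), self.fc_logvar(pooled), feature_map

    def encode_ids(self, kmer_ids, mask):
        return self.encode_features(self.embedding(kmer_ids), mask)

    def reparameterize(self, mu, log_var, rng: np.random.Generator | None):
        """z = mu + exp(0.5*log_var) * eps; eval mode (rng None) gives z = mu."""
        if rng is None or not self.training:
            return mu, np.zeros(mu.shape)
        eps = rng.standard_normal(mu.shape)
        z = mu + (log_var * 0.5).exp() * eps
        return z, eps

    def decode(self, z):
        """z (B, L_p) -> reconstruction profile (B, theta_p)."""
        if not isinstance(z, Tensor):
            z = Tensor(z)
        b = z.shape[0]
        wd = self.cfg.n_filters_de
        h = self.fc_resize(z).reshape(b, self.cfg.max_positions, wd)
        for deconv in self.deconvs:
            h = deconv(h).relu()
        return self.fc_recon(h).reshape(b, self.cfg.max_positions)


# ------------------------------------------------------------ spec wrappers
def vae_encode(kmers: ProteinKmerMatrix, model: ProteinVAE,
               rng_seed: int | None = None) -> ProteinEncoding:
    """Encode one pre-embedded k-mer matrix. With ``rng_seed`` given the
    latent is sampled by reparameterization; otherwise z = mu."""
    mask = np.zeros(kmers.kmer_features.shape[0])
    mask[:kmers.n_real] = 1.0
    mu_t, lv_t, fmap_t = model.encode_features(
        Tensor(kmers.kmer_features[None]), mask[None])
    mu, log_var = mu_t.data[0], lv_t.data[0]
    if rng_seed is None:
        z, eps = mu.copy(), np.zeros_like(mu)
    else:
        eps = np.random.default_rng(rng_seed).standard_normal(mu.shape)
        z = mu + np.exp(0.5 * log_var) * eps
    return ProteinEncoding(mu=mu, log_var=log_var, z=z, eps=eps,
                           feature_map=fmap_t.data[0], mask=mask)


def vae_decode(z: np.ndarray, model: ProteinVAE) -> np.ndarray:
    """Decode a latent vector to the theta_p-length reconstruction."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("latent vector must be finite")
    return model.decode(z[None]).data[0]


def kl_divergence(mu, log_var):
    """KL( N(mu, exp(log_var)) || N(0, 1) ), summed over latent dims.

    Works on numpy arrays or Tensors; always >= 0.
    """
    if isinstance(mu, Tensor) or isinstance(log_var, Tensor):
        term = (mu * mu + log_var.exp() - log_var - 1.0) * 0.5
        return term.sum(axis=-1)
    return 0.5 * np.sum(mu**2 + np.exp(log_var) - log_var - 1.0, axis=-1)


def reconstruction_binding_profile(enc: ProteinEncoding | np.ndarray,
                                   top_fraction: float = 0.1,
                                   binary: bool = True) -> np.ndarray:
    """Saliency profile s over protein positions from the reconstruction.

    Saliency is the min-max normalised reconstruction magnitude. With
    ``binary`` the top ceil(top_fraction * theta_p) positions are marked 1
    (stable index order on ties); otherwise the continuous normalised
    saliency is returned.
    """
    recon = enc.reconstruction if isinstance(enc, ProteinEncoding) else enc
    if recon is None:
        raise ValueError("encoding has no reconstruction")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    mag = np.abs(np.asarray(recon, dtype=float))
    span = mag.max() - mag.min()
    saliency = (mag - mag.min()) / span if span > 0 else np.zeros_like(mag)
    if not binary:
        return saliency
    n = mag.shape[0]
    k = int(np.ceil(top_fraction * n))
    order = np.lexsort((np.arange(n), -saliency))
    s = np.zeros(n)
    s[order[:k]] = 1.0
    return s


def reconstruction_target(kmer_ids: np.ndarray) -> np.ndarray:
    """Fixed scalar profile per 3-mer id used as the decoder target.

    A frozen pseudo-random table maps each k-mer id to [0, 1); padding
    (id 0) maps to 0. This makes the reconstruction objective a
    deterministic 1-D profile of the input protein.
    """
    table = _recon_table()
    return table[np.asarray(kmer_ids, dtype=np.intp)]


_RECON_TABLE: np.ndarray | None = None


def _recon_table() -> np.ndarray:
    global _RECON_TABLE
    if _RECON_TABLE is None:
        rng = np.random.default_rng(0xC0FFEE)
        table = rng.uniform(0.0, 1.0, size=kmer_vocab_size() + 1)
        table[0] = 0.0
        _RECON_TABLE = table
    return _RECON_TABLE
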