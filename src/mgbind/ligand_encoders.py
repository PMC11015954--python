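"""Three parallel ligand feature extractors.

* graph-attention encoder over the molecular graph (atomic environment),
* residual CNN over the SMILES character codes (global sequence),
* transformer over sub-structure tokens (local mutual effects).

Each produces a pooled vector plus the position-wise feature map that the
interaction module consumes. The math core functions (`gat_attention`,
`gat_propagate`) are written against the numpy/Tensor dual surface so the
exact same code runs inside the trainable model and in plain-numpy tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .featurize import ATOM_FEATURE_DIM, LigandCodes, MolecularGraph, SubstructureTokens
from .nn import Tensor, functional as F
from .nn.layers import masked_max

__all__ = [
    "GATConfig", "CNNConfig", "MTConfig", "EncodedLigand",
    "gat_attention", "gat_propagate", "gat_layer",
    "GATEncoder", "CNNEncoder", "MTEncoder",
    "gat_encode", "cnn_encode", "mt_encode",
]


# ----------------------------------------------------------------- configs
@dataclass
class GATConfig:
    embed_dim: int = 128          # E_g, post linear-transform width
    out_dim: int = 128            # L_g
    n_heads: int = 4              # first-layer heads
    n_layers: int = 2
    zeta: str = "leaky_relu"      # attention-logit activation
    sigma: str = "elu"            # aggregation activation

    def __post_init__(self):
        if min(self.embed_dim, self.out_dim, self.n_heads, self.n_layers) < 1:
            raise ValueError("all GAT dimensions must be >= 1")
        if self.out_dim % self.n_heads:
            raise ValueError(
                f"out_dim {self.out_dim} not divisible by n_heads {self.n_heads}")


@dataclass
class CNNConfig:
    embed_dim: int = 128   # E_c
    n_filters: int = 128   # W_cnn
    kernel_size: int = 7   # K_f, "large-kernel"
    out_dim: int = 128     # L_c

    def __post_init__(self):
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for same-length padding")
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")


@dataclass
class MTConfig:
    embed_dim: int = 128   # E_t
    n_heads: int = 4       # H
    n_blocks: int = 3
    out_dim: int = 128     # L_t

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"n_heads {self.n_heads}")


@dataclass
class EncodedLigand:
    x_g: np.ndarray
    x_c: np.ndarray
    x_t: np.ndarray
    map_g: np.ndarray
    map_c: np.ndarray
    map_t: np.ndarray
    atom_mask: np.ndarray = field(default=None)
    code_mask: np.ndarray = field(default=None)
    token_mask: np.ndarray = field(default=None)


# ------------------------------------------------------------- GAT math core
def gat_attention(h_i, h_j, a, zeta="leaky_relu"):
    """Unnormalised attention logit  e_ij = zeta(a^T [h_i || h_j])."""
    h_i, h_j, a = (np.asarray(x, dtype=float) for x in (h_i, h_j, a))
    if a.shape[0] != h_i.shape[0] + h_j.shape[0]:
        raise ValueError(
            f"attention vector length {a.shape[0]} != "
            f"{h_i.shape[0]} + {h_j.shape[0]}")
    act = F.get_activation(zeta)
    return float(act(a @ np.concatenate([h_i, h_j])))


def gat_propagate(h, adj_mask, weight, a_src, a_dst,
                  zeta="leaky_relu", sigma="elu"):
    """One GAT head on dense (masked) adjacency.

    h: (..., A, Din); adj_mask: (..., A, A) with 1 for edges (self-loops
    included by the caller); weight: (Din, Dout); a_src/a_dst: (Dout, 1).
    Returns sigma(alpha @ (h W)) with alpha a masked softmax per row.
    Works for both numpy arrays and autodiff Tensors.
    """
    zeta_f, sigma_f = F.get_activation(zeta), F.get_activation(sigma)
    hw = h @ weight
    s_src = hw @ a_src                       # (..., A, 1)
    s_dst = (hw @ a_dst).swapaxes(-1, -2)    # (..., 1, A)
    e = zeta_f(s_src + s_dst)
    masked = e * adj_mask + (-1e9) * (1.0 - adj_mask)
    alpha = F.softmax(masked, axis=-1)
    return sigma_f(alpha @ hw), alpha


def gat_layer(node_feats, edges, weight, a, zeta="leaky_relu", sigma="elu",
              n_real: int | None = None):
    """Single-head GAT layer on an explicit edge list (numpy, unbatched).

    Self-loops are always added so no neighbourhood is empty. ``a`` is the
    concatenated attention vector of length 2*Dout, split into its source
    and destination halves.
    """
    node_feats = np.asarray(node_feats, dtype=float)
    n = node_feats.shape[0]
    n_real = n if n_real is None else n_real
    for i, j in edges:
        if i >= n_real or j >= n_real:
            raise ValueError(f"edge ({i},{j}) references a padding node")
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = 1.0
    adj[np.arange(n_real), np.arange(n_real)] = 1.0
    a = np.asarray(a, dtype=float)
    d_out = np.asarray(weight).shape[1]
    if a.shape[0] != 2 * d_out:
        raise ValueError(f"attention vector length {a.shape[0]} != 2*{d_out}")
    out, _ = gat_propagate(node_feats, adj, np.asarray(weight, dtype=float),
                           a[:d_out, None], a[d_out:, None], zeta, sigma)
    return out


# ----------------------------------------------------------------- encoders
class _GATLayer(nn.Module):
    """Multi-head dense GAT layer; heads concatenated."""

    def __init__(self, in_dim: int, out_dim: int, n_heads: int,
                 rng: np.random.Generator, zeta: str, sigma: str):
        super().__init__()
        if out_dim % n_heads:
            raise ValueError("out_dim must divide by n_heads")
        self.n_heads = n_heads
        head_dim = out_dim // n_heads
        self.weights = [nn.Parameter(nn.glorot(rng, in_dim, head_dim,
                                               (in_dim, head_dim)))
                        for _ in range(n_heads)]
        self.a_src = [nn.Parameter(rng.normal(0, 0.1, size=(head_dim, 1)))
                      for _ in range(n_heads)]
        self.a_dst = [nn.Parameter(rng.normal(0, 0.1, size=(head_dim, 1)))
                      for _ in range(n_heads)]
        self.zeta, self.sigma = zeta, sigma

    def named_parameters(self, prefix: str = ""):
        for group in ("weights", "a_src", "a_dst"):
            for i, p in enumerate(getattr(self, group)):
                yield f"{prefix}{group}.{i}", p
        yield from super().named_parameters(prefix)

    def forward(self, h, adj_mask):
        outs = [gat_propagate(h, adj_mask, self.weights[k],
                              self.a_src[k], self.a_dst[k],
                              self.zeta, self.sigma)[0]
                for k in range(self.n_heads)]
        return outs[0] if len(outs) == 1 else nn.concat(outs, axis=-1)


class GATEncoder(nn.Module):
    """Linear lift of 78-dim atom features, multi-head GAT stack, global
    max pooling over real atoms."""

    def __init__(self, cfg: GATConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.lift = nn.Linear(ATOM_FEATURE_DIM, cfg.embed_dim, rng)
        layers = [_GATLayer(cfg.embed_dim, cfg.out_dim, cfg.n_heads, rng,
                            cfg.zeta, cfg.sigma)]
        for _ in range(cfg.n_layers - 1):
            layers.append(_GATLayer(cfg.out_dim, cfg.out_dim, 1, rng,
                                    cfg.zeta, cfg.sigma))
        self.layers = layers

    def forward(self, atom_feats, adj_mask, atom_mask):
        """atom_feats (B,A,78), adj_mask (B,A,A) incl. self-loops,
        atom_mask (B,A). Returns (x_g (B,L_g), map_g (B,A,L_g))."""
        h = self.lift(atom_feats if isinstance(atom_feats, Tensor)
                      else Tensor(atom_feats))
        for layer in self.layers:
            h = layer(h, adj_mask)
        x_g = masked_max(h, atom_mask, axis=1)
        return x_g, h


class CNNEncoder(nn.Module):
    """Character-code embedding, three conv->batchnorm->ReLU blocks with a
    residual skip in embedding space, shared FC projection."""

    def __init__(self, cfg: CNNConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embedding = nn.Embedding(65, cfg.embed_dim, rng)
        chans = [cfg.embed_dim, cfg.n_filters, cfg.n_filters, cfg.embed_dim]
        self.convs = [nn.Conv1d(chans[i], chans[i + 1], cfg.kernel_size, rng)
                      for i in range(3)]
        self.norms = [nn.BatchNorm1d(chans[i + 1]) for i in range(3)]
        self.project = nn.Linear(cfg.embed_dim, cfg.out_dim, rng)

    def forward(self, codes, code_mask):
        """codes (B, T) ints, code_mask (B, T). Returns (x_c, map_c)."""
        x_seq = self.embedding(codes)
        h = x_seq
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).relu()
        residual = x_seq + h
        map_c = self.project(residual)
        x_c = self.project(masked_max(residual, code_mask, axis=1))
        return x_c, map_c


class _TransformerBlock(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        self.msa = nn.MultiHeadSelfAttention(dim, n_heads, rng)
        self.fc_att = nn.Linear(dim, dim, rng)
        self.fc_mlp = nn.Linear(dim, dim, rng)
        self.norm1 = nn.LayerNorm(dim)
        self.norm2 = nn.LayerNorm(dim)

    def forward(self, x, mask):
        x_att = self.norm1(self.fc_att(self.msa(x, mask=mask)).relu() + x)
        x_mlp = self.norm2(self.fc_mlp(x_att) + x_att)
        return x_mlp


class MTEncoder(nn.Module):
    """Sub-structure token transformer with learned positional signal."""

    def __init__(self, cfg: MTConfig, vocab_size: int, max_tokens: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embedding = nn.Embedding(vocab_size + 1, cfg.embed_dim, rng)
        self.positional = nn.Parameter(rng.normal(0, 0.1,
                                                  size=(max_tokens, cfg.embed_dim)))
        self.blocks = [_TransformerBlock(cfg.embed_dim, cfg.n_heads, rng)
                       for _ in range(cfg.n_blocks)]
        self.mlp_hidden = nn.Linear(cfg.embed_dim, cfg.out_dim, rng)
        self.mlp_out = nn.Linear(cfg.out_dim, cfg.out_dim, rng)

    def _mlp(self, x):
        return self.mlp_out(self.mlp_hidden(x).relu())

    def forward(self, token_ids, token_mask):
        """token_ids (B,T) 1-based ids with 0 padding. Returns (x_t, map_t)."""
        t = np.asarray(token_ids).shape[1]
        x = self.embedding(token_ids) + self.positional[:t, :]
        for block in self.blocks:
            x = block(x, token_mask)
        map_t = self._mlp(x)
        x_t = self._mlp(masked_max(x, token_mask, axis=1))
        return x_t, map_t


# --------------------------------------------------- single-instance wrappers
def _atom_mask(g: MolecularGraph) -> np.ndarray:
    mask = np.zeros(g.node_features.shape[0])
    mask[:g.n_real_atoms] = 1.0
    return mask


def gat_encode(g: MolecularGraph, encoder: GATEncoder):
    """Encode one molecular graph; returns numpy (x_g, map_g)."""
    encoder.eval()
    adj = g.adjacency(self_loops=True)[None]
    mask = _atom_mask(g)[None]
    x_g, map_g = encoder(Tensor(g.node_features[None]), adj, mask)
    return x_g.data[0], map_g.data[0]


def cnn_encode(codes: LigandCodes, encoder: CNNEncoder):
    """Encode one code sequence; returns numpy (x_c, map_c)."""
    encoder.eval()
    mask = np.zeros(codes.codes.shape[0])
    mask[:codes.n_real] = 1.0
    x_c, map_c = encoder(codes.codes[None], mask[None])
    return x_c.data[0], map_c.data[0]


def mt_encode(tokens: SubstructureTokens, encoder: MTEncoder):
    """Encode one token sequence; returns numpy (x_t, map_t)."""
    encoder.eval()
    mask = np.zeros(tokens.token_ids.shape[0])
    mask[:tokens.n_real] = 1.0
    ids = np.where(mask > 0, tokens.token_ids + 1, 0)  # shift to 1-based, 0 pad
    x_t, map_t = encoder(ids[None], mask[None])
    return x_t.data[0], map_t.data[0]
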