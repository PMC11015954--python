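"""Pairwise protein-ligand representation learning.

Builds the ligand kernel from the three pooled ligand features, filters
the protein feature sequence with it to get the per-position response
vector r, combines r with the reconstruction-derived profile s into the
binding-region profile BR, computes bilinear interaction maps between the
protein feature map and each granular ligand map, fuses them with a
softmax attention over the concatenated ligand axis, and decodes the
fused vector to a scalar affinity.

All math functions operate on either numpy arrays or autodiff Tensors
and accept arbitrary leading batch dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, functional as F

__all__ = [
    "InteractionResult", "make_ligand_kernel", "response_vector",
    "assemble_binding_region", "minmax_normalize", "bilinear_map",
    "fuse_interactions", "predict_affinity",
]


@dataclass
class InteractionResult:
    r: np.ndarray                  # (theta_p,) response vector
    s: np.ndarray                  # (theta_p,) original binding area
    br: np.ndarray                 # (theta_p,) combined profile
    region: tuple[int, int]        # [start, end), width R
    i_pg: np.ndarray
    i_pc: np.ndarray
    i_pt: np.ndarray
    v_out: np.ndarray
    affinity: float


def make_ligand_kernel(x_g, x_c, x_t, weight, bias=None):
    """K_l = linear(concat(x_g, x_c, x_t)).

    weight: (L_g + L_c + L_t, L_s). Accepts batched (..., L) inputs.
    """
    f_l = F.concatenate([x_g, x_c, x_t], axis=-1)
    expected = f_l.shape[-1]
    w_shape = weight.shape
    if w_shape[0] != expected:
        raise ValueError(
            f"kernel projection expects input dim {w_shape[0]}, got {expected}")
    k_l = f_l @ weight
    if bias is not None:
        k_l = k_l + bias
    return k_l


def _zeros_like_rows(ref, n: int):
    shape = tuple(ref.shape[:-1]) + (n,)
    zeros = np.zeros(shape)
    return Tensor(zeros) if isinstance(ref, Tensor) else zeros


def response_vector(k_l, f_p, w_bs, mode: str = "correlation"):
    """Per-position response of a protein to a ligand kernel.

    k_l: (..., L_s); f_p: (..., T, d_p) protein feature map.

    mode="correlation" (default): w_bs (d_p, 1) projects each position to
    a scalar profile which is then filtered with k_l as a centred 1-D
    correlation kernel, zero-padded:
        r_i = sum_m k_l[m] * profile[i + m - floor(L_s/2)].

    mode="literal": w_bs (d_p, L_s) projects each position to L_s channels
    and r_i = sum_m k_l[m] * proj[i, m] (no positional offset).
    """
    t = f_p.shape[-2]
    l_s = k_l.shape[-1]
    if mode == "literal":
        if w_bs.shape[-1] != l_s:
            raise ValueError(
                f"literal mode needs w_bs with {l_s} output channels, "
                f"got {w_bs.shape[-1]}")
        proj = f_p @ w_bs                       # (..., T, L_s)
        if isinstance(proj, Tensor) or isinstance(k_l, Tensor):
            k_exp = k_l.reshape(*k_l.shape[:-1], 1, l_s) \
                if isinstance(k_l, Tensor) else np.expand_dims(k_l, -2)
        else:
            k_exp = np.expand_dims(k_l, -2)
        return (proj * k_exp).sum(axis=-1)
    if mode != "correlation":
        raise ValueError(f"unknown response mode {mode!r}")
    if w_bs.shape[-1] != 1:
        raise ValueError(
            f"correlation mode needs w_bs with one output column, "
            f"got {w_bs.shape[-1]}")
    profile = (f_p @ w_bs).reshape(*f_p.shape[:-2], t)   # (..., T)
    center = l_s // 2
    pad_left = _zeros_like_rows(profile, center)
    pad_right = _zeros_like_rows(profile, l_s - 1 - center)
    padded = F.concatenate([pad_left, profile, pad_right], axis=-1)
    r = None
    for m in range(l_s):
        term = k_l[..., m:m + 1] * padded[..., m:m + t]
        r = term if r is None else r + term
    return r


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def assemble_binding_region(r: np.ndarray, s: np.ndarray, R: int,
                            mode: str = "max"):
    """Combine response r and original-area s into BR and pick a region.

    BR is the elementwise max (mode="max", union-of-evidence default) or
    min (mode="min", shared-support) of the min-max normalised profiles.
    The region is the width-R half-open window whose midpoint is
    argmax(BR), clipped at the ends with the width preserved; ties at the
    maximum resolve to the response argmax.
    """
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape:
        raise ValueError(f"shape mismatch: r {r.shape} vs s {s.shape}")
    t = r.shape[0]
    if not 1 <= R <= t:
        raise ValueError(f"region width R={R} outside [1, {t}]")
    nr, ns = minmax_normalize(r), minmax_normalize(s)
    if mode == "max":
        br = np.maximum(nr, ns)
    elif mode == "min":
        br = np.minimum(nr, ns)
    else:
        raise ValueError(f"unknown combine mode {mode!r}")
    peak = br.max()
    mid = int(np.argmax(br))
    r_mid = int(np.argmax(nr))
    if br[r_mid] >= peak - 1e-12:   # prefer response evidence on ties
        mid = r_mid
    start = mid - R // 2
    start = max(0, min(start, t - R))
    return br, (start, start + R)


def bilinear_map(p, g, u, v, q, activation="relu"):
    """Bilinear interaction map I[i, j] = sum_c q_c * act(pU)[i,c] * act(gV)[j,c].

    p: (..., n_p, d_p); g: (..., n_g, d_g); u: (d_p, C); v: (d_g, C);
    q: (C,). Returns (..., n_p, n_g).
    """
    act = F.get_activation(activation)
    if p.shape[-1] != u.shape[0] or g.shape[-1] != v.shape[0]:
        raise ValueError(
            f"shape mismatch: p {p.shape} @ u {u.shape} / g {g.shape} @ v {v.shape}")
    a = act(p @ u)              # (..., n_p, C)
    b = act(g @ v)              # (..., n_g, C)
    return (a * q) @ b.swapaxes(-1, -2)


def fuse_interactions(i_pg, i_pc, i_pt, w_a, w_m, w_out=None, b_out=None):
    """Attention fusion of the three granular interaction maps.

    I = concat along the ligand axis; f_a = softmax(I W_m / n_lig) row-wise
    over the ligand axis; X_out = (I W_a) * f_a; v_out = linear(global
    average pool of X_out over the protein axis) (identity linear when
    w_out is None). Returns (X_out, v_out).
    """
    i_all = F.concatenate([i_pg, i_pc, i_pt], axis=-1)
    n_lig = i_all.shape[-1]
    if w_a.shape[0] != n_lig or w_m.shape[0] != n_lig:
        raise ValueError(
            f"fusion weights expect ligand dim {n_lig}, "
            f"got W_a {w_a.shape}, W_m {w_m.shape}")
    f_a = F.softmax((i_all @ w_m) * (1.0 / n_lig), axis=-1)
    x_out = (i_all @ w_a) * f_a
    pooled = x_out.mean(axis=-2)
    if w_out is None:
        return x_out, pooled
    v_out = pooled @ w_out
    if b_out is not None:
        v_out = v_out + b_out
    return x_out, v_out


def predict_affinity(v_out, head):
    """Scalar affinity from the fused interaction vector.

    ``head`` is either a callable module or a list of (W, b, activation)
    layer triples applied in order; the final output must be scalar per
    sample.
    """
    if callable(head):
        out = head(v_out)
    else:
        out = v_out
        for w, b, act in head:
            out = out @ w
            if b is not None:
                out = out + b
            if act is not None:
                out = F.get_activation(act)(out)
    return out
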