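"""End-to-end binding model: ligand encoders + protein VAE + interaction.

The model consumes batches of featurized pairs (see :func:`collate`) and
returns affinity predictions, the per-position response vector, and the
VAE quantities needed for the auxiliary objectives. Inference helpers
assemble the binding-region profile per pair.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import featurize as ft
from . import nn
from .interaction import (
    InteractionResult,
    assemble_binding_region,
    bilinear_map,
    fuse_interactions,
    make_ligand_kernel,
    response_vector,
)
from .ligand_encoders import CNNConfig, CNNEncoder, GATConfig, GATEncoder, MTConfig, MTEncoder
from .nn import Tensor
from .protein_vae import ProteinVAE, VAEConfig, reconstruction_binding_profile, reconstruction_target

__all__ = ["ModelConfig", "BindingModel", "collate", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class ModelConfig:
    max_atoms: int = 100          # theta_g
    max_codes: int = 100          # theta_c
    max_tokens: int = 50          # theta_t
    max_kmers: int = 1000         # theta_p
    token_len: int = 3            # l
    substructure_vocab_size: int = 256
    gat: GATConfig = field(default_factory=GATConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    mt: MTConfig = field(default_factory=MTConfig)
    vae: VAEConfig = field(default_factory=VAEConfig)
    kernel_dim: int = 64          # L_s
    bilinear_channels: int = 64   # C
    fused_dim: int = 256          # L
    response_mode: str = "correlation"
    region_combine: str = "max"
    top_fraction: float = 0.1
    region_scale: int = 10        # R

    def __post_init__(self):
        self.vae.max_positions = self.max_kmers

    @classmethod
    def small(cls, max_kmers: int = 96, **overrides) -> "ModelConfig":
        """Reduced-dimension configuration for desk-scale runs (dims <= 64)."""
        defaults = dict(
            max_atoms=48, max_codes=72, max_tokens=24, max_kmers=max_kmers,
            substructure_vocab_size=128,
            gat=GATConfig(embed_dim=32, out_dim=32, n_heads=2),
            cnn=CNNConfig(embed_dim=32, n_filters=32, kernel_size=7, out_dim=32),
            mt=MTConfig(embed_dim=32, n_heads=2, n_blocks=2, out_dim=32),
            vae=VAEConfig(n_filters=8, kernel_en=7, n_filters_de=8,
                          kernel_de=7, latent_dim=32, embed_dim=32,
                          max_positions=max_kmers),
            kernel_dim=16, bilinear_channels=16, fused_dim=64,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key, sub in (("gat", GATConfig), ("cnn", CNNConfig),
                         ("mt", MTConfig), ("vae", VAEConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


class BindingModel(nn.Module):
    def __init__(self, cfg: ModelConfig, vocab: ft.SubstructureVocab,
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        self.gat = GATEncoder(cfg.gat, rng)
        self.cnn = CNNEncoder(cfg.cnn, rng)
        self.mt = MTEncoder(cfg.mt, len(vocab), cfg.max_tokens, rng)
        self.vae = ProteinVAE(cfg.vae, rng)

        lig_dim = cfg.gat.out_dim + cfg.cnn.out_dim + cfg.mt.out_dim
        self.kernel_proj = nn.Linear(lig_dim, cfg.kernel_dim, rng)
        d_p = self.vae.feature_dim
        w_bs_cols = 1 if cfg.response_mode == "correlation" else cfg.kernel_dim
        self.w_bs = nn.Parameter(nn.glorot(rng, d_p, w_bs_cols, (d_p, w_bs_cols)))
        c = cfg.bilinear_channels
        self.u_p = nn.Parameter(nn.glorot(rng, d_p, c, (d_p, c)))
        self.v_g = nn.Parameter(nn.glorot(rng, cfg.gat.out_dim, c,
                                          (cfg.gat.out_dim, c)))
        self.v_c = nn.Parameter(nn.glorot(rng, cfg.cnn.out_dim, c,
                                          (cfg.cnn.out_dim, c)))
        self.v_t = nn.Parameter(nn.glorot(rng, cfg.mt.out_dim, c,
                                          (cfg.mt.out_dim, c)))
        self.q = nn.Parameter(rng.normal(0, 0.1, size=c))
        n_lig = cfg.max_atoms + cfg.max_codes + cfg.max_tokens
        self.w_a = nn.Parameter(nn.glorot(rng, n_lig, n_lig, (n_lig, n_lig)))
        self.w_m = nn.Parameter(nn.glorot(rng, n_lig, n_lig, (n_lig, n_lig)))
        self.fc_fuse = nn.Linear(n_lig, cfg.fused_dim, rng)
        self.head_hidden = nn.Linear(cfg.fused_dim, cfg.fused_dim // 2, rng)
        self.head_out = nn.Linear(cfg.fused_dim // 2, 1, rng)

    # ------------------------------------------------------------- forward
    def forward(self, batch: dict, rng: np.random.Generator | None = None):
        x_g, map_g = self.gat(Tensor(batch["atom_feats"]), batch["adj"],
                              batch["atom_mask"])
        x_c, map_c = self.cnn(batch["codes"], batch["code_mask"])
        x_t, map_t = self.mt(batch["token_ids"], batch["token_mask"])
        mu, log_var, fmap = self.vae.encode_ids(batch["kmer_ids"],
                                                batch["kmer_mask"])
        z, eps = self.vae.reparameterize(mu, log_var, rng)
        recon = self.vae.decode(z)

        k_l = make_ligand_kernel(x_g, x_c, x_t, self.kernel_proj.weight,
                                 self.kernel_proj.bias)
        r = response_vector(k_l, fmap, self.w_bs, mode=self.cfg.response_mode)
        i_pg = bilinear_map(fmap, map_g, self.u_p, self.v_g, self.q)
        i_pc = bilinear_map(fmap, map_c, self.u_p, self.v_c, self.q)
        i_pt = bilinear_map(fmap, map_t, self.u_p, self.v_t, self.q)
        _, pooled = fuse_interactions(i_pg, i_pc, i_pt, self.w_a, self.w_m)
        v_out = self.fc_fuse(pooled)
        affinity = self.head_out(self.head_hidden(v_out).relu())
        b = affinity.shape[0]
        return {
            "affinity": affinity.reshape(b),
            "response": r,
            "mu": mu, "log_var": log_var, "z": z, "eps": eps,
            "reconstruction": recon,
            "feature_map": fmap,
            "v_out": v_out,
            "maps": (i_pg, i_pc, i_pt),
        }

    # ----------------------------------------------------------- inference
    def predict_batch(self, batch: dict, region_scale: int | None = None
                      ) -> tuple[np.ndarray, list[InteractionResult]]:
        """Eval-mode predictions with assembled binding regions."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(batch)
        finally:
            if was_training:
                self.train()
        R = self.cfg.region_scale if region_scale is None else region_scale
        affinities = out["affinity"].data
        results = []
        for i in range(affinities.shape[0]):
            r_i = out["response"].data[i]
            s_i = reconstruction_binding_profile(
                out["reconstruction"].data[i], self.cfg.top_fraction,
                binary=False)
            br, region = assemble_binding_region(r_i, s_i, R,
                                                 mode=self.cfg.region_combine)
            i_pg, i_pc, i_pt = (m.data[i] for m in out["maps"])
            results.append(InteractionResult(
                r=r_i, s=s_i, br=br, region=region,
                i_pg=i_pg, i_pc=i_pc, i_pt=i_pt,
                v_out=out["v_out"].data[i], affinity=float(affinities[i])))
        return affinities, results


# ------------------------------------------------------------------ collate
def collate(records, cfg: ModelConfig, vocab: ft.SubstructureVocab) -> dict:
    """Featurize a list of PairRecord-like objects into batch arrays."""
    n = len(records)
    batch = {
        "atom_feats": np.zeros((n, cfg.max_atoms, ft.ATOM_FEATURE_DIM)),
        "adj": np.zeros((n, cfg.max_atoms, cfg.max_atoms)),
        "atom_mask": np.zeros((n, cfg.max_atoms)),
        "codes": np.zeros((n, cfg.max_codes), dtype=np.int64),
        "code_mask": np.zeros((n, cfg.max_codes)),
        "token_ids": np.zeros((n, cfg.max_tokens), dtype=np.int64),
        "token_mask": np.zeros((n, cfg.max_tokens)),
        "kmer_ids": np.zeros((n, cfg.max_kmers), dtype=np.int64),
        "kmer_mask": np.zeros((n, cfg.max_kmers)),
    }
    for i, rec in enumerate(records):
        g = ft.smiles_to_graph(rec.ligand_smiles, cfg.max_atoms)
        batch["atom_feats"][i] = g.node_features
        batch["adj"][i] = g.adjacency(self_loops=True)
        batch["atom_mask"][i, :g.n_real_atoms] = 1.0
        codes = ft.smiles_to_codes(rec.ligand_smiles, max_len=cfg.max_codes)
        batch["codes"][i] = codes.codes
        batch["code_mask"][i, :codes.n_real] = 1.0
        toks = ft.tokenize_substructures(rec.ligand_smiles, vocab,
                                         cfg.max_tokens)
        batch["token_ids"][i, :toks.n_real] = toks.token_ids[:toks.n_real] + 1
        batch["token_mask"][i, :toks.n_real] = 1.0
        ids, n_real = ft.protein_to_kmer_ids(rec.protein_seq, cfg.max_kmers)
        batch["kmer_ids"][i] = ids
        batch["kmer_mask"][i, :n_real] = 1.0
    batch["recon_target"] = reconstruction_target(batch["kmer_ids"])
    return batch


# --------------------------------------------------------------- checkpoints
def save_checkpoint(model: BindingModel, path) -> None:
    """Single-file archive: weights + config + sub-structure vocabulary."""
    state = model.state_dict()
    meta = json.dumps({
        "config": model.cfg.to_dict(),
        "vocab_tokens": model.vocab.tokens,
        "vocab_max_token_len": model.vocab.max_token_len,
    })
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> BindingModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    vocab = ft.SubstructureVocab(meta["vocab_tokens"],
                                 meta["vocab_max_token_len"])
    model = BindingModel(cfg, vocab)
    model.load_state_dict(state)
    model.eval()
    return model
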