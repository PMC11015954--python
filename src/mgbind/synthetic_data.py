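"""Desk-scale synthetic datasets with planted, recoverable binding rules.

Ligands are valid SMILES over a small dialect (branched C/N/O chains,
optional ring) with a counted pharmacophore atom; proteins are random
amino-acid sequences optionally carrying a planted binding motif; the
affinity follows an additive motif x pharmacophore rule plus Gaussian
noise, and the region label is the motif interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .featurize import AMINO_ACIDS
from .training import PairRecord

__all__ = ["SimConfig", "generate_ligand", "generate_protein",
           "generate_dataset"]


@dataclass
class SimConfig:
    n_pairs: int = 2000
    n_ligands: int = 200
    n_proteins: int = 100
    motif: str = "HWKH"
    pharmacophore: str = "N"
    base_affinity: float = 4.0
    effect_per_unit: float = 2.0
    max_effect_units: int = 3
    noise_sd: float = 0.3
    protein_len_range: tuple = (40, 80)
    ligand_len_range: tuple = (8, 20)
    motif_fraction: float = 0.5   # fraction of proteins with a planted motif
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.motif) >= self.protein_len_range[0]:
            raise ValueError("motif must be shorter than the minimum "
                             "protein length")
        for lo, hi in (self.protein_len_range, self.ligand_len_range):
            if not 1 <= lo <= hi:
                raise ValueError("invalid length range")


_BRANCH_CAPACITY = {"C": 2, "N": 1, "O": 0}


def generate_ligand(cfg: SimConfig, rng: np.random.Generator,
                    k: int | None = None) -> tuple[str, int]:
    """One random SMILES string and its pharmacophore count.

    With ``k`` given, exactly k pharmacophore atoms are placed (capped at
    the backbone length). Emitted strings stay inside the supported
    dialect: single bonds, branches, one optional ring.
    """
    lo, hi = cfg.ligand_len_range
    n = int(rng.integers(lo, hi + 1))
    if k is None:
        k = int(rng.integers(0, cfg.max_effect_units + 2))
    k = min(k, n)
    symbols = ["C"] * n
    if k:
        for p in rng.choice(n, size=k, replace=False):
            symbols[p] = cfg.pharmacophore
    for i in range(n):
        if symbols[i] == "C" and rng.random() < 0.2:
            symbols[i] = "O"
    branches: dict[int, str] = {}
    for i in range(1, n - 1):
        if _BRANCH_CAPACITY[symbols[i]] and rng.random() < 0.25:
            branches[i] = "C" * int(rng.integers(1, 3))
    ring = n >= 4 and rng.random() < 0.3
    parts = []
    for i, sym in enumerate(symbols):
        parts.append(sym)
        if ring and i == 0:
            parts.append("1")
        if i in branches:
            parts.append(f"({branches[i]})")
    if ring:
        parts.append("1")
    smiles = "".join(parts)
    count = sum(sym == cfg.pharmacophore for sym in symbols)
    count += sum(b.count(cfg.pharmacophore) for b in branches.values())
    return smiles, count


def generate_protein(cfg: SimConfig, rng: np.random.Generator,
                     plant_motif: bool) -> tuple[str, int | None]:
    """Uniform-random protein; optionally writes the motif at a uniform
    admissible position and reports it."""
    lo, hi = cfg.protein_len_range
    length = int(rng.integers(lo, hi + 1))
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    pos = None
    if plant_motif:
        pos = int(rng.integers(0, length - len(cfg.motif) + 1))
        seq[pos:pos + len(cfg.motif)] = list(cfg.motif)
    return "".join(seq), pos


def generate_dataset(cfg: SimConfig):
    """Sample ligand and protein pools, pair them, and apply the affinity
    rule. Returns (records, truth) where truth is a per-pair DataFrame
    with the latent generative variables."""
    rng = np.random.default_rng(cfg.seed)
    ligands = [generate_ligand(cfg, rng) for _ in range(cfg.n_ligands)]
    n_planted = int(round(cfg.motif_fraction * cfg.n_proteins))
    proteins = [generate_protein(cfg, rng, plant_motif=(i < n_planted))
                for i in range(cfg.n_proteins)]

    n_cells = cfg.n_ligands * cfg.n_proteins
    if cfg.n_pairs <= n_cells:
        flat = rng.choice(n_cells, size=cfg.n_pairs, replace=False)
    else:
        flat = rng.integers(0, n_cells, size=cfg.n_pairs)
    records, rows = [], []
    for cell in flat:
        li, pi = divmod(int(cell), cfg.n_proteins)
        smiles, k = ligands[li]
        seq, motif_pos = proteins[pi]
        planted = motif_pos is not None
        clean = cfg.base_affinity + (
            cfg.effect_per_unit * min(k, cfg.max_effect_units)
            if planted else 0.0)
        affinity = clean + rng.normal(0.0, cfg.noise_sd)
        region = ((motif_pos, motif_pos + len(cfg.motif))
                  if planted else None)
        records.append(PairRecord(ligand_smiles=smiles, protein_seq=seq,
                                  affinity=float(affinity), region=region))
        rows.append({"ligand_id": f"L{li:04d}", "protein_id": f"P{pi:04d}",
                     "ligand_smiles": smiles, "k": k,
                     "motif_planted": planted,
                     "motif_position": -1 if motif_pos is None else motif_pos,
                     "noiseless_affinity": clean,
                     "affinity": float(affinity)})
    return records, pd.DataFrame(rows)
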