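"""Featurization of ligands (SMILES) and proteins (amino-acid strings).

Three ligand views are produced: a molecular graph with 78-dimensional
atom descriptors, an integer character-code sequence over a frozen
64-letter SMILES alphabet, and a sub-structure token sequence from a
frequency-ranked corpus vocabulary. Proteins become overlapping 3-mer
matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolecularGraph", "LigandCodes", "SubstructureTokens", "SubstructureVocab",
    "ProteinKmerMatrix", "SmilesParseError", "EncodingError",
    "TokenizationError", "SMILES_CODES", "ATOM_FEATURE_DIM",
    "smiles_to_graph", "smiles_to_codes", "build_substructure_vocab",
    "tokenize_substructures", "decode_tokens", "protein_kmers",
    "protein_to_kmer_ids", "protein_to_kmers", "kmer_vocab_size",
    "read_vocab_tsv", "write_vocab_tsv",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class EncodingError(ValueError):
    """Raised when a character has no code in the active vocabulary."""


class TokenizationError(ValueError):
    """Raised when a string cannot be segmented over a sub-structure vocab."""


# --------------------------------------------------------------------------
# Frozen 64-letter SMILES character table. Codes are 1..64; 0 is padding.
# The layout is the DeepDTA-style alternating table; anchor pairs
# C->42, O->48, '1'->35, ')'->31, 'l'->25 are pinned by tests.
# --------------------------------------------------------------------------
_GROUP_A = "(.02468@BDFHLNPRTVX\\bdfhlnrt"          # codes 1..28
_GROUP_B = "#%)+-/13579=ACEGIKMOSUWYZ[]acegimosu"   # codes 29..64

SMILES_CODES: dict[str, int] = {
    **{ch: i + 1 for i, ch in enumerate(_GROUP_A)},
    **{ch: i + 29 for i, ch in enumerate(_GROUP_B)},
}

# GraphDTA-style atom descriptor: 44 element symbols + degree(11)
# + total H count(11) + implicit valence(11) + aromatic flag = 78.
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
]
ATOM_FEATURE_DIM = len(ATOM_SYMBOLS) + 11 + 11 + 11 + 1  # = 78

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ALPHABET = AMINO_ACIDS + "X"
_AA_INDEX = {ch: i for i, ch in enumerate(_AA_ALPHABET)}


# ------------------------------------------------------------------- types
@dataclass
class MolecularGraph:
    node_features: np.ndarray      # (max_atoms, 78)
    edges: list[tuple[int, int]]   # symmetric undirected pairs
    n_real_atoms: int

    def adjacency(self, self_loops: bool = False) -> np.ndarray:
        n = self.node_features.shape[0]
        adj = np.zeros((n, n))
        for i, j in self.edges:
            adj[i, j] = 1.0
        if self_loops:
            adj[np.arange(self.n_real_atoms), np.arange(self.n_real_atoms)] = 1.0
        return adj


@dataclass
class LigandCodes:
    codes: np.ndarray  # (max_len,) ints in [0, 64], 0 = padding
    n_real: int


@dataclass
class SubstructureTokens:
    token_ids: np.ndarray     # (max_tokens,) indices into vocab, 0-padded
    token_lengths: np.ndarray  # (max_tokens,) character lengths, 0-padded
    n_real: int


@dataclass
class SubstructureVocab:
    tokens: list[str]
    max_token_len: int
    frequency_floor: int = 1
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        if any(len(t) > self.max_token_len for t in self.tokens):
            raise ValueError("vocabulary token exceeds max_token_len")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index


@dataclass
class ProteinKmerMatrix:
    kmer_features: np.ndarray  # (max_len, embed_dim)
    n_real: int


# -------------------------------------------------------------- SMILES graph
def _one_hot(value, choices, unknown_last: bool = False) -> list[float]:
    if value not in choices:
        if not unknown_last:
            raise ValueError(f"value {value!r} outside supported range {choices}")
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def atom_descriptor(atom: Chem.Atom) -> np.ndarray:
    """78-dimensional per-atom descriptor."""
    feats = (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS, unknown_last=True)
        + _one_hot(min(atom.GetDegree(), 10), list(range(11)))
        + _one_hot(min(atom.GetTotalNumHs(), 10), list(range(11)))
        + _one_hot(min(atom.GetImplicitValence(), 10), list(range(11)))
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.array(feats)


def _locate_parse_error(smiles: str) -> int:
    for pos, ch in enumerate(smiles):
        if ch not in SMILES_CODES:
            return pos
    return 0


def smiles_to_graph(smiles: str, max_atoms: int) -> MolecularGraph:
    """Convert a SMILES string into a padded undirected molecular graph.

    Molecules with more than ``max_atoms`` heavy atoms are truncated;
    smaller ones are zero-padded.
    """
    if max_atoms < 1:
        raise ValueError(f"max_atoms must be >= 1, got {max_atoms}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        pos = _locate_parse_error(smiles)
        raise SmilesParseError(
            f"cannot parse SMILES {smiles!r} (around position {pos})")
    n_atoms = mol.GetNumAtoms()
    n_real = min(n_atoms, max_atoms)
    feats = np.zeros((max_atoms, ATOM_FEATURE_DIM))
    for atom in mol.GetAtoms():
        if atom.GetIdx() < n_real:
            feats[atom.GetIdx()] = atom_descriptor(atom)
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i < n_real and j < n_real:
            edges.append((i, j))
            edges.append((j, i))
    return MolecularGraph(node_features=feats, edges=edges, n_real_atoms=n_real)


# --------------------------------------------------------------- char codes
def smiles_to_codes(smiles: str, vocab: dict[str, int] | None = None,
                    max_len: int = 100,
                    unknown_code: int | None = None) -> LigandCodes:
    """Encode SMILES characters as integer codes (0 = padding).

    Strict by default: an unknown character raises :class:`EncodingError`
    unless ``unknown_code`` is given.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    vocab = SMILES_CODES if vocab is None else vocab
    codes = np.zeros(max_len, dtype=np.int64)
    n_real = min(len(smiles), max_len)
    for i in range(n_real):
        ch = smiles[i]
        if ch in vocab:
            codes[i] = vocab[ch]
        elif unknown_code is not None:
            codes[i] = unknown_code
        else:
            raise EncodingError(
                f"character {ch!r} at position {i} not in the SMILES vocabulary")
    return LigandCodes(codes=codes, n_real=n_real)


# ------------------------------------------------------------ sub-structures
def build_substructure_vocab(corpus: list[str], max_token_len: int,
                             vocab_size: int,
                             frequency_floor: int = 1) -> SubstructureVocab:
    """Frequency-ranked vocabulary of consecutive sub-sequences.

    All single characters of the corpus are always included (so any
    string over the corpus alphabet tokenizes); the most frequent
    multi-character substrings up to ``max_token_len`` fill the remaining
    slots. Ties break longer-first, then lexicographic.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    if max_token_len < 1:
        raise ValueError("max_token_len must be >= 1")
    counts: Counter[str] = Counter()
    for s in corpus:
        for length in range(1, max_token_len + 1):
            for start in range(len(s) - length + 1):
                counts[s[start:start + length]] += 1
    singles = sorted({ch for s in corpus for ch in s})
    multi = [t for t, c in counts.items() if len(t) > 1 and c >= frequency_floor]
    multi.sort(key=lambda t: (-counts[t], -len(t), t))
    tokens = list(singles)
    for t in multi:
        if len(tokens) >= vocab_size:
            break
        tokens.append(t)
    return SubstructureVocab(tokens=tokens, max_token_len=max_token_len,
                             frequency_floor=frequency_floor)


def tokenize_substructures(smiles: str, vocab: SubstructureVocab,
                           max_tokens: int = 50) -> SubstructureTokens:
    """Greedy longest-match left-to-right segmentation."""
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    ids: list[int] = []
    lengths: list[int] = []
    pos = 0
    while pos < len(smiles) and len(ids) < max_tokens:
        for length in range(min(vocab.max_token_len, len(smiles) - pos), 0, -1):
            piece = smiles[pos:pos + length]
            if piece in vocab:
                ids.append(vocab.index[piece])
                lengths.append(length)
                pos += length
                break
        else:
            raise TokenizationError(
                f"character {smiles[pos]!r} at position {pos} "
                f"not covered by the sub-structure vocabulary")
    token_ids = np.zeros(max_tokens, dtype=np.int64)
    token_lengths = np.zeros(max_tokens, dtype=np.int64)
    token_ids[:len(ids)] = ids
    token_lengths[:len(ids)] = lengths
    return SubstructureTokens(token_ids=token_ids, token_lengths=token_lengths,
                              n_real=len(ids))


def decode_tokens(tokens: SubstructureTokens, vocab: SubstructureVocab) -> str:
    return "".join(vocab.tokens[i] for i in tokens.token_ids[:tokens.n_real])


# ------------------------------------------------------------------ proteins
def protein_kmers(seq: str) -> list[str]:
    """Overlapping 3-mers of an amino-acid sequence."""
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} is shorter than 3")
    for pos, ch in enumerate(seq):
        if ch not in _AA_INDEX:
            raise EncodingError(
                f"illegal residue {ch!r} at position {pos}")
    return [seq[i:i + 3] for i in range(len(seq) - 2)]


def kmer_vocab_size() -> int:
    """Number of distinct 3-mer ids (padding id 0 excluded)."""
    return len(_AA_ALPHABET) ** 3


def kmer_id(kmer: str) -> int:
    """1-based integer id of a 3-mer; 0 is reserved for padding."""
    a, b, c = (_AA_INDEX[ch] for ch in kmer)
    n = len(_AA_ALPHABET)
    return 1 + (a * n + b) * n + c


def protein_to_kmer_ids(seq: str, max_len: int) -> tuple[np.ndarray, int]:
    """Integer 3-mer ids, truncated/zero-padded to ``max_len``."""
    kmers = protein_kmers(seq)
    n_real = min(len(kmers), max_len)
    ids = np.zeros(max_len, dtype=np.int64)
    ids[:n_real] = [kmer_id(k) for k in kmers[:n_real]]
    return ids, n_real


def protein_to_kmers(seq: str, max_len: int, embed_dim: int,
                     embedding) -> ProteinKmerMatrix:
    """Embed overlapping 3-mers with a caller-supplied 3-mer -> vector map."""
    kmers = protein_kmers(seq)
    n_real = min(len(kmers), max_len)
    mat = np.zeros((max_len, embed_dim))
    for i in range(n_real):
        vec = np.asarray(embedding[kmers[i]], dtype=np.float64)
        if vec.shape != (embed_dim,):
            raise ValueError(
                f"embedding for {kmers[i]!r} has shape {vec.shape}, "
                f"expected ({embed_dim},)")
        mat[i] = vec
    return ProteinKmerMatrix(kmer_features=mat, n_real=n_real)


# ----------------------------------------------------------------- vocab I/O
def write_vocab_tsv(vocab: dict[str, int] | SubstructureVocab, path) -> None:
    """Two-column (token, id) TSV."""
    if isinstance(vocab, SubstructureVocab):
        items = [(t, i) for i, t in enumerate(vocab.tokens)]
    else:
        items = sorted(vocab.items(), key=lambda kv: kv[1])
    with open(path, "w") as fh:
        for token, idx in items:
            fh.write(f"{token}\t{idx}\n")


def read_vocab_tsv(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            token, idx = line.split("\t")
            out[token] = int(idx)
    return out
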