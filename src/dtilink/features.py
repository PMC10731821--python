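"""Local (structure-derived) drug and protein features.

Drugs: SMILES -> Avalon substructure fingerprint -> 64-dimensional reduction
(seeded single-hidden-layer autoencoder, or PCA as a deterministic drop-in).

Proteins: a width-3 sliding window over the sequence, each residue mapped to
one of four biochemical groups (non-polar, polar-neutral, acidic, basic), so
each window is one of 4^3 = 64 group-triplets; the feature vector counts
windows per triplet, normalized to frequencies by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from rdkit import Chem
from rdkit.Avalon import pyAvalonTools
from sklearn.decomposition import PCA

__all__ = [
    "AA_GROUPS",
    "GROUP_CODES",
    "avalon_fingerprint",
    "read_smiles_table",
    "fingerprint_matrix",
    "Autoencoder",
    "reduce_features",
    "protein_feature_vector",
    "triplet_index",
    "read_fasta",
]

logger = logging.getLogger(__name__)

# Textbook polarity classes of the 20 standard amino acids.  Non-standard
# codes (X, B, Z, U, O, ...) are deliberately absent: windows containing one
# are skipped rather than guessed at.
AA_GROUPS: dict[str, frozenset[str]] = {
    "non-polar": frozenset("GAVLIPFMW"),
    "polar-neutral": frozenset("STCYNQ"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KRH"),
}
GROUP_CODES: dict[str, int] = {"non-polar": 0, "polar-neutral": 1, "acidic": 2, "basic": 3}

_RESIDUE_CODE: dict[str, int] = {
    aa: GROUP_CODES[group] for group, members in AA_GROUPS.items() for aa in members
}

N_TRIPLETS = 64  # 4 groups ** window of 3


def avalon_fingerprint(smiles: str, nbits: int = 512, drug_id: str | None = None) -> np.ndarray:
    """Binary Avalon substructure fingerprint of one molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = drug_id if drug_id is not None else smiles
        raise ValueError(f"unparseable SMILES for drug {label!r}")
    fp = pyAvalonTools.GetAvalonFP(mol, nBits=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def read_smiles_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``drug_id<TAB>smiles`` table (header line optional)."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>smiles'")
            if lineno == 1 and fields[1].lower() in ("smiles",):
                continue
            out[fields[0]] = fields[1]
    if not out:
        raise ValueError(f"{path}: no SMILES rows found")
    return out


def fingerprint_matrix(smiles_map: dict[str, str], nbits: int = 512) -> tuple[list[str], np.ndarray]:
    """Stack fingerprints row-wise for all drugs, preserving mapping order."""
    ids = list(smiles_map)
    rows = np.stack([avalon_fingerprint(smiles_map[i], nbits, drug_id=i) for i in ids])
    return ids, rows


@dataclass
class Autoencoder:
    """Single-hidden-layer autoencoder with a linear code and sigmoid output.

    Trained full-batch with gradient descent on mean-squared reconstruction
    error; all state is seeded so fitting is bitwise reproducible.
    """

    target_dim: int = 64
    epochs: int = 150
    learning_rate: float = 0.1
    seed: int = 0
    losses_: list[float] = field(default_factory=list, repr=False)

    def fit(self, X: np.ndarray) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        scale1 = 1.0 / np.sqrt(d)
        scale2 = 1.0 / np.sqrt(self.target_dim)
        self.W1 = rng.uniform(-scale1, scale1, size=(d, self.target_dim))
        self.b1 = np.zeros(self.target_dim)
        self.W2 = rng.uniform(-scale2, scale2, size=(self.target_dim, d))
        self.b2 = np.zeros(d)
        self.losses_ = []
        for _ in range(self.epochs):
            H = X @ self.W1 + self.b1
            out = 1.0 / (1.0 + np.exp(-(H @ self.W2 + self.b2)))
            err = out - X
            self.losses_.append(float(np.mean(err**2)))
            g_out = (2.0 / err.size) * err * out * (1 - out)
            gW2 = H.T @ g_out
            gb2 = g_out.sum(axis=0)
            g_h = g_out @ self.W2.T
            gW1 = X.T @ g_h
            gb1 = g_h.sum(axis=0)
            lr = self.learning_rate
            self.W1 -= lr * gW1
            self.b1 -= lr * gb1
            self.W2 -= lr * gW2
            self.b2 -= lr * gb2
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.W1 + self.b1


def reduce_features(
    matrix: np.ndarray,
    target_dim: int = 64,
    method: str = "autoencoder",
    seed: int = 0,
) -> np.ndarray:
    """Reduce row features to ``target_dim`` columns.

    ``autoencoder`` uses the seeded :class:`Autoencoder` code layer;
    ``pca`` is a deterministic drop-in (full SVD solver, axes oriented so
    the largest-magnitude loading is positive).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if target_dim > X.shape[1]:
        raise ValueError(f"target_dim {target_dim} exceeds input dimension {X.shape[1]}")
    if method == "autoencoder":
        return Autoencoder(target_dim=target_dim, seed=seed).fit(X).encode(X)
    if method == "pca":
        n_comp = min(target_dim, X.shape[0] - 1, X.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        reduced = pca.fit_transform(X)
        comp = pca.components_
        signs = np.sign(comp[np.arange(n_comp), np.argmax(np.abs(comp), axis=1)])
        signs[signs == 0] = 1.0
        reduced = reduced * signs
        if n_comp < target_dim:  # pad rank-deficient reductions with zeros
            reduced = np.hstack([reduced, np.zeros((X.shape[0], target_dim - n_comp))])
        return reduced
    raise ValueError("method must be 'autoencoder' or 'pca'")


def triplet_index(window: str) -> int:
    """Base-4 positional code of a 3-residue window: ``16*g1 + 4*g2 + g3``."""
    if len(window) != 3:
        raise ValueError("window must have exactly 3 residues")
    g1, g2, g3 = (_RESIDUE_CODE[a] for a in window)
    return 16 * g1 + 4 * g2 + g3


def protein_feature_vector(sequence: str, normalize: bool = True) -> np.ndarray:
    """Length-64 group-triplet composition of an amino-acid sequence.

    A width-3 window slides with step 1; windows containing a residue outside
    the 20 standard amino acids are skipped.  With ``normalize`` the counts
    are divided by the number of valid windows (so they sum to 1 whenever at
    least one window is valid); otherwise raw integer counts are returned.
    """
    seq = sequence.upper()
    counts = np.zeros(N_TRIPLETS, dtype=float)
    if len(seq) < 3:
        logger.warning("sequence of length %d has no width-3 windows", len(seq))
        return counts
    valid = 0
    for i in range(len(seq) - 2):
        window = seq[i : i + 3]
        if all(a in _RESIDUE_CODE for a in window):
            counts[triplet_index(window)] += 1
            valid += 1
    if normalize and valid > 0:
        counts /= valid
    return counts


def _fasta_id(header_id: str) -> str:
    """UniProt-style ``sp|ACC|NAME`` headers yield ACC; otherwise the first token."""
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id.split()[0]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences, keyed by accession, multi-line records joined."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records[_fasta_id(rec.id)] = seq
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records
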