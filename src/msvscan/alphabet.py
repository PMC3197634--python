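"""Protein alphabet, degeneracy mapping, and background residue composition.

Residues are handled internally as small integers 0..19 in the canonical
order ``ACDEFGHIKLMNPQRSTVWY``; every degenerate or unknown code maps to the
extra index 20 (``X``), which scores zero bits everywhere (neutral under
log-odds).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
K = len(AMINO_ACIDS)  # 20
X_INDEX = K  # index of the wildcard residue

# codes that legally appear in protein sequence data but are not one of the 20
DEGENERATE_CODES = "BZJUOX*"

_CODE_TO_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Average residue composition of well-curated protein databases
# (Swiss-Prot-style frequencies; normalized below).
_BG = {
    "A": 0.0787, "R": 0.0551, "N": 0.0405, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0708, "H": 0.0227, "I": 0.0598,
    "L": 0.0966, "K": 0.0584, "M": 0.0241, "F": 0.0386, "P": 0.0470,
    "S": 0.0657, "T": 0.0534, "W": 0.0109, "Y": 0.0292, "V": 0.0686,
}

BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS], dtype=float)
BACKGROUND /= BACKGROUND.sum()

# translation table: byte value -> residue index (X for anything unknown)
_ENCODE_TABLE = np.full(256, X_INDEX, dtype=np.int8)
for _aa, _i in _CODE_TO_INDEX.items():
    _ENCODE_TABLE[ord(_aa)] = _i
    _ENCODE_TABLE[ord(_aa.lower())] = _i


class Alphabet:
    """The 20-letter amino acid alphabet with degenerate codes mapped to X.

    Exists mostly as a namespace: all methods are stateless, and a single
    module-level instance :data:`AMINO` is shared by the whole package.
    """

    symbols = AMINO_ACIDS
    size = K

    def encode(self, seq: str) -> np.ndarray:
        """Encode a residue string to an int8 array (values 0..20)."""
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        return _ENCODE_TABLE[raw].copy()

    def decode(self, idx: np.ndarray) -> str:
        letters = AMINO_ACIDS + "X"
        return "".join(letters[i] for i in idx)

    def canonicalize(self, seq: str) -> str:
        """Uppercase and map every degenerate code to X."""
        return self.decode(self.encode(seq))

    def count_degenerate(self, seq: str) -> int:
        return int(np.sum(self.encode(seq) == X_INDEX))


AMINO = Alphabet()


def encode_seqs(seqs: list[str]) -> np.ndarray:
    """Encode same-length sequences into an (n, L) int8 matrix."""
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal length for batch encoding")
    out = np.empty((len(seqs), L), dtype=np.int8)
    for i, s in enumerate(seqs):
        out[i] = AMINO.encode(s)
    return out
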