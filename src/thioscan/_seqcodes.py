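"""Shared numeric encodings for nucleotide and amino-acid sequences.

Everything downstream (the ORF caller, the profile-HMM kernels, the motif
scanner) works on small integer codes so that numpy/numba can do the heavy
lifting; this module is the single place those encodings are defined.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

# Canonical 20-letter amino-acid alphabet; index 20 is the wildcard X
# (emitted for any codon containing an ambiguous base).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
X_CODE = 20
N_AA = 20

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _NT_CODE[raw]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT.get(c, "N") for c in reversed(seq))


def encode_protein(protein: str) -> np.ndarray:
    """Encode an amino-acid string; residues outside the 20-letter alphabet map to X."""
    out = np.full(len(protein), X_CODE, dtype=np.uint8)
    for i, aa in enumerate(protein):
        out[i] = AA_INDEX.get(aa, X_CODE)
    return out


def _build_codon_lookup(table_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon amino-acid byte, stop flag and start flag for codon ids 16a+4b+c."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = np.full(64, ord("X"), dtype=np.uint8)
    stop = np.zeros(64, dtype=bool)
    start = np.zeros(64, dtype=bool)
    bases = "ACGT"
    for i in range(64):
        codon = bases[i >> 4] + bases[(i >> 2) & 3] + bases[i & 3]
        if codon in table.stop_codons:
            aa[i] = ord("*")
            stop[i] = True
        else:
            aa[i] = ord(table.forward_table[codon])
        if codon in table.start_codons:
            start[i] = True
    return aa, stop, start


_CODON_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def codon_tables(table_id: int = 11) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if table_id not in _CODON_CACHE:
        _CODON_CACHE[table_id] = _build_codon_lookup(table_id)
    return _CODON_CACHE[table_id]


def codon_ids(nt_codes: np.ndarray) -> np.ndarray:
    """Codon id starting at every position (length L-2); 64 marks an ambiguous codon."""
    a, b, c = nt_codes[:-2], nt_codes[1:-1], nt_codes[2:]
    valid = (a < 4) & (b < 4) & (c < 4)
    ids = (a.astype(np.int16) << 4) | (b.astype(np.int16) << 2) | c
    ids[~valid] = 64
    return ids


def codon_id_of(codon: str) -> int:
    codes = encode_nt(codon)
    if codes.max() > 3:
        raise ValueError(f"ambiguous codon {codon!r}")
    return int((codes[0] << 4) | (codes[1] << 2) | codes[2])
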