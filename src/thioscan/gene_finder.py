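"""Deterministic six-frame ORF caller with a small-ORF rescue pass.

The caller is intentionally simple: an ORF runs from a start codon to the
first in-frame stop, and per stop codon only the longest ORF is kept
(leftmost start on the forward strand). There is no coding-potential model;
users with trusted annotations can bypass it entirely. The rescue pass
re-scans a restricted region with a short-protein length window so that
small precursor-peptide genes (<360 bp) missed at the default length cutoff
can still be recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seqcodes import codon_ids, codon_tables, encode_nt
from .sequence_io import GeneCall, GenomeSequence

DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
DEFAULT_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class OrfParams:
    """ORF-calling parameters.

    ``rescue_max_protein_aa`` defaults to 119 aa: thiopeptide precursor
    peptides are under 120 residues, and their genes (<360 bp) are the ones
    routinely missed by standard gene finders.
    """

    min_protein_aa: int = 30
    start_codons: frozenset[str] = DEFAULT_START_CODONS
    stop_codons: frozenset[str] = DEFAULT_STOP_CODONS
    translation_table: int = 11
    rescue_min_protein_aa: int = 15
    rescue_max_protein_aa: int = 119

    def __post_init__(self) -> None:
        if self.min_protein_aa < 1:
            raise ValueError("min_protein_aa must be >= 1")
        if not self.rescue_min_protein_aa < self.rescue_max_protein_aa < 120:
            raise ValueError("rescue window must satisfy min < max < 120 aa")


def translate(cds: str, table: int = 11, initiator: bool = False) -> str:
    """Translate a CDS with the given code; trailing stop dropped, N-codons -> X.

    With ``initiator=True`` the first codon is translated as Met regardless
    of which start codon it is (the bacterial initiator rule).
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa_lut, _, _ = codon_tables(table)
    codes = encode_nt(cds)
    n = len(cds) // 3
    if n == 0:
        return ""
    cod = (
        codes[0::3].astype(np.int16) << 4
        | codes[1::3].astype(np.int16) << 2
        | codes[2::3]
    )
    ambiguous = (codes[0::3] > 3) | (codes[1::3] > 3) | (codes[2::3] > 3)
    cod = np.where(ambiguous, 64, cod)
    lut = np.concatenate([aa_lut, np.array([ord("X")], dtype=np.uint8)])
    prot = lut[cod].tobytes().decode("ascii")
    if prot.endswith("*"):
        prot = prot[:-1]
    if initiator and prot:
        prot = "M" + prot[1:]
    return prot


def _codon_masks(params: OrfParams) -> tuple[np.ndarray, np.ndarray]:
    from ._seqcodes import codon_id_of

    start = np.zeros(65, dtype=bool)
    stop = np.zeros(65, dtype=bool)
    for c in params.start_codons:
        start[codon_id_of(c)] = True
    for c in params.stop_codons:
        stop[codon_id_of(c)] = True
    return start, stop


def _scan_strand(
    codes: np.ndarray,
    params: OrfParams,
    min_aa: int,
    max_aa: int | None,
) -> list[tuple[int, int, str]]:
    """ORFs on one strand as (start, end, protein) in local forward coordinates."""
    L = len(codes)
    if L < 3:
        return []
    cod = codon_ids(codes)
    start_mask, stop_mask = _codon_masks(params)
    aa_lut, _, _ = codon_tables(params.translation_table)
    lut = np.concatenate([aa_lut, np.array([ord("X")], dtype=np.uint8)])
    out: list[tuple[int, int, str]] = []
    for frame in range(3):
        fc = cod[frame::3]
        starts = np.flatnonzero(start_mask[fc])
        stops = np.flatnonzero(stop_mask[fc])
        prev = -1
        for s in stops:
            # leftmost usable start strictly after the previous in-frame stop
            lo = np.searchsorted(starts, prev + 1)
            if max_aa is not None:
                lo = max(lo, np.searchsorted(starts, s - max_aa))
            if lo < len(starts) and starts[lo] < s:
                p = starts[lo]
                if s - p >= min_aa:
                    g_start = frame + 3 * int(p)
                    g_end = frame + 3 * int(s) + 3
                    prot_codes = fc[p:s]
                    prot = lut[np.where(prot_codes > 63, 64, prot_codes)]
                    prot = prot.tobytes().decode("ascii")
                    prot = "M" + prot[1:]  # initiator codon translates as Met
                    out.append((g_start, g_end, prot))
            prev = s
    return out


def find_orfs(
    genome: GenomeSequence,
    params: OrfParams | None = None,
    *,
    _min_aa: int | None = None,
    _max_aa: int | None = None,
    _offset: int = 0,
    _source: str = "builtin_orf",
) -> list[GeneCall]:
    """Call ORFs on all six frames of ``genome``.

    Minus-strand ORFs are reported on the forward axis with strand='-'.
    ORFs truncated by the contig ends (no start or no stop in range) are
    not called.
    """
    params = params or OrfParams()
    if genome.length < 3:
        return []
    min_aa = params.min_protein_aa if _min_aa is None else _min_aa
    codes = encode_nt(genome.seq)
    L = len(codes)
    raw: list[tuple[int, int, str, str]] = []
    for s, e, prot in _scan_strand(codes, params, min_aa, _max_aa):
        raw.append((s, e, "+", prot))
    rc = codes[::-1].copy()
    rc[rc < 4] = 3 - rc[rc < 4]
    for s, e, prot in _scan_strand(rc, params, min_aa, _max_aa):
        raw.append((L - e, L - s, "-", prot))
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    calls = []
    for i, (s, e, strand, prot) in enumerate(raw, start=1):
        calls.append(
            GeneCall(
                gene_id=f"{genome.id}_orf{_offset + s:08d}_{strand}",
                contig_id=genome.id,
                start=_offset + s,
                end=_offset + e,
                strand=strand,
                protein=prot,
                source=_source,
            )
        )
    return calls


def rescue_small_orfs(
    genome: GenomeSequence,
    region: tuple[int, int],
    params: OrfParams | None = None,
    existing: list[GeneCall] | None = None,
) -> list[GeneCall]:
    """Second-pass ORF calling over ``region`` with the short-protein window.

    Returns calls marked ``source='rescue'``; any call identical in
    (start, end, strand) to one in ``existing`` is suppressed.
    """
    params = params or OrfParams()
    lo = max(0, region[0])
    hi = min(genome.length, region[1])
    if hi - lo < 3:
        return []
    sub = GenomeSequence(id=genome.id, seq=genome.seq[lo:hi])
    calls = find_orfs(
        sub,
        params,
        _min_aa=params.rescue_min_protein_aa,
        _max_aa=params.rescue_max_protein_aa,
        _offset=lo,
        _source="rescue",
    )
    if existing:
        seen = {(g.start, g.end, g.strand) for g in existing}
        calls = [g for g in calls if (g.start, g.end, g.strand) not in seen]
    return calls
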