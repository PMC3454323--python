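"""Leader/core cleavage-site detection in thiopeptide precursor peptides.

Thiopeptide structural (core) peptides are Cys/Ser/Thr-rich and strongly
conserved; the scanner uses the 11-position consensus pattern
``SCTT[CS][GI]CT[CS]S[CS]`` both as an exact degenerate pattern and as a
position weight matrix with exact p-values. P-values are the probability,
under the background model, that a random 11-mer scores at least as high as
the observed window, computed by dynamic programming over the discretized
score distribution (bin width 0.01 bits, shared by the scanner so DP
p-values and window scores live on the same grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seqcodes import AA_ALPHABET, AA_INDEX, N_AA
from .sequence_io import GeneCall

DEFAULT_PATTERN = "SCTT[CS][GI]CT[CS]S[CS]"
DEFAULT_P_THRESHOLD = 1e-4
SCORE_BIN_BITS = 0.01
DISALLOWED_FLOOR = 0.01


def parse_pattern(pattern: str) -> tuple[frozenset[str], ...]:
    """Parse a bracket-notation degenerate pattern into per-position residue sets."""
    sets: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            allowed = pattern[i + 1 : j]
            i = j + 1
        else:
            allowed = c
            i += 1
        allowed = allowed.upper()
        if not allowed or any(a not in AA_INDEX for a in allowed):
            raise ValueError(f"bad pattern position {allowed!r}")
        sets.append(frozenset(allowed))
    if not sets:
        raise ValueError("empty pattern")
    return tuple(sets)


@dataclass
class StructuralMotif:
    """A degenerate core-peptide pattern with a derived log-odds PWM.

    Allowed residues at a position share the column probability mass
    uniformly after a small floor (0.01) is granted to each disallowed
    residue, keeping log-odds scores finite.
    """

    pattern: tuple[frozenset[str], ...]
    background: np.ndarray
    pwm_bits: np.ndarray = field(init=False)  # (length, 20)
    _int_scores: np.ndarray = field(init=False, repr=False)
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_pattern(
        cls, pattern: str = DEFAULT_PATTERN, background: np.ndarray | None = None
    ) -> "StructuralMotif":
        bg = (
            np.full(N_AA, 1.0 / N_AA)
            if background is None
            else np.asarray(background, float)
        )
        return cls(pattern=parse_pattern(pattern), background=bg)

    def __post_init__(self) -> None:
        L = len(self.pattern)
        probs = np.empty((L, N_AA))
        for i, allowed in enumerate(self.pattern):
            n_dis = N_AA - len(allowed)
            p_allowed = (1.0 - DISALLOWED_FLOOR * n_dis) / len(allowed)
            for a in range(N_AA):
                probs[i, a] = (
                    p_allowed if AA_ALPHABET[a] in allowed else DISALLOWED_FLOOR
                )
        self.pwm_bits = np.log2(probs / self.background)
        self._int_scores = np.rint(self.pwm_bits / SCORE_BIN_BITS).astype(np.int64)

    @property
    def length(self) -> int:
        return len(self.pattern)

    def _survival(self) -> tuple[np.ndarray, int]:
        """Exact survival function of the integer window score under background."""
        if "sf" not in self._cache:
            pmf = np.array([1.0])
            offset = 0  # score value of pmf[0]
            for i in range(self.length):
                col = self._int_scores[i]
                lo, hi = int(col.min()), int(col.max())
                col_pmf = np.zeros(hi - lo + 1)
                for a in range(N_AA):
                    col_pmf[col[a] - lo] += self.background[a]
                pmf = np.convolve(pmf, col_pmf)
                offset += lo
            sf = np.cumsum(pmf[::-1])[::-1]
            self._cache["sf"] = (sf, offset)
        return self._cache["sf"]

    def window_int_score(self, window_codes: np.ndarray) -> int:
        """Integer-binned score of one window; wildcard X takes the column minimum."""
        s = 0
        for i, c in enumerate(window_codes):
            col = self._int_scores[i]
            s += int(col[c]) if c < N_AA else int(col.min())
        return s

    def pvalue_of_int_score(self, s: int) -> float:
        sf, offset = self._survival()
        idx = s - offset
        if idx <= 0:
            return 1.0
        if idx >= len(sf):
            return 0.0
        return float(sf[idx])


@dataclass
class MotifMatch:
    offset: int
    score_bits: float
    pvalue: float
    exact: bool = False


@dataclass
class PrecursorPeptide:
    """A precursor peptide split into leader and core segments."""

    gene: GeneCall
    leader: str
    core: str
    cleavage_index: int | None
    motif_pvalue: float | None
    evidence: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.cleavage_index is not None:
            if self.leader + self.core != self.gene.protein:
                raise ValueError("leader + core must reconstruct the protein")
            if len(self.leader) != self.cleavage_index:
                raise ValueError("cleavage_index inconsistent with leader length")


def motif_match(protein: str, motif: StructuralMotif) -> list[tuple[int, bool]]:
    """Offsets of windows satisfying every positional residue set exactly."""
    L = motif.length
    out: list[tuple[int, bool]] = []
    for off in range(len(protein) - L + 1):
        if all(protein[off + i] in motif.pattern[i] for i in range(L)):
            out.append((off, True))
    return out


def pwm_scan(
    protein: str,
    motif: StructuralMotif,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[MotifMatch]:
    """Score every window under the PWM; return matches with exact p-values.

    Results are sorted by p-value, then offset. Windows containing the
    wildcard X take the column-minimum score at those positions.
    """
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    L = motif.length
    n = len(protein) - L + 1
    if n <= 0:
        return []
    codes = np.array([AA_INDEX.get(c, N_AA) for c in protein], dtype=np.int64)
    exact_offsets = {off for off, _ in motif_match(protein, motif)}
    out: list[MotifMatch] = []
    for off in range(n):
        s = motif.window_int_score(codes[off : off + L])
        p = motif.pvalue_of_int_score(s)
        if p <= p_threshold:
            out.append(
                MotifMatch(
                    offset=off,
                    score_bits=s * SCORE_BIN_BITS,
                    pvalue=p,
                    exact=off in exact_offsets,
                )
            )
    out.sort(key=lambda m: (m.pvalue, m.offset))
    return out


def split_precursor(
    gene: GeneCall,
    matches: Sequence[MotifMatch],
    evidence: set[str] | None = None,
) -> PrecursorPeptide:
    """Split a precursor at the best motif match (lowest p-value).

    Ties go to the rightmost match: known thiopeptide cores are C-terminal.
    The core starts at the motif's first residue; the leader is everything
    upstream.
    """
    if not matches:
        raise ValueError("no motif matches: cannot resolve a cleavage site")
    best_p = min(m.pvalue for m in matches)
    cleavage = max(m.offset for m in matches if m.pvalue == best_p)
    ev = set(evidence) if evidence is not None else {"motif"}
    return PrecursorPeptide(
        gene=gene,
        leader=gene.protein[:cleavage],
        core=gene.protein[cleavage:],
        cleavage_index=cleavage,
        motif_pvalue=best_p,
        evidence=ev,
    )
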