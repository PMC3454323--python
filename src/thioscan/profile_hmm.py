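"""Profile HMMs for thiopeptide protein families: build, score, calibrate, search.

A profile is built from a seed alignment (aligned FASTA or Stockholm) with
Laplace smoothing; scoring is exact local dynamic programming (Viterbi for
reported bit scores and envelopes, forward available for diagnostics), and
statistical significance comes from a Gumbel law fitted to scores of random
background sequences. ``search_proteome`` scores a whole predicted proteome
against a library of family profiles and keeps the best hit per gene and
family above the score/E-value thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from ._dp import forward_kernel, viterbi_kernel
from ._seqcodes import AA_ALPHABET, AA_INDEX, N_AA, encode_protein
from .sequence_io import GeneCall

LN2 = math.log(2.0)
EULER_GAMMA = 0.5772156649015329

# Roles a family can play in cluster detection / classification.
ROLE_ANCHOR_CYCLASE = "anchor_cyclase"
ROLE_ANCHOR_DEHYDRATASE = "anchor_dehydratase"
ROLE_ACCESSORY = "accessory"
ROLE_TYPE1_MARKER = "type1_marker"
ROLE_TYPE2_MARKER_RADICAL = "type2_marker_radical"
ROLE_TYPE2_MARKER_CYCLASE = "type2_marker_cyclase"
ROLE_PREP = "prep_profile"

VALID_ROLES = {
    ROLE_ANCHOR_CYCLASE,
    ROLE_ANCHOR_DEHYDRATASE,
    ROLE_ACCESSORY,
    ROLE_TYPE1_MARKER,
    ROLE_TYPE2_MARKER_RADICAL,
    ROLE_TYPE2_MARKER_CYCLASE,
    ROLE_PREP,
}

DEFAULT_MIN_BITS = 20.0
DEFAULT_MAX_EVALUE = 1e-3


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


@dataclass
class ProfileHMM:
    """A match/insert/delete protein profile with optional Gumbel calibration.

    ``transitions`` columns are (M>M, M>I, M>D, I>M, I>I, D>M, D>D) per
    match state.
    """

    family_id: str
    n_match: int
    match_emissions: np.ndarray  # (n_match, 20)
    insert_emissions: np.ndarray  # (n_match, 20)
    transitions: np.ndarray  # (n_match, 7)
    background: np.ndarray  # (20,)
    accession: str | None = None
    gumbel_mu: float | None = None
    gumbel_lambda: float | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> None:
        if self.n_match < 1:
            raise ValueError("profile needs at least one match state")
        for name, arr in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            if arr.shape != (self.n_match, N_AA):
                raise ValueError(f"{name} has shape {arr.shape}")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")
        if not np.allclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background does not sum to 1")
        t = self.transitions
        if t.shape != (self.n_match, 7):
            raise ValueError(f"transitions have shape {t.shape}")
        groups = (t[:, 0] + t[:, 1] + t[:, 2], t[:, 3] + t[:, 4], t[:, 5] + t[:, 6])
        for g in groups:
            if not np.allclose(g, 1.0, atol=1e-9):
                raise ValueError("transition groups do not sum to 1")

    # -- derived arrays -----------------------------------------------------

    def _dp_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if "dp" not in self._cache:
            bg = self.background
            with np.errstate(divide="ignore", invalid="ignore"):
                mlo = np.log(self.match_emissions / bg)
                ilo = np.log(self.insert_emissions / bg)
                tr = np.log(self.transitions)
            # zero-probability emissions/transitions are simply impossible
            for arr in (mlo, ilo, tr):
                arr[~np.isfinite(arr)] = -1.0e30
            # column 20: wildcard X scores as background (log-odds 0)
            mlo = np.hstack([mlo, np.zeros((self.n_match, 1))])
            ilo = np.hstack([ilo, np.zeros((self.n_match, 1))])
            self._cache["dp"] = (
                np.ascontiguousarray(mlo),
                np.ascontiguousarray(ilo),
                np.ascontiguousarray(tr),
            )
        return self._cache["dp"]

    @property
    def consensus(self) -> str:
        if "consensus" not in self._cache:
            idx = np.argmax(self.match_emissions, axis=1)
            self._cache["consensus"] = "".join(AA_ALPHABET[i] for i in idx)
        return self._cache["consensus"]

    def consensus_kmers(self, k: int = 4) -> np.ndarray:
        key = ("kmers", k)
        if key not in self._cache:
            codes = encode_protein(self.consensus).astype(np.int64)
            self._cache[key] = np.unique(_kmer_codes(codes, k))
        return self._cache[key]


@dataclass
class DomainHit:
    """A profile match on a gene's protein."""

    gene_id: str
    family_id: str
    bit_score: float
    e_value: float | None
    env_start: int
    env_end: int
    gene: GeneCall | None = field(default=None, compare=False)


@dataclass
class ProfileLibrary:
    profiles: dict[str, ProfileHMM]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for fam, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for family {fam!r}")
            if fam not in self.profiles:
                raise ValueError(f"role declared for missing family {fam!r}")
        for role in (ROLE_ANCHOR_CYCLASE, ROLE_ANCHOR_DEHYDRATASE):
            n = sum(1 for r in self.roles.values() if r == role)
            if n != 1:
                raise ValueError(f"library must declare exactly one {role} family")

    def family_with_role(self, role: str) -> str:
        for fam, r in self.roles.items():
            if r == role:
                return fam
        raise KeyError(role)

    def families_with_role(self, role: str) -> list[str]:
        return sorted(f for f, r in self.roles.items() if r == role)

    @property
    def prep_profile(self) -> ProfileHMM | None:
        fams = self.families_with_role(ROLE_PREP)
        return self.profiles[fams[0]] if fams else None


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

GAP_CHARS = set("-.")


def build_profile(
    alignment: Sequence[str],
    family_id: str,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    accession: str | None = None,
) -> ProfileHMM:
    """Build a profile from equal-length aligned rows.

    Columns with gap fraction < 0.5 become match states; emissions and
    transitions get a Laplace pseudocount; insert emissions are the
    background.
    """
    rows = [r.upper() for r in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    width = len(rows[0])
    if width == 0 or any(len(r) != width for r in rows):
        raise ValueError("alignment rows are empty or ragged")
    bg = uniform_background() if background is None else np.asarray(background, float)
    n = len(rows)
    is_match = []
    for j in range(width):
        gaps = sum(1 for r in rows if r[j] in GAP_CHARS)
        is_match.append(gaps / n < 0.5)
    match_cols = [j for j, m in enumerate(is_match) if m]
    m = len(match_cols)
    if m == 0:
        raise ValueError("no consensus columns")

    kappa = float(pseudocount)
    emis = np.full((m, N_AA), kappa)
    # transition counts per state: columns as in ProfileHMM.transitions
    tcount = np.zeros((m, 7))
    for row in rows:
        # walk this sequence's path through the match/insert/delete skeleton
        path: list[tuple[str, int, int]] = []  # (state, index, column)
        k = -1
        for j in range(width):
            c = row[j]
            if is_match[j]:
                k += 1
                if c in GAP_CHARS:
                    path.append(("D", k, j))
                else:
                    path.append(("M", k, j))
                    if c in AA_INDEX:
                        emis[k, AA_INDEX[c]] += 1.0
            elif c not in GAP_CHARS:
                path.append(("I", max(k, 0), j))
        for (s1, k1, _), (s2, k2, _) in zip(path, path[1:]):
            if s1 == "M":
                if s2 == "M" and k2 == k1 + 1:
                    tcount[k1, 0] += 1
                elif s2 == "I" and k2 == k1:
                    tcount[k1, 1] += 1
                elif s2 == "D" and k2 == k1 + 1:
                    tcount[k1, 2] += 1
            elif s1 == "I":
                if s2 == "M" and k2 == k1 + 1:
                    tcount[k1, 3] += 1
                elif s2 == "I" and k2 == k1:
                    tcount[k1, 4] += 1
            elif s1 == "D":
                if s2 == "M" and k2 == k1 + 1:
                    tcount[k1, 5] += 1
                elif s2 == "D" and k2 == k1 + 1:
                    tcount[k1, 6] += 1

    emis = emis / emis.sum(axis=1, keepdims=True)
    tcount += kappa
    trans = np.empty_like(tcount)
    trans[:, 0:3] = tcount[:, 0:3] / tcount[:, 0:3].sum(axis=1, keepdims=True)
    trans[:, 3:5] = tcount[:, 3:5] / tcount[:, 3:5].sum(axis=1, keepdims=True)
    trans[:, 5:7] = tcount[:, 5:7] / tcount[:, 5:7].sum(axis=1, keepdims=True)

    hmm = ProfileHMM(
        family_id=family_id,
        n_match=m,
        match_emissions=emis,
        insert_emissions=np.tile(bg, (m, 1)),
        transitions=trans,
        background=bg,
        accession=accession,
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def viterbi_score(hmm: ProfileHMM, protein: str) -> tuple[float, int, int]:
    """Best local alignment log-odds score in bits plus the residue envelope."""
    if len(protein) == 0:
        raise ValueError("empty protein")
    mlo, ilo, tr = hmm._dp_arrays()
    seq = encode_protein(protein)
    nats, s, e = viterbi_kernel(seq, mlo, ilo, tr)
    return nats / LN2, int(s), int(e)


def forward_score(hmm: ProfileHMM, protein: str) -> float:
    """Log-odds of the sum over all local alignments, in bits."""
    if len(protein) == 0:
        raise ValueError("empty protein")
    mlo, ilo, tr = hmm._dp_arrays()
    seq = encode_protein(protein)
    return forward_kernel(seq, mlo, ilo, tr) / LN2


def sample_background(
    rng: np.random.Generator, background: np.ndarray, length: int
) -> str:
    idx = rng.choice(N_AA, size=length, p=background)
    return "".join(AA_ALPHABET[i] for i in idx)


def calibrate(
    hmm: ProfileHMM,
    n_samples: int = 1000,
    sample_length: int = 100,
    seed: int = 0,
) -> ProfileHMM:
    """Fit a Gumbel law to Viterbi scores of random background sequences.

    Method of moments: lambda = pi / (sd * sqrt(6)), mu = mean - gamma/lambda.
    Deterministic given the seed.
    """
    if n_samples < 200:
        raise ValueError("n_samples must be >= 200 for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        prot = sample_background(rng, hmm.background, sample_length)
        scores[i], _, _ = viterbi_score(hmm, prot)
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate score distribution (all scores equal)")
    lam = math.pi / (sd * math.sqrt(6.0))
    mu = float(scores.mean()) - EULER_GAMMA / lam
    out = replace(hmm, gumbel_mu=mu, gumbel_lambda=lam, _cache=hmm._cache)
    return out


def gumbel_pvalue(hmm: ProfileHMM, bit_score: float) -> float:
    """P(random background sequence scores >= bit_score) under the fitted Gumbel."""
    if hmm.gumbel_mu is None or hmm.gumbel_lambda is None:
        raise ValueError(f"profile {hmm.family_id} is not calibrated")
    x = hmm.gumbel_lambda * (bit_score - hmm.gumbel_mu)
    # survival = 1 - exp(-exp(-x)), stable for large x
    return float(-math.expm1(-math.exp(-x)))


def evalue(hmm: ProfileHMM, bit_score: float, database_size: int) -> float:
    return database_size * gumbel_pvalue(hmm, bit_score)


# ---------------------------------------------------------------------------
# Proteome search
# ---------------------------------------------------------------------------


def _kmer_codes(codes: np.ndarray, k: int = 4) -> np.ndarray:
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(len(c) - k + 1, dtype=np.int64)
    valid = np.ones(len(c) - k + 1, dtype=bool)
    for j in range(k):
        part = c[j : len(c) - k + 1 + j]
        out = out * 21 + part
        valid &= part < N_AA
    return out[valid]


def search_proteome(
    library: ProfileLibrary,
    genes: Sequence[GeneCall],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_bits: float = DEFAULT_MIN_BITS,
    database_size: int | None = None,
    prefilter: bool = True,
) -> list[DomainHit]:
    """Score every gene against every profile; keep the best hit per gene/family.

    With ``prefilter=True`` (default) a gene/profile pair is fully aligned
    only when the protein shares at least one exact 4-mer word with the
    profile consensus — a BLAST-style word screen that is deterministic and,
    at the divergences profiles are meant to detect, lossless in practice.
    ``prefilter=False`` forces the full dynamic programming on every pair.
    """
    genes = list(genes)
    if not genes:
        return []
    n_db = database_size if database_size is not None else len(genes)

    gene_codes = [encode_protein(g.protein) for g in genes]
    if prefilter:
        all_kmers = []
        owner = []
        for i, codes in enumerate(gene_codes):
            km = _kmer_codes(codes)
            all_kmers.append(km)
            owner.append(np.full(len(km), i, dtype=np.int64))
        big = np.concatenate(all_kmers) if all_kmers else np.empty(0, np.int64)
        big_owner = np.concatenate(owner) if owner else np.empty(0, np.int64)

    hits: list[DomainHit] = []
    for fam in sorted(library.profiles):
        hmm = library.profiles[fam]
        if prefilter:
            mask = np.isin(big, hmm.consensus_kmers())
            cand = np.unique(big_owner[mask])
        else:
            cand = np.arange(len(genes))
        for gi in cand:
            gene = genes[gi]
            if len(gene.protein) == 0:
                continue
            bits, s, e = viterbi_score(hmm, gene.protein)
            if bits < min_bits:
                continue
            ev = None
            if hmm.gumbel_lambda is not None:
                ev = evalue(hmm, bits, n_db)
                if ev > max_evalue:
                    continue
            hits.append(
                DomainHit(
                    gene_id=gene.gene_id,
                    family_id=fam,
                    bit_score=bits,
                    e_value=ev,
                    env_start=s,
                    env_end=e,
                    gene=gene,
                )
            )
    # best hit per (gene, family) is guaranteed: one DP per pair. Sort by position.
    hits.sort(key=lambda h: (h.gene.contig_id, h.gene.start, h.gene.end, h.family_id))
    return hits


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA or Stockholm file into a list of rows."""
    from Bio import AlignIO

    path = Path(path)
    fmt = "stockholm" if path.suffix in (".sto", ".stk", ".stockholm") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in aln]


def load_library(
    directory: str | Path,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileLibrary:
    """Load a profile library from a directory of seed alignments.

    Layout: one alignment file per family plus ``manifest.yaml`` mapping
    family_id -> {file, role, accession?}.
    """
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    profiles: dict[str, ProfileHMM] = {}
    roles: dict[str, str] = {}
    for fam, info in manifest["families"].items():
        rows = read_alignment(directory / info["file"])
        profiles[fam] = build_profile(
            rows,
            fam,
            pseudocount=pseudocount,
            background=background,
            accession=info.get("accession"),
        )
        roles[fam] = info["role"]
    return ProfileLibrary(profiles=profiles, roles=roles)


def calibrate_library(
    library: ProfileLibrary,
    n_samples: int = 1000,
    sample_length: int = 100,
    seed: int = 0,
) -> ProfileLibrary:
    """Calibrate every profile; per-family seeds are derived deterministically."""
    out: dict[str, ProfileHMM] = {}
    for i, fam in enumerate(sorted(library.profiles)):
        out[fam] = calibrate(
            library.profiles[fam],
            n_samples=n_samples,
            sample_length=sample_length,
            seed=(seed * 1009 + i) % (2**31),
        )
    return ProfileLibrary(profiles=out, roles=dict(library.roles))
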