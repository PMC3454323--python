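"""Deterministic fixtures: seed alignments, profile-sampled homologues, and
synthetic genomes with planted thiopeptide cassettes plus truth annotations.

The generator makes the whole pipeline testable without downloading Pfam:
each protein family gets a fixed random consensus (pairwise <30% identical),
seed alignments are derived from the consensus by seeded mutation, planted
clusters realize the canonical gene organization (anchor cyclase +
dehydratase, accessory framework genes, genotype markers, and one to four
short precursor genes whose core peptide matches the structural motif
exactly). Planted proteins are reverse-translated with uniform seeded codon
choice (table 11), and an in-frame stop codon is written immediately
upstream of every planted start codon so the built-in ORF caller recovers
planted coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Data import CodonTable

from ._seqcodes import AA_ALPHABET, N_AA
from .precursor_analysis import DEFAULT_PATTERN, parse_pattern
from .profile_hmm import (
    ProfileHMM,
    ProfileLibrary,
    build_profile,
)
from .sequence_io import GenomeSequence

FIXTURE_SEED = 20120913
ALIGNMENT_ROWS = 8
ALIGNMENT_DIVERGENCE = 0.10
PREP_LEADER_LEN = 40
PREP_CORE = "SCTTCGCTCSC"  # one exact instance of the structural pattern

# family -> (role, Pfam accession or None)
FAMILY_ROLES: dict[str, tuple[str, str | None]] = {
    "YcaO": ("anchor_cyclase", "PF02624"),
    "Lant_dehyd_C": ("anchor_dehydratase", "PF04738"),
    "nitroreductase": ("accessory", "PF00881"),
    "SpaB_C": ("accessory", "PF14028"),
    "NosO_like": ("accessory", None),
    "NosH_like": ("accessory", None),
    "BATS": ("type1_marker", "PF06968"),
    "Radical_SAM": ("type2_marker_radical", "PF04055"),
    "SnoaL": ("type2_marker_cyclase", "PF07366"),
    "Prep": ("prep_profile", None),
}

ACCESSORY_FAMILIES = ["nitroreductase", "SpaB_C", "NosO_like", "NosH_like"]
TYPE_MARKERS = {"I": ["BATS"], "II": ["Radical_SAM", "SnoaL"], "III": []}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` by a different residue."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AA_ALPHABET if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def family_consensi(seed: int = FIXTURE_SEED) -> dict[str, str]:
    """Fixed per-family consensus sequences, pairwise <30% identical."""
    rng = np.random.default_rng(seed)
    cons: dict[str, str] = {}
    for fam in FAMILY_ROLES:
        if fam == "Prep":
            leader = "".join(
                AA_ALPHABET[i] for i in rng.integers(0, N_AA, PREP_LEADER_LEN)
            )
            cons[fam] = "M" + leader[1:] + PREP_CORE
        else:
            length = int(rng.integers(40, 81))
            cons[fam] = "".join(AA_ALPHABET[i] for i in rng.integers(0, N_AA, length))
    fams = list(cons)
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            ident = _identity(cons[fams[i]], cons[fams[j]])
            if ident >= 0.3:
                raise RuntimeError(
                    f"fixture consensi {fams[i]}/{fams[j]} too similar ({ident:.2f})"
                )
    return cons


def fixture_alignments(seed: int = FIXTURE_SEED) -> dict[str, list[str]]:
    """Deterministic 8-row seed alignments derived from each family consensus."""
    cons = family_consensi(seed)
    rng = np.random.default_rng(seed + 1)
    out: dict[str, list[str]] = {}
    for fam in FAMILY_ROLES:
        out[fam] = [
            _mutate(cons[fam], ALIGNMENT_DIVERGENCE, rng) for _ in range(ALIGNMENT_ROWS)
        ]
    return out


def make_fixture_alignments(outdir: str | Path, seed: int = FIXTURE_SEED) -> Path:
    """Write the fixture profile-library source files (alignments + manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    alignments = fixture_alignments(seed)
    manifest: dict = {"families": {}}
    for fam, rows in alignments.items():
        fname = f"{fam}.afa"
        lines = []
        for i, row in enumerate(rows, start=1):
            lines.append(f">{fam}_seq{i}")
            lines.append(row)
        (outdir / fname).write_text("\n".join(lines) + "\n")
        role, accession = FAMILY_ROLES[fam]
        entry = {"file": fname, "role": role}
        if accession:
            entry["accession"] = accession
        manifest["families"][fam] = entry
    (outdir / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return outdir


def fixture_library(seed: int = FIXTURE_SEED) -> ProfileLibrary:
    """Build the fixture profile library in memory (uncalibrated)."""
    alignments = fixture_alignments(seed)
    profiles: dict[str, ProfileHMM] = {}
    roles: dict[str, str] = {}
    for fam, rows in alignments.items():
        role, accession = FAMILY_ROLES[fam]
        profiles[fam] = build_profile(rows, fam, accession=accession)
        roles[fam] = role
    return ProfileLibrary(profiles=profiles, roles=roles)


def sample_from_profile(hmm: ProfileHMM, divergence: float, seed: int) -> str:
    """Sample the match-state consensus, then apply seeded substitutions."""
    rng = np.random.default_rng(seed)
    return _mutate(hmm.consensus, divergence, rng)


# ---------------------------------------------------------------------------
# Genome planting
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    """What to plant: genotype, precursor copies, divergence and layout."""

    cluster_type: str = "I"
    n_prep: int = 1
    divergence: float = 0.1
    spacing_bp: int = 150
    strand_plan: tuple[str, ...] | None = None
    seed: int = 0
    leader_aa: int = PREP_LEADER_LEN
    prep_gap_bp: int | None = None  # gap from anchor-span end to the first prep start

    def __post_init__(self) -> None:
        if self.cluster_type not in ("I", "II", "III"):
            raise ValueError("cluster_type must be I, II or III")
        if not 1 <= self.n_prep <= 4:
            raise ValueError("n_prep must be 1..4")
        if not 0.0 <= self.divergence <= 0.4:
            raise ValueError("divergence must be in [0, 0.4]")
        if self.spacing_bp < 50:
            raise ValueError("spacing_bp must be >= 50")


@dataclass
class PlantedGene:
    family: str
    role: str
    start: int
    end: int
    strand: str
    protein: str
    leader_len: int | None = None


_BACK_TABLE: dict[str, list[str]] | None = None


def _back_table() -> dict[str, list[str]]:
    global _BACK_TABLE
    if _BACK_TABLE is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        bt: dict[str, list[str]] = {}
        for codon, aa in sorted(table.forward_table.items()):
            bt.setdefault(aa, []).append(codon)
        _BACK_TABLE = bt
    return _BACK_TABLE


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform seeded codon choice per residue (table 11), stop codon appended."""
    bt = _back_table()
    codons = [bt[aa][rng.integers(len(bt[aa]))] for aa in protein]
    return "".join(codons) + "TAA"


_RC = str.maketrans("ACGT", "TGCA")


def random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def plant_cluster(
    background_length: int,
    gc: float,
    spec: PlantSpec,
    library: ProfileLibrary | None = None,
) -> tuple[GenomeSequence, list[PlantedGene]]:
    """Generate a background genome with one planted thiopeptide cassette.

    Returns the genome and the truth records of every planted gene.
    """
    library = library or fixture_library()
    rng = np.random.default_rng(spec.seed)
    prep_gap = spec.prep_gap_bp if spec.prep_gap_bp is not None else spec.spacing_bp
    if prep_gap < 6:
        raise ValueError("prep_gap_bp must be >= 6 (room for the guard stop codon)")

    families = (
        list(ACCESSORY_FAMILIES)
        + TYPE_MARKERS[spec.cluster_type]
        + ["YcaO", "Lant_dehyd_C"]
    )
    proteins: list[tuple[str, str, int | None]] = []  # (family, protein, leader_len)
    for fam in families:
        sub_seed = int(rng.integers(0, 2**31))
        prot = "M" + sample_from_profile(
            library.profiles[fam], spec.divergence, sub_seed
        )
        proteins.append((fam, prot, None))
    prep_profile = library.prep_profile
    prep_cons = prep_profile.consensus if prep_profile is not None else None
    prep_proteins: list[tuple[str, str, int | None]] = []
    for _ in range(spec.n_prep):
        sub_seed = int(rng.integers(0, 2**31))
        leader_src = (
            prep_cons[: spec.leader_aa]
            if prep_cons is not None and len(prep_cons) >= spec.leader_aa
            else "".join(
                AA_ALPHABET[i] for i in rng.integers(0, N_AA, spec.leader_aa)
            )
        )
        leader = "M" + _mutate(
            leader_src[1:], spec.divergence, np.random.default_rng(sub_seed)
        )
        prot = leader + PREP_CORE
        if len(prot) > 119:
            raise ValueError("planted precursor exceeds 119 aa")
        prep_proteins.append(("Prep", prot, spec.leader_aa))

    # layout: accessory + markers + anchors, then the prep gene(s) after prep_gap
    dnas = []
    strand_plan = spec.strand_plan
    all_genes = proteins + prep_proteins
    for i, (fam, prot, _) in enumerate(all_genes):
        if strand_plan:
            strand = strand_plan[i % len(strand_plan)]
        else:
            strand = "+" if i % 2 == 0 else "-"
        dnas.append((fam, prot, strand, reverse_translate(prot, rng)))

    total_gene_span = sum(len(d[3]) + spec.spacing_bp for d in dnas) + prep_gap
    margin = 2 * 25000 + 1000
    if background_length < total_gene_span + margin:
        raise ValueError(
            f"background_length {background_length} too small for the cassette"
        )

    genome_arr = random_background(background_length, gc, rng)
    truth: list[PlantedGene] = []
    cursor = (background_length - total_gene_span) // 2
    anchor_span_end: int | None = None
    for (fam, prot, leader_len), (_, _, strand, dna) in zip(all_genes, dnas):
        if fam == "Prep" and anchor_span_end is not None:
            if not truth or truth[-1].family != "Prep":
                # first precursor copy: exactly prep_gap from the anchor span end
                cursor = anchor_span_end + prep_gap
        p = cursor
        placed = dna if strand == "+" else dna[::-1].translate(_RC)
        genome_arr[p : p + len(dna)] = np.frombuffer(
            placed.encode("ascii"), dtype=np.uint8
        )
        if strand == "+":
            genome_arr[p - 3 : p] = np.frombuffer(b"TAA", dtype=np.uint8)
        else:
            genome_arr[p + len(dna) : p + len(dna) + 3] = np.frombuffer(
                b"TTA", dtype=np.uint8
            )
        role = FAMILY_ROLES[fam][0]
        truth.append(
            PlantedGene(
                family=fam,
                role=role,
                start=p,
                end=p + len(dna),
                strand=strand,
                protein=prot,
                leader_len=leader_len,
            )
        )
        if fam == "Lant_dehyd_C":
            anchor_span_end = p + len(dna)
        cursor = p + len(dna) + spec.spacing_bp
    seq = genome_arr.tobytes().decode("ascii")
    genome = GenomeSequence(
        id=f"synthetic_{spec.cluster_type}_{spec.seed}",
        seq=seq,
        description=f"synthetic genome, planted type {spec.cluster_type} cassette",
    )
    return genome, truth


def random_genome(length: int, gc: float = 0.5, seed: int = 0) -> GenomeSequence:
    """A background genome with no planted genes (null model for specificity)."""
    rng = np.random.default_rng(seed)
    seq = random_background(length, gc, rng).tobytes().decode("ascii")
    return GenomeSequence(id=f"null_{seed}", seq=seq, description="random background")


def truth_to_gff3(genome: GenomeSequence, truth: list[PlantedGene]) -> str:
    lines = ["##gff-version 3"]
    for i, g in enumerate(truth, start=1):
        attrs = f"ID=planted_{i};family={g.family};role={g.role}"
        if g.leader_len is not None:
            attrs += f";leader_len={g.leader_len}"
        lines.append(
            "\t".join(
                [
                    genome.id,
                    "thioscan_sim",
                    "CDS",
                    str(g.start + 1),
                    str(g.end),
                    ".",
                    g.strand,
                    "0",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"
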