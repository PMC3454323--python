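"""Reading genomes/annotations and writing cluster calls as GFF3 + JSON.

Internal coordinates are 0-based half-open throughout the package; the one
place they are converted to the 1-based inclusive GFF3 convention is here.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_ALLOWED = set("ACGTN")


@dataclass
class GenomeSequence:
    """A named nucleotide sequence normalized to the {A,C,G,T,N} alphabet."""

    id: str
    seq: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneCall:
    """A protein-coding region on a contig.

    ``start``/``end`` are 0-based half-open base offsets on the forward axis;
    ``protein`` excludes the stop symbol. ``source`` records where the call
    came from (``builtin_orf``, ``user_annotation`` or ``rescue``).
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    source: str = "builtin_orf"
    partial: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _normalize(seq: str) -> tuple[str, int]:
    seq = seq.upper()
    n_replaced = sum(1 for c in seq if c not in _ALLOWED)
    if n_replaced:
        seq = re.sub("[^ACGTN]", "N", seq)
    return seq, n_replaced


def read_genome(path: str | Path, format: str = "fasta") -> list[GenomeSequence]:
    """Read genome records from FASTA or GenBank, normalizing the alphabet.

    Characters outside {A,C,G,T,N} are coerced to N (scaffolds with odd
    ambiguity codes are valid input); the replacement count is logged.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported genome format {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no sequences in {path}")
    genomes: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in records:
        seq, n_replaced = _normalize(str(rec.seq))
        if len(seq) == 0:
            raise ValueError(f"record {rec.id!r} has length 0")
        if not rec.id:
            raise ValueError("record with empty id")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if n_replaced:
            logger.warning(
                "record %s: %d non-ACGTN characters replaced by N", rec.id, n_replaced
            )
        genomes.append(GenomeSequence(id=rec.id, seq=seq, description=rec.description))
    return genomes


def _translate_span(genome: GenomeSequence, start: int, end: int, strand: str) -> str:
    dna = genome.seq[start:end]
    if strand == "-":
        dna = str(Seq(dna).reverse_complement())
    dna = dna[: 3 * (len(dna) // 3)]
    prot = str(Seq(dna).translate(table=11))
    return prot.rstrip("*")


def read_annotations(
    path: str | Path,
    format: str,
    genomes: list[GenomeSequence],
) -> list[GeneCall]:
    """Read user-supplied CDS annotations from GFF3 or GenBank.

    Coordinates are converted to the internal 0-based half-open convention;
    translations are taken from the file when present, otherwise derived from
    the genome with translation table 11.
    """
    by_id = {g.id: g for g in genomes}
    if format == "gff3":
        calls = _read_gff3_cds(Path(path), by_id)
    elif format == "genbank":
        calls = _read_genbank_cds(Path(path), by_id)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    return sorted(calls, key=lambda g: (g.contig_id, g.start, g.end, g.strand))


def _read_gff3_cds(path: Path, by_id: dict[str, GenomeSequence]) -> list[GeneCall]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    calls: list[GeneCall] = []
    unknown: list[str] = []
    n = 0
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        n += 1
        if feat.seqid not in by_id:
            unknown.append(feat.seqid)
            continue
        genome = by_id[feat.seqid]
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if not 0 <= start < end <= genome.length:
            raise ValueError(
                f"CDS {feat.id or n} out of bounds on {feat.seqid}: {feat.start}..{feat.end}"
            )
        strand = feat.strand if feat.strand in "+-" else "+"
        gene_id = feat.id or f"cds_{n}"
        partial = feat.attributes.get("partial", ["false"])[0].lower() == "true"
        calls.append(
            GeneCall(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=start,
                end=end,
                strand=strand,
                protein=_translate_span(genome, start, end, strand),
                source="user_annotation",
                partial=partial,
            )
        )
    if unknown:
        raise ValueError(
            "CDS features reference contigs absent from the genome: "
            + ", ".join(sorted(set(unknown)))
        )
    return calls


def _read_genbank_cds(path: Path, by_id: dict[str, GenomeSequence]) -> list[GeneCall]:
    calls: list[GeneCall] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        if rec.id not in by_id:
            raise ValueError(f"annotation record {rec.id!r} not among input genomes")
        genome = by_id[rec.id]
        n = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n += 1
            start = int(feat.location.start)
            end = int(feat.location.end)
            if not 0 <= start < end <= genome.length:
                raise ValueError(f"CDS out of bounds on {rec.id}: {start}..{end}")
            strand = "-" if feat.location.strand == -1 else "+"
            partial = "<" in str(feat.location) or ">" in str(feat.location)
            translation = feat.qualifiers.get("translation", [None])[0]
            if translation is None:
                translation = _translate_span(genome, start, end, strand)
            gene_id = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("gene", [f"{rec.id}_cds{n}"])
            )[0]
            calls.append(
                GeneCall(
                    gene_id=gene_id,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    protein=translation,
                    source="user_annotation",
                    partial=partial,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def _gff3_escape(value: str) -> str:
    return value.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _core_genomic_span(prep) -> tuple[int, int] | None:
    """Genomic interval of the core (structural) peptide of a resolved precursor."""
    if prep.cleavage_index is None:
        return None
    gene = prep.gene
    core_nt = 3 * len(prep.core)
    if gene.strand == "+":
        end = gene.end - 3  # exclude stop codon
        return end - core_nt, end
    start = gene.start + 3
    return start, start + core_nt


def write_gff3(result, path: str | Path) -> None:
    """Write one ``gene_cluster`` feature per candidate plus member CDS children."""
    lines = ["##gff-version 3"]
    for ci, cluster in enumerate(result.clusters, start=1):
        cid = f"cluster_{ci}"
        anchors = ",".join(
            _gff3_escape(h.gene_id)
            for h in (cluster.anchor_cyclase_hit, cluster.anchor_dehydratase_hit)
        )
        attrs = (
            f"ID={cid};cluster_type={cluster.cluster_type};"
            f"complete={'true' if cluster.complete else 'false'};anchors={anchors}"
        )
        lines.append(
            "\t".join(
                [
                    cluster.contig_id,
                    "thioscan",
                    "gene_cluster",
                    str(cluster.region_start + 1),
                    str(cluster.region_end),
                    ".",
                    ".",
                    ".",
                    attrs,
                ]
            )
        )
        for gene in cluster.member_genes():
            fams = ",".join(
                sorted(h.family_id for h in cluster.hits_for_gene(gene.gene_id))
            )
            gattrs = f"ID={_gff3_escape(gene.gene_id)};Parent={cid}"
            if fams:
                gattrs += f";families={_gff3_escape(fams)}"
            lines.append(
                "\t".join(
                    [
                        gene.contig_id,
                        "thioscan",
                        "CDS",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        "0",
                        gattrs,
                    ]
                )
            )
        for pi, prep in enumerate(cluster.prep_candidates, start=1):
            span = _core_genomic_span(prep)
            if span is None:
                continue
            lines.append(
                "\t".join(
                    [
                        prep.gene.contig_id,
                        "thioscan",
                        "mature_peptide_region",
                        str(span[0] + 1),
                        str(span[1]),
                        ".",
                        prep.gene.strand,
                        ".",
                        f"ID={cid}_core_{pi};Parent={cid};"
                        f"core_peptide={prep.core}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _hit_dict(hit) -> dict:
    return {
        "gene_id": hit.gene_id,
        "family_id": hit.family_id,
        "bit_score": round(float(hit.bit_score), 4),
        "e_value": float(f"{hit.e_value:.4g}") if hit.e_value is not None else None,
        "env_start": hit.env_start,
        "env_end": hit.env_end,
    }


def _gene_dict(gene: GeneCall) -> dict:
    return {
        "gene_id": gene.gene_id,
        "contig_id": gene.contig_id,
        "start": gene.start,
        "end": gene.end,
        "strand": gene.strand,
        "length_aa": len(gene.protein),
        "source": gene.source,
    }


def _prep_dict(prep) -> dict:
    return {
        "gene": _gene_dict(prep.gene),
        "leader": prep.leader,
        "core": prep.core,
        "cleavage_index": prep.cleavage_index,
        "motif_pvalue": (
            float(f"{prep.motif_pvalue:.6g}") if prep.motif_pvalue is not None else None
        ),
        "evidence": sorted(prep.evidence),
        "leaderless": prep.cleavage_index == 0,
    }


def _cluster_dict(cluster) -> dict:
    return {
        "contig_id": cluster.contig_id,
        "region_start": cluster.region_start,
        "region_end": cluster.region_end,
        "cluster_type": cluster.cluster_type,
        "complete": cluster.complete,
        "anchor_cyclase": _hit_dict(cluster.anchor_cyclase_hit),
        "anchor_dehydratase": _hit_dict(cluster.anchor_dehydratase_hit),
        "accessory_hits": [_hit_dict(h) for h in cluster.accessory_hits],
        "prep_candidates": [_prep_dict(p) for p in cluster.prep_candidates],
        "member_strands": {g.gene_id: g.strand for g in cluster.member_genes()},
        "rationale": cluster.type_rationale,
    }


def input_checksum(genomes: Iterable[GenomeSequence]) -> str:
    h = hashlib.sha256()
    for g in genomes:
        h.update(g.id.encode())
        h.update(b"\0")
        h.update(g.seq.encode())
        h.update(b"\0")
    return h.hexdigest()


def write_report(result, path: str | Path) -> None:
    """Write the structured single-document JSON run report."""
    doc = report_document(result)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def report_document(result) -> dict:
    return {
        "tool": "thioscan",
        "version": result.version,
        "timestamp": result.timestamp,
        "input_checksum": result.input_checksum,
        "parameters": result.params,
        "stage_counts": result.stage_counts,
        "clusters": [_cluster_dict(c) for c in result.clusters],
    }
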