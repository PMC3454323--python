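"""End-to-end cluster scan: genes -> profile hits -> anchors -> clusters.

``run_pipeline`` is the single entry point the CLI wraps: it reads (or
receives) genomes, calls genes with the built-in ORF caller or ingests user
annotations, searches the proteome against the profile library, co-localizes
anchors, attaches precursor and accessory genes, assembles and classifies
cluster candidates, and returns a result object that the I/O layer can
serialize as GFF3 + JSON.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifier import classify_all
from .cluster_detector import (
    ClusterCandidate,
    ScanParams,
    assemble_clusters,
    assign_accessory,
    attach_prep,
    find_anchors,
)
from .gene_finder import OrfParams, find_orfs
from .precursor_analysis import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_PATTERN,
    StructuralMotif,
)
from .profile_hmm import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_BITS,
    ProfileLibrary,
    calibrate_library,
    load_library,
    search_proteome,
)
from .sequence_io import (
    GenomeSequence,
    input_checksum,
    read_annotations,
    read_genome,
    write_gff3,
    write_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a scan needs; defaults are the documented pipeline constants."""

    input_path: str | None = None
    input_format: str = "fasta"
    annotations_path: str | None = None
    annotations_format: str = "gff3"
    gene_finder: str = "builtin"  # "builtin" or "annotations"
    profiles_dir: str | None = None  # None -> bundled synthetic fixture library
    out_dir: str | None = None
    motif_pattern: str = DEFAULT_PATTERN
    motif_pvalue: float = DEFAULT_P_THRESHOLD
    min_bits: float = DEFAULT_MIN_BITS
    max_evalue: float = DEFAULT_MAX_EVALUE
    anchor_window_bp: int = 20000
    prep_flank_bp: int = 25000
    prep_max_aa: int = 119
    max_prep_copies: int = 4
    min_protein_aa: int = 30
    rescue_min_protein_aa: int = 15
    rescue_max_protein_aa: int = 119
    calibration_samples: int = 1000
    calibration_length: int = 100
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scan_params(self) -> ScanParams:
        return ScanParams(
            anchor_window_bp=self.anchor_window_bp,
            prep_flank_bp=self.prep_flank_bp,
            prep_max_aa=self.prep_max_aa,
            max_prep_copies=self.max_prep_copies,
        )

    def orf_params(self) -> OrfParams:
        return OrfParams(
            min_protein_aa=self.min_protein_aa,
            rescue_min_protein_aa=self.rescue_min_protein_aa,
            rescue_max_protein_aa=self.rescue_max_protein_aa,
        )


@dataclass
class PipelineResult:
    clusters: list[ClusterCandidate]
    params: dict
    stage_counts: dict
    input_checksum: str
    version: str = __version__
    timestamp: str = ""


def prepare_library(config: RunConfig) -> ProfileLibrary:
    """Load (or build) and calibrate the profile library for a run."""
    if config.profiles_dir:
        library = load_library(config.profiles_dir)
    else:
        from .synthetic_data import fixture_library

        library = fixture_library()
    return calibrate_library(
        library,
        n_samples=config.calibration_samples,
        sample_length=config.calibration_length,
        seed=config.seed,
    )


def run_pipeline(
    config: RunConfig,
    genomes: list[GenomeSequence] | None = None,
    library: ProfileLibrary | None = None,
) -> PipelineResult:
    """Execute the full scan; zero clusters is a valid outcome."""
    if genomes is None:
        if not config.input_path:
            raise ValueError("run_pipeline needs genomes or config.input_path")
        genomes = read_genome(config.input_path, config.input_format)
    if library is None:
        library = prepare_library(config)

    scan = config.scan_params()
    orfp = config.orf_params()
    motif = StructuralMotif.from_pattern(config.motif_pattern)

    user_genes = None
    if config.gene_finder == "annotations":
        if not config.annotations_path:
            raise ValueError("gene_finder='annotations' requires annotations_path")
        user_genes = read_annotations(
            config.annotations_path, config.annotations_format, genomes
        )

    counts = {
        "genomes": len(genomes),
        "genes_called": 0,
        "domain_hits": 0,
        "anchors": 0,
        "clusters": 0,
        "prep_candidates": 0,
        "rescued_preps": 0,
    }
    all_clusters: list[ClusterCandidate] = []
    for genome in genomes:
        if user_genes is not None:
            genes = [g for g in user_genes if g.contig_id == genome.id]
        else:
            genes = find_orfs(genome, orfp)
        counts["genes_called"] += len(genes)
        hits = search_proteome(
            library,
            genes,
            max_evalue=config.max_evalue,
            min_bits=config.min_bits,
        )
        counts["domain_hits"] += len(hits)
        anchors = find_anchors(hits, library, scan)
        counts["anchors"] += len(anchors)
        accessory = assign_accessory(anchors, hits, library, scan)
        preps = [
            attach_prep(
                anchor,
                genes,
                genome,
                library.prep_profile,
                motif,
                scan,
                orfp,
                min_bits=config.min_bits,
                motif_p_threshold=config.motif_pvalue,
            )
            for anchor in anchors
        ]
        clusters = assemble_clusters(anchors, preps, accessory)
        classify_all(clusters, library)
        for c in clusters:
            counts["prep_candidates"] += len(c.prep_candidates)
            counts["rescued_preps"] += sum(
                1 for p in c.prep_candidates if p.gene.source == "rescue"
            )
        all_clusters.extend(clusters)
        logger.info(
            "%s: %d genes, %d hits, %d anchors, %d clusters",
            genome.id,
            len(genes),
            len(hits),
            len(anchors),
            len(clusters),
        )
    counts["clusters"] = len(all_clusters)

    params = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("input_path", "out_dir", "verbosity")
    }
    return PipelineResult(
        clusters=all_clusters,
        params=params,
        stage_counts=counts,
        input_checksum=input_checksum(genomes),
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out / "clusters.gff3",
        "report": out / "report.json",
        "summary": out / "summary.txt",
    }
    write_gff3(result, paths["gff3"])
    write_report(result, paths["report"])
    paths["summary"].write_text(summarize(result))
    return paths


def summarize(result: PipelineResult) -> str:
    lines = [
        f"thioscan {result.version}",
        f"input checksum: {result.input_checksum}",
        f"clusters found: {len(result.clusters)}",
        "",
    ]
    for i, c in enumerate(result.clusters, start=1):
        lines.append(
            f"cluster {i}: {c.contig_id}:{c.region_start + 1}-{c.region_end} "
            f"type {c.cluster_type} complete={str(c.complete).lower()}"
        )
        lines.append(
            f"  anchors: {c.anchor_cyclase_hit.family_id} "
            f"({c.anchor_cyclase_hit.bit_score:.1f} bits), "
            f"{c.anchor_dehydratase_hit.family_id} "
            f"({c.anchor_dehydratase_hit.bit_score:.1f} bits)"
        )
        if c.accessory_hits:
            fams = ", ".join(sorted(h.family_id for h in c.accessory_hits))
            lines.append(f"  accessory: {fams}")
        for p in c.prep_candidates:
            if p.cleavage_index is not None:
                lines.append(
                    f"  precursor {p.gene.gene_id}: leader {len(p.leader)} aa, "
                    f"core {p.core} (p={p.motif_pvalue:.3g})"
                )
            else:
                lines.append(
                    f"  precursor {p.gene.gene_id}: no resolved cleavage site"
                )
    return "\n".join(lines) + "\n"
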