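"""Cluster candidate assembly from profile hits.

The detection rule mirrors how thiopeptide biosynthetic loci are organized:
a YcaO-like cyclase gene and a lantibiotic-type dehydratase gene
co-localized on one contig anchor a candidate; the precursor-peptide gene
(*prep*) is then sought in a 25-kb flanking window, accessory
framework genes are attached, and candidates lacking any prep are still
reported as incomplete clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .gene_finder import OrfParams, rescue_small_orfs
from .precursor_analysis import (
    DEFAULT_P_THRESHOLD,
    PrecursorPeptide,
    StructuralMotif,
    motif_match,
    pwm_scan,
    split_precursor,
)
from .profile_hmm import (
    DEFAULT_MIN_BITS,
    ROLE_ACCESSORY,
    ROLE_ANCHOR_CYCLASE,
    ROLE_ANCHOR_DEHYDRATASE,
    ROLE_TYPE1_MARKER,
    ROLE_TYPE2_MARKER_CYCLASE,
    ROLE_TYPE2_MARKER_RADICAL,
    DomainHit,
    ProfileHMM,
    ProfileLibrary,
    viterbi_score,
)
from .sequence_io import GeneCall, GenomeSequence

logger = logging.getLogger(__name__)

ATTACHABLE_ROLES = {
    ROLE_ACCESSORY,
    ROLE_TYPE1_MARKER,
    ROLE_TYPE2_MARKER_RADICAL,
    ROLE_TYPE2_MARKER_CYCLASE,
}


@dataclass
class ScanParams:
    """Cluster-scan windows and precursor limits.

    ``prep_flank_bp`` is the 25-kb region scanned for the precursor gene
    around the anchor pair; ``prep_max_aa`` caps precursors at 119 residues
    (<120 aa); ``max_prep_copies`` reflects the up-to-4 near-identical
    precursor genes seen in known clusters.
    """

    anchor_window_bp: int = 20000
    prep_flank_bp: int = 25000
    prep_max_aa: int = 119
    max_prep_copies: int = 4

    def __post_init__(self) -> None:
        for name in ("anchor_window_bp", "prep_flank_bp", "prep_max_aa", "max_prep_copies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AnchorPair:
    cyclase_hit: DomainHit
    dehydratase_hit: DomainHit

    @property
    def contig_id(self) -> str:
        return self.cyclase_hit.gene.contig_id

    @property
    def span_start(self) -> int:
        return min(self.cyclase_hit.gene.start, self.dehydratase_hit.gene.start)

    @property
    def span_end(self) -> int:
        return max(self.cyclase_hit.gene.end, self.dehydratase_hit.gene.end)

    def gap(self) -> int:
        a, b = self.cyclase_hit.gene, self.dehydratase_hit.gene
        return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class ClusterCandidate:
    contig_id: str
    region_start: int
    region_end: int
    anchor_cyclase_hit: DomainHit
    anchor_dehydratase_hit: DomainHit
    accessory_hits: list[DomainHit] = field(default_factory=list)
    prep_candidates: list[PrecursorPeptide] = field(default_factory=list)
    cluster_type: str = "unclassified"
    type_rationale: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return bool(self.prep_candidates)

    def member_genes(self) -> list[GeneCall]:
        genes: dict[str, GeneCall] = {}
        for hit in [self.anchor_cyclase_hit, self.anchor_dehydratase_hit] + list(
            self.accessory_hits
        ):
            genes[hit.gene.gene_id] = hit.gene
        for prep in self.prep_candidates:
            genes[prep.gene.gene_id] = prep.gene
        return sorted(genes.values(), key=lambda g: (g.start, g.end, g.strand))

    def hits_for_gene(self, gene_id: str) -> list[DomainHit]:
        return [
            h
            for h in [self.anchor_cyclase_hit, self.anchor_dehydratase_hit]
            + list(self.accessory_hits)
            if h.gene_id == gene_id
        ]


def _flank_interval(anchor: AnchorPair, params: ScanParams) -> tuple[int, int]:
    return anchor.span_start - params.prep_flank_bp, anchor.span_end + params.prep_flank_bp


def find_anchors(
    hits: Sequence[DomainHit],
    library: ProfileLibrary,
    params: ScanParams | None = None,
) -> list[AnchorPair]:
    """Pair co-localized cyclase and dehydratase hits into anchors.

    Every same-contig (cyclase, dehydratase) hit pair whose inter-gene
    nearest-edge gap is at most ``anchor_window_bp`` is a candidate; pairs
    are merged greedily closest-first (ties to the leftmost pair) so that
    each gene belongs to at most one anchor.
    """
    params = params or ScanParams()
    cyc_fams = set(library.families_with_role(ROLE_ANCHOR_CYCLASE))
    deh_fams = set(library.families_with_role(ROLE_ANCHOR_DEHYDRATASE))
    cyc = [h for h in hits if h.family_id in cyc_fams]
    deh = [h for h in hits if h.family_id in deh_fams]
    pairs: list[tuple[int, int, AnchorPair]] = []
    for c in cyc:
        for d in deh:
            if c.gene.contig_id != d.gene.contig_id:
                continue
            pair = AnchorPair(cyclase_hit=c, dehydratase_hit=d)
            if pair.gap() <= params.anchor_window_bp:
                pairs.append((pair.gap(), pair.span_start, pair))
    pairs.sort(key=lambda t: (t[0], t[1], t[2].span_end))
    used: set[str] = set()
    anchors: list[AnchorPair] = []
    for _, _, pair in pairs:
        ids = {pair.cyclase_hit.gene_id, pair.dehydratase_hit.gene_id}
        if ids & used:
            continue
        used |= ids
        anchors.append(pair)
    anchors.sort(key=lambda a: (a.contig_id, a.span_start, a.span_end))
    return anchors


def _evaluate_prep_candidate(
    gene: GeneCall,
    prep_hmm: ProfileHMM | None,
    motif: StructuralMotif,
    min_bits: float,
    motif_p_threshold: float,
) -> PrecursorPeptide | None:
    """Detect a precursor gene and, if possible, resolve its cleavage site.

    Detection evidence is an exact structural-peptide pattern match or a
    Prep-profile score above threshold; the PWM p-value scan then locates
    the leader/core cleavage site among candidate windows.
    """
    if not gene.protein:
        return None
    exact = motif_match(gene.protein, motif)
    hmm_ok = False
    if prep_hmm is not None:
        bits, _, _ = viterbi_score(prep_hmm, gene.protein)
        hmm_ok = bits >= min_bits
    if not exact and not hmm_ok:
        return None
    evidence: set[str] = set()
    if exact:
        evidence.add("motif")
    if hmm_ok:
        evidence.add("prep_hmm")
    matches = pwm_scan(gene.protein, motif, motif_p_threshold)
    if matches:
        return split_precursor(gene, matches, evidence=evidence)
    return PrecursorPeptide(
        gene=gene,
        leader=gene.protein,
        core="",
        cleavage_index=None,
        motif_pvalue=None,
        evidence=evidence,
    )


def attach_prep(
    anchor: AnchorPair,
    genes: Sequence[GeneCall],
    genome: GenomeSequence,
    prep_hmm: ProfileHMM | None,
    motif: StructuralMotif,
    params: ScanParams | None = None,
    orf_params: OrfParams | None = None,
    min_bits: float = DEFAULT_MIN_BITS,
    motif_p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[PrecursorPeptide]:
    """Search the 25-kb flank of an anchor for precursor-peptide genes.

    A candidate must lie fully inside the flank interval, encode at most
    ``prep_max_aa`` residues, and either score above the Prep profile
    threshold or carry a structural-peptide motif match. When no existing
    gene call qualifies, the short-ORF rescue pass re-scans the interval —
    automating the manual check that short prep genes (<360 bp) need when
    standard gene callers miss them.
    """
    params = params or ScanParams()
    orf_params = orf_params or OrfParams()
    lo, hi = _flank_interval(anchor, params)
    lo, hi = max(0, lo), min(genome.length, hi)

    def in_window(g: GeneCall) -> bool:
        return lo <= g.start and g.end <= hi and len(g.protein) <= params.prep_max_aa

    anchor_ids = {anchor.cyclase_hit.gene_id, anchor.dehydratase_hit.gene_id}
    preps: list[PrecursorPeptide] = []
    for gene in genes:
        if gene.contig_id != genome.id or gene.gene_id in anchor_ids:
            continue
        if not in_window(gene):
            continue
        prep = _evaluate_prep_candidate(
            gene, prep_hmm, motif, min_bits, motif_p_threshold
        )
        if prep is not None:
            preps.append(prep)
    if not preps:
        rescued = rescue_small_orfs(genome, (lo, hi), orf_params, existing=list(genes))
        for gene in rescued:
            if not in_window(gene):
                continue
            prep = _evaluate_prep_candidate(
                gene, prep_hmm, motif, min_bits, motif_p_threshold
            )
            if prep is not None:
                preps.append(prep)
    preps.sort(
        key=lambda p: (
            p.motif_pvalue if p.motif_pvalue is not None else float("inf"),
            p.gene.start,
        )
    )
    return preps[: params.max_prep_copies]


def collect_accessory(
    anchor: AnchorPair,
    hits: Sequence[DomainHit],
    library: ProfileLibrary,
    params: ScanParams | None = None,
) -> list[DomainHit]:
    """Accessory and type-marker hits inside the anchor's flank interval."""
    params = params or ScanParams()
    lo, hi = _flank_interval(anchor, params)
    anchor_ids = {anchor.cyclase_hit.gene_id, anchor.dehydratase_hit.gene_id}
    out = []
    for h in hits:
        if library.roles.get(h.family_id) not in ATTACHABLE_ROLES:
            continue
        if h.gene.contig_id != anchor.contig_id or h.gene_id in anchor_ids:
            continue
        if lo <= h.gene.start and h.gene.end <= hi:
            out.append(h)
    return out


def assign_accessory(
    anchors: Sequence[AnchorPair],
    hits: Sequence[DomainHit],
    library: ProfileLibrary,
    params: ScanParams | None = None,
) -> list[list[DomainHit]]:
    """Per-anchor accessory hits; a hit eligible for several anchors goes to the nearest."""
    params = params or ScanParams()
    candidates = [collect_accessory(a, hits, library, params) for a in anchors]
    owner: dict[str, tuple[int, int]] = {}  # hit gene_id+family -> (distance, anchor idx)
    for ai, anchor in enumerate(anchors):
        for h in candidates[ai]:
            d = max(0, max(anchor.span_start, h.gene.start) - min(anchor.span_end, h.gene.end))
            key = f"{h.gene_id}\0{h.family_id}"
            if key not in owner or (d, ai) < owner[key]:
                owner[key] = (d, ai)
    out: list[list[DomainHit]] = [[] for _ in anchors]
    for ai in range(len(anchors)):
        for h in candidates[ai]:
            if owner[f"{h.gene_id}\0{h.family_id}"][1] == ai:
                out[ai].append(h)
    return out


def assemble_clusters(
    anchors: Sequence[AnchorPair],
    prep_lists: Sequence[list[PrecursorPeptide]],
    accessory_lists: Sequence[list[DomainHit]],
) -> list[ClusterCandidate]:
    """Build cluster candidates; clusters sharing a member gene are merged."""
    clusters: list[ClusterCandidate] = []
    for anchor, preps, acc in zip(anchors, prep_lists, accessory_lists):
        c = ClusterCandidate(
            contig_id=anchor.contig_id,
            region_start=0,
            region_end=0,
            anchor_cyclase_hit=anchor.cyclase_hit,
            anchor_dehydratase_hit=anchor.dehydratase_hit,
            accessory_hits=list(acc),
            prep_candidates=list(preps),
        )
        _update_region(c)
        clusters.append(c)

    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ids_i = {g.gene_id for g in clusters[i].member_genes()}
                ids_j = {g.gene_id for g in clusters[j].member_genes()}
                if ids_i & ids_j:
                    logger.info(
                        "merging overlapping clusters on %s sharing genes %s",
                        clusters[i].contig_id,
                        sorted(ids_i & ids_j),
                    )
                    clusters[i] = _merge(clusters[i], clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    clusters.sort(key=lambda c: (c.contig_id, c.region_start, c.region_end))
    return clusters


def _update_region(c: ClusterCandidate) -> None:
    genes = c.member_genes()
    c.region_start = min(g.start for g in genes)
    c.region_end = max(g.end for g in genes)


def _merge(a: ClusterCandidate, b: ClusterCandidate) -> ClusterCandidate:
    # keep the anchor pair with the higher combined bit score; the other
    # pair's hits become accessory evidence of the merged cluster
    sa = a.anchor_cyclase_hit.bit_score + a.anchor_dehydratase_hit.bit_score
    sb = b.anchor_cyclase_hit.bit_score + b.anchor_dehydratase_hit.bit_score
    keep, other = (a, b) if sa >= sb else (b, a)
    extra = [other.anchor_cyclase_hit, other.anchor_dehydratase_hit]
    acc = list(keep.accessory_hits)
    have = {(h.gene_id, h.family_id) for h in acc} | {
        (keep.anchor_cyclase_hit.gene_id, keep.anchor_cyclase_hit.family_id),
        (keep.anchor_dehydratase_hit.gene_id, keep.anchor_dehydratase_hit.family_id),
    }
    for h in list(other.accessory_hits) + extra:
        if (h.gene_id, h.family_id) not in have:
            acc.append(h)
            have.add((h.gene_id, h.family_id))
    prep_ids = {p.gene.gene_id for p in keep.prep_candidates}
    preps = list(keep.prep_candidates) + [
        p for p in other.prep_candidates if p.gene.gene_id not in prep_ids
    ]
    out = ClusterCandidate(
        contig_id=keep.contig_id,
        region_start=0,
        region_end=0,
        anchor_cyclase_hit=keep.anchor_cyclase_hit,
        anchor_dehydratase_hit=keep.anchor_dehydratase_hit,
        accessory_hits=acc,
        prep_candidates=preps,
    )
    _update_region(out)
    return out
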