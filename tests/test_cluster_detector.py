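"""Anchor co-localization, prep flank search, accessory attachment, assembly."""

import numpy as np
import pytest

from thioscan.cluster_detector import (
    AnchorPair,
    ClusterCandidate,
    ScanParams,
    assemble_clusters,
    assign_accessory,
    attach_prep,
    collect_accessory,
    find_anchors,
)
from thioscan.gene_finder import OrfParams, find_orfs
from thioscan.precursor_analysis import DEFAULT_PATTERN, StructuralMotif
from thioscan.profile_hmm import DomainHit
from thioscan.sequence_io import GeneCall, GenomeSequence
from thioscan.synthetic_data import PlantSpec, plant_cluster


def _gene(gene_id, start, end, strand="+", contig="c1", protein=None):
    n_aa = max(1, (end - start) // 3 - 1)
    return GeneCall(
        gene_id=gene_id,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        protein=protein if protein is not None else "M" + "A" * (n_aa - 1),
    )


def _hit(gene, family, bits=50.0):
    return DomainHit(
        gene_id=gene.gene_id,
        family_id=family,
        bit_score=bits,
        e_value=1e-10,
        env_start=0,
        env_end=len(gene.protein),
        gene=gene,
    )


@pytest.fixture()
def motif():
    return StructuralMotif.from_pattern(DEFAULT_PATTERN)


def test_anchor_within_window(library):
    cyc = _hit(_gene("a", 10000, 12000), "YcaO")
    deh = _hit(_gene("b", 18000, 20500), "Lant_dehyd_C")
    anchors = find_anchors([cyc, deh], library, ScanParams())
    assert len(anchors) == 1
    assert anchors[0].gap() == 6000


def test_anchor_gap_exceeding_window(library):
    cyc = _hit(_gene("a", 10000, 12000), "YcaO")
    deh = _hit(_gene("b", 40000, 42000), "Lant_dehyd_C")
    assert find_anchors([cyc, deh], library, ScanParams()) == []


def test_anchor_on_different_contigs(library):
    cyc = _hit(_gene("a", 1000, 2000, contig="c1"), "YcaO")
    deh = _hit(_gene("b", 3000, 4000, contig="c2"), "Lant_dehyd_C")
    assert find_anchors([cyc, deh], library, ScanParams()) == []


def test_anchor_tie_breaks_to_leftmost_cyclase(library):
    deh = _hit(_gene("d", 20000, 21000), "Lant_dehyd_C")
    left = _hit(_gene("l", 14000, 15000), "YcaO")
    right = _hit(_gene("r", 26000, 27000), "YcaO")
    anchors = find_anchors([left, deh, right], library, ScanParams())
    assert len(anchors) == 1
    assert anchors[0].cyclase_hit.gene_id == "l"


def test_each_gene_in_at_most_one_anchor(library):
    c1 = _hit(_gene("c1g", 1000, 2000), "YcaO")
    c2 = _hit(_gene("c2g", 9000, 10000), "YcaO")
    d = _hit(_gene("dg", 4000, 5000), "Lant_dehyd_C")
    anchors = find_anchors([c1, c2, d], library, ScanParams())
    assert len(anchors) == 1  # the shared dehydratase can anchor only once
    assert anchors[0].cyclase_hit.gene_id == "c1g"  # closer pair wins


def _planted_setup(seed=3, **spec_kw):
    spec = PlantSpec(cluster_type="I", seed=seed, **spec_kw)
    genome, truth = plant_cluster(150_000, 0.5, spec)
    genes = find_orfs(genome, OrfParams())
    byloc = {(g.start, g.end, g.strand): g for g in genes}
    def hit_of(fam):
        t = next(t for t in truth if t.family == fam)
        return _hit(byloc[(t.start, t.end, t.strand)], fam)
    anchor = AnchorPair(cyclase_hit=hit_of("YcaO"), dehydratase_hit=hit_of("Lant_dehyd_C"))
    return genome, truth, genes, anchor


def test_attach_prep_finds_planted_gene(calibrated_library, motif):
    genome, truth, genes, anchor = _planted_setup()
    preps = attach_prep(
        anchor, genes, genome, calibrated_library.prep_profile, motif
    )
    t = next(t for t in truth if t.family == "Prep")
    assert preps and preps[0].gene.start == t.start
    assert preps[0].cleavage_index == t.leader_len
    assert {"motif", "prep_hmm"} <= preps[0].evidence


def test_prep_flank_window_monotonicity(calibrated_library, motif):
    genome, truth, genes, anchor = _planted_setup(prep_gap_bp=20000)
    def found(flank):
        params = ScanParams(prep_flank_bp=flank)
        return {
            p.gene.gene_id
            for p in attach_prep(
                anchor, genes, genome, calibrated_library.prep_profile, motif, params
            )
        }
    small, default, large = found(5000), found(25000), found(40000)
    assert small <= default <= large
    assert found(25000)  # planted 20 kb away: inside the default flank


def test_prep_beyond_flank_excluded(calibrated_library, motif):
    genome, truth, genes, anchor = _planted_setup(prep_gap_bp=25100)
    preps = attach_prep(
        anchor, genes, genome, calibrated_library.prep_profile, motif
    )
    t = next(t for t in truth if t.family == "Prep")
    assert all(p.gene.start != t.start for p in preps)


def test_oversized_protein_excluded_by_length_bound(calibrated_library, motif):
    genome, truth, genes, anchor = _planted_setup()
    # a 130-aa gene with a perfect motif match is not a precursor candidate
    big = _gene(
        "big",
        anchor.span_end + 500,
        anchor.span_end + 500 + 3 * 131,
        contig=genome.id,
        protein="M" + "A" * 118 + "SCTTCGCTCSC",
    )
    assert len(big.protein) == 130
    preps = attach_prep(
        anchor,
        list(genes) + [big],
        genome,
        calibrated_library.prep_profile,
        motif,
    )
    assert all(p.gene.gene_id != "big" for p in preps)


def test_collect_accessory_window(library):
    cyc = _hit(_gene("a", 100000, 102000), "YcaO")
    deh = _hit(_gene("b", 103000, 105000), "Lant_dehyd_C")
    anchor = AnchorPair(cyclase_hit=cyc, dehydratase_hit=deh)
    near = _hit(_gene("near", 108000, 109000), "SpaB_C")
    far = _hit(_gene("far", 135500, 136500), "nitroreductase")  # 30 kb past span end
    got = collect_accessory(anchor, [cyc, deh, near, far], library)
    assert [h.gene_id for h in got] == ["near"]


def test_accessory_assigned_to_nearest_anchor(library):
    a1 = AnchorPair(
        cyclase_hit=_hit(_gene("c1", 10000, 11000), "YcaO"),
        dehydratase_hit=_hit(_gene("d1", 12000, 13000), "Lant_dehyd_C"),
    )
    a2 = AnchorPair(
        cyclase_hit=_hit(_gene("c2", 40000, 41000), "YcaO"),
        dehydratase_hit=_hit(_gene("d2", 42000, 43000), "Lant_dehyd_C"),
    )
    acc = _hit(_gene("acc", 35000, 36000), "BATS")  # nearer to a2
    lists = assign_accessory([a1, a2], [acc], library)
    assert [h.gene_id for h in lists[0]] == []
    assert [h.gene_id for h in lists[1]] == ["acc"]


def test_assembly_sets_region_completeness_and_order(library):
    a = AnchorPair(
        cyclase_hit=_hit(_gene("c", 50000, 51000), "YcaO"),
        dehydratase_hit=_hit(_gene("d", 52000, 53000), "Lant_dehyd_C"),
    )
    clusters = assemble_clusters([a], [[]], [[]])
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.region_start, c.region_end) == (50000, 53000)
    assert not c.complete  # no prep: still reported, flagged incomplete


def test_clusters_sharing_a_gene_are_merged(library):
    shared_deh = _gene("d", 20000, 21000)
    a1 = AnchorPair(
        cyclase_hit=_hit(_gene("c1", 10000, 11000), "YcaO", bits=80),
        dehydratase_hit=_hit(shared_deh, "Lant_dehyd_C", bits=60),
    )
    a2 = AnchorPair(
        cyclase_hit=_hit(_gene("c2", 30000, 31000), "YcaO", bits=40),
        dehydratase_hit=_hit(shared_deh, "Lant_dehyd_C", bits=60),
    )
    clusters = assemble_clusters([a1, a2], [[], []], [[], []])
    assert len(clusters) == 1
    c = clusters[0]
    assert c.anchor_cyclase_hit.gene_id == "c1"  # higher-scoring pair kept
    member_ids = {g.gene_id for g in c.member_genes()}
    assert member_ids == {"c1", "c2", "d"}
    assert (c.region_start, c.region_end) == (10000, 31000)


def test_scan_params_validation():
    with pytest.raises(ValueError):
        ScanParams(prep_flank_bp=-1)
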