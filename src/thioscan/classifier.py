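"""Genotype assignment for thiopeptide gene clusters.

Known clusters fall into three genotypes keyed to the side-ring
biosynthesis genes: Type I carries a NosL-like indolic-acid synthase
(detected through its BATS domain), Type II carries the TsrT/TsrD pair for
quinaldic-acid formation (a radical-SAM enzyme plus a SnoaL-like cyclase),
and Type III carries neither and makes members without an
L-tryptophan-derived side ring. A cluster presenting both marker sets is
labelled ambiguous rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cluster_detector import ClusterCandidate
from .profile_hmm import (
    ROLE_TYPE1_MARKER,
    ROLE_TYPE2_MARKER_CYCLASE,
    ROLE_TYPE2_MARKER_RADICAL,
    ProfileLibrary,
)


@dataclass
class ClusterType:
    value: str  # one of I, II, III, ambiguous
    rationale: list[str] = field(default_factory=list)


def classify(cluster: ClusterCandidate, library: ProfileLibrary) -> ClusterType:
    """Assign the genotype from the marker families present in the cluster.

    Markers count only when attached to the cluster (within its assembled
    region), not anywhere on the contig.
    """
    families = {h.family_id for h in cluster.accessory_hits}
    families.add(cluster.anchor_cyclase_hit.family_id)
    families.add(cluster.anchor_dehydratase_hit.family_id)

    t1 = sorted(
        f for f in families if library.roles.get(f) == ROLE_TYPE1_MARKER
    )
    rad = sorted(
        f for f in families if library.roles.get(f) == ROLE_TYPE2_MARKER_RADICAL
    )
    cyc = sorted(
        f for f in families if library.roles.get(f) == ROLE_TYPE2_MARKER_CYCLASE
    )
    type1 = bool(t1)
    type2 = bool(rad) and bool(cyc)
    if type1 and type2:
        return ClusterType("ambiguous", rationale=t1 + rad + cyc)
    if type1:
        return ClusterType("I", rationale=t1)
    if type2:
        return ClusterType("II", rationale=rad + cyc)
    return ClusterType("III", rationale=[])


def classify_all(clusters: list[ClusterCandidate], library: ProfileLibrary) -> None:
    for c in clusters:
        ct = classify(c, library)
        c.cluster_type = ct.value
        c.type_rationale = ct.rationale
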