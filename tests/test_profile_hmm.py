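"""Profile construction, exact local scoring, calibration and proteome search.

The Viterbi/forward kernels are checked against an independent oracle that
exhaustively enumerates every local path (enter at any match state, walk
M/I/D, exit at any match state) for small profiles and short sequences.
"""

import math

import numpy as np
import pytest

from thioscan._seqcodes import AA_ALPHABET, AA_INDEX
from thioscan.profile_hmm import (
    DomainHit,
    ProfileHMM,
    ProfileLibrary,
    build_profile,
    calibrate,
    evalue,
    forward_score,
    sample_background,
    search_proteome,
    uniform_background,
    viterbi_score,
)
from thioscan.sequence_io import GeneCall
from thioscan.synthetic_data import sample_from_profile

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def test_build_profile_pseudocount_formula():
    hmm = build_profile(["ACD", "ACD"], "toy", pseudocount=1.0)
    assert hmm.n_match == 3
    a = AA_INDEX["A"]
    assert hmm.match_emissions[0, a] == pytest.approx((2 + 1) / (2 + 20), abs=1e-12)


def test_gap_majority_column_is_not_match():
    rows = ["A-CD", "A-CD", "AACD", "A-CD"]  # column 2: 3/4 gapped
    hmm = build_profile(rows, "toy")
    assert hmm.n_match == 3


def test_build_profile_errors():
    with pytest.raises(ValueError):
        build_profile(["ACD"], "toy")
    with pytest.raises(ValueError):
        build_profile(["ACD", "AC"], "toy")
    with pytest.raises(ValueError):
        build_profile(["--", "AA", "--", "--"], "toy")


def test_fixture_profiles_satisfy_invariants(library):
    for hmm in library.profiles.values():
        hmm.validate()
        assert hmm.n_match >= 1


# ---------------------------------------------------------------------------
# toy profiles with hand-derived scores
# ---------------------------------------------------------------------------


def _toy_profile(emissions_ac, forced=True):
    """Profile over an effective {A, C} alphabet with background 0.5/0.5."""
    m = len(emissions_ac)
    emis = np.zeros((m, 20))
    for k, (pa, pc) in enumerate(emissions_ac):
        emis[k, AA_INDEX["A"]] = pa
        emis[k, AA_INDEX["C"]] = pc
    bg = np.zeros(20)
    bg[AA_INDEX["A"]] = bg[AA_INDEX["C"]] = 0.5
    tr = np.zeros((m, 7))
    tr[:, 0] = 1.0  # M->M forced
    tr[:, 3] = 1.0  # I->M
    tr[:, 5] = 1.0  # D->M
    hmm = ProfileHMM(
        family_id="toy",
        n_match=m,
        match_emissions=emis,
        insert_emissions=np.tile(bg, (m, 1)),
        transitions=tr,
        background=bg,
    )
    hmm.validate()
    return hmm


def test_viterbi_two_state_forced_path():
    hmm = _toy_profile([(0.9, 0.1), (0.1, 0.9)])
    bits, s, e = viterbi_score(hmm, "AC")
    assert bits == pytest.approx(2 * math.log2(1.8), abs=1e-9)
    assert (s, e) == (0, 2)


def test_viterbi_local_alignment_beats_poor_full_path():
    # the full-model path for "CA" scores 2*log2(0.2); the local optimum is a
    # single well-matched residue at one state, scoring log2(1.8)
    hmm = _toy_profile([(0.9, 0.1), (0.1, 0.9)])
    bits, s, e = viterbi_score(hmm, "CA")
    assert bits == pytest.approx(math.log2(1.8), abs=1e-9)
    assert e - s == 1


def test_forward_single_state_certain_emission():
    hmm = _toy_profile([(1.0, 0.0)])
    assert forward_score(hmm, "A") == pytest.approx(1.0, abs=1e-9)
    bits, _, _ = viterbi_score(hmm, "A")
    assert bits == pytest.approx(1.0, abs=1e-9)


def test_viterbi_never_exceeds_forward(library):
    rng = np.random.default_rng(11)
    for fam in ("YcaO", "Prep"):
        hmm = library.profiles[fam]
        for _ in range(5):
            prot = sample_background(rng, uniform_background(), 60)
            v, _, _ = viterbi_score(hmm, prot)
            assert v <= forward_score(hmm, prot) + 1e-9


def test_empty_protein_rejected(library):
    hmm = library.profiles["YcaO"]
    with pytest.raises(ValueError):
        viterbi_score(hmm, "")
    with pytest.raises(ValueError):
        forward_score(hmm, "")


# ---------------------------------------------------------------------------
# exhaustive path-enumeration oracle
# ---------------------------------------------------------------------------


def _oracle_scores(hmm, protein):
    """Enumerate every local path and return its log-odds score (nats)."""
    with np.errstate(divide="ignore"):
        mlo = np.log(hmm.match_emissions / hmm.background)
        ilo = np.log(hmm.insert_emissions / hmm.background)
        tr = np.log(hmm.transitions)
    for arr in (mlo, ilo, tr):
        arr[~np.isfinite(arr)] = -1.0e30
    seq = [AA_INDEX[c] for c in protein]
    L, m = len(seq), hmm.n_match
    scores = []

    def walk(state, k, i, acc):
        if state == "M":
            scores.append(acc)  # a path may exit from any match state
        if state == "M":
            if k + 1 < m and i < L:
                walk("M", k + 1, i + 1, acc + tr[k, 0] + mlo[k + 1, seq[i]])
            if i < L:
                walk("I", k, i + 1, acc + tr[k, 1] + ilo[k, seq[i]])
            if k + 1 < m:
                walk("D", k + 1, i, acc + tr[k, 2])
        elif state == "I":
            if k + 1 < m and i < L:
                walk("M", k + 1, i + 1, acc + tr[k, 3] + mlo[k + 1, seq[i]])
            if i < L:
                walk("I", k, i + 1, acc + tr[k, 4] + ilo[k, seq[i]])
        else:  # D
            if k + 1 < m and i < L:
                walk("M", k + 1, i + 1, acc + tr[k, 5] + mlo[k + 1, seq[i]])
            if k + 1 < m:
                walk("D", k + 1, i, acc + tr[k, 6])

    for i in range(L):
        for k in range(m):
            walk("M", k, i + 1, mlo[k, seq[i]])
    return np.array(scores)


def _random_small_profile(rng, m):
    emis = rng.dirichlet(np.full(20, 0.5), size=m)
    ins = rng.dirichlet(np.full(20, 1.0), size=m)
    tr = np.empty((m, 7))
    tr[:, 0:3] = rng.dirichlet(np.ones(3), size=m)
    tr[:, 3:5] = rng.dirichlet(np.ones(2), size=m)
    tr[:, 5:7] = rng.dirichlet(np.ones(2), size=m)
    hmm = ProfileHMM(
        family_id=f"rand{m}",
        n_match=m,
        match_emissions=emis,
        insert_emissions=ins,
        transitions=tr,
        background=uniform_background(),
    )
    hmm.validate()
    return hmm


def test_viterbi_and_forward_match_exhaustive_enumeration():
    """DP equals max / log-sum over all enumerated local paths (<=3 states)."""
    rng = np.random.default_rng(2024)
    alphabet = "ACDE"
    seqs = [a for a in alphabet]
    seqs += [a + b for a in alphabet for b in alphabet]
    seqs += [a + b + c for a in alphabet for b in alphabet for c in alphabet]
    long_seqs = [
        "".join(alphabet[i] for i in rng.integers(0, 4, n)) for n in (4, 5, 6, 6)
    ]
    for m in (1, 2, 3):
        hmm = _random_small_profile(rng, m)
        for prot in seqs + long_seqs:
            ref = _oracle_scores(hmm, prot)
            v_bits, _, _ = viterbi_score(hmm, prot)
            f_bits = forward_score(hmm, prot)
            assert v_bits * LN2 == pytest.approx(ref.max(), abs=1e-9)
            # log-sum-exp of all path scores, numerically careful
            mx = ref.max()
            f_ref = mx + math.log(np.exp(ref - mx).sum())
            assert f_bits * LN2 == pytest.approx(f_ref, abs=1e-9)


def test_local_score_never_decreases_with_flanking_background(library):
    hmm = library.profiles["YcaO"]
    rng = np.random.default_rng(5)
    core = sample_from_profile(hmm, 0.1, seed=9)
    base, _, _ = viterbi_score(hmm, core)
    for _ in range(5):
        left = sample_background(rng, uniform_background(), rng.integers(1, 30))
        right = sample_background(rng, uniform_background(), rng.integers(1, 30))
        padded, _, _ = viterbi_score(hmm, left + core + right)
        assert padded >= base - 1e-9


# ---------------------------------------------------------------------------
# calibration and E-values
# ---------------------------------------------------------------------------


def test_calibration_is_deterministic_and_positive(library):
    hmm = library.profiles["SnoaL"]
    a = calibrate(hmm, n_samples=300, seed=4)
    b = calibrate(hmm, n_samples=300, seed=4)
    assert a.gumbel_lambda > 0
    assert (a.gumbel_mu, a.gumbel_lambda) == (b.gumbel_mu, b.gumbel_lambda)


def test_calibration_rejects_degenerate_scores():
    bg = uniform_background()
    hmm = ProfileHMM(
        family_id="flat",
        n_match=1,
        match_emissions=bg[None, :].copy(),
        insert_emissions=bg[None, :].copy(),
        transitions=np.array([[1 / 3, 1 / 3, 1 / 3, 0.5, 0.5, 0.5, 0.5]]),
        background=bg,
    )
    with pytest.raises(ValueError, match="degenerate"):
        calibrate(hmm, n_samples=200, seed=0)


def test_evalue_calibration_on_fresh_background(calibrated_library):
    """Scores with E <= 1 should occur about once per database-size draw."""
    hmm = calibrated_library.profiles["YcaO"]
    rng = np.random.default_rng(99)
    n = 1000
    count = 0
    for _ in range(n):
        prot = sample_background(rng, hmm.background, 100)
        bits, _, _ = viterbi_score(hmm, prot)
        if evalue(hmm, bits, n) <= 1.0:
            count += 1
    assert count <= 4  # ~Poisson(1): 1 + 3*sqrt(1)


# ---------------------------------------------------------------------------
# proteome search
# ---------------------------------------------------------------------------


def _gene(protein, gene_id="g1", start=0):
    return GeneCall(
        gene_id=gene_id,
        contig_id="c",
        start=start,
        end=start + 3 * (len(protein) + 1),
        strand="+",
        protein=protein,
    )


def test_search_empty_gene_list(calibrated_library):
    assert search_proteome(calibrated_library, []) == []


def test_search_detects_profile_sampled_protein(calibrated_library):
    hmm = calibrated_library.profiles["YcaO"]
    genes = [_gene("M" + sample_from_profile(hmm, 0.1, seed=21))]
    hits = search_proteome(calibrated_library, genes)
    assert any(h.family_id == "YcaO" and h.gene_id == "g1" for h in hits)
    hit = [h for h in hits if h.family_id == "YcaO"][0]
    assert hit.e_value <= 1e-3 and hit.bit_score >= 20


def test_search_background_proteins_yield_no_hits(calibrated_library):
    rng = np.random.default_rng(1234)
    genes = [
        _gene(sample_background(rng, uniform_background(), 80), f"g{i}", start=300 * i)
        for i in range(100)
    ]
    hits = search_proteome(calibrated_library, genes)
    assert len(hits) <= 2


def test_prefilter_agrees_with_full_search(calibrated_library):
    rng = np.random.default_rng(55)
    genes = [
        _gene(sample_background(rng, uniform_background(), 60), f"g{i}", start=200 * i)
        for i in range(20)
    ]
    genes.append(
        _gene(
            "M" + sample_from_profile(calibrated_library.profiles["BATS"], 0.1, 3),
            "planted",
            start=10000,
        )
    )
    fast = search_proteome(calibrated_library, genes, prefilter=True)
    full = search_proteome(calibrated_library, genes, prefilter=False)
    assert [(h.gene_id, h.family_id) for h in fast] == [
        (h.gene_id, h.family_id) for h in full
    ]


def test_detection_agrees_with_hmmer(library):
    """Independent cross-check: HMMER (pyhmmer), built from the same seed
    alignment, separates profile-sampled homologues from background exactly
    as our detector does."""
    import pyhmmer

    from thioscan.synthetic_data import fixture_alignments

    alph = pyhmmer.easel.Alphabet.amino()
    rows = fixture_alignments()["YcaO"]
    msa = pyhmmer.easel.TextMSA(
        name=b"YcaO",
        sequences=[
            pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=r)
            for i, r in enumerate(rows)
        ],
    )
    bg = pyhmmer.plan7.Background(alph)
    hmm3, _, _ = pyhmmer.plan7.Builder(alph).build_msa(msa.digitize(alph), bg)

    ours = library.profiles["YcaO"]
    rng = np.random.default_rng(0)
    seqs, labels = [], []
    for i in range(5):
        seqs.append(sample_from_profile(ours, 0.1, seed=i))
        labels.append(True)
        seqs.append(sample_background(rng, uniform_background(), 60))
        labels.append(False)

    block = pyhmmer.easel.DigitalSequenceBlock(
        alph,
        [
            pyhmmer.easel.TextSequence(name=f"q{i}".encode(), sequence=s).digitize(alph)
            for i, s in enumerate(seqs)
        ],
    )
    hits = pyhmmer.plan7.Pipeline(alph, background=bg).search_hmm(hmm3, block)
    hmmer_detected = {
        h.name if isinstance(h.name, str) else h.name.decode()
        for h in hits
        if h.evalue < 1e-3
    }
    ours_detected = {
        f"q{i}" for i, s in enumerate(seqs) if viterbi_score(ours, s)[0] >= 20.0
    }
    expected = {f"q{i}" for i, l in enumerate(labels) if l}
    assert hmmer_detected == expected
    assert ours_detected == expected


def test_score_separation_between_family_and_background(library):
    """Sampled homologues and background proteins are fully separated at 20 bits."""
    for fam in ("YcaO", "Lant_dehyd_C", "BATS"):
        hmm = library.profiles[fam]
        rng = np.random.default_rng(hash(fam) % 2**31)
        fam_scores = []
        bg_scores = []
        for i in range(50):
            fam_scores.append(
                viterbi_score(hmm, sample_from_profile(hmm, 0.2, seed=i))[0]
            )
            bg_scores.append(
                viterbi_score(
                    hmm, sample_background(rng, uniform_background(), hmm.n_match)
                )[0]
            )
        assert min(fam_scores) >= 20.0
        assert max(bg_scores) < 20.0
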