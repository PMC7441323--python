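import math

import numpy as np
import pytest

from _oracles import sw_score, translate_oracle
from trgscreen import (
    MolType,
    SequenceRecord,
    evalue,
    local_align,
    seeded_search,
    six_frame_translate,
    translated_search,
)
from trgscreen.records import AlphabetError, bit_score
from trgscreen.simulate import evolve_sequence, random_protein, reverse_translate, revcomp

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_prot(rng, lo, hi):
    return "".join(rng.choice(list(AA), size=int(rng.integers(lo, hi + 1))))


# ---------------------------------------------------------------------------
# local_align


def test_self_alignment_scores_diagonal_sum(scoring):
    seq = "MKTAYIAKQR"
    res = local_align(seq, seq, scoring)
    assert res is not None
    raw, q_start, q_end, s_start, s_end = res
    assert raw == sum(scoring.score(a, a) for a in seq)
    assert (q_start, q_end, s_start, s_end) == (1, len(seq), 1, len(seq))


def test_all_negative_pair_yields_no_hit(scoring):
    assert scoring.score("W", "C") < 0
    assert local_align("W", "C", scoring) is None


def test_invalid_residue_rejected(scoring):
    with pytest.raises(AlphabetError):
        local_align("MKJ", "MKT", scoring)


def test_matches_full_dp_oracle_on_random_pairs(scoring, rng):
    """Exact-oracle equivalence on 200 random pairs of length <= 50."""
    for _ in range(200):
        q = _rand_prot(rng, 1, 50)
        s = _rand_prot(rng, 1, 50)
        expect = sw_score(q, s, scoring.score, scoring.gap_open,
                          scoring.gap_extend)
        got = local_align(q, s, scoring)
        assert (0 if got is None else got[0]) == expect


def test_gapped_alignment_matches_oracle(scoring):
    # deletion of 3 residues forces an affine gap
    q = "MKTAYIAKQRNDLLWWF"
    s = q[:6] + q[9:]
    expect = sw_score(q, s, scoring.score, scoring.gap_open, scoring.gap_extend)
    got = local_align(q, s, scoring)
    assert got is not None and got[0] == expect
    # a length-3 gap costs open + 3*extend
    assert expect == sum(scoring.score(a, a) for a in s) + scoring.gap_open + 3 * scoring.gap_extend


# ---------------------------------------------------------------------------
# E-values


def test_zero_score_evalue_is_kmn(scoring):
    assert math.isclose(evalue(0, 10, 100, scoring), scoring.K * 10 * 100)


def test_evalue_linear_in_n_and_monotone_in_s(scoring):
    assert math.isclose(
        evalue(50, 100, 2000, scoring), 2 * evalue(50, 100, 1000, scoring)
    )
    assert evalue(60, 100, 1000, scoring) < evalue(50, 100, 1000, scoring)


@pytest.mark.parametrize("S,m,n", [(0, 1, 1), (37, 120, 5000), (200, 300, 1e6)])
def test_evalue_spot_values_match_closed_form(scoring, S, m, n):
    direct = scoring.K * m * n * math.exp(-scoring.lam * S)
    assert math.isclose(evalue(S, int(m), int(n), scoring), direct, rel_tol=1e-12)


def test_bit_score_evalue_duality(scoring, rng):
    """Recomputing the E-value from a stored hit's raw score reproduces
    the stored E-value."""
    q = SequenceRecord("q", "G1", _rand_prot(rng, 80, 120))
    subjects = [
        SequenceRecord(f"s{i}", "G2", _rand_prot(rng, 80, 120))
        for i in range(5)
    ] + [SequenceRecord("twin", "G2", q.residues)]
    n = sum(len(s) for s in subjects)
    for hit in seeded_search(q, subjects, scoring):
        assert math.isclose(
            hit.evalue, evalue(hit.raw_score, len(q), n, scoring),
            rel_tol=1e-9,
        )
        assert math.isclose(
            hit.bit_score, bit_score(hit.raw_score, scoring.lam, scoring.K),
            abs_tol=1e-6,
        )


# ---------------------------------------------------------------------------
# seeded_search


def test_identical_subject_found_with_self_score(scoring, rng):
    q = SequenceRecord("q", "G1", _rand_prot(rng, 60, 80))
    decoys = [
        SequenceRecord(f"d{i}", "G2", _rand_prot(rng, 60, 80))
        for i in range(10)
    ]
    twin = SequenceRecord("twin", "G2", q.residues)
    hits = seeded_search(q, decoys + [twin], scoring)
    by_id = {h.subject_id: h for h in hits}
    assert by_id["twin"].raw_score == sum(
        scoring.score(a, a) for a in q.residues
    )


def test_no_shared_kmer_no_hits(scoring):
    q = SequenceRecord("q", "G1", "AAAAAAAAAA")
    s = SequenceRecord("s", "G2", "WWWWWWWWWW")
    assert seeded_search(q, [s], scoring) == []


def test_at_most_one_hit_per_subject(scoring, rng):
    q = SequenceRecord("q", "G1", _rand_prot(rng, 100, 150))
    subjects = [
        SequenceRecord(f"s{i}", "G2", q.residues[:50] + _rand_prot(rng, 50, 80))
        for i in range(6)
    ]
    hits = seeded_search(q, subjects, scoring)
    assert len({h.subject_id for h in hits}) == len(hits)


def test_seeded_score_equals_exact_sw_on_ortholog_pairs(scoring):
    """Seeding is conservative; on simulated ortholog pairs (<=30%
    divergence) the seeded score equals the exact Smith-Waterman score."""
    rng = np.random.default_rng(42)
    agree = 0
    for i in range(50):
        parent = random_protein(int(rng.integers(60, 120)), rng)
        child = evolve_sequence(parent, 0.35, 1.0, rng)  # ~30% changed sites
        q = SequenceRecord("q", "G1", parent)
        s = SequenceRecord("s", "G2", child)
        exact = sw_score(parent, child, scoring.score, scoring.gap_open,
                         scoring.gap_extend)
        hits = seeded_search(q, [s], scoring)
        got = hits[0].raw_score if hits else 0
        assert got <= exact  # never an over-estimate
        agree += got == exact
    assert agree >= 48  # >= 95% of pairs


# ---------------------------------------------------------------------------
# six-frame translation


def test_first_frame_standard_code():
    frames = dict(six_frame_translate("ATGGCC"))
    assert frames[1] == "MA"


def test_stops_and_ambiguity():
    frames = dict(six_frame_translate("TAAANT"))
    assert frames[1] == "*X"


def test_partial_codon_dropped():
    frames = dict(six_frame_translate("ATGGC"))
    assert frames[1] == "M"
    assert frames[2] == "W"


def test_non_nucleotide_rejected():
    with pytest.raises(AlphabetError):
        six_frame_translate("ATGQCC")


def test_reverse_complement_symmetry(rng):
    dna = "".join(rng.choice(list("ACGT"), size=300))
    fwd = dict(six_frame_translate(dna))
    rev = dict(six_frame_translate(revcomp(dna)))
    for f in (1, 2, 3):
        assert rev[f] == fwd[-f]


def test_all_frames_match_codon_table_oracle(rng):
    for _ in range(5):
        dna = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(60, 300))))
        assert six_frame_translate(dna) == translate_oracle(dna)


# ---------------------------------------------------------------------------
# translated search


def _embed(protein, rng, strand=1):
    cds = reverse_translate(protein, rng)
    left = "".join(rng.choice(list("ACGT"), size=200))
    right = "".join(rng.choice(list("ACGT"), size=200))
    block = cds if strand == 1 else revcomp(cds)
    return left + block + right


def test_planted_cds_found_below_threshold(scoring):
    rng = np.random.default_rng(3)
    prot = random_protein(120, rng)
    scaffold = SequenceRecord("scafA", "G", _embed(prot, rng, 1), MolType.dna)
    q = SequenceRecord("q", "F", prot)
    (hit,) = translated_search(q, [scaffold], scoring, threshold=1e-7)
    assert hit.frame > 0
    assert hit.evalue < 1e-7
    assert hit.raw_score == sum(scoring.score(a, a) for a in prot)
    # DNA span covers the full embedded coding block
    assert hit.s_end - hit.s_start + 1 == 3 * len(prot)


def test_reverse_strand_same_score_negative_frame(scoring):
    rng = np.random.default_rng(3)
    prot = random_protein(120, rng)
    fwd = SequenceRecord("f", "G", _embed(prot, rng, 1), MolType.dna)
    rev = SequenceRecord("r", "G", _embed(prot, rng, -1), MolType.dna)
    q = SequenceRecord("q", "F", prot)
    (h_fwd,) = translated_search(q, [fwd], scoring, threshold=1e-7)
    (h_rev,) = translated_search(q, [rev], scoring, threshold=1e-7)
    assert h_rev.frame < 0 and h_fwd.frame > 0
    assert h_rev.raw_score == h_fwd.raw_score


def test_null_scaffolds_give_no_hits(scoring):
    """Random scaffolds vs a length-100 query yield nothing at 1e-7
    across 20 seeded replicates."""
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        q = SequenceRecord("q", "F", random_protein(100, rng))
        scaffold = SequenceRecord(
            "s", "G", "".join(rng.choice(list("ACGT"), size=1500)),
            MolType.dna,
        )
        assert translated_search(q, [scaffold], scoring, threshold=1e-7) == []


def test_strand_symmetry_score_multiset(scoring):
    """Reverse-complementing every scaffold flips frame signs but leaves
    the hit score multiset unchanged."""
    rng = np.random.default_rng(8)
    prots = [random_protein(90, rng) for _ in range(3)]
    scaffolds = [
        SequenceRecord(f"s{i}", "G", _embed(p, rng, 1 if i % 2 else -1),
                       MolType.dna)
        for i, p in enumerate(prots)
    ]
    flipped = [
        SequenceRecord(r.seq_id, r.genome_id, revcomp(r.residues), MolType.dna)
        for r in scaffolds
    ]
    for p in prots:
        q = SequenceRecord("q", "F", p)
        h1 = translated_search(q, scaffolds, scoring, threshold=1e-3)
        h2 = translated_search(q, flipped, scoring, threshold=1e-3)
        assert sorted(h.raw_score for h in h1) == sorted(h.raw_score for h in h2)
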