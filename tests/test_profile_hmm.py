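"""Profile HMM construction, scoring, calibration, and alignment insertion.

The dynamic-programming scorers are validated against a brute-force
enumeration of all legal state paths on tiny instances; emission and
transition estimation is validated against independently hand-computed
smoothed frequencies.
"""

import itertools
import math

import numpy as np
import pytest

from conftest import make_alignment
from egt_screen.profile_hmm import (
    BACKGROUND,
    ProfileHMM,
    align_to_profile,
    build_profile,
    calibrate,
    evalue,
    forward_score,
    profile_from_json,
    profile_to_json,
    score_at_evalue,
    ungapped_filter_bits,
    viterbi_bits,
    viterbi_score,
)
from egt_screen.seqio import AMINO_ACIDS, ProteinRecord
from egt_screen.validation import (
    brute_forward,
    brute_viterbi,
    sequence_probability,
)

AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@pytest.fixture(scope="module")
def toy_profile():
    aln = make_alignment("toy", [("a", "MKLA"), ("b", "M-LA"), ("c", "MKIA")])
    return build_profile(aln)


# -- construction -----------------------------------------------------------


def test_identical_rows_give_match_states_and_peaked_emissions():
    aln = make_alignment("fam", [(f"r{i}", "MKL") for i in range(4)])
    prof = build_profile(aln)
    assert prof.M == 3
    assert int(np.argmax(prof.match_emissions[1])) == AA_IDX["K"]


def test_all_gap_column_excluded():
    aln = make_alignment("fam", [("a", "M-K"), ("b", "M-K"), ("c", "M-K")])
    prof = build_profile(aln)
    assert prof.M == 2
    assert prof.match_columns == [0, 2]


def test_no_qualifying_columns_is_an_error():
    aln = make_alignment("fam", [("a", "M-"), ("b", "-K")])
    with pytest.raises(ValueError, match="occupancy"):
        build_profile(aln, occupancy_threshold=0.2)


def test_hand_computed_emissions_and_transitions(toy_profile):
    """3-row toy: MKLA / M-LA / MKIA, all four columns are match states.

    Hand calculation: column 2 holds two K residues (one gap), so the K
    emission is (2 + 1*bg_K) / (2 + 1); the begin node sees three M->M
    transitions and none to I/D, so t_mm[0] = (3+1)/(3+3).
    """
    prof = toy_profile
    assert prof.M == 4
    bg_k = BACKGROUND[AA_IDX["K"]]
    assert prof.match_emissions[1, AA_IDX["K"]] == pytest.approx(
        (2 + bg_k) / 3.0, abs=1e-12
    )
    bg_l = BACKGROUND[AA_IDX["L"]]
    # column 3: two L, one I
    assert prof.match_emissions[2, AA_IDX["L"]] == pytest.approx(
        (2 + bg_l) / 4.0, abs=1e-12
    )
    assert prof.t_mm[0] == pytest.approx(4 / 6)
    # node 1: two M->M (rows a, c), one M->D (row b), Laplace +1 each
    assert prof.t_mm[1] == pytest.approx(3 / 6)
    assert prof.t_md[1] == pytest.approx(2 / 6)
    assert prof.t_mi[1] == pytest.approx(1 / 6)
    # D2 -> M3 once; Laplace over {M, D}
    assert prof.t_dm[2] == pytest.approx(2 / 3)


def test_stochastic_vector_validation():
    bad = np.zeros((1, 20))
    bad[0, 0] = 0.5  # does not sum to 1
    with pytest.raises(ValueError, match="sums to"):
        ProfileHMM(
            "bad", 1, bad, BACKGROUND.copy(), BACKGROUND.copy(),
            t_mm=np.array([0.9, 1.0]), t_mi=np.array([0.05, 0.0]),
            t_md=np.array([0.05, 0.0]), t_im=np.array([0.9, 1.0]),
            t_ii=np.array([0.1, 0.0]), t_dm=np.array([1.0, 1.0]),
            t_dd=np.array([0.0, 0.0]),
        )


# -- scoring vs enumeration oracle ------------------------------------------


@pytest.mark.parametrize("mode", ["local", "glocal"])
def test_scores_match_path_enumeration(toy_profile, mode):
    rng = np.random.default_rng(0)
    seqs = ["M", "MK", "MKLA", "QQQQQ", "KKLAM"]
    seqs += ["".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 6)))
             for _ in range(20)]
    for seq in seqs:
        bv = brute_viterbi(toy_profile, seq, mode)
        dv = viterbi_bits(toy_profile, seq, mode)
        assert dv == pytest.approx(bv, abs=1e-9), (seq, mode)
        bf = brute_forward(toy_profile, seq, mode)
        df = forward_score(toy_profile, seq, mode)
        assert df == pytest.approx(bf, abs=1e-9), (seq, mode)


def test_forward_at_least_viterbi(toy_profile):
    rng = np.random.default_rng(1)
    for _ in range(100):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(1, 6)))
        for mode in ("local", "glocal"):
            assert forward_score(toy_profile, seq, mode) >= \
                viterbi_bits(toy_profile, seq, mode) - 1e-9


def test_consensus_beats_all_single_substitutions():
    s = "MKLAV"
    aln = make_alignment("fam", [(f"r{i}", s) for i in range(5)])
    prof = build_profile(aln)
    base = viterbi_bits(prof, s)
    for pos, alt in itertools.product(range(len(s)), AMINO_ACIDS):
        if alt == s[pos]:
            continue
        mutant = s[:pos] + alt + s[pos + 1:]
        assert viterbi_bits(prof, mutant) <= base + 1e-9


def test_glocal_short_sequence_finite(toy_profile):
    # deletions allow traversal even when the sequence is shorter than M
    assert math.isfinite(viterbi_bits(toy_profile, "M", "glocal"))


def test_x_residue_scores_as_background(toy_profile):
    # X contributes zero log-odds wherever it lands
    assert viterbi_bits(toy_profile, "MKLA", "glocal") >= \
        viterbi_bits(toy_profile, "MXLA", "glocal")
    assert forward_score(toy_profile, "XXXX", "local") == pytest.approx(
        forward_score(toy_profile, "XXXX", "local")
    )


def test_ungapped_filter_lower_bounds_viterbi(toy_profile):
    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=rng.integers(2, 30)))
        assert ungapped_filter_bits(toy_profile, seq) <= \
            viterbi_bits(toy_profile, seq) + 1e-9


# -- probability conservation -----------------------------------------------


def two_symbol_profile(M=4):
    """Insert-free two-residue profile: emitted sequences have length <= M,
    so the sequence space is exhaustively enumerable."""
    me = np.zeros((M, 20))
    me[:, :2] = [[0.7, 0.3], [0.5, 0.5], [0.2, 0.8], [0.6, 0.4]][:M]
    bg = np.zeros(20)
    bg[:2] = 0.5
    return ProfileHMM(
        "two", M, me, bg.copy(), bg,
        t_mm=np.array([0.8, 0.7, 0.9, 0.75, 1.0][: M + 1]),
        t_mi=np.zeros(M + 1),
        t_md=np.array([0.2, 0.3, 0.1, 0.25, 0.0][: M + 1]),
        t_im=np.ones(M + 1), t_ii=np.zeros(M + 1),
        t_dm=np.array([0.0, 0.6, 0.5, 0.7, 1.0][: M + 1]),
        t_dd=np.array([1.0, 0.4, 0.5, 0.3, 0.0][: M + 1]),
    )


def test_glocal_forward_probability_mass_sums_to_one():
    prof = two_symbol_profile()
    total = 0.0
    for L in range(0, prof.M + 1):
        for tup in itertools.product("AC", repeat=L):
            seq = "".join(tup)
            total += sequence_probability(
                prof, seq, forward_score(prof, seq, "glocal")
            )
    assert total == pytest.approx(1.0, abs=1e-9)


# -- calibration and E-values -----------------------------------------------


@pytest.fixture(scope="module")
def calibrated_profile():
    rng = np.random.default_rng(7)
    rows = []
    base = rng.choice(20, size=120, p=BACKGROUND)
    for i in range(6):
        mut = base.copy()
        flip = rng.random(120) < 0.15
        mut[flip] = rng.choice(20, size=int(flip.sum()))
        rows.append((f"r{i}", "".join(AMINO_ACIDS[j] for j in mut)))
    prof = build_profile(make_alignment("cal", rows))
    return calibrate(prof, n_decoys=200, decoy_length=150, seed=42)


def test_calibration_reproducible_and_lambda_positive(calibrated_profile):
    mu, lam = calibrated_profile.calibration
    assert lam > 0
    # same seed, same decoys -> identical parameters
    fresh = profile_from_json(profile_to_json(calibrated_profile))
    fresh.calibration = None
    calibrate(fresh, n_decoys=200, decoy_length=150, seed=42)
    assert fresh.calibration == pytest.approx((mu, lam))


def test_calibration_rejects_degenerate_scores():
    me = np.tile(BACKGROUND, (1, 1)).reshape(1, 20)
    prof = ProfileHMM(
        "flat", 1, me.copy(), BACKGROUND.copy(), BACKGROUND.copy(),
        t_mm=np.array([0.9, 1.0]), t_mi=np.array([0.05, 0.0]),
        t_md=np.array([0.05, 0.0]), t_im=np.array([0.9, 1.0]),
        t_ii=np.array([0.1, 0.0]), t_dm=np.array([1.0, 1.0]),
        t_dd=np.array([0.0, 0.0]),
    )
    # emissions equal background: every decoy scores identically
    with pytest.raises(ValueError, match="degenerate"):
        calibrate(prof, n_decoys=50, decoy_length=30, seed=0)


def test_evalue_monotone_and_linear_in_database_size(calibrated_profile):
    e1 = evalue(calibrated_profile, 20.0, 1000)
    e2 = evalue(calibrated_profile, 25.0, 1000)
    assert e2 < e1
    assert evalue(calibrated_profile, 20.0, 2000) == pytest.approx(2 * e1)
    s = score_at_evalue(calibrated_profile, 1e-5, 1000)
    assert evalue(calibrated_profile, s, 1000) == pytest.approx(1e-5, rel=1e-6)


def test_evalue_requires_calibration(toy_profile):
    with pytest.raises(ValueError, match="calibrat"):
        evalue(toy_profile, 10.0, 100)


def test_median_decoy_evalue_near_half_database(calibrated_profile):
    rng = np.random.default_rng(9)
    scores = []
    for _ in range(200):
        seq = "".join(
            AMINO_ACIDS[i] for i in rng.choice(20, size=150, p=BACKGROUND)
        )
        scores.append(viterbi_bits(calibrated_profile, seq))
    med = float(np.median(scores))
    e = evalue(calibrated_profile, med, 200)
    assert 50 <= e <= 200  # n/2 within a factor of 2


# -- alignment insertion ----------------------------------------------------


def test_align_identical_reference_row(toy_profile):
    aln = make_alignment("toy", [("a", "MKLA"), ("b", "M-LA"), ("c", "MKIA")])
    rec = ProteinRecord("new", "t", "MKLA")
    out = align_to_profile(toy_profile, rec, aln)
    assert out.n_rows == 4
    assert out.row("new")[1] == "MKLA"
    assert out.row("a")[1] == "MKLA"


def test_insertion_opens_column_for_all_rows(toy_profile):
    aln = make_alignment("toy", [("a", "MKLA"), ("b", "M-LA"), ("c", "MKIA")])
    rec = ProteinRecord("new", "t", "MKWLA")  # extra W between columns 2 and 3
    out = align_to_profile(toy_profile, rec, aln)
    assert out.n_columns == 5
    assert out.row("new")[1].replace("-", "") == "MKWLA"
    # original rows gain exactly one gap, and dropping the new row recovers
    # the original columns in order
    for rid, orig in (("a", "MKLA"), ("b", "M-LA"), ("c", "MKIA")):
        row = out.row(rid)[1]
        assert row.count("-") == orig.count("-") + 1
        assert row.replace("-", "") == orig.replace("-", "")


def test_augment_then_rebuild_scores_no_worse():
    rng = np.random.default_rng(21)
    for _ in range(5):
        base = rng.choice(20, size=60, p=BACKGROUND)
        rows = []
        for i in range(5):
            mut = base.copy()
            flip = rng.random(60) < 0.2
            mut[flip] = rng.choice(20, size=int(flip.sum()))
            rows.append((f"r{i}", "".join(AMINO_ACIDS[j] for j in mut)))
        aln = make_alignment("fam", rows)
        prof = build_profile(aln)
        newseq = base.copy()
        flip = rng.random(60) < 0.25
        newseq[flip] = rng.choice(20, size=int(flip.sum()))
        rec = ProteinRecord("new", "t", "".join(AMINO_ACIDS[j] for j in newseq))
        before = forward_score(prof, rec.sequence, "glocal")
        rebuilt = build_profile(align_to_profile(prof, rec, aln))
        after = forward_score(rebuilt, rec.sequence, "glocal")
        assert after >= before - 1e-6


def test_profile_json_round_trip(calibrated_profile):
    back = profile_from_json(profile_to_json(calibrated_profile))
    assert back.M == calibrated_profile.M
    assert np.allclose(back.match_emissions, calibrated_profile.match_emissions)
    assert back.calibration == pytest.approx(calibrated_profile.calibration)
    seq = "MKLAVMKLAV"
    assert viterbi_bits(back, seq) == pytest.approx(
        viterbi_bits(calibrated_profile, seq)
    )
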