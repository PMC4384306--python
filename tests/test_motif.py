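"""Background estimation, weight-matrix construction, and sequence scoring."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gapmer as g
from gapmer import (
    AlignedSites,
    BackgroundModel,
    GappedNmer,
    WeightMatrix,
    build_weight_matrix,
    estimate_background,
    score_sequence,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


# -- aligned sites ------------------------------------------------------


def test_aligned_sites_validation():
    sites = AlignedSites(["ttttttg", "TTTTTTG"])
    assert sites.site_length == 7 and sites.count == 2
    assert sites.sequences[0] == "TTTTTTG"  # upper-cased
    with pytest.raises(ValueError, match="record 2"):
        AlignedSites(["TTTTTTG", "TTTTTTGA"])
    with pytest.raises(ValueError, match="non-ACGT"):
        AlignedSites(["TTTNTTG"])
    with pytest.raises(ValueError):
        AlignedSites([])


# -- background ---------------------------------------------------------


def test_background_mononucleotide_hand_count():
    bg = estimate_background("AAAA", GappedNmer("m"))
    assert bg.freq("A") == pytest.approx((4 + 0.25) / 5)
    for b in "CGT":
        assert bg.freq(b) == pytest.approx(0.25 / 5)
    assert bg.total_windows == 4


def test_background_gapped_hand_count():
    # "ACGT" has two mkm frames: ACG (word AG) and CGT (word CT)
    bg = estimate_background("ACGT", GappedNmer("mkm"))
    assert bg.total_windows == 2
    assert bg.freq("AG") == pytest.approx((1 + 1 / 16) / 3)
    assert bg.freq("CT") == pytest.approx((1 + 1 / 16) / 3)
    assert bg.freq("AA") == pytest.approx((1 / 16) / 3)
    assert bg.freqs.sum() == pytest.approx(1.0, abs=1e-12)


@given(seq=dna, type_id=st.integers(0, 31))
def test_background_frequencies_sum_to_one(seq, type_id):
    pat = g.decode_type_id(type_id, 6)
    if len(seq) < pat.frame_length:
        return
    bg = estimate_background(seq, pat)
    assert abs(bg.freqs.sum() - 1.0) < 1e-12
    assert np.all(bg.freqs > 0)


def test_background_too_short_errors():
    with pytest.raises(ValueError, match="no valid window"):
        estimate_background("ACG", GappedNmer("mkkkkm"))


def test_background_skips_ambiguous_windows():
    # N at position 2 invalidates windows overlapping it
    bg = estimate_background("AANAA", GappedNmer("m"))
    assert bg.total_windows == 4
    bg2 = estimate_background("ACNGT", GappedNmer("mm"))
    assert bg2.total_windows == 2  # AC and GT only


def test_background_records_do_not_join():
    # two records: no window spans the junction
    joined = estimate_background("ACGTACGT", GappedNmer("mm"))
    split = estimate_background(["ACGT", "ACGT"], GappedNmer("mm"))
    assert joined.total_windows == 7
    assert split.total_windows == 6
    assert split.freq("TA") == pytest.approx((0 + 1 / 16) / 7)


def test_user_background_rejects_nonpositive():
    with pytest.raises(ValueError, match="> 0"):
        BackgroundModel.from_frequencies(
            GappedNmer("m"), {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0}
        )


# -- weight matrix ------------------------------------------------------


def test_single_site_hand_weights(uniform_bg_m):
    wm = build_weight_matrix(AlignedSites(["AA"]), GappedNmer("m"), uniform_bg_m)
    # raw: ln((1+.25)/(.25*2)) for A, ln(.25/(.25*2)) otherwise; shift to 0
    expected_off = -math.log(5)
    assert wm.weights[0] == pytest.approx([0.0, 0.0])
    for row in (1, 2, 3):
        assert wm.weights[row] == pytest.approx([expected_off, expected_off])


def test_matrix_geometry(hb_like_sites, random_background):
    wm16 = build_weight_matrix(
        hb_like_sites,
        GappedNmer("mkkkkm"),
        estimate_background(random_background, GappedNmer("mkkkkm")),
    )
    assert wm16.weights.shape == (16, 2)
    wm0 = build_weight_matrix(
        hb_like_sites,
        GappedNmer("m"),
        estimate_background(random_background, GappedNmer("m")),
    )
    assert wm0.weights.shape == (4, 7)


@pytest.mark.parametrize("type_id", range(32))
def test_matrix_invariants_all_patterns(type_id, hb_like_sites, random_background):
    """Counts sum to L per column; column max exactly 0; column min < 0."""
    pat = g.decode_type_id(type_id, 6)
    bg = estimate_background(random_background, pat)
    wm = build_weight_matrix(hb_like_sites, pat, bg)
    assert np.all(wm.counts.sum(axis=0) == hb_like_sites.count)
    assert np.all(wm.weights.max(axis=0) == 0.0)
    assert np.all(wm.weights.min(axis=0) < 0.0)


def test_pattern_longer_than_site_errors(uniform_bg_m):
    bg = BackgroundModel.from_frequencies(GappedNmer("mkm"), np.full(16, 1 / 16))
    with pytest.raises(ValueError, match="exceeds the site length"):
        build_weight_matrix(AlignedSites(["AA"]), GappedNmer("mkm"), bg)


def test_background_pattern_mismatch_errors(uniform_bg_m):
    with pytest.raises(ValueError, match="background was built"):
        build_weight_matrix(AlignedSites(["AAA"]), GappedNmer("mm"), uniform_bg_m)


# -- scoring ------------------------------------------------------------


def test_score_consensus_and_worst(hb_like_sites, random_background):
    pat = GappedNmer("m")
    bg = estimate_background(random_background, pat)
    wm = build_weight_matrix(hb_like_sites, pat, bg)
    consensus = wm.consensus
    assert score_sequence(consensus, wm) == pytest.approx(1.0)
    worst = "".join(
        "ACGT"[int(np.argmin(wm.weights[:, i]))] for i in range(wm.n_frames)
    )
    assert score_sequence(worst, wm) == pytest.approx(0.0)


def test_score_hand_example(uniform_bg_m):
    wm = build_weight_matrix(AlignedSites(["AA"]), GappedNmer("m"), uniform_bg_m)
    assert score_sequence("CA", wm) == pytest.approx(0.5)
    assert score_sequence("AA", wm) == pytest.approx(1.0)
    assert score_sequence("CC", wm) == pytest.approx(0.0)


def test_score_input_validation(uniform_bg_m):
    wm = build_weight_matrix(AlignedSites(["AA"]), GappedNmer("m"), uniform_bg_m)
    with pytest.raises(ValueError, match="length"):
        score_sequence("AAA", wm)
    with pytest.raises(ValueError, match="non-ACGT"):
        score_sequence("AN", wm)


@given(seq=st.text(alphabet="ACGT", min_size=7, max_size=7), type_id=st.integers(0, 31))
def test_score_in_unit_interval(seq, type_id, hb_like_sites, random_background):
    pat = g.decode_type_id(type_id, 6)
    bg = estimate_background(random_background, pat)
    wm = build_weight_matrix(hb_like_sites, pat, bg)
    s = score_sequence(seq, wm)
    assert 0.0 <= s <= 1.0


def _pwm_oracle_score(seq, sites, bg_freqs):
    """Independent per-position PWM log-odds with the same normalization."""
    L = len(sites.sequences)
    l = sites.site_length
    total = 0.0
    denom = 0.0
    for i in range(l):
        col = {}
        for b in "ACGT":
            n = sum(site[i] == b for site in sites.sequences)
            col[b] = math.log((n + bg_freqs[b]) / (bg_freqs[b] * (L + 1)))
        shift = max(col.values())
        shifted = {b: v - shift for b, v in col.items()}
        total += shifted[seq[i]]
        denom += min(shifted.values())
    return 1.0 - total / denom


@given(seq=st.text(alphabet="ACGT", min_size=7, max_size=7))
def test_mononucleotide_matches_classic_pwm(seq, hb_like_sites, random_background):
    pat = GappedNmer("m")
    bg = estimate_background(random_background, pat)
    wm = build_weight_matrix(hb_like_sites, pat, bg)
    oracle = _pwm_oracle_score(seq, hb_like_sites, bg.as_dict())
    assert score_sequence(seq, wm) == pytest.approx(oracle, abs=1e-12)


def test_both_strand_scoring(uniform_bg_m):
    wm = build_weight_matrix(AlignedSites(["AA"]), GappedNmer("m"), uniform_bg_m)
    # TT is the reverse complement of the consensus AA
    assert score_sequence("TT", wm) == pytest.approx(0.0)
    assert score_sequence("TT", wm, both_strands=True) == pytest.approx(1.0)


def test_matrix_tsv_roundtrip(tmp_path, hb_like_sites, random_background):
    pat = GappedNmer("mkmkm")
    bg = estimate_background(random_background, pat)
    wm = build_weight_matrix(hb_like_sites, pat, bg)
    path = tmp_path / "wm.tsv"
    wm.to_tsv(path)
    loaded = WeightMatrix.from_tsv(path)
    assert loaded.pattern == wm.pattern
    assert loaded.site_length == wm.site_length
    rng = np.random.default_rng(0)
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=7))
        assert score_sequence(seq, loaded) == score_sequence(seq, wm)  # bit-identical
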