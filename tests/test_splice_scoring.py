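"""Weight-matrix splice scoring: hand-checked arithmetic, additivity,
strand handling and the compound-impact / strongest-site rules."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cishap import splice_scoring as ss
from cishap.splice_scoring import (
    HaplotypeEdit, ScorerModel, SpliceWindow, apply_edits, compound_impact,
    score, score_delta_lookup, strongest_site, train_scorer,
)


def _window(seq="ACAGGTAAGTC", site_type="donor_5ss", anchor=None):
    """Small donor window: GT at the centre of an odd layout is not
    required; positions are explicit."""
    d = seq.find("GT", 2) + 1  # 1-based position of G
    return SpliceWindow(site_type, seq, (d, d + 1), anchor)


# ---------------------------------------------------------------- training

def test_wmm_hand_arithmetic_single_sequence():
    """One training 2-mer, pseudocount 1, uniform background: observed base
    frequency (1 + 1/4) / (1 + 1), others (1/4) / 2."""
    model = train_scorer(["AC"], None, "wmm", pseudocount=1.0, motif_span=(0, 2))
    f_obs, f_other = 1.25 / 2, 0.25 / 2
    assert model.log_odds[0, 0] == pytest.approx(math.log2(f_obs / 0.25))
    assert model.log_odds[0, 1] == pytest.approx(math.log2(f_other / 0.25))
    assert model.log_odds[1, 1] == pytest.approx(math.log2(f_obs / 0.25))


def test_sites_matching_decoy_composition_score_zero():
    """Per-position frequencies equal to the decoy composition give
    all-zero log odds, hence score 0 for any sequence."""
    seqs = ["AC", "CA", "GT", "TG"]
    model = train_scorer(seqs, decoys=seqs, model_type="wmm", motif_span=(0, 2))
    assert np.allclose(model.log_odds, 0, atol=1e-12)
    w = SpliceWindow("donor_5ss", "AGTA", (2, 3))
    assert score(model, w) == pytest.approx(0.0)


def test_training_recovers_known_frequencies():
    """Law of large numbers: n = 10000 draws from a known table recover
    the per-position frequencies within 0.02."""
    rng = np.random.default_rng(0)
    truth = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.2, 0.3, 0.4]])
    seqs = [
        "".join("ACGT"[rng.choice(4, p=truth[i])] for i in range(2))
        for _ in range(10_000)
    ]
    model = train_scorer(seqs, None, "wmm", motif_span=(0, 2))
    recovered = 0.25 * np.exp2(model.log_odds)
    assert np.abs(recovered - truth).max() < 0.02


def test_training_length_mismatch_is_hard_error():
    with pytest.raises(ValueError, match="length"):
        train_scorer(["ACG", "AC"], None, "wmm", motif_span=(0, 3))


def test_consensus_is_argmax_under_peaked_wmm():
    consensus = "CAGGTAAGT"
    seqs = [consensus] * 50
    model = train_scorer(seqs, None, "wmm", motif_span=(3, 6), site_type="donor_5ss")
    w = SpliceWindow("donor_5ss", "AA" + consensus[:3] + "GT" + consensus[5:] + "AA", (6, 7))
    ref = score(model, w)
    for pos, alt in [(p, a) for p in range(3, 12) for a in "ACGT"
                     if w.sequence[p - 1] != a]:
        assert score(model, w, HaplotypeEdit.single(pos, alt)) < ref


# ---------------------------------------------------------------- scoring

@pytest.fixture(scope="module")
def toy_wmm():
    rng = np.random.default_rng(1)
    seqs = ["".join(rng.choice(list("ACGT"), p=[0.55, 0.15, 0.15, 0.15]))
            + "AGGTAAGT" for _ in range(200)]
    return train_scorer(seqs, None, "wmm", motif_span=(3, 6), site_type="donor_5ss")


@pytest.fixture(scope="module")
def toy_window():
    return SpliceWindow("donor_5ss", "TTCAGGTAAGTCC", (6, 7))


def test_edit_validation(toy_window):
    with pytest.raises(ValueError, match="does not change"):
        apply_edits(toy_window, HaplotypeEdit.single(1, "T"))
    with pytest.raises(ValueError, match="duplicate"):
        HaplotypeEdit(((3, "A"), (3, "C")))
    with pytest.raises(IndexError):
        apply_edits(toy_window, HaplotypeEdit.single(99, "A"))


def test_edit_at_dinucleotide_destroys_site(toy_wmm, toy_window):
    ref = score(toy_wmm, toy_window)
    assert score(toy_wmm, toy_window, HaplotypeEdit.single(6, "A")) < ref


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.tuples(st.integers(1, 13), st.sampled_from("ACGT")),
                min_size=1, max_size=5))
def test_wmm_delta_lookup_equals_full_rescoring(toy_wmm, toy_window, raw_edits):
    """Score difference from the reference depends only on the edited
    positions (WMM additivity): table lookup equals full rescoring."""
    seen, subs = set(), []
    for pos, alt in raw_edits:
        if pos in seen or toy_window.sequence[pos - 1] == alt:
            continue
        seen.add(pos)
        subs.append((pos, alt))
    if not subs:
        return
    e = HaplotypeEdit(tuple(subs))
    full = score(toy_wmm, toy_window, e) - score(toy_wmm, toy_window)
    assert score_delta_lookup(toy_wmm, toy_window, e) == pytest.approx(full)


def test_multi_edit_equals_sequential_single_edits(toy_wmm, toy_window):
    e1, e2 = HaplotypeEdit.single(2, "G"), HaplotypeEdit.single(9, "C")
    combined = apply_edits(toy_window, e1 + e2)
    w2 = SpliceWindow("donor_5ss", apply_edits(toy_window, e1),
                      toy_window.dinucleotide_positions)
    assert apply_edits(w2, e2) == combined
    assert score(toy_wmm, toy_window, e1 + e2) == pytest.approx(
        score(toy_wmm, SpliceWindow("donor_5ss", combined,
                                    toy_window.dinucleotide_positions)))


def test_reverse_strand_windows_score_identically(toy_wmm):
    """A minus-strand window built from plus-strand sequence equals the
    window built directly in transcript orientation."""
    from Bio.Seq import Seq

    transcript = "TTCAGGTAAGTCC"
    plus = str(Seq(transcript).reverse_complement())
    w_minus = SpliceWindow.from_genomic(plus, "chr15", 1000, "-", "donor_5ss")
    assert len(w_minus) == len(transcript)
    # from_genomic centres the dinucleotide; adjust via direct construction
    w_direct = SpliceWindow("donor_5ss", transcript, (6, 7))
    assert w_minus.sequence == transcript
    assert score(toy_wmm, w_direct) == pytest.approx(
        score(toy_wmm, SpliceWindow("donor_5ss", w_minus.sequence, (6, 7))))


def test_genome_map_round_trip_on_minus_strand():
    from Bio.Seq import Seq

    transcript = "TTCAGGTAAGTCC"
    plus = str(Seq(transcript).reverse_complement())
    w = SpliceWindow.from_genomic(plus, "chr15", 1000, "-", "donor_5ss")
    contig, gpos, strand = w.genome_map[1]
    assert (contig, strand) == ("chr15", "-")
    assert gpos == 1000 + len(plus) - 1  # transcript start = plus-strand end
    assert w.window_index("chr15", gpos) == 1


# ---------------------------------------------------------------- serialization

@pytest.mark.parametrize("model_type", ["wmm", "wam"])
def test_model_text_round_trip(tmp_path, model_type):
    rng = np.random.default_rng(2)
    seqs = ["".join(rng.choice(list("ACGT"))) + "GTAAGTAC" for _ in range(100)]
    decoys = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(100)]
    m = train_scorer(seqs, decoys, model_type, motif_span=(3, 6), site_type="donor_5ss")
    p = tmp_path / "m.txt"
    m.to_text(p)
    m2 = ScorerModel.from_text(p)
    w = SpliceWindow("donor_5ss", "TTCAGGTAAGTCC", (6, 7))
    assert score(m2, w) == pytest.approx(score(m, w))
    assert score(m2, w, HaplotypeEdit.single(4, "T")) == pytest.approx(
        score(m, w, HaplotypeEdit.single(4, "T")))


# ---------------------------------------------------------------- compound

def test_compound_impact_noop_anchor_outside_span(toy_wmm, toy_window):
    """An anchor outside the motif span leaves the haplotype delta equal
    to the variant's own delta."""
    variant = HaplotypeEdit.single(5, "T")
    anchor = HaplotypeEdit.single(13, "A")  # beyond the 9-mer span
    dv, dh = compound_impact(toy_wmm, toy_window, variant, anchor)
    assert dh == pytest.approx(dv)


def test_compound_impact_wmm_additivity(toy_wmm, toy_window):
    variant = HaplotypeEdit.single(5, "T")
    anchor = HaplotypeEdit.single(9, "C")
    dv, dh = compound_impact(toy_wmm, toy_window, variant, anchor)
    da = score(toy_wmm, toy_window, anchor) - score(toy_wmm, toy_window)
    assert dh == pytest.approx(dv + da)


def test_compound_impact_wam_against_direct_scoring():
    """With adjacent variant/anchor a first-order model is not additive in
    general; the compound delta must still equal direct rescoring."""
    rng = np.random.default_rng(3)
    seqs = []
    for _ in range(300):
        first = "C" if rng.random() < 0.8 else "A"
        second = ("A" if rng.random() < 0.9 else "G") if first == "C" else \
                 ("G" if rng.random() < 0.9 else "A")
        seqs.append(first + second + "GGTAAGT")
    m = train_scorer(seqs, None, "wam", motif_span=(3, 6), site_type="donor_5ss")
    w = SpliceWindow("donor_5ss", "TCAGGTAAGTT", (5, 6))
    variant, anchor = HaplotypeEdit.single(2, "G"), HaplotypeEdit.single(3, "T")
    dv, dh = compound_impact(m, w, variant, anchor)
    ref = score(m, w)
    assert dv == pytest.approx(score(m, w, variant) - ref)
    assert dh == pytest.approx(score(m, w, variant + anchor) - ref)
    da = score(m, w, anchor) - ref
    assert dh != pytest.approx(dv + da)  # adjacent edits interact


def test_compound_impact_rejects_overlapping_edits(toy_wmm, toy_window):
    with pytest.raises(ValueError, match="overlap"):
        compound_impact(toy_wmm, toy_window, HaplotypeEdit.single(5, "T"),
                        HaplotypeEdit.single(5, "A"))


# ---------------------------------------------------------------- strongest

def _site_setup(donor_boost):
    """Two toy windows and models where the donor reference score can be
    tuned relative to the acceptor's."""
    rng = np.random.default_rng(4)
    donor_seqs = ["CAG" + "GTAAGT" for _ in range(50)]
    acc_seqs = ["TTTTTTTTTTTTTTTTTT" + "AG" + "GTT" for _ in range(50)]
    md = train_scorer(donor_seqs, None, "wmm", motif_span=(3, 6), site_type="donor_5ss")
    ma = train_scorer(acc_seqs, None, "wmm", motif_span=(3, 20), site_type="acceptor_3ss")
    wd = SpliceWindow("donor_5ss", ("CAG" if donor_boost else "TTT") + "GTAAGTAA", (4, 5))
    wa = SpliceWindow("acceptor_3ss", "TTTTTTTTTTTTTTTTTTAGGTTAA", (19, 20))
    return {"donor_5ss": md, "acceptor_3ss": ma}, {"donor_5ss": wd, "acceptor_3ss": wa}


def test_strongest_site_single_window_variant():
    models, windows = _site_setup(True)
    site, impact = strongest_site(models, windows,
                                  {"donor_5ss": HaplotypeEdit.single(1, "G")})
    assert site == "donor_5ss"
    assert impact == pytest.approx(
        score(models["donor_5ss"], windows["donor_5ss"], HaplotypeEdit.single(1, "G"))
        - score(models["donor_5ss"], windows["donor_5ss"]))


def test_strongest_site_picks_higher_reference_score():
    models, windows = _site_setup(True)
    refs = {s: score(models[s], windows[s]) for s in models}
    edits = {"donor_5ss": HaplotypeEdit.single(2, "C"),
             "acceptor_3ss": HaplotypeEdit.single(22, "C")}
    site, _ = strongest_site(models, windows, edits)
    assert site == max(refs, key=refs.get)


def test_strongest_site_tie_breaks_to_acceptor():
    models, windows = _site_setup(True)

    class Zero:
        model_type = "wmm"

    zd = train_scorer(["AAA"], None, "wmm", motif_span=(0, 3), site_type="donor_5ss")
    za = train_scorer(["AAA"], None, "wmm", motif_span=(0, 3), site_type="acceptor_3ss")
    zd.log_odds[:] = 0
    za.log_odds[:] = 0
    wd = SpliceWindow("donor_5ss", "AGTA", (2, 3))
    wa = SpliceWindow("acceptor_3ss", "AAGA", (2, 3))
    site, impact = strongest_site(
        {"donor_5ss": zd, "acceptor_3ss": za},
        {"donor_5ss": wd, "acceptor_3ss": wa},
        {"donor_5ss": HaplotypeEdit.single(1, "C"),
         "acceptor_3ss": HaplotypeEdit.single(1, "C")},
    )
    assert site == "acceptor_3ss" and impact == pytest.approx(0.0)


def test_window_rejects_wrong_dinucleotide():
    with pytest.raises(ValueError, match="consensus"):
        SpliceWindow("donor_5ss", "AAAAAA", (3, 4))
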