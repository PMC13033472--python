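"""Trio- and fragment-based phasing against independent oracles."""
import itertools

import numpy as np
import pytest

from cishap import phasing as ph
from cishap.cohort_model import AlleleCall, ProbandRecord


def _trio(pa, pb, fa, fb, ma, mb):
    mk = lambda d: {"a": ph.SiteGenotype("a", d[0]), "b": ph.SiteGenotype("b", d[1])}
    return ph.Trio(proband=mk((pa, pb)), father=mk((fa, fb)), mother=mk((ma, mb)))


def _oracle_trio(pa, pb, fa, fb, ma, mb):
    """Brute-force reference: enumerate each parent's phased diplotypes and
    the four transmission combinations; classify surviving configurations."""

    def diplotypes(da, db):
        out = []
        for h1a, h2a in itertools.product((0, 1), repeat=2):
            for h1b, h2b in itertools.product((0, 1), repeat=2):
                if h1a + h2a == da and h1b + h2b == db:
                    out.append(((h1a, h1b), (h2a, h2b)))
        return out

    cis_flags = []
    for fd in diplotypes(fa, fb):
        for md in diplotypes(ma, mb):
            for fh in fd:  # transmitted paternal haplotype
                for mh in md:  # transmitted maternal haplotype
                    if (fh[0] + mh[0], fh[1] + mh[1]) == (pa, pb):
                        cis_flags.append(fh == (1, 1) or mh == (1, 1))
    if not cis_flags:
        return "mendelian_error"
    if all(cis_flags):
        return "cis"
    if not any(cis_flags):
        return "trans"
    return "ambiguous"


def test_trio_phasing_matches_exhaustive_oracle():
    """All 3^6 = 729 dosage configurations agree with the brute-force
    transmission enumerator (skipping proband non-carrier configurations,
    which are a precondition violation)."""
    checked = 0
    for cfg in itertools.product(range(3), repeat=6):
        pa, pb, fa, fb, ma, mb = cfg
        if pa == 0 or pb == 0:
            with pytest.raises(ValueError):
                ph.phase_trio(_trio(*cfg), "a", "b")
            continue
        call = ph.phase_trio(_trio(*cfg), "a", "b")
        assert call.relation == _oracle_trio(*cfg), cfg
        checked += 1
    assert checked == 4 * 81  # proband dosages {1,2}^2 x parental 3^4


def test_trio_phase_is_symmetric():
    for cfg in itertools.product((1, 2), (1, 2), range(3), range(3), range(3), range(3)):
        pa, pb, fa, fb, ma, mb = cfg
        ab = ph.phase_trio(_trio(pa, pb, fa, fb, ma, mb), "a", "b")
        ba = ph.phase_trio(_trio(pa, pb, fa, fb, ma, mb), "b", "a")
        assert ab.relation == ba.relation and ab.pair == ba.pair


def test_trio_examples():
    """Informative het-by-each-parent trio is trans with known origins;
    homozygosity at one site forces cis regardless of parents."""
    call = ph.phase_trio(_trio(1, 1, 1, 0, 0, 1), "a", "b")
    assert call.relation == "trans"
    assert call.origin == {"a": "paternal", "b": "maternal"}
    for fa, fb, ma, mb in itertools.product(range(3), repeat=4):
        c = ph.phase_trio(_trio(2, 1, fa, fb, ma, mb), "a", "b")
        assert c.relation in ("cis", "mendelian_error")


def test_trio_de_novo_is_mendelian_error():
    assert ph.phase_trio(_trio(1, 1, 0, 0, 0, 0), "a", "b").relation == "mendelian_error"


def test_trio_missing_parents_degrade_to_ambiguous():
    mk = lambda d, miss=(): {
        s: ph.SiteGenotype(s, d[i], missing=s in miss) for i, s in enumerate("ab")
    }
    t = ph.Trio(proband=mk((1, 1)), father=mk((0, 0), miss="ab"), mother=mk((0, 0), miss="ab"))
    assert ph.phase_trio(t, "a", "b").relation == "ambiguous"
    t2 = ph.Trio(proband=mk((2, 1)), father=mk((0, 0), miss="ab"), mother=mk((0, 0), miss="ab"))
    assert ph.phase_trio(t2, "a", "b").relation == "cis"


def test_trio_never_contradicts_planted_truth():
    """On trios generated from known parental haplotypes without error,
    the call never contradicts the truth (ambiguous is allowed)."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        fh = rng.integers(0, 2, size=(2, 2))  # father's two haplotypes x 2 sites
        mh = rng.integers(0, 2, size=(2, 2))
        ft, mt = fh[rng.integers(2)], mh[rng.integers(2)]
        pa, pb = ft[0] + mt[0], ft[1] + mt[1]
        if pa == 0 or pb == 0:
            continue
        truth = "cis" if (tuple(ft) == (1, 1) or tuple(mt) == (1, 1)) else "trans"
        call = ph.phase_trio(
            _trio(pa, pb, *(fh[0] + fh[1]), *(mh[0] + mh[1])), "a", "b"
        )
        assert call.relation in (truth, "ambiguous")


# ---------------------------------------------------------------- fragments

def _frag(i, oa, ob):
    return ph.Fragment(f"f{i}", {"a": oa, "b": ob})


def test_fragment_phasing_clear_cis_and_no_coverage():
    frags = [_frag(i, "alt", "alt") for i in range(5)]
    call = ph.phase_fragments(frags, "a", "b")
    assert call.relation == "cis" and call.support == 5
    empty = ph.phase_fragments([ph.Fragment("x", {"a": "alt"})], "a", "b")
    assert empty.relation == "ambiguous" and empty.support == 0


def test_fragment_phasing_trans_and_conflict_tolerance():
    frags = [_frag(i, "alt", "ref") for i in range(10)] + \
            [_frag(100 + i, "ref", "alt") for i in range(10)]
    assert ph.phase_fragments(frags, "a", "b").relation == "trans"
    # 50% conflicting observations cannot resolve
    mixed = [_frag(i, "alt", "alt") for i in range(5)] + \
            [_frag(50 + i, "alt", "ref") for i in range(5)]
    assert ph.phase_fragments(mixed, "a", "b").relation == "ambiguous"


def test_fragment_phasing_recovers_planted_cis_under_error():
    """Planted cis pair, 30x co-coverage, 2% per-observation error:
    recovered as cis in >= 99% of 200 seeded replicates."""
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        frags = []
        for i in range(30):
            chrom_alt = rng.random() < 0.5  # alt haplotype or ref haplotype
            obs = {}
            for s in ("a", "b"):
                allele = "alt" if chrom_alt else "ref"
                if rng.random() < 0.02:
                    allele = "ref" if allele == "alt" else "alt"
                obs[s] = allele
            frags.append(ph.Fragment(f"f{i}", obs))
        if ph.phase_fragments(frags, "a", "b").relation == "cis":
            hits += 1
    assert hits >= 198


# ---------------------------------------------------------------- combining

def _record():
    return ProbandRecord("P", "F", AlleleCall(("a",)), AlleleCall(("b",)))


def test_resolve_proband_evidence_combination():
    """Truth table: concordant resolved calls keep the relation; a single
    resolved source dominates ambiguity; discordant resolved calls raise a
    conflict flag."""
    trio_cis = _trio(1, 1, 2, 2, 0, 0)  # father hom at both -> cis forced
    frags_cis = [_frag(i, "alt", "alt") for i in range(5)]
    frags_trans = [_frag(i, "alt", "ref") for i in range(5)] + \
                  [_frag(9 + i, "ref", "alt") for i in range(5)]

    both = ph.resolve_proband(_record(), trio_cis, frags_cis)[("a", "b")]
    assert both.relation == "cis" and not both.conflict

    frag_only = ph.resolve_proband(_record(), None, frags_cis)[("a", "b")]
    assert frag_only.relation == "cis"

    disagree = ph.resolve_proband(_record(), trio_cis, frags_trans)[("a", "b")]
    assert disagree.relation == "mendelian_error" and disagree.conflict


def test_resolve_proband_genotype_only_homozygote_forces_cis():
    rec = ProbandRecord("P", "F", AlleleCall(("a", "b")), AlleleCall(("a",)))
    calls = ph.resolve_proband(rec)
    assert calls[("a", "b")].relation == "cis"
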