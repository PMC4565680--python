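"""Codon counting vs exhaustive enumeration oracles, JC correction,
identity policies, Z-test behaviour, and the selection summary."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from te_evoscan.evometrics import (
    IdenticalSequencesError,
    SaturationError,
    codon_pair_differences,
    distance_matrix,
    drop_identical_duplicates,
    identity_range,
    jc_correct,
    ng_pairwise,
    ng_site_counts,
    pairwise_identity,
    summarize_selection,
    z_test_neutrality,
)
from te_evoscan.records import CodonAlignment

# --- independent oracle (biopython translation, explicit enumeration) -------

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
NT = "ACGT"


def aa(codon):
    return str(Seq(codon).translate())


def oracle_site_counts(codon):
    """Equal-weight synonymous-site fraction by enumerating all 9 neighbors."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for alt in NT:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOPS:
                continue
            tot += 1
            if aa(mut) == aa(codon):
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def oracle_pair_differences(c1, c2):
    """Average syn/nonsyn steps over minimal pathways avoiding stops."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
            if aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((sd, nd, blocked))
    ok = [r for r in results if not r[2]] or results
    return (
        sum(r[0] for r in ok) / len(ok),
        sum(r[1] for r in ok) / len(ok),
    )


ALL_CODONS = ["".join(c) for c in itertools.product(NT, repeat=3) if "".join(c) not in STOPS]


# --- identity and JC --------------------------------------------------------


def test_identity_basic_and_policies():
    assert pairwise_identity("ACGT", "ACGT") == 1.0
    assert pairwise_identity("ACGT", "ACGA") == 0.75
    assert pairwise_identity("AC-T", "ACGT", "pairwise_deletion") == 1.0
    assert pairwise_identity("AC-T", "ACGT", "complete") == 0.75


def test_identity_no_comparable_columns_errors():
    with pytest.raises(ValueError, match="comparable"):
        pairwise_identity("--", "AA")


def test_jc_closed_form_values():
    assert jc_correct(0.0) == 0.0
    assert jc_correct(0.1) == pytest.approx(0.10732, abs=1e-5)
    with pytest.raises(SaturationError):
        jc_correct(0.75)


@given(st.floats(min_value=1e-6, max_value=0.74))
def test_jc_expands_distances_and_monotone(p):
    d = jc_correct(p)
    assert d >= p
    assert jc_correct(p * 0.5) <= d


# --- site counts vs oracle --------------------------------------------------


@pytest.mark.parametrize("codon,expected_s", [("TTT", 1 / 3), ("CTT", 1.0), ("ATG", 0.0)])
def test_site_counts_known_codons(codon, expected_s):
    s, n = ng_site_counts(codon)
    assert s == pytest.approx(expected_s)
    assert s + n == pytest.approx(3.0)


def test_site_counts_match_oracle_for_all_codons():
    for codon in ALL_CODONS:
        s, n = ng_site_counts(codon)
        so, no = oracle_site_counts(codon)
        assert s == pytest.approx(so), codon
        assert n == pytest.approx(no), codon


def test_site_counts_reject_ambiguous_codon():
    with pytest.raises(ValueError):
        ng_site_counts("A-G")
    with pytest.raises(ValueError):
        ng_site_counts("ANG")


# --- pairwise counting vs oracle -------------------------------------------


def test_pair_differences_match_oracle_all_pairs():
    """Every sense-codon pair (<= 3 differing positions): equality with the
    exhaustive pathway oracle, plus Sd+Nd conservation."""
    for c1, c2 in itertools.combinations(ALL_CODONS, 2):
        sd, nd = codon_pair_differences(c1, c2)
        sdo, ndo = oracle_pair_differences(c1, c2)
        assert sd == pytest.approx(sdo), (c1, c2)
        assert nd == pytest.approx(ndo), (c1, c2)
        assert sd + nd == pytest.approx(sum(a != b for a, b in zip(c1, c2)))


def test_ng_pairwise_single_codon_example():
    r = ng_pairwise("TTT", "TTA")
    assert (r.S, r.N) == (pytest.approx(0.5), pytest.approx(2.5))
    assert (r.Sd, r.Nd) == (0.0, 1.0)
    assert r.pN == pytest.approx(0.4)
    assert r.omega is None  # dS = 0


def test_ng_pairwise_identical_signaled():
    r = ng_pairwise("TTTAAA", "TTTAAA")
    assert r.identical and r.omega is None and r.dS == r.dN == 0.0


def test_ng_pairwise_symmetric_and_conserves_differences():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = 5
        a = "".join(rng.choice(ALL_CODONS, size=n))
        b = "".join(rng.choice(ALL_CODONS, size=n))
        try:
            r1, r2 = ng_pairwise(a, b), ng_pairwise(b, a)
        except SaturationError:
            continue  # random unrelated codons can exceed the JC domain
        assert r1.Sd + r1.Nd == pytest.approx(r2.Sd + r2.Nd)
        assert r1.S == pytest.approx(r2.S)
        assert r1.dN == pytest.approx(r2.dN)
        observed = sum(
            x != y
            for ca, cb in zip(
                [a[i : i + 3] for i in range(0, len(a), 3)],
                [b[i : i + 3] for i in range(0, len(b), 3)],
            )
            if ca not in STOPS and cb not in STOPS
            for x, y in zip(ca, cb)
        )
        assert r1.Sd + r1.Nd == pytest.approx(observed)


def test_ng_pairwise_drops_gap_and_n_codons():
    r = ng_pairwise("TTT" + "A-A" + "GGG", "TTA" + "AAA" + "GNG")
    assert r.n_codons == 1  # only the first codon is comparable


def test_adding_synonymous_difference_does_not_decrease_ds():
    base_a, base_b = "TTTGGG" * 10, "TTTGGG" * 10
    r0 = ng_pairwise(base_a, base_b)
    # introduce one synonymous change (GGG -> GGA)
    b1 = base_b[:5] + "A" + base_b[6:]
    r1 = ng_pairwise(base_a, b1)
    assert r1.dS >= r0.dS


# --- Z-test -----------------------------------------------------------------


def test_z_test_identical_pair_raises():
    with pytest.raises(IdenticalSequencesError):
        z_test_neutrality("TTTAAA", "TTTAAA")


def test_z_test_deterministic_given_seed():
    from te_evoscan.simulate import simulate_codon_pair

    a, b = simulate_codon_pair(60, divergence=0.3, omega=0.2, seed=5)
    t1 = z_test_neutrality(a, b, seed=42, n_bootstrap=200)
    t2 = z_test_neutrality(a, b, seed=42, n_bootstrap=200)
    assert t1.statistic == t2.statistic and t1.p_value == t2.p_value


def test_z_test_detects_strong_purifying_selection():
    """omega = 0.1 over 120 codons: the purifying tail should reject in the
    majority of replicates."""
    from te_evoscan.simulate import simulate_codon_pair

    rejections = 0
    n = 30
    for i in range(n):
        a, b = simulate_codon_pair(120, divergence=0.4, omega=0.1, seed=1000 + i)
        t = z_test_neutrality(a, b, seed=i, n_bootstrap=300, alternative="purifying")
        rejections += t.p_value < 0.05
    assert rejections > n / 2


def test_z_test_low_power_flag():
    t = z_test_neutrality("TTTAAAGGGCCCAAATTT", "TTAAAAGGACCCAAATTT", n_bootstrap=200)
    assert t.low_power  # fewer than 10 comparable codons


# --- selection summary ------------------------------------------------------


def test_drop_identical_duplicates_keeps_first():
    aln = CodonAlignment([("a", "TTTAAA"), ("b", "TTTAAA"), ("c", "TTAAAA")])
    out, removed = drop_identical_duplicates(aln)
    assert out.ids == ["a", "c"]
    assert removed == [("a", "b")]


def test_summary_two_sequences_one_row():
    aln = CodonAlignment([("a", "TTTGGGAAACCC"), ("b", "TTAGGGAAACCC")])
    table, summary = summarize_selection(aln, n_bootstrap=100)
    assert len(table) == 1
    assert summary["n_pairs"] == 1


def test_summary_all_identical_errors():
    aln = CodonAlignment([("a", "TTTAAA"), ("b", "TTTAAA")])
    with pytest.raises(ValueError, match="identical"):
        summarize_selection(aln)


# --- distance matrix --------------------------------------------------------


def test_distance_matrix_symmetric_zero_diagonal():
    aln = CodonAlignment(
        [("a", "TTTGGGAAA"), ("b", "TTAGGGAAA"), ("c", "TTAGGGATA")]
    )
    D = distance_matrix(aln, model="p")
    assert np.allclose(D.values, D.values.T)
    assert np.allclose(np.diag(D.values), 0)
    assert D.get("a", "b") == pytest.approx(1 / 9)


def test_identity_range_reports_most_divergent_pair():
    aln = CodonAlignment(
        [("a", "TTTGGGAAA"), ("b", "TTTGGGAAT"), ("c", "CCCGGGTTT")]
    )
    lo, hi, pair = identity_range(aln)
    assert pair == ("a", "c") or pair == ("b", "c")
    assert lo < hi <= 1.0
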