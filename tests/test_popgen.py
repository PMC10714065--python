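"""Diversity/neutrality/differentiation statistics against independent oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from mtcohort.alignment import pairwise_differences
from mtcohort.popgen import (
    AlignmentError,
    achaz_y,
    achaz_constants,
    differentiation,
    diversity_stats,
    fu_sigma_matrix,
    haplotype_diversity,
    harmonic,
    harmonic2,
    hudson_fst,
    hudson_fst_from_dist,
    nucleotide_diversity,
    permutation_test,
    phi_st,
    phi_st_from_dist,
    tajimas_d,
    watterson_theta,
)

from conftest import make_alignment


# ---------------------------------------------------------------------------
# independent oracles (deliberately written as plain loops over pairs/sites)


def oracle_pi_per_site(seqs):
    """Mean pairwise differences per usable site by explicit double loop."""
    usable = [j for j in range(len(seqs[0])) if all(s[j] in "ACGT" for s in seqs)]
    n = len(seqs)
    total = 0
    for a, b in itertools.combinations(range(n), 2):
        total += sum(seqs[a][j] != seqs[b][j] for j in usable)
    return total / (n * (n - 1) / 2) / len(usable)


def oracle_tajimas_d(seqs):
    """Textbook Tajima (1989) D from S and mean pairwise differences."""
    usable = [j for j in range(len(seqs[0])) if all(s[j] in "ACGT" for s in seqs)]
    n = len(seqs)
    S = sum(1 for j in usable if len({s[j] for s in seqs}) > 1)
    if S == 0:
        return np.nan
    k = 0.0
    for a, b in itertools.combinations(range(n), 2):
        k += sum(seqs[a][j] != seqs[b][j] for j in usable)
    k /= n * (n - 1) / 2
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_achaz_y(seqs):
    """Folded Achaz Y from the minor-allele spectrum, written longhand.

    Builds the folded spectrum, removes the singleton class, forms the two
    theta estimators and the exact variance from the Fu (1995) covariances,
    evaluated with explicit python sums (no shared code path with the
    implementation beyond the published sigma coefficients).
    """
    usable = [j for j in range(len(seqs[0])) if all(s[j] in "ACGT" for s in seqs)]
    n = len(seqs)
    kept_cols = []
    for j in usable:
        counts = {}
        for s in seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        if len(counts) < 2:
            continue
        n_ge2 = sum(1 for c in counts.values() if c >= 2)
        if n_ge2 >= 2:  # parsimony-informative = non-singleton
            kept_cols.append(counts)
    S_ns = len(kept_cols)
    if S_ns == 0:
        return np.nan
    pair_ns = sum((n * n - sum(c * c for c in col.values())) / 2 for col in kept_cols)

    K = list(range(2, n - 1))  # frequency classes 2..n-2
    pi_den = sum(n - i for i in K)
    w_den = sum(1.0 / i for i in K)
    theta_pi = pair_ns / pi_den
    theta_w = S_ns / w_den

    sigma = fu_sigma_matrix(n)
    omega = {i: (n - i) / pi_den - (1.0 / i) / w_den for i in K}
    alpha = sum(i * omega[i] ** 2 for i in K)
    beta = sum(i * omega[i] * j * omega[j] * sigma[i - 1, j - 1] for i in K for j in K)
    c2 = sum(sigma[i - 1, j - 1] for i in K for j in K)
    theta_hat = S_ns / w_den
    theta_sq = S_ns * (S_ns - 1) / (w_den**2 + c2)
    return (theta_pi - theta_w) / np.sqrt(alpha * theta_hat + beta * theta_sq)


def oracle_hudson_fst(seqs, labels):
    usable = [j for j in range(len(seqs[0])) if all(s[j] in "ACGT" for s in seqs)]

    def d(a, b):
        return sum(seqs[a][j] != seqs[b][j] for j in usable)

    groups = sorted(set(labels))
    within = []
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        within.append(np.mean([d(a, b) for a, b in itertools.combinations(idx, 2)]))
    i1 = [i for i, l in enumerate(labels) if l == groups[0]]
    i2 = [i for i, l in enumerate(labels) if l == groups[1]]
    hb = np.mean([d(a, b) for a in i1 for b in i2])
    return 1 - np.mean(within) / hb


def oracle_phi_st(seqs, labels):
    """AMOVA phi_ST via explicit sums of squared deviations."""
    usable = [j for j in range(len(seqs[0])) if all(s[j] in "ACGT" for s in seqs)]

    def d(a, b):
        return sum(seqs[a][j] != seqs[b][j] for j in usable)

    n = len(seqs)
    groups = sorted(set(labels))
    sizes = {g: sum(1 for l in labels if l == g) for g in groups}
    ss_total = sum(d(a, b) for a, b in itertools.combinations(range(n), 2)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d(a, b) for a, b in itertools.combinations(idx, 2)) / len(idx)
    ss_among = ss_total - ss_within
    ms_among = ss_among / (len(groups) - 1)
    ms_within = ss_within / (n - len(groups))
    n0 = (n - sum(s**2 for s in sizes.values()) / n) / (len(groups) - 1)
    var_a = (ms_among - ms_within) / n0
    return var_a / (var_a + ms_within)


def random_alignment(rng, n, L, alphabet="ACGT"):
    # skewed base draws so sites carry singletons, shared variants and gaps
    letters = list(alphabet)
    probs = np.full(len(letters), 0.3 / (len(letters) - 1))
    probs[0] = 0.7
    rows = ["".join(rng.choice(letters, p=probs) for _ in range(L)) for _ in range(n)]
    return rows


# ---------------------------------------------------------------------------
# simple estimators


def test_haplotype_diversity_examples():
    assert haplotype_diversity([4]) == 0.0
    assert haplotype_diversity([1, 1]) == pytest.approx(1.0)
    # n=4 two haplotypes 2+2: (4/3)(1-0.5)=2/3
    assert haplotype_diversity([2, 2]) == pytest.approx(2.0 / 3.0)
    with pytest.raises(AlignmentError):
        haplotype_diversity([1])


def test_watterson_theta_examples():
    assert watterson_theta(0, 5, 100) == 0.0
    assert watterson_theta(3, 4, 100) == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 100))


def test_nucleotide_diversity_two_sequences():
    aln = make_alignment(["ACGTACGTAC", "ACGTACGTAT"])
    assert nucleotide_diversity(aln) == pytest.approx(0.1)


def test_nucleotide_diversity_errors():
    with pytest.raises(AlignmentError):
        nucleotide_diversity(make_alignment(["ACGT"]))
    with pytest.raises(AlignmentError):
        nucleotide_diversity(make_alignment(["----", "ACGT"]))


@pytest.mark.parametrize("seed", range(6))
def test_pi_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    seqs = random_alignment(rng, n=rng.integers(4, 9), L=30, alphabet="ACGT-")
    aln = make_alignment(seqs)
    assert nucleotide_diversity(aln) == pytest.approx(oracle_pi_per_site(seqs), abs=1e-12)


# ---------------------------------------------------------------------------
# neutrality tests


def test_tajimas_d_undefined_without_segregation(monomorphic4):
    with pytest.warns(UserWarning):
        assert np.isnan(tajimas_d(monomorphic4))


@pytest.mark.parametrize("seed", range(8))
def test_tajimas_d_matches_textbook_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    seqs = random_alignment(rng, n=int(rng.integers(4, 10)), L=40)
    aln = make_alignment(seqs)
    expected = oracle_tajimas_d(seqs)
    if np.isnan(expected):
        pytest.skip("monomorphic draw")
    assert tajimas_d(aln) == pytest.approx(expected, abs=1e-12)


def test_achaz_y_undefined_when_only_singletons():
    aln = make_alignment(["AAAA", "AAAT", "AACA", "ATAA", "AAAA"])
    with pytest.warns(UserWarning):
        assert np.isnan(achaz_y(aln))


@pytest.mark.parametrize("seed", range(8))
def test_achaz_y_matches_sfs_oracle(seed):
    rng = np.random.default_rng(200 + seed)
    seqs = random_alignment(rng, n=int(rng.integers(5, 12)), L=60)
    aln = make_alignment(seqs)
    expected = oracle_achaz_y(seqs)
    if np.isnan(expected):
        pytest.skip("no non-singleton site in draw")
    assert achaz_y(aln) == pytest.approx(expected, abs=1e-12)


def test_sigma_matrix_reproduces_tajima_variances():
    """Fu's covariance coefficients must reproduce Tajima's closed forms:
    sum sigma_ij = b_n (variance of S) and the pi-weighted quadratic form
    equals Tajima's b2 constant."""
    for n in (4, 7, 12, 19, 52):
        sigma = fu_sigma_matrix(n)
        assert sigma.sum() == pytest.approx(harmonic2(n), rel=1e-9)
        i = np.arange(1, n, dtype=float)
        w = i * (n - i) / (n * (n - 1) / 2.0)
        assert np.sum(w**2 / i) == pytest.approx((n + 1) / (3.0 * (n - 1)), rel=1e-12)
        assert w @ sigma @ w == pytest.approx(
            2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0)), rel=1e-9
        )


def test_theta_estimators_coincide_on_neutral_sfs():
    """pi- and S-based theta agree when the SFS is proportional to 1/i.

    Built directly from column allele counts: for n=6, place round(C/i)
    columns at each derived count i with C large; then pi_locus ~ theta*a_n
    structure makes D's numerator ~ 0."""
    n = 6
    cols = []
    C = 60
    for i in range(1, n):
        cols += [i] * (C // i)
    seqs = []
    for row in range(n):
        seqs.append("".join("T" if row < c else "A" for c in cols))
    aln = make_alignment(seqs)
    # expected: pi_per_locus == S/a1 exactly for this constructed spectrum
    S = len(cols)
    pairs = n * (n - 1) / 2
    pi_locus = sum(c * (n - c) for c in cols) / pairs
    assert pi_locus == pytest.approx(S / harmonic(n), rel=0.02)
    assert abs(tajimas_d(aln)) < 0.1


# ---------------------------------------------------------------------------
# differentiation


def test_fst_phist_identical_groups_near_zero():
    # both groups hold the same haplotype multiset (10 + 10 of two types);
    # the residual is the O(1/n) within-group sampling bias of Hudson's Hw
    seqs = (["AAAA"] * 10 + ["AATT"] * 10) * 2
    aln = make_alignment(seqs)
    groups = pd.Series(["x"] * 20 + ["y"] * 20, index=aln.ids)
    assert abs(hudson_fst(aln, groups, ("x", "y"))) < 0.06
    assert abs(phi_st(aln, groups, ("x", "y"))) < 0.06


def test_fst_phist_fixed_difference_is_one():
    seqs = ["AAAA", "AAAA", "TTTT", "TTTT"]
    aln = make_alignment(seqs)
    groups = pd.Series(["x", "x", "y", "y"], index=aln.ids)
    assert hudson_fst(aln, groups, ("x", "y")) == pytest.approx(1.0)
    assert phi_st(aln, groups, ("x", "y")) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(6))
def test_fst_phist_match_bruteforce_oracles(seed):
    rng = np.random.default_rng(300 + seed)
    n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
    seqs = random_alignment(rng, n=n1 + n2, L=25)
    labels = ["g1"] * n1 + ["g2"] * n2
    aln = make_alignment(seqs)
    groups = pd.Series(labels, index=aln.ids)
    assert hudson_fst(aln, groups, ("g1", "g2")) == pytest.approx(
        oracle_hudson_fst(seqs, labels), abs=1e-12
    )
    assert phi_st(aln, groups, ("g1", "g2")) == pytest.approx(
        oracle_phi_st(seqs, labels), abs=1e-12
    )


def test_statistics_invariant_to_sequence_order():
    rng = np.random.default_rng(17)
    seqs = random_alignment(rng, 8, 30)
    aln = make_alignment(seqs)
    perm = rng.permutation(8)
    aln_p = aln.take(perm)
    assert nucleotide_diversity(aln) == pytest.approx(nucleotide_diversity(aln_p), abs=1e-15)
    assert tajimas_d(aln) == pytest.approx(tajimas_d(aln_p), abs=1e-15, nan_ok=True)
    assert achaz_y(aln) == pytest.approx(achaz_y(aln_p), abs=1e-15, nan_ok=True)


# ---------------------------------------------------------------------------
# permutation tests


def test_permutation_p_is_one_when_statistic_constant():
    # distance matrix all equal -> every permutation ties the observed value
    dist = np.ones((6, 6)) - np.eye(6)
    mask = np.array([True] * 3 + [False] * 3)
    p = permutation_test(hudson_fst_from_dist, dist, mask, n_perm=99, seed=0)
    assert p == pytest.approx(1.0)


def test_permutation_reproducible_and_in_range():
    rng = np.random.default_rng(4)
    seqs = random_alignment(rng, 10, 40)
    aln = make_alignment(seqs)
    groups = pd.Series(["a"] * 5 + ["b"] * 5, index=aln.ids)
    r1 = differentiation(aln, groups, ("a", "b"), n_perm=199, seed=11)
    r2 = differentiation(aln, groups, ("a", "b"), n_perm=199, seed=11)
    assert r1.p_fst == r2.p_fst and r1.p_phist == r2.p_phist
    assert 1 / 200 <= r1.p_fst <= 1.0


def test_degenerate_labels_rejected():
    dist = np.zeros((4, 4))
    with pytest.raises(AlignmentError):
        permutation_test(hudson_fst_from_dist, dist, np.zeros(4, bool), n_perm=10)


# ---------------------------------------------------------------------------
# aggregate report


def test_diversity_stats_report(iberia_fixture):
    aln, meta, _ = iberia_fixture
    stats = diversity_stats(aln)
    assert stats.n == 71
    assert 0 <= stats.Hd <= 1
    assert stats.pi_pct >= 0 and stats.thetaW_pct >= 0
    assert stats.H <= stats.n
    assert stats.S == stats.singletons + stats.parsimony_informative
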