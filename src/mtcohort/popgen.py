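"""Diversity, neutrality and differentiation statistics for haploid alignments.

Implements the statistics used to contrast temporal cohorts of a single
mtDNA population:

* haplotype count ``H`` and Nei's bias-corrected haplotype diversity ``Hd``;
* nucleotide diversity ``pi`` and Watterson's ``theta_W`` (per usable site);
* Tajima's ``D`` (1989 normalisation);
* Achaz's ``Y`` — a Tajima-like test that discards singleton site classes and
  is therefore robust to sequencing errors.  The default variant works on the
  folded site-frequency spectrum (no outgroup needed): a "singleton" is any
  segregating column whose minor alleles are each carried by exactly one
  sequence.  Its variance uses the exact covariances of the site-frequency
  spectrum under the neutral coalescent (Fu 1995), assembled through a
  general weighted-estimator test framework;
* Hudson's ``F_ST`` and the AMOVA ``phi_ST`` between two groups, with
  label-permutation significance tests.

All statistics honour complete deletion: columns carrying a gap or ambiguity
in any analysed sequence are excluded.  Undefined values (e.g. ``D`` with no
segregating site) are returned as ``nan`` with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .alignment import Alignment, AlignmentError, classify_sites, collapse_haplotypes, pairwise_differences

__all__ = [
    "DiversityStats",
    "DifferentiationResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "achaz_y",
    "hudson_fst",
    "phi_st",
    "permutation_test",
    "diversity_stats",
    "diversity_table",
    "differentiation",
    "allele_count_matrix",
    "stats_from_counts",
    "tajima_constants",
    "achaz_constants",
    "fu_sigma_matrix",
]


# ---------------------------------------------------------------------------
# site-frequency-spectrum machinery


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


@lru_cache(maxsize=256)
def fu_sigma_matrix(n: int) -> np.ndarray:
    """Second-order coefficients of the neutral SFS covariances (Fu 1995).

    Returns the symmetric ``(n-1, n-1)`` matrix ``sigma`` such that for the
    unfolded spectrum counts ``xi_i`` (class ``i`` = derived-allele count,
    1-based stored at index ``i-1``)::

        Var(xi_i)      = theta / i + sigma_ii * theta**2
        Cov(xi_i,xi_j) = sigma_ij * theta**2        (i != j)

    Validated elsewhere against Tajima's closed-form variances of S and pi.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    # cumulative harmonic: a[k] = sum_{m=1}^{k-1} 1/m, defined for k >= 1
    a = np.zeros(n + 2)
    for k in range(2, n + 2):
        a[k] = a[k - 1] + 1.0 / (k - 1)

    def beta(i: int) -> float:
        # valid for 1 <= i <= n
        return (
            2.0 * n * (a[n + 1] - a[i]) / ((n - i + 1.0) * (n - i))
            - 2.0 / (n - i)
        )

    sigma = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        if 2 * i < n:
            s = beta(i + 1)
        elif 2 * i == n:
            s = 2.0 * (a[n] - a[i]) / (n - i) - 1.0 / i**2
        else:
            s = beta(i) - 1.0 / i**2
        sigma[i - 1, i - 1] = s
    for j in range(1, n):
        for i in range(j + 1, n):  # i > j
            if i + j < n:
                s = (beta(i + 1) - beta(i)) / 2.0
            elif i + j == n:
                s = (
                    (a[n] - a[i]) / (n - i)
                    + (a[n] - a[j]) / (n - j)
                    - (beta(i) + beta(j + 1)) / 2.0
                    - 1.0 / (i * j)
                )
            else:
                s = (beta(j) - beta(j + 1)) / 2.0 - 1.0 / (i * j)
            sigma[i - 1, j - 1] = sigma[j - 1, i - 1] = s
    sigma.setflags(write=False)
    return sigma


@lru_cache(maxsize=256)
def tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) of Tajima's D for sample size n."""
    if n < 3:
        raise ValueError("Tajima's D needs n >= 3")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


@lru_cache(maxsize=256)
def achaz_constants(n: int) -> tuple[float, float, float, float, float]:
    """Constants of the folded, singleton-free Tajima-like test (Achaz's Y).

    The two compared estimators of theta act on frequency classes
    ``K = {2, ..., n-2}`` (folded minor-allele classes >= 2):

    * pi-type:        weights ``w1_i = n - i`` on K
    * Watterson-type: weights ``w2_i = 1 / i`` on K

    Returns ``(pi_denom, w_denom, alpha, beta, c2)`` where ``pi_denom`` and
    ``w_denom`` normalise the two estimators, the test variance is
    ``alpha * theta + beta * theta**2``, and ``c2`` enters the unbiased
    ``theta**2`` estimator ``S'(S'-1) / (w_denom**2 + c2)`` built from the
    non-singleton segregating-site count ``S'``.
    """
    if n < 4:
        raise ValueError("Achaz's Y needs n >= 4")
    i = np.arange(1, n, dtype=float)  # classes 1..n-1
    keep = (i >= 2) & (i <= n - 2)
    w1 = np.where(keep, n - i, 0.0)
    w2 = np.where(keep, 1.0 / i, 0.0)
    pi_denom = w1.sum()
    w_denom = w2.sum()
    omega = w1 / pi_denom - w2 / w_denom
    sigma = fu_sigma_matrix(n)
    alpha = float(np.sum(i * omega**2))
    io = i * omega
    beta = float(io @ sigma @ io)
    kv = keep.astype(float)
    c2 = float(kv @ sigma @ kv)
    return float(pi_denom), float(w_denom), alpha, beta, c2


# ---------------------------------------------------------------------------
# per-column allele counts and count-based statistics


def allele_count_matrix(aln: Alignment, rows=None) -> tuple[np.ndarray, int]:
    """Return ``(counts, L_usable)`` under complete deletion over ``rows``.

    ``counts`` is ``(v, 4)`` for the segregating usable columns only; the
    monomorphic usable columns enter only through ``L_usable``.
    """
    matrix = aln.matrix if rows is None else aln.matrix[np.asarray(rows, dtype=int)]
    called = np.isin(matrix, np.frombuffer(b"ACGT", dtype=np.uint8))
    usable = called.all(axis=0)
    counts = np.stack(
        [(matrix[:, usable] == code).sum(axis=0) for code in np.frombuffer(b"ACGT", dtype=np.uint8)],
        axis=1,
    )
    seg = (counts > 0).sum(axis=1) >= 2
    return counts[seg], int(usable.sum())


def _pair_diffs_per_column(counts: np.ndarray, n: int) -> np.ndarray:
    """Number of mismatching pairs per column from allele counts."""
    return (n * n - (counts.astype(np.int64) ** 2).sum(axis=1)) / 2.0


def _singleton_mask(counts: np.ndarray) -> np.ndarray:
    """Columns whose minor alleles are all singletons (not parsimony-informative)."""
    return (counts >= 2).sum(axis=1) < 2


def haplotype_diversity(hap_counts) -> float:
    """Nei's bias-corrected haplotype diversity ``n/(n-1) * (1 - sum p_i^2)``."""
    c = np.asarray(hap_counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        raise AlignmentError("haplotype diversity needs n >= 2")
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's theta per site: ``S / (a_n * L)``."""
    if n < 2 or L < 1:
        raise AlignmentError("Watterson's theta needs n >= 2 and L >= 1")
    return S / (harmonic(n) * L)


def nucleotide_diversity(aln: Alignment, rows=None) -> float:
    """Mean pairwise differences per usable site over all C(n,2) pairs."""
    counts, L = allele_count_matrix(aln, rows)
    n = aln.n if rows is None else len(np.asarray(rows))
    if n < 2:
        raise AlignmentError("nucleotide diversity needs n >= 2")
    if L == 0:
        raise AlignmentError("no usable columns under complete deletion")
    total = _pair_diffs_per_column(counts, n).sum()
    return float(total / (n * (n - 1) / 2.0) / L)


def _tajima_from_summaries(S: float, pi_locus: float, n: int):
    if S < 1:
        return np.nan
    a1, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return np.nan
    return (pi_locus - S / a1) / np.sqrt(var)


def _achaz_from_counts(counts: np.ndarray, n: int):
    if n < 4:
        return np.nan
    pi_denom, w_denom, alpha, beta, c2 = achaz_constants(n)
    singleton = _singleton_mask(counts)
    S_ns = float((~singleton).sum())
    if S_ns < 1:
        return np.nan
    pair_ns = _pair_diffs_per_column(counts[~singleton], n).sum()
    theta_pi = pair_ns / pi_denom
    theta_w = S_ns / w_denom
    theta_hat = S_ns / w_denom
    theta_sq = S_ns * (S_ns - 1.0) / (w_denom**2 + c2)
    var = alpha * theta_hat + beta * theta_sq
    if var <= 0:
        return np.nan
    return (theta_pi - theta_w) / np.sqrt(var)


def tajimas_d(aln: Alignment, rows=None) -> float:
    """Tajima's D; ``nan`` (with a warning) when no site segregates."""
    counts, L = allele_count_matrix(aln, rows)
    n = aln.n if rows is None else len(np.asarray(rows))
    if n < 3:
        raise AlignmentError("Tajima's D needs n >= 3")
    S = counts.shape[0]
    if S == 0:
        warnings.warn("Tajima's D undefined: no segregating site", stacklevel=2)
        return np.nan
    pi_locus = _pair_diffs_per_column(counts, n).sum() / (n * (n - 1) / 2.0)
    return float(_tajima_from_summaries(S, pi_locus, n))


def achaz_y(aln: Alignment, rows=None) -> float:
    """Achaz's Y (folded variant): Tajima-like test ignoring singleton columns."""
    counts, L = allele_count_matrix(aln, rows)
    n = aln.n if rows is None else len(np.asarray(rows))
    if n < 4:
        raise AlignmentError("Achaz's Y needs n >= 4")
    y = _achaz_from_counts(counts, n)
    if np.isnan(y) and counts.shape[0] > 0:
        warnings.warn(
            "Achaz's Y undefined: every segregating site is a singleton", stacklevel=2
        )
    elif counts.shape[0] == 0:
        warnings.warn("Achaz's Y undefined: no segregating site", stacklevel=2)
    return float(y) if not np.isnan(y) else np.nan


# ---------------------------------------------------------------------------
# whole-sample summaries


@dataclass
class DiversityStats:
    """Per-group diversity summary mirroring a standard mtDNA report row."""

    n: int
    S: int
    singletons: int
    parsimony_informative: int
    H: int
    Hd: float
    pi_pct: float
    thetaW_pct: float
    D: float
    Y: float
    L_usable: int


def diversity_stats(aln: Alignment) -> DiversityStats:
    """All Table-style statistics for one group (complete deletion)."""
    sites = classify_sites(aln)
    haps = collapse_haplotypes(aln)
    counts, L = allele_count_matrix(aln)
    n = aln.n
    if L == 0:
        raise AlignmentError("no usable columns under complete deletion")
    pair_total = _pair_diffs_per_column(counts, n).sum()
    pi_locus = pair_total / (n * (n - 1) / 2.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = _tajima_from_summaries(sites.S, pi_locus, n) if n >= 3 else np.nan
        Y = _achaz_from_counts(counts, n) if n >= 4 else np.nan
    return DiversityStats(
        n=n,
        S=sites.S,
        singletons=sites.singletons,
        parsimony_informative=sites.parsimony_informative,
        H=haps.n_haplotypes,
        Hd=haplotype_diversity(haps.counts.values),
        pi_pct=100.0 * pi_locus / L,
        thetaW_pct=100.0 * watterson_theta(sites.S, n, L),
        D=float(D),
        Y=float(Y),
        L_usable=L,
    )


def diversity_table(aln: Alignment, groups: pd.Series, order=None) -> pd.DataFrame:
    """Per-group + pooled diversity report (one row per group label).

    ``groups`` is a per-sequence-id Series of group labels; statistics for
    each group use complete deletion within that group only.
    """
    order = list(order) if order is not None else sorted(groups.unique())
    rows = {}
    for g in order:
        ids = groups.index[groups == g]
        rows[g] = diversity_stats(aln.subset(ids)).__dict__
    rows["all"] = diversity_stats(aln.subset(groups.index)).__dict__
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    return df


# ---------------------------------------------------------------------------
# differentiation between two groups


def _group_indices(aln: Alignment, groups: pd.Series, pair):
    g1, g2 = pair
    idx1 = aln.index_of(groups.index[groups == g1])
    idx2 = aln.index_of(groups.index[groups == g2])
    if len(idx1) < 2 or len(idx2) < 2:
        raise AlignmentError("both groups need n >= 2 for differentiation statistics")
    return idx1, idx2


def hudson_fst_from_dist(dist: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> float:
    """Hudson's F_ST = 1 - Hw/Hb from a pairwise-difference matrix."""

    def mean_within(m):
        idx = np.flatnonzero(m)
        sub = dist[np.ix_(idx, idx)]
        k = len(idx)
        return sub[np.triu_indices(k, 1)].mean()

    hw = 0.5 * (mean_within(mask1) + mean_within(mask2))
    hb = dist[np.ix_(np.flatnonzero(mask1), np.flatnonzero(mask2))].mean()
    if hb == 0:
        warnings.warn("Hudson F_ST undefined: no between-group differences", stacklevel=2)
        return np.nan
    return float(1.0 - hw / hb)


def phi_st_from_dist(dist: np.ndarray, mask1: np.ndarray, mask2: np.ndarray) -> float:
    """AMOVA phi_ST from a pairwise-difference matrix (two groups).

    Treats the nucleotide difference count as the squared inter-individual
    distance and partitions molecular variance among vs. within groups.
    """
    masks = [np.flatnonzero(mask1), np.flatnonzero(mask2)]
    n_tot = sum(len(m) for m in masks)
    order = np.concatenate(masks)
    sub = dist[np.ix_(order, order)]
    ss_total = sub[np.triu_indices(n_tot, 1)].sum() / n_tot
    ss_within = 0.0
    for m in masks:
        d = dist[np.ix_(m, m)]
        ss_within += d[np.triu_indices(len(m), 1)].sum() / len(m)
    ss_among = ss_total - ss_within
    df_among = 1
    df_within = n_tot - 2
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    n0 = (n_tot - sum(len(m) ** 2 for m in masks) / n_tot) / df_among
    var_a = (ms_among - ms_within) / n0
    total = var_a + ms_within
    if total == 0:
        warnings.warn("phi_ST undefined: total molecular variance is zero", stacklevel=2)
        return np.nan
    return float(var_a / total)


def hudson_fst(aln: Alignment, groups: pd.Series, pair) -> float:
    idx1, idx2 = _group_indices(aln, groups, pair)
    rows = np.concatenate([idx1, idx2])
    sub = aln.take(rows)
    dist = pairwise_differences(sub.matrix, sub.usable_columns())
    m1 = np.zeros(len(rows), bool)
    m1[: len(idx1)] = True
    return hudson_fst_from_dist(dist, m1, ~m1)


def phi_st(aln: Alignment, groups: pd.Series, pair) -> float:
    idx1, idx2 = _group_indices(aln, groups, pair)
    rows = np.concatenate([idx1, idx2])
    sub = aln.take(rows)
    dist = pairwise_differences(sub.matrix, sub.usable_columns())
    m1 = np.zeros(len(rows), bool)
    m1[: len(idx1)] = True
    return phi_st_from_dist(dist, m1, ~m1)


def permutation_test(stat_fn, dist: np.ndarray, mask1: np.ndarray, n_perm: int = 1000, seed=None) -> float:
    """Randomisation p-value for a two-group statistic on a distance matrix.

    Labels are shuffled preserving group sizes; ties count as extreme and the
    add-one estimator keeps p in ``[1/(n_perm+1), 1]``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = dist.shape[0]
    n1 = int(mask1.sum())
    if n1 == 0 or n1 == n:
        raise AlignmentError("permutation test needs two non-empty groups")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        observed = stat_fn(dist, mask1, ~mask1)
        hits = 0
        for _ in range(n_perm):
            perm = np.zeros(n, bool)
            perm[rng.choice(n, size=n1, replace=False)] = True
            val = stat_fn(dist, perm, ~perm)
            if np.isnan(val) or val >= observed - 1e-12:
                hits += 1
    return (1.0 + hits) / (n_perm + 1.0)


@dataclass
class DifferentiationResult:
    fst_hudson: float
    phi_st: float
    p_fst: float
    p_phist: float
    n_permutations: int


def differentiation(aln: Alignment, groups: pd.Series, pair, n_perm: int = 1000, seed=None) -> DifferentiationResult:
    """Hudson's F_ST and phi_ST between two groups with permutation p-values."""
    idx1, idx2 = _group_indices(aln, groups, pair)
    rows = np.concatenate([idx1, idx2])
    sub = aln.take(rows)
    dist = pairwise_differences(sub.matrix, sub.usable_columns())
    m1 = np.zeros(len(rows), bool)
    m1[: len(idx1)] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fst = hudson_fst_from_dist(dist, m1, ~m1)
        phi = phi_st_from_dist(dist, m1, ~m1)
    rng = np.random.default_rng(seed)
    p_fst = permutation_test(hudson_fst_from_dist, dist, m1, n_perm, rng.integers(2**31))
    p_phi = permutation_test(phi_st_from_dist, dist, m1, n_perm, rng.integers(2**31))
    return DifferentiationResult(fst, phi, p_fst, p_phi, n_perm)


def stats_from_counts(counts: np.ndarray, n: int, L_usable: int) -> dict:
    """All count-derivable statistics for one sample (helper shared with
    the simulation summary layer)."""
    seg = counts.shape[0]
    singleton = _singleton_mask(counts) if seg else np.zeros(0, bool)
    pair_total = _pair_diffs_per_column(counts, n).sum() if seg else 0.0
    pairs = n * (n - 1) / 2.0
    pi_locus = pair_total / pairs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        D = _tajima_from_summaries(seg, pi_locus, n) if n >= 3 else np.nan
        Y = _achaz_from_counts(counts, n) if n >= 4 else np.nan
    return {
        "S": int(seg),
        "singletons": int(singleton.sum()),
        "pi_site": pi_locus / L_usable if L_usable else np.nan,
        "pi_locus": float(pi_locus),
        "thetaW_site": seg / (harmonic(n) * L_usable) if L_usable else np.nan,
        "D": float(D) if D == D else np.nan,
        "Y": float(Y) if Y == Y else np.nan,
    }
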