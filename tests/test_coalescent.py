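"""Serial-coalescent simulator: analytic moments, serial-sampling behaviour,
and statistical equivalence with an independent simulator (msprime)."""

import numpy as np
import pytest
from scipy import stats as sps

from mtcohort.alignment import classify_sites
from mtcohort.coalescent import (
    DemographicModel,
    MutationModel,
    SamplingScheme,
    drop_mutations,
    make_fixture,
    simulate_alignment,
    simulate_genealogy,
)
from mtcohort.popgen import allele_count_matrix, harmonic, stats_from_counts


def seeds(rng, n):
    return rng.integers(2**31, size=n)


def test_model_validation():
    with pytest.raises(ValueError):
        DemographicModel(((1.0, 100.0),))  # must start at 0
    with pytest.raises(ValueError):
        DemographicModel(((0.0, 100.0), (0.0, 50.0)))
    with pytest.raises(ValueError):
        DemographicModel(((0.0, -5.0),))
    m = DemographicModel(((0.0, 10.0), (5.0, 100.0)))
    assert m.size_at(0) == 10 and m.size_at(4.9) == 10 and m.size_at(5.0) == 100
    assert m.next_boundary(0) == 5.0 and np.isinf(m.next_boundary(5.0))


def test_pairwise_tmrca_matches_ne():
    """E[T2] = Ne for a haploid pair under constant size."""
    rng = np.random.default_rng(0)
    model = DemographicModel.constant(500.0)
    scheme = SamplingScheme((("A", 2, 0.0),), L=10)
    t = np.array([simulate_genealogy(model, scheme, int(s)).tmrca for s in seeds(rng, 10_000)])
    se = t.std(ddof=1) / np.sqrt(len(t))
    assert abs(t.mean() - 500.0) <= 3 * se


def test_serial_samples_cannot_coalesce_before_both_exist():
    model = DemographicModel.constant(50.0)
    scheme = SamplingScheme((("A", 1, 0.0), ("B", 1, 40.0)), L=10)
    rng = np.random.default_rng(1)
    tm = [simulate_genealogy(model, scheme, int(s)).tmrca for s in seeds(rng, 1000)]
    assert min(tm) >= 40.0


def test_total_branch_length_matches_harmonic_sum():
    """E[total length] = 2 Ne sum_{i=1}^{n-1} 1/i for isochronous samples."""
    rng = np.random.default_rng(2)
    model = DemographicModel.constant(300.0)
    scheme = SamplingScheme((("A", 10, 0.0),), L=10)
    tl = np.array([simulate_genealogy(model, scheme, int(s)).total_branch_length
                   for s in seeds(rng, 4000)])
    expected = 2 * 300.0 * harmonic(10)
    se = tl.std(ddof=1) / np.sqrt(len(tl))
    assert abs(tl.mean() - expected) <= 3 * se


def test_tree_structure_is_valid():
    model = DemographicModel(((0.0, 100.0), (30.0, 10.0)))
    scheme = SamplingScheme((("A", 5, 0.0), ("B", 4, 10.0)), L=10)
    tree = simulate_genealogy(model, scheme, 7)
    assert tree.n_nodes == 2 * 9 - 1
    # parent strictly older than child
    for node, par in enumerate(tree.parent):
        if par >= 0:
            assert tree.time[par] > tree.time[node]
    # leaf times honour the scheme
    assert np.allclose(np.sort(tree.time[:9]), np.sort(scheme.leaf_times()))


def test_zero_mutation_rate_gives_identical_sequences():
    model = DemographicModel.constant(100.0)
    scheme = SamplingScheme((("A", 6, 0.0),), L=50)
    aln = simulate_alignment(model, scheme, MutationModel(mu=0.0), seed=3)
    assert len(set(aln.sequences())) == 1


def test_watterson_and_pi_expectations():
    """E[S] = theta a_n and E[pi] = theta (per locus, theta = 2 Ne mu L)."""
    rng = np.random.default_rng(4)
    ne, mu, L, n = 800.0, 1e-6, 800, 8
    model = DemographicModel.constant(ne)
    scheme = SamplingScheme((("A", n, 0.0),), L=L)
    mm = MutationModel(mu=mu, kappa=10.0)
    S, pi = [], []
    for s in seeds(rng, 3000):
        aln = simulate_alignment(model, scheme, mm, int(s))
        counts, Lu = allele_count_matrix(aln)
        d = stats_from_counts(counts, n, Lu)
        S.append(d["S"])
        pi.append(d["pi_locus"])
    theta = 2 * ne * mu * L
    S, pi = np.array(S, float), np.array(pi)
    for obs, expected in ((S, theta * harmonic(n)), (pi, theta)):
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - expected) <= 3 * se, (obs.mean(), expected)


def test_transition_bias_visible_in_substitutions():
    """With kappa = 10, far more A<->G / C<->T differences than transversions."""
    model = DemographicModel.constant(2000.0)
    scheme = SamplingScheme((("A", 2, 0.0),), L=5000)
    mm = MutationModel(mu=5e-7, kappa=10.0)
    ts = tv = 0
    rng = np.random.default_rng(5)
    for s in seeds(rng, 60):
        aln = simulate_alignment(model, scheme, mm, int(s))
        a, b = aln.sequences()
        for x, y in zip(a, b):
            if x != y:
                if {x, y} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
    assert ts > 2 * tv, (ts, tv)


def test_mean_between_cohort_divergence_increases_with_gap():
    """Widening the sampling gap adds gap/2 expected pairwise differences
    per between-cohort pair (extra branch on one side only)."""
    rng = np.random.default_rng(6)
    ne, mu, L = 200.0, 2e-6, 500
    model = DemographicModel.constant(ne)
    mm = MutationModel(mu=mu)
    means = []
    for gap in (0.0, 200.0, 400.0):
        scheme = SamplingScheme((("new", 6, 0.0), ("old", 6, gap)), L=L)
        vals = []
        for s in seeds(rng, 800):
            aln = simulate_alignment(model, scheme, mm, int(s))
            sub = aln.matrix
            new_rows = [i for i, x in enumerate(aln.ids) if x.startswith("new")]
            old_rows = [i for i, x in enumerate(aln.ids) if x.startswith("old")]
            from mtcohort.alignment import pairwise_differences

            dist = pairwise_differences(aln.matrix, aln.usable_columns())
            vals.append(dist[np.ix_(new_rows, old_rows)].mean())
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2], means


@pytest.mark.parametrize("serial", [False, True])
def test_segregating_sites_distribution_matches_msprime(serial):
    """Distributional equivalence with an independent coalescent simulator
    on a matched model (two-sample KS on S at alpha = 0.01)."""
    msprime = pytest.importorskip("msprime")
    ne, mu, L, n = 400.0, 1e-6, 600, 10
    reps = 400
    if serial:
        scheme = SamplingScheme((("a", 5, 0.0), ("b", 5, 300.0)), L=L)
        samplesets = [
            msprime.SampleSet(5, time=0.0, ploidy=1),
            msprime.SampleSet(5, time=300.0, ploidy=1),
        ]
    else:
        scheme = SamplingScheme((("a", n, 0.0),), L=L)
        samplesets = [msprime.SampleSet(n, time=0.0, ploidy=1)]
    model = DemographicModel.constant(ne)
    mm = MutationModel(mu=mu, kappa=10.0)

    rng = np.random.default_rng(8 + serial)
    S_ours = []
    for s in seeds(rng, reps):
        aln = simulate_alignment(model, scheme, mm, int(s))
        S_ours.append(classify_sites(aln).S)

    S_ref = []
    for s in seeds(rng, reps):
        ts = msprime.sim_ancestry(
            samples=samplesets, population_size=ne, ploidy=1,
            sequence_length=L, random_seed=int(s) % (2**31 - 1) + 1,
        )
        mts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.HKY(kappa=10.0),
            random_seed=int(s) % (2**31 - 1) + 1,
        )
        G = mts.genotype_matrix()
        S_ref.append(int((G != G[:, [0]]).any(axis=1).sum()) if G.size else 0)

    res = sps.ks_2samp(S_ours, S_ref)
    assert res.pvalue > 0.01, (np.mean(S_ours), np.mean(S_ref), res.pvalue)


def test_fixture_presets():
    aln, meta = make_fixture("iberia_like", seed=0)
    assert aln.n == 71 and aln.L == 4175
    assert set(meta["group"]) == {"IB_O", "IB_N"}
    assert meta["time_gen"].nunique() == 2
    with pytest.raises(ValueError, match="preset"):
        make_fixture("nope")


def test_fixture_files_written(tmp_path):
    from mtcohort.alignment import read_alignment

    make_fixture("null_panmixia", seed=1, outdir=tmp_path)
    aln, meta = read_alignment(tmp_path / "null_panmixia.fasta", tmp_path / "null_panmixia.tsv")
    assert aln.n == 50
    assert set(meta["group"]) == {"A", "B"}


def test_two_pop_toy_is_strongly_differentiated():
    import pandas as pd

    from mtcohort.popgen import hudson_fst

    aln, meta = make_fixture("two_pop_toy", seed=11)
    fst = hudson_fst(aln, meta["group"], ("P1", "P2"))
    assert fst > 0.3


def test_simulation_reproducible_under_seed():
    model = DemographicModel.constant(100.0)
    scheme = SamplingScheme((("A", 8, 0.0),), L=200)
    mm = MutationModel(mu=1e-5)
    a = simulate_alignment(model, scheme, mm, seed=99)
    b = simulate_alignment(model, scheme, mm, seed=99)
    assert a.sequences() == b.sequences()
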