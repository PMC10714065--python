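"""Shared fixtures: toy alignments and a moderate simulated training table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtcohort.alignment import Alignment
from mtcohort.coalescent import make_fixture
from mtcohort.scenarios import build_training_table, compute_sumstat_vector, default_scenarios, default_scheme


def make_alignment(seqs, ids=None) -> Alignment:
    """Build an Alignment from a list of equal-length strings."""
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    matrix = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return Alignment(list(ids), matrix)


@pytest.fixture
def toy4():
    """The 4-sequence hand-countable example: S=3, singletons=2, informative=1."""
    return make_alignment(["AACA", "AACT", "AGCT", "AGTT"])


@pytest.fixture
def monomorphic4():
    return make_alignment(["ACGT" * 3] * 4)


@pytest.fixture(scope="session")
def iberia_fixture():
    """One synthetic two-cohort dataset emulating the study design."""
    aln, meta = make_fixture("iberia_like", seed=1234)
    cohorts = meta["group"].map({"IB_O": "old", "IB_N": "new"})
    return aln, meta, cohorts


@pytest.fixture(scope="session")
def small_training_table():
    """A compact six-scenario training table for classifier-level tests.

    Uses a short locus and modest cohort sizes so several hundred
    simulations stay cheap; statistically it is the same generative process
    as the full-scale table.
    """
    scheme = default_scheme(L=1500, n_old=12, n_new=25)
    return build_training_table(default_scenarios(), n_per_scenario=120, scheme=scheme, seed=77)


@pytest.fixture(scope="session")
def small_observed(small_training_table):
    """A pseudo-observed vector matched to the small training scheme."""
    from mtcohort.coalescent import DemographicModel, MutationModel, simulate_alignment
    from mtcohort.scenarios import default_scheme

    scheme = default_scheme(L=1500, n_old=12, n_new=25)
    model = DemographicModel(((0.0, 200.0), (3.0, 5000.0), (500.0, 500.0)))
    aln = simulate_alignment(model, scheme, MutationModel(5e-8), seed=5)
    return compute_sumstat_vector(aln, scheme.metadata()["group"])
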