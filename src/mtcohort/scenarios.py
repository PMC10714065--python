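"""Demographic scenarios, priors and ABC training tables.

Six single-population scenarios describe alternative histories of a small
coastal mtDNA population observed through two temporal cohorts:

* **SC1** — constant, large effective size;
* **SC2** — constant, small effective size;
* **SC3** — old expansion (>= 150 generations ago);
* **SC4** — old decline (>= 150 generations ago);
* **SC5** — recent decline (<= 3 generations ago);
* **SC6** — old expansion (> 150 generations ago) followed by a recent
  decline (<= 3 generations ago) by a factor >= 10.

Each scenario owns parameter priors (log-uniform for sizes, rate and
magnitude factors; uniform for event times); draws are rejection-sampled
against the scenario constraints.  A training table row is one parameter
draw -> serial-coalescent simulation -> fixed-order summary-statistic
vector; rows are reproducible from a single master seed.

The default priors and mutation model are package defaults declared in
``DEFAULT_PRIORS`` and echoed into every table manifest; see
``docs/methods.md`` for their rationale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, AlignmentError, collapse_haplotypes
from .coalescent import DemographicModel, MutationModel, SamplingScheme, simulate_alignment
from .popgen import (
    allele_count_matrix,
    harmonic,
    haplotype_diversity,
    hudson_fst_from_dist,
    phi_st_from_dist,
    stats_from_counts,
)
from .alignment import pairwise_differences
from ._seeds import derive_seed

__all__ = [
    "Prior",
    "ScenarioSpec",
    "DEFAULT_PRIORS",
    "TIGHT_PRIORS",
    "default_scenarios",
    "default_scheme",
    "sample_parameters",
    "build_model",
    "compute_sumstat_vector",
    "sumstat_manifest",
    "build_training_table",
    "simulate_one",
    "write_training_table",
    "read_training_table",
]


@dataclass(frozen=True)
class Prior:
    """Uniform or log-uniform prior on one scalar parameter."""

    family: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self):
        if self.family == "fixed":
            if not np.isfinite(self.low):
                raise ValueError("fixed prior needs a finite value")
            object.__setattr__(self, "high", self.low)
            return
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError(f"invalid prior bounds ({self.low}, {self.high})")
        if self.family not in ("uniform", "loguniform"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "loguniform" and self.low <= 0:
            raise ValueError("log-uniform priors need positive bounds")

    @classmethod
    def fixed(cls, value: float) -> "Prior":
        return cls("fixed", value, value)

    def draw(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return float(self.low)
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


#: Package-default priors (declared substitutes for the study's unpublished
#: simulation settings; every output manifest echoes them).
DEFAULT_PRIORS: dict[str, Prior] = {
    "ne_large": Prior("loguniform", 2_000.0, 20_000.0),
    "ne_small": Prior("loguniform", 100.0, 2_000.0),
    "ne": Prior("loguniform", 100.0, 20_000.0),
    "t_old": Prior("uniform", 150.0, 2_000.0),
    "t_rec": Prior("uniform", 1.0, 3.0),
    "factor": Prior("loguniform", 10.0, 100.0),
    "mu": Prior("loguniform", 1e-8, 1e-7),
}


#: Alternative, sharply separated prior set used only for prior-sensitivity
#: reporting: scenario discriminability depends strongly on how much the
#: scenario parameter ranges overlap, and this set bounds the constant-size
#: scenarios apart (SC1 vs SC2) and narrows the mid-size range.
TIGHT_PRIORS: dict[str, Prior] = {
    "ne_large": Prior("loguniform", 5_000.0, 50_000.0),
    "ne_small": Prior("loguniform", 50.0, 500.0),
    "ne": Prior("loguniform", 500.0, 5_000.0),
    "t_old": Prior("uniform", 150.0, 2_000.0),
    "t_rec": Prior("uniform", 1.0, 3.0),
    "factor": Prior("loguniform", 10.0, 100.0),
    "mu": Prior.fixed(5e-8),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A demographic scenario template with free parameters and constraints.

    ``params`` maps parameter names to priors; ``builder`` turns a draw into
    a :class:`DemographicModel`; ``constraint`` (optional) accepts a draw
    dict and returns True when the draw is admissible.
    """

    id: str
    params: dict
    builder: object
    constraint: object = None
    description: str = ""


def _sc1(p):
    return DemographicModel.constant(p["ne_large"])


def _sc2(p):
    return DemographicModel.constant(p["ne_small"])


def _sc3(p):
    # old expansion: ancestral size smaller by `factor`
    return DemographicModel(((0.0, p["ne"]), (p["t_old"], p["ne"] / p["factor"])))


def _sc4(p):
    # old decline: ancestral size larger by `factor`
    return DemographicModel(((0.0, p["ne"]), (p["t_old"], p["ne"] * p["factor"])))


def _sc5(p):
    # recent decline: current size is ancestral / factor
    return DemographicModel(((0.0, p["ne"] / p["factor"]), (p["t_rec"], p["ne"])))


def _sc6(p):
    # old expansion then recent decline (decline factor >= 10 by prior)
    mid = p["ne"]
    return DemographicModel(
        (
            (0.0, mid / p["factor_dec"]),
            (p["t_rec"], mid),
            (p["t_old"], mid / p["factor_exp"]),
        )
    )


def default_scenarios(priors: dict[str, Prior] | None = None) -> list[ScenarioSpec]:
    pr = dict(DEFAULT_PRIORS)
    if priors:
        pr.update(priors)
    return [
        ScenarioSpec("SC1", {"ne_large": pr["ne_large"], "mu": pr["mu"]}, _sc1,
                     description="constant large Ne"),
        ScenarioSpec("SC2", {"ne_small": pr["ne_small"], "mu": pr["mu"]}, _sc2,
                     description="constant small Ne"),
        ScenarioSpec("SC3", {"ne": pr["ne"], "t_old": pr["t_old"], "factor": pr["factor"], "mu": pr["mu"]},
                     _sc3, constraint=lambda p: p["t_old"] >= 150.0,
                     description="old expansion (>=150 gen)"),
        ScenarioSpec("SC4", {"ne": pr["ne"], "t_old": pr["t_old"], "factor": pr["factor"], "mu": pr["mu"]},
                     _sc4, constraint=lambda p: p["t_old"] >= 150.0,
                     description="old decline (>=150 gen)"),
        ScenarioSpec("SC5", {"ne": pr["ne"], "t_rec": pr["t_rec"], "factor": pr["factor"], "mu": pr["mu"]},
                     _sc5, constraint=lambda p: p["t_rec"] <= 3.0,
                     description="recent decline (<=3 gen)"),
        ScenarioSpec("SC6", {"ne": pr["ne"], "t_old": pr["t_old"], "t_rec": pr["t_rec"],
                             "factor_exp": pr["factor"], "factor_dec": pr["factor"], "mu": pr["mu"]},
                     _sc6,
                     constraint=lambda p: p["t_old"] > 150.0 and p["t_rec"] <= 3.0 and p["factor_dec"] >= 10.0,
                     description="old expansion then recent decline (factor >= 10)"),
    ]


def default_scheme(L: int = 4175, n_old: int = 19, n_new: int = 52, gap: float = 2.0) -> SamplingScheme:
    """The study design: two cohorts of one population, ``gap`` generations apart."""
    return SamplingScheme((("new", n_new, 0.0), ("old", n_old, gap)), L=L)


def sample_parameters(spec: ScenarioSpec, seed=None, max_tries: int = 10_000) -> dict:
    """Rejection-sample one admissible parameter draw for a scenario."""
    rng = np.random.default_rng(seed)
    for tries in range(1, max_tries + 1):
        draw = {name: prior.draw(rng) for name, prior in spec.params.items()}
        if spec.constraint is None or spec.constraint(draw):
            return draw
    raise RuntimeError(
        f"{spec.id}: constraint acceptance below {1.0 / max_tries:.2%}; revise priors"
    )


def build_model(spec: ScenarioSpec, draw: dict) -> DemographicModel:
    return spec.builder(draw)


# ---------------------------------------------------------------------------
# summary statistics


#: per-cohort statistics (old cohort, new cohort, pooled) + between-cohort block
_PER_GROUP = ("S", "H", "Hd", "pi", "thetaW", "D", "pairdiff", "singl")
_BETWEEN = ("fst", "phist", "between_pairdiff", "shared_haps", "private_old", "private_new")


def sumstat_manifest() -> list[str]:
    """Fixed ordering of the default summary-statistic vector."""
    names = []
    for g in ("old", "new", "pool"):
        names.extend(f"{g}_{s}" for s in _PER_GROUP)
    names.extend(_BETWEEN)
    return names


def _group_block(aln: Alignment, rows: np.ndarray) -> dict:
    counts, L = allele_count_matrix(aln, rows)
    n = len(rows)
    base = stats_from_counts(counts, n, L)
    sub = aln.take(rows)
    haps = collapse_haplotypes(sub)
    return {
        "S": base["S"],
        "H": haps.n_haplotypes,
        "Hd": haplotype_diversity(haps.counts.values),
        "pi": base["pi_site"],
        "thetaW": base["thetaW_site"],
        "D": base["D"],
        "pairdiff": base["pi_locus"],
        "singl": base["singletons"],
    }


def compute_sumstat_vector(aln: Alignment, cohorts: pd.Series) -> pd.Series:
    """Fixed-order summary vector from an alignment and a 2-cohort table.

    ``cohorts`` maps sequence id -> cohort label; exactly the labels
    ``{"old", "new"}`` must be present.  Undefined statistics are encoded as
    ``nan`` (imputed identically for simulated and observed data downstream).
    """
    labels = set(cohorts.unique())
    if labels != {"old", "new"}:
        raise AlignmentError(f"expected cohorts {{'old','new'}}, got {sorted(labels)}")
    idx_old = aln.index_of(cohorts.index[cohorts == "old"])
    idx_new = aln.index_of(cohorts.index[cohorts == "new"])

    out: dict[str, float] = {}
    for g, rows in (("old", idx_old), ("new", idx_new), ("pool", np.concatenate([idx_old, idx_new]))):
        block = _group_block(aln, rows)
        for s in _PER_GROUP:
            out[f"{g}_{s}"] = block[s]

    # between-cohort block on the pooled complete-deletion mask
    rows = np.concatenate([idx_old, idx_new])
    sub = aln.take(rows)
    dist = pairwise_differences(sub.matrix, sub.usable_columns())
    m_old = np.zeros(len(rows), bool)
    m_old[: len(idx_old)] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["fst"] = hudson_fst_from_dist(dist, m_old, ~m_old)
        out["phist"] = phi_st_from_dist(dist, m_old, ~m_old)
    out["between_pairdiff"] = float(
        dist[np.ix_(np.flatnonzero(m_old), np.flatnonzero(~m_old))].mean()
    )
    haps = collapse_haplotypes(sub)
    hap_groups = haps.group_counts(
        pd.Series(np.where(m_old, "old", "new"), index=sub.ids)
    )
    in_old = hap_groups.get("old", pd.Series(0, index=hap_groups.index)) > 0
    in_new = hap_groups.get("new", pd.Series(0, index=hap_groups.index)) > 0
    out["shared_haps"] = int((in_old & in_new).sum())
    out["private_old"] = int((in_old & ~in_new).sum())
    out["private_new"] = int((in_new & ~in_old).sum())

    return pd.Series(out, index=sumstat_manifest(), dtype=float)


def simulate_one(spec: ScenarioSpec, scheme: SamplingScheme, seed, kappa: float = 10.0):
    """Draw parameters, simulate, summarise.  Returns (draw, sumstats)."""
    rng = np.random.default_rng(seed)
    draw = sample_parameters(spec, int(rng.integers(2**31)))
    model = build_model(spec, draw)
    mm = MutationModel(mu=draw["mu"], kappa=kappa)
    aln = simulate_alignment(model, scheme, mm, int(rng.integers(2**31)))
    cohorts = scheme.metadata()["group"]
    stats = compute_sumstat_vector(aln, cohorts)
    return draw, stats


def build_training_table(
    scenarios: list[ScenarioSpec],
    n_per_scenario: int,
    scheme: SamplingScheme | None = None,
    seed: int = 0,
    kappa: float = 10.0,
) -> pd.DataFrame:
    """Simulate the ABC training table: ``n_per_scenario`` rows per scenario.

    Columns: the summary-statistic manifest, then ``scenario`` and the
    parameter draw (``param_*``).  Deterministic given ``seed``; each row
    uses a seed derived from ``(seed, scenario id, row index)`` so tables
    are reproducible row-by-row and order-independent.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    scheme = scheme if scheme is not None else default_scheme()
    cohort_labels = {lab for lab, _, _ in scheme.samples}
    if cohort_labels != {"old", "new"}:
        raise AlignmentError("training scheme must define cohorts 'old' and 'new'")
    records = []
    for spec in scenarios:
        for i in range(n_per_scenario):
            row_seed = derive_seed(seed, f"{spec.id}:{i}")
            try:
                draw, stats = simulate_one(spec, scheme, row_seed, kappa)
            except Exception as exc:  # pragma: no cover - row context for debugging
                raise RuntimeError(f"simulation failed for {spec.id} row {i}") from exc
            rec = stats.to_dict()
            rec["scenario"] = spec.id
            for k, v in draw.items():
                rec[f"param_{k}"] = v
            records.append(rec)
    cols = sumstat_manifest() + ["scenario"]
    df = pd.DataFrame.from_records(records)
    param_cols = [c for c in df.columns if c.startswith("param_")]
    return df[cols + sorted(param_cols)]


def _manifest_lines(scenarios, scheme, seed, kappa, n_per_scenario):
    lines = [
        f"# mtcohort training table",
        f"# seed={seed} kappa={kappa} n_per_scenario={n_per_scenario}",
        f"# scheme={scheme.samples} L={scheme.L}",
        f"# statistics={','.join(sumstat_manifest())}",
    ]
    for spec in scenarios:
        pr = {k: (v.family, v.low, v.high) for k, v in spec.params.items()}
        lines.append(f"# scenario {spec.id}: {spec.description}; priors={pr}")
    return lines


def write_training_table(df: pd.DataFrame, path, scenarios=None, scheme=None,
                         seed=None, kappa=None, n_per_scenario=None) -> None:
    """Write a training table as TSV with a ``#`` manifest header block."""
    with open(path, "w") as fh:
        if scenarios is not None and scheme is not None:
            for line in _manifest_lines(scenarios, scheme, seed, kappa, n_per_scenario):
                fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_training_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
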