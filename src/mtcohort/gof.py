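"""Goodness-of-fit between observed and scenario-simulated summary statistics.

Two complementary checks of prior compatibility:

* an envelope test: a statistic is flagged as an outlier when the observed
  value falls outside the central ``1 - alpha`` interval of its simulated
  distribution under a scenario (empirical order-statistic quantiles with
  linear interpolation); the per-scenario outlier count ranks how well each
  scenario's prior predictive reproduces the data;
* projections of the simulated clouds and the observed point onto the first
  two PCA and LDA axes of the training set, for the visual check that the
  observed statistics sit inside at least one scenario's cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["GofReport", "gof_outliers", "gof_by_scenario", "project_clouds"]


@dataclass
class GofReport:
    """Envelope test of one scenario: per-statistic rows + outlier count."""

    scenario: str
    table: pd.DataFrame  # columns: observed, q_low, q_high, outlier
    alpha: float

    @property
    def n_outliers(self) -> int:
        return int(self.table["outlier"].sum())


def gof_outliers(
    simulated: pd.DataFrame,
    observed: pd.Series,
    alpha: float = 0.05,
    scenario: str = "",
    min_rows: int = 100,
) -> GofReport:
    """Flag statistics whose observed value escapes the simulated envelope.

    ``simulated`` holds one scenario's summary-statistic rows; statistics
    where the observed value is missing are skipped.  For a constant
    simulated column the statistic is flagged only when the observed value
    differs from that constant.
    """
    stats = [c for c in simulated.columns if c in observed.index]
    if len(simulated) < min_rows:
        raise ValueError(f"need >= {min_rows} simulated rows for stable quantiles")
    rows = []
    for s in stats:
        obs = observed[s]
        if not np.isfinite(obs):
            continue
        col = simulated[s].dropna().values
        if len(col) < min_rows:
            continue
        lo, hi = np.quantile(col, [alpha / 2.0, 1.0 - alpha / 2.0])
        if lo == hi:
            outlier = not np.isclose(obs, lo)
        else:
            outlier = bool(obs < lo or obs > hi)
        rows.append({"statistic": s, "observed": obs, "q_low": lo, "q_high": hi, "outlier": outlier})
    table = pd.DataFrame(rows).set_index("statistic")
    return GofReport(scenario=scenario, table=table, alpha=alpha)


def gof_by_scenario(
    training_table: pd.DataFrame,
    observed: pd.Series,
    alpha: float = 0.05,
    label_col: str = "scenario",
) -> pd.Series:
    """Outlier counts per scenario (lower = better prior-predictive fit)."""
    stat_cols = [
        c for c in training_table.columns if c != label_col and not c.startswith("param_")
    ]
    counts = {}
    for scen, sub in training_table.groupby(label_col):
        counts[scen] = gof_outliers(sub[stat_cols], observed, alpha, scenario=scen).n_outliers
    return pd.Series(counts).sort_index()


def project_clouds(
    training_table: pd.DataFrame,
    observed: pd.Series,
    label_col: str = "scenario",
) -> dict:
    """First two PCA and LDA coordinates of simulations and the observed point.

    Statistics are median-imputed and standardised on the training set;
    zero-variance columns are dropped with a warning.  Returns a dict with
    ``"pca"``/``"lda"`` DataFrames (columns axis1, axis2, scenario) and
    ``"pca_observed"``/``"lda_observed"`` coordinate pairs.
    """
    if len(training_table) < 3:
        raise ValueError("projection needs at least 3 simulated rows")
    stat_cols = [
        c for c in training_table.columns if c != label_col and not c.startswith("param_")
    ]
    X = training_table[stat_cols].copy()
    medians = X.median()
    X = X.fillna(medians)
    obs = observed.reindex(stat_cols).fillna(medians)
    sd = X.std(ddof=0)
    dead = sd.index[(sd == 0) | X.isna().any()]
    if len(dead):
        warnings.warn(f"dropping zero-variance columns from projection: {list(dead)}")
        X = X.drop(columns=dead)
        obs = obs.drop(labels=dead)
        sd = sd.drop(labels=dead)
    mean = X.mean()
    Z = (X - mean) / sd
    z_obs = ((obs - mean) / sd).values[None, :]

    pca = PCA(n_components=2)
    pc = pca.fit_transform(Z.values)
    pc_obs = pca.transform(z_obs)[0]

    labels = training_table[label_col].astype(str).values
    out = {
        "pca": pd.DataFrame({"axis1": pc[:, 0], "axis2": pc[:, 1], label_col: labels}),
        "pca_observed": (float(pc_obs[0]), float(pc_obs[1])),
    }
    if len(np.unique(labels)) >= 3:
        lda = LinearDiscriminantAnalysis(n_components=2)
        ld = lda.fit_transform(Z.values, labels)
        ld_obs = lda.transform(z_obs)[0]
        out["lda"] = pd.DataFrame({"axis1": ld[:, 0], "axis2": ld[:, 1], label_col: labels})
        out["lda_observed"] = (float(ld_obs[0]), float(ld_obs[1]))
    else:
        lda = LinearDiscriminantAnalysis(n_components=1)
        ld = lda.fit_transform(Z.values, labels)
        ld_obs = lda.transform(z_obs)[0]
        out["lda"] = pd.DataFrame({"axis1": ld[:, 0], label_col: labels})
        out["lda_observed"] = (float(ld_obs[0]),)
    return out
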