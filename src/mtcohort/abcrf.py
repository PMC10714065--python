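"""Random-forest ABC model choice with LDA augmentation and OOB diagnostics.

Model selection follows the classification-forest ABC procedure of Pudlo and
colleagues: a random forest is trained on simulated summary-statistic vectors
labelled by scenario, augmented with the linear-discriminant axes of the
training set.  The observed dataset is classified by per-tree majority vote;
forest quality is read off the out-of-bag (OOB) predictions — the prior
error rate is the OOB misclassification fraction, the confusion matrix is
built from OOB predictions, and a scenario's type II error is the fraction
of its simulations OOB-classified as any other scenario.  The posterior
probability of the selected scenario is estimated with a regression forest
fitted to the indicator "OOB prediction correct", evaluated at the observed
point.

Missing statistic values (undefined ``D``/``Y`` etc.) are imputed with the
training-column medians, identically for simulated and observed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._seeds import derive_seed

__all__ = [
    "AugmentedTable",
    "ForestDiagnostics",
    "RFResult",
    "ReplicateSummary",
    "augment_with_lda",
    "augment_observed",
    "train_classifier",
    "classify_observed",
    "posterior_probability",
    "run_model_choice",
    "replicate_analysis",
]


@dataclass
class AugmentedTable:
    """Training matrix + observed vector after imputation and LDA augmentation."""

    X: pd.DataFrame
    y: pd.Series
    observed: pd.Series
    medians: pd.Series
    lda: LinearDiscriminantAnalysis
    feature_names: list[str]


def _impute(df: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    out = df.fillna(medians)
    # a column that is all-NaN in training has no median; drop it explicitly
    dead = out.columns[out.isna().any()]
    if len(dead):
        warnings.warn(f"dropping all-missing statistic columns: {list(dead)}")
        out = out.drop(columns=dead)
    return out


def augment_with_lda(
    table: pd.DataFrame,
    observed: pd.Series,
    stat_cols: list[str] | None = None,
    label_col: str = "scenario",
) -> AugmentedTable:
    """Append the training-set LDA axes to both table and observed vector.

    The LDA is fitted on the training statistics only; the observed point is
    projected afterwards (no leakage).  With ``k`` scenarios, ``k - 1`` axes
    are appended.  A singular within-class covariance falls back to a
    ridge-regularised (shrinkage) solver with a warning.
    """
    if label_col not in table.columns:
        raise ValueError(f"training table lacks a {label_col!r} column")
    stat_cols = stat_cols or [
        c for c in table.columns if c != label_col and not c.startswith("param_")
    ]
    labels = table[label_col].astype(str)
    if labels.nunique() < 2:
        raise ValueError("LDA augmentation needs >= 2 scenarios")
    if len(table) <= len(stat_cols):
        raise ValueError("LDA augmentation needs more rows than statistics")

    medians = table[stat_cols].median()
    X = _impute(table[stat_cols], medians)
    obs = _impute(observed.reindex(stat_cols).to_frame().T, medians).iloc[0]
    used = list(X.columns)

    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            Z = lda.fit_transform(X.values, labels.values)
        except (np.linalg.LinAlgError, RuntimeWarning):
            warnings.simplefilter("default")
            warnings.warn("singular within-class covariance; using shrinkage LDA")
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(X.values, labels.values)
            Z = lda.decision_function(X.values)  # lsqr has no transform
    if Z.ndim == 1:
        Z = Z[:, None]
    axes = [f"LD{i + 1}" for i in range(Z.shape[1])]
    Xa = X.copy()
    Xa[axes] = Z
    try:
        z_obs = lda.transform(obs.values[None, :])
    except AttributeError:
        z_obs = lda.decision_function(obs.values[None, :])
    if z_obs.ndim == 1:
        z_obs = z_obs[:, None]
    obs_a = pd.concat([obs, pd.Series(z_obs[0], index=axes)])
    return AugmentedTable(
        X=Xa, y=labels, observed=obs_a, medians=medians, lda=lda,
        feature_names=used + axes,
    )


def augment_observed(aug: AugmentedTable, observed: pd.Series) -> pd.Series:
    """Project a new observed vector into an existing augmented feature space.

    Applies the stored training medians and the fitted LDA, so many
    pseudo-observed datasets can be classified by one trained forest.
    """
    stat_cols = [c for c in aug.X.columns if not c.startswith("LD")]
    obs = observed.reindex(stat_cols).fillna(aug.medians).astype(float)
    try:
        z = aug.lda.transform(obs.values[None, :])
    except AttributeError:
        z = aug.lda.decision_function(obs.values[None, :])
    if z.ndim == 1:
        z = z[:, None]
    axes = [c for c in aug.X.columns if c.startswith("LD")]
    return pd.concat([obs, pd.Series(z[0], index=axes)])


@dataclass
class ForestDiagnostics:
    """Out-of-bag quality summary of a trained classification forest."""

    forest: RandomForestClassifier
    classes: list[str]
    prior_error: float
    confusion: pd.DataFrame  # row-normalised, rows = true scenario
    type2_error: pd.Series
    oob_correct: np.ndarray
    n_trees: int
    seed: int | None


def train_classifier(
    aug: AugmentedTable, n_trees: int = 1000, seed: int | None = None
) -> ForestDiagnostics:
    """Train the classification forest and compute OOB diagnostics."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=None if seed is None else int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        forest.fit(aug.X.values, aug.y.values)
    classes = list(forest.classes_)
    oob = forest.oob_decision_function_
    # rows never OOB (tiny forests) get a uniform vote -> handled by nan check
    valid = ~np.isnan(oob).any(axis=1)
    pred = np.array(classes, dtype=object)[np.argmax(np.where(valid[:, None], oob, 0), axis=1)]
    truth = aug.y.values
    correct = (pred == truth) & valid
    prior_error = 1.0 - correct[valid].mean() if valid.any() else np.nan

    conf = pd.DataFrame(0.0, index=classes, columns=classes)
    for t, p in zip(truth[valid], pred[valid]):
        conf.loc[t, p] += 1
    row_sums = conf.sum(axis=1).replace(0, np.nan)
    conf = conf.div(row_sums, axis=0)
    type2 = 1.0 - pd.Series(np.diag(conf), index=classes)
    return ForestDiagnostics(
        forest=forest,
        classes=classes,
        prior_error=float(prior_error),
        confusion=conf,
        type2_error=type2,
        oob_correct=correct,
        n_trees=n_trees,
        seed=seed,
    )


def classify_observed(diag: ForestDiagnostics, observed: pd.Series, feature_names=None) -> pd.Series:
    """Per-tree hard-vote fractions for the observed vector (sums to 1)."""
    x = observed.values[None, :].astype(float)
    if x.shape[1] != diag.forest.n_features_in_:
        raise ValueError(
            f"observed vector has {x.shape[1]} features, forest expects "
            f"{diag.forest.n_features_in_}"
        )
    if not np.isfinite(x).all():
        raise ValueError("observed vector contains non-finite values after imputation")
    # hard vote = argmax of each tree's leaf class distribution
    votes = np.zeros(len(diag.classes))
    for tree in diag.forest.estimators_:
        votes[int(np.argmax(tree.predict_proba(x)[0]))] += 1
    votes /= votes.sum()
    return pd.Series(votes, index=diag.classes, name="votes")


def posterior_probability(
    diag: ForestDiagnostics, aug: AugmentedTable, seed: int | None = None,
    n_trees: int | None = None,
) -> float:
    """P(selected scenario | observed), via a regression forest on OOB success.

    Regression-forest hyperparameters follow the ranger regression defaults
    (features per split = p/3, minimum node size 5), the conventions of the
    reference ABC-RF implementation.
    """
    reg = RandomForestRegressor(
        n_estimators=n_trees or diag.n_trees,
        max_features=1.0 / 3.0,
        min_samples_leaf=5,
        random_state=None if seed is None else int(seed),
        n_jobs=1,
    )
    reg.fit(aug.X.values, diag.oob_correct.astype(float))
    p = reg.predict(aug.observed.values[None, :].astype(float))[0]
    return float(np.clip(p, 0.0, 1.0))


@dataclass
class RFResult:
    """One complete model-choice run."""

    votes: pd.Series
    selected: str
    posterior: float
    prior_error: float
    confusion: pd.DataFrame
    type2_error: pd.Series
    n_trees: int
    seed: int | None


def run_model_choice(
    table: pd.DataFrame,
    observed: pd.Series,
    n_trees: int = 1000,
    seed: int | None = None,
) -> RFResult:
    """Full ABC-RF model choice: LDA augmentation, forest, votes, posterior."""
    aug = augment_with_lda(table, observed)
    diag = train_classifier(aug, n_trees=n_trees, seed=seed)
    votes = classify_observed(diag, aug.observed)
    selected = votes.idxmax()
    post = posterior_probability(
        diag, aug, seed=None if seed is None else derive_seed(seed, "posterior")
    )
    return RFResult(
        votes=votes,
        selected=str(selected),
        posterior=post,
        prior_error=diag.prior_error,
        confusion=diag.confusion,
        type2_error=diag.type2_error,
        n_trees=n_trees,
        seed=seed,
    )


@dataclass
class ReplicateSummary:
    """Convergence of model choice over repeated forest trainings."""

    vote_mean: pd.Series
    vote_sd: pd.Series
    posterior_mean: float
    posterior_sd: float
    selections: list[str]
    agreement: int
    R: int

    @property
    def modal_selection(self) -> str:
        return pd.Series(self.selections).mode().iloc[0]


def replicate_analysis(
    table: pd.DataFrame,
    observed: pd.Series,
    R: int = 10,
    n_trees: int = 1000,
    master_seed: int = 0,
) -> ReplicateSummary:
    """Repeat forest training + classification with independent derived seeds.

    Replicates share the training table (forest-only variance); re-simulating
    the table per replicate is available by rebuilding it with a new seed.
    With ``R == 1`` the standard deviations are reported as ``nan``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    votes = []
    posts = []
    selections = []
    for r in range(R):
        res = run_model_choice(
            table, observed, n_trees=n_trees, seed=derive_seed(master_seed, f"replicate:{r}")
        )
        votes.append(res.votes)
        posts.append(res.posterior)
        selections.append(res.selected)
    vdf = pd.DataFrame(votes)
    modal = pd.Series(selections).mode().iloc[0]
    return ReplicateSummary(
        vote_mean=vdf.mean(),
        vote_sd=vdf.std(ddof=1) if R > 1 else vdf.iloc[0] * np.nan,
        posterior_mean=float(np.mean(posts)),
        posterior_sd=float(np.std(posts, ddof=1)) if R > 1 else float("nan"),
        selections=selections,
        agreement=int(sum(s == modal for s in selections)),
        R=R,
    )
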