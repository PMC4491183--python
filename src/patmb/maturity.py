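"""Microbiota age, microbial maturity (MM) and microbiota-for-age z-scores (MAZ).

A random-forest regression is trained on control mice to predict
chronological day of life from community composition (per-sample relative
abundances). The stated ensemble is 10,000 trees with n/3 predictors tried
per split (n = number of predictor OTUs); out-of-bag (OOB) predictions and
the OOB variance explained are recorded. The full model is then refined:
OTUs are ranked by OOB permutation importance (% increase in MSE when an
OTU's values are shuffled), candidate subset sizes descend geometrically
(n, n/2, n/4, ..., 2), each size is scored by cross-validated MSE, and the
smallest subset whose CV MSE is within one standard error of the minimum is
retrained as the final sparse model.

Maturity scores follow the microbiota-for-age convention:

    MM  = microbiota age - median control microbiota age at similar age
    MAZ = MM / s.d. of control microbiota age at similar age

"Similar age" is the scheduled timepoint index (mice are sampled on a
common schedule). Control reference statistics use OOB predictions to
avoid resubstitution bias. Group differences in MAZ are tested per
timepoint with one-way ANOVA followed (when significant) by Fisher's LSD
contrasts against control, Benjamini-Hochberg corrected within the
timepoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .io import CohortMetadata, OtuTable

logger = logging.getLogger(__name__)

__all__ = [
    "MaturityModel",
    "ReferenceStats",
    "fit_age_model",
    "refine_model",
    "predict_microbiota_age",
    "reference_stats",
    "maz_scores",
    "compare_maz_groups",
]

DEFAULT_N_TREES = 10_000


def _relative_abundance_matrix(table: OtuTable) -> np.ndarray:
    totals = table.counts.sum(axis=1).astype(float)
    if np.any(totals == 0):
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total sample(s) cannot be scored: {bad}")
    return table.counts / totals[:, None]


@dataclass
class MaturityModel:
    """A trained microbiota-age regressor plus its refinement record."""

    selected_otus: list[str]
    n_trees: int
    vars_per_split: int
    ensemble: RandomForestRegressor
    oob_predictions: pd.Series  # training sample -> OOB-predicted age
    variation_explained: float  # OOB R^2
    importances: pd.Series  # %IncMSE per OTU, descending
    training_sample_ids: list[str]
    seed: int
    cv_curve: list[tuple[int, float, float]] = field(default_factory=list)
    # (candidate size, CV MSE, SE of CV MSE)

    @property
    def hyperparams(self) -> dict[str, int]:
        return {"n_trees": self.n_trees, "vars_per_split": self.vars_per_split}


def _fit_forest(
    X: np.ndarray, y: np.ndarray, n_trees: int, seed: int
) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, X.shape[1] // 3),
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny ensembles can leave a sample with no OOB trees; handled below
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    return rf


def _oob_permutation_importance(
    rf: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    max_trees: int = 300,
) -> np.ndarray:
    """Per-feature % increase in MSE when the feature is permuted on OOB data.

    Averaged over (a deterministic subsample of) the trees; a subsample is
    statistically equivalent because trees are exchangeable, and keeps the
    cost independent of the ensemble size.
    """
    n, p = X.shape
    rng = np.random.default_rng(seed)
    n_trees = min(len(rf.estimators_), max_trees)
    inc = np.zeros(p)
    n_used = np.zeros(p)
    for t in range(n_trees):
        tree = rf.estimators_[t]
        sampled = rf.estimators_samples_[t]
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sampled] = False
        idx = np.flatnonzero(oob_mask)
        if idx.size < 2:
            continue
        X_oob = X[idx]
        y_oob = y[idx]
        base_mse = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        # one stacked predict per tree: block j has feature j permuted
        m = idx.size
        stacked = np.repeat(X_oob[None, :, :], p, axis=0)  # p x m x p
        for j in range(p):
            stacked[j, :, j] = X_oob[rng.permutation(m), j]
        preds = tree.predict(stacked.reshape(p * m, p)).reshape(p, m)
        perm_mse = np.mean((preds - y_oob[None, :]) ** 2, axis=1)
        if base_mse > 0:
            inc += (perm_mse - base_mse) / base_mse * 100.0
        else:
            inc += np.where(perm_mse > 0, 100.0, 0.0)
        n_used += 1
    with np.errstate(invalid="ignore"):
        out = np.where(n_used > 0, inc / np.maximum(n_used, 1), 0.0)
    return out


def fit_age_model(
    control_table: OtuTable,
    ages: pd.Series | np.ndarray,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    min_samples: int = 20,
    compute_importances: bool = True,
    importance_trees: int = 300,
) -> MaturityModel:
    """Train the microbiota-age random forest on control samples.

    ``ages`` is the chronological day of life per sample, aligned with (or
    indexed by) the table's sample order. Requires at least ``min_samples``
    samples spanning >= 4 distinct ages. ``compute_importances=False``
    skips the OOB permutation-importance pass (only needed ahead of
    :func:`refine_model`).
    """
    if isinstance(ages, pd.Series):
        y = ages.loc[control_table.sample_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(ages, dtype=float)
        if y.shape[0] != control_table.n_samples:
            raise ValueError("ages length does not match table samples")
    if control_table.n_samples < min_samples:
        raise ValueError(
            f"need >= {min_samples} control samples, got {control_table.n_samples}"
        )
    if np.unique(y).size < 4:
        raise ValueError("control ages must span >= 4 distinct values")

    X = _relative_abundance_matrix(control_table)
    rf = _fit_forest(X, y, n_trees, seed)
    oob = pd.Series(
        rf.oob_prediction_, index=pd.Index(control_table.sample_ids,
                                           name="sample_id"),
        name="microbiota_age",
    )
    if compute_importances:
        importances = pd.Series(
            _oob_permutation_importance(
                rf, X, y, seed=seed, max_trees=importance_trees
            ),
            index=control_table.otu_ids,
        ).sort_values(ascending=False)
    else:
        importances = pd.Series(dtype=float)
    return MaturityModel(
        selected_otus=list(control_table.otu_ids),
        n_trees=n_trees,
        vars_per_split=max(1, control_table.n_otus // 3),
        ensemble=rf,
        oob_predictions=oob,
        variation_explained=float(rf.oob_score_),
        importances=importances,
        training_sample_ids=list(control_table.sample_ids),
        seed=seed,
    )


def _candidate_sizes(n: int) -> list[int]:
    sizes = []
    s = n
    while s > 2:
        sizes.append(s)
        s = int(np.ceil(s / 2))
        if sizes and s == sizes[-1]:
            s -= 1
    sizes.append(2)
    return sizes


def refine_model(
    model: MaturityModel,
    control_table: OtuTable,
    ages: pd.Series | np.ndarray,
    n_folds: int = 100,
    seed: int = 0,
    cv_n_trees: int | None = None,
) -> MaturityModel:
    """Select the minimal predictive OTU subset by cross-validation.

    OTUs are ranked once by the fitted model's permutation importance;
    candidate sizes descend geometrically from the full set to 2. Each
    size's top-ranked subset is scored by K-fold CV MSE; the smallest size
    within one standard error of the minimum wins and is retrained with the
    full ensemble size. CV forests default to min(n_trees, 500) trees —
    the error curve is flat in ensemble size well below that.
    """
    if isinstance(ages, pd.Series):
        y = ages.loc[control_table.sample_ids].to_numpy(dtype=float)
    else:
        y = np.asarray(ages, dtype=float)
    n_samples = control_table.n_samples
    if n_folds > n_samples:
        logger.warning(
            "refine_model: n_folds=%d > %d samples; using leave-one-out",
            n_folds, n_samples,
        )
        n_folds = n_samples
    cv_trees = cv_n_trees if cv_n_trees is not None else min(model.n_trees, 500)

    if model.importances.empty:
        raise ValueError(
            "model has no importance scores; refit with compute_importances=True"
        )
    ranked = [o for o in model.importances.index if o in set(control_table.otu_ids)]
    X_full = _relative_abundance_matrix(control_table)
    col = {o: i for i, o in enumerate(control_table.otu_ids)}
    order = np.array([col[o] for o in ranked])

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X_full))
    sizes = _candidate_sizes(len(ranked))
    curve: list[tuple[int, float, float]] = []
    for size in sizes:
        cols = order[:size]
        fold_mse = []
        for train_idx, test_idx in splits:
            rf = RandomForestRegressor(
                n_estimators=cv_trees,
                max_features=max(1, size // 3),
                random_state=seed,
                n_jobs=1,
            )
            rf.fit(X_full[np.ix_(train_idx, cols)], y[train_idx])
            pred = rf.predict(X_full[np.ix_(test_idx, cols)])
            fold_mse.append(float(np.mean((pred - y[test_idx]) ** 2)))
        fold_mse = np.asarray(fold_mse)
        curve.append(
            (size, float(fold_mse.mean()),
             float(fold_mse.std(ddof=1) / np.sqrt(len(fold_mse)))
             if len(fold_mse) > 1 else 0.0)
        )

    mses = np.array([c[1] for c in curve])
    best = int(np.argmin(mses))
    threshold = curve[best][1] + curve[best][2]  # one-SE rule
    chosen = min(
        (c for c in curve if c[1] <= threshold), key=lambda c: c[0]
    )
    selected = [ranked[i] for i in range(chosen[0])]

    sub = control_table.subset_otus(selected)
    refined = fit_age_model(
        sub, pd.Series(y, index=sub.sample_ids), seed=seed,
        n_trees=model.n_trees, min_samples=min(20, n_samples),
    )
    refined.cv_curve = curve
    return refined


def predict_microbiota_age(
    model: MaturityModel,
    table: OtuTable,
    use_oob_for_training: bool = True,
) -> pd.Series:
    """Predicted day of life per sample.

    OTUs the model selected but the table lacks are treated as zero
    abundance (logged). For samples the model was trained on, OOB
    predictions are substituted by default so downstream reference
    statistics are free of resubstitution bias.
    """
    rel_all = _relative_abundance_matrix(table)
    col = {o: i for i, o in enumerate(table.otu_ids)}
    missing = [o for o in model.selected_otus if o not in col]
    if missing:
        logger.warning(
            "predict_microbiota_age: %d selected OTU(s) absent from table, "
            "treated as zero: %s", len(missing), missing[:5],
        )
    X = np.zeros((table.n_samples, len(model.selected_otus)))
    for j, o in enumerate(model.selected_otus):
        if o in col:
            X[:, j] = rel_all[:, col[o]]
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        logger.warning(
            "predict_microbiota_age: %d sample(s) have zero coverage of the "
            "selected OTUs; predictions fall back to the ensemble baseline",
            zero_rows.size,
        )
    pred = pd.Series(
        model.ensemble.predict(X),
        index=pd.Index(table.sample_ids, name="sample_id"),
        name="microbiota_age",
    )
    if use_oob_for_training:
        shared = pred.index.intersection(model.oob_predictions.index)
        pred.loc[shared] = model.oob_predictions.loc[shared]
    return pred


@dataclass
class ReferenceStats:
    """Per-age-bin control reference: median and s.d. of microbiota age.

    Bins are scheduled timepoint indices. A bin is unusable when it holds
    fewer than ``min_per_bin`` control samples or its s.d. is zero.
    """

    frame: pd.DataFrame  # index bin; columns median, sd, n, usable
    min_per_bin: int = 3

    def require_usable(self, bins: np.ndarray) -> None:
        bad = sorted(
            {int(b) for b in bins}
            - set(self.frame.index[self.frame["usable"]].astype(int))
        )
        if bad:
            raise ValueError(f"unusable reference bin(s): {bad}")


def reference_stats(
    control_ages: pd.Series,
    meta: CohortMetadata,
    min_per_bin: int = 3,
) -> ReferenceStats:
    """Median and sample s.d. (n-1) of control microbiota age per timepoint bin."""
    bins = meta.frame.loc[control_ages.index, "timepoint_index"]
    rows = []
    for b, vals in control_ages.groupby(bins):
        v = vals.to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        usable = v.size >= min_per_bin and sd > 0
        if not usable:
            logger.warning(
                "reference_stats: bin %s unusable (n=%d, sd=%.3g)", b, v.size, sd
            )
        rows.append(
            {"bin": int(b), "median": float(np.median(v)), "sd": sd,
             "n": int(v.size), "usable": usable}
        )
    frame = pd.DataFrame(rows).set_index("bin").sort_index()
    return ReferenceStats(frame=frame, min_per_bin=min_per_bin)


def maz_scores(
    predicted_ages: pd.Series,
    ref: ReferenceStats,
    meta: CohortMetadata,
) -> pd.DataFrame:
    """MM and MAZ per sample.

    MM = microbiota age - median control microbiota age of the sample's
    bin; MAZ = MM / s.d. of control microbiota age of the bin.
    """
    bins = meta.frame.loc[predicted_ages.index, "timepoint_index"].astype(int)
    ref.require_usable(bins.to_numpy())
    med = ref.frame["median"].reindex(bins.to_numpy()).to_numpy()
    sd = ref.frame["sd"].reindex(bins.to_numpy()).to_numpy()
    mm = predicted_ages.to_numpy(dtype=float) - med
    out = pd.DataFrame(
        {
            "bin": bins.to_numpy(),
            "microbiota_age": predicted_ages.to_numpy(dtype=float),
            "mm": mm,
            "maz": mm / sd,
        },
        index=predicted_ages.index,
    )
    return out


def compare_maz_groups(
    scores: pd.DataFrame,
    meta: CohortMetadata,
    control_group: str = "control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint ANOVA on MAZ with protected Fisher-LSD contrasts.

    For each timepoint with >= 2 groups of >= 2 samples, a one-way ANOVA is
    run on MAZ; when it is significant at ``alpha``, each treatment group
    is contrasted against control with Fisher's LSD t-test (pooled ANOVA
    MSE, df = N - k), and the contrast p-values are Benjamini-Hochberg
    adjusted within the timepoint. Non-significant ANOVAs report contrasts
    with NaN p/q.
    """
    df = scores.join(meta.frame[["group", "timepoint_index"]])
    rows = []
    for tp, sub in df.groupby("timepoint_index"):
        groups = {
            g: s["maz"].to_numpy()
            for g, s in sub.groupby("group")
            if len(s) >= 2
        }
        if len(groups) < 2 or control_group not in groups:
            logger.warning("compare_maz_groups: timepoint %s skipped", tp)
            continue
        names = sorted(groups)
        arrays = [groups[g] for g in names]
        f_stat, p_anova = stats.f_oneway(*arrays)
        n_total = sum(len(a) for a in arrays)
        k = len(arrays)
        grand = np.concatenate(arrays)
        mse = sum(
            ((a - a.mean()) ** 2).sum() for a in arrays
        ) / (n_total - k)
        df_err = n_total - k
        contrasts = []
        for g in names:
            if g == control_group:
                continue
            a, c = groups[g], groups[control_group]
            diff = a.mean() - c.mean()
            if mse > 0:
                t = diff / np.sqrt(mse * (1 / len(a) + 1 / len(c)))
                p = 2 * stats.t.sf(abs(t), df_err)
            else:
                t, p = 0.0, 1.0
            contrasts.append({"group": g, "diff": diff, "t": t, "p": p})
        significant = bool(p_anova < alpha)
        if significant and contrasts:
            qs = multipletests(
                [c["p"] for c in contrasts], method="fdr_bh"
            )[1]
        else:
            qs = [np.nan] * len(contrasts)
        for c, q in zip(contrasts, qs):
            rows.append(
                {
                    "timepoint_index": int(tp),
                    "F": float(f_stat),
                    "p_anova": float(p_anova),
                    "anova_significant": significant,
                    "group": c["group"],
                    "diff_vs_control": float(c["diff"]),
                    "t": float(c["t"]),
                    "p": float(c["p"]) if significant else np.nan,
                    "q": float(q) if significant else np.nan,
                }
            )
    return pd.DataFrame(rows)
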