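import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patmb import maturity as mat
from patmb.io import OtuTable
from patmb.simulate import SimulationConfig, simulate_cohort

from conftest import make_metadata


def _control_model(control_cohort, n_trees=300, **kw):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    return table, meta, ages, mat.fit_age_model(
        table, ages, seed=1, n_trees=n_trees, **kw
    )


def test_fit_requires_enough_samples_and_ages(rng):
    t = OtuTable(["a", "b"], ["o1", "o2"], rng.integers(1, 9, (2, 2)), {})
    with pytest.raises(ValueError, match="control samples"):
        mat.fit_age_model(t, np.array([1.0, 2.0]), n_trees=10)
    t2 = OtuTable([f"s{i}" for i in range(24)], ["o1", "o2"],
                  rng.integers(1, 9, (24, 2)), {})
    with pytest.raises(ValueError, match="distinct"):
        mat.fit_age_model(t2, np.full(24, 30.0), n_trees=10)


def test_hyperparameter_contract(control_cohort):
    table, meta, ages, model = _control_model(
        control_cohort, n_trees=50, compute_importances=False
    )
    assert model.hyperparams == {"n_trees": 50,
                                 "vars_per_split": table.n_otus // 3}
    assert model.ensemble.n_estimators == 50
    assert model.ensemble.max_features == table.n_otus // 3
    # the stated full-scale ensemble is the default
    assert mat.DEFAULT_N_TREES == 10_000


def test_fit_is_deterministic_under_fixed_seed(control_cohort):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    m1 = mat.fit_age_model(table, ages, seed=3, n_trees=100,
                           compute_importances=False)
    m2 = mat.fit_age_model(table, ages, seed=3, n_trees=100,
                           compute_importances=False)
    pd.testing.assert_series_equal(m1.oob_predictions, m2.oob_predictions)
    assert m1.variation_explained == m2.variation_explained


def test_oob_predictions_track_age(control_cohort):
    table, meta, ages, model = _control_model(
        control_cohort, compute_importances=False
    )
    rho = stats.spearmanr(model.oob_predictions, ages).statistic
    assert rho >= 0.8
    assert 0.0 <= model.variation_explained <= 1.0


def test_predict_duplicated_sample_identical(control_cohort):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(table, ages, seed=1, n_trees=60,
                              compute_importances=False)
    two = table.subset_samples(table.sample_ids[:1])
    dup = OtuTable(["x", "y"], two.otu_ids,
                   np.vstack([two.counts[0], two.counts[0]]), two.taxonomy)
    pred = mat.predict_microbiota_age(model, dup)
    assert pred["x"] == pred["y"]


def test_predict_handles_missing_and_uncovered_otus(control_cohort, caplog):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(table, ages, seed=1, n_trees=60,
                              compute_importances=False)
    # a table with only the last OTU present: the selected OTUs are mostly
    # missing (treated as zero) and predictions are still defined
    other = OtuTable(["q"], [table.otu_ids[-1]], np.array([[50]]),
                     {table.otu_ids[-1]: "Unclassified"})
    with caplog.at_level("WARNING"):
        pred = mat.predict_microbiota_age(model, other)
    assert np.isfinite(pred["q"])
    assert any("absent" in r.message for r in caplog.records)


def test_oob_substitution_for_training_samples(control_cohort):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(table, ages, seed=1, n_trees=80,
                              compute_importances=False)
    pred = mat.predict_microbiota_age(model, table)
    pd.testing.assert_series_equal(pred, model.oob_predictions,
                                   check_names=False)
    resub = mat.predict_microbiota_age(model, table,
                                       use_oob_for_training=False)
    assert not np.allclose(resub.to_numpy(), pred.to_numpy())


# --- reference stats and MAZ ---


def test_reference_stats_hand_arithmetic():
    meta = make_metadata(n_mice=3, days=(21,))
    ages = pd.Series([40.0, 42.0, 44.0], index=meta.sample_ids)
    ref = mat.reference_stats(ages, meta)
    assert ref.frame.loc[1, "median"] == 42.0
    assert ref.frame.loc[1, "sd"] == pytest.approx(2.0)
    assert bool(ref.frame.loc[1, "usable"])


def test_reference_stats_degenerate_bins_flagged():
    meta = make_metadata(n_mice=3, days=(21,))
    same = pd.Series([40.0, 40.0, 40.0], index=meta.sample_ids)
    ref = mat.reference_stats(same, meta)
    assert not ref.frame.loc[1, "usable"]
    with pytest.raises(ValueError, match="unusable"):
        mat.maz_scores(same, ref, meta)


def test_maz_formula_exact():
    meta = make_metadata(n_mice=3, days=(21,))
    ctrl = pd.Series([40.0, 42.0, 44.0], index=meta.sample_ids)
    ref = mat.reference_stats(ctrl, meta)
    scores = mat.maz_scores(ctrl, ref, meta)
    # sample at the bin median: MM = MAZ = 0; at median + 1 sd: MAZ = 1
    assert scores["maz"].loc[meta.sample_ids[1]] == 0.0
    probe = pd.Series([44.0], index=[meta.sample_ids[0]])
    assert mat.maz_scores(probe, ref, meta)["maz"].iloc[0] == pytest.approx(1.0)
    # control median MAZ is zero by construction in every bin
    assert scores.groupby("bin")["maz"].median().abs().max() == 0.0


def test_maz_affine_invariance():
    meta = make_metadata(n_mice=5, days=(21,))
    rng = np.random.default_rng(2)
    ages = pd.Series(rng.normal(40, 3, 5), index=meta.sample_ids)
    ref = mat.reference_stats(ages, meta)
    base = mat.maz_scores(ages, ref, meta)["maz"]
    a, b = 2.5, -7.0
    ref2 = mat.reference_stats(a * ages + b, meta)
    trans = mat.maz_scores(a * ages + b, ref2, meta)["maz"]
    np.testing.assert_allclose(base.to_numpy(), trans.to_numpy(), atol=1e-12)


# --- refinement ---


def test_refinement_curve_and_one_se_rule(control_cohort):
    cfg, table, meta, truth = control_cohort
    small = table.subset_otus(table.otu_ids[:30])
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(small, ages, seed=2, n_trees=120,
                              importance_trees=80)
    refined = mat.refine_model(model, small, ages, n_folds=6, seed=2,
                               cv_n_trees=40)
    sizes = [s for s, _, _ in refined.cv_curve]
    assert sizes[0] == 30 and sizes[-1] == 2
    assert all(a > b for a, b in zip(sizes, sizes[1:]))
    assert len(refined.selected_otus) <= 30
    mses = {s: m for s, m, _ in refined.cv_curve}
    ses = {s: se for s, _, se in refined.cv_curve}
    best = min(mses, key=mses.get)
    chosen = len(refined.selected_otus)
    assert mses[chosen] <= mses[best] + ses[best] + 1e-12
    full_size = sizes[0]
    assert mses[chosen] <= mses[full_size] + ses[full_size] + 1e-12


def test_refinement_requires_importances(control_cohort):
    cfg, table, meta, truth = control_cohort
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(table, ages, seed=1, n_trees=40,
                              compute_importances=False)
    with pytest.raises(ValueError, match="importance"):
        mat.refine_model(model, table, ages)


def test_refinement_reduces_folds_to_loo_with_warning(control_cohort, caplog):
    cfg, table, meta, truth = control_cohort
    top = (table.to_frame().sum().sort_values(ascending=False)
           .index[:6].tolist())
    tiny = table.subset_samples(table.sample_ids[:24]).subset_otus(top)
    ages = meta.frame.loc[tiny.sample_ids, "day_of_life"].astype(float)
    model = mat.fit_age_model(tiny, ages, seed=0, n_trees=40,
                              importance_trees=40, min_samples=20)
    with caplog.at_level("WARNING"):
        refined = mat.refine_model(model, tiny, ages, n_folds=100, seed=0,
                                   cv_n_trees=20)
    assert any("leave-one-out" in r.message for r in caplog.records)
    assert [s for s, _, _ in refined.cv_curve][0] == 6


def test_planted_sparse_signal_recovered_single_seed():
    cfg = SimulationConfig(seed=303, n_mice_per_group={"control": 6},
                           n_succession_pairs=5, n_diet_pairs=0, n_otus=100,
                           paired_succession=False, succession_mass=0.22,
                           succession_scale_days=5.0)
    table, meta, truth = simulate_cohort(cfg)
    informative = {o for o, g in zip(cfg.layout.otu_ids, cfg.layout.guild)
                   if g in ("early", "late")}
    ages = meta.frame["day_of_life"].astype(float)
    model = mat.fit_age_model(table, ages, seed=3, n_trees=250,
                              importance_trees=120)
    refined = mat.refine_model(model, table, ages, n_folds=12, seed=3,
                               cv_n_trees=60)
    assert len(refined.selected_otus) <= 20
    assert len(set(refined.selected_otus) & informative) >= 8


# --- group comparisons ---


def _scores_frame(meta, values):
    return pd.DataFrame(
        {"bin": meta.frame["timepoint_index"], "microbiota_age": np.nan,
         "mm": np.nan, "maz": values},
        index=meta.frame.index,
    )


def _group_meta(groups=("control", "tylosin"), n=6, days=(21,)):
    from patmb.io import CohortMetadata
    frames = [make_metadata(n_mice=n, days=days, group=g).frame
              for g in groups]
    return CohortMetadata(pd.concat(frames))


def test_identical_groups_give_f_zero():
    meta = _group_meta(n=4)
    vals = np.tile([0.1, -0.2, 0.3, -0.1], 2)
    res = mat.compare_maz_groups(_scores_frame(meta, vals), meta)
    assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res["p_anova"].iloc[0] == pytest.approx(1.0)
    assert np.isnan(res["q"].iloc[0])


def test_planted_shift_detected():
    rng = np.random.default_rng(5)
    detected = 0
    for _ in range(25):
        meta = _group_meta(n=6)
        vals = np.concatenate([rng.normal(0, 1, 6), rng.normal(-1.5, 1, 6)])
        res = mat.compare_maz_groups(_scores_frame(meta, vals), meta)
        row = res[res["group"] == "tylosin"].iloc[0]
        detected += bool(row["q"] < 0.05)
    assert detected >= 0.6 * 25  # power check at a single timepoint


def test_null_type_one_error_controlled():
    # all four design groups drawn from the same distribution: the
    # protected LSD should flag contrasts in well under 7% of timepoints
    rng = np.random.default_rng(8)
    groups = ("control", "amoxicillin", "tylosin", "mixture")
    meta = _group_meta(groups, n=6)
    flags = trials = 0
    for _ in range(200):
        vals = rng.normal(0, 1, 24)
        res = mat.compare_maz_groups(_scores_frame(meta, vals), meta)
        q = res["q"].to_numpy()
        flags += int(np.nansum(q < 0.05))
        trials += len(q)
    assert flags / trials <= 0.07


def test_degenerate_timepoints_skipped(caplog):
    meta = make_metadata(n_mice=4, days=(21,))  # control only
    vals = np.arange(4, dtype=float)
    with caplog.at_level("WARNING"):
        res = mat.compare_maz_groups(_scores_frame(meta, vals), meta)
    assert res.empty
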