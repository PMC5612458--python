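"""Learning stack: normalization, filters, folds, models, permutations."""
import numpy as np
import pandas as pd
import pytest

from t1qc import qc_learn as ql
from t1qc.errors import ContractError, InvalidSpecError, ValidationError
from t1qc.evalmetrics import roc_auc
from t1qc.phantom import SiteEffectSpec, synth_iqm_table

from conftest import make_sites


def small_table(seed=0, n=40, n_sites=2, effect=2.0, prevalence=0.4):
    eff = np.zeros(4)
    eff[:2] = effect
    return synth_iqm_table(make_sites([0.0] * n_sites, n=n,
                                      prevalences=[prevalence] * n_sites),
                           4, eff, seed=seed)


class TestBinarize:
    def test_three_class_mapping(self):
        t = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "site": ["s"] * 3,
                "label": ["accept", "doubtful", "exclude"],
                "f0": [0.0, 1.0, 2.0],
            }
        )
        out = ql.binarize_labels(t)
        assert list(out["label"]) == ["accept", "accept", "exclude"]
        assert (out["label"] == "exclude").sum() == (t["label"] == "exclude").sum()

    def test_unknown_label_rejected(self):
        t = pd.DataFrame(
            {"subject_id": ["a"], "site": ["s"], "label": ["maybe"], "f0": [0.0]}
        )
        with pytest.raises(ValidationError):
            ql.binarize_labels(t)

    def test_duplicate_subjects_rejected(self):
        t = pd.DataFrame(
            {"subject_id": ["a", "a"], "site": ["s", "s"],
             "label": ["accept", "accept"], "f0": [0.0, 1.0]}
        )
        with pytest.raises(ValidationError):
            ql.binarize_labels(t)


class TestSiteNormalizer:
    def test_center_and_scale_zero_median_unit_iqr(self):
        tab = small_table(seed=1, n=60, n_sites=3)
        norm = ql.SiteNormalizer(center=True, scale=True).fit(tab)
        out = norm.transform(tab)
        for _, grp in out.groupby("site"):
            med = grp[["iqm_00", "iqm_01"]].median()
            iqr = grp[["iqm_00", "iqm_01"]].quantile(0.75) - grp[
                ["iqm_00", "iqm_01"]
            ].quantile(0.25)
            assert np.allclose(med, 0.0, atol=1e-12)
            assert np.allclose(iqr, 1.0, atol=1e-12)

    def test_center_only_preserves_iqr(self):
        tab = small_table(seed=2)
        norm = ql.SiteNormalizer(center=True, scale=False).fit(tab)
        out = norm.transform(tab)
        before = tab.groupby("site")["iqm_00"].quantile(0.75) - tab.groupby(
            "site"
        )["iqm_00"].quantile(0.25)
        after = out.groupby("site")["iqm_00"].quantile(0.75) - out.groupby(
            "site"
        )["iqm_00"].quantile(0.25)
        assert np.allclose(before.values, after.values)

    def test_removes_constructed_site_shifts(self):
        sites = make_sites([5.0, -5.0], n=80, prevalences=[0.0, 0.0])
        tab = synth_iqm_table(sites, 3, 0.0, seed=3)
        out = ql.SiteNormalizer().fit(tab).transform(tab)
        medians = out.groupby("site")["iqm_00"].median()
        assert medians.abs().max() < 1e-12

    def test_zero_iqr_falls_back_with_warning(self):
        tab = small_table(seed=4)
        tab["iqm_03"] = 1.0
        with pytest.warns(UserWarning):
            norm = ql.SiteNormalizer().fit(tab)
        out = norm.transform(tab)
        assert np.allclose(out["iqm_03"], 0.0)

    def test_unseen_site_uses_its_own_stats(self):
        tab = small_table(seed=5, n=60)
        norm = ql.SiteNormalizer().fit(tab)
        new = small_table(seed=6, n=60)
        new["site"] = "unseen"
        new["subject_id"] = [f"u{i}" for i in range(len(new))]
        new["iqm_00"] += 100.0
        out = norm.transform(new)
        assert abs(out["iqm_00"].median()) < 1e-12


class TestSiteElimination:
    def test_site_coding_feature_removed_first(self):
        hits = 0
        for seed in range(5):
            sites = make_sites([0.0] * 3, n=40, prevalences=[0.4] * 3)
            tab = synth_iqm_table(sites, 6, 1.0, seed=seed)
            codes = tab["site"].astype("category").cat.codes.to_numpy(float)
            tab["iqm_00"] = codes + np.random.default_rng(seed).normal(
                0, 0.01, len(tab)
            )
            _, removed = ql.site_predictability_elimination(
                tab, max_removed=3, seed=seed
            )
            hits += bool(removed and removed[0] == "iqm_00")
        assert hits >= 4

    def test_floor_of_one_stops_immediately(self):
        tab = small_table(seed=0, n_sites=3)
        reduced, removed = ql.site_predictability_elimination(
            tab, max_removed=5, floor_accuracy=1.0, seed=0
        )
        assert removed == []
        assert ql.feature_columns(reduced) == ql.feature_columns(tab)

    def test_single_site_rejected(self):
        tab = small_table(seed=0, n_sites=1)
        with pytest.raises(ValidationError):
            ql.site_predictability_elimination(tab)


class TestNoiseProbe:
    def test_noise_feature_dropped_informative_kept(self):
        dropped = kept = 0
        for seed in range(5):
            sites = [SiteEffectSpec(site_id="s0", n_subjects=400,
                                    exclude_prevalence=0.5)]
            eff = np.zeros(6)
            eff[:5] = 2.0
            tab = synth_iqm_table(sites, 6, eff, seed=seed)
            reduced, removed = ql.noise_probe_selection(tab, seed=seed)
            dropped += "iqm_05" in removed
            kept += all(f"iqm_0{k}" in reduced.columns for k in range(5))
        assert dropped >= 4
        assert kept >= 4

    def test_zero_probes_is_identity(self):
        tab = small_table(seed=1)
        reduced, removed = ql.noise_probe_selection(tab, n_probes=0, seed=0)
        assert removed == []
        pd.testing.assert_frame_equal(reduced, tab)


class TestLosoFolds:
    def test_construction_example(self):
        tab = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "site": ["A", "A", "B", "C"],
                "label": ["accept"] * 4,
                "f0": [0.0, 1.0, 2.0, 3.0],
            }
        )
        plan = ql.loso_folds(tab)
        assert len(plan.folds) == 3
        train_for_a = dict((t, tr) for tr, t in plan.folds)["A"]
        assert set(train_for_a) == {"B", "C"}

    def test_each_row_tested_exactly_once(self, batch_effect_table):
        plan = ql.loso_folds(batch_effect_table)
        tested = []
        for _, test_site in plan.folds:
            tested.extend(
                batch_effect_table.index[batch_effect_table["site"] == test_site]
            )
        assert sorted(tested) == list(batch_effect_table.index)

    def test_single_site_rejected(self):
        tab = small_table(n_sites=1)
        with pytest.raises(ValidationError, match="k-fold"):
            ql.loso_folds(tab)

    def test_fold_plan_invariants_enforced(self):
        with pytest.raises(InvalidSpecError):
            ql.FoldPlan(folds=[(("A",), "B"), (("A",), "B")])
        with pytest.raises(InvalidSpecError):
            ql.FoldPlan(folds=[(("A", "B"), "B")])


class TestFitPredict:
    def test_linearly_separable_svc(self):
        tab = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "site": ["s"] * 4,
                "label": ["accept", "accept", "exclude", "exclude"],
                "f0": [0.0, 0.1, 5.0, 5.1],
                "f1": [0.0, 0.1, 5.0, 5.1],
            }
        )
        spec = ql.ModelSpec(family="svc_lin", norm_center=False, norm_scale=False)
        model = ql.fit_model(tab, spec, seed=0)
        labels, _ = ql.predict(model, tab)
        assert list(labels) == list(tab["label"])

    def test_depth_one_stump_cannot_solve_xor(self):
        rows = []
        for i, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)] * 10):
            rows.append(
                {
                    "subject_id": f"r{i}",
                    "site": "s",
                    "label": "exclude" if a ^ b else "accept",
                    "f0": float(a),
                    "f1": float(b),
                }
            )
        tab = pd.DataFrame(rows)
        spec = ql.ModelSpec(family="rfc", n_trees=1, max_depth=1,
                            norm_center=False, norm_scale=False)
        model = ql.fit_model(tab, spec, seed=0)
        labels, _ = ql.predict(model, tab)
        assert (labels == tab["label"]).mean() <= 0.75

    def test_same_seed_same_predictions(self, batch_effect_table):
        spec = ql.ModelSpec(family="rfc", n_trees=30)
        m1 = ql.fit_model(batch_effect_table, spec, seed=5)
        m2 = ql.fit_model(batch_effect_table, spec, seed=5)
        np.testing.assert_array_equal(
            m1.predict_scores(batch_effect_table),
            m2.predict_scores(batch_effect_table),
        )

    def test_single_class_train_rejected(self):
        tab = small_table(prevalence=0.0)
        with pytest.raises(ValidationError):
            ql.fit_model(tab, ql.ModelSpec(), seed=0)

    def test_missing_feature_contract_error(self, batch_effect_table):
        model = ql.fit_model(batch_effect_table, ql.ModelSpec(n_trees=10), seed=0)
        broken = batch_effect_table.drop(columns=["iqm_03"])
        with pytest.raises(ContractError, match="iqm_03"):
            model.predict_scores(broken)

    def test_threshold_monotonicity(self, batch_effect_table):
        model = ql.fit_model(batch_effect_table, ql.ModelSpec(n_trees=30), seed=0)
        counts = []
        for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
            labels, _ = ql.predict(model, batch_effect_table, threshold=thr)
            counts.append((labels == "exclude").sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0  # score ties at 1.0 break toward accept

    def test_nan_features_imputed_with_train_medians(self, batch_effect_table):
        tab = batch_effect_table.copy()
        tab.loc[tab.index[:5], "iqm_02"] = np.nan
        model = ql.fit_model(tab, ql.ModelSpec(n_trees=10), seed=0)
        scores = model.predict_scores(tab)
        assert np.all(np.isfinite(scores))


class TestNestedCV:
    def test_null_table_scores_near_chance(self):
        aucs = []
        for seed in range(3):
            sites = make_sites([0.0] * 3, n=60, prevalences=[0.5] * 3)
            tab = synth_iqm_table(sites, 6, 0.0, seed=seed)
            res = ql.nested_cv_select(
                tab, [ql.ModelSpec(family="rfc", n_trees=30)],
                outer_split="loso", n_sampled=1, seed=seed,
            )
            aucs.append(res.auc_mean)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_strong_signal_high_loso_auc(self):
        eff = np.zeros(10)
        eff[:5] = 2.0
        aucs = []
        for seed in range(3):
            tab = synth_iqm_table(make_sites([0, 1, -1, 2], n=80), 10, eff,
                                  seed=seed)
            spec = ql.ModelSpec(family="rfc", n_trees=100)
            fold_aucs = []
            for tr, te, _ in ql._outer_folds(tab, "loso", seed):
                m = ql.fit_model(tab.iloc[tr].reset_index(drop=True), spec,
                                 seed=seed)
                test = tab.iloc[te].reset_index(drop=True)
                fold_aucs.append(
                    roc_auc(m.predict_scores(test),
                            (test["label"] == "exclude").to_numpy())
                )
            aucs.append(np.mean(fold_aucs))
        assert np.mean(aucs) > 0.9

    def test_outer_loso_folds_are_site_named(self, batch_effect_table):
        res = ql.nested_cv_select(
            batch_effect_table, [ql.ModelSpec(n_trees=20)],
            outer_split="loso", n_sampled=1, seed=0,
        )
        assert sorted(res.per_fold["fold"]) == sorted(
            batch_effect_table["site"].unique()
        )

    def test_grid_of_one_returns_that_spec(self, batch_effect_table):
        only = ql.ModelSpec(family="rfc", n_trees=15)
        best, model, results = ql.grid_search_final(
            batch_effect_table, [only], seed=0
        )
        assert best is only
        assert len(results) == 1

    def test_grid_search_enumerates_product(self, batch_effect_table):
        grid = [
            ql.ModelSpec(family="rfc", n_trees=n, max_depth=d)
            for n in (5, 10) for d in (2, 4)
        ]
        _, _, results = ql.grid_search_final(batch_effect_table, grid, seed=0)
        assert len(results) == 4


class TestPermutationTest:
    def test_single_worse_permutation_gives_half(self):
        tr = small_table(seed=0, n=30, effect=8.0, prevalence=0.5)
        te = small_table(seed=1, n=15, effect=8.0, prevalence=0.5)
        spec = ql.ModelSpec(family="rfc", n_trees=10, norm_center=False,
                            norm_scale=False)
        p, observed, perms = ql.permutation_test(tr, te, spec, n_perm=1, seed=0)
        assert observed > perms[0]
        assert p == 0.5

    def test_add_one_convention(self):
        tr = small_table(seed=2, n=30, effect=8.0, prevalence=0.5)
        te = small_table(seed=3, n=20, effect=8.0, prevalence=0.5)
        spec = ql.ModelSpec(family="rfc", n_trees=10, norm_center=False,
                            norm_scale=False)
        p, observed, perms = ql.permutation_test(tr, te, spec, n_perm=49, seed=0)
        assert p == (1 + np.sum(perms >= observed)) / 50.0


class TestFeatureImportances:
    def test_single_feature_has_unit_importance(self):
        tab = small_table(seed=0, effect=3.0)[
            ["subject_id", "site", "label", "iqm_00"]
        ]
        model = ql.fit_model(
            tab, ql.ModelSpec(n_trees=10, norm_center=False, norm_scale=False),
            seed=0,
        )
        imp = ql.feature_importances(model)
        assert imp.index.tolist() == ["iqm_00"]
        assert imp.iloc[0] == pytest.approx(1.0)

    def test_strong_feature_outranks_noise(self):
        wins = 0
        for seed in range(5):
            sites = [SiteEffectSpec(site_id="s", n_subjects=200,
                                    exclude_prevalence=0.5)]
            eff = np.array([3.0, 0.0])
            tab = synth_iqm_table(sites, 2, eff, seed=seed)
            model = ql.fit_model(tab, ql.ModelSpec(n_trees=50), seed=seed)
            wins += ql.feature_importances(model).index[0] == "iqm_00"
        assert wins >= 4

    def test_svc_not_supported(self, batch_effect_table):
        model = ql.fit_model(
            batch_effect_table, ql.ModelSpec(family="svc_lin"), seed=0
        )
        with pytest.raises(InvalidSpecError):
            ql.feature_importances(model)

    def test_report_length_matches_surviving_features(self, batch_effect_table):
        spec = ql.ModelSpec(n_trees=20, use_noise_probe=True)
        model = ql.fit_model(batch_effect_table, spec, seed=0)
        imp = ql.feature_importances(model)
        assert len(imp) == len(model.selected_features)


class TestDefaultGrid:
    def test_compact_and_full_sizes(self):
        assert len(ql.default_model_grid()) == 24
        assert len(ql.default_model_grid(full=True)) == 512
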