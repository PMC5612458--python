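"""Batch-effect-robust supervised quality classification.

Image quality features derived from multi-site MRI carry strong *batch
effects*: systematic per-site shifts caused by acquisition differences
that let a classifier learn the site instead of the quality.  This
module implements the counter-measures and the evaluation protocol:

* site-wise robust normalization (per-site median / interquartile range);
* a feature-elimination filter that iteratively drops the feature most
  predictive of the acquisition site (extremely-randomized trees);
* a Winnow-style filter that drops features whose importance for the
  quality label falls below that of random-noise probe features;
* random-forest and support-vector classifiers with inverse-frequency
  class weighting;
* leave-one-site-out (LoSo) fold plans, nested cross-validation with
  randomized hyper-parameter search, exhaustive final grid search,
  label-permutation significance testing and Gini feature ranking.

Tables are plain :class:`pandas.DataFrame` objects with ``subject_id``,
``site`` and ``label`` columns followed by feature columns.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ContractError, InvalidSpecError, ValidationError
from .evalmetrics import NEGATIVE_LABEL, POSITIVE_LABEL, roc_auc

META_COLUMNS = ("subject_id", "site", "label")
LABEL_VOCABULARY = ("accept", "doubtful", "exclude")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_table(table: pd.DataFrame) -> None:
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"table lacks required column '{col}'")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes}")
    if not feature_columns(table):
        raise ValidationError("table has no feature columns")


def binarize_labels(table: pd.DataFrame) -> pd.DataFrame:
    """Map the 3-class rater vocabulary to binary quality ratings:
    "doubtful" and "accept" collapse to "accept"; "exclude" is the
    positive class and its count is preserved."""
    validate_table(table)
    unknown = set(table["label"]) - set(LABEL_VOCABULARY)
    if unknown:
        raise ValidationError(f"unknown labels: {sorted(unknown)}")
    out = table.copy()
    out["label"] = np.where(
        out["label"] == POSITIVE_LABEL, POSITIVE_LABEL, NEGATIVE_LABEL
    )
    return out


def _binary_y(table: pd.DataFrame) -> np.ndarray:
    return (table["label"].to_numpy() == POSITIVE_LABEL).astype(int)


@dataclass
class ModelSpec:
    """One point of the hyper-parameter space.

    ``family`` is one of rfc / svc_lin / svc_rbf.  ``C`` and ``gamma``
    drive the SVCs; the tree parameters drive the random forest.  The
    boolean flags switch the batch-effect counter-measures on and off —
    they are hyper-parameters of the framework, searched like any other.
    """

    family: str = "rfc"
    C: float = 1.0
    gamma: float = 0.01
    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    min_leaf: int = 1
    class_weighted: bool = True
    norm_center: bool = True
    norm_scale: bool = True
    use_site_elimination: bool = False
    use_noise_probe: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("rfc", "svc_lin", "svc_rbf"):
            raise InvalidSpecError(f"unknown model family '{self.family}'")
        if self.C <= 0 or self.gamma <= 0 or self.n_trees < 1:
            raise InvalidSpecError("require C > 0, gamma > 0, n_trees >= 1")


@dataclass
class FoldPlan:
    """Leave-one-site-out folds: each site is the test set exactly once."""

    folds: list[tuple[tuple[str, ...], str]]

    def __post_init__(self) -> None:
        tests = [t for _, t in self.folds]
        if len(set(tests)) != len(tests):
            raise InvalidSpecError("a site appears as test set more than once")
        for train, test in self.folds:
            if test in train:
                raise InvalidSpecError(f"site {test} leaks into its training fold")


def loso_folds(table: pd.DataFrame) -> FoldPlan:
    sites = sorted(table["site"].unique())
    if len(sites) < 2:
        raise ValidationError(
            "leave-one-site-out needs >= 2 sites; use a k-fold split instead"
        )
    return FoldPlan(
        folds=[(tuple(s for s in sites if s != t), t) for t in sites]
    )


class SiteNormalizer:
    """Robust site-wise feature normalization.

    Per site and feature, center on the median and scale by the
    interquartile range (each switchable).  At prediction time an unseen
    site's statistics are computed from its own samples (no labels are
    needed); sites with fewer than ``min_site_samples`` rows fall back to
    the training-global statistics.  A zero IQR falls back to a scale of
    1 with a warning.
    """

    def __init__(self, center: bool = True, scale: bool = True,
                 min_site_samples: int = 5) -> None:
        self.center = center
        self.scale = scale
        self.min_site_samples = min_site_samples
        self.site_stats_: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.global_stats_: tuple[np.ndarray, np.ndarray] | None = None
        self.features_: list[str] = []

    @staticmethod
    def _stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        med = np.median(X, axis=0)
        iqr = np.percentile(X, 75, axis=0) - np.percentile(X, 25, axis=0)
        if np.any(iqr == 0):
            warnings.warn("zero IQR for some features; scale falls back to 1",
                          stacklevel=3)
            iqr = np.where(iqr == 0, 1.0, iqr)
        return med, iqr

    def fit(self, table: pd.DataFrame) -> "SiteNormalizer":
        self.features_ = feature_columns(table)
        X = table[self.features_].to_numpy(dtype=float)
        self.global_stats_ = self._stats(X)
        for site, idx in table.groupby("site").groups.items():
            self.site_stats_[site] = self._stats(
                table.loc[idx, self.features_].to_numpy(dtype=float)
            )
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for site, idx in table.groupby("site").groups.items():
            X = table.loc[idx, self.features_].to_numpy(dtype=float)
            if site in self.site_stats_:
                med, iqr = self.site_stats_[site]
            elif len(idx) >= self.min_site_samples:
                med, iqr = self._stats(X)
            else:
                med, iqr = self.global_stats_
            if self.center:
                X = X - med
            if self.scale:
                X = X / iqr
            out.loc[idx, self.features_] = X
        return out


def _site_cv_accuracy(X: np.ndarray, sites: np.ndarray, seed: int,
                      n_estimators: int) -> tuple[float, np.ndarray]:
    """Cross-validated accuracy of an extremely-randomized-trees site
    classifier plus its full-fit feature importances."""
    counts = pd.Series(sites).value_counts()
    n_splits = int(min(3, counts.min(), len(X)))
    clf = ExtraTreesClassifier(n_estimators=n_estimators, random_state=seed)
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, sites):
            clf.fit(X[tr], sites[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == sites[te])))
        acc = float(np.mean(accs))
    else:
        clf.fit(X, sites)
        acc = float(np.mean(clf.predict(X) == sites))
    clf.fit(X, sites)
    return acc, clf.feature_importances_


def site_predictability_elimination(
    table: pd.DataFrame,
    max_removed: int = 14,
    floor_accuracy: float | None = None,
    seed: int = 0,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively remove the feature most predictive of the acquisition
    site until ``max_removed`` features are gone or site-prediction
    accuracy drops to ``floor_accuracy`` (default: chance + 0.05)."""
    sites = table["site"].to_numpy()
    n_sites = len(np.unique(sites))
    if n_sites < 2:
        raise ValidationError("site elimination needs >= 2 sites")
    if floor_accuracy is None:
        floor_accuracy = 1.0 / n_sites + 0.05
    features = feature_columns(table)
    removed: list[str] = []
    while len(removed) < max_removed:
        if len(features) <= 1:
            raise ValidationError("site elimination would remove every feature")
        X = table[features].to_numpy(dtype=float)
        acc, importances = _site_cv_accuracy(X, sites, seed + len(removed),
                                             n_estimators)
        if acc <= floor_accuracy:
            break
        worst = features[int(np.argmax(importances))]
        removed.append(worst)
        features = [f for f in features if f != worst]
    return table[list(META_COLUMNS) + features], removed


def noise_probe_selection(
    table: pd.DataFrame,
    n_probes: int = 5,
    seed: int = 0,
    max_rounds: int = 3,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, list[str]]:
    """Winnow-style selection: append random standard-normal probe
    features, rank everything with extremely-randomized trees against the
    quality label, and drop real features that do not beat the best
    probe.  Iterates up to ``max_rounds`` or until nothing is dropped."""
    features = feature_columns(table)
    if len(features) < 2:
        raise ValidationError("noise-probe selection needs >= 2 features")
    if n_probes == 0:
        return table.copy(), []
    y = _binary_y(table)
    rng = np.random.default_rng(seed)
    removed: list[str] = []
    for _ in range(max_rounds):
        X = table[features].to_numpy(dtype=float)
        probes = rng.standard_normal((len(table), n_probes))
        Xp = np.hstack([X, probes])
        clf = ExtraTreesClassifier(n_estimators=n_estimators,
                                   random_state=int(rng.integers(2**31)))
        clf.fit(Xp, y)
        imp = clf.feature_importances_
        probe_max = imp[len(features):].max()
        drop = [f for f, v in zip(features, imp[: len(features)]) if v <= probe_max]
        if len(drop) == len(features):
            raise ValidationError(
                "noise-probe filter would drop every feature "
                f"(probe importance {probe_max:.4f} dominates)"
            )
        if not drop:
            break
        removed.extend(drop)
        features = [f for f in features if f not in drop]
    return table[list(META_COLUMNS) + features], removed


@dataclass
class FittedModel:
    """A trained classifier together with its frozen preprocessing.

    Carries the feature-name contract, the training-median imputation
    values, the (optional) site normalizer and the surviving feature list
    so that prediction on new tables applies exactly the training-time
    transformations.
    """

    spec: ModelSpec
    feature_names: list[str]
    impute_medians: pd.Series
    normalizer: SiteNormalizer | None
    selected_features: list[str]
    estimator: object
    removed_site_predictive: list[str] = dc_field(default_factory=list)
    removed_low_snr: list[str] = dc_field(default_factory=list)

    def _prepare(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ContractError(f"table lacks trained features: {missing}")
        work = table[list(META_COLUMNS) + self.feature_names].copy()
        work[self.feature_names] = work[self.feature_names].fillna(
            self.impute_medians
        )
        if self.normalizer is not None:
            work = self.normalizer.transform(work)
        return work[self.selected_features].to_numpy(dtype=float)

    def predict_scores(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous scores in [0, 1]: random-forest vote fraction or the
        Platt-calibrated SVC probability of the "exclude" class."""
        X = self._prepare(table)
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, pos_col]

    def predict_labels(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        """Threshold the scores; ties at the threshold go to "accept"."""
        scores = self.predict_scores(table)
        return np.where(scores > threshold, POSITIVE_LABEL, NEGATIVE_LABEL)


def _make_estimator(spec: ModelSpec, seed: int):
    cw = "balanced" if spec.class_weighted else None
    if spec.family == "rfc":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_depth=spec.max_depth,
            min_samples_split=spec.min_samples_split,
            min_samples_leaf=spec.min_leaf,
            class_weight=cw,
            random_state=seed,
        )
    kernel = "linear" if spec.family == "svc_lin" else "rbf"
    return SVC(
        kernel=kernel,
        C=spec.C,
        gamma=spec.gamma if kernel == "rbf" else "scale",
        probability=True,
        class_weight=cw,
        random_state=seed,
    )


def fit_model(train: pd.DataFrame, spec: ModelSpec, seed: int = 0) -> FittedModel:
    """Fit preprocessing (impute -> site-normalize -> site elimination ->
    noise-probe selection, per the spec flags) followed by the classifier.

    Missing feature values are imputed with training medians; class
    weights are inverse class frequencies when ``class_weighted``.
    """
    validate_table(train)
    y = _binary_y(train)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set contains a single class")
    features = feature_columns(train)
    work = train.copy()
    medians = work[features].median()
    work[features] = work[features].fillna(medians)
    normalizer = None
    if spec.norm_center or spec.norm_scale:
        normalizer = SiteNormalizer(center=spec.norm_center, scale=spec.norm_scale)
        normalizer.fit(work)
        work = normalizer.transform(work)
    removed_site: list[str] = []
    if spec.use_site_elimination and work["site"].nunique() >= 2:
        work, removed_site = site_predictability_elimination(work, seed=seed)
    removed_snr: list[str] = []
    if spec.use_noise_probe:
        work, removed_snr = noise_probe_selection(work, seed=seed)
    selected = feature_columns(work)
    est = _make_estimator(spec, seed)
    est.fit(work[selected].to_numpy(dtype=float), y)
    return FittedModel(
        spec=spec,
        feature_names=features,
        impute_medians=medians,
        normalizer=normalizer,
        selected_features=selected,
        estimator=est,
        removed_site_predictive=removed_site,
        removed_low_snr=removed_snr,
    )


def predict(model: FittedModel, table: pd.DataFrame, threshold: float = 0.5):
    """Score and threshold new samples; returns (labels, scores)."""
    scores = model.predict_scores(table)
    labels = np.where(scores > threshold, POSITIVE_LABEL, NEGATIVE_LABEL)
    return labels, scores


@dataclass
class CVResult:
    per_fold: pd.DataFrame
    auc_mean: float
    auc_sd: float
    acc_mean: float
    acc_sd: float
    best_model: ModelSpec
    importances: pd.Series | None = None


def _outer_folds(table: pd.DataFrame, scheme: str, seed: int):
    """Yield (train_index, test_index, fold_name) for the outer loop."""
    if scheme == "loso":
        plan = loso_folds(table)
        for _, test_site in plan.folds:
            mask = (table["site"] == test_site).to_numpy()
            yield np.flatnonzero(~mask), np.flatnonzero(mask), test_site
    elif scheme in ("kfold10", "kfold5"):
        k = 10 if scheme == "kfold10" else 5
        y = _binary_y(table)
        k = int(min(k, np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for i, (tr, te) in enumerate(skf.split(np.zeros(len(table)), y)):
            yield tr, te, f"fold{i}"
    else:
        raise InvalidSpecError(f"unknown split scheme '{scheme}'")


def _score_fold(model: FittedModel, test: pd.DataFrame) -> tuple[float, float]:
    y = _binary_y(test)
    scores = model.predict_scores(test)
    acc = float(np.mean((scores > 0.5).astype(int) == y))
    if len(np.unique(y)) < 2:
        return float("nan"), acc
    return roc_auc(scores, y), acc


def _inner_score(train: pd.DataFrame, spec: ModelSpec, scheme: str, seed: int) -> float:
    aucs = []
    for tr, te, _ in _outer_folds(train, scheme, seed):
        inner_train = train.iloc[tr].reset_index(drop=True)
        inner_test = train.iloc[te].reset_index(drop=True)
        if inner_train["label"].nunique() < 2:
            continue
        model = fit_model(inner_train, spec, seed=seed)
        auc, _ = _score_fold(model, inner_test)
        if np.isfinite(auc):
            aucs.append(auc)
    return float(np.mean(aucs)) if aucs else float("nan")


def nested_cv_select(
    table: pd.DataFrame,
    grid: list[ModelSpec],
    inner_split: str = "kfold5",
    outer_split: str = "loso",
    n_sampled: int = 50,
    seed: int = 0,
) -> CVResult:
    """Nested cross-validation: an inner randomized search of
    ``n_sampled`` grid points selects the best mean-AUC model per outer
    training set; the winner is refit and scored on the outer test fold.

    Outer folds with a single class report accuracy only (AUC is NaN and
    excluded from the mean).  When the grid is smaller than ``n_sampled``
    the search is exhaustive.
    """
    validate_table(table)
    rng = np.random.default_rng(seed)
    if len(grid) > n_sampled:
        candidates = [grid[i] for i in rng.choice(len(grid), n_sampled, replace=False)]
    else:
        candidates = list(grid)
    rows = []
    winners: list[int] = []
    for tr, te, name in _outer_folds(table, outer_split, seed):
        outer_train = table.iloc[tr].reset_index(drop=True)
        outer_test = table.iloc[te].reset_index(drop=True)
        inner_scores = [
            _inner_score(outer_train, spec, inner_split, seed) for spec in candidates
        ]
        best_i = int(np.nanargmax(inner_scores))
        winners.append(best_i)
        model = fit_model(outer_train, candidates[best_i], seed=seed)
        auc, acc = _score_fold(model, outer_test)
        rows.append({"fold": name, "auc": auc, "acc": acc,
                     "selected": best_i})
    per_fold = pd.DataFrame(rows)
    best_spec = candidates[int(np.bincount(winners).argmax())]
    final = fit_model(table, best_spec, seed=seed)
    importances = (
        feature_importances(final) if best_spec.family == "rfc" else None
    )
    aucs = per_fold["auc"].to_numpy()
    return CVResult(
        per_fold=per_fold,
        auc_mean=float(np.nanmean(aucs)),
        auc_sd=float(np.nanstd(aucs)),
        acc_mean=float(per_fold["acc"].mean()),
        acc_sd=float(per_fold["acc"].std(ddof=0)),
        best_model=best_spec,
        importances=importances,
    )


def grid_search_final(
    table: pd.DataFrame,
    grid: list[ModelSpec],
    seed: int = 0,
) -> tuple[ModelSpec, FittedModel, pd.DataFrame]:
    """Exhaustive (non-nested) leave-one-site-out search over the grid;
    the best mean-AUC spec is refit on the full table."""
    if not grid:
        raise InvalidSpecError("empty hyper-parameter grid")
    validate_table(table)
    results = []
    for i, spec in enumerate(grid):
        aucs = []
        for tr, te, _ in _outer_folds(table, "loso", seed):
            train = table.iloc[tr].reset_index(drop=True)
            test = table.iloc[te].reset_index(drop=True)
            if train["label"].nunique() < 2:
                continue
            auc, _ = _score_fold(fit_model(train, spec, seed=seed), test)
            if np.isfinite(auc):
                aucs.append(auc)
        results.append({"spec_index": i, "mean_auc": float(np.mean(aucs)) if aucs else float("nan")})
    table_res = pd.DataFrame(results)
    best_i = int(table_res["mean_auc"].idxmax())
    best = grid[best_i]
    return best, fit_model(table, best, seed=seed), table_res


def permutation_test(
    train: pd.DataFrame,
    test: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Label-permutation significance of the observed test accuracy.

    Both training and test labels are shuffled independently at each
    repetition, the model refit, and the test accuracy recorded.  The
    p-value uses the add-one convention p = (1 + #{perm >= observed}) /
    (1 + n_perm), so its smallest attainable value is 1/(n_perm+1).

    Returns (p_value, observed_accuracy, permuted_accuracies).
    """
    if n_perm < 1:
        raise InvalidSpecError("n_perm must be >= 1")
    model = fit_model(train, spec, seed=seed)
    y_train = _binary_y(train)
    y_test = _binary_y(test)
    observed = float(np.mean(
        (model.predict_scores(test) > 0.5).astype(int) == y_test
    ))
    rng = np.random.default_rng(seed)
    perm_accs = np.empty(n_perm)
    reuse_preproc = not spec.use_noise_probe
    if reuse_preproc:
        # label shuffling leaves the features untouched, so everything up
        # to the estimator can be computed once (the noise-probe filter is
        # the only label-driven preprocessing step)
        Xtr = model._prepare(train)
        Xte = model._prepare(test)
    for i in range(n_perm):
        yp_tr = rng.permutation(y_train)
        yp_te = rng.permutation(y_test)
        if len(np.unique(yp_tr)) < 2:
            # a degenerate shuffle cannot be fit; it scores at chance
            perm_accs[i] = float(np.mean(yp_te == 0))
            continue
        if reuse_preproc:
            est = _make_estimator(spec, seed)
            est.fit(Xtr, yp_tr)
            pos = int(np.flatnonzero(est.classes_ == 1)[0])
            pred = (est.predict_proba(Xte)[:, pos] > 0.5).astype(int)
        else:
            tr = train.copy()
            te = test.copy()
            tr["label"] = np.where(yp_tr == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
            te["label"] = np.where(yp_te == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
            m = fit_model(tr, spec, seed=seed)
            pred = (m.predict_scores(te) > 0.5).astype(int)
        perm_accs[i] = float(np.mean(pred == yp_te))
    p = (1.0 + float(np.sum(perm_accs >= observed))) / (1.0 + n_perm)
    return p, observed, perm_accs


def feature_importances(model: FittedModel) -> pd.Series:
    """Median Gini importance across the trees of a random forest,
    sorted descending over the surviving features."""
    if model.spec.family != "rfc":
        raise InvalidSpecError("feature ranking requires the rfc family")
    per_tree = np.stack([t.feature_importances_ for t in model.estimator.estimators_])
    med = np.median(per_tree, axis=0)
    return pd.Series(med, index=model.selected_features).sort_values(ascending=False)


def default_model_grid(full: bool = False) -> list[ModelSpec]:
    """Default hyper-parameter grid.

    The compact grid (24 points) spans the three families, a few
    regularization / forest-size settings and the preprocessing switches;
    ``full=True`` expands every switch combination into a 512-point grid
    of the same dimensionality for exhaustive final searches.
    """
    specs: list[ModelSpec] = []
    if not full:
        for family in ("rfc", "svc_lin", "svc_rbf"):
            for cw in (True, False):
                for norm in (True, False):
                    for filt in (True, False):
                        specs.append(
                            ModelSpec(
                                family=family,
                                class_weighted=cw,
                                norm_center=norm,
                                norm_scale=norm,
                                use_site_elimination=filt,
                                use_noise_probe=filt,
                            )
                        )
        return specs
    for family, hyper in (
        ("rfc", [dict(n_trees=n, max_depth=d, min_leaf=l)
                 for n in (50, 100) for d in (None, 10) for l in (1, 5)]),
        ("svc_lin", [dict(C=c) for c in (0.1, 1.0, 10.0, 100.0)]),
        ("svc_rbf", [dict(C=c, gamma=g) for c in (1.0, 10.0) for g in (0.01, 0.1)]),
    ):
        for h in hyper:
            for cw in (True, False):
                for center in (True, False):
                    for scale in (True, False):
                        for se in (True, False):
                            for npb in (True, False):
                                specs.append(
                                    ModelSpec(
                                        family=family,
                                        class_weighted=cw,
                                        norm_center=center,
                                        norm_scale=scale,
                                        use_site_elimination=se,
                                        use_noise_probe=npb,
                                        **h,
                                    )
                                )
    return specs
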