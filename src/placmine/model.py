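"""Phenotype prediction from significant omics features.

Four traits are modelled from the significant-feature matrix: case/control
group (classification, accuracy), and premature birth (39 - gestational
age in weeks), birth-weight Z and head-circumference Z (regression,
Pearson r).  The workflow is: stratified 2/3 train / 1/3 test split,
column standardization on the training samples, SMOTE oversampling of the
minority stratum on the training side only, grid-search cross-validated
support-vector models, evaluation on the untouched test set, and
permutation feature importance expressed as percent of the maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

__all__ = [
    "TraitSpec",
    "TRAITS",
    "derive_traits",
    "zscore_from_reference",
    "select_features",
    "stratified_split",
    "smote_augment",
    "train_trait_model",
    "evaluate_model",
    "permutation_importance",
    "FittedTraitModel",
    "TraitModelResult",
    "run_trait_models",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitSpec:
    name: str
    task: str    # "classification" | "regression"
    metric: str  # "accuracy" | "pearson_r"


TRAITS = (
    TraitSpec("group", "classification", "accuracy"),
    TraitSpec("premature_birth", "regression", "pearson_r"),
    TraitSpec("birth_weight_z", "regression", "pearson_r"),
    TraitSpec("head_circumference_z", "regression", "pearson_r"),
)

TERM_WEEKS = 39.0


def zscore_from_reference(values, ga, sex, reference: pd.DataFrame) -> np.ndarray:
    """Growth Z-scores from a reference table of columns
    (gestational_age, sex, mean, sd), linearly interpolated in
    gestational age within each sex."""
    values = np.asarray(values, dtype=float)
    ga = np.asarray(ga, dtype=float)
    sex = np.asarray(sex)
    out = np.empty_like(values)
    for s in np.unique(sex):
        ref = reference[reference["sex"] == s].sort_values("gestational_age")
        if ref.empty:
            raise ValueError(f"reference table has no rows for sex {s!r}")
        g = ga[sex == s]
        lo, hi = ref["gestational_age"].min(), ref["gestational_age"].max()
        bad = (g < lo) | (g > hi)
        if bad.any():
            idx = np.where(sex == s)[0][bad]
            raise ValueError(
                f"gestational age outside reference range for sample index {idx.tolist()}"
            )
        mean = np.interp(g, ref["gestational_age"], ref["mean"])
        sd = np.interp(g, ref["gestational_age"], ref["sd"])
        out[sex == s] = (values[sex == s] - mean) / sd
    return out


def derive_traits(
    phenotypes: pd.DataFrame,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add the derived trait columns.

    ``premature_birth`` is exactly 39 - gestational age (values > 2
    pre-term, <= -3 post-term).  If Z-score columns are absent they are
    derived from raw columns (``birth_weight_g`` / ``head_circumference_cm``
    plus ``sex``) against the supplied growth reference table.
    """
    out = phenotypes.copy()
    if "gestational_age" not in out:
        raise ValueError("phenotype table lacks gestational_age")
    out["premature_birth"] = TERM_WEEKS - out["gestational_age"].astype(float)
    for zcol, raw in (
        ("birth_weight_z", "birth_weight_g"),
        ("head_circumference_z", "head_circumference_cm"),
    ):
        if zcol not in out:
            if reference is None or raw not in out or "sex" not in out:
                raise ValueError(
                    f"{zcol} absent: supply it directly or provide {raw!r}, 'sex' "
                    "and a growth reference table"
                )
            out[zcol] = zscore_from_reference(
                out[raw], out["gestational_age"], out["sex"], reference
            )
    for zcol in ("birth_weight_z", "head_circumference_z"):
        if not np.isfinite(out[zcol].astype(float)).all():
            raise ValueError(f"non-finite values in {zcol}")
    return out


def select_features(*stats_tables: pd.DataFrame) -> list[str]:
    """Union of features flagged significant across the per-layer screens,
    in deterministic (table, then row) order."""
    selected: list[str] = []
    seen = set()
    for tbl in stats_tables:
        for f in tbl.index[tbl["significant"]]:
            if f not in seen:
                seen.add(f)
                selected.append(f)
    if not selected:
        raise ValueError(
            "no significant features selected; review the Levene/q thresholds"
        )
    return selected


def stratified_split(
    sample_ids,
    groups,
    ratio: float = 2 / 3,
    seed: int = 0,
) -> tuple[list, list]:
    """Per-group train/test partition.

    Each group contributes ``floor(n * ratio + 0.5)`` samples to the
    training set (nearest-integer rounding), the rest to the test set.
    Deterministic given the seed; errors if any group has a single sample
    or either side of the split comes out empty.
    """
    sample_ids = np.asarray(sample_ids)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for g in np.unique(groups):
        members = sample_ids[groups == g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        members = members[rng.permutation(len(members))]
        n_train = int(np.floor(len(members) * ratio + 0.5))
        train.extend(members[:n_train].tolist())
        test.extend(members[n_train:].tolist())
    if not train or not test:
        raise ValueError("degenerate split: empty train or test set")
    return train, test


def smote_augment(
    X: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    target_balance: float = 1.0,
):
    """Synthetic minority oversampling.

    Classification: ``strata`` defaults to ``y``; synthetic samples are
    drawn for the minority class as x + lambda * (x_nn - x) with
    lambda ~ U(0,1) and x_nn one of x's ``k`` nearest minority neighbours
    (Euclidean), until minority size reaches ``target_balance`` times the
    majority size.  Continuous targets: pass the group labels as
    ``strata``; the target value is interpolated with the same lambda.
    Returns (X_aug, y_aug, strata_aug).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    strata = y if strata is None else np.asarray(strata)
    classes, counts = np.unique(strata, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE here expects exactly two strata")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority stratum needs at least 2 samples")
    n_new = int(round(target_balance * n_maj)) - n_min
    if n_new <= 0:
        return X, y, strata
    if k >= n_min:
        log.warning("SMOTE k=%d >= minority size %d; lowering to %d", k, n_min, n_min - 1)
        k = n_min - 1
    rng = np.random.default_rng(seed)
    idx_min = np.where(strata == minority)[0]
    Xm = X[idx_min]
    d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :k]
    base = rng.integers(0, len(idx_min), n_new)
    pick = nn[base, rng.integers(0, k, n_new)]
    lam = rng.random(n_new)
    X_new = Xm[base] + lam[:, None] * (Xm[pick] - Xm[base])
    ym = y[idx_min]
    if np.issubdtype(y.dtype, np.number):
        y_new = ym[base] + lam * (ym[pick] - ym[base])
    else:
        y_new = ym[base]
    X_aug = np.vstack([X, X_new])
    y_aug = np.concatenate([y, y_new])
    strata_aug = np.concatenate([strata, np.full(n_new, minority, dtype=strata.dtype)])
    return X_aug, y_aug, strata_aug


def default_grid(task: str) -> list[dict]:
    """Compact default hyperparameter grid for the SVM inner solver."""
    grid = []
    for kernel in ("linear", "rbf"):
        for C in (0.1, 1.0, 10.0, 100.0):
            point = {"kernel": kernel, "C": C}
            if task == "regression":
                for eps in (0.1, 0.5):
                    grid.append({**point, "epsilon": eps})
            else:
                grid.append(point)
    return grid


@dataclass
class FittedTraitModel:
    trait: TraitSpec
    estimator: object
    best_params: dict
    cv_scores: pd.DataFrame
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    features: list[str] = field(default_factory=list)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_sd


def _make_estimator(trait: TraitSpec, params: dict, seed: int,
                    calibrated: bool = False, cv: int = 5):
    """SVM inner solver.  For classification the final refit wraps the SVC
    in a sigmoid calibrator so class probabilities are available."""
    if trait.task == "classification":
        svc = SVC(random_state=seed, gamma="scale", **params)
        if calibrated:
            return CalibratedClassifierCV(svc, method="sigmoid", cv=cv,
                                          ensemble=False)
        return svc
    return SVR(gamma="scale", **params)


def _score(trait: TraitSpec, y_true: np.ndarray, y_pred: np.ndarray) -> float:
    if trait.metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return -np.inf
    return float(sps.pearsonr(y_true, y_pred).statistic)


def train_trait_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    trait: TraitSpec,
    grid: list[dict] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Grid-search cross-validation over the SVM hyperparameter grid.

    Folds are stratified on the labels for classification, plain shuffled
    k-fold for regression.  Returns the winning grid point (ties broken by
    grid order) and the per-point mean CV score table; the caller refits
    on the full training set.
    """
    if grid is None:
        grid = default_grid(trait.task)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if trait.task == "classification":
        _, counts = np.unique(y_train, return_counts=True)
        folds = max(2, min(cv_folds, counts.min()))
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X_train, y_train))
    else:
        folds = max(2, min(cv_folds, len(y_train)))
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X_train))
    rows = []
    for params in grid:
        scores = []
        for tr, va in split_iter:
            est = _make_estimator(trait, params, seed)
            est.fit(X_train[tr], y_train[tr])
            scores.append(_score(trait, y_train[va], est.predict(X_train[va])))
        rows.append({**params, "cv_score": float(np.mean(scores))})
    table = pd.DataFrame(rows)
    best = grid[int(np.argmax(table["cv_score"].to_numpy()))]
    return best, table


def evaluate_model(model: FittedTraitModel, X_test, y_test) -> "TraitModelResult":
    """Metric on the untouched test set.

    Classification: accuracy plus per-sample case probabilities.
    Regression: Pearson r with its two-sided p (flagged undefined for
    constant predictions).
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    Xs = model.transform(X_test)
    pred = model.estimator.predict(Xs)
    trait = model.trait
    proba = None
    p_value = np.nan
    defined = True
    if trait.task == "classification":
        metric = float(np.mean(pred == y_test))
        prob_mat = model.estimator.predict_proba(Xs)
        case_col = list(model.estimator.classes_).index("case") if "case" in model.estimator.classes_ else 1
        proba = prob_mat[:, case_col]
    else:
        if np.std(pred) < 1e-10 or np.std(y_test) < 1e-10:
            metric, p_value, defined = np.nan, np.nan, False
        else:
            r = sps.pearsonr(y_test, pred)
            metric, p_value = float(r.statistic), float(r.pvalue)
    return TraitModelResult(
        trait=trait,
        best_params=model.best_params,
        metric=metric,
        p_value=p_value,
        defined=defined,
        predictions=pred,
        probabilities=proba,
        y_test=y_test,
    )


@dataclass
class TraitModelResult:
    trait: TraitSpec
    best_params: dict
    metric: float
    p_value: float
    defined: bool
    predictions: np.ndarray
    probabilities: np.ndarray | None
    y_test: np.ndarray
    importance: pd.DataFrame | None = None


def permutation_importance(
    model: FittedTraitModel,
    X_test,
    y_test,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance on the test set.

    importance_j = mean over repeats of (baseline metric - metric with
    feature j's test column shuffled); negatives are floored at zero and
    rescaled to percent of the maximum (all-zero importances stay zero).
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(y_test) < 2:
        raise ValueError("need more than one test sample")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    trait = model.trait
    Xs = model.transform(X_test)
    baseline = _score(trait, y_test, model.estimator.predict(Xs))
    if not np.isfinite(baseline):
        baseline = 0.0
    rng = np.random.default_rng(seed)
    n_feat = Xs.shape[1]
    raw = np.zeros(n_feat)
    for j in range(n_feat):
        drops = []
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[:, j] = Xp[rng.permutation(len(y_test)), j]
            s = _score(trait, y_test, model.estimator.predict(Xp))
            if not np.isfinite(s):
                s = 0.0
            drops.append(baseline - s)
        raw[j] = np.mean(drops)
    floored = np.maximum(raw, 0.0)
    top = floored.max()
    percent = 100.0 * floored / top if top > 0 else np.zeros(n_feat)
    features = model.features or [f"f{j}" for j in range(n_feat)]
    return pd.DataFrame(
        {"raw": raw, "percent": percent},
        index=pd.Index(features, name="feature"),
    )


def run_trait_models(
    features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    traits: tuple[TraitSpec, ...] = TRAITS,
    ratio: float = 2 / 3,
    smote_k: int = 5,
    cv_folds: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> dict[str, TraitModelResult]:
    """Full model stage on a features x samples matrix.

    One shared stratified split serves all four traits.  Standardization
    uses training-sample statistics only; SMOTE sees only training data;
    the test set is never modified.
    """
    pheno = derive_traits(phenotypes)
    samples = list(features.columns)
    groups = pheno.loc[samples, "group"].to_numpy()
    train_ids, test_ids = stratified_split(samples, groups, ratio=ratio, seed=seed)
    X = features.T  # samples x features
    X_train = X.loc[train_ids].to_numpy(dtype=float)
    X_test = X.loc[test_ids].to_numpy(dtype=float)
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xs_train = (X_train - mean) / sd
    g_train = pheno.loc[train_ids, "group"].to_numpy()

    results: dict[str, TraitModelResult] = {}
    for i, trait in enumerate(traits):
        sub_seed = int((seed * 1000 + i) % 2_147_483_647)
        y_train = pheno.loc[train_ids, trait.name].to_numpy()
        y_test = pheno.loc[test_ids, trait.name].to_numpy()
        strata = y_train if trait.task == "classification" else g_train
        Xa, ya, _ = smote_augment(
            Xs_train, y_train, strata=strata, k=smote_k, seed=sub_seed
        )
        best, cv_table = train_trait_model(
            Xa, ya, trait, grid=grid, cv_folds=cv_folds, seed=sub_seed
        )
        if trait.task == "classification":
            _, cal_counts = np.unique(ya, return_counts=True)
            est = _make_estimator(trait, best, sub_seed, calibrated=True,
                                  cv=max(2, min(5, cal_counts.min())))
        else:
            est = _make_estimator(trait, best, sub_seed)
        est.fit(Xa, ya)
        fitted = FittedTraitModel(
            trait=trait,
            estimator=est,
            best_params=best,
            cv_scores=cv_table,
            scaler_mean=mean,
            scaler_sd=sd,
            features=list(features.index),
        )
        res = evaluate_model(fitted, X_test, y_test)
        res.importance = permutation_importance(
            fitted, X_test, y_test, n_repeats=n_repeats, seed=sub_seed
        )
        results[trait.name] = res
    return results
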