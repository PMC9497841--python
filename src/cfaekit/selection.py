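"""Feature assembly, redundancy filtering, relevance ranking, coarse trees.

A patient-level feature matrix (index x recording site, 24 columns for the
full four-index, six-site design) feeds: a correlation filter that greedily
drops the most redundant member of every highly correlated pair
(|r| > 0.60 by default); a Random-Forest Gini-importance ranking rescaled to
0-100 with a score > 40 selection rule; and shallow "coarse" decision trees
(Gini criterion, at most 4 splits) evaluated with leave-one-patient-out
cross-validation, exhaustively over feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier, export_text
from sklearn.utils.validation import check_is_fitted, check_X_y

from .synthetic import SITES

INDEX_NAMES = ("SE", "DET", "AFCL", "DF")
LABEL_CODES = {"ParAF": 0, "PerAF": 1}
MAX_SUBSET_FEATURES = 12


@dataclass(frozen=True)
class SelectionConfig:
    """corr_cutoff: absolute-correlation redundancy threshold; importance_cutoff:
    RF score (0-100 scale) a feature must exceed; n_trees: forest size."""

    corr_cutoff: float = 0.60
    importance_cutoff: float = 40.0
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.corr_cutoff < 1):
            raise ValueError("corr_cutoff must lie in (0, 1)")
        if not (0 <= self.importance_cutoff <= 100):
            raise ValueError("importance_cutoff must lie in [0, 100]")


def build_feature_matrix(
    seg_table: pd.DataFrame,
    rec_table: pd.DataFrame,
    w: int,
    sites: tuple[str, ...] = SITES,
    use_discards: bool = True,
) -> pd.DataFrame:
    """One row per patient; columns ``<INDEX><SITE>`` plus integer ``TYPE``
    (0 = ParAF, 1 = PerAF).

    SE/DET are the mean over usable segments of length ``w`` in each
    recording; AFCL/DF come from the 16 s computation. Missing cells are NaN,
    never imputed. Patients missing every site are dropped.
    """
    t = seg_table[seg_table["w"] == w]
    if use_discards:
        t = t[t["quality"] == 1]
    se_det = t.groupby(["patient_id", "site"])[["SE", "DET"]].mean()
    rec = rec_table.set_index(["patient_id", "site"])[["AFCL_ms", "DF_Hz"]]
    patients = sorted(
        set(seg_table["patient_id"]),
        key=lambda p: (LABEL_CODES[_af_of(seg_table, p)], p),
    )
    cols = [f"{idx}{site}" for idx in INDEX_NAMES for site in sites]
    data = {}
    for pid in patients:
        row = {}
        for site in sites:
            sd = se_det.loc[(pid, site)] if (pid, site) in se_det.index else None
            rc = rec.loc[(pid, site)] if (pid, site) in rec.index else None
            row[f"SE{site}"] = float(sd["SE"]) if sd is not None else float("nan")
            row[f"DET{site}"] = float(sd["DET"]) if sd is not None else float("nan")
            row[f"AFCL{site}"] = float(rc["AFCL_ms"]) if rc is not None else float("nan")
            row[f"DF{site}"] = float(rc["DF_Hz"]) if rc is not None else float("nan")
        if all(np.isnan(v) for v in row.values()):
            continue
        row["TYPE"] = LABEL_CODES[_af_of(seg_table, pid)]
        data[pid] = row
    fm = pd.DataFrame.from_dict(data, orient="index")[cols + ["TYPE"]]
    fm.index.name = "patient_id"
    return fm


def _af_of(table: pd.DataFrame, pid: str) -> str:
    return table.loc[table["patient_id"] == pid, "af_type"].iloc[0]


def averaged_correlation_matrix(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of the Pearson correlation matrices of the per-window
    feature matrices (label column included if present). Constant columns give
    NaN rows/columns — flagged by construction, never silently filled."""
    if not matrices:
        raise ValueError("no matrices")
    cols = list(matrices[0].columns)
    for m in matrices[1:]:
        if list(m.columns) != cols:
            raise ValueError("matrices must share columns")
    corrs = []
    for m in matrices:
        c = np.corrcoef(m.to_numpy(dtype=float), rowvar=False)
        corrs.append(c)
    avg = np.mean(corrs, axis=0)
    return pd.DataFrame(avg, index=cols, columns=cols)


class CorrelationFilter(TransformerMixin, BaseEstimator):
    """Greedy redundancy filter on absolute Pearson correlation.

    While any remaining pair exceeds ``cutoff`` in |r|, the member of the most
    correlated pair with the larger mean absolute correlation to all other
    remaining variables is dropped (ties: the later column goes). Fitting on a
    precomputed (averaged) correlation matrix is supported via
    :meth:`fit_from_corr`.

    Fitted attributes: ``support_`` (bool mask), ``retained_`` (column names
    when fitted from a DataFrame/corr matrix).
    """

    def __init__(self, cutoff: float = 0.60):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        corr = pd.DataFrame(
            np.corrcoef(X.to_numpy(dtype=float), rowvar=False),
            index=X.columns,
            columns=X.columns,
        )
        return self.fit_from_corr(corr)

    def fit_from_corr(self, corr: pd.DataFrame):
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must lie in (0, 1)")
        corr = pd.DataFrame(corr)
        cols = list(corr.columns)
        a = np.abs(corr.to_numpy(dtype=float).copy())
        np.fill_diagonal(a, 0.0)
        alive = np.ones(len(cols), dtype=bool)
        while True:
            sub = np.where(alive[:, None] & alive[None, :], a, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] <= self.cutoff or not np.isfinite(sub[i, j]):
                break
            mean_i = sub[i, alive].sum() / max(alive.sum() - 1, 1)
            mean_j = sub[j, alive].sum() / max(alive.sum() - 1, 1)
            # drop the one more correlated with everything else; tie -> later column
            drop = (j if mean_j >= mean_i else i) if i < j else (i if mean_i >= mean_j else j)
            alive[drop] = False
        self.support_ = alive
        self.retained_ = [c for c, keep in zip(cols, alive) if keep]
        self.n_features_in_ = len(cols)
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]


def correlation_filter(corr: pd.DataFrame, cfg: SelectionConfig = SelectionConfig()) -> list[str]:
    """Column names retained after greedy |r| > cutoff elimination."""
    return CorrelationFilter(cutoff=cfg.corr_cutoff).fit_from_corr(corr).retained_


class GiniImportanceRanker(TransformerMixin, BaseEstimator):
    """Random-Forest mean-decrease-Gini ranking rescaled so max = 100.

    Features with ``scores_ > importance_cutoff`` form the selection
    (``support_``). Seeded for determinism.
    """

    def __init__(self, n_trees: int = 500, importance_cutoff: float = 40.0, random_state: int = 0):
        self.n_trees = n_trees
        self.importance_cutoff = importance_cutoff
        self.random_state = random_state

    def fit(self, X, y):
        Xdf = pd.DataFrame(X)
        Xa, ya = check_X_y(Xdf.to_numpy(dtype=float), np.asarray(y))
        if len(np.unique(ya)) < 2:
            raise ValueError("need both classes to rank features")
        # all features considered at every split: tree diversity comes from the
        # bootstrap alone, so a dominant feature is never displaced by the
        # feature-subsampling lottery and noise importances stay near zero
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features=None,
            random_state=self.random_state,
        ).fit(Xa, ya)
        imp = forest.feature_importances_
        top = imp.max()
        self.scores_ = 100.0 * imp / top if top > 0 else np.zeros_like(imp)
        self.support_ = self.scores_ > self.importance_cutoff
        self.feature_names_in_ = np.asarray(list(Xdf.columns))
        self.n_features_in_ = Xa.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return pd.DataFrame(X).loc[:, self.support_]

    def ranking_table(self) -> pd.DataFrame:
        check_is_fitted(self, "scores_")
        return (
            pd.DataFrame({"feature": self.feature_names_in_, "score": self.scores_})
            .sort_values("score", ascending=False, kind="stable")
            .reset_index(drop=True)
        )


def rf_rank(features: pd.DataFrame, labels, cfg: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """0-100 Gini-importance scores, sorted descending."""
    return GiniImportanceRanker(
        n_trees=cfg.n_trees, importance_cutoff=cfg.importance_cutoff, random_state=cfg.seed
    ).fit(features, labels).ranking_table()


class CoarseTreeClassifier(ClassifierMixin, BaseEstimator):
    """Shallow Gini decision tree capped at ``max_splits`` internal splits.

    The "coarse tree" of interpretable-toolbox parlance: a
    ``DecisionTreeClassifier`` with ``max_leaf_nodes = max_splits + 1``.
    """

    def __init__(self, max_splits: int = 4, random_state: int = 0):
        self.max_splits = max_splits
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), np.asarray(y))
        self.tree_ = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=self.max_splits + 1,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.tree_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict(np.asarray(X, dtype=float))

    @property
    def n_splits_(self) -> int:
        check_is_fitted(self, "tree_")
        return int((self.tree_.tree_.children_left >= 0).sum())

    def describe(self, feature_names=None) -> str:
        check_is_fitted(self, "tree_")
        return export_text(self.tree_, feature_names=list(feature_names) if feature_names is not None else None)


def coarse_tree_fit(features: pd.DataFrame, labels, random_state: int = 0) -> CoarseTreeClassifier:
    """Fit a coarse tree (Gini, <= 4 splits) on a feature subset."""
    if pd.DataFrame(features).shape[1] == 0:
        raise ValueError("empty feature subset")
    return CoarseTreeClassifier(random_state=random_state).fit(
        pd.DataFrame(features).to_numpy(dtype=float), labels
    )


@dataclass
class ModelResult:
    """A fitted subset model: features, per-fold LOPO predictions, accuracy %
    and a text description of the tree refit on all patients."""

    features: tuple[str, ...]
    accuracy: float
    predictions: pd.DataFrame = field(repr=False)
    tree_description: str = field(repr=False, default="")


def lopo_accuracy(
    features: pd.DataFrame,
    labels,
    patient_ids,
    random_state: int = 0,
    return_predictions: bool = False,
):
    """Leave-one-patient-out accuracy (%) of a coarse tree.

    One fold per patient; the tree is refit on the remaining patients each
    fold, and every row of the held-out patient is scored. Folds whose
    training part degenerates to a single class are flagged (prediction kept,
    ``degenerate_fold=True``).
    """
    X = pd.DataFrame(features).to_numpy(dtype=float)
    y = np.asarray(labels)
    pids = np.asarray(patient_ids)
    unique = list(dict.fromkeys(pids))
    if len(unique) < 3:
        raise ValueError("need >= 3 patients for leave-one-patient-out")
    records = []
    base = CoarseTreeClassifier(random_state=random_state)
    for pid in unique:
        test = pids == pid
        train = ~test
        assert not np.any(pids[train] == pid), "fold leakage: test patient in training"
        degenerate = len(np.unique(y[train])) < 2
        if degenerate:
            pred = np.full(test.sum(), np.bincount(y[train].astype(int)).argmax())
        else:
            pred = clone(base).fit(X[train], y[train]).predict(X[test])
        for yi, pi in zip(y[test], pred):
            records.append({"patient_id": pid, "true": int(yi), "pred": int(pi), "degenerate_fold": degenerate})
    preds = pd.DataFrame(records)
    acc = float(100.0 * (preds["true"] == preds["pred"]).mean())
    return (acc, preds) if return_predictions else acc


def subset_search(
    features: pd.DataFrame, labels, patient_ids, random_state: int = 0
) -> tuple[ModelResult, pd.DataFrame]:
    """Exhaustive LOPO evaluation of every non-empty feature subset.

    Best model: highest accuracy, ties broken by smaller subset then by
    column order (the minimal set is considered optimal). Refuses more than
    12 candidate features (4095 subsets) — prune with the correlation filter
    and the importance ranking first.
    """
    features = pd.DataFrame(features)
    cols = list(features.columns)
    k = len(cols)
    if k == 0:
        raise ValueError("no candidate features")
    if k > MAX_SUBSET_FEATURES:
        raise ValueError(
            f"{k} features -> {2**k - 1} subsets; reduce to <= {MAX_SUBSET_FEATURES} "
            "with the correlation filter and importance ranking first"
        )
    rows = []
    best = None  # (-acc, size, order, subset)
    for size in range(1, k + 1):
        for subset in combinations(range(k), size):
            names = tuple(cols[i] for i in subset)
            acc = lopo_accuracy(features.iloc[:, list(subset)], labels, patient_ids, random_state)
            rows.append({"features": "+".join(names), "n_features": size, "accuracy_pct": acc})
            key = (-acc, size, subset)
            if best is None or key < best[0]:
                best = (key, names, list(subset))
    table = pd.DataFrame(rows)
    _, names, idx = best
    acc, preds = lopo_accuracy(
        features.iloc[:, idx], labels, patient_ids, random_state, return_predictions=True
    )
    tree = coarse_tree_fit(features.iloc[:, idx], labels, random_state)
    result = ModelResult(
        features=names,
        accuracy=acc,
        predictions=preds,
        tree_description=tree.describe(names),
    )
    return result, table


def single_feature_accuracies(
    features: pd.DataFrame, labels, patient_ids, random_state: int = 0
) -> pd.DataFrame:
    """LOPO accuracy of a one-feature coarse tree per feature, sorted
    descending. Run on the full unfiltered feature set."""
    features = pd.DataFrame(features)
    rows = [
        {
            "feature": col,
            "accuracy_pct": lopo_accuracy(features[[col]], labels, patient_ids, random_state),
        }
        for col in features.columns
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("accuracy_pct", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
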