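"""Leave-one-study-out prediction of shared species / transmitted strains in
infants from maternal species profiles.

For each admissible target (a species whose shared/non-shared labels show
both classes in every study) a classifier — random forest with 1000 trees, or
stochastic gradient boosting (depth 1, 100 trees, shrinkage 0.1, minimum 5
observations per leaf) — is trained on the pooled maternal delivery-window
profiles of all studies but one and scored on the held-out study by
rank-based AUC.  Feature filtering (near-zero variance, then pairwise
correlation) is fitted on the training fold only, so nothing about the
held-out study leaks into model selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier

logger = logging.getLogger("dyadshare")


@dataclass
class PredictionTask:
    """One binary target: does the dyad share the target feature?"""

    target_id: str
    features: pd.DataFrame      # dyads x maternal species abundances
    labels: pd.Series           # 1 shared / 0 not, indexed by dyad
    study: pd.Series            # study per dyad

    def admissible(self) -> bool:
        """Both label classes present within every study."""
        counts = pd.crosstab(self.study, self.labels)
        return counts.shape[1] == 2 and (counts > 0).all().all()


@dataclass
class PredictionResult:
    target_id: str
    held_out_study: str
    model: str
    auc: float
    n_train: int
    n_test: int
    importances: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Feature filters (caret nearZeroVar / findCorrelation semantics)
# ---------------------------------------------------------------------------

def near_zero_variance_filter(features: pd.DataFrame, freq_cut: float = 95 / 5,
                              unique_cut: float = 0.10) -> list[str]:
    """Columns retained after removing zero- and near-zero-variance features.

    A feature is near-zero-variance when the frequency ratio of its two most
    common values exceeds ``freq_cut`` AND its fraction of unique values is
    below ``unique_cut``.
    """
    keep = []
    n = len(features)
    for col in features.columns:
        v = features[col]
        counts = v.value_counts()
        if len(counts) == 1:
            continue  # zero variance
        ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = len(counts) / n
        if ratio > freq_cut and pct_unique < unique_cut:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("all features removed by near-zero-variance filter")
    return keep


def correlation_filter(features: pd.DataFrame, cutoff: float = 0.90) -> list[str]:
    """Greedy removal of highly correlated features.

    Repeatedly takes the remaining pair with the largest |Pearson r| above
    ``cutoff`` and drops the member with the larger mean absolute correlation
    to all other remaining features; ties drop the lexicographically later
    feature.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    with np.errstate(invalid="ignore"):
        corr = features.corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)
    active = set(cols)
    while True:
        sub = corr.loc[sorted(active), sorted(active)]
        idx = np.unravel_index(np.argmax(sub.values), sub.shape)
        if sub.values[idx] <= cutoff:
            break
        a, b = sub.index[idx[0]], sub.columns[idx[1]]
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        active.discard(drop)
        if len(active) < 2:
            break
    return [c for c in cols if c in active]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    Returns NaN with a warning when only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("AUC undefined: single-class labels")
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# Task construction
# ---------------------------------------------------------------------------

def build_tasks(
    dyad_shared: pd.DataFrame,
    maternal_table,
    pairing: pd.DataFrame,
    metadata: pd.DataFrame,
    targets,
    require_admissible: bool = True,
) -> dict[str, PredictionTask]:
    """Assemble per-target tasks from dyad-level sharing and maternal profiles.

    ``dyad_shared`` holds (dyad_id, feature_id) rows (sharing at any infant
    timepoint); the feature matrix takes the mother's delivery-window sample
    per dyad.  Targets whose labels are single-class in some study are
    dropped when ``require_admissible``.
    """
    mother_sample = pairing.drop_duplicates("dyad_id").set_index("dyad_id")["mother_sample"]
    dyads = sorted(mother_sample.index)
    feats = maternal_table.values[[mother_sample[d] for d in dyads]].T
    feats.index = dyads
    study = metadata.drop_duplicates("dyad_id").set_index("dyad_id")["study_id"].loc[dyads]
    shared_sets = dyad_shared.groupby("dyad_id")["feature_id"].agg(set)
    tasks = {}
    for target in targets:
        labels = pd.Series(
            [1 if target in shared_sets.get(d, set()) else 0 for d in dyads],
            index=dyads, name=target)
        task = PredictionTask(target, feats, labels, study)
        if require_admissible and not task.admissible():
            logger.info("target %s inadmissible (single-class study)", target)
            continue
        tasks[target] = task
    return tasks


# ---------------------------------------------------------------------------
# Models and evaluation
# ---------------------------------------------------------------------------

def _make_model(model: str, seed: int, n_trees: int = 1000):
    if model == "rf":
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                      n_jobs=1)
    if model == "gbm":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=1, learning_rate=0.1,
            min_samples_leaf=5, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _filter_columns(X: pd.DataFrame, corr_cutoff: float = 0.90) -> list[str]:
    cols = near_zero_variance_filter(X)
    return correlation_filter(X[cols], cutoff=corr_cutoff)


def loso_evaluate(
    tasks: dict[str, PredictionTask],
    model: str = "rf",
    seeds=(0, 1, 2, 3, 4),
    n_trees: int = 1000,
    pooled_filter: bool = False,
    corr_cutoff: float = 0.90,
) -> list[PredictionResult]:
    """One AUC per (target, held-out study), averaged over seeds.

    Feature filters run on the training fold by default; ``pooled_filter``
    fits them once on the pooled matrix instead (no label leakage, but the
    held-out study's marginals inform the filter).
    """
    results = []
    for target, task in sorted(tasks.items()):
        pooled_cols = _filter_columns(task.features, corr_cutoff) if pooled_filter else None
        for study in sorted(task.study.unique()):
            test = task.study == study
            y_tr, y_te = task.labels[~test], task.labels[test]
            if y_te.nunique() < 2 or y_tr.nunique() < 2:
                results.append(PredictionResult(target, study, model, float("nan"),
                                                int((~test).sum()), int(test.sum())))
                continue
            cols = pooled_cols or _filter_columns(task.features.loc[~test], corr_cutoff)
            X_tr = task.features.loc[~test, cols].values
            X_te = task.features.loc[test, cols].values
            aucs, imps = [], []
            for seed in seeds:
                clf = _make_model(model, seed, n_trees)
                clf.fit(X_tr, y_tr.values)
                scores = clf.predict_proba(X_te)[:, 1]
                aucs.append(auc(scores, y_te.values))
                if hasattr(clf, "feature_importances_"):
                    imps.append(clf.feature_importances_)
            importances = pd.Series(np.mean(imps, axis=0), index=cols) if imps else None
            results.append(PredictionResult(
                target, study, model, float(np.mean(aucs)),
                int((~test).sum()), int(test.sum()), importances))
    return results


def results_matrix(results: list[PredictionResult]) -> pd.DataFrame:
    """Pivot LOSO results into a targets x held-out-study AUC matrix."""
    rows = [{"target_id": r.target_id, "held_out_study": r.held_out_study,
             "auc": r.auc} for r in results]
    return pd.DataFrame(rows).pivot(index="target_id", columns="held_out_study",
                                    values="auc")


def gini_top_k_curve(
    task: PredictionTask,
    ks=(1, 2, 5, 10, 20),
    seeds=(0, 1, 2),
    n_trees: int = 1000,
    corr_cutoff: float = 0.90,
) -> pd.DataFrame:
    """AUC after retraining on the top-k features by mean decrease in GINI.

    Importances are ranked on the training fold of each LOSO split; ``k``
    larger than the available feature count is capped with a log message.
    Returns the per-(k, held-out study) mean AUC over seeds plus the top-1
    feature name per fold.
    """
    rows = []
    for study in sorted(task.study.unique()):
        test = task.study == study
        y_tr, y_te = task.labels[~test], task.labels[test]
        if y_te.nunique() < 2 or y_tr.nunique() < 2:
            continue
        cols = _filter_columns(task.features.loc[~test], corr_cutoff)
        X_tr = task.features.loc[~test, cols]
        X_te = task.features.loc[test, cols]
        rank_clf = _make_model("rf", seeds[0], n_trees)
        rank_clf.fit(X_tr.values, y_tr.values)
        order = pd.Series(rank_clf.feature_importances_, index=cols) \
            .sort_values(ascending=False)
        for k in ks:
            kk = min(k, len(cols))
            if kk < k:
                logger.info("top-k curve: k=%d capped to %d features", k, kk)
            top = list(order.index[:kk])
            aucs = []
            for seed in seeds:
                clf = _make_model("rf", seed, n_trees)
                clf.fit(X_tr[top].values, y_tr.values)
                aucs.append(auc(clf.predict_proba(X_te[top].values)[:, 1], y_te.values))
            rows.append({"held_out_study": study, "k": kk,
                         "auc": float(np.mean(aucs)), "top_feature": order.index[0]})
    return pd.DataFrame(rows, columns=["held_out_study", "k", "auc", "top_feature"])


def stratified_evaluate(
    tasks: dict[str, PredictionTask],
    metadata: pd.DataFrame,
    stratum: str = "delivery_mode",
    model: str = "rf",
    seeds=(0, 1, 2, 3, 4),
    n_trees: int = 1000,
) -> dict[str, list[PredictionResult]]:
    """Independent LOSO runs per stratum (e.g. delivery mode).

    Strata or folds lacking both classes yield NaN AUCs.
    """
    dyad_stratum = metadata.drop_duplicates("dyad_id").set_index("dyad_id")[stratum]
    out = {}
    for value in sorted(dyad_stratum.dropna().unique()):
        dyads = dyad_stratum.index[dyad_stratum == value]
        sub = {}
        for target, task in tasks.items():
            keep = task.labels.index.intersection(dyads)
            if len(keep) == 0:
                continue
            sub[target] = PredictionTask(
                target, task.features.loc[keep], task.labels.loc[keep],
                task.study.loc[keep])
        out[value] = loso_evaluate(sub, model=model, seeds=seeds, n_trees=n_trees)
    return out
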