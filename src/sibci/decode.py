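"""Scenario enumeration, mRMR feature selection and leakage-safe decoding.

Classification scenarios are task subsets of size 2, 4, 5 or 6; subsets
larger than two never contain both singing-imagery variants.  Within each
of ``n_repeats x n_folds`` stratified cross-validation folds, *everything*
that learns from data — CSP filters, discretization edges, mRMR feature
ranking and the random forest — is fitted on the training fold only.

Feature selection is greedy mRMR with the mutual-information-difference
(MID) criterion: the first pick maximizes relevance I(f; y); each further
pick maximizes I(f; y) minus the mean mutual information with the
already-selected features.  Mutual information uses plug-in estimates on
an equal-frequency discretization of the continuous log-variance features.

The classifier is a 100-tree random forest (Gini impurity, unlimited
depth, bootstrap, sqrt(n_features) split candidates), the scikit-learn
default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold

from .config import SI_TASKS, TASK_NAMES, AnalysisConfig
from .fbcsp import (
    FilterBankSpec,
    apply_filterbank,
    design_filterbank,
    extract_logvar_features,
    fit_csp,
)
from .preprocess import EpochSet


@dataclass(frozen=True)
class ScenarioSpec:
    """One task-subset classification experiment."""

    tasks: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.tasks)

    @property
    def name(self) -> str:
        return "+".join(self.tasks)

    def __post_init__(self) -> None:
        if not 2 <= self.k <= 6:
            raise ValueError("scenario size must be in [2, 6]")
        unknown = set(self.tasks) - set(TASK_NAMES)
        if unknown:
            raise ValueError(f"unknown task(s) {sorted(unknown)}")
        if len(set(self.tasks)) != self.k:
            raise ValueError("scenario tasks must be unique")
        if self.k > 2 and set(SI_TASKS) <= set(self.tasks):
            raise ValueError(
                "scenarios beyond 2 classes may include at most one "
                "singing-imagery variant"
            )


def enumerate_scenarios(k: int, tasks: tuple[str, ...] = TASK_NAMES) -> list[ScenarioSpec]:
    """All task subsets of size k, in deterministic task-vocabulary order.

    Pairs may oppose the two singing-imagery variants; larger subsets
    include at most one of them.  For the default 7-task vocabulary this
    yields 21 / 25 / 11 / 2 scenarios for k = 2 / 4 / 5 / 6.
    """
    if k not in (2, 4, 5, 6):
        raise ValueError(f"scenario size must be one of 2, 4, 5, 6; got {k}")
    out = []
    for combo in combinations(tasks, k):
        if k > 2 and set(SI_TASKS) <= set(combo):
            continue
        out.append(ScenarioSpec(tasks=combo))
    return out


# --------------------------------------------------------------------------
# Discretization + mutual information + mRMR
# --------------------------------------------------------------------------

def discretize_features(
    X: np.ndarray, n_bins: int = 5, edges: list[np.ndarray] | None = None
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equal-frequency binning per column; returns (integer codes, edges).

    Edges are computed from ``X`` when not supplied (training data) and can
    be re-applied to held-out data.  A constant column collapses to a
    single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    if edges is None:
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = [np.unique(np.quantile(X[:, j], qs)) for j in range(X.shape[1])]
    codes = np.empty(X.shape, dtype=np.int64)
    for j, e in enumerate(edges):
        codes[:, j] = np.searchsorted(e, X[:, j], side="right")
    return codes, edges


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete sequences."""
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = len(ai)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))


def mrmr_select(Xd: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Greedy mRMR ranking with the MID criterion; ties go to the lower index."""
    Xd = np.asarray(Xd)
    if Xd.ndim != 2 or Xd.shape[0] == 0 or Xd.shape[1] == 0:
        raise ValueError("feature matrix must be non-empty")
    n_feat = Xd.shape[1]
    if k > n_feat:
        raise ValueError(f"cannot select {k} of {n_feat} features")
    relevance = np.array([mutual_information(Xd[:, j], y) for j in range(n_feat)])
    selected: list[int] = [int(np.argmax(relevance))]
    redundancy_sum = np.zeros(n_feat)
    while len(selected) < k:
        last = selected[-1]
        for j in range(n_feat):
            if j not in selected:
                redundancy_sum[j] += mutual_information(Xd[:, j], Xd[:, last])
        score = relevance - redundancy_sum / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))  # argmax takes first (lowest) index on ties
    return selected


def train_classifier(X: np.ndarray, y: np.ndarray, cfg: AnalysisConfig, seed: int):
    """Random forest with the configuration used throughout the analysis."""
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_depth=None,
        bootstrap=True,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


# --------------------------------------------------------------------------
# Cross-validated scenario decoding
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Fold accuracies, summary statistics and pooled confusion matrix."""

    scenario: ScenarioSpec
    fold_accuracies: np.ndarray  # (n_repeats, n_folds), balanced accuracy in %
    #: Pooled test-fold confusion counts averaged over repeats (each trial
    #: is tested exactly once per repeat), so rows sum to per-class counts.
    confusion: np.ndarray  # (k, k)
    classes: list[str]
    selected_counts: pd.Series  # how often each feature column was selected

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))


def crossvalidate_scenario(
    epochs: EpochSet,
    scenario: ScenarioSpec,
    cfg: AnalysisConfig,
    seed: int,
) -> ScenarioResult:
    """Repeated stratified k-fold decoding of one task subset.

    The filter bank (label-independent) is applied once; CSP fitting,
    discretization edges, mRMR ranking and classifier training happen
    inside each training fold only.  Accuracies are balanced accuracy in
    percent; with the protocol's exact class balance this coincides with
    plain accuracy.
    """
    missing = set(scenario.tasks) - set(epochs.trials["task"])
    if missing:
        raise ValueError(f"epochs lack scenario task(s) {sorted(missing)}")
    sub = epochs.select_tasks(scenario.tasks)
    y = sub.labels
    classes = sorted(scenario.tasks)

    spec = FilterBankSpec(bands=cfg.bands, numtaps=cfg.fir_numtaps)
    coeffs = design_filterbank(spec, sub.fs)
    band = apply_filterbank(sub, coeffs, cfg.bands, cfg.analysis_window_s)

    global_selection: list[int] | None = None
    if cfg.mrmr_outside_cv:
        # Leakage-prone literal reading: rank features once on all trials.
        model_all = fit_csp(
            band, cfg.n_csp_pairs, cfg.diag_loading, cfg.multiclass_csp_for_binary
        )
        feats_all = extract_logvar_features(
            band, model_all, cfg.normalized_logvar, cfg.diag_loading
        )
        codes_all, _ = discretize_features(feats_all.X, cfg.discretize_bins)
        global_selection = mrmr_select(codes_all, y, cfg.selector_k)

    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.n_folds, n_repeats=cfg.n_repeats, random_state=seed
    )
    n_feat_total = len(cfg.bands) * cfg.n_csp_filters
    accs = np.empty(cfg.n_repeats * cfg.n_folds)
    confusion = np.zeros((len(classes), len(classes)))
    sel_counts = np.zeros(n_feat_total)
    feature_names: list[str] | None = None

    for fold_i, (train, test) in enumerate(splitter.split(np.zeros(len(y)), y)):
        if len(set(y[train])) < len(classes) or len(set(y[test])) < len(classes):
            raise RuntimeError("a fold is missing a class despite stratification")
        band_tr = band.select_trials(train)
        model = fit_csp(
            band_tr, cfg.n_csp_pairs, cfg.diag_loading, cfg.multiclass_csp_for_binary
        )
        feats_tr = extract_logvar_features(
            band_tr, model, cfg.normalized_logvar, cfg.diag_loading
        )
        feats_te = extract_logvar_features(
            band.select_trials(test), model, cfg.normalized_logvar, cfg.diag_loading
        )
        if feature_names is None:
            feature_names = [
                f"b{int(r.band_idx)}f{int(r.filter_idx)}"
                for r in feats_tr.columns.itertuples(index=False)
            ]
        if global_selection is not None:
            sel = global_selection
        else:
            codes_tr, edges = discretize_features(feats_tr.X, cfg.discretize_bins)
            sel = mrmr_select(codes_tr, y[train], cfg.selector_k)
        sel_counts[sel] += 1

        clf = train_classifier(feats_tr.X[:, sel], y[train], cfg, seed=seed + fold_i)
        pred = clf.predict(feats_te.X[:, sel])
        accs[fold_i] = 100.0 * balanced_accuracy_score(y[test], pred)
        confusion += confusion_matrix(y[test], pred, labels=classes)

    return ScenarioResult(
        scenario=scenario,
        fold_accuracies=accs.reshape(cfg.n_repeats, cfg.n_folds),
        confusion=confusion / cfg.n_repeats,
        classes=classes,
        selected_counts=pd.Series(sel_counts, index=feature_names),
    )
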