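"""Drug-response classification on the cell-drug bipartite graph.

Continuous dose-response AUC values (AUC_DR; lower = more sensitive) are
*digitalized* into binary edge labels — by default a per-drug median split,
because AUC_DR scales differ between compounds.  Labeled (cell, drug) pairs,
represented by anchor-kernel features, are fed to one of three
interchangeable classifiers: random forest (RF), RBF-kernel support vector
machine (SVM), or a small feed-forward network (DN).  SVM penalty C and RBF
width gamma are tuned by grid search with stratified 5-fold cross-validation,
scored by AUROC on held-out folds; ties prefer the smallest penalty, then the
smallest width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .kernels import PairFeatureSet

__all__ = [
    "LabeledPairSet",
    "TrainedResponseModel",
    "digitalize",
    "auroc",
    "train",
    "evaluate_auc",
    "default_grid",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class LabeledPairSet:
    """Binary sensitive/resistant labels on observed (cell, drug) edges.

    ``pairs`` has columns ``cell_id, drug_id, label`` (1 = sensitive); only
    non-missing sensitivity entries appear.  ``thresholds`` records the
    per-drug cut-off that produced the labels.
    """

    pairs: pd.DataFrame
    thresholds: Mapping[str, float]
    rule: str = "quantile:0.5"

    def __post_init__(self) -> None:
        labels = set(self.pairs["label"].unique())
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be binary, got {sorted(labels)}")


def digitalize(
    sensitivity: pd.DataFrame,
    rule: str = "quantile",
    q: float = 0.5,
    threshold: Optional[float] = None,
) -> LabeledPairSet:
    """Threshold an AUC_DR matrix (cells x drugs, NaN = missing) into labels.

    ``rule="quantile"`` labels a pair sensitive (1) iff its AUC_DR is <= the
    drug's ``q``-quantile over non-missing cells (default the median);
    ``rule="global"`` applies one absolute ``threshold`` to every drug.
    Lower AUC_DR means more sensitive, so the boundary uses ``<=``.
    """
    if rule == "quantile" and not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if rule == "global" and threshold is None:
        raise ValueError("global rule requires a threshold")
    n_obs = sensitivity.notna().sum(axis=0)
    bad = sorted(n_obs.index[n_obs == 0])
    if bad:
        raise ValueError(f"drug(s) with no measurements: {bad}")
    thin = sorted(n_obs.index[n_obs < 4])
    if thin:
        raise ValueError(f"drug(s) with < 4 measurements: {thin}")
    thresholds: Dict[str, float] = {}
    rows = []
    for drug in sensitivity.columns:
        col = sensitivity[drug].dropna()
        t = float(col.quantile(q)) if rule == "quantile" else float(threshold)
        thresholds[drug] = t
        labels = (col <= t).astype(int)
        rows.append(
            pd.DataFrame(
                {"cell_id": col.index, "drug_id": drug, "label": labels.to_numpy()}
            )
        )
    pairs = pd.concat(rows, ignore_index=True)
    rule_str = f"quantile:{q}" if rule == "quantile" else f"global:{threshold}"
    return LabeledPairSet(pairs, thresholds, rule_str)


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUROC: P(random positive scores above random negative),
    ties counted 1/2 (the Mann-Whitney U construction)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


#: SVM grid: penalty C and RBF width gamma.  RF uses a 500-tree forest with
#: default feature subsampling; DN a single 64-unit hidden layer with early
#: stopping — both a single grid point.
def default_grid(kind: str) -> Tuple[Dict[str, float], ...]:
    kind = kind.lower()
    if kind == "svm":
        return tuple(
            {"C": c, "gamma": g}
            for c in (0.01, 0.1, 1.0, 10.0, 100.0)
            for g in (1e-3, 1e-2, 0.1, 1.0, 10.0)
        )
    if kind == "rf":
        return ({"n_estimators": 500},)
    if kind == "dn":
        return ({"hidden_layer_sizes": (64,)},)
    raise ValueError(f"unknown model kind {kind!r}")


def _make_estimator(kind: str, params: Mapping, seed: int, balanced: bool, final: bool):
    cw = "balanced" if balanced else None
    if kind == "svm":
        svc = SVC(
            C=params.get("C", 1.0),
            gamma=params.get("gamma", "scale"),
            kernel="rbf",
            class_weight=cw,
            cache_size=500,
            random_state=seed,
        )
        if final:
            # sigmoid (Platt) calibration so the deployed model emits
            # sensitive-class probabilities in [0, 1]
            return CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)
        return svc
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(params.get("n_estimators", 500)),
            class_weight=cw,
            random_state=seed,
            n_jobs=1,
        )
    if kind == "dn":
        return MLPClassifier(
            hidden_layer_sizes=tuple(params.get("hidden_layer_sizes", (64,))),
            early_stopping=True,
            max_iter=300,
            random_state=seed,
        )
    raise ValueError(f"unknown model kind {kind!r}")


#: Above this many pairs the precomputed RBF Gram (O(n^2) memory) is skipped
#: and grid search falls back to per-fit kernel evaluation.
_PRECOMPUTE_MAX_PAIRS = 12_000


def _svm_grid_cv_precomputed(X, y, grid, splits, balanced):
    """Grid-search CV for the RBF-SVM using one precomputed Gram per gamma.

    Mathematically identical to fitting ``SVC(kernel="rbf")`` per fold, but
    the pairwise squared distances are computed once and every (C, fold)
    combination reuses the same Gram matrix.
    """
    cw = "balanced" if balanced else None
    row_sq = (X ** 2).sum(axis=1)
    sq = np.maximum(row_sq[:, None] - 2.0 * (X @ X.T) + row_sq[None, :], 0.0)
    records = []
    for gamma in dict.fromkeys(p["gamma"] for p in grid):
        K = np.exp(-gamma * sq)
        for params in (p for p in grid if p["gamma"] == gamma):
            fold_aucs = []
            for tr, te in splits:
                est = SVC(
                    C=params.get("C", 1.0), kernel="precomputed",
                    class_weight=cw, cache_size=500,
                )
                est.fit(K[np.ix_(tr, tr)], y[tr])
                fold_aucs.append(auroc(y[te], est.decision_function(K[np.ix_(te, tr)])))
            records.append({**params, "cv_auc": float(np.mean(fold_aucs))})
    del sq
    return records


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "predict_proba") and getattr(estimator, "probability", True):
        proba = estimator.predict_proba(X)
        return proba[:, list(estimator.classes_).index(1)]
    return estimator.decision_function(X)


@dataclass
class TrainedResponseModel:
    """A fitted response classifier plus everything prediction needs.

    ``reference_profiles`` (training-cell mutation matrix) and
    ``reference_drugs`` (training drug records) let a new patient enter
    through kernel rows against the anchors without refitting.
    """

    model_kind: str
    estimator: object
    anchor_cells: Tuple[str, ...]
    anchor_drugs: Tuple[str, ...]
    hyperparams: Dict[str, float]
    cv_auc: float
    seed: int
    kernel_kind: str = "jaccard"
    reference_profiles: Optional[pd.DataFrame] = None
    reference_drugs: Optional[pd.DataFrame] = None
    rule: str = "quantile:0.5"
    grid_results: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)


def train(
    pairs: LabeledPairSet,
    feats: PairFeatureSet,
    kind: str = "rf",
    grid: Optional[Sequence[Mapping]] = None,
    folds: int = 5,
    seed: int = 0,
    cv_unit: str = "pair",
    reference: Optional[Tuple[pd.DataFrame, pd.DataFrame]] = None,
) -> TrainedResponseModel:
    """Grid-search ``folds``-fold CV, refit the best model on all pairs.

    The CV unit is the (cell, drug) pair by default (stratified by label,
    seeded); ``cv_unit="cell"`` holds out whole cells instead, which avoids
    leaking cell identity across folds.  The selected grid point maximises
    mean held-out AUROC; ties pick the smallest C, then the smallest gamma.
    Instance re-weighting (``class_weight="balanced"``) is applied whenever
    the digitalization rule was not a median split.
    """
    kind = kind.lower()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X = feats.X
    if np.isnan(X).any():
        raise ValueError("NaN in feature matrix")
    y = pairs.pairs["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) != len(X):
        raise ValueError("pairs and features are misaligned")
    balanced = not pairs.rule.startswith("quantile:0.5")
    grid = tuple(grid) if grid is not None else default_grid(kind)

    if cv_unit == "pair":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    elif cv_unit == "cell":
        groups = pairs.pairs["cell_id"].to_numpy()
        splitter = GroupKFold(n_splits=folds)
        splits = list(splitter.split(X, y, groups))
    else:
        raise ValueError(f"unknown cv_unit {cv_unit!r}")

    for tr, te in splits:
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("a CV fold contains a single class; use more data or fewer folds")

    if kind == "svm" and len(X) <= _PRECOMPUTE_MAX_PAIRS and all("gamma" in p for p in grid):
        records = _svm_grid_cv_precomputed(X, y, grid, splits, balanced)
    else:
        records = []
        for params in grid:
            fold_aucs = []
            for tr, te in splits:
                est = _make_estimator(kind, params, seed, balanced, final=False)
                est.fit(X[tr], y[tr])
                fold_aucs.append(auroc(y[te], _scores(est, X[te])))
            records.append({**params, "cv_auc": float(np.mean(fold_aucs))})
    results = pd.DataFrame(records)

    # argmax with deterministic tie-break: smallest penalty, then smallest width
    order_cols = [c for c in ("C", "gamma") if c in results.columns]
    ordered = results.sort_values(order_cols, kind="mergesort") if order_cols else results
    aucs = ordered["cv_auc"].to_numpy()
    best_idx = ordered.index[int(np.flatnonzero(aucs == aucs.max())[0])]
    best_params = {k: v for k, v in results.loc[best_idx].items() if k != "cv_auc"}
    cv_auc = float(results.loc[best_idx, "cv_auc"])

    final = _make_estimator(kind, best_params, seed, balanced, final=True)
    final.fit(X, y)

    ref_prof, ref_drugs = (None, None) if reference is None else reference
    return TrainedResponseModel(
        model_kind=kind,
        estimator=final,
        anchor_cells=feats.anchor_cells,
        anchor_drugs=feats.anchor_drugs,
        hyperparams={k: (tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in best_params.items()},
        cv_auc=cv_auc,
        seed=seed,
        reference_profiles=ref_prof,
        reference_drugs=ref_drugs,
        rule=pairs.rule,
        grid_results=results,
    )


def evaluate_auc(
    model: TrainedResponseModel,
    pairs: LabeledPairSet,
    feats: PairFeatureSet,
) -> float:
    """AUROC of the model's scores on a labelled pair set."""
    y = pairs.pairs["label"].to_numpy()
    return auroc(y, _scores(model.estimator, feats.X))


def save_model(model: TrainedResponseModel, path: Union[str, Path]) -> None:
    """Serialise the model bundle (parameters, anchors, config, seed)."""
    joblib.dump(model, path, compress=3)


def load_model(path: Union[str, Path]) -> TrainedResponseModel:
    return joblib.load(path)
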