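"""Training protocol: stratified split, 5-fold CV grid search, final models.

The benchmark protocol mirrors the published design: an 80:20 per-class
split (floor rounding, so 313/2908 peptides give 250/2326 training and
63/582 validation), greedy mRMR ranking computed on the training partition
only, then for each feature-count k and each of seven classifier kinds a
stratified 5-fold cross-validated grid search selecting the parameter set
with the best mean CV AUCROC. Min-max scaling lives inside each pipeline,
so it is fitted on training folds only and never leaks validation data.
All randomness flows from one top-level seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .features import encode_batch
from .metrics import ConfusionCounts, EvalReport, binary_metrics, confusion_at_threshold, roc_auc
from .mrmr import MrmrResult, mrmr_select, top_k_slice
from .sequences import Peptide

CLASSIFIER_KINDS = ("DT", "GNB", "KNN", "LR", "SVM", "RF", "XGB")

#: Conservative default hyperparameter grids (overridable via config);
#: values are ordered simplest-first so the deterministic tie-break prefers
#: the less complex setting.
DEFAULT_GRIDS: Dict[str, Dict[str, list]] = {
    "DT": {"clf__max_depth": [3, 5, 10, None], "clf__min_samples_leaf": [1, 5]},
    "GNB": {"clf__var_smoothing": [1e-9, 1e-8, 1e-7]},
    "KNN": {"clf__n_neighbors": [3, 5, 7, 9]},
    "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "SVM": {"clf__C": [0.1, 1.0, 10.0]},
    "RF": {"clf__n_estimators": [100], "clf__max_depth": [5, None]},
    "XGB": {
        "clf__n_estimators": [100],
        "clf__max_depth": [3, 5],
        "clf__learning_rate": [0.1, 0.3],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier kind plus its hyperparameter grid."""

    kind: str
    grid: Mapping[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; "
                f"expected one of {CLASSIFIER_KINDS}"
            )
        if not self.grid:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.kind])


def make_estimator(kind: str, params: Optional[Mapping] = None, seed: int = 0) -> Pipeline:
    """Min-max-scaled classifier pipeline for one of the seven kinds."""
    if kind == "DT":
        clf = DecisionTreeClassifier(random_state=seed)
    elif kind == "GNB":
        clf = GaussianNB()
    elif kind == "KNN":
        clf = KNeighborsClassifier()
    elif kind == "LR":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "SVM":
        clf = SVC(probability=True, random_state=seed)
    elif kind == "RF":
        clf = RandomForestClassifier(random_state=seed)
    elif kind == "XGB":
        clf = XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss"
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    pipe = Pipeline([("scale", MinMaxScaler()), ("clf", clf)])
    if params:
        pipe.set_params(**params)
    return pipe


# ---------------------------------------------------------------------------
# dataset splitting

@dataclass(frozen=True)
class SplitResult:
    train_pos: List[Peptide]
    train_neg: List[Peptide]
    val_pos: List[Peptide]
    val_neg: List[Peptide]
    seed: int


def split_dataset(
    pos: Sequence[Peptide],
    neg: Sequence[Peptide],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitResult:
    """Seeded per-class split; training size is floor(fraction * class size)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)

    def _split(items: Sequence[Peptide]) -> Tuple[List[Peptide], List[Peptide]]:
        order = rng.permutation(len(items))
        n_train = int(np.floor(train_fraction * len(items)))
        train = [items[i] for i in order[:n_train]]
        val = [items[i] for i in order[n_train:]]
        return train, val

    train_pos, val_pos = _split(list(pos))
    train_neg, val_neg = _split(list(neg))
    return SplitResult(train_pos, train_neg, val_pos, val_neg, seed)


# ---------------------------------------------------------------------------
# cross-validated grid search

def _param_sort_key(params: Mapping) -> str:
    return repr(sorted(params.items(), key=lambda kv: kv[0]))


def cv_grid_search(
    table: pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec,
    folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> Tuple[Dict, EvalReport]:
    """Exhaustive grid search maximizing mean CV AUCROC.

    Returns the winning parameter set and the mean-of-folds evaluation
    report (confusion counts are summed over the out-of-fold predictions).
    Ties in mean AUCROC break deterministically by parameter order.
    """
    X = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < {folds} folds; "
            "stratified folding would produce a degenerate fold — reduce "
            "folds or change the split seed"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    candidates = sorted(ParameterGrid(dict(spec.grid)), key=_param_sort_key)
    best_params, best_auc = None, -np.inf
    for params in candidates:
        aucs = []
        for tr, te in splits:
            est = make_estimator(spec.kind, params, seed)
            est.fit(X[tr], y[tr])
            aucs.append(roc_auc(est.predict_proba(X[te])[:, 1], y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:
            best_auc, best_params = mean_auc, params

    # full per-fold metric report for the winner
    fold_metrics, tp = [], np.zeros(4, dtype=int)
    aucs = []
    for tr, te in splits:
        est = make_estimator(spec.kind, best_params, seed)
        est.fit(X[tr], y[tr])
        scores = est.predict_proba(X[te])[:, 1]
        c = confusion_at_threshold(scores, y[te], threshold)
        fold_metrics.append(binary_metrics(c))
        tp += np.array([c.TP, c.FP, c.TN, c.FN])
        aucs.append(roc_auc(scores, y[te]))
    mean = {k: float(np.mean([m[k] for m in fold_metrics])) for k in fold_metrics[0]}
    report = EvalReport(
        sensitivity=mean["sensitivity"],
        specificity=mean["specificity"],
        accuracy=mean["accuracy"],
        aucroc=float(np.mean(aucs)),
        mcc=mean["mcc"],
        counts=ConfusionCounts(*map(int, tp)),
        split="train-cv",
    )
    return dict(best_params), report


# ---------------------------------------------------------------------------
# final models

FORMAT_VERSION = 1


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reapply it."""

    kind: str
    params: Dict
    selected_features: List[str]
    pipeline: Pipeline
    seed: int
    fingerprint: str

    def predict_proba(self, table: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Positive-class probability; DataFrames are sliced to the model's
        selected features, arrays must already be in that order."""
        if isinstance(table, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in table.columns]
            if missing:
                raise KeyError(f"feature table missing {missing[:3]}...")
            X = table[self.selected_features].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(table, dtype=np.float64)
            if X.shape[1] != len(self.selected_features):
                raise ValueError(
                    f"expected {len(self.selected_features)} features, "
                    f"got {X.shape[1]}"
                )
        return self.pipeline.predict_proba(X)[:, 1]

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "format_version": FORMAT_VERSION,
                "kind": self.kind,
                "params": self.params,
                "selected_features": self.selected_features,
                "pipeline": self.pipeline,
                "seed": self.seed,
                "fingerprint": self.fingerprint,
            },
            path,
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"incompatible model artifact (format "
                f"{blob.get('format_version')!r}, expected {FORMAT_VERSION})"
            )
        return cls(
            kind=blob["kind"],
            params=blob["params"],
            selected_features=blob["selected_features"],
            pipeline=blob["pipeline"],
            seed=blob["seed"],
            fingerprint=blob["fingerprint"],
        )


def train_final(
    table: pd.DataFrame,
    labels: Sequence[int],
    spec: ModelSpec,
    best_params: Mapping,
    selected_features: Sequence[str],
    seed: int = 0,
) -> TrainedModel:
    """Fit the final model on the full training partition, restricted to the
    selected features."""
    missing = [f for f in selected_features if f not in table.columns]
    if missing:
        raise KeyError(f"unknown feature name(s): {missing[:5]}")
    X = table[list(selected_features)].to_numpy(dtype=np.float64)
    y = np.asarray(labels, dtype=int)
    pipe = make_estimator(spec.kind, dict(best_params), seed)
    pipe.fit(X, y)
    return TrainedModel(
        kind=spec.kind,
        params=dict(best_params),
        selected_features=list(selected_features),
        pipeline=pipe,
        seed=seed,
        fingerprint=_fingerprint(X, y),
    )


def evaluate(
    model: TrainedModel,
    table: pd.DataFrame,
    labels: Sequence[int],
    threshold: float = 0.5,
    split: str = "validation",
) -> EvalReport:
    scores = model.predict_proba(table)
    return EvalReport.from_scores(scores, labels, threshold=threshold, split=split)


# ---------------------------------------------------------------------------
# full benchmark protocol

DEFAULT_K_LIST = (10, 20, 30, 40, 50, 60, 70, 80, 90, 95)


@dataclass
class ProtocolResult:
    """Benchmark table plus the artifacts behind it."""

    table: pd.DataFrame
    ranking: MrmrResult
    models: Dict[Tuple[str, int], TrainedModel]
    split: SplitResult


def run_protocol(
    pos: Sequence[Peptide],
    neg: Sequence[Peptide],
    k_list: Sequence[int] = DEFAULT_K_LIST,
    kinds: Sequence[str] = CLASSIFIER_KINDS,
    seed: int = 0,
    variant: str = "difference",
    bin_count: int = 10,
    folds: int = 5,
    grids: Optional[Mapping[str, Mapping]] = None,
    threshold: float = 0.5,
    catalog=None,
    out_tsv: Optional[str] = None,
) -> ProtocolResult:
    """Run the full benchmark: split, encode, mRMR rank, CV-train, evaluate.

    Produces one train-cv row and one validation row per (classifier, k).
    """
    split = split_dataset(pos, neg, seed=seed)
    train = split.train_pos + split.train_neg
    y_train = np.array([1] * len(split.train_pos) + [0] * len(split.train_neg))
    val = split.val_pos + split.val_neg
    y_val = np.array([1] * len(split.val_pos) + [0] * len(split.val_neg))

    X_train = encode_batch(train, catalog)
    X_val = encode_batch(val, catalog)

    ranking = mrmr_select(
        X_train, y_train, k=max(k_list), variant=variant, bin_count=bin_count
    )

    rows: List[Dict] = []
    models: Dict[Tuple[str, int], TrainedModel] = {}
    for k in k_list:
        feats = top_k_slice(ranking, k)
        Xk = X_train[feats]
        for kind in kinds:
            spec = ModelSpec(kind, dict(grids[kind]) if grids and kind in grids else {})
            best_params, cv_report = cv_grid_search(
                Xk, y_train, spec, folds=folds, seed=seed, threshold=threshold
            )
            model = train_final(X_train, y_train, spec, best_params, feats, seed)
            models[(kind, k)] = model
            val_report = evaluate(model, X_val, y_val, threshold=threshold)
            for rep in (cv_report, val_report):
                rows.append({"classifier": kind, "k": k, **rep.as_dict()})

    table = pd.DataFrame(rows)
    if out_tsv:
        table.to_csv(out_tsv, sep="\t", index=False)
    return ProtocolResult(table=table, ranking=ranking, models=models, split=split)
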