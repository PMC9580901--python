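"""Classifier training (SVM / random forest / neural network), prediction,
and evaluation metrics.

Each classifier is wrapped in a pipeline whose first stage standardizes the
8 features to zero mean and unit variance using training-fold statistics
only.  Hyperparameters are chosen by grid search under stratified 5-fold
cross-validation, scored by mean ROC AUC, and the winning configuration is
refit on the full dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import LabeledDataset, TrainingConfig
from .features import FeatureVector
from .voting import ClassifierPrediction

CLASSIFIER_KINDS = ("SVM", "RF", "NN")

#: default hyperparameter grids; the classifier-specific names follow the
#: underlying estimators (C/gamma for the RBF SVM; max_features/max_depth for
#: the forest; learning rate, epochs and architecture for the network).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": [1e-3, 1e-2, 1e-1, 1.0]},
    "RF": {"max_features": [2, 3, 8], "max_depth": [3, 5, 10, None]},
    "NN": {
        "learning_rate_init": [1e-3, 1e-2, 1e-1],
        "max_iter": [50, 200],
        "hidden_layer_sizes": [(8,), (16,), (8, 8), (16, 16)],
    },
}

#: smaller grids for quick evaluation runs (same families, fewer points)
SMALL_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [1.0, 10.0], "gamma": [1e-2, 1e-1]},
    "RF": {"max_features": [2, 3], "max_depth": [5, None]},
    "NN": {
        "learning_rate_init": [1e-2, 1e-1],
        "max_iter": [200],
        "hidden_layer_sizes": [(16,)],
    },
}

RF_N_ESTIMATORS = 500


@dataclass
class HyperparamGrid:
    entries: dict[str, list]

    def __post_init__(self) -> None:
        if not self.entries or any(not v for v in self.entries.values()):
            raise ValueError("grid must be nonempty with nonempty candidate lists")


@dataclass
class MetricsReport:
    acc: float
    prec: float
    rec: float
    mcc: float
    roc_auc: float
    auprc: float
    npv: float
    ppv: float
    undefined_ratio_warning: bool = False


@dataclass
class CVReport:
    fold_reports: list[MetricsReport]
    fold_roc_auc: list[float]
    mean_roc_auc: float


@dataclass
class TrainedModelBundle:
    classifier_kind: str
    best_params: dict
    standardizer: tuple[np.ndarray, np.ndarray]  # per-feature (mean, sd)
    model_state: Pipeline
    cv_report: CVReport
    rng_seed: int


def _make_estimator(kind: str, rng_seed: int):
    if kind == "SVM":
        # posteriors via sigmoid calibration fitted on the training folds
        from sklearn.calibration import CalibratedClassifierCV

        return CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=rng_seed), ensemble=False
        )
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=RF_N_ESTIMATORS, random_state=rng_seed
        )
    if kind == "NN":
        return MLPClassifier(
            solver="sgd",
            activation="relu",
            random_state=rng_seed,
        )
    raise ValueError(f"unknown classifier kind {kind!r}; use one of {CLASSIFIER_KINDS}")


def metrics_from_confusion(
    tp: int, tn: int, fp: int, fn: int
) -> tuple[dict[str, float], bool]:
    """Confusion-matrix metrics; zero-denominator ratios reported as 0."""
    warned = False

    def ratio(num: float, den: float) -> float:
        nonlocal warned
        if den == 0:
            warned = True
            return 0.0
        return num / den

    total = tp + tn + fp + fn
    acc = ratio(tp + tn, total)
    prec = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    npv = ratio(tn, tn + fn)
    mcc_den = float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, np.sqrt(mcc_den) if mcc_den > 0 else 0.0)
    return (
        {
            "acc": acc,
            "prec": prec,
            "rec": rec,
            "mcc": mcc,
            "npv": npv,
            "ppv": prec,  # PPV is precision by definition
        },
        warned,
    )


def evaluate_predictions(
    preds: Sequence[ClassifierPrediction], labels: Sequence[int]
) -> MetricsReport:
    """Metrics from predicted classes and posteriors against ±1 labels.

    ROC AUC / AUPRC use the positive-class probability, recovered from the
    predicted-class posterior (``p`` if class +1, ``1 - p`` otherwise).
    """
    if len(preds) != len(labels):
        raise ValueError("preds and labels length mismatch")
    if not preds:
        raise ValueError("empty prediction list")
    y = np.asarray(labels, dtype=int)
    yhat = np.array([p.cls for p in preds], dtype=int)
    p_pos = np.array(
        [p.posterior if p.cls == 1 else 1.0 - p.posterior for p in preds]
    )
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == -1) & (y == -1)))
    fp = int(np.sum((yhat == 1) & (y == -1)))
    fn = int(np.sum((yhat == -1) & (y == 1)))
    base, warned = metrics_from_confusion(tp, tn, fp, fn)
    if len(set(y.tolist())) < 2:
        roc, auprc = 0.0, 0.0
        warned = True
    else:
        roc = float(roc_auc_score(y, p_pos))
        auprc = float(average_precision_score(y, p_pos))
    return MetricsReport(
        acc=base["acc"],
        prec=base["prec"],
        rec=base["rec"],
        mcc=base["mcc"],
        roc_auc=roc,
        auprc=auprc,
        npv=base["npv"],
        ppv=base["ppv"],
        undefined_ratio_warning=warned,
    )


def _pipeline_predictions(pipe: Pipeline, x: np.ndarray) -> list[ClassifierPrediction]:
    proba = pipe.predict_proba(x)
    pos_col = list(pipe.classes_).index(1)
    out = []
    for row in proba:
        p_pos = float(row[pos_col])
        cls = 1 if p_pos > 0.5 else -1
        out.append(
            ClassifierPrediction(
                kind="SVM",  # overwritten by callers that know the kind
                cls=cls,
                posterior=p_pos if cls == 1 else 1.0 - p_pos,
            )
        )
    return out


def train_model(
    ds: LabeledDataset,
    kind: str,
    grid: HyperparamGrid | Mapping[str, list] | None = None,
    rng_seed: int = 0,
) -> TrainedModelBundle:
    """Grid-searched, cross-validated fit of one classifier family.

    Raises on single-class datasets and on datasets too small to stratify
    into 5 folds with both classes present.
    """
    x, y, _ = ds.to_arrays()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("dataset contains a single class")
    if len(y) < 10:
        raise ValueError("dataset must contain at least 10 rows")
    if counts.min() < 5:
        raise ValueError(
            "stratification error: fewer than 5 members in the minority class"
        )

    if grid is None:
        grid = DEFAULT_GRIDS[kind]
    entries = grid.entries if isinstance(grid, HyperparamGrid) else dict(grid)
    HyperparamGrid(dict(entries))  # validate
    if kind == "RF":
        n_feat = x.shape[1]
        entries = {
            k: ([v for v in vals if not (k == "max_features" and v > n_feat)] or vals)
            for k, vals in entries.items()
        }

    pipe = Pipeline(
        [("scale", StandardScaler()), ("est", _make_estimator(kind, rng_seed))]
    )
    prefix = "est__estimator__" if kind == "SVM" else "est__"
    param_grid = {f"{prefix}{k}": v for k, v in entries.items()}
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=rng_seed)
    search = GridSearchCV(
        pipe, param_grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        search.fit(x, y)

        best_params = {
            k.removeprefix(prefix): v for k, v in search.best_params_.items()
        }

        # per-fold report at the winning configuration
        fold_reports: list[MetricsReport] = []
        fold_auc: list[float] = []
        for train_idx, test_idx in cv.split(x, y):
            fold_pipe = Pipeline(
                [("scale", StandardScaler()), ("est", _make_estimator(kind, rng_seed))]
            )
            fold_pipe.set_params(**search.best_params_)
            fold_pipe.fit(x[train_idx], y[train_idx])
            preds = _pipeline_predictions(fold_pipe, x[test_idx])
            for p in preds:
                p.kind = kind
            report = evaluate_predictions(preds, y[test_idx].tolist())
            fold_reports.append(report)
            fold_auc.append(report.roc_auc)

    scaler: StandardScaler = search.best_estimator_.named_steps["scale"]
    return TrainedModelBundle(
        classifier_kind=kind,
        best_params=best_params,
        standardizer=(scaler.mean_.copy(), scaler.scale_.copy()),
        model_state=search.best_estimator_,
        cv_report=CVReport(
            fold_reports=fold_reports,
            fold_roc_auc=fold_auc,
            mean_roc_auc=float(np.mean(fold_auc)),
        ),
        rng_seed=rng_seed,
    )


def predict_with_model(
    bundle: TrainedModelBundle, fv: FeatureVector | np.ndarray
) -> ClassifierPrediction:
    """Class (±1) and posterior of the predicted class (>= 0.5) for one
    raw feature vector; standardization is applied internally."""
    x = fv.as_array() if isinstance(fv, FeatureVector) else np.asarray(fv, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite values")
    pred = _pipeline_predictions(bundle.model_state, x.reshape(1, -1))[0]
    pred.kind = bundle.classifier_kind
    return pred


def predict_many(
    bundle: TrainedModelBundle, x: np.ndarray
) -> list[ClassifierPrediction]:
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    preds = _pipeline_predictions(bundle.model_state, x)
    for p in preds:
        p.kind = bundle.classifier_kind
    return preds


def select_best_model(
    reports: Mapping[TrainingConfig, float]
) -> TrainingConfig:
    """Config with maximal mean CV ROC AUC; ties prefer smaller neg_ratio,
    then smaller threshold, then enumeration order."""
    if not reports:
        raise ValueError("no reports supplied")
    items = list(reports.items())
    best_idx = 0
    for i, (cfg, auc) in enumerate(items[1:], start=1):
        b_cfg, b_auc = items[best_idx]
        if auc > b_auc or (
            auc == b_auc
            and (cfg.neg_ratio, cfg.diamond_threshold)
            < (b_cfg.neg_ratio, b_cfg.diamond_threshold)
        ):
            best_idx = i
    return items[best_idx][0]


def save_bundle(bundle: TrainedModelBundle, directory: str) -> None:
    """Persist a bundle: params + standardizer as JSON, fitted pipeline via
    joblib, CV report as TSV."""
    import json
    from pathlib import Path

    import joblib

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "classifier_kind": bundle.classifier_kind,
        "best_params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in bundle.best_params.items()
        },
        "standardizer_mean": bundle.standardizer[0].tolist(),
        "standardizer_sd": bundle.standardizer[1].tolist(),
        "rng_seed": bundle.rng_seed,
        "mean_cv_roc_auc": bundle.cv_report.mean_roc_auc,
    }
    (d / "bundle.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(bundle, d / "bundle.joblib")
    export_cv_report(bundle, str(d / "cv_report.tsv"))


def load_bundle(directory: str) -> TrainedModelBundle:
    from pathlib import Path

    import joblib

    return joblib.load(Path(directory) / "bundle.joblib")


def export_cv_report(bundle: TrainedModelBundle, path: str) -> None:
    """Write the per-fold CV report as TSV."""
    cols = ["fold", "roc_auc", "acc", "prec", "rec", "mcc", "auprc", "npv", "ppv"]
    with open(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, rep in enumerate(bundle.cv_report.fold_reports, start=1):
            vals = [
                str(i),
                *(
                    f"{getattr(rep, c):.6f}"
                    for c in ["roc_auc", "acc", "prec", "rec", "mcc", "auprc", "npv", "ppv"]
                ),
            ]
            fh.write("\t".join(vals) + "\n")
        fh.write(f"mean\t{bundle.cv_report.mean_roc_auc:.6f}" + "\t" * 7 + "\n")
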