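"""SVM training, hyperparameter search and cross-validated evaluation.

The classifier is a support-vector machine (Gaussian, polynomial or linear
kernel) preceded by feature standardization.  Hyperparameters are found by
a seeded sequential model-based (Bayesian) optimizer maximizing mean
cross-validated accuracy within a fixed evaluation budget.  Evaluation is
repeated k-fold cross-validation with confusion counts accumulated over
held-out folds, ROC/AUC from pooled decision scores, and the operating
point chosen by Youden's J = TPR − FPR.  The AUD-like cohort is the
positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

POSITIVE_CLASS = "AUD-like"

META_COLUMNS = ("subject_id", "class_label", "segment")


@dataclass(frozen=True)
class SVMSpec:
    """One SVM configuration (kernel + its parameters)."""

    kernel: str = "gaussian"  # gaussian | polynomial | linear
    box_constraint: float = 1.0
    kernel_scale: float = 1.0  # gaussian only; gamma = 1 / kernel_scale**2
    degree: int = 3  # polynomial only
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("gaussian", "polynomial", "linear"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ValueError("box constraint and kernel scale must be positive")
        if self.kernel == "polynomial" and not 2 <= self.degree <= 4:
            raise ValueError("polynomial degree must be 2..4")

    def make_estimator(self) -> Pipeline:
        if self.kernel == "gaussian":
            svc = SVC(kernel="rbf", C=self.box_constraint,
                      gamma=1.0 / self.kernel_scale ** 2)
        elif self.kernel == "polynomial":
            svc = SVC(kernel="poly", C=self.box_constraint, degree=self.degree,
                      gamma="scale", coef0=1.0)
        else:
            svc = SVC(kernel="linear", C=self.box_constraint)
        return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def table_xy(table: pd.DataFrame, positive: str = POSITIVE_CLASS):
    """Split a feature table into (X, y, groups); y is 1 for the positive class."""
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    x = table[feat_cols].to_numpy(dtype=float)
    y = (table["class_label"].to_numpy() == positive).astype(int)
    groups = table["subject_id"].to_numpy()
    return x, y, groups


def _as_binary(y, positive):
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == positive).astype(int)
    return y.astype(int)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, sensitivity, specificity and precision from confusion counts.

    Zero-denominator ratios are reported as NaN with a warning, never as a
    silent zero.
    """
    counts = dict(tp=tp, tn=tn, fp=fp, fn=fn)
    if any(v < 0 for v in counts.values()):
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning,
                          stacklevel=3)
            return float("nan")
        return num / den

    return {
        **counts,
        "accuracy": (tp + tn) / total,
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "precision": ratio(tp, tp + fp, "precision"),
    }


@dataclass
class EvaluationReport:
    """Cross-validated classification metrics for one feature table."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    accuracy_sd: float
    sensitivity: float
    specificity: float
    precision: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    operating_point: tuple[float, float]
    identifier: str = ""
    split: str = "segment"
    k: int = 5
    repeats: int = 5
    seed: int = 0
    repeat_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in
             ("tp", "tn", "fp", "fn", "accuracy", "accuracy_sd", "sensitivity",
              "specificity", "precision", "auc", "identifier", "split", "k",
              "repeats", "seed")}
        d["operating_point"] = list(self.operating_point)
        d["roc"] = [[float(a), float(b)] for a, b in zip(self.fpr, self.tpr)]
        d["repeat_accuracies"] = [float(a) for a in self.repeat_accuracies]
        return d

    def summary(self) -> str:
        op = self.operating_point
        return "\n".join([
            f"Evaluation report {self.identifier or '(unnamed)'}",
            f"  split: {self.split}-level, {self.k}-fold x {self.repeats} repeats",
            f"  confusion (pos=AUD-like): TP={self.tp} TN={self.tn} "
            f"FP={self.fp} FN={self.fn}",
            f"  accuracy:    {100 * self.accuracy:.2f} +/- {100 * self.accuracy_sd:.2f} %",
            f"  sensitivity: {self.sensitivity:.4f}",
            f"  specificity: {self.specificity:.4f}",
            f"  precision:   {self.precision:.4f}",
            f"  AUC:         {self.auc:.4f}  operating point (FPR, TPR) = "
            f"({op[0]:.3f}, {op[1]:.3f})",
        ])


def _splitter(split: str, k: int, seed: int):
    if split == "segment":
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    if split == "subject":
        return StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    raise ValueError(f"unknown split policy {split!r}")


def evaluate(x, y, spec: SVMSpec, groups=None, split: str = "segment",
             k: int = 5, repeats: int = 5, seed: int = 0,
             positive: str = POSITIVE_CLASS, identifier: str = "") -> EvaluationReport:
    """Repeated k-fold cross-validated evaluation of one SVM configuration.

    Confusion counts and pooled ROC decision scores come from the first
    repeat (each row held out exactly once, so TP+TN+FP+FN equals the row
    count); the accuracy mean ± sd is taken over all repeats.
    """
    x = np.asarray(x, dtype=float)
    y = _as_binary(y, positive)
    if x.ndim != 2 or len(y) != len(x):
        raise ValueError("x must be 2-D with one label per row")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if k < 2:
        raise ValueError("k must be >= 2")
    if split == "subject":
        if groups is None:
            raise ValueError("subject split requires groups")
        groups = np.asarray(groups)
        for cls in (0, 1):
            if len(np.unique(groups[y == cls])) < k:
                raise ValueError(
                    f"subject-grouped split needs >= {k} subjects per class"
                )
    rep_acc = []
    tp = tn = fp = fn = 0
    scores = np.empty(len(y))
    for rep in range(repeats):
        cv = _splitter(split, k, seed + rep)
        cv_groups = groups if split == "subject" else None
        correct = 0
        for train, test in cv.split(x, y, cv_groups):
            est = spec.make_estimator()
            est.fit(x[train], y[train])
            pred = est.predict(x[test])
            correct += int((pred == y[test]).sum())
            if rep == 0:
                scores[test] = est.decision_function(x[test])
                tp += int(((pred == 1) & (y[test] == 1)).sum())
                tn += int(((pred == 0) & (y[test] == 0)).sum())
                fp += int(((pred == 1) & (y[test] == 0)).sum())
                fn += int(((pred == 0) & (y[test] == 1)).sum())
        rep_acc.append(correct / len(y))
    rep_acc = np.asarray(rep_acc)
    metrics = confusion_metrics(tp, tn, fp, fn)
    fpr, tpr, _ = roc_curve(y, scores)
    roc_auc = float(sk_auc(fpr, tpr))
    j = int(np.argmax(tpr - fpr))
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=float(rep_acc.mean()),
        accuracy_sd=float(rep_acc.std(ddof=1)) if repeats > 1 else 0.0,
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        precision=metrics["precision"], fpr=fpr, tpr=tpr, auc=roc_auc,
        operating_point=(float(fpr[j]), float(tpr[j])), identifier=identifier,
        split=split, k=k, repeats=repeats, seed=seed, repeat_accuracies=rep_acc)


# ---------------------------------------------------------------------------
# sequential model-based hyperparameter search
# ---------------------------------------------------------------------------

_LOG_C = (-3.0, 3.0)  # log10 box constraint
_LOG_SCALE = (-2.0, 2.0)  # log10 gaussian kernel scale
_ARMS = (("gaussian", None), ("linear", None),
         ("polynomial", 2), ("polynomial", 3), ("polynomial", 4))


def _arm_dims(kernel):
    return 2 if kernel == "gaussian" else 1


def _sample_params(kernel, rng):
    logc = rng.uniform(*_LOG_C)
    if kernel == "gaussian":
        return np.array([logc, rng.uniform(*_LOG_SCALE)])
    return np.array([logc])


def _spec_from(arm, params, seed):
    kernel, degree = arm
    return SVMSpec(kernel=kernel, box_constraint=10.0 ** params[0],
                   kernel_scale=10.0 ** params[1] if kernel == "gaussian" else 1.0,
                   degree=degree if degree is not None else 3, seed=seed)


def _expected_improvement(mu, sd, best):
    from scipy.stats import norm

    sd = np.maximum(sd, 1e-9)
    z = (mu - best) / sd
    return (mu - best) * norm.cdf(z) + sd * norm.pdf(z)


def tune_svm(x, y, budget: int = 30, k: int = 5, seed: int = 0,
             positive: str = POSITIVE_CLASS, kernels=None) -> SVMSpec:
    """Sequential model-based search for the best SVM configuration.

    A Gaussian-process surrogate per kernel arm models mean k-fold CV
    accuracy as a function of the (log-scaled) numeric hyperparameters;
    each iteration evaluates the candidate with the highest expected
    improvement.  Deterministic given ``seed``; the CV folds are fixed
    across the whole search so configurations are compared on identical
    splits.
    """
    x = np.asarray(x, dtype=float)
    y = _as_binary(y, positive)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 10:
        raise ValueError("need at least 10 rows per class to tune")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    arms = [a for a in _ARMS if kernels is None or a[0] in kernels]
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(x, y))

    def objective(spec: SVMSpec) -> float:
        accs = []
        for train, test in folds:
            est = spec.make_estimator()
            est.fit(x[train], y[train])
            accs.append(float((est.predict(x[test]) == y[test]).mean()))
        return float(np.mean(accs))

    history: dict[int, list[tuple[np.ndarray, float]]] = {i: [] for i in range(len(arms))}
    evals = 0
    best_score, best_spec = -np.inf, None

    def run(arm_i, params):
        nonlocal evals, best_score, best_spec
        spec = _spec_from(arms[arm_i], params, seed)
        score = objective(spec)
        history[arm_i].append((params, score))
        evals += 1
        if score > best_score:
            best_score, best_spec = score, spec

    # initial design: one random configuration per arm (round-robin)
    for i in range(min(len(arms), budget)):
        run(i, _sample_params(arms[i][0], rng))

    while evals < budget:
        proposals = []
        for i, (kernel, _) in enumerate(arms):
            obs = history[i]
            cands = np.array([_sample_params(kernel, rng) for _ in range(128)])
            if len(obs) >= 2:
                xs = np.array([p for p, _ in obs])
                ys = np.array([s for _, s in obs])
                gp = GaussianProcessRegressor(
                    kernel=Matern(length_scale=np.ones(_arm_dims(kernel)), nu=2.5)
                    + WhiteKernel(1e-4), normalize_y=True, random_state=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gp.fit(xs, ys)
                    mu, sd = gp.predict(cands, return_std=True)
                ei = _expected_improvement(mu, sd, max(ys))
            else:  # force exploration of untried arms
                ei = np.full(len(cands), np.inf)
            j = int(np.argmax(ei))
            proposals.append((float(np.max(ei)), i, cands[j]))
        _, arm_i, params = max(proposals, key=lambda t: t[0])
        run(arm_i, params)
    return best_spec


def per_band_sweep(features, band_list=None, spec: SVMSpec | None = None,
                   budget: int = 30, split: str = "segment", k: int = 5,
                   repeats: int = 2, seed: int = 0) -> dict:
    """Independent tune + evaluate for every band; returns reports and ranking.

    ``spec`` short-circuits tuning with a fixed configuration (used for
    large sweeps where per-band search is not the question being asked).
    Returns ``{"reports": {band: EvaluationReport}, "ranking": [...],
    "top5": [...], "mean_accuracy": float}``.
    """
    if band_list is None:
        band_list = list(features.band_index)
    band_list = sorted(set(int(b) for b in band_list))
    y = features.labels
    groups = features.subjects
    reports = {}
    for b in band_list:
        xb = features.band_matrix(b)  # raises on a missing band
        band_seed = seed + 1000 * b
        spec_b = spec if spec is not None else tune_svm(xb, y, budget=budget,
                                                        k=k, seed=band_seed)
        reports[b] = evaluate(xb, y, spec_b, groups=groups, split=split, k=k,
                              repeats=repeats, seed=band_seed,
                              identifier=f"band {b}")
    ranking = sorted(band_list, key=lambda b: (-reports[b].accuracy, b))
    return {"reports": reports, "ranking": ranking, "top5": ranking[:5],
            "mean_accuracy": float(np.mean([reports[b].accuracy for b in band_list]))}
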