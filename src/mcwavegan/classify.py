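"""Reference classifier (MFCC -> LDA -> SVM) and evaluation reporting.

Each 1-s segment is represented by 20 MFCC coefficients, z-scored,
projected by linear discriminant analysis onto C−1 dimensions (2 for
the three hive-event classes), and classified by a linear-kernel SVM.
The module also hosts the class-distribution tables, standard metrics,
and the class-imbalance augmentation experiment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import SegmentSet
from .features import FeatureConfig, MfccExtractor


class LdaSvmClassifier(BaseEstimator, ClassifierMixin):
    """MFCC -> StandardScaler -> LDA(C−1) -> linear SVM.

    ``X`` is a ``(n, segment_len)`` array of waveform segments sampled at
    ``rate``.  Deterministic given the data.
    """

    def __init__(self, rate: float = 16384.0, svm_c: float = 1.0,
                 feature_config: FeatureConfig | None = None):
        self.rate = rate
        self.svm_c = svm_c
        self.feature_config = feature_config

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("LdaSvmClassifier requires at least 2 classes")
        n_components = len(classes) - 1
        self.pipeline_ = Pipeline(
            [
                ("mfcc", MfccExtractor(rate=self.rate, config=self.feature_config)),
                ("scale", StandardScaler()),
                ("lda", LinearDiscriminantAnalysis(n_components=n_components)),
                ("svm", SVC(kernel="linear", C=self.svm_c)),
            ]
        )
        self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
        self.n_components_ = n_components
        return self

    def predict(self, X):
        if not hasattr(self, "pipeline_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.pipeline_.predict(X)

    def transform_lda(self, X):
        """Project segments into the discriminant plane (n, C−1)."""
        if not hasattr(self, "pipeline_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        partial = Pipeline(self.pipeline_.steps[:-1])
        return partial.transform(X)

    # SegmentSet conveniences --------------------------------------------
    def fit_segments(self, segments: SegmentSet):
        self.rate = segments.rate
        return self.fit(segments.segments, segments.labels.astype(str))

    def predict_segments(self, segments: SegmentSet):
        return self.predict(segments.segments)


def fit(train: SegmentSet, svm_c: float = 1.0,
        feature_config: FeatureConfig | None = None) -> LdaSvmClassifier:
    """Module-level front of :meth:`LdaSvmClassifier.fit_segments`."""
    model = LdaSvmClassifier(rate=train.rate, svm_c=svm_c, feature_config=feature_config)
    return model.fit_segments(train)


def classify(model: LdaSvmClassifier, segments: SegmentSet) -> np.ndarray:
    return model.predict_segments(segments)


def class_distribution(predictions, alphabet) -> pd.DataFrame:
    """Counts and percentages per class; counts sum to n by construction."""
    predictions = np.asarray(predictions)
    n = len(predictions)
    counts = [int(np.sum(predictions == c)) for c in alphabet]
    pct = [100.0 * c / n if n else 0.0 for c in counts]
    return pd.DataFrame({"class": list(alphabet), "count": counts, "percent": pct})


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics.

    ``per_class`` rows: precision/recall/F1/support per label
    (one-vs-rest); ``positive`` holds the metrics of the designated
    positive class; macro averages are included since table-style
    reports are sometimes macro-averaged and sometimes minority-class.
    """

    accuracy: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame  # rows = truth, columns = predicted
    positive_class: str
    precision: float
    recall: float
    f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float


def metrics(predictions, truths, positive_class) -> MetricsReport:
    """Standard one-vs-rest metrics with precision/recall = 0 when undefined."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    labels = sorted(set(truths) | set(predictions) | {positive_class})
    prec, rec, f1, support = precision_recall_fscore_support(
        truths, predictions, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {"class": labels, "precision": prec, "recall": rec, "f1": f1, "support": support}
    ).set_index("class")
    cm = confusion_matrix(truths, predictions, labels=labels)
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    acc = float(accuracy_score(truths, predictions))
    pos = per_class.loc[positive_class]
    return MetricsReport(
        accuracy=acc,
        per_class=per_class,
        confusion=confusion,
        positive_class=positive_class,
        precision=float(pos["precision"]),
        recall=float(pos["recall"]),
        f1=float(pos["f1"]),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
    )


def _segment_hash(segments: SegmentSet) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(segments.segments).tobytes())
    h.update("|".join(map(str, segments.labels)).encode())
    return h.hexdigest()


def run_augmentation_experiment(
    real: SegmentSet,
    synthetic: SegmentSet,
    minority_class: str,
    steps,
    test_size: float = 0.2,
    seed: int = 0,
    svm_c: float = 1.0,
) -> pd.DataFrame:
    """Class-imbalance augmentation sweep.

    The real set is split stratified 80/20 once; the test split is
    frozen before any augmentation.  The training set starts with the
    minority class at ``steps[0]`` (a proportion of the total training
    set, e.g. 0.20) using real minority samples only, and each further
    step adds synthetic minority samples until the requested proportion
    is reached.  Every row reports minority-class precision/recall/F1
    and overall accuracy on the fixed real test split.
    """
    steps = [float(s) / 100.0 if s > 1 else float(s) for s in steps]
    if any(not (0 < s < 1) for s in steps):
        raise ValueError("steps must be proportions in (0, 1) (or percents in (0, 100))")
    if not np.all(synthetic.labels == minority_class):
        raise ValueError("synthetic set must contain only minority-class samples")

    idx = np.arange(len(real))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_size, random_state=seed, stratify=real.labels.astype(str)
    )
    train, test = real.subset(train_idx), real.subset(test_idx)
    test_hash = _segment_hash(test)

    maj_mask = train.labels != minority_class
    majority = train.subset(np.flatnonzero(maj_mask))
    minority_real = train.subset(np.flatnonzero(~maj_mask))
    n_maj = len(majority)

    # the first step defines the scarce-real baseline: real minority
    # samples are capped there, and every later step is reached by
    # adding synthetic minority samples only
    n_real_base = min(
        int(round(steps[0] / (1.0 - steps[0]) * n_maj)), len(minority_real)
    )

    rng = np.random.default_rng(seed)
    rows = []
    for step in steps:
        n_min_target = int(round(step / (1.0 - step) * n_maj))
        n_real_min = min(n_min_target, n_real_base)
        n_syn = n_min_target - n_real_min
        if n_syn > len(synthetic):
            raise ValueError(
                f"step {step:.3f} needs {n_syn} synthetic minority samples, "
                f"only {len(synthetic)} available (short by {n_syn - len(synthetic)})"
            )
        parts = [majority, minority_real.subset(np.arange(n_real_min))]
        if n_syn:
            pick = rng.choice(len(synthetic), size=n_syn, replace=False)
            syn = synthetic.subset(pick)
            parts.append(syn)
        train_step = SegmentSet.concatenate(parts)
        model = LdaSvmClassifier(rate=real.rate, svm_c=svm_c)
        model.fit(train_step.segments, train_step.labels.astype(str))
        pred = model.predict(test.segments)
        rep = metrics(pred, test.labels.astype(str), minority_class)
        assert _segment_hash(test) == test_hash, "test split changed during augmentation"
        rows.append(
            {
                "minority_proportion": step,
                "n_majority": n_maj,
                "n_minority_real": n_real_min,
                "n_minority_synthetic": n_syn,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
                "accuracy": rep.accuracy,
                "macro_f1": rep.macro_f1,
            }
        )
    return pd.DataFrame(rows)
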