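"""Confusion-matrix metrics (support-weighted precision/recall/F1) and the
tf-idf Naive Bayes baseline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.naive_bayes import MultinomialNB

from textcam.preprocess import Document, TokenizerConfig, tokenize


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints; rows = true class, cols = predicted
    class_labels: list[int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float
    class_labels: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "weighted_recall": self.weighted_recall,
            "weighted_precision": self.weighted_precision,
            "weighted_f1": self.weighted_f1,
            "accuracy": self.accuracy,
            "per_class": [
                {
                    "label": int(lbl),
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for lbl, p, r, f, s in zip(
                    self.class_labels, self.precision, self.recall, self.f1, self.support
                )
            ],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label,precision,recall,f1,support\n")
            for lbl, p, r, f, s in zip(
                self.class_labels, self.precision, self.recall, self.f1, self.support
            ):
                fh.write(f"{lbl},{p},{r},{f},{s}\n")
            fh.write(
                f"weighted,{self.weighted_precision},{self.weighted_recall},"
                f"{self.weighted_f1},{int(self.support.sum())}\n"
            )


def confusion(
    preds: Sequence[int], labels: Sequence[int], n_classes: Optional[int] = None
) -> ConfusionMatrix:
    """counts[i, j] = number of documents with true class i predicted as j."""
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if preds.shape != labels.shape:
        raise ValueError(f"length mismatch: {len(preds)} predictions, {len(labels)} labels")
    if preds.size == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    if n_classes is None:
        n_classes = int(max(preds.max(), labels.max())) + 1
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (labels, preds), 1)
    return ConfusionMatrix(counts=counts, class_labels=list(range(n_classes)))


def weighted_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F1 (0/0 -> 0) and their support-weighted
    averages; weighted recall coincides with accuracy."""
    counts = cm.counts.astype(np.float64)
    if counts.sum() <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    support = counts.sum(axis=1)
    predicted = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / np.where(predicted > 0, predicted, 1), 0.0)
        recall = np.where(support > 0, tp / np.where(support > 0, support, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    n = counts.sum()
    weights = support / n
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(np.int64),
        weighted_precision=float((weights * precision).sum()),
        weighted_recall=float((weights * recall).sum()),
        weighted_f1=float((weights * f1).sum()),
        accuracy=float(tp.sum() / n),
        class_labels=list(cm.class_labels),
    )


def baseline_nb(
    train_docs: Sequence[Document],
    test_docs: Sequence[Document],
    rules: TokenizerConfig = TokenizerConfig(),
    alpha: float = 1.0,
) -> MetricsReport:
    """Multinomial Naive Bayes over tf-idf features of the raw tokenized
    text — no grid formatting, no padding, no word embedding."""
    if not train_docs or not test_docs:
        raise ValueError("both train and test splits must be non-empty")
    vectorizer = TfidfVectorizer(analyzer=lambda text: tokenize(text, rules))
    x_train = vectorizer.fit_transform([d.text for d in train_docs])
    if x_train.shape[1] == 0:
        raise ValueError("empty vocabulary after tokenization")
    y_train = np.array([d.label for d in train_docs], dtype=np.int64)
    clf = MultinomialNB(alpha=alpha)
    clf.fit(x_train, y_train)
    x_test = vectorizer.transform([d.text for d in test_docs])
    preds = clf.predict(x_test).astype(np.int64)
    labels = np.array([d.label for d in test_docs], dtype=np.int64)
    n_classes = int(max(labels.max(), preds.max(), y_train.max())) + 1
    return weighted_metrics(confusion(preds, labels, n_classes=n_classes))
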