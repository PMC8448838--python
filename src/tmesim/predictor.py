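"""Test phase: the phenotype classifier that replaces Q-value computation.

The experience dataset is rescaled attribute-wise to [0, 1] and fed to a
fully connected feedforward network with two hidden layers of 35 and 25
nodes (logistic activations, softmax/cross-entropy output); the output
width equals the number of phenotypes of the agent class -- five for cells,
three for vessels.  During the test phase every agent's next phenotype is
the argmax class for its current record.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier

from .sarsa import LABEL_COLUMN, ExperienceDataset


@dataclasses.dataclass
class NormalizationSpec:
    """Per-attribute (min, max) learned from the training dataset."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.hi < self.lo):
            raise ValueError("normalization requires min <= max per attribute")

    def apply(self, x: np.ndarray) -> np.ndarray:
        """(v − min)/(max − min); constant attributes map to 0."""
        span = self.hi - self.lo
        safe = np.where(span > 0, span, 1.0)
        return np.where(span > 0, (x - self.lo) / safe, 0.0)

    def invert(self, z: np.ndarray) -> np.ndarray:
        return z * (self.hi - self.lo) + self.lo


def normalize(x: np.ndarray, spec: NormalizationSpec | None = None
              ) -> tuple[np.ndarray, NormalizationSpec]:
    """Rescale attributes to [0, 1]; returns the data and the spec used."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty dataset")
    if spec is None:
        spec = NormalizationSpec(x.min(axis=0), x.max(axis=0))
    return spec.apply(x), spec


@dataclasses.dataclass
class ClassifierSpec:
    """Architecture and training hyperparameters."""

    n_outputs: int  # 5 for cells, 3 for vessels
    hidden: tuple[int, int] = (35, 25)
    epochs: int = 200
    learning_rate: float = 0.01


class PhenotypeModel:
    """A trained classifier plus its normalization spec and feature schema."""

    def __init__(self, clf: MLPClassifier, norm: NormalizationSpec,
                 feature_columns: list[str], spec: ClassifierSpec):
        self.clf = clf
        self.norm = norm
        self.feature_columns = feature_columns
        self.spec = spec

    @property
    def n_outputs(self) -> int:
        return self.spec.n_outputs

    @property
    def classes_(self) -> np.ndarray:
        return self.clf.classes_

    def predict(self, records: np.ndarray) -> np.ndarray:
        """Argmax phenotype per record; ties break toward the lowest class."""
        records = np.atleast_2d(np.asarray(records, dtype=float))
        if records.shape[1] != len(self.feature_columns):
            raise ValueError(
                f"record has {records.shape[1]} attributes, model expects "
                f"{len(self.feature_columns)}")
        proba = self.clf.predict_proba(self.norm.apply(records))
        return self.classes_[np.argmax(proba, axis=1)].astype(int)

    def predict_proba(self, records: np.ndarray) -> np.ndarray:
        records = np.atleast_2d(np.asarray(records, dtype=float))
        return self.clf.predict_proba(self.norm.apply(records))

    def sample(self, records: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw one phenotype per record from the predicted distribution.

        The classifier distills the stochastic roulette policy; sampling
        from its softmax output reproduces that policy's action mixture,
        where the argmax would collapse it to a single phenotype per state.
        """
        proba = self.predict_proba(records)
        u = rng.random(proba.shape[0])
        cum = np.cumsum(proba, axis=1)
        idx = np.minimum((u[:, None] >= cum).sum(axis=1), proba.shape[1] - 1)
        return self.classes_[idx].astype(int)

    # -- portable JSON weights -------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_columns": self.feature_columns,
            "spec": dataclasses.asdict(self.spec),
            "norm": {"lo": self.norm.lo.tolist(), "hi": self.norm.hi.tolist()},
            "classes": self.clf.classes_.tolist(),
            "coefs": [w.tolist() for w in self.clf.coefs_],
            "intercepts": [b.tolist() for b in self.clf.intercepts_],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PhenotypeModel":
        payload = json.loads(Path(path).read_text())
        spec = ClassifierSpec(**{**payload["spec"],
                                 "hidden": tuple(payload["spec"]["hidden"])})
        clf = _rebuild_mlp(payload, spec)
        norm = NormalizationSpec(np.array(payload["norm"]["lo"]),
                                 np.array(payload["norm"]["hi"]))
        return cls(clf, norm, payload["feature_columns"], spec)


def _rebuild_mlp(payload, spec: ClassifierSpec) -> MLPClassifier:
    clf = MLPClassifier(hidden_layer_sizes=spec.hidden, activation="logistic")
    clf.coefs_ = [np.array(w) for w in payload["coefs"]]
    clf.intercepts_ = [np.array(b) for b in payload["intercepts"]]
    clf.classes_ = np.array(payload["classes"])
    clf.n_layers_ = len(clf.coefs_) + 1
    clf.n_outputs_ = clf.coefs_[-1].shape[1]  # 1 for binary models
    clf.out_activation_ = "softmax" if clf.n_outputs_ > 1 else "logistic"
    clf._label_binarizer = _binarizer(clf.classes_)
    return clf


def _binarizer(classes):
    from sklearn.preprocessing import LabelBinarizer

    lb = LabelBinarizer()
    lb.fit(classes)
    return lb


def fit_classifier(dataset: ExperienceDataset | np.ndarray,
                   spec: ClassifierSpec,
                   rng: np.random.Generator,
                   columns: list[str] | None = None,
                   max_records: int | None = None) -> PhenotypeModel:
    """Fit the feedforward phenotype classifier on an experience dataset.

    Labels are the chosen-phenotype column; all other attributes (except
    provenance) are features.  Deterministic given the RNG.  A single-class
    dataset yields a constant predictor with a warning.
    """
    if isinstance(dataset, ExperienceDataset):
        data = dataset.to_array()
        columns = dataset.columns
    else:
        data = np.atleast_2d(np.asarray(dataset, dtype=float))
        if columns is None:
            raise ValueError("columns required for a raw array dataset")
    if data.shape[0] == 0:
        raise ValueError("cannot fit a classifier on an empty dataset")
    # Q-values are recorded for provenance but are unavailable in the test
    # phase (the classifier replaces their computation), so they are not
    # model inputs.
    label_idx = columns.index(LABEL_COLUMN)
    feature_idx = [i for i, c in enumerate(columns)
                   if c not in (LABEL_COLUMN, "repetition", "q", "prev_q")]
    feature_columns = [columns[i] for i in feature_idx]
    if max_records is not None and data.shape[0] > max_records:
        sel = rng.choice(data.shape[0], size=max_records, replace=False)
        data = data[sel]
    x = data[:, feature_idx]
    y = data[:, label_idx].astype(int)
    xn, norm = normalize(x)
    seed = int(rng.integers(2**31))
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden,
        activation="logistic",
        learning_rate_init=spec.learning_rate,
        max_iter=spec.epochs,
        random_state=seed,
    )
    if np.unique(y).size < 2:
        warnings.warn("single-class dataset: fitting a constant predictor",
                      stacklevel=2)
        clf = _ConstantPredictor(int(y[0]))
        model = PhenotypeModel(clf, norm, feature_columns, spec)
        model.training_accuracy = 1.0
        return model
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(xn, y)
    model = PhenotypeModel(clf, norm, feature_columns, spec)
    model.training_accuracy = float(clf.score(xn, y))
    return model


class _ConstantPredictor:
    """Degenerate stand-in when the dataset contains a single class."""

    def __init__(self, label: int):
        self.classes_ = np.array([label])

    def predict_proba(self, x):
        return np.ones((np.atleast_2d(x).shape[0], 1))


def predict_phenotype(model: PhenotypeModel, record: np.ndarray) -> int:
    """Predict the next phenotype for one record."""
    return int(model.predict(np.atleast_2d(record))[0])
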