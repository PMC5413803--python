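"""The three PDT classifier families under one score/predict contract.

* SVM — maximum-margin classifier with a polynomial kernel
  K(x, z) = (x.z + 1)^d; the decision score is the signed margin
  f(x) = sum_i alpha_i y_i K(x_i, x) + b, class = sign(f), ties -> control.
* RBFN — radial basis function network: K prototype vectors chosen by
  k-means on the training inputs, Gaussian activations
  a_i(x) = exp(-beta_i ||x - mu_i||^2) with beta_i = 1/(2 sigma_i^2) from the
  within-cluster spread, and one linear output node per class fit by least
  squares against one-hot targets; class = argmax over output nodes.
* RF — random forest: bootstrap-sampled decision trees with random feature
  subsets per split; the positive-class score is the fraction of trees
  voting positive, class = majority vote, ties -> control.

SVM and RBFN standardize features internally (fit on training data only);
the forest operates on raw features.  Every model exposes
``fit(dataset)``, ``predict(X) -> {-1,+1}`` and a monotone
``decision_score(X)`` usable for ROC analysis, plus a JSON-serializable
``to_dict``/``from_dict`` pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .errors import ContractError, DataError, ParameterError, TrainingError

__all__ = [
    "LabeledDataset",
    "ClassifierSpec",
    "polynomial_kernel",
    "SVMClassifier",
    "RBFNClassifier",
    "RFClassifier",
    "make_classifier",
    "save_model",
    "load_model",
]

POSITIVE, NEGATIVE = 1, -1  # +1 patient, -1 control


@dataclass
class LabeledDataset:
    """Feature matrix with +/-1 class labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ContractError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ContractError("y length must match number of rows of X")
        if self.X.shape[0] < 2:
            raise DataError("need at least 2 samples")
        if not np.all(np.isfinite(self.X)):
            raise DataError("missing/non-finite feature values")
        if not set(np.unique(self.y)) <= {NEGATIVE, POSITIVE}:
            raise ContractError("labels must be +1 (patient) or -1 (control)")
        if len(self.feature_names) != self.X.shape[1]:
            raise ContractError("feature_names length must match number of columns")
        if self.subject_ids is not None and len(self.subject_ids) != self.X.shape[0]:
            raise ContractError("subject_ids length must match number of rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def both_classes(self) -> bool:
        return {NEGATIVE, POSITIVE} <= set(np.unique(self.y))

    def subset(self, columns: Sequence[int]) -> "LabeledDataset":
        """Restrict to the given feature columns."""
        cols = list(columns)
        return LabeledDataset(
            X=self.X[:, cols],
            y=self.y,
            feature_names=[self.feature_names[j] for j in cols],
            subject_ids=self.subject_ids,
        )

    def rows(self, index: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(index)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=self.feature_names,
            subject_ids=[self.subject_ids[i] for i in idx] if self.subject_ids else None,
        )


def polynomial_kernel(x: np.ndarray, z: np.ndarray, degree: int = 2, coef0: float = 1.0) -> float:
    """K(x, z) = (x.z + coef0)^degree."""
    return float((np.dot(np.asarray(x, float), np.asarray(z, float)) + coef0) ** degree)


class _Standardizer:
    """Per-feature zero-mean unit-variance scaling fit on training data only."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "_Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], float)
        s.scale_ = np.asarray(d["scale"], float)
        return s


class _BaseClassifier:
    """Common checks for the three families."""

    m_: int

    def _check_fitted(self) -> None:
        if not hasattr(self, "m_"):
            raise ContractError(f"{type(self).__name__} is not fitted")

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.m_:
            raise ContractError(
                f"dimension mismatch: model expects {self.m_} features, got {X.shape[1]}"
            )
        return X

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels from the decision score; ties go to the control class."""
        return np.where(self.decision_score(X) > 0, POSITIVE, NEGATIVE)

    def decision_score(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @staticmethod
    def _require_both_classes(data: LabeledDataset) -> None:
        if not data.both_classes:
            raise TrainingError("training data must contain both classes")


class SVMClassifier(_BaseClassifier):
    """Polynomial-kernel support vector machine (maximum-margin separator)."""

    def __init__(self, degree: int = 2, C: float = 1.0, coef0: float = 1.0):
        if degree < 1:
            raise ParameterError(f"degree must be >= 1, got {degree}")
        if C <= 0:
            raise ParameterError(f"C must be positive, got {C}")
        self.degree = degree
        self.C = C
        self.coef0 = coef0

    def fit(self, data: LabeledDataset) -> "SVMClassifier":
        self._require_both_classes(data)
        self.m_ = data.m
        self.scaler_ = _Standardizer().fit(data.X)
        self.svc_ = SVC(
            kernel="poly", degree=self.degree, gamma=1.0, coef0=self.coef0, C=self.C
        )
        self.svc_.fit(self.scaler_.transform(data.X), data.y)
        return self

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        """Signed margin f(x) = sum_i alpha_i y_i K(x_i, x) + b."""
        X = self._check_X(X)
        return self.svc_.decision_function(self.scaler_.transform(X))

    @property
    def dual_coef_signed(self) -> np.ndarray:
        """alpha_i * y_i for each support vector (KKT check: they sum to ~0)."""
        self._check_fitted()
        return self.svc_.dual_coef_.ravel()

    @property
    def alphas(self) -> np.ndarray:
        return np.abs(self.dual_coef_signed)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "family": "svm",
            "degree": self.degree,
            "C": self.C,
            "coef0": self.coef0,
            "scaler": self.scaler_.to_dict(),
            "support_vectors": self.svc_.support_vectors_.tolist(),
            "dual_coef": self.svc_.dual_coef_.ravel().tolist(),
            "intercept": float(self.svc_.intercept_[0]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_LoadedSVM":
        return _LoadedSVM(d)


class _LoadedSVM(_BaseClassifier):
    """SVM restored from its JSON form; scores via the explicit kernel sum."""

    def __init__(self, d: dict):
        self.degree = int(d["degree"])
        self.coef0 = float(d["coef0"])
        self.scaler_ = _Standardizer.from_dict(d["scaler"])
        self.sv_ = np.asarray(d["support_vectors"], float)
        self.dual_ = np.asarray(d["dual_coef"], float)
        self.b_ = float(d["intercept"])
        self.m_ = self.sv_.shape[1]

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        Z = self.scaler_.transform(X)
        K = (Z @ self.sv_.T + self.coef0) ** self.degree
        return K @ self.dual_ + self.b_


class RBFNClassifier(_BaseClassifier):
    """Radial basis function network with k-means prototypes.

    Output scores are one linear combination of Gaussian activations per
    class; ``decision_score`` is score(+1) - score(-1) and ``predict_proba``
    the softmax of the two output nodes.
    """

    WIDTH_FLOOR = 1e-6

    def __init__(self, n_clusters: int = 2, seed: int = 0):
        if n_clusters < 1:
            raise ParameterError(f"n_clusters must be >= 1, got {n_clusters}")
        self.n_clusters = n_clusters
        self.seed = seed

    def fit(self, data: LabeledDataset) -> "RBFNClassifier":
        # single-class data is allowed: the least-squares readout simply
        # learns a constant in favour of that class
        if self.n_clusters > data.n:
            raise ParameterError(
                f"n_clusters={self.n_clusters} exceeds sample count {data.n}"
            )
        self.m_ = data.m
        self.scaler_ = _Standardizer().fit(data.X)
        Z = self.scaler_.transform(data.X)
        km = KMeans(n_clusters=self.n_clusters, n_init=1, random_state=self.seed)
        labels = km.fit_predict(Z)
        self.prototypes_ = km.cluster_centers_
        sigmas = np.empty(self.n_clusters)
        for i in range(self.n_clusters):
            members = Z[labels == i]
            if members.size:
                d2 = np.sum((members - self.prototypes_[i]) ** 2, axis=1)
                sigmas[i] = np.sqrt(np.mean(d2))
            else:  # k-means relocates empty clusters; guard anyway
                sigmas[i] = 0.0
        if self.n_clusters > 1:
            # Moody-Darken-style floor: a near-degenerate cluster (tiny
            # within-spread) must still respond on the scale of the gap to
            # its nearest neighbour, or held-out points fall back to the bias
            dc = np.linalg.norm(
                self.prototypes_[:, None, :] - self.prototypes_[None, :, :], axis=2
            )
            np.fill_diagonal(dc, np.inf)
            sigmas = np.maximum(sigmas, 0.5 * dc.min(axis=1))
        self.betas_ = 1.0 / (2.0 * np.maximum(sigmas, self.WIDTH_FLOOR) ** 2)
        Phi = self._activations(Z)
        A = np.column_stack([Phi, np.ones(data.n)])
        # one-hot targets, output order (negative, positive)
        T = np.column_stack([(data.y == NEGATIVE), (data.y == POSITIVE)]).astype(float)
        self.weights_, *_ = np.linalg.lstsq(A, T, rcond=None)
        return self

    def _activations(self, Z: np.ndarray) -> np.ndarray:
        d2 = ((Z[:, None, :] - self.prototypes_[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.betas_[None, :] * d2)

    def activations(self, X: np.ndarray) -> np.ndarray:
        """Gaussian neuron activations for raw-feature inputs."""
        X = self._check_X(X)
        return self._activations(self.scaler_.transform(X))

    def output_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) linear output-node scores, column order (negative, positive)."""
        X = self._check_X(X)
        Phi = self._activations(self.scaler_.transform(X))
        return np.column_stack([Phi, np.ones(Phi.shape[0])]) @ self.weights_

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        s = self.output_scores(X)
        return s[:, 1] - s[:, 0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability surrogate: softmax over the two outputs."""
        s = self.output_scores(X)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e[:, 1] / e.sum(axis=1)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "family": "rbfn",
            "n_clusters": self.n_clusters,
            "seed": self.seed,
            "scaler": self.scaler_.to_dict(),
            "prototypes": self.prototypes_.tolist(),
            "betas": self.betas_.tolist(),
            "weights": self.weights_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFNClassifier":
        model = cls(n_clusters=int(d["n_clusters"]), seed=int(d["seed"]))
        model.scaler_ = _Standardizer.from_dict(d["scaler"])
        model.prototypes_ = np.asarray(d["prototypes"], float)
        model.betas_ = np.asarray(d["betas"], float)
        model.weights_ = np.asarray(d["weights"], float)
        model.m_ = model.prototypes_.shape[1]
        return model


class RFClassifier(_BaseClassifier):
    """Random forest: bagged decision trees with per-split feature sampling."""

    def __init__(self, n_trees: int = 100, seed: int = 0, max_features: str | int = "sqrt"):
        if n_trees < 1:
            raise ParameterError(f"n_trees must be >= 1, got {n_trees}")
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features

    def fit(self, data: LabeledDataset, *, oob: bool = False) -> "RFClassifier":
        self._require_both_classes(data)
        self.m_ = data.m
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features=self.max_features,
            bootstrap=True,
            oob_score=oob,
            random_state=self.seed,
        )
        import warnings

        with warnings.catch_warnings():
            # tiny n can leave a few samples with no OOB vote; handled below
            warnings.filterwarnings("ignore", message=".*out-of-bag.*")
            self.forest_.fit(data.X, data.y)
        return self

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive class, in [0, 1]."""
        X = self._check_X(X)
        pos_col = int(np.where(self.forest_.classes_ == POSITIVE)[0][0])
        return self.forest_.predict_proba(X)[:, pos_col]

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        """Vote fraction centered at 0 so that sign(score) is the majority vote."""
        return self.vote_fraction(X) - 0.5

    @property
    def oob_accuracy(self) -> float:
        """Out-of-bag accuracy (requires ``fit(..., oob=True)``)."""
        self._check_fitted()
        if not getattr(self.forest_, "oob_score", False):
            raise ContractError("forest was fit without oob=True")
        return float(self.forest_.oob_score_)

    def to_dict(self) -> dict:
        self._check_fitted()
        trees = []
        for est in self.forest_.estimators_:
            t = est.tree_
            trees.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "value": t.value[:, 0, :].tolist(),
                }
            )
        return {
            "family": "rf",
            "n_trees": self.n_trees,
            "seed": self.seed,
            "classes": self.forest_.classes_.tolist(),
            "n_features": self.m_,
            "trees": trees,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_LoadedRF":
        return _LoadedRF(d)


class _LoadedRF(_BaseClassifier):
    """Forest restored from exported tree arrays; votes by explicit traversal."""

    def __init__(self, d: dict):
        self.m_ = int(d["n_features"])
        self.classes_ = np.asarray(d["classes"], int)
        self.trees_ = d["trees"]

    @staticmethod
    def _tree_votes(tree: dict, X: np.ndarray) -> np.ndarray:
        left = tree["children_left"]
        right = tree["children_right"]
        feat = tree["feature"]
        thr = tree["threshold"]
        value = tree["value"]
        out = np.empty(X.shape[0], dtype=int)
        for r in range(X.shape[0]):
            node = 0
            while left[node] != -1:
                node = left[node] if X[r, feat[node]] <= thr[node] else right[node]
            out[r] = int(np.argmax(value[node]))
        return out

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        pos_col = int(np.where(self.classes_ == POSITIVE)[0][0])
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += self._tree_votes(tree, X) == pos_col
        return votes / len(self.trees_)

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        return self.vote_fraction(X) - 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    """Named configuration for one classifier family (hashable, reusable)."""

    family: str  # "svm" | "rbfn" | "rf"
    degree: int = 2
    C: float = 1.0
    n_clusters: int = 2
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("svm", "rbfn", "rf"):
            raise ParameterError(f"unknown classifier family {self.family!r}")

    def make(self):
        return make_classifier(self)


def make_classifier(spec: ClassifierSpec):
    if spec.family == "svm":
        return SVMClassifier(degree=spec.degree, C=spec.C)
    if spec.family == "rbfn":
        return RBFNClassifier(n_clusters=spec.n_clusters, seed=spec.seed)
    return RFClassifier(n_trees=spec.n_trees, seed=spec.seed)


_FAMILIES = {"svm": SVMClassifier, "rbfn": RBFNClassifier, "rf": RFClassifier}


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a documented JSON file."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path):
    """Restore a model saved by :func:`save_model`."""
    d = json.loads(Path(path).read_text())
    family = d.get("family")
    if family not in _FAMILIES:
        raise ParameterError(f"unknown model family {family!r} in {path}")
    return _FAMILIES[family].from_dict(d)
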