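"""Three-level slice triage via discrete AdaBoost over depth-3 CART trees.

A binary boosted classifier (hot spot present / absent) is trained on
pooled sparse-code image features.  Its signed vote sum ("margin")
doubles as a confidence: slices whose |margin| falls inside a band
[-theta, theta] are labelled *uncertain* rather than forced into a binary
call, giving the three clinical levels

    I   margin >  theta   — hot spot certainly present
    II  |margin| <= theta — uncertain
    III margin < -theta   — no hot spot.

The band width theta is calibrated on held-out data as a low percentile
of |margin| (the classifier's least confident calls).
"""

from __future__ import annotations

import json
import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier

from .exceptions import InputError, SizeError, TrainingError
from .phantom import LEVEL_I, LEVEL_II, LEVEL_III

_EPS_FLOOR = 1e-10


def alpha_from_error(eps: float, floor: float = _EPS_FLOOR) -> float:
    """AdaBoost learner weight 0.5*ln((1-eps)/eps), with eps floored.

    A perfect learner (eps = 0) would get infinite weight; ``floor``
    (typically 1/(2n), the Laplace-style smoothing) caps it.
    """
    eps = min(max(eps, floor), 1.0 - floor)
    return 0.5 * math.log((1.0 - eps) / eps)


def tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    """Serialize a fitted sklearn CART into a nested plain dict."""
    t = tree.tree_
    classes = tree.classes_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            cls = classes[int(np.argmax(t.value[i][0]))]
            return {"leaf": int(cls)}
        return {
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(int(t.children_left[i])),
            "right": node(int(t.children_right[i])),
        }

    return node(0)


def predict_tree_dict(node: dict, x: np.ndarray) -> int:
    """Traverse a serialized tree for one sample (x[f] <= thr goes left)."""
    while "leaf" not in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return int(node["leaf"])


class AdaBoostTriage(ClassifierMixin, BaseEstimator):
    """Discrete AdaBoost (CART weak learners) with an uncertainty band.

    Parameters
    ----------
    n_rounds : int
        Maximum boosting rounds T.
    max_depth : int
        Weak-learner tree depth (default 3).
    theta : float or None
        Uncertainty band half-width; if None it must be calibrated with
        :meth:`calibrate_theta` before three-level prediction.
    random_state : int
        Seed for the weak-learner tie-breaking.

    Attributes
    ----------
    estimators_ : list of DecisionTreeClassifier
    alphas_ : ndarray — vote weight per learner, 0.5*ln((1-eps)/eps)
    errors_ : ndarray — weighted training error eps_t per kept learner
    trees_ : list of dict — JSON-serializable tree structures
    theta_ : float — calibrated band half-width
    weight_history_ : list of ndarray — sample weights after each round
    """

    def __init__(
        self,
        n_rounds: int = 100,
        max_depth: int = 3,
        theta: float | None = None,
        random_state: int = 0,
    ):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.theta = theta
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if self.n_rounds < 1:
            raise TrainingError("n_rounds must be >= 1")
        if set(np.unique(y)) - {-1, 1}:
            raise TrainingError("labels must be in {-1, +1}")
        if len(np.unique(y)) < 2:
            raise TrainingError("training requires at least one sample per class")

        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        alphas: list[float] = []
        errors: list[float] = []
        self.weight_history_: list[np.ndarray] = []
        for t in range(self.n_rounds):
            tree = DecisionTreeClassifier(
                max_depth=self.max_depth,
                random_state=self.random_state + t,
            ).fit(X, y, sample_weight=w)
            pred = tree.predict(X)
            eps = float(np.sum(w[pred != y]))
            if eps >= 0.5:
                break  # weak learner no better than chance on current weights
            alpha = alpha_from_error(eps, floor=1.0 / (2.0 * n))
            self.estimators_.append(tree)
            alphas.append(alpha)
            errors.append(eps)
            if eps <= 0.0:
                break  # perfect learner; further rounds cannot help
            w = w * np.exp(-alpha * y * pred)
            w = w / w.sum()
            self.weight_history_.append(w.copy())
        if not self.estimators_:
            raise TrainingError(
                "no weak learner achieved error below 0.5 on round 1"
            )
        self.alphas_ = np.asarray(alphas)
        self.errors_ = np.asarray(errors)
        self.trees_ = [tree_to_dict(t) for t in self.estimators_]
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([-1, 1])
        if self.theta is not None:
            self.theta_ = float(self.theta)
        return self

    # -- scoring

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise SizeError(
                f"feature length {X.shape[1]} does not match training "
                f"length {self.n_features_in_}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Signed vote sum: margin(x) = sum_t alpha_t * h_t(x)."""
        X = self._check_X(X)
        out = np.zeros(len(X))
        if hasattr(self, "estimators_") and self.estimators_:
            for alpha, tree in zip(self.alphas_, self.estimators_):
                out += alpha * tree.predict(X)
        else:  # model loaded from JSON — traverse serialized trees
            for alpha, tree in zip(self.alphas_, self.trees_):
                out += alpha * np.array(
                    [predict_tree_dict(tree, x) for x in X]
                )
        return out

    def staged_margins(self, X) -> np.ndarray:
        """Margins after each boosting round, shape (T, n_samples)."""
        X = self._check_X(X)
        stages = np.zeros((len(self.alphas_), len(X)))
        acc = np.zeros(len(X))
        for t, (alpha, tree) in enumerate(zip(self.alphas_, self.estimators_)):
            acc = acc + alpha * tree.predict(X)
            stages[t] = acc
        return stages

    def predict(self, X) -> np.ndarray:
        m = self.decision_function(X)
        return np.where(m > 0, 1, -1)

    # -- three-level rule

    def calibrate_theta(self, X, percentile: float = 10.0) -> float:
        """Set theta to a low percentile of |margin| on held-out data."""
        m = np.abs(self.decision_function(X))
        # nudge just below the percentile so samples sitting exactly on it
        # stay decided (the band test is inclusive: |margin| <= theta -> II)
        self.theta_ = float(max(np.nextafter(np.percentile(m, percentile), 0.0), 0.0))
        return self.theta_

    def predict_level(self, X) -> np.ndarray:
        """Three-level call: I (> theta), II (|margin| <= theta), III (< -theta)."""
        if not hasattr(self, "theta_"):
            raise InputError("theta is not set; call calibrate_theta or pass theta")
        if self.theta_ < 0:
            raise InputError("theta must be >= 0")
        m = self.decision_function(X)
        out = np.full(m.shape, LEVEL_II, dtype=object)
        out[m > self.theta_] = LEVEL_I
        out[m < -self.theta_] = LEVEL_III
        return out.astype(str)

    def training_error_bound(self) -> float:
        """Classical exponential bound prod_t 2*sqrt(eps_t*(1-eps_t))."""
        e = np.clip(self.errors_, 0.0, 1.0)
        return float(np.prod(2.0 * np.sqrt(e * (1.0 - e))))

    # -- serialization

    def to_json(self) -> str:
        return json.dumps(
            {
                "trees": self.trees_,
                "alphas": self.alphas_.tolist(),
                "errors": self.errors_.tolist(),
                "theta": getattr(self, "theta_", None),
                "n_features_in": int(self.n_features_in_),
                "max_depth": self.max_depth,
                "n_rounds": self.n_rounds,
                "random_state": self.random_state,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AdaBoostTriage":
        d = json.loads(text)
        model = cls(
            n_rounds=d["n_rounds"],
            max_depth=d["max_depth"],
            random_state=d["random_state"],
        )
        model.trees_ = d["trees"]
        model.alphas_ = np.asarray(d["alphas"], dtype=float)
        model.errors_ = np.asarray(d["errors"], dtype=float)
        model.n_features_in_ = d["n_features_in"]
        model.classes_ = np.array([-1, 1])
        model.estimators_ = []
        if d["theta"] is not None:
            model.theta_ = float(d["theta"])
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def train_adaboost(
    features, labels, T: int = 100, seed: int = 0, theta: float | None = None
) -> AdaBoostTriage:
    """Fit an :class:`AdaBoostTriage` model on (features, +/-1 labels)."""
    return AdaBoostTriage(
        n_rounds=T, theta=theta, random_state=seed
    ).fit(np.asarray(features, dtype=float), labels)


def margin(model: AdaBoostTriage, x) -> float:
    """Signed confidence of one sample."""
    return float(model.decision_function(np.asarray(x, dtype=float))[0])


def classify_three_level(model: AdaBoostTriage, x) -> str:
    """Apply the three-level band rule to one sample."""
    return str(model.predict_level(np.asarray(x, dtype=float))[0])
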