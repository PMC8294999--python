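"""Multi-instance boosting of hot-spot detectors and probability-map scanning.

Supervision is at the *bag* (image) level: a positive bag (slice with a
lesion) contains at least one lesion-centred patch, a negative bag (clean
slice) contains none.  Instance-level labels are never used — only bag
labels enter the loss

    Loss(m) = - sum_j [ 1(y_j=+1) log p_j + 1(y_j=-1) log(1-p_j) ],

where the bag probability p_j aggregates instance probabilities
p_jl = sigmoid(m(x_jl)) by noisy-OR (default, differentiable) or by max
(subgradient at the argmax).  Boosting follows the classical functional
gradient recipe: per round the instance weights w_jl = -dLoss/dm(x_jl)
are computed, a decision stump is fitted to sign(w) weighted by |w|, and
its coefficient is found by a line search on the loss; the ensemble is
m(x) = sum_t beta_t * m_t(x).

Scanning slides an l-by-l window over an image, sparse-codes each window
with the shared patch dictionary, scores it with the ensemble, and
averages window probabilities into a per-pixel hot-spot probability map.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from .exceptions import InputError, SizeError, TrainingError
from .phantom import PhantomCase
from .sparse_features import Dictionary, encode, grid_positions, patches_on_grid

_CLIP = 1e-12


@dataclass
class Bag:
    """A labelled set of instance feature vectors from one image."""

    instances: np.ndarray  # (k, d)
    label: int  # +1 or -1

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if len(self.instances) < 1:
            raise InputError("a bag needs at least one instance")
        if self.label not in (-1, 1):
            raise InputError("bag label must be +1 or -1")


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def bag_probability(instance_probs, rule: str = "noisy-or") -> float:
    """Aggregate instance probabilities into a bag probability."""
    p = np.asarray(instance_probs, dtype=float)
    if p.size == 0:
        raise InputError("instance probability list is empty")
    if rule == "max":
        return float(p.max())
    if rule == "noisy-or":
        return float(1.0 - np.prod(1.0 - p))
    raise InputError(f"unknown bag rule {rule!r}")


def mil_loss(bag_probs, labels) -> float:
    """Negative log-likelihood of the bag labels under bag probabilities."""
    p = np.clip(np.asarray(bag_probs, dtype=float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise InputError("bag_probs and labels must have equal length")
    pos = y == 1
    return float(-(np.log(p[pos]).sum() + np.log(1.0 - p[~pos]).sum()))


# ---------------------------------------------------------------------------
# decision stumps


@dataclass(frozen=True)
class Stump:
    """h(x) = polarity if x[feature] > threshold else -polarity."""

    feature: int
    threshold: float
    polarity: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = np.where(X[:, self.feature] > self.threshold, 1, -1)
        return self.polarity * raw


def fit_stump(X: np.ndarray, u: np.ndarray) -> Stump:
    """Stump maximizing sum_i u_i * h(x_i) over features/thresholds/polarity.

    u carries both the target sign and the weight magnitude.  Ties are
    broken toward the lowest feature index, then the lowest threshold.
    """
    n, d = X.shape
    total = u.sum()
    best = (-np.inf, 0, -np.inf, 1)  # score, feature, threshold, polarity
    for f in range(d):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        us = u[order]
        # thresholds between consecutive distinct values, plus one below min
        suffix = np.concatenate([[total], total - np.cumsum(us)])
        # suffix[k] = sum of u over instances with rank >= k (x > threshold)
        cut_vals = np.concatenate([[xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0])
        valid = np.concatenate([[True], xs[:-1] < xs[1:]])
        for k in np.flatnonzero(valid):
            score_plus = 2.0 * suffix[k] - total
            for s, score in ((1, score_plus), (-1, -score_plus)):
                if score > best[0] + 1e-15:
                    best = (score, f, float(cut_vals[k]), s)
    return Stump(feature=best[1], threshold=best[2], polarity=best[3])


# ---------------------------------------------------------------------------
# estimator


class MILBoostDetector(BaseEstimator):
    """Boosted decision-stump ensemble trained from bag-level labels.

    Parameters
    ----------
    n_rounds : int
        Maximum boosting rounds T.
    bag_rule : {"noisy-or", "max"}
        Instance-to-bag probability aggregation.
    beta_max : float
        Upper bound of the per-round line search.
    tol : float
        Stop early when a round improves the loss by less than this.

    Attributes
    ----------
    stumps_ : list of Stump
    betas_ : ndarray
    loss_trace_ : list of float — loss before training and after each round
    """

    def __init__(
        self,
        n_rounds: int = 30,
        bag_rule: str = "noisy-or",
        beta_max: float = 10.0,
        tol: float = 1e-9,
        random_state: int = 0,
    ):
        self.n_rounds = n_rounds
        self.bag_rule = bag_rule
        self.beta_max = beta_max
        self.tol = tol
        self.random_state = random_state

    # -- internals

    def _bag_probs(self, scores: np.ndarray, bag_idx: np.ndarray, n_bags: int):
        p_inst = sigmoid(scores)
        p_bag = np.empty(n_bags)
        for j in range(n_bags):
            p_bag[j] = bag_probability(p_inst[bag_idx == j], self.bag_rule)
        return p_inst, p_bag

    def _instance_weights(
        self,
        p_inst: np.ndarray,
        p_bag: np.ndarray,
        bag_idx: np.ndarray,
        labels: np.ndarray,
    ) -> np.ndarray:
        """w_jl = -dLoss/dm(x_jl) for the chosen bag rule."""
        w = np.zeros_like(p_inst)
        pb = np.clip(p_bag, _CLIP, 1.0 - _CLIP)
        if self.bag_rule == "noisy-or":
            for j, y in enumerate(labels):
                sel = bag_idx == j
                if y == 1:
                    w[sel] = (1.0 - pb[j]) * p_inst[sel] / pb[j]
                else:
                    w[sel] = -p_inst[sel]
        else:  # max rule: subgradient concentrated at the (first) argmax
            for j, y in enumerate(labels):
                sel = np.flatnonzero(bag_idx == j)
                top = sel[int(np.argmax(p_inst[sel]))]
                w[top] = (1.0 - pb[j]) if y == 1 else -pb[j]
        return w

    # -- sklearn-style API

    def fit(self, bags: list[Bag], y=None):
        if self.n_rounds < 0:
            raise TrainingError("n_rounds must be >= 0")
        labels = np.array([b.label for b in bags], dtype=int)
        if len(set(labels)) < 2:
            raise TrainingError("training requires positive and negative bags")
        X = np.vstack([b.instances for b in bags])
        bag_idx = np.concatenate(
            [np.full(len(b.instances), j) for j, b in enumerate(bags)]
        )
        n_bags = len(bags)

        scores = np.zeros(len(X))
        self.stumps_: list[Stump] = []
        betas: list[float] = []
        _, p_bag = self._bag_probs(scores, bag_idx, n_bags)
        trace = [mil_loss(p_bag, labels)]
        for _ in range(self.n_rounds):
            p_inst, p_bag = self._bag_probs(scores, bag_idx, n_bags)
            w = self._instance_weights(p_inst, p_bag, bag_idx, labels)
            stump = fit_stump(X, w)
            h = stump.predict(X).astype(float)

            def round_loss(beta: float) -> float:
                _, pb = self._bag_probs(scores + beta * h, bag_idx, n_bags)
                return mil_loss(pb, labels)

            res = minimize_scalar(
                round_loss, bounds=(0.0, self.beta_max), method="bounded",
                options={"xatol": 1e-6},
            )
            beta = float(res.x)
            new_loss = round_loss(beta)
            if new_loss > trace[-1]:
                beta, new_loss = 0.0, trace[-1]  # keep the trace monotone
            self.stumps_.append(stump)
            betas.append(beta)
            scores = scores + beta * h
            trace.append(new_loss)
            if trace[-2] - trace[-1] < self.tol:
                break
        self.betas_ = np.asarray(betas)
        self.loss_trace_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def instance_score(self, X) -> np.ndarray:
        """Ensemble score m(x) = sum_t beta_t * m_t(x) per instance."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if getattr(self, "stumps_", None):
            if X.shape[1] != self.n_features_in_:
                raise SizeError(
                    f"feature length {X.shape[1]} does not match training "
                    f"length {self.n_features_in_}"
                )
        out = np.zeros(len(X))
        for beta, stump in zip(getattr(self, "betas_", []), getattr(self, "stumps_", [])):
            out += beta * stump.predict(X)
        return out

    def instance_proba(self, X) -> np.ndarray:
        return sigmoid(self.instance_score(X))

    def bag_proba(self, bag: Bag) -> float:
        return bag_probability(self.instance_proba(bag.instances), self.bag_rule)

    def predict_bag(self, bag: Bag) -> int:
        return 1 if self.bag_proba(bag) > 0.5 else -1

    # -- serialization

    def to_json(self) -> str:
        return json.dumps(
            {
                "stumps": [
                    {"feature": s.feature, "threshold": s.threshold,
                     "polarity": s.polarity}
                    for s in self.stumps_
                ],
                "betas": self.betas_.tolist(),
                "loss_trace": self.loss_trace_,
                "bag_rule": self.bag_rule,
                "n_rounds": self.n_rounds,
                "n_features_in": int(self.n_features_in_),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MILBoostDetector":
        d = json.loads(text)
        model = cls(n_rounds=d["n_rounds"], bag_rule=d["bag_rule"])
        model.stumps_ = [Stump(**s) for s in d["stumps"]]
        model.betas_ = np.asarray(d["betas"], dtype=float)
        model.loss_trace_ = d["loss_trace"]
        model.n_features_in_ = d["n_features_in"]
        return model


# ---------------------------------------------------------------------------
# bag construction and scanning


def instance_features(patches, dictionary: Dictionary) -> np.ndarray:
    """Instance feature = magnitude of the patch's sparse code (length m)."""
    return np.abs(encode(patches, dictionary))


def make_bags(
    cases: list[PhantomCase],
    dictionary: Dictionary,
    l: int | None = None,
    per_bag: int = 20,
    seed: int = 0,
    pos_fraction: float = 0.5,
) -> list[Bag]:
    """One bag per image; lesion images give positive bags.

    Positive bags draw at least ``pos_fraction`` of their instances from
    windows centred inside the ground-truth mask (the rest anywhere);
    negative bags come only from lesion-free images.
    """
    if per_bag < 1:
        raise InputError("per_bag must be >= 1")
    l = dictionary.patch_side if l is None else l
    if not any(not c.mask.any() for c in cases):
        raise TrainingError("no lesion-free images available for negative bags")
    rng = np.random.default_rng(seed)
    half = l // 2
    bags: list[Bag] = []
    for case in cases:
        H, W = case.image.shape
        if l > min(H, W):
            raise SizeError("window larger than image")
        if case.mask.any():
            n_pos = max(1, math.ceil(pos_fraction * per_bag))
            centers = np.argwhere(case.mask)
            pick = centers[rng.integers(0, len(centers), size=n_pos)]
            tl = np.clip(pick - half, 0, [H - l, W - l])
            n_rest = per_bag - n_pos
            rows = np.concatenate(
                [tl[:, 0], rng.integers(0, H - l + 1, size=n_rest)]
            )
            cols = np.concatenate(
                [tl[:, 1], rng.integers(0, W - l + 1, size=n_rest)]
            )
            label = 1
        else:
            rows = rng.integers(0, H - l + 1, size=per_bag)
            cols = rng.integers(0, W - l + 1, size=per_bag)
            label = -1
        patches = np.stack(
            [case.image[r : r + l, c : c + l].ravel() for r, c in zip(rows, cols)]
        )
        bags.append(Bag(instances=instance_features(patches, dictionary), label=label))
    return bags


def scan_probability_map(
    model: MILBoostDetector,
    image: np.ndarray,
    dictionary: Dictionary,
    l: int | None = None,
    stride: int = 2,
) -> np.ndarray:
    """Per-pixel hot-spot probability by sliding-window scoring.

    Every window on the stride grid is sparse-coded and scored
    p = sigmoid(m(x)); each pixel receives the mean probability of all
    windows covering it.  Output shape equals the input image.
    """
    image = np.asarray(image, dtype=float)
    l = dictionary.patch_side if l is None else l
    if l > min(image.shape):
        raise SizeError(
            f"window side {l} exceeds image dimensions {image.shape}"
        )
    stride = min(stride, l)  # a stride beyond the window would skip pixels
    ps = patches_on_grid(image, l, stride)
    feats = instance_features(ps, dictionary)
    probs = sigmoid(model.instance_score(feats))
    sums = np.zeros(image.shape)
    counts = np.zeros(image.shape)
    for (r, c), p in zip(ps.positions, probs):
        sums[r : r + l, c : c + l] += p
        counts[r : r + l, c : c + l] += 1.0
    # grid_positions guarantees full coverage, so counts >= 1 everywhere
    return sums / counts


def train_milboost(
    bags: list[Bag], T: int = 30, seed: int = 0, bag_rule: str = "noisy-or"
) -> tuple[MILBoostDetector, list[float]]:
    """Fit a MILBoost detector; returns (model, loss trace)."""
    model = MILBoostDetector(
        n_rounds=T, bag_rule=bag_rule, random_state=seed
    ).fit(bags)
    return model, model.loss_trace_
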