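"""Multi-instance boosting: bag rules, loss, descent, and map scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotspotseg import (
    Bag,
    Dictionary,
    MILBoostDetector,
    PhantomSpec,
    bag_probability,
    generate_phantom,
    make_bags,
    mil_loss,
    scan_probability_map,
    train_milboost,
)
from hotspotseg.exceptions import InputError, SizeError, TrainingError
from hotspotseg.mil_hotspot import Stump, fit_stump, sigmoid


def _planted_bags(n_pos=20, n_neg=20, per_bag=8, d=5, seed=0):
    """Positive bags hide one instance with a high value on coordinate 2."""
    rng = np.random.default_rng(seed)
    bags = []
    for _ in range(n_pos):
        inst = rng.normal(0, 0.3, size=(per_bag, d))
        inst[rng.integers(per_bag), 2] = 3.0 + rng.random()
        bags.append(Bag(instances=inst, label=1))
    for _ in range(n_neg):
        bags.append(Bag(instances=rng.normal(0, 0.3, size=(per_bag, d)), label=-1))
    return bags


# ---------------------------------------------------------------------------
# bag probability and loss


@pytest.mark.parametrize("rule", ["max", "noisy-or"])
def test_single_instance_bag_probability(rule):
    assert bag_probability([0.3], rule) == pytest.approx(0.3)


def test_noisy_or_of_two_halves():
    assert bag_probability([0.5, 0.5], "noisy-or") == pytest.approx(0.75)


def test_max_rule_picks_maximum():
    assert bag_probability([0.2, 0.9, 0.4], "max") == pytest.approx(0.9)


def test_empty_instance_list_rejected():
    with pytest.raises(InputError):
        bag_probability([], "max")
    with pytest.raises(InputError):
        bag_probability([0.5], "unknown-rule")


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
def test_noisy_or_dominates_max_dominates_instances(probs):
    noisy = bag_probability(probs, "noisy-or")
    mx = bag_probability(probs, "max")
    assert noisy >= mx - 1e-12
    assert all(mx >= p - 1e-12 for p in probs)


def test_loss_closed_forms():
    assert mil_loss([1.0], [1]) == pytest.approx(0.0, abs=1e-10)
    assert mil_loss([0.5], [1]) == pytest.approx(np.log(2))
    assert mil_loss([0.0], [-1]) == pytest.approx(0.0, abs=1e-10)
    assert mil_loss([0.0], [1]) > 0  # clipping keeps the loss finite
    assert np.isfinite(mil_loss([0.0], [1]))


def test_loss_nonnegative_random(rng):
    p = rng.random(20)
    y = np.where(rng.random(20) > 0.5, 1, -1)
    assert mil_loss(p, y) >= 0.0


# ---------------------------------------------------------------------------
# stump fitting oracle


def test_stump_matches_exhaustive_search():
    rng = np.random.default_rng(6)
    for _ in range(5):
        X = rng.normal(size=(10, 3))
        u = rng.normal(size=10)
        stump = fit_stump(X, u)
        got = float(u @ stump.predict(X))
        best = -np.inf  # exhaustive oracle over features/cuts/polarities
        for f in range(3):
            for thr in np.concatenate([[X[:, f].min() - 1], X[:, f]]):
                for s in (1, -1):
                    h = s * np.where(X[:, f] > thr, 1, -1)
                    best = max(best, float(u @ h))
        assert got == pytest.approx(best, abs=1e-9)


# ---------------------------------------------------------------------------
# training


def test_empty_ensemble_has_half_probabilities():
    # single-instance bags: the bag probability equals the instance's 0.5
    bags = _planted_bags(2, 2, per_bag=1)
    model = MILBoostDetector(n_rounds=0).fit(bags)
    assert np.allclose(model.instance_proba(bags[0].instances), 0.5)
    n_bags = 4
    assert model.loss_trace_[0] == pytest.approx(n_bags * np.log(2))


@pytest.mark.parametrize("rule", ["noisy-or", "max"])
def test_loss_trace_non_increasing(rule):
    bags = _planted_bags(seed=4)
    model, trace = train_milboost(bags, T=15, seed=0, bag_rule=rule)
    assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))
    # final trace value matches an independent re-evaluation via the
    # bag rule and the negative-log loss
    probs = [bag_probability(model.instance_proba(b.instances), rule) for b in bags]
    labels = [b.label for b in bags]
    assert trace[-1] == pytest.approx(mil_loss(probs, labels), abs=1e-9)


def test_planted_discriminative_feature_is_recovered():
    bags = _planted_bags(seed=1)
    model, _ = train_milboost(bags, T=30, seed=0)
    pred = [model.predict_bag(b) for b in bags]
    assert pred == [b.label for b in bags]


def test_single_label_bags_rejected():
    bags = _planted_bags(n_pos=4, n_neg=0)
    with pytest.raises(TrainingError):
        train_milboost(bags, T=5)


def test_model_json_round_trip():
    bags = _planted_bags(seed=2)
    model, _ = train_milboost(bags, T=10, seed=0)
    clone = MILBoostDetector.from_json(model.to_json())
    X = bags[0].instances
    assert np.allclose(clone.instance_score(X), model.instance_score(X))


# ---------------------------------------------------------------------------
# bag construction from images


def _small_dictionary():
    rng = np.random.default_rng(0)
    atoms = rng.normal(size=(4, 36))
    atoms /= np.linalg.norm(atoms, axis=1, keepdims=True)
    return Dictionary(atoms=atoms, lam=0.1, patch_side=6)


def test_make_bags_labels_and_mask_coverage():
    spec = PhantomSpec(height=64, width=64, n_hotspots=1)
    cases = [
        generate_phantom(spec, seed=1),
        generate_phantom(
            PhantomSpec(height=64, width=64, n_hotspots=0), seed=2
        ),
    ]
    d = _small_dictionary()
    bags = make_bags(cases, d, per_bag=10, seed=0)
    assert [b.label for b in bags] == [1, -1]
    assert all(len(b.instances) == 10 for b in bags)
    # determinism
    again = make_bags(cases, d, per_bag=10, seed=0)
    for a, b in zip(bags, again):
        assert np.array_equal(a.instances, b.instances)


def test_make_bags_requires_negative_images():
    cases = [generate_phantom(PhantomSpec(height=64, width=64), seed=3)]
    with pytest.raises(TrainingError):
        make_bags(cases, _small_dictionary(), per_bag=5, seed=0)


# ---------------------------------------------------------------------------
# probability-map scanning


class _FixedScorer:
    """Duck-typed detector returning preset window scores."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def instance_score(self, X):
        assert len(X) == len(self.scores)
        return self.scores


def test_empty_ensemble_scans_to_uniform_half():
    bags = _planted_bags(2, 2, d=4)
    model = MILBoostDetector(n_rounds=0).fit(bags)
    d = Dictionary(
        atoms=np.eye(4, 16), lam=0.1, patch_side=4, meta={"center": True}
    )
    pm = scan_probability_map(model, np.random.default_rng(0).random((12, 12)), d)
    assert pm.shape == (12, 12)
    assert np.allclose(pm, 0.5)


def test_scan_output_dimensions_for_any_stride():
    d = _small_dictionary()
    model = MILBoostDetector(n_rounds=0).fit(_planted_bags(1, 1, d=4))
    img = np.random.default_rng(1).random((31, 45))
    for stride in (1, 3, 7):
        pm = scan_probability_map(model, img, d, stride=stride)
        assert pm.shape == img.shape
        assert pm.min() >= 0.0 and pm.max() <= 1.0


def test_coverage_averaging_two_window_oracle():
    # 4x6 image, l=4, stride 2 -> windows at columns 0 and 2; the middle
    # two columns are covered by both windows and must average them.
    img = np.zeros((4, 6))
    p_left, p_right = 0.2, 0.8
    scorer = _FixedScorer([np.log(p / (1 - p)) for p in (p_left, p_right)])
    d = Dictionary(atoms=np.eye(1, 16), lam=0.0, patch_side=4)
    pm = scan_probability_map(scorer, img, d, stride=2)
    assert np.allclose(pm[:, :2], p_left)
    assert np.allclose(pm[:, 2:4], (p_left + p_right) / 2)
    assert np.allclose(pm[:, 4:], p_right)


def test_scan_translation_equivariance(trained):
    model, d = trained.mil, trained.dictionary
    rng = np.random.default_rng(9)
    img = rng.random((40, 40))
    shifted = np.roll(img, 8, axis=1)
    a = scan_probability_map(model, img, d, stride=2)
    b = scan_probability_map(model, shifted, d, stride=2)
    # compare away from the borders where window coverage differs
    assert np.allclose(a[:, 8:24], b[:, 16:32], atol=1e-12)


def test_scan_window_larger_than_image_rejected():
    d = _small_dictionary()
    model = MILBoostDetector(n_rounds=0).fit(_planted_bags(1, 1, d=4))
    with pytest.raises(SizeError):
        scan_probability_map(model, np.zeros((4, 4)), d)


def test_sigmoid_bounds():
    z = np.array([-1e4, 0.0, 1e4])
    s = sigmoid(z)
    assert s[0] >= 0 and s[2] <= 1 and s[1] == 0.5
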