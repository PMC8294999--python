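"""Sparse coding: alternation descent, lasso oracle, pooling invariants."""

import numpy as np
import pytest

from hotspotseg import (
    Dictionary,
    SparsePatchCoder,
    encode,
    extract_patches,
    image_feature,
    learn_dictionary,
    sparse_objective,
)
from hotspotseg.exceptions import InputError, SizeError


def grid_search_codes(x, atoms, lam, lo=-2.0, hi=2.0, step=1e-3):
    """Exhaustive lasso minimizer over a 2-coefficient grid (oracle)."""
    c1 = np.arange(lo, hi + step / 2, step)
    c2 = c1.copy()
    a1, a2 = atoms
    # expand ||x - c1 a1 - c2 a2||^2 into scalar terms to keep memory sane
    xx = float(x @ x)
    xa1, xa2 = float(x @ a1), float(x @ a2)
    n1, n2, g12 = float(a1 @ a1), float(a2 @ a2), float(a1 @ a2)
    C1 = c1[:, None]
    C2 = c2[None, :]
    obj = (
        xx - 2 * C1 * xa1 - 2 * C2 * xa2
        + C1**2 * n1 + C2**2 * n2 + 2 * C1 * C2 * g12
        + lam * (np.abs(C1) + np.abs(C2))
    )
    i, j = np.unravel_index(np.argmin(obj), obj.shape)
    return np.array([c1[i], c2[j]]), float(obj[i, j])


# ---------------------------------------------------------------------------
# patch extraction


def test_extract_patches_shape_and_determinism():
    rng = np.random.default_rng(0)
    img = rng.random((32, 32))
    a = extract_patches(img, l=8, n=100, seed=7)
    b = extract_patches(img, l=8, n=100, seed=7)
    assert a.patches.shape == (100, 64)
    assert np.array_equal(a.patches, b.patches)
    assert np.array_equal(a.positions, b.positions)


def test_extract_patch_covering_whole_image():
    img = np.arange(64, dtype=float).reshape(8, 8) / 64
    ps = extract_patches(img, l=8, n=1, seed=0)
    assert np.array_equal(ps.patches[0], img.ravel())


def test_extract_constant_image_gives_identical_patches():
    ps = extract_patches(np.full((20, 20), 0.3), l=4, n=10, seed=1)
    assert np.allclose(ps.patches, 0.3)


def test_patch_larger_than_image_rejected():
    with pytest.raises(SizeError):
        extract_patches(np.zeros((6, 6)), l=8, n=1, seed=0)


# ---------------------------------------------------------------------------
# dictionary learning


def test_zero_patches_give_zero_objective():
    _, codes, trace = learn_dictionary(np.zeros((20, 16)), m=4, lam=0.1, seed=0)
    assert np.allclose(codes, 0)
    assert trace[-1] == 0.0


def test_huge_penalty_forces_zero_codes():
    rng = np.random.default_rng(3)
    X = rng.random((15, 9))
    lam = float(np.abs(X @ X.T).max()) * 1e3
    _, codes, trace = learn_dictionary(
        X, m=3, lam=lam, n_iters=5, seed=0, center=False
    )
    assert np.allclose(codes, 0)
    assert np.isclose(trace[-1], np.sum(X * X))


def test_objective_trace_non_increasing_and_consistent():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(10, 9))
    coder = SparsePatchCoder(
        n_atoms=4, lam=0.1, n_iters=25, tol=0.0, center=False, random_state=1
    ).fit(X)
    trace = coder.objective_trace_
    assert all(a >= b - 1e-10 for a, b in zip(trace, trace[1:]))
    # final trace value must match an independent re-evaluation of the
    # objective on the returned codes and atoms
    assert np.isclose(
        trace[-1],
        sparse_objective(X, coder.codes_, coder.components_, 0.1),
        rtol=1e-12,
    )
    assert np.allclose(np.linalg.norm(coder.components_, axis=1), 1.0)


def test_empty_patch_set_rejected():
    with pytest.raises(InputError):
        SparsePatchCoder(n_atoms=2).fit(np.zeros((0, 4)))


# ---------------------------------------------------------------------------
# encoding


def _toy_dictionary(rng, m=2, p=4, lam=0.1):
    atoms = rng.normal(size=(m, p))
    atoms /= np.linalg.norm(atoms, axis=1, keepdims=True)
    return Dictionary(atoms=atoms, lam=lam, patch_side=2, meta={"center": False})


def test_zero_patch_codes_to_zero(rng):
    d = _toy_dictionary(np.random.default_rng(0))
    assert np.allclose(encode(np.zeros((1, 4)), d), 0)


def test_exact_single_atom_representation():
    atom = np.array([[0.5, 0.5, 0.5, 0.5]])
    d = Dictionary(atoms=atom, lam=0.0, patch_side=2, meta={"center": False})
    codes = encode(atom.copy(), d)
    assert np.allclose(codes, 1.0, atol=1e-10)
    assert np.allclose(codes @ atom, atom)


def test_encode_matches_grid_search_oracle():
    rng = np.random.default_rng(11)
    d = _toy_dictionary(rng)
    for _ in range(5):
        x = rng.uniform(-1, 1, size=4)
        got = encode(x[None, :], d)[0]
        want, _ = grid_search_codes(x, d.atoms, lam=0.1)
        assert np.all(np.abs(got - want) <= 2e-3)


def test_encode_sign_flip_equivariance():
    rng = np.random.default_rng(21)
    d = _toy_dictionary(rng, m=3, p=9)
    X = rng.normal(size=(6, 9))
    flipped = Dictionary(
        atoms=d.atoms * np.array([[-1], [1], [-1]]), lam=d.lam,
        patch_side=d.patch_side, meta=d.meta,
    )
    a = encode(X, d)
    b = encode(X, flipped)
    assert np.allclose(a * np.array([-1, 1, -1]), b, atol=1e-8)


def test_encode_dimension_mismatch():
    d = _toy_dictionary(np.random.default_rng(0))
    with pytest.raises(SizeError):
        encode(np.zeros((1, 9)), d)


# ---------------------------------------------------------------------------
# image-level features


def test_feature_of_zero_image_is_zero():
    d = _toy_dictionary(np.random.default_rng(1), m=4, p=16)
    d.meta["center"] = True
    d.patch_side = 4
    f = image_feature(np.zeros((16, 16)), d, stride=4)
    assert f.shape == (8,)
    assert np.allclose(f, 0)


def test_feature_length_and_pooling_order(rng):
    img = np.random.default_rng(2).random((24, 24))
    d = _toy_dictionary(np.random.default_rng(1), m=4, p=16)
    d.meta["center"] = True
    d.patch_side = 4
    f = image_feature(img, d, stride=3)
    assert f.shape == (8,)
    assert np.all(f[:4] >= f[4:] - 1e-12)  # max-pool >= mean-pool >= 0
    assert np.all(f >= 0)


def test_feature_invariant_to_global_brightness_shift():
    rng = np.random.default_rng(4)
    img = rng.random((20, 20)) * 0.5  # keep +0.2 shift clip-free
    d = _toy_dictionary(rng, m=3, p=16)
    d.meta["center"] = True
    d.patch_side = 4
    assert np.allclose(
        image_feature(img, d, stride=2),
        image_feature(img + 0.2, d, stride=2),
        atol=1e-10,
    )


def test_dictionary_json_round_trip():
    d = _toy_dictionary(np.random.default_rng(8), m=3, p=9, lam=0.2)
    d2 = Dictionary.from_json(d.to_json())
    assert np.allclose(d.atoms, d2.atoms)
    assert d2.lam == d.lam and d2.patch_side == d.patch_side
    assert d2.meta == d.meta
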