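import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femsym import (ShapeFit, SimilarityTransform, align_similarity,
                    build_model, centroid_size, fit_shape,
                    generalized_procrustes, load_model, mode_shape,
                    reconstruct, save_model)


def random_shapes(rng, n_shapes, n_points, scale=10.0):
    base = rng.normal(size=(n_points, 2)) * scale
    return base + rng.normal(size=(n_shapes, n_points, 2))


def apply_similarity(points, scale, rot, t):
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    return scale * points @ R.T + t


# ---------------------------------------------------------------------------
# align_similarity
# ---------------------------------------------------------------------------

def test_align_identity_when_source_equals_target(rng):
    pts = rng.normal(size=(12, 2))
    t = align_similarity(pts, pts)
    assert t.scale == pytest.approx(1.0, abs=1e-12)
    assert t.rotation == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(t.translation, (0, 0), atol=1e-12)


def test_align_recovers_known_rotation_and_scale(rng):
    src = rng.normal(size=(8, 2))
    tgt = apply_similarity(src, 2.0, np.radians(30), np.array([5.0, -2.0]))
    t = align_similarity(src, tgt)
    assert t.scale == pytest.approx(2.0, abs=1e-8)
    assert t.rotation == pytest.approx(np.radians(30), abs=1e-8)
    np.testing.assert_allclose(t.apply(src), tgt, atol=1e-8)


def test_align_beats_ten_thousand_random_transforms(rng):
    src = rng.normal(size=(10, 2))
    tgt = rng.normal(size=(10, 2))
    best = align_similarity(src, tgt)
    best_ssd = np.sum((best.apply(src) - tgt) ** 2)
    scales = np.exp(rng.normal(0, 0.5, 10_000))
    rots = rng.uniform(-np.pi, np.pi, 10_000)
    ts = rng.normal(0, 2, (10_000, 2))
    z = src[:, 0] + 1j * src[:, 1]
    a = scales * np.exp(1j * rots)
    w = a[:, None] * z[None, :] + (ts[:, 0] + 1j * ts[:, 1])[:, None]
    zt = tgt[:, 0] + 1j * tgt[:, 1]
    ssds = np.abs(w - zt[None, :]) ** 2
    assert best_ssd <= ssds.sum(axis=1).min() + 1e-9


def test_align_rejects_degenerate_source():
    with pytest.raises(ValueError, match="degenerate"):
        align_similarity(np.zeros((5, 2)), np.random.default_rng(0).normal(size=(5, 2)))


@settings(max_examples=25, derandomize=True)
@given(st.floats(0.2, 5.0), st.floats(-3.0, 3.0),
       st.floats(-50, 50), st.floats(-50, 50))
def test_align_inverts_arbitrary_similarities(scale, rot, tx, ty):
    src = np.array([[0.0, 0.0], [10.0, 0.0], [3.0, 7.0], [-4.0, 2.0]])
    tgt = apply_similarity(src, scale, rot, np.array([tx, ty]))
    t = align_similarity(src, tgt)
    np.testing.assert_allclose(t.apply(src), tgt, atol=1e-6)


def test_transform_compose_and_inverse_round_trip(rng):
    a = SimilarityTransform(1.7, 0.3, (2.0, -1.0))
    b = SimilarityTransform(0.6, -1.1, (-4.0, 0.5))
    pts = rng.normal(size=(7, 2))
    np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-10)
    np.testing.assert_allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-10)


# ---------------------------------------------------------------------------
# generalized Procrustes
# ---------------------------------------------------------------------------

def test_gpa_fixed_point_for_identical_shapes(rng):
    shape = rng.normal(size=(9, 2)) * 20
    res = generalized_procrustes(np.stack([shape] * 5), canonicalize=False)
    centred = shape - shape.mean(axis=0)
    np.testing.assert_allclose(res.mean_shape, centred, atol=1e-8)
    for a in res.aligned:
        np.testing.assert_allclose(a, centred, atol=1e-8)


def test_gpa_result_insensitive_to_input_order(small_dataset):
    contours, _ = small_dataset
    shapes = np.stack([c.points for c in contours])
    res1 = generalized_procrustes(shapes)
    res2 = generalized_procrustes(shapes[::-1])
    np.testing.assert_allclose(res1.mean_shape, res2.mean_shape, atol=1e-7)


def test_gpa_invariant_under_rigid_perturbation_of_inputs(small_dataset, rng):
    contours, _ = small_dataset
    shapes = np.stack([c.points for c in contours])
    res1 = generalized_procrustes(shapes)
    perturbed = np.stack([
        apply_similarity(s, 1.0, rng.uniform(-np.pi, np.pi), rng.normal(0, 30, 2))
        for s in shapes])
    res2 = generalized_procrustes(perturbed)
    np.testing.assert_allclose(res1.aligned, res2.aligned, atol=1e-6)


def test_gpa_preserves_mm_scale(small_dataset):
    contours, _ = small_dataset
    shapes = np.stack([c.points for c in contours])
    res = generalized_procrustes(shapes)
    target = np.mean([centroid_size(s) for s in shapes])
    assert centroid_size(res.mean_shape) == pytest.approx(target, rel=1e-9)


# ---------------------------------------------------------------------------
# build_model / fit / reconstruct / mode_shape
# ---------------------------------------------------------------------------

def test_model_variances_match_bruteforce_covariance(rng):
    shapes = random_shapes(rng, 20, 10)
    model = build_model(shapes, variance_threshold=1.0)
    D = shapes.reshape(20, -1)
    C = np.cov(D, rowvar=False, ddof=1)
    w = np.sort(np.linalg.eigvalsh(C))[::-1]
    np.testing.assert_allclose(model.variances, w[:model.k], rtol=1e-8)
    assert model.total_variance == pytest.approx(np.trace(C), rel=1e-10)


def test_model_modes_are_orthonormal(rng):
    shapes = random_shapes(rng, 15, 8)
    model = build_model(shapes)
    gram = model.modes.T @ model.modes
    np.testing.assert_allclose(gram, np.eye(model.k), atol=1e-8)


def test_identical_shapes_give_zero_variance_model(rng):
    shape = rng.normal(size=(6, 2))
    model = build_model(np.stack([shape] * 5))
    assert model.k == 0
    assert model.total_variance == pytest.approx(0.0, abs=1e-18)


def test_full_threshold_reconstructs_training_shapes_exactly(rng):
    # with threshold 1.0 the model keeps the full rank of the training data,
    # so every aligned training shape is represented with zero residual
    shapes = random_shapes(rng, 8, 6)
    res = generalized_procrustes(shapes)
    model = build_model(res.aligned, variance_threshold=1.0)
    assert model.k == 7  # n_shapes - 1 similarity-reduced rank at most
    for s in res.aligned:
        fit = fit_shape(model, s)
        np.testing.assert_allclose(reconstruct(model, fit, include_residual=False),
                                   s, atol=1e-7)
        assert np.linalg.norm(fit.residual) < 1e-7


def test_retention_is_minimal(small_dataset):
    contours, _ = small_dataset
    res = generalized_procrustes(np.stack([c.points for c in contours]))
    model = build_model(res.aligned, variance_threshold=0.95)
    frac = model.variances.sum() / model.total_variance
    assert frac >= 0.95
    assert (model.variances[:-1].sum() / model.total_variance) < 0.95


def test_mode_sign_convention_is_deterministic(rng):
    shapes = random_shapes(rng, 12, 7)
    m1 = build_model(shapes)
    m2 = build_model(shapes[::-1])  # same data, different order
    for j in range(min(m1.k, m2.k)):
        col = m1.modes[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_fit_recovers_zero_coefficients_for_posed_mean(rng, small_dataset):
    contours, _ = small_dataset
    res = generalized_procrustes(np.stack([c.points for c in contours]))
    model = build_model(res.aligned)
    posed = apply_similarity(model.mean_points, 1.3, 0.4, np.array([12.0, -8.0]))
    fit = fit_shape(model, posed)
    np.testing.assert_allclose(fit.b, 0.0, atol=1e-6)


def test_fit_recovers_known_coefficients(rng, small_dataset):
    contours, _ = small_dataset
    res = generalized_procrustes(np.stack([c.points for c in contours]))
    model = build_model(res.aligned)
    b0 = np.zeros(model.k)
    b0[: min(3, model.k)] = 2.0 * np.sqrt(model.variances[: min(3, model.k)])
    vec = model.mean_shape + model.modes @ b0
    posed = apply_similarity(vec.reshape(-1, 2), 0.8, -0.7, np.array([3.0, 9.0]))
    fit = fit_shape(model, posed)
    np.testing.assert_allclose(fit.b, b0, atol=1e-6)


def test_fit_reconstruct_round_trip(small_dataset):
    contours, _ = small_dataset
    shapes = np.stack([c.points for c in contours])
    res = generalized_procrustes(shapes)
    model = build_model(res.aligned)
    for s in shapes:
        fit = fit_shape(model, s)
        np.testing.assert_allclose(reconstruct(model, fit), s, atol=1e-6)


def test_mode_shape_geometry(small_dataset):
    contours, _ = small_dataset
    res = generalized_procrustes(np.stack([c.points for c in contours]))
    model = build_model(res.aligned)
    np.testing.assert_allclose(mode_shape(model, 1, 0.0), model.mean_points)
    plus = mode_shape(model, 1, 2.5)
    minus = mode_shape(model, 1, -2.5)
    np.testing.assert_allclose(plus + minus, 2 * model.mean_points, atol=1e-9)
    disp = np.linalg.norm((plus - model.mean_points).reshape(-1))
    assert disp == pytest.approx(2.5 * np.sqrt(model.variances[0]), rel=1e-9)
    with pytest.raises(IndexError):
        mode_shape(model, model.k + 1, 1.0)


def test_model_serialisation_round_trip(tmp_path, rng):
    shapes = random_shapes(rng, 10, 6)
    model = build_model(shapes)
    save_model(model, tmp_path / "m.ssm")
    back = load_model(tmp_path / "m.ssm")
    assert back.n_points == model.n_points
    np.testing.assert_allclose(back.mean_shape, model.mean_shape)
    np.testing.assert_allclose(back.modes, model.modes)
    np.testing.assert_allclose(back.variances, model.variances)
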