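import numpy as np
import pytest

from femsym import (ShapeFit, ShapeModel, SimilarityTransform, adjustment_effect,
                    build_model, classify_modes, combined_point_to_curve,
                    exclude_modes_and_reevaluate, fit_shape,
                    generalized_procrustes, oppositional_score,
                    point_to_curve_distance, reconstruct)


def make_combined_model(fields, variances=None):
    """Combined 130-point model with hand-constructed unit mode fields."""
    rng = np.random.default_rng(0)
    mean = rng.normal(size=(130, 2)) * 30
    modes = []
    for f in fields:
        v = np.asarray(f, dtype=float).reshape(-1)
        modes.append(v / np.linalg.norm(v))
    modes = np.stack(modes, axis=1)
    k = modes.shape[1]
    variances = np.arange(k, 0, -1, dtype=float) if variances is None else variances
    return ShapeModel(n_points=130, mean_shape=mean.reshape(-1), modes=modes,
                      variances=variances, total_variance=float(np.sum(variances)),
                      variance_threshold=0.95)


def symmetric_field(rng):
    dL = rng.normal(size=(65, 2))
    dR = dL.copy()
    dR[:, 0] = -dR[:, 0]     # mirror of the left displacement
    return np.vstack([dL, dR])


def oppositional_field(rng):
    f = symmetric_field(rng)
    f[65:] = -f[65:]
    return f


def test_mirror_symmetric_mode_scores_plus_one(rng):
    model = make_combined_model([symmetric_field(rng)])
    assert oppositional_score(model, 1).score == pytest.approx(1.0)
    assert oppositional_score(model, 1).classification == "symmetric"


def test_mirror_opposed_mode_scores_minus_one(rng):
    model = make_combined_model([oppositional_field(rng)])
    s = oppositional_score(model, 1)
    assert s.score == pytest.approx(-1.0)
    assert s.classification == "oppositional"


def test_score_is_invariant_to_mode_sign(rng):
    f = rng.normal(size=(130, 2))
    m_plus = make_combined_model([f])
    m_minus = make_combined_model([-f])
    assert oppositional_score(m_plus, 1).score == pytest.approx(
        oppositional_score(m_minus, 1).score)


def test_score_requires_combined_model(rng):
    shapes = np.stack([rng.normal(size=(65, 2)) for _ in range(5)])
    model = build_model(shapes)
    with pytest.raises(ValueError, match="combined"):
        oppositional_score(model, 1)


def test_classification_with_extreme_thresholds(rng):
    # sparse unit fields make the cosine exactly +/-1 in floating point
    sym = np.zeros((130, 2)); sym[3, 1] = 1.0; sym[68, 1] = 1.0
    opp = np.zeros((130, 2)); opp[3, 1] = 1.0; opp[68, 1] = -1.0
    model = make_combined_model([sym, opp, rng.normal(size=(130, 2))])
    scores = classify_modes(model, sym_threshold=1.0, opp_threshold=-1.0)
    assert scores[0].classification == "symmetric"          # exactly +1
    assert scores[1].classification == "oppositional"       # exactly -1
    assert scores[2].classification == "indeterminate"


def test_classify_rejects_invalid_threshold_order(rng):
    model = make_combined_model([symmetric_field(rng)])
    with pytest.raises(ValueError):
        classify_modes(model, sym_threshold=-0.5, opp_threshold=0.5)


# ---------------------------------------------------------------------------
# mode exclusion
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_combined(small_dataset):
    contours, _ = small_dataset
    shapes = np.stack([c.points for c in contours])
    res = generalized_procrustes(shapes)
    model = build_model(res.aligned)
    fits = [fit_shape(model, s) for s in shapes]
    return contours, model, fits


def test_excluding_nothing_reproduces_original_points(fitted_combined):
    contours, model, fits = fitted_combined
    for c, f in zip(contours, fits):
        out = exclude_modes_and_reevaluate(model, f, [])
        np.testing.assert_allclose(out, c.points, atol=1e-6)


def test_excluding_all_modes_with_zero_residual_gives_posed_mean(fitted_combined):
    _, model, fits = fitted_combined
    f = fits[0]
    bare = ShapeFit(b=f.b, pose=f.pose, residual=np.zeros_like(f.residual))
    out = exclude_modes_and_reevaluate(model, bare, range(1, model.k + 1))
    np.testing.assert_allclose(out, f.pose.apply(model.mean_points), atol=1e-9)


def test_single_mode_exclusion_moves_shape_by_coefficient_norm(fitted_combined):
    _, model, fits = fitted_combined
    f = fits[0]
    j = int(np.argmax(np.abs(f.b))) + 1
    kept = exclude_modes_and_reevaluate(model, f, [])
    dropped = exclude_modes_and_reevaluate(model, f, [j])
    moved = np.linalg.norm((kept - dropped).reshape(-1)) / f.pose.scale
    assert moved == pytest.approx(abs(f.b[j - 1]), rel=1e-9)


def test_exclusion_rejects_out_of_range_mode(fitted_combined):
    _, model, fits = fitted_combined
    with pytest.raises(IndexError):
        exclude_modes_and_reevaluate(model, fits[0], [model.k + 1])


# ---------------------------------------------------------------------------
# point-to-curve distances
# ---------------------------------------------------------------------------

def test_distance_is_zero_for_identical_point_sets(template):
    contour, _ = template
    assert point_to_curve_distance(contour.points, contour.points) == pytest.approx(0.0)


def test_perpendicular_foot_distance():
    assert point_to_curve_distance([(0.0, 1.0)], [(-1.0, 0.0), (1.0, 0.0)]) == pytest.approx(1.0)


def test_distance_never_exceeds_corresponding_point_distance(small_dataset):
    contours, _ = small_dataset
    a = contours[0].left.points
    b = contours[1].left.points
    p2c = point_to_curve_distance(a, b)
    p2p = float(np.mean(np.linalg.norm(a - b, axis=1)))
    assert p2c <= p2p + 1e-12


def test_symmetric_distance_averages_both_directions(rng):
    a = rng.normal(size=(10, 2))
    b = rng.normal(size=(10, 2)) + 3
    fwd = point_to_curve_distance(a, b)
    bwd = point_to_curve_distance(b, a)
    sym = point_to_curve_distance(a, b, symmetric=True)
    assert sym == pytest.approx(0.5 * (fwd + bwd))


def test_distance_against_dense_sampling_oracle(small_dataset):
    contours, _ = small_dataset
    a = contours[0].left.points
    b = contours[1].left.points
    # oracle: sample the polyline at 10^4 points per segment, min distance
    samples = []
    for p, q in zip(b[:-1], b[1:]):
        t = np.linspace(0, 1, 10_000)[:, None]
        samples.append(p + t * (q - p))
    S = np.vstack(samples)
    dmin = np.array([np.min(np.linalg.norm(S - x, axis=1)) for x in a])
    assert point_to_curve_distance(a, b) == pytest.approx(float(dmin.mean()), abs=1e-3)


def test_combined_distance_never_bridges_the_two_femurs():
    # two horizontal segments far apart; a point midway between them should
    # be measured against its own side only
    left = np.column_stack([np.linspace(-10, -5, 65), np.zeros(65)])
    right = np.column_stack([np.linspace(5, 10, 65), np.zeros(65)])
    curve = np.vstack([left, right])
    points = curve.copy()
    points[0] = (-7.5, 2.0)   # 2 mm above the left polyline
    d = combined_point_to_curve(points, curve)
    assert d == pytest.approx(2.0 / 130, abs=1e-9)


def test_adjustment_effect_identity_and_similarity_invariance(small_dataset):
    contours, _ = small_dataset
    pts = contours[0].points
    assert adjustment_effect(pts, pts) == pytest.approx(0.0, abs=1e-12)
    moved = SimilarityTransform(1.4, 0.6, (20.0, -7.0)).apply(pts)
    assert adjustment_effect(pts, moved) == pytest.approx(0.0, abs=1e-9)


def test_adjustment_effect_matches_rotation_displacement_oracle(template):
    """A 3-degree oppositional per-femur rotation, after the global
    similarity re-alignment, must produce a mean point-to-curve effect within
    20% of the closed-form prediction (residual field after least-squares
    similarity absorption, normal component to the local contour tangent)."""
    contour, _ = template
    left = contour.points + np.array([-80.0, 0.0])
    right = left.copy()
    right[:, 0] = -right[:, 0]
    combined = np.vstack([left, right])
    theta = np.radians(3.0)

    def rot_field(pts):
        c = pts.mean(axis=0)
        return theta * np.column_stack([-(pts[:, 1] - c[1]), pts[:, 0] - c[0]])

    d = np.vstack([rot_field(left), rot_field(right)])
    rotated = combined + d
    effect = adjustment_effect(combined, rotated)

    # closed-form absorption of the best global similarity: least squares of
    # d over the linearised similarity span {alpha * z + tau}
    z = combined[:, 0] + 1j * combined[:, 1]
    dz = d[:, 0] + 1j * d[:, 1]
    A = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(A, dz, rcond=None)
    r = dz - A @ coef
    res = np.column_stack([r.real, r.imag])
    # tangential residual slides along the contour, only the normal part
    # contributes to point-to-curve distance
    oracle = []
    for sl in (slice(0, 65), slice(65, 130)):
        tang = np.gradient(combined[sl], axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = res[sl, 0] * (-tang[:, 1]) + res[sl, 1] * tang[:, 0]
        oracle.append(np.abs(normal))
    oracle = float(np.concatenate(oracle).mean())
    assert effect == pytest.approx(oracle, rel=0.2)
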