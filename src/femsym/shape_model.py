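"""Similarity alignment, generalized Procrustes analysis and linear shape models.

The point-distribution model represents a configuration of m landmarks as

    x = T_theta(mean + P b + r)

where ``mean`` is the mean shape in a common reference frame, the columns of
``P`` are orthonormal modes of variation from PCA of the aligned training
shapes, ``b`` are per-shape mode coefficients, ``r`` is a small residual and
``T_theta`` is a per-shape similarity transform (scale, rotation,
translation).

Conventions used throughout:

* shapes are ``(m, 2)`` arrays in mm; flattened vectors interleave
  coordinates as ``x0, y0, x1, y1, ...`` (``shape.reshape(-1)``);
* the GPA reference frame is centred at the origin and preserves the mm
  scale: the mean shape's centroid size equals the mean centroid size of the
  input set (model-space distances stay in mm);
* mode indices in the public API are 1-based ("mode 1" is the largest-
  variance mode), matching how modes are numbered in the morphometrics
  literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SimilarityTransform",
    "ShapeModel",
    "ShapeFit",
    "GPAResult",
    "align_similarity",
    "generalized_procrustes",
    "build_model",
    "fit_shape",
    "reconstruct",
    "mode_shape",
    "centroid_size",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# Similarity transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTransform:
    """Plane similarity x' = s R(angle) x + t, with s > 0 (no reflection)."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))

    @property
    def _complex(self) -> tuple[complex, complex]:
        a = self.scale * np.exp(1j * self.rotation)
        t = complex(*self.translation)
        return a, t

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        a, t = self._complex
        z = pts[:, 0] + 1j * pts[:, 1]
        w = a * z + t
        return np.column_stack([w.real, w.imag])

    def inverse(self) -> "SimilarityTransform":
        a, t = self._complex
        ai = 1.0 / a
        ti = -t / a
        return SimilarityTransform(abs(ai), float(np.angle(ai)), (ti.real, ti.imag))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        a1, t1 = self._complex
        a2, t2 = other._complex
        a = a1 * a2
        t = a1 * t2 + t1
        return SimilarityTransform(abs(a), float(np.angle(a)), (t.real, t.imag))


def centroid_size(points) -> float:
    """Frobenius norm of the centred configuration (standard centroid size)."""
    pts = np.asarray(points, dtype=float)
    return float(np.linalg.norm(pts - pts.mean(axis=0)))


def align_similarity(source, target) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``source`` onto ``target``.

    Closed form via centroids and the complex cross-covariance; minimises
    sum_i |T(source_i) - target_i|^2 over scale, rotation and translation
    (rotation only, no reflection).
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 2 or S.shape[0] < 2:
        raise ValueError("source and target must be matching (n>=2, 2) arrays")
    zs = S[:, 0] + 1j * S[:, 1]
    zt = T[:, 0] + 1j * T[:, 1]
    cs, ct = zs.mean(), zt.mean()
    zs0 = zs - cs
    zt0 = zt - ct
    denom = float(np.sum(zs0.real**2 + zs0.imag**2))
    if denom < 1e-12:
        raise ValueError("degenerate source: all points coincident")
    a = np.sum(np.conj(zs0) * zt0) / denom
    if abs(a) < 1e-15:
        # orthogonal configurations; fall back to pure translation
        a = complex(1.0, 0.0)
    t = ct - a * cs
    return SimilarityTransform(abs(a), float(np.angle(a)), (t.real, t.imag))


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class GPAResult:
    mean_shape: np.ndarray            # (m, 2), centred, mm scale
    aligned: np.ndarray               # (n, m, 2)
    transforms: list[SimilarityTransform]  # original -> frame
    iterations: int
    converged: bool


def _canonical_rotation(mean: np.ndarray) -> float:
    """Rotation angle putting ``mean`` into a canonical orientation.

    The major principal axis of the (centred) mean is rotated onto +x; the
    180-degree ambiguity is resolved by requiring the larger-magnitude third
    central moment of the coordinates to be positive.  Rotations only — a
    reflection would mirror anatomy.
    """
    C = mean.T @ mean
    w, V = np.linalg.eigh(C)
    major = V[:, -1]
    theta = -np.arctan2(major[1], major[0])

    def skew_disc(angle: float) -> float:
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        Y = mean @ R.T
        mx = np.mean((Y[:, 0] - Y[:, 0].mean()) ** 3)
        my = np.mean((Y[:, 1] - Y[:, 1].mean()) ** 3)
        return mx if abs(mx) >= abs(my) else my

    if skew_disc(theta) < 0:
        theta += np.pi
    return float(theta)


def generalized_procrustes(shapes, tol: float = 1e-8, max_iter: int = 100,
                           canonicalize: bool = True) -> GPAResult:
    """Iteratively align shapes to their evolving mean under similarities.

    The common frame is centred at the origin with the mean shape's centroid
    size fixed to the mean centroid size of the inputs (mm preserved).  With
    ``canonicalize`` the frame orientation is additionally pinned by the
    principal axes of the mean, making the result invariant (to numerical
    tolerance) under rotation/translation of the inputs.

    Non-convergence at ``max_iter`` yields ``converged=False``, not an error.
    """
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 3 or X.shape[2] != 2:
        raise ValueError("shapes must be an (n_shapes, m, 2) array-like")
    n = X.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 shapes")
    target_size = float(np.mean([centroid_size(x) for x in X]))
    if target_size <= 0:
        raise ValueError("degenerate input: zero mean centroid size")

    def normalise(shape: np.ndarray) -> np.ndarray:
        c = shape - shape.mean(axis=0)
        size = np.linalg.norm(c)
        if size < 1e-12:
            raise ValueError("degenerate mean shape")
        return c * (target_size / size)

    mean = normalise(X[0])
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        aligned = np.stack([align_similarity(x, mean).apply(x) for x in X])
        new_mean = normalise(aligned.mean(axis=0))
        delta = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if delta < tol * target_size:
            converged = True
            break

    if canonicalize:
        theta = _canonical_rotation(mean)
        rot = SimilarityTransform(1.0, theta, (0.0, 0.0))
        mean = rot.apply(mean)

    transforms = [align_similarity(x, mean) for x in X]
    aligned = np.stack([t.apply(x) for t, x in zip(transforms, X)])
    return GPAResult(mean_shape=mean, aligned=aligned, transforms=transforms,
                     iterations=iterations, converged=converged)


# ---------------------------------------------------------------------------
# Shape model
# ---------------------------------------------------------------------------

@dataclass
class ShapeModel:
    """Linear point-distribution model over m landmarks.

    ``mean_shape`` is a flat 2m-vector in the GPA frame; ``modes`` is a
    (2m, k) matrix with orthonormal columns; ``variances`` holds the k
    retained per-mode variances in descending order; ``total_variance`` is
    the trace of the full sample covariance, so
    ``variances.sum() / total_variance >= variance_threshold``.
    """

    n_points: int
    mean_shape: np.ndarray        # (2m,)
    modes: np.ndarray             # (2m, k)
    variances: np.ndarray         # (k,)
    total_variance: float
    variance_threshold: float

    def __post_init__(self) -> None:
        self.mean_shape = np.asarray(self.mean_shape, dtype=float).reshape(-1)
        self.modes = np.asarray(self.modes, dtype=float).reshape(len(self.mean_shape), -1)
        self.variances = np.asarray(self.variances, dtype=float).reshape(-1)
        if len(self.mean_shape) != 2 * self.n_points:
            raise ValueError("mean_shape length must equal 2 * n_points")
        if self.modes.shape[1] != len(self.variances):
            raise ValueError("modes and variances disagree on k")
        if np.any(np.diff(self.variances) > 1e-12):
            raise ValueError("variances must be sorted descending")

    @property
    def k(self) -> int:
        return self.modes.shape[1]

    @property
    def mean_points(self) -> np.ndarray:
        return self.mean_shape.reshape(self.n_points, 2)

    def explained_variance_fraction(self) -> float:
        if self.total_variance <= 0:
            return 1.0
        return float(self.variances.sum() / self.total_variance)


@dataclass
class ShapeFit:
    """Result of projecting one shape into a model: pose, coefficients, residual."""

    b: np.ndarray                 # (k,)
    pose: SimilarityTransform
    residual: np.ndarray          # (2m,)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        self.residual = np.asarray(self.residual, dtype=float).reshape(-1)


def build_model(aligned_shapes, variance_threshold: float = 0.95) -> ShapeModel:
    """PCA shape model from shapes already in a common reference frame.

    Eigen-decomposition of the sample covariance (divisor n-1), computed in
    point space or in the dual n x n space, whichever is smaller.  Retains
    the smallest k whose cumulative variance fraction reaches the threshold;
    mode signs are fixed so each mode's largest-magnitude loading is
    positive.
    """
    X = np.asarray(aligned_shapes, dtype=float)
    if X.ndim != 3 or X.shape[2] != 2:
        raise ValueError("aligned_shapes must be (n_shapes, m, 2)")
    n, m, _ = X.shape
    if n < 3:
        raise ValueError("need at least 3 shapes to build a model")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    D = X.reshape(n, 2 * m)
    mean = D.mean(axis=0)
    Xc = D - mean

    if 2 * m <= n:
        C = Xc.T @ Xc / (n - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w = w[order]
        V = V[:, order]
    else:
        G = Xc @ Xc.T / (n - 1)
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w = w[order]
        U = U[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            V = Xc.T @ U / np.sqrt(np.maximum(w, 1e-300) * (n - 1))

    w = np.clip(w, 0.0, None)
    total = float(np.trace(Xc.T @ Xc) / (n - 1)) if 2 * m <= n else float(w.sum())
    # numerical rank cut: keep directions carrying real variance, with an
    # absolute floor tied to the coordinate scale so that numerically
    # identical shapes yield rank zero
    scale_floor = 1e-20 * float(np.mean(D * D) + 1.0)
    rank_tol = max(max(w[0], 0.0) * 1e-10, scale_floor) if len(w) else 0.0
    nz = int(np.sum(w > rank_tol))
    w = w[:nz]
    V = V[:, :nz]

    if total <= 0 or nz == 0:
        k = 0
    else:
        frac = np.cumsum(w) / total
        reached = np.nonzero(frac >= variance_threshold - 1e-12)[0]
        k = int(reached[0]) + 1 if len(reached) else nz

    modes = V[:, :k]
    # stable sign convention: largest-|loading| entry positive
    for j in range(k):
        col = modes[:, j]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            modes[:, j] = -col
    return ShapeModel(n_points=m, mean_shape=mean, modes=modes, variances=w[:k],
                      total_variance=total, variance_threshold=variance_threshold)


def fit_shape(model: ShapeModel, shape, tol: float = 1e-8,
              max_iter: int = 50) -> ShapeFit:
    """Fit pose and mode coefficients of one shape by alternating projection.

    Alternates similarity-pose estimation (model reconstruction -> shape)
    with coefficient projection ``b = P^T (pose^{-1}(shape) - mean)`` until
    the coefficient update falls below ``tol`` or ``max_iter`` sweeps.  The
    residual is taken in the final model frame, so reconstruction with the
    residual reproduces the input exactly (to rounding).
    """
    S = np.asarray(shape, dtype=float)
    if S.shape != (model.n_points, 2):
        raise ValueError(f"shape must be ({model.n_points}, 2), got {S.shape}")
    b = np.zeros(model.k)
    mean = model.mean_shape
    pose = SimilarityTransform.identity()
    y = S.reshape(-1)
    for _ in range(max_iter):
        recon = (mean + model.modes @ b).reshape(model.n_points, 2)
        pose = align_similarity(recon, S)
        y = pose.inverse().apply(S).reshape(-1)
        b_new = model.modes.T @ (y - mean)
        if np.linalg.norm(b_new - b) < tol:
            b = b_new
            break
        b = b_new
    residual = y - mean - model.modes @ b
    return ShapeFit(b=b, pose=pose, residual=residual)


def reconstruct(model: ShapeModel, fit: ShapeFit,
                include_residual: bool = True) -> np.ndarray:
    """Evaluate T_theta(mean + P b (+ r)) as an (m, 2) point set."""
    if len(fit.b) != model.k or len(fit.residual) != 2 * model.n_points:
        raise ValueError("fit dimensions do not match model")
    vec = model.mean_shape + model.modes @ fit.b
    if include_residual:
        vec = vec + fit.residual
    return fit.pose.apply(vec.reshape(model.n_points, 2))


def mode_shape(model: ShapeModel, mode_index: int, c: float) -> np.ndarray:
    """Mean shape displaced along one mode by c standard deviations (1-based).

    ``mode_shape(model, j, 2.5)`` / ``-2.5`` are the conventional renderings
    of a mode of variation.
    """
    if not 1 <= mode_index <= model.k:
        raise IndexError(f"mode_index must be in [1, {model.k}], got {mode_index}")
    j = mode_index - 1
    vec = model.mean_shape + c * np.sqrt(model.variances[j]) * model.modes[:, j]
    return vec.reshape(model.n_points, 2)


# ---------------------------------------------------------------------------
# Serialisation (ssm-v1): a single JSON document
# ---------------------------------------------------------------------------

def save_model(model: ShapeModel, path: str | Path) -> None:
    doc = {
        "format": "ssm-v1",
        "n_points": model.n_points,
        "variance_threshold": model.variance_threshold,
        "total_variance": model.total_variance,
        "mean_shape": model.mean_shape.tolist(),
        "variances": model.variances.tolist(),
        "modes": model.modes.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> ShapeModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ssm-v1":
        raise ValueError(f"{path}: not an ssm-v1 model file")
    return ShapeModel(
        n_points=int(doc["n_points"]),
        mean_shape=np.asarray(doc["mean_shape"], dtype=float),
        modes=np.asarray(doc["modes"], dtype=float),
        variances=np.asarray(doc["variances"], dtype=float),
        total_variance=float(doc["total_variance"]),
        variance_threshold=float(doc["variance_threshold"]),
    )
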