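"""Detection and removal of oppositional-asymmetric modes (positioning artefacts).

A combined 130-point left+right shape model can express patterns in which
the two sides deform as mirror images (anatomically symmetric variation) or
in mirror-opposed directions (oppositional variation).  Oppositional
patterns arise from subject positioning during image acquisition — pelvic
rotation changes the apparent orientation/projection of the two femurs in
opposite senses, and leg rotation causes landmark "shaft sliding" — rather
than from anatomy, and can therefore be removed by zeroing the offending
mode coefficients and re-evaluating all 130 points.

The oppositional score of a mode is the cosine similarity between the
left-side displacement field and the mirrored right-side displacement field
(mirroring negates x-components; indices already correspond).  +1 means
perfectly mirror-symmetric variation, -1 perfectly oppositional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .landmark_io import N_COMBINED_POINTS, N_FEMUR_POINTS
from .shape_model import ShapeFit, ShapeModel, align_similarity, reconstruct

__all__ = [
    "ModeSymmetryScore",
    "oppositional_score",
    "classify_modes",
    "exclude_modes_and_reevaluate",
    "point_to_curve_distance",
    "combined_point_to_curve",
    "adjustment_effect",
    "DEFAULT_SYM_THRESHOLD",
    "DEFAULT_OPP_THRESHOLD",
]

DEFAULT_SYM_THRESHOLD = 0.7
DEFAULT_OPP_THRESHOLD = -0.7


@dataclass(frozen=True)
class ModeSymmetryScore:
    """Mirror-symmetry score of one combined-model mode (1-based index)."""

    mode_index: int
    score: float
    classification: str  # "symmetric" | "oppositional" | "indeterminate"


def _require_combined(model: ShapeModel) -> None:
    if model.n_points != N_COMBINED_POINTS:
        raise ValueError(
            f"oppositional analysis needs a {N_COMBINED_POINTS}-point combined "
            f"model, got {model.n_points} points")


def _classify(score: float, sym_threshold: float, opp_threshold: float) -> str:
    if score <= opp_threshold:
        return "oppositional"
    if score >= sym_threshold:
        return "symmetric"
    return "indeterminate"


def oppositional_score(model: ShapeModel, mode_index: int,
                       sym_threshold: float = DEFAULT_SYM_THRESHOLD,
                       opp_threshold: float = DEFAULT_OPP_THRESHOLD) -> ModeSymmetryScore:
    """Score one mode of a combined model for mirror symmetry vs opposition.

    The mode displacement is split into its left (points 0-64) and right
    (65-129) fields; the right field is mirrored into the left frame by
    negating x-components.  The score is the cosine similarity of the two
    130-dimensional fields; it is invariant to the arbitrary sign of the
    mode vector because flipping the mode flips both fields.
    """
    _require_combined(model)
    if not 1 <= mode_index <= model.k:
        raise IndexError(f"mode_index must be in [1, {model.k}], got {mode_index}")
    disp = model.modes[:, mode_index - 1].reshape(N_COMBINED_POINTS, 2)
    d_left = disp[:N_FEMUR_POINTS].copy()
    d_right = disp[N_FEMUR_POINTS:].copy()
    d_right[:, 0] = -d_right[:, 0]
    a = d_left.reshape(-1)
    b = d_right.reshape(-1)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    score = 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))
    return ModeSymmetryScore(mode_index, score,
                             _classify(score, sym_threshold, opp_threshold))


def classify_modes(model: ShapeModel,
                   sym_threshold: float = DEFAULT_SYM_THRESHOLD,
                   opp_threshold: float = DEFAULT_OPP_THRESHOLD) -> list[ModeSymmetryScore]:
    """Score and classify every retained mode of a combined model."""
    if not -1 <= opp_threshold < sym_threshold <= 1:
        raise ValueError("need -1 <= opp_threshold < sym_threshold <= 1")
    _require_combined(model)
    return [oppositional_score(model, j, sym_threshold, opp_threshold)
            for j in range(1, model.k + 1)]


def exclude_modes_and_reevaluate(model: ShapeModel, fit: ShapeFit,
                                 exclude: Iterable[int]) -> np.ndarray:
    """Re-evaluate a fitted shape with selected mode coefficients zeroed.

    ``exclude`` holds 1-based mode indices.  The pose and the residual of the
    fit are retained, so only the targeted modes' contributions are removed;
    an empty exclusion set reproduces the original points.
    """
    excl = sorted(set(int(j) for j in exclude))
    if any(j < 1 or j > model.k for j in excl):
        raise IndexError(f"exclude indices must be in [1, {model.k}], got {excl}")
    b = fit.b.copy()
    for j in excl:
        b[j - 1] = 0.0
    adjusted = ShapeFit(b=b, pose=fit.pose, residual=fit.residual)
    return reconstruct(model, adjusted, include_residual=True)


# ---------------------------------------------------------------------------
# Point-to-curve distances
# ---------------------------------------------------------------------------

def _point_polyline_distances(points: np.ndarray, curve: np.ndarray,
                              return_feet: bool = False):
    """Distance from each point to an open polyline through ``curve``."""
    P = np.asarray(points, dtype=float)
    C = np.asarray(curve, dtype=float)
    A, B = C[:-1], C[1:]
    d = B - A                                   # (m-1, 2)
    L2 = np.einsum("ij,ij->i", d, d)
    L2safe = np.where(L2 > 0, L2, 1.0)
    ap = P[:, None, :] - A[None, :, :]          # (n, m-1, 2)
    t = np.clip(np.einsum("nij,ij->ni", ap, d) / L2safe, 0.0, 1.0)
    feet = A[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(P[:, None, :] - feet, axis=2)
    seg = np.argmin(dist, axis=1)
    dmin = dist[np.arange(len(P)), seg]
    if return_feet:
        return dmin, feet[np.arange(len(P)), seg]
    return dmin


def point_to_curve_distance(points, curve_points, symmetric: bool = False) -> float:
    """Mean distance from each point to the open polyline through the curve.

    With ``symmetric`` the mean of both directions (points -> curve and curve
    vertices -> points polyline) is returned; the default is one-directional.
    """
    P = np.asarray(points, dtype=float)
    C = np.asarray(curve_points, dtype=float)
    if len(P) == 0 or len(C) < 2:
        raise ValueError("need at least one point and a 2-point curve")
    forward = float(np.mean(_point_polyline_distances(P, C)))
    if not symmetric:
        return forward
    if len(P) < 2:
        raise ValueError("symmetric distance needs >= 2 evaluated points")
    backward = float(np.mean(_point_polyline_distances(C, P)))
    return 0.5 * (forward + backward)


def combined_point_to_curve(points, curve_points, symmetric: bool = False) -> float:
    """Mean point-to-curve distance over all 130 points, evaluated per side.

    The left 65 points are measured against the polyline through the left 65
    curve points and likewise for the right side: the polyline never crosses
    the gap between the two femurs.
    """
    P = np.asarray(points, dtype=float)
    C = np.asarray(curve_points, dtype=float)
    if P.shape != (N_COMBINED_POINTS, 2) or C.shape != (N_COMBINED_POINTS, 2):
        raise ValueError("combined distance needs two (130, 2) configurations")
    h = N_FEMUR_POINTS
    dists = []
    for sl in (slice(0, h), slice(h, None)):
        dists.append(_point_polyline_distances(P[sl], C[sl]))
        if symmetric:
            dists.append(_point_polyline_distances(C[sl], P[sl]))
    return float(np.mean(np.concatenate(dists)))


def adjustment_effect(original, adjusted, symmetric: bool = False) -> float:
    """Shape difference (mm) introduced by a positioning adjustment.

    Similarity-aligns the adjusted 130-point configuration onto the original
    one and returns the mean point-to-curve distance over all 130 points.
    """
    orig = np.asarray(getattr(original, "points", original), dtype=float)
    adj = np.asarray(adjusted, dtype=float)
    if orig.shape != (N_COMBINED_POINTS, 2) or adj.shape != (N_COMBINED_POINTS, 2):
        raise ValueError("adjustment_effect needs (130, 2) configurations")
    pose = align_similarity(adj, orig)
    return combined_point_to_curve(pose.apply(adj), orig, symmetric=symmetric)
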