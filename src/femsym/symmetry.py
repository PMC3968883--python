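"""Single-femur shape models and left-right symmetry statistics.

All femurs of a cohort — lefts and mirrored rights — are pooled into one
65-point shape model, so each femur gets a coefficient vector b in a common
mode basis.  Symmetry is then quantified three ways:

* the per-subject mean point-to-curve distance between the left femur and
  the aligned mirrored right femur;
* per-mode two-sample Welch's t-tests of left vs right mean coefficients
  (with Kolmogorov-Smirnov normality checks and Bonferroni correction);
* per-mode comparison of the cohort-wide coefficient SD with the SD of the
  within-subject left-right coefficient difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .landmark_io import CombinedContour, FemurContour, reflect_points
from .positioning import point_to_curve_distance
from .shape_model import (GPAResult, ShapeFit, ShapeModel, align_similarity,
                          build_model, fit_shape, generalized_procrustes)

__all__ = [
    "SingleModelResult",
    "SymmetryReport",
    "build_single_model",
    "left_right_distance",
    "per_mode_tests",
    "mode_sd_comparison",
    "analyze_symmetry",
    "coefficient_matrix",
]


@dataclass
class SingleModelResult:
    """A pooled 65-point model with per-femur fits, pairable by subject."""

    model: ShapeModel
    gpa: GPAResult
    subject_ids: list[str]
    fits_left: list[ShapeFit]
    fits_right: list[ShapeFit]


def coefficient_matrix(fits: Sequence[ShapeFit]) -> np.ndarray:
    """Stack mode coefficients of many fits into an (n, k) matrix."""
    return np.vstack([f.b for f in fits]) if fits else np.empty((0, 0))


def build_single_model(dataset: Sequence[CombinedContour],
                       mirror_axis: float = 0.0,
                       variance_threshold: float = 0.95) -> SingleModelResult:
    """Build one 65-point model from all femurs, rights mirrored to lefts.

    Every subject contributes two training shapes (left, reflected right);
    the reflection axis is immaterial up to the subsequent alignment.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 subjects")
    shapes = []
    ids = []
    for c in dataset:
        shapes.append(c.left.points)
        shapes.append(reflect_points(c.right.points, axis_x=mirror_axis))
        ids.append(c.subject_id)
    gpa = generalized_procrustes(np.stack(shapes))
    model = build_model(gpa.aligned, variance_threshold=variance_threshold)
    fits = [fit_shape(model, s) for s in shapes]
    return SingleModelResult(model=model, gpa=gpa, subject_ids=ids,
                             fits_left=fits[0::2], fits_right=fits[1::2])


def left_right_distance(left: FemurContour | np.ndarray,
                        right: FemurContour | np.ndarray,
                        symmetric: bool = False) -> float:
    """Mean point-to-curve distance between a subject's two femurs (mm).

    The right femur is mirrored, similarity-aligned onto the left (the
    left's mm scale is the reference), and the 65 left landmarks are
    measured against the polyline through the aligned right landmarks.
    """
    L = np.asarray(getattr(left, "points", left), dtype=float)
    R = np.asarray(getattr(right, "points", right), dtype=float)
    mirrored = reflect_points(R, axis_x=0.0)
    aligned = align_similarity(mirrored, L).apply(mirrored)
    return point_to_curve_distance(L, aligned, symmetric=symmetric)


def per_mode_tests(b_left: np.ndarray, b_right: np.ndarray,
                   family_alpha: float = 0.05) -> pd.DataFrame:
    """Welch's t-test of left vs right coefficients for every mode.

    Two-sided, unequal variances, Welch-Satterthwaite degrees of freedom.
    Normality of each group is checked with the estimated-parameter
    Kolmogorov-Smirnov test (Lilliefors correction, since mean and SD are
    estimated from the data).  Bonferroni-corrected significance uses
    ``family_alpha / k``.  Modes with zero variance in both groups get NaN
    statistics and a ``degenerate`` flag.
    """
    BL = np.atleast_2d(np.asarray(b_left, dtype=float))
    BR = np.atleast_2d(np.asarray(b_right, dtype=float))
    if BL.shape[1] != BR.shape[1]:
        raise ValueError("left and right coefficient matrices disagree on k")
    if BL.shape[0] < 2 or BR.shape[0] < 2:
        raise ValueError("need >= 2 observations per group")
    k = BL.shape[1]
    bonferroni_alpha = family_alpha / k if k else np.nan
    rows = []
    for j in range(k):
        x, y = BL[:, j], BR[:, j]
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        degenerate = vx == 0.0 and vy == 0.0
        if degenerate:
            t = p = df = np.nan
        else:
            t, p = stats.ttest_ind(x, y, equal_var=False)
            nx, ny = len(x), len(y)
            num = (vx / nx + vy / ny) ** 2
            den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            df = num / den if den > 0 else np.nan
        ks_p = []
        for g in (x, y):
            # Lilliefors needs >= 4 observations and non-degenerate spread
            if len(g) < 4 or g.std(ddof=1) == 0.0:
                ks_p.append(np.nan)
            else:
                ks_p.append(float(lilliefors(g, dist="norm")[1]))
        rows.append({
            "mode_index": j + 1,
            "mean_b_left": float(x.mean()),
            "mean_b_right": float(y.mean()),
            "sd_overall": float(np.concatenate([x, y]).std(ddof=1)),
            "sd_lr_difference": np.nan,  # filled by analyze_symmetry for paired data
            "welch_t": float(t) if t == t else np.nan,
            "welch_df": float(df) if df == df else np.nan,
            "p_value": float(p) if p == p else np.nan,
            "ks_p_left": ks_p[0],
            "ks_p_right": ks_p[1],
            "significant_raw": bool(p == p and p < family_alpha),
            "significant_bonferroni": bool(p == p and p < bonferroni_alpha),
            "degenerate": degenerate,
        })
    out = pd.DataFrame(rows)
    out.attrs["family_alpha"] = family_alpha
    out.attrs["bonferroni_alpha"] = bonferroni_alpha
    return out


def mode_sd_comparison(b_left: np.ndarray, b_right: np.ndarray) -> pd.DataFrame:
    """Cohort-wide coefficient SD vs SD of the paired left-right difference.

    For anatomy-driven modes the within-subject difference is far smaller
    than the cohort spread; comparable magnitudes indicate noise- or
    artefact-driven modes.
    """
    BL = np.atleast_2d(np.asarray(b_left, dtype=float))
    BR = np.atleast_2d(np.asarray(b_right, dtype=float))
    if BL.shape != BR.shape:
        raise ValueError("paired comparison needs matching (n, k) matrices")
    sd_overall = np.vstack([BL, BR]).std(axis=0, ddof=1)
    sd_diff = (BL - BR).std(axis=0, ddof=1)
    return pd.DataFrame({"mode_index": np.arange(1, BL.shape[1] + 1),
                         "sd_overall": sd_overall,
                         "sd_lr_difference": sd_diff})


@dataclass
class SymmetryReport:
    """Left-right symmetry summary for one condition (before or after)."""

    n_subjects: int
    retained_modes: int
    mean_lr_distance: float          # mm
    per_mode: pd.DataFrame
    family_alpha: float
    bonferroni_alpha: float

    def round_for_reporting(self) -> pd.DataFrame:
        """Report-granularity copy: distances 0.1 mm, p-values 3 sig. figs."""
        df = self.per_mode.copy()
        for col in ("p_value", "ks_p_left", "ks_p_right"):
            df[col] = df[col].map(
                lambda p: float(f"{p:.3g}") if p == p else np.nan)
        return df


def analyze_symmetry(dataset: Sequence[CombinedContour],
                     variance_threshold: float = 0.95,
                     family_alpha: float = 0.05,
                     single: SingleModelResult | None = None) -> SymmetryReport:
    """Full single-model symmetry analysis of one landmark dataset.

    Builds the pooled model (unless a prebuilt one is supplied), averages
    the per-subject left-right distances, and runs the per-mode statistics.
    """
    if single is None:
        single = build_single_model(dataset, variance_threshold=variance_threshold)
    dists = [left_right_distance(c.left, c.right) for c in dataset]
    BL = coefficient_matrix(single.fits_left)
    BR = coefficient_matrix(single.fits_right)
    per_mode = per_mode_tests(BL, BR, family_alpha=family_alpha)
    per_mode["sd_lr_difference"] = mode_sd_comparison(BL, BR)["sd_lr_difference"]
    return SymmetryReport(
        n_subjects=len(dataset),
        retained_modes=single.model.k,
        mean_lr_distance=float(np.mean(dists)),
        per_mode=per_mode,
        family_alpha=family_alpha,
        bonferroni_alpha=per_mode.attrs["bonferroni_alpha"],
    )
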