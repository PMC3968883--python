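"""Conventional hip geometric measurements and paired asymmetry statistics.

Four measurements are derived from a 65-point proximal-femur contour:

* femoral head diameter — twice the radius of an algebraic least-squares
  (Kasa) circle fit to the head landmarks;
* neck width — the minimum distance between the upper and lower neck border
  polylines (the anatomical "waist" of the neck);
* shaft width — the mean distance between paired medial/lateral shaft
  border landmarks measured perpendicular to the shaft axis (a total-least-
  squares line through the pair midpoints);
* neck-shaft angle — the obtuse anatomical angle between the neck axis
  (femoral head centre to the neck waist midpoint) and the shaft axis.

For a left/right pair, per-subject symmetry is summarised by the absolute
difference AD = |m_l - m_r| and the absolute percent asymmetry

    AA% = |m_l - m_r| / mu * 100,   mu = (m_l + m_r) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landmark_io import FemurContour, IndexMap
from .positioning import _point_polyline_distances

__all__ = [
    "HipMeasurements",
    "AsymmetryStats",
    "MeasurementError",
    "MEASUREMENT_NAMES",
    "fit_circle",
    "measure_hip",
    "asymmetry_stats",
    "summarize_cohort",
]

MEASUREMENT_NAMES = ("head_diameter", "neck_width", "shaft_width", "neck_shaft_angle")


class MeasurementError(ValueError):
    """Raised when a contour's geometry is too degenerate to measure."""


@dataclass(frozen=True)
class HipMeasurements:
    subject_id: str
    side: str
    head_diameter: float   # mm
    neck_width: float      # mm
    shaft_width: float     # mm
    neck_shaft_angle: float  # degrees, obtuse anatomical convention

    def __post_init__(self) -> None:
        for name in ("head_diameter", "neck_width", "shaft_width"):
            if not getattr(self, name) > 0:
                raise MeasurementError(f"{name} must be positive")
        if not 90.0 < self.neck_shaft_angle < 180.0:
            raise MeasurementError(
                f"neck-shaft angle {self.neck_shaft_angle:.1f} outside (90, 180)")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASUREMENT_NAMES}


@dataclass(frozen=True)
class AsymmetryStats:
    measurement_name: str
    m_l: float
    m_r: float
    mu: float
    abs_difference: float
    aa_percent: float


def fit_circle(points) -> tuple[np.ndarray, float]:
    """Algebraic least-squares (Kasa) circle fit; returns (centre, radius)."""
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or len(P) < 3:
        raise MeasurementError("circle fit needs at least 3 planar points")
    A = np.column_stack([2.0 * P[:, 0], 2.0 * P[:, 1], np.ones(len(P))])
    rhs = (P ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise MeasurementError("circle fit degenerate: points are collinear")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise MeasurementError("circle fit degenerate: non-positive radius")
    return np.array([cx, cy]), float(np.sqrt(r2))


def _resample_polyline(curve: np.ndarray, per_segment: int = 40) -> np.ndarray:
    """Vertices plus ``per_segment`` interpolated samples on each segment."""
    out = [curve[:1]]
    for a, b in zip(curve[:-1], curve[1:]):
        t = np.linspace(0.0, 1.0, per_segment + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def _narrowest_crossing(upper: np.ndarray, lower: np.ndarray):
    """Minimum distance between two border polylines and its midpoint.

    Searched from both directions over densely resampled borders so the
    result is symmetric in the two inputs.
    """
    best = (np.inf, None, None)
    for src, dst in ((upper, lower), (lower, upper)):
        samples = _resample_polyline(src)
        d, feet = _point_polyline_distances(samples, dst, return_feet=True)
        i = int(np.argmin(d))
        if d[i] < best[0]:
            best = (float(d[i]), samples[i], feet[i])
    width, p, q = best
    return width, 0.5 * (p + q)


def _tls_direction(points: np.ndarray) -> np.ndarray:
    """Unit direction of the total-least-squares line through the points."""
    c = points - points.mean(axis=0)
    C = c.T @ c
    w, V = np.linalg.eigh(C)
    if w[-1] < 1e-12:
        raise MeasurementError("shaft axis degenerate: anchor points coincide")
    return V[:, -1]


def measure_hip(contour: FemurContour, index_map: IndexMap) -> HipMeasurements:
    """Compute the four hip geometric measurements from one contour.

    The measurements are invariant under rigid motion and reflection; the
    lengths scale with the contour and the angle does not.
    """
    P = contour.points
    if len(index_map.head_indices) < 3:
        raise MeasurementError("need >= 3 head landmarks for the circle fit")
    centre, radius = fit_circle(P[list(index_map.head_indices)])

    upper = P[list(index_map.neck_upper)]
    lower = P[list(index_map.neck_lower)]
    if len(upper) < 2 or len(lower) < 2:
        raise MeasurementError("need >= 2 landmarks on each neck border")
    neck_width, waist_mid = _narrowest_crossing(upper, lower)

    med = P[list(index_map.shaft_medial)]
    lat = P[list(index_map.shaft_lateral)]
    if len(med) < 2:
        raise MeasurementError("need >= 2 paired shaft landmarks")
    mids = 0.5 * (med + lat)
    shaft_dir = _tls_direction(mids)
    # orient the shaft axis distally (away from the femoral head)
    if shaft_dir @ (centre - mids.mean(axis=0)) > 0:
        shaft_dir = -shaft_dir
    perp = np.array([-shaft_dir[1], shaft_dir[0]])
    shaft_width = float(np.mean(np.abs((med - lat) @ perp)))

    neck_dir = centre - waist_mid
    nn = np.linalg.norm(neck_dir)
    if nn < 1e-9:
        raise MeasurementError("neck axis degenerate: waist coincides with head centre")
    neck_dir = neck_dir / nn
    angle = float(np.degrees(np.arccos(np.clip(neck_dir @ shaft_dir, -1.0, 1.0))))
    if angle <= 90.0:
        angle = 180.0 - angle

    return HipMeasurements(contour.subject_id, contour.side,
                           head_diameter=2.0 * radius, neck_width=neck_width,
                           shaft_width=shaft_width, neck_shaft_angle=angle)


def asymmetry_stats(m_l: float, m_r: float,
                    measurement_name: str = "") -> AsymmetryStats:
    """Paired left/right asymmetry: AD = |m_l - m_r|, AA% = AD / mu * 100."""
    if not (m_l > 0 and m_r > 0):
        raise ValueError("measurement values must be positive")
    mu = 0.5 * (m_l + m_r)
    ad = abs(m_l - m_r)
    return AsymmetryStats(measurement_name, m_l, m_r, mu, ad, 100.0 * ad / mu)


def _mean_sd_ci(values: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(values))
    return mean, sd, mean - half, mean + half


def summarize_cohort(left: Sequence[HipMeasurements],
                     right: Sequence[HipMeasurements]) -> pd.DataFrame:
    """Cohort table of measurement values, AD and AA% with mean, SD, 95% CI.

    ``left`` and ``right`` must be paired by position (same subject order).
    The value columns pool both femurs; AD and AA% are per-subject paired
    statistics.  CIs use the normal approximation mean +/- 1.96 SD / sqrt(n).
    """
    if len(left) != len(right) or len(left) < 2:
        raise ValueError("need >= 2 paired subjects")
    rows = []
    for name in MEASUREMENT_NAMES:
        ml = np.array([getattr(m, name) for m in left])
        mr = np.array([getattr(m, name) for m in right])
        pairs = [asymmetry_stats(a, b, name) for a, b in zip(ml, mr)]
        values = np.concatenate([ml, mr])
        ad = np.array([p.abs_difference for p in pairs])
        aa = np.array([p.aa_percent for p in pairs])
        vm, vs, vlo, vhi = _mean_sd_ci(values)
        am, asd, alo, ahi = _mean_sd_ci(ad)
        pm, psd, plo, phi = _mean_sd_ci(aa)
        rows.append({
            "measurement": name,
            "value_mean": vm, "value_sd": vs, "value_ci_lo": vlo, "value_ci_hi": vhi,
            "ad_mean": am, "ad_sd": asd, "ad_ci_lo": alo, "ad_ci_hi": ahi,
            "aa_pct_mean": pm, "aa_pct_sd": psd, "aa_pct_ci_lo": plo, "aa_pct_ci_hi": phi,
            "n_subjects": len(left),
        })
    return pd.DataFrame(rows)


def compare_adjustment(before_left: Sequence[HipMeasurements],
                       before_right: Sequence[HipMeasurements],
                       after_left: Sequence[HipMeasurements],
                       after_right: Sequence[HipMeasurements]) -> pd.DataFrame:
    """Paired test of the before-vs-after change in per-subject AD.

    A two-sided paired t-test per measurement supports claims of a
    significant decrease in left-right absolute difference after the
    positioning adjustment.
    """
    rows = []
    for name in MEASUREMENT_NAMES:
        ad_before = np.array([abs(getattr(l, name) - getattr(r, name))
                              for l, r in zip(before_left, before_right)])
        ad_after = np.array([abs(getattr(l, name) - getattr(r, name))
                             for l, r in zip(after_left, after_right)])
        diff = ad_after - ad_before
        if np.allclose(diff, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(ad_after, ad_before)
        rows.append({"measurement": name,
                     "ad_mean_before": float(ad_before.mean()),
                     "ad_mean_after": float(ad_after.mean()),
                     "t_paired": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
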