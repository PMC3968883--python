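"""Synthetic landmark datasets with the statistical structure of paired AP hips.

The generator emulates what the analysis pipeline assumes about bilateral
radiographic data:

* a shared per-subject anatomy, instantiated as a parametric 65-point left
  proximal femur (circular head arc, concave neck borders, parallel shaft
  borders, no trochanters) whose default dimensions are typical cohort means
  for Caucasian females (head diameter 51.6 mm, neck width 35.3 mm, shaft
  width 37.0 mm, neck-shaft angle 126.7 deg);
* an exact mirror relation between the sides plus small independent
  per-point left-right anatomical noise;
* subject-positioning artefacts: pelvic rotation beta rotates BOTH projected
  femurs in the same image-plane direction about their own centroids (the
  classic oppositional orientation pattern) and, because the anteverted
  femoral neck foreshortens oppositely on the two sides, shifts the apparent
  neck-shaft angle by +/- beta (projection foreshortening); "shaft sliding" re-parameterises the
  shaft border landmarks along the border polylines without changing the
  silhouette, on one side or anti-symmetrically on both;
* a per-subject global similarity pose (absorbed by alignment).

Every subject draws from its own random stream derived from
``(seed, subject index)``, so datasets are reproducible and stable when
``n_subjects`` changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .landmark_io import (CombinedContour, FemurContour, IndexMap,
                          N_FEMUR_POINTS, reflect_points, write_manifest,
                          write_pts)

__all__ = [
    "TemplateParams",
    "AnatomySDs",
    "PositioningParams",
    "PoseParams",
    "SyntheticConfig",
    "SubjectTruth",
    "GroundTruth",
    "make_template",
    "build_contour",
    "generate_dataset",
    "write_dataset",
    "NSA_PROJECTION_COEF",
]

# Apparent neck-shaft-angle change (deg) per degree of pelvic rotation.
# Projection sensitivity of an anteverted neck; fixed design constant.
NSA_PROJECTION_COEF = 1.2

# Horizontal half-separation of the two femur shafts in the combined image (mm)
_FEMUR_OFFSET = 80.0


@dataclass(frozen=True)
class TemplateParams:
    """Dimensions of the parametric femur template (cohort-mean defaults)."""

    head_diameter: float = 51.6    # mm
    neck_width: float = 35.3       # mm
    shaft_width: float = 37.0      # mm
    neck_shaft_angle: float = 126.7  # degrees


@dataclass(frozen=True)
class AnatomySDs:
    """Between-subject anatomical variation (shared by the two sides).

    A correlated overall body-size factor (``global_size_sd``, absorbed by
    the similarity alignment) carries part of the cohort spread of each
    measurement; the per-measurement SDs below are the residual,
    size-independent variation.

    Two shared (mirrored) per-subject displacement fields give the cohort
    the many-mode decaying anatomy spectrum real bone shape has instead of
    an artificially low-rank four-parameter one: ``detail_sd`` drives
    coarse low-order variation (contour harmonic 1) and ``texture_sd``
    drives fine local boundary texture (harmonics 3-32, flat spectrum).

    The cohort is kept anatomically homogeneous on purpose (single-gender
    single-ethnicity levels of spread): a combined left-right model can only
    distinguish positioning modes from anatomy modes cleanly when the
    anatomy spectrum does not overlap the positioning-artefact variances.
    """

    head_radius_sd: float = 1.8        # mm
    neck_width_sd: float = 2.6         # mm
    shaft_width_sd: float = 3.3        # mm
    neck_shaft_angle_sd: float = 2.5   # degrees
    global_size_sd: float = 0.05       # fraction
    detail_sd: float = 1.5             # mm, coarse shared shape detail
    texture_sd: float = 0.16           # mm, fine shared boundary texture


@dataclass(frozen=True)
class PositioningParams:
    """Subject-positioning artefact magnitudes."""

    pelvic_rotation_sd: float = 3.0    # degrees (beta)
    shaft_slide_sd: float = 2.0        # mm arc length
    slide_prevalence: float = 0.2      # fraction of subjects with sliding
    slide_bilateral_prob: float = 1.0  # of sliders, fraction sliding on both sides


@dataclass(frozen=True)
class PoseParams:
    """Per-subject global similarity pose of the combined configuration."""

    global_rotation_sd: float = 2.0  # degrees
    translation_sd: float = 10.0     # mm
    scale_sd: float = 0.02           # fraction


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 200
    seed: int = 0
    template: TemplateParams = field(default_factory=TemplateParams)
    anatomy_sds: AnatomySDs = field(default_factory=AnatomySDs)
    lr_noise_sd: float = 0.3  # mm, independent per-point per-side
    positioning: PositioningParams = field(default_factory=PositioningParams)
    pose: PoseParams = field(default_factory=PoseParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        sds = [self.lr_noise_sd,
               *(getattr(self.anatomy_sds, f) for f in
                 ("head_radius_sd", "neck_width_sd", "shaft_width_sd",
                  "neck_shaft_angle_sd", "global_size_sd", "detail_sd",
                  "texture_sd")),
               self.positioning.pelvic_rotation_sd, self.positioning.shaft_slide_sd,
               self.pose.global_rotation_sd, self.pose.translation_sd,
               self.pose.scale_sd]
        if any(s < 0 for s in sds):
            raise ValueError("all standard deviations must be >= 0")
        for p in (self.positioning.slide_prevalence,
                  self.positioning.slide_bilateral_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth parameters of one simulated subject."""

    subject_id: str
    head_radius: float
    neck_width: float
    shaft_width: float
    neck_shaft_angle: float
    size: float
    pelvic_rotation_deg: float
    slide_left_mm: float
    slide_right_mm: float
    pose_rotation_deg: float
    pose_tx: float
    pose_ty: float
    pose_scale: float


@dataclass
class GroundTruth:
    subjects: list[SubjectTruth]

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.subjects])

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(asdict(self.subjects[0])))
            writer.writeheader()
            for s in self.subjects:
                writer.writerow(asdict(s))


# ---------------------------------------------------------------------------
# Parametric template
#
# The contour is an open outline in anatomical order: lateral shaft border
# (distal -> proximal), trochanteric cut to the upper neck border, head arc,
# lower neck border, medial shaft border (proximal -> distal).  Point counts:
# 16 + 6 + 21 + 6 + 16 = 65.
# ---------------------------------------------------------------------------

_N_SHAFT = 16
_N_NECK = 6
_N_HEAD = 21

_SHAFT_TOP_Y = -50.0
_SHAFT_BOT_Y = -80.0
_NECK_BASE = np.array([0.0, -40.0])
_HEAD_DIST = 48.0     # neck base -> head centre along the neck axis (mm)
_NECK_S0 = 10.0       # neck border span along the axis (mm from the base)
_NECK_S1 = 30.0
_NECK_FLARE = 0.008   # quadratic flare of the border away from the waist (1/mm)


def build_contour(params: TemplateParams = TemplateParams()) -> tuple[np.ndarray, IndexMap]:
    """Deterministic 65-point left-femur outline for the given dimensions.

    The head landmarks lie exactly on a circle of the requested diameter,
    the shaft borders are exactly parallel at the requested width, and the
    neck waist crossing is perpendicular to the neck axis at the requested
    width, so the construction parameters are recoverable by measurement.
    """
    r_head = params.head_diameter / 2.0
    half_shaft = params.shaft_width / 2.0
    half_neck = params.neck_width / 2.0
    alpha = np.radians(params.neck_shaft_angle)

    # neck axis unit vector (toward the head) and its upper-side normal;
    # the shaft axis is vertical, pointing distally (0, -1), so the angle
    # between the two axes is exactly the requested neck-shaft angle.
    d_n = np.array([np.sin(alpha), -np.cos(alpha)])
    p_n = np.array([-d_n[1], d_n[0]])

    head_centre = _NECK_BASE + _HEAD_DIST * d_n

    # shaft borders, distal -> proximal on the lateral (-x) side
    ys_up = np.linspace(_SHAFT_BOT_Y, _SHAFT_TOP_Y, _N_SHAFT)
    lateral = np.column_stack([np.full(_N_SHAFT, -half_shaft), ys_up])
    medial = np.column_stack([np.full(_N_SHAFT, half_shaft), ys_up[::-1]])

    # neck borders: offset curves of the axis with a quadratic flare whose
    # waist sits midway between the two central samples, making the
    # narrowest crossing perpendicular to the axis and centred on it
    s = np.linspace(_NECK_S0, _NECK_S1, _N_NECK)
    s_waist = 0.5 * (s[_N_NECK // 2 - 1] + s[_N_NECK // 2])
    h = half_neck + _NECK_FLARE * (s - s_waist) ** 2
    axis_pts = _NECK_BASE[None, :] + s[:, None] * d_n[None, :]
    neck_upper = axis_pts + h[:, None] * p_n[None, :]
    neck_lower_fwd = axis_pts - h[:, None] * p_n[None, :]

    # head arc between the two neck junctions, through the far pole
    psi = np.arctan2(d_n[1], d_n[0])
    phi_j = np.arctan2(h[-1], _NECK_S1 - _HEAD_DIST)
    arc = np.linspace(psi + phi_j, psi - phi_j, _N_HEAD)
    head = head_centre[None, :] + r_head * np.column_stack([np.cos(arc), np.sin(arc)])

    points = np.vstack([lateral, neck_upper, head, neck_lower_fwd[::-1], medial])
    assert points.shape == (N_FEMUR_POINTS, 2)

    i0 = 0
    idx_lat = tuple(range(i0, i0 + _N_SHAFT)); i0 += _N_SHAFT
    idx_nu = tuple(range(i0, i0 + _N_NECK)); i0 += _N_NECK
    idx_head = tuple(range(i0, i0 + _N_HEAD)); i0 += _N_HEAD
    idx_nl = tuple(range(i0, i0 + _N_NECK)); i0 += _N_NECK
    idx_med = tuple(range(i0, i0 + _N_SHAFT))
    index_map = IndexMap(
        head_indices=idx_head,
        neck_upper=idx_nu,
        neck_lower=idx_nl[::-1],            # stored head -> shaft reversed: distal-consistent
        shaft_medial=idx_med[::-1],         # distal -> proximal, paired with lateral
        shaft_lateral=idx_lat,
        neck_axis_anchor=idx_nu + idx_nl,
        shaft_axis_anchor=idx_lat + idx_med,
    )
    return points, index_map


def make_template(params: TemplateParams = TemplateParams()) -> tuple[FemurContour, IndexMap]:
    """The canonical left-femur template contour and its index map."""
    pts, imap = build_contour(params)
    return FemurContour("template", "left", pts), imap


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _slide_along_polyline(points: np.ndarray, order: tuple[int, ...],
                          offset: float) -> None:
    """Shift the listed landmarks by ``offset`` mm of arc length along the
    polyline they form, extrapolating linearly beyond its ends (in place)."""
    idx = list(order)
    poly = points[idx]
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    new_arc = arc + offset
    total = arc[-1]
    for j, a in zip(idx, new_arc):
        if a <= 0.0:
            t = poly[0] + (a / seg_len[0]) * seg[0] if seg_len[0] > 0 else poly[0]
        elif a >= total:
            t = poly[-1] + ((a - total) / seg_len[-1]) * seg[-1] if seg_len[-1] > 0 else poly[-1]
        else:
            k = int(np.searchsorted(arc, a, side="right")) - 1
            frac = (a - arc[k]) / seg_len[k]
            t = poly[k] + frac * seg[k]
        points[j] = t


def _detail_field(rng: np.random.Generator, coarse_sd: float,
                  texture_sd: float) -> np.ndarray:
    """Smooth random displacement field along the contour parameter.

    Contour harmonic 1 carries amplitude ``coarse_sd`` per coordinate;
    harmonics 3-32 carry a flat ``texture_sd``.  Harmonic 2 is left empty so
    the coarse and texture bands are spectrally separated.
    """
    u = np.linspace(0.0, 1.0, N_FEMUR_POINTS)
    f = np.zeros((N_FEMUR_POINTS, 2))
    bands = [(1, coarse_sd)]
    bands += [(h, texture_sd) for h in range(3, 33)]
    for h, sd in bands:
        coef = rng.normal(0.0, sd, size=4)
        c = np.cos(np.pi * h * u)
        s = np.sin(np.pi * h * u)
        f[:, 0] += coef[0] * c + coef[1] * s
        f[:, 1] += coef[2] * c + coef[3] * s
    return f


def _rotate_about(points: np.ndarray, centre: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.array([[c, -s], [s, c]])
    return (points - centre) @ R.T + centre


def generate_dataset(config: SyntheticConfig) -> tuple[list[CombinedContour], GroundTruth]:
    """Simulate a cohort of combined 130-point configurations.

    Per subject: sample shared anatomy once; instantiate the left femur and
    mirror it for the right; add independent per-point noise to each side;
    apply the pelvic-rotation artefact (same-sign in-plane rotation about
    each femur's own centroid plus oppositional apparent neck-shaft-angle
    shift) and, with the configured prevalence, shaft sliding; compose the
    130-point configuration and apply one global similarity pose.
    """
    tp = config.template
    an = config.anatomy_sds
    po = config.positioning
    gp = config.pose
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)

    contours: list[CombinedContour] = []
    truths: list[SubjectTruth] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sid = f"S{i:04d}"

        head_r = tp.head_diameter / 2.0 + rng.normal(0.0, an.head_radius_sd)
        neck_w = tp.neck_width + rng.normal(0.0, an.neck_width_sd)
        shaft_w = tp.shaft_width + rng.normal(0.0, an.shaft_width_sd)
        nsa = tp.neck_shaft_angle + rng.normal(0.0, an.neck_shaft_angle_sd)
        size = max(0.5, 1.0 + rng.normal(0.0, an.global_size_sd))
        detail = _detail_field(rng, an.detail_sd, an.texture_sd)
        beta = rng.normal(0.0, po.pelvic_rotation_sd)

        slide_left = slide_right = 0.0
        if po.slide_prevalence > 0 and rng.uniform() < po.slide_prevalence:
            delta = rng.normal(0.0, po.shaft_slide_sd)
            if rng.uniform() < po.slide_bilateral_prob:
                slide_left, slide_right = delta, -delta
            elif rng.uniform() < 0.5:
                slide_left = delta
            else:
                slide_right = delta

        # apparent per-side anatomy: the pelvic rotation foreshortens the
        # anteverted neck oppositely on the two sides.  The bend is injected
        # as the analytic derivative field of the contour w.r.t. the
        # neck-shaft angle so the artefact is exactly linear in beta (like
        # the orientation field below) and stays within one model mode.
        left_pts, imap = build_contour(TemplateParams(2 * head_r, neck_w, shaft_w, nsa))
        d = 0.5
        hi, _ = build_contour(TemplateParams(2 * head_r, neck_w, shaft_w, nsa + d))
        lo, _ = build_contour(TemplateParams(2 * head_r, neck_w, shaft_w, nsa - d))
        bend = (hi - lo) / (2.0 * d)       # points per degree of apparent angle
        shift = NSA_PROJECTION_COEF * beta
        right_src = left_pts - shift * bend
        left_pts = left_pts + shift * bend

        # shaft sliding re-parameterises landmarks along the underlying
        # smooth bone boundary, so it is applied before the fine detail and
        # noise are painted on (the slid point still carries its own detail
        # and noise displacement)
        for pts, off in ((left_pts, slide_left), (right_src, slide_right)):
            if off != 0.0:
                _slide_along_polyline(pts, imap.shaft_lateral, off)
                _slide_along_polyline(pts, imap.shaft_medial, off)

        left_pts = left_pts + detail   # shared anatomy detail, applied pre-mirror
        right_src = right_src + detail

        left_pts = size * left_pts + np.array([-_FEMUR_OFFSET * size, 0.0])
        right_src = size * right_src + np.array([-_FEMUR_OFFSET * size, 0.0])
        right_pts = reflect_points(right_src, axis_x=0.0)

        left_pts += rng.normal(0.0, config.lr_noise_sd, left_pts.shape)
        right_pts += rng.normal(0.0, config.lr_noise_sd, right_pts.shape)

        # oppositional orientation artefact: both femurs rotate the same way
        # in the image plane, which is mirror-opposed between the sides.
        # Applied as the linearised rotation field so the artefact is exactly
        # linear in beta and hence lies in the span of one model mode.
        rot = np.radians(beta)
        for pts in (left_pts, right_pts):
            centred = pts - pts.mean(axis=0)
            pts += rot * np.column_stack([-centred[:, 1], centred[:, 0]])

        combined = np.vstack([left_pts, right_pts])
        pose_rot = rng.normal(0.0, gp.global_rotation_sd)
        pose_t = rng.normal(0.0, gp.translation_sd, 2)
        pose_s = max(0.5, 1.0 + rng.normal(0.0, gp.scale_sd))
        centre = combined.mean(axis=0)
        combined = pose_s * _rotate_about(combined, centre, np.radians(pose_rot)) + pose_t

        contours.append(CombinedContour(sid, combined))
        truths.append(SubjectTruth(sid, head_r, neck_w, shaft_w, nsa, size, beta,
                                   slide_left, slide_right, pose_rot,
                                   float(pose_t[0]), float(pose_t[1]), pose_s))
    return contours, GroundTruth(truths)


def write_dataset(contours: list[CombinedContour], out_dir: str | Path,
                  ground_truth: GroundTruth | None = None) -> Path:
    """Write .pts files plus a manifest (and optional ground-truth CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in contours:
        lp = f"{c.subject_id}_left.pts"
        rp = f"{c.subject_id}_right.pts"
        write_pts(out / lp, c.left.points)
        write_pts(out / rp, c.right.points)
        entries.append((c.subject_id, lp, rp))
    manifest = out / "manifest.csv"
    write_manifest(manifest, entries)
    if ground_truth is not None:
        ground_truth.write_csv(out / "ground_truth.csv")
    return manifest
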