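"""Landmark file I/O, contour containers and the left/right mirroring convention.

A proximal femur is represented by 65 ordered 2D landmarks in millimetres;
point index ``i`` has the same anatomical meaning on every contour
(correspondence).  A subject is represented by the 130-point combined
configuration ``[left 0..64, right 65..129]`` in which index ``i`` and
``i + 65`` are anatomically corresponding points on the two sides.

Coordinate convention: x increases to the viewer's right, y increases upward.
Files produced by image tools with a y-down axis must be flipped at import
(``read_pts(..., y_down=True)`` / the ``--y-down`` CLI flag).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

N_FEMUR_POINTS = 65
N_COMBINED_POINTS = 2 * N_FEMUR_POINTS

__all__ = [
    "N_FEMUR_POINTS",
    "N_COMBINED_POINTS",
    "FemurContour",
    "CombinedContour",
    "IndexMap",
    "PtsParseError",
    "read_pts",
    "write_pts",
    "reflect",
    "reflect_points",
    "load_dataset",
    "write_manifest",
]


class PtsParseError(ValueError):
    """Raised for a malformed .pts file; message names the offending line."""


def _as_points(points, n_expected: int | None) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be an (n, 2) array, got shape {pts.shape}")
    if n_expected is not None and pts.shape[0] != n_expected:
        raise ValueError(f"expected {n_expected} points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("all coordinates must be finite")
    return pts


@dataclass
class FemurContour:
    """Ordered 65-point landmark contour of one proximal femur (mm)."""

    subject_id: str
    side: str  # "left" or "right"
    points: np.ndarray  # (65, 2) float64

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.points = _as_points(self.points, N_FEMUR_POINTS)


@dataclass
class CombinedContour:
    """130-point left+right configuration; indices 0-64 left, 65-129 right."""

    subject_id: str
    points: np.ndarray  # (130, 2) float64

    def __post_init__(self) -> None:
        self.points = _as_points(self.points, N_COMBINED_POINTS)

    @property
    def left(self) -> FemurContour:
        return FemurContour(self.subject_id, "left", self.points[:N_FEMUR_POINTS].copy())

    @property
    def right(self) -> FemurContour:
        return FemurContour(self.subject_id, "right", self.points[N_FEMUR_POINTS:].copy())

    @classmethod
    def from_sides(cls, left: FemurContour, right: FemurContour) -> "CombinedContour":
        if left.subject_id != right.subject_id:
            raise ValueError("left and right contours belong to different subjects")
        if left.side != "left" or right.side != "right":
            raise ValueError("from_sides expects (left, right) in that order")
        return cls(left.subject_id, np.vstack([left.points, right.points]))


@dataclass
class IndexMap:
    """Anatomical index semantics for a 65-point landmark scheme.

    The published 65-point scheme ships no index table, so region membership
    is configuration data.  The defaults used throughout this package are the
    synthetic template's (:func:`femsym.synthetic.make_template`).
    """

    head_indices: tuple[int, ...]
    neck_upper: tuple[int, ...]
    neck_lower: tuple[int, ...]
    shaft_medial: tuple[int, ...]   # ordered distal -> proximal, paired with shaft_lateral
    shaft_lateral: tuple[int, ...]  # ordered distal -> proximal
    neck_axis_anchor: tuple[int, ...] = field(default=())
    shaft_axis_anchor: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("head_indices", "neck_upper", "neck_lower", "shaft_medial",
                     "shaft_lateral", "neck_axis_anchor", "shaft_axis_anchor"):
            idx = tuple(int(i) for i in getattr(self, name))
            if any(i < 0 or i >= N_FEMUR_POINTS for i in idx):
                raise ValueError(f"{name}: indices must lie in [0, {N_FEMUR_POINTS - 1}]")
            setattr(self, name, idx)
        if len(self.shaft_medial) != len(self.shaft_lateral):
            raise ValueError("shaft_medial and shaft_lateral must pair one-to-one")
        head = set(self.head_indices)
        if head & set(self.neck_upper) or head & set(self.neck_lower):
            raise ValueError("head indices must be disjoint from neck border indices")
        if set(self.neck_upper) & set(self.neck_lower):
            raise ValueError("upper and lower neck borders must be disjoint")
        if set(self.shaft_medial) & set(self.shaft_lateral):
            raise ValueError("medial and lateral shaft borders must be disjoint")


# ---------------------------------------------------------------------------
# .pts dialect
#
#   version: 1
#   n_points: <N>
#   {
#   <x> <y>          (N lines, ASCII decimals)
#   }
# ---------------------------------------------------------------------------

def read_pts(path: str | Path, y_down: bool = False) -> np.ndarray:
    """Read a .pts file and return its points as an (n, 2) float array.

    ``y_down=True`` negates y at import for files written in image (y-down)
    coordinates.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    def fail(lineno: int, msg: str):
        raise PtsParseError(f"{path}:{lineno}: {msg}")

    if len(lines) < 4:
        fail(1, "file too short for the .pts format")
    if lines[0].strip() != "version: 1":
        fail(1, f"expected 'version: 1', got {lines[0]!r}")
    head = lines[1].strip()
    if not head.startswith("n_points:"):
        fail(2, f"expected 'n_points: <N>', got {lines[1]!r}")
    try:
        n = int(head.split(":", 1)[1])
    except ValueError:
        fail(2, f"non-integer point count in {lines[1]!r}")
    if lines[2].strip() != "{":
        fail(3, f"expected '{{', got {lines[2]!r}")

    pts = []
    lineno = 3
    for lineno, line in enumerate(lines[3:], start=4):
        s = line.strip()
        if s == "}":
            break
        if not s:
            continue
        tok = s.split()
        if len(tok) != 2:
            fail(lineno, f"expected '<x> <y>', got {line!r}")
        try:
            pts.append((float(tok[0]), float(tok[1])))
        except ValueError:
            fail(lineno, f"non-numeric coordinate in {line!r}")
    else:
        fail(len(lines), "missing closing '}'")

    if len(pts) != n:
        fail(lineno, f"header declares n_points: {n} but file contains {len(pts)} pairs")
    out = np.asarray(pts, dtype=float)
    if y_down:
        out[:, 1] = -out[:, 1]
    return out


def write_pts(path: str | Path, points) -> None:
    """Write points in the .pts dialect with 6-decimal precision."""
    pts = _as_points(points, None)
    lines = ["version: 1", f"n_points: {len(pts)}", "{"]
    lines += [f"{x:.6f} {y:.6f}" for x, y in pts]
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mirroring
# ---------------------------------------------------------------------------

def reflect_points(points, axis_x: float = 0.0) -> np.ndarray:
    """Reflect points about the vertical line x = axis_x (x -> 2*axis_x - x)."""
    pts = _as_points(points, None).copy()
    pts[:, 0] = 2.0 * axis_x - pts[:, 0]
    return pts


def reflect(contour: FemurContour, axis_x: float = 0.0) -> FemurContour:
    """Mirror a femur contour about a vertical axis, toggling the side label.

    Index order is unchanged: landmark indices are anatomical, so the mirror
    of point i is still point i on the other side.
    """
    other = "right" if contour.side == "left" else "left"
    return FemurContour(contour.subject_id, other, reflect_points(contour.points, axis_x))


# ---------------------------------------------------------------------------
# Dataset manifest (CSV: subject_id,left_pts,right_pts)
# ---------------------------------------------------------------------------

def load_dataset(manifest: str | Path, y_down: bool = False) -> list[CombinedContour]:
    """Load a dataset manifest into combined 130-point contours.

    Subjects whose files are missing or malformed are skipped with a logged
    warning.  An empty manifest or a duplicated subject_id is an error.
    """
    manifest = Path(manifest)
    with open(manifest, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"subject_id", "left_pts", "right_pts"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{manifest}: manifest must have header {sorted(required)}")
        rows = list(reader)
    if not rows:
        raise ValueError(f"{manifest}: empty manifest")
    seen: set[str] = set()
    out: list[CombinedContour] = []
    n_skipped = 0
    for row in rows:
        sid = row["subject_id"]
        if sid in seen:
            raise ValueError(f"{manifest}: duplicate subject_id {sid!r}")
        seen.add(sid)
        try:
            left = read_pts(manifest.parent / row["left_pts"], y_down=y_down)
            right = read_pts(manifest.parent / row["right_pts"], y_down=y_down)
            out.append(CombinedContour(sid, np.vstack([left, right])))
        except (OSError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping subject %s: %s", sid, exc)
    logger.info("loaded %d subjects (%d skipped) from %s", len(out), n_skipped, manifest)
    return out


def write_manifest(path: str | Path, entries: Iterable[Sequence[str]]) -> None:
    """Write a manifest CSV from (subject_id, left_pts, right_pts) triples."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "left_pts", "right_pts"])
        for row in entries:
            writer.writerow(list(row))
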