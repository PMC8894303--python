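"""Regions of interest around the pleural line.

The operator draws either a rectangle or a polygon following the course of
the pleural line (excluding rib shadows); here those shapes arrive as vertex
lists and are rasterized to boolean pixel masks.  Conventions, declared
once for the whole package:

* coordinates are 0-based ``(row, column)`` pairs, row increasing downward;
* a pixel belongs to a polygon when its centre satisfies the even-odd
  interior rule; pixels whose centre lies exactly on an edge are inside;
* a rectangle covers the closed interval between its two corners.

Non-convex polygons are allowed — a ROI following a bending pleural line is
elongated and frequently non-convex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["RoiShape", "RoiMask", "rasterize"]

_EPS = 1e-9


@dataclass(frozen=True)
class RoiShape:
    """A rectangle (two opposite corners) or polygon (>= 3 vertices).

    Parameters
    ----------
    kind
        ``"rectangle"`` or ``"polygon"``.
    vertices
        Sequence of ``(row, column)`` pixel coordinates.
    """

    kind: str
    vertices: tuple[tuple[float, float], ...]

    def __init__(self, kind: str, vertices: Sequence[Sequence[float]]):
        if kind not in ("rectangle", "polygon"):
            raise ValidationError(f"unknown ROI kind {kind!r}")
        verts = tuple((float(r), float(c)) for r, c in vertices)
        if kind == "rectangle" and len(verts) != 2:
            raise ValidationError("rectangle requires exactly 2 corner vertices")
        if kind == "polygon":
            if len(verts) < 3:
                raise ValidationError("polygon requires at least 3 vertices")
            if abs(_shoelace_area(verts)) < _EPS:
                raise ValidationError("degenerate polygon with zero area")
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def from_dict(cls, d: dict) -> "RoiShape":
        return cls(d["kind"], d["vertices"])

    def to_dict(self) -> dict:
        return {"kind": self.kind, "vertices": [list(v) for v in self.vertices]}


@dataclass(frozen=True)
class RoiMask:
    """Boolean pixel mask with the same shape as its frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if int(m.sum()) < 2:
            raise ValidationError(
                "ROI covers fewer than 2 pixels; no pixel pair can be formed"
            )
        object.__setattr__(self, "mask", m)

    @property
    def n_inside(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _shoelace_area(verts: Sequence[tuple[float, float]]) -> float:
    r = np.array([v[0] for v in verts])
    c = np.array([v[1] for v in verts])
    return 0.5 * float(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r))


def _point_on_boundary(r: np.ndarray, c: np.ndarray, verts) -> np.ndarray:
    """True where pixel centre (r, c) lies on a polygon edge."""
    on = np.zeros(r.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        r1, c1 = verts[k]
        r2, c2 = verts[(k + 1) % n]
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        within = (
            (np.minimum(r1, r2) - _EPS <= r)
            & (r <= np.maximum(r1, r2) + _EPS)
            & (np.minimum(c1, c2) - _EPS <= c)
            & (c <= np.maximum(c1, c2) + _EPS)
        )
        on |= (np.abs(cross) <= _EPS * max(1.0, abs(r2 - r1) + abs(c2 - c1))) & within
    return on


def _even_odd_interior(r: np.ndarray, c: np.ndarray, verts) -> np.ndarray:
    """Even-odd crossing test with a ray cast along +column."""
    inside = np.zeros(r.shape, dtype=bool)
    n = len(verts)
    for k in range(n):
        r1, c1 = verts[k]
        r2, c2 = verts[(k + 1) % n]
        crosses = (r1 > r) != (r2 > r)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_at = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (c < c_at)
    return inside


def rasterize(shape: RoiShape, height: int, width: int) -> RoiMask:
    """Rasterize an ROI shape to a boolean mask of the given frame size.

    Raises
    ------
    ValidationError
        If a vertex falls outside the frame, the polygon is degenerate, or
        the resulting mask covers fewer than 2 pixels.
    """
    for r, c in shape.vertices:
        if not (0 <= r <= height - 1 and 0 <= c <= width - 1):
            raise ValidationError(
                f"vertex ({r}, {c}) outside frame bounds {height}x{width}"
            )
    rr, cc = np.meshgrid(
        np.arange(height, dtype=float), np.arange(width, dtype=float), indexing="ij"
    )
    if shape.kind == "rectangle":
        (r1, c1), (r2, c2) = shape.vertices
        mask = (
            (np.minimum(r1, r2) <= rr)
            & (rr <= np.maximum(r1, r2))
            & (np.minimum(c1, c2) <= cc)
            & (cc <= np.maximum(c1, c2))
        )
    else:
        mask = _even_odd_interior(rr, cc, shape.vertices)
        mask |= _point_on_boundary(rr, cc, shape.vertices)
    return RoiMask(mask)
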