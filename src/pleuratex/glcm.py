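"""Grey-level quantization and masked co-occurrence matrices.

The co-occurrence matrix P(i, j; d, θ) holds the probability of finding a
pixel with quantized level *i* at displacement (d, θ) from a pixel with
level *j*, counting only pairs whose two pixels both lie inside the ROI
mask.  Accumulation is symmetric — every pair increments (i, j) and
(j, i) — so θ and θ+180° are equivalent and the matrix is exactly
symmetric.  Normalization divides by the realized pair count (mask- and
border-aware), not a nominal count, because ROIs are irregular polygons.

Quantization is uniform over the fixed 0–255 intensity range
(``level = grey * Ng // 256``), never min–max per image: per-image
rescaling would destroy the cross-image comparability of level-valued
features such as ``mean`` and ``mean_sum``.

Direction offsets, 0-based (row, column) with row increasing downward::

    0°   -> (0,  d)     horizontal
    45°  -> (-d, d)     right diagonal
    90°  -> (-d, 0)     vertical
    135° -> (-d, -d)    left diagonal

The sign convention is observationally irrelevant under symmetric
accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyRoiError, ValidationError
from .io import GreyFrame
from .roi import RoiMask

__all__ = [
    "ANGLE_OFFSETS",
    "GlcmConfig",
    "QuantizedFrame",
    "CooccurrenceMatrix",
    "quantize",
    "compute_glcm",
    "average_glcms",
]

#: Unit offsets (row, col) per direction in degrees.
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class GlcmConfig:
    """GLCM computation parameters.

    Defaults follow the setup that balances computation time against
    preservation of image information for pleural-line ultrasound:
    16 grey levels, distances 1–4, all four directions, with features
    computed per (d, θ) matrix and then averaged (``averaging="feature"``).
    ``averaging="matrix"`` instead averages the four directional matrices
    at each distance into one direction-invariant matrix before feature
    computation.
    """

    n_levels: int = 16
    distances: tuple[int, ...] = (1, 2, 3, 4)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    averaging: str = "feature"

    def __post_init__(self) -> None:
        if not 2 <= self.n_levels <= 256:
            raise ValidationError(f"n_levels must be in [2, 256], got {self.n_levels}")
        object.__setattr__(self, "distances", tuple(int(d) for d in self.distances))
        object.__setattr__(self, "angles", tuple(int(a) for a in self.angles))
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValidationError("distances must be a non-empty list of counts >= 1")
        if not self.angles:
            raise ValidationError("angles must be non-empty")
        if len(set(self.angles)) != len(self.angles):
            raise ValidationError("duplicate angles")
        for a in self.angles:
            if a not in ANGLE_OFFSETS:
                raise ValidationError(
                    f"angle {a} not in supported set {sorted(ANGLE_OFFSETS)}"
                )
        if self.averaging not in ("feature", "matrix"):
            raise ValidationError('averaging must be "feature" or "matrix"')

    @classmethod
    def from_dict(cls, d: dict) -> "GlcmConfig":
        return cls(
            n_levels=int(d.get("n_levels", 16)),
            distances=tuple(d.get("distances", (1, 2, 3, 4))),
            angles=tuple(d.get("angles", (0, 45, 90, 135))),
            averaging=d.get("averaging", "feature"),
        )


@dataclass(frozen=True)
class QuantizedFrame:
    """A frame reduced to ``n_levels`` grey levels."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.min() < 0 or lv.max() > self.n_levels - 1:
            raise ValidationError("quantized levels out of [0, Ng-1]")
        object.__setattr__(self, "levels", lv.astype(np.intp))


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalized symmetric co-occurrence matrix for one (d, θ).

    ``theta`` is the direction in degrees, or the string ``"averaged"`` for
    a direction-averaged matrix.  ``n_pairs`` counts ordered pairs (each
    geometric pair contributes twice under symmetric accumulation).
    """

    p: np.ndarray
    d: int
    theta: int | str
    n_pairs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValidationError("p must be square")
        if p.min() < 0:
            raise ValidationError("negative probability entry")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"entries must sum to 1, got {p.sum()!r}")
        if not np.array_equal(p, p.T):
            raise ValidationError("p must be exactly symmetric")
        object.__setattr__(self, "p", p)

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


def quantize(frame: GreyFrame | np.ndarray, n_levels: int = 16) -> QuantizedFrame:
    """Quantize 8-bit grey values to ``n_levels`` uniform bins.

    ``level = grey * n_levels // 256`` — monotone non-decreasing, mapping 0
    to level 0 and 255 to level ``n_levels - 1``.
    """
    if not 2 <= n_levels <= 256:
        raise ValidationError(f"n_levels must be in [2, 256], got {n_levels}")
    px = frame.pixels if isinstance(frame, GreyFrame) else np.asarray(frame)
    levels = (px.astype(np.int64) * n_levels) // 256
    return QuantizedFrame(levels=levels, n_levels=n_levels)


def offset_for(theta: int, d: int) -> tuple[int, int]:
    """(row, col) displacement for direction ``theta`` at distance ``d``."""
    try:
        dr, dc = ANGLE_OFFSETS[int(theta)]
    except KeyError:
        raise ValidationError(f"unsupported angle {theta}") from None
    if d < 1:
        raise ValidationError("distance must be >= 1")
    return dr * d, dc * d


def compute_glcm(
    q: QuantizedFrame,
    mask: RoiMask | None,
    d: int,
    theta: int,
) -> CooccurrenceMatrix:
    """Accumulate the symmetric co-occurrence matrix for one (d, θ).

    Every ordered pixel pair ``(a, a + offset)`` with both pixels inside
    the mask adds one count at (i, j) and one at (j, i); probabilities are
    counts divided by the total.  ``mask=None`` means the full frame.

    Raises
    ------
    EmptyRoiError
        If no valid pair exists for this offset.
    """
    levels = q.levels
    h, w = levels.shape
    if mask is not None and mask.shape != levels.shape:
        raise ValidationError(
            f"mask shape {mask.shape} != frame shape {levels.shape}"
        )
    m = mask.mask if mask is not None else np.ones((h, w), dtype=bool)
    dr, dc = offset_for(theta, d)

    # Slice the overlap of the frame with itself shifted by (dr, dc).
    r0a, r1a = max(0, -dr), min(h, h - dr)
    c0a, c1a = max(0, -dc), min(w, w - dc)
    if r0a >= r1a or c0a >= c1a:
        raise EmptyRoiError(f"offset ({dr}, {dc}) exceeds frame size {h}x{w}")
    a = levels[r0a:r1a, c0a:c1a]
    b = levels[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
    valid = m[r0a:r1a, c0a:c1a] & m[r0a + dr : r1a + dr, c0a + dc : c1a + dc]
    i = a[valid]
    j = b[valid]
    if i.size == 0:
        raise EmptyRoiError(
            f"ROI admits no pixel pair for d={d}, theta={theta}"
        )
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    np.add.at(counts, (i, j), 1)
    counts = counts + counts.T  # symmetric accumulation
    total = int(counts.sum())
    return CooccurrenceMatrix(p=counts / total, d=d, theta=int(theta), n_pairs=total)


def average_glcms(matrices: Sequence[CooccurrenceMatrix]) -> CooccurrenceMatrix:
    """Entrywise arithmetic mean of co-occurrence matrices (tagged "averaged")."""
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("cannot average an empty list of matrices")
    ng = matrices[0].n_levels
    if any(m.n_levels != ng for m in matrices):
        raise ValidationError("all matrices must share the same number of levels")
    p = np.mean([m.p for m in matrices], axis=0)
    p = (p + p.T) / 2.0  # guard exact symmetry against float summation order
    d = matrices[0].d if len({m.d for m in matrices}) == 1 else 0
    return CooccurrenceMatrix(
        p=p,
        d=d,
        theta="averaged",
        n_pairs=int(sum(m.n_pairs for m in matrices)),
    )
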