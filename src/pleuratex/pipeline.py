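"""Frame → ROI → GLCM → features → zone → subject orchestration.

One still frame is analysed per scan zone (the clinical workflow selects a
single representative frame from each clip); per-frame features are
averaged across the configured (distance, direction) set, and per-subject
values are the arithmetic mean over that subject's available zones — the
study retains the mean of the 12 standard areas per subject.  Zones whose
correlation is undefined (constant ROI) are excluded from the correlation
mean only.

:class:`GlcmTextureTransformer` exposes the per-frame step as a
scikit-learn transformer so extraction composes with sklearn pipelines and
model selection; :func:`analyze_frame` is its single-sample functional
wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ValidationError
from .features import FEATURE_NAMES, TextureFeatureVector, compute_features
from .glcm import GlcmConfig, average_glcms, compute_glcm, quantize
from .io import GreyFrame
from .roi import RoiMask, RoiShape, rasterize

__all__ = [
    "ZoneRecord",
    "SubjectFeatures",
    "GlcmTextureTransformer",
    "analyze_frame",
    "aggregate_zones",
]


@dataclass(frozen=True)
class ZoneRecord:
    """Features of the representative frame of one (subject, zone)."""

    subject_id: str
    zone_id: str
    features: TextureFeatureVector


@dataclass(frozen=True)
class SubjectFeatures:
    """Per-subject feature means over available zones."""

    subject_id: str
    group: str
    features: TextureFeatureVector
    n_zones: int


def _nanmean_columns(stacked: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN; an all-NaN column yields NaN silently."""
    counts = np.sum(~np.isnan(stacked), axis=0)
    sums = np.nansum(stacked, axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _resolve_mask(
    frame: GreyFrame, roi: RoiShape | RoiMask | None
) -> RoiMask | None:
    if roi is None:
        return None
    if isinstance(roi, RoiShape):
        return rasterize(roi, frame.height, frame.width)
    if isinstance(roi, RoiMask):
        if roi.shape != frame.pixels.shape:
            raise ValidationError(
                f"mask shape {roi.shape} != frame shape {frame.pixels.shape}"
            )
        return roi
    raise ValidationError(f"unsupported ROI type {type(roi).__name__}")


class GlcmTextureTransformer(BaseEstimator, TransformerMixin):
    """Extract GLCM texture features from masked greyscale frames.

    Parameters
    ----------
    n_levels : int, default=16
        Number of quantized grey levels (uniform bins over 0–255).
    distances : tuple of int, default=(1, 2, 3, 4)
        Pixel-pair displacement distances.
    angles : tuple of int, default=(0, 45, 90, 135)
        Displacement directions in degrees.
    averaging : {"feature", "matrix"}, default="feature"
        ``"feature"``: compute the features of each (d, θ) matrix and
        average them (NaN correlations excluded).  ``"matrix"``: average
        the four directional matrices at each distance into one
        direction-invariant matrix first, then compute features and
        average over distances.

    Attributes
    ----------
    config_ : GlcmConfig
        Validated configuration, set by :meth:`fit`.
    n_features_out_ : int
        Number of output feature columns (12).

    Examples
    --------
    >>> import numpy as np
    >>> from pleuratex import GreyFrame, GlcmTextureTransformer
    >>> rng = np.random.default_rng(0)
    >>> frames = [GreyFrame(rng.integers(0, 256, (32, 32))) for _ in range(3)]
    >>> X = GlcmTextureTransformer().fit_transform(frames)
    >>> X.shape
    (3, 12)
    """

    def __init__(
        self,
        n_levels: int = 16,
        distances: tuple[int, ...] = (1, 2, 3, 4),
        angles: tuple[int, ...] = (0, 45, 90, 135),
        averaging: str = "feature",
    ):
        self.n_levels = n_levels
        self.distances = distances
        self.angles = angles
        self.averaging = averaging

    def fit(self, X=None, y=None) -> "GlcmTextureTransformer":
        """Validate the configuration; the transformer learns nothing from data."""
        self.config_ = GlcmConfig(
            n_levels=self.n_levels,
            distances=tuple(self.distances),
            angles=tuple(self.angles),
            averaging=self.averaging,
        )
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        """Extract one feature row per frame.

        Parameters
        ----------
        X : sequence
            Each element is a :class:`GreyFrame` (or 2-D uint8 array), or a
            ``(frame, roi)`` pair where ``roi`` is a :class:`RoiShape`,
            :class:`RoiMask` or ``None`` (full frame).

        Returns
        -------
        ndarray of shape (n_frames, 12)
            Feature rows in :data:`FEATURE_NAMES` order; the correlation
            column is NaN where it is undefined for every matrix.
        """
        if not hasattr(self, "config_"):
            self.fit()
        rows = []
        for item in X:
            if isinstance(item, tuple):
                frame, roi = item
            else:
                frame, roi = item, None
            if not isinstance(frame, GreyFrame):
                frame = GreyFrame(frame)
            rows.append(self._transform_one(frame, roi).as_array())
        return np.array(rows).reshape(len(rows), len(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(FEATURE_NAMES, dtype=object)

    def _transform_one(
        self, frame: GreyFrame, roi: RoiShape | RoiMask | None
    ) -> TextureFeatureVector:
        cfg = self.config_
        mask = _resolve_mask(frame, roi)
        q = quantize(frame, cfg.n_levels)
        if cfg.averaging == "matrix":
            matrices = [
                average_glcms(
                    [compute_glcm(q, mask, d, a) for a in cfg.angles]
                )
                for d in cfg.distances
            ]
        else:
            matrices = [
                compute_glcm(q, mask, d, a)
                for d in cfg.distances
                for a in cfg.angles
            ]
        per_matrix = np.array([compute_features(m).as_array() for m in matrices])
        averaged = _nanmean_columns(per_matrix)
        # the correlation column stays NaN if it was undefined for every matrix
        return TextureFeatureVector(**dict(zip(FEATURE_NAMES, map(float, averaged))))


def analyze_frame(
    frame: GreyFrame,
    roi: RoiShape | RoiMask | None,
    cfg: GlcmConfig | None = None,
) -> TextureFeatureVector:
    """Texture features of one frame restricted to one ROI.

    Equivalent to quantize → rasterize → compute_glcm per (d, θ) →
    compute_features → average, with the averaging mode taken from ``cfg``.
    """
    cfg = cfg or GlcmConfig()
    tr = GlcmTextureTransformer(
        n_levels=cfg.n_levels,
        distances=cfg.distances,
        angles=cfg.angles,
        averaging=cfg.averaging,
    ).fit()
    return tr._transform_one(frame, roi)


def aggregate_zones(
    records: Iterable[ZoneRecord],
    group_map: Mapping[str, str],
) -> list[SubjectFeatures]:
    """Average zone-level features into one row per subject.

    Features are averaged arithmetically over the subject's available
    zones; NaN correlations are excluded from the correlation mean only.
    Several records for the same (subject, zone) — multiple frames from
    one clip — are first collapsed into one zone value by the same mean,
    so each zone weighs equally regardless of its frame count.  The
    result is sorted by subject_id and independent of record order.

    Raises
    ------
    ValidationError
        If a subject is missing from ``group_map``.
    """
    by_zone: dict[tuple[str, str], list[ZoneRecord]] = {}
    for rec in records:
        by_zone.setdefault((rec.subject_id, rec.zone_id), []).append(rec)
    by_subject: dict[str, dict[str, np.ndarray]] = {}
    for (subject_id, zone_id) in sorted(by_zone):
        stacked = np.array(
            [r.features.as_array() for r in by_zone[(subject_id, zone_id)]]
        )
        by_subject.setdefault(subject_id, {})[zone_id] = _nanmean_columns(stacked)
    out = []
    for subject_id in sorted(by_subject):
        if subject_id not in group_map:
            raise ValidationError(f"subject {subject_id!r} missing from group map")
        # fixed zone order makes the mean independent of record order
        zones = by_subject[subject_id]
        stacked = np.array([zones[z] for z in sorted(zones)])
        means = _nanmean_columns(stacked)
        out.append(
            SubjectFeatures(
                subject_id=subject_id,
                group=group_map[subject_id],
                features=TextureFeatureVector(
                    **dict(zip(FEATURE_NAMES, map(float, means)))
                ),
                n_zones=len(zones),
            )
        )
    return out
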