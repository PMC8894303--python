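"""Synthetic inputs: pleural-line texture phantoms and feature simulators.

No patient images are distributed with the package, so two generators make
every downstream stage testable:

**Phantoms.**  :func:`generate_phantom` renders a speckled 8-bit image
emulating the visual texture of the three pleural-line classes:

* ``healthy`` — sparse bright discs on a darker light-grey background
  (bright-on-dark skew, hence positive cluster shade);
* ``cpe`` — sparse dark discs on a lighter background (negative cluster
  shade);
* ``ards`` — large connected patches of uniform dark grey produced by
  thresholding a smoothed Gaussian random field (long-range uniformity,
  hence high correlation).

Speckle is a multiplicative Rayleigh field (unit mean), the minimal
ultrasound speckle surrogate; only sign and ordering claims are asserted on
phantoms, never feature magnitudes.

**Feature simulator.**  :func:`simulate_group_features` draws per-subject
feature values from independent Gaussians parameterized by the published
per-group means and SDs (ARDS n = 8, CPE n = 16) shipped in
``data/ards_cpe_group_stats.yaml``.  Normality is the minimal generative
assumption available from summary statistics; draws falling outside a
feature's theoretical range (e.g. correlation above 1) are clipped and the
clipping fraction is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .features import FEATURE_NAMES
from .io import GreyFrame

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "load_group_stats",
    "simulate_group_features",
    "simulate_feature_table",
]

logger = logging.getLogger(__name__)

PHANTOM_CLASSES = ("healthy", "cpe", "ards")

#: Theoretical bounds used to clip Gaussian feature draws.
_FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "contrast": (0.0, math.inf),
    "cluster_shade": (-math.inf, math.inf),
    "cluster_prominence": (0.0, math.inf),
    "entropy": (0.0, math.inf),
    "variance": (0.0, math.inf),
    "mean": (0.0, math.inf),
    "correlation": (-1.0, 1.0),
    "energy": (0.0, 1.0),
    "homogeneity": (0.0, 1.0),
    "mean_sum": (0.0, math.inf),
    "entropy_sum": (0.0, math.inf),
    "variance_sum": (0.0, math.inf),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one texture phantom.

    ``blob_density`` is the fraction of the frame area covered by discs
    (healthy/cpe); ``smoothing_scale`` is the Gaussian smoothing length of
    the random field whose thresholding yields the ARDS patches;
    ``speckle_strength`` in [0, 1] blends the unit-mean Rayleigh speckle
    field into the scene (0 = none).
    """

    class_label: str
    size: tuple[int, int] = (128, 128)
    seed: int = 0
    background_level: float = 100.0
    feature_level: float = 220.0
    blob_density: float = 0.04
    blob_radius: float = 3.0
    smoothing_scale: float = 8.0
    speckle_strength: float = 0.35

    def __post_init__(self) -> None:
        if self.class_label not in PHANTOM_CLASSES:
            raise ValidationError(
                f"class_label must be one of {PHANTOM_CLASSES}, got {self.class_label!r}"
            )
        for name in ("background_level", "feature_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValidationError(f"{name} must be in [0, 255], got {v}")
        if not 0 < self.blob_density < 1:
            raise ValidationError("blob_density must be in (0, 1)")
        if self.blob_radius >= min(self.size) / 2:
            raise ValidationError("blob_radius must be < min(size)/2")
        if not 0 <= self.speckle_strength <= 1:
            raise ValidationError("speckle_strength must be in [0, 1]")

    @classmethod
    def for_class(cls, class_label: str, seed: int = 0, **overrides) -> "PhantomSpec":
        """Default spec for one of the three phantom classes."""
        defaults = {
            "healthy": dict(background_level=100.0, feature_level=220.0),
            "cpe": dict(background_level=170.0, feature_level=60.0),
            "ards": dict(background_level=150.0, feature_level=70.0),
        }
        if class_label not in defaults:
            raise ValidationError(
                f"class_label must be one of {PHANTOM_CLASSES}, got {class_label!r}"
            )
        kw = {**defaults[class_label], **overrides}
        return cls(class_label=class_label, seed=seed, **kw)

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "size": list(self.size),
            "seed": self.seed,
            "background_level": self.background_level,
            "feature_level": self.feature_level,
            "blob_density": self.blob_density,
            "blob_radius": self.blob_radius,
            "smoothing_scale": self.smoothing_scale,
            "speckle_strength": self.speckle_strength,
        }


def _disc_scene(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    scene = np.full((h, w), spec.background_level, dtype=float)
    blob_area = math.pi * spec.blob_radius**2
    n_blobs = max(1, round(spec.blob_density * h * w / blob_area))
    centers_r = rng.uniform(0, h, n_blobs)
    centers_c = rng.uniform(0, w, n_blobs)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for r0, c0 in zip(centers_r, centers_c):
        scene[(rr - r0) ** 2 + (cc - c0) ** 2 <= spec.blob_radius**2] = (
            spec.feature_level
        )
    return scene


def _patch_scene(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    field = gaussian_filter(
        rng.standard_normal(spec.size), sigma=spec.smoothing_scale, mode="wrap"
    )
    patches = field > np.quantile(field, 0.55)
    scene = np.where(patches, spec.feature_level, spec.background_level)
    return scene, patches


def generate_phantom(spec: PhantomSpec) -> GreyFrame:
    """Render a deterministic 8-bit phantom for the given spec.

    The same spec (including its seed) always produces identical pixels.
    """
    rng = np.random.default_rng(spec.seed)
    # unit-mean Rayleigh speckle: mean of Rayleigh(scale) is scale*sqrt(pi/2)
    speckle = rng.rayleigh(scale=math.sqrt(2 / math.pi), size=spec.size)
    if spec.class_label == "ards":
        scene, patches = _patch_scene(spec, rng)
        strength = np.where(patches, 0.25 * spec.speckle_strength, spec.speckle_strength)
    else:
        scene = _disc_scene(spec, rng)
        strength = spec.speckle_strength
    img = scene * ((1.0 - strength) + strength * speckle)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return GreyFrame(pixels, source_id=f"phantom-{spec.class_label}-seed{spec.seed}")


def load_group_stats(path: str | Path | None = None) -> dict:
    """Load per-group feature means/SDs (defaults to the packaged values).

    Returns
    -------
    dict
        ``{"groups": {group: {"n": int, "features": {name: {"mean", "sd"}}}}}``
    """
    if path is None:
        text = (
            resources.files("pleuratex.data")
            .joinpath("ards_cpe_group_stats.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    params = yaml.safe_load(text)
    if "groups" not in params:
        raise ValidationError("group stats file must contain a 'groups' mapping")
    for group, spec in params["groups"].items():
        for name, ms in spec["features"].items():
            if float(ms["sd"]) <= 0:
                raise ValidationError(f"{group}/{name}: SD must be > 0")
    return params


def simulate_group_features(
    params: dict | None,
    feature: str,
    n_per_group: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-subject values of one feature for every group.

    Parameters
    ----------
    params
        Group statistics as returned by :func:`load_group_stats`
        (``None`` loads the packaged defaults).
    feature
        Feature name present in the params.
    n_per_group
        Draws per group; ``None`` uses each group's own published size.
    seed
        Seed for the random generator.

    Returns
    -------
    scores, labels
        Feature draws and the corresponding group labels.
    """
    params = params or load_group_stats()
    scores, labels = [], []
    rng = np.random.default_rng(seed)
    for group in sorted(params["groups"]):
        spec = params["groups"][group]
        if feature not in spec["features"]:
            raise ValidationError(
                f"unknown feature {feature!r} for group {group}; "
                f"available: {sorted(spec['features'])}"
            )
        ms = spec["features"][feature]
        n = int(spec["n"]) if n_per_group is None else int(n_per_group)
        draws = rng.normal(float(ms["mean"]), float(ms["sd"]), size=n)
        lo, hi = _FEATURE_BOUNDS.get(feature, (-math.inf, math.inf))
        clipped = np.clip(draws, lo, hi)
        n_clip = int(np.sum(clipped != draws))
        if n_clip:
            logger.info(
                "%s/%s: clipped %d/%d draws (%.3f%%) to [%s, %s]",
                group, feature, n_clip, n, 100.0 * n_clip / n, lo, hi,
            )
        scores.append(clipped)
        labels.append(np.full(n, group, dtype=object))
    return np.concatenate(scores), np.concatenate(labels)


def simulate_feature_table(
    params: dict | None = None,
    n_per_group: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-subject feature table (all features, all groups).

    Features are drawn independently per subject; the published summary
    statistics carry no between-feature covariance, so none is imposed.
    """
    params = params or load_group_stats()
    rng = np.random.default_rng(seed)
    frames = []
    for group in sorted(params["groups"]):
        spec = params["groups"][group]
        n = int(spec["n"]) if n_per_group is None else int(n_per_group)
        cols: dict[str, np.ndarray] = {"group": np.full(n, group, dtype=object)}
        for feature in FEATURE_NAMES:
            if feature not in spec["features"]:
                continue
            ms = spec["features"][feature]
            lo, hi = _FEATURE_BOUNDS.get(feature, (-math.inf, math.inf))
            cols[feature] = np.clip(
                rng.normal(float(ms["mean"]), float(ms["sd"]), size=n), lo, hi
            )
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)
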