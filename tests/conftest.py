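"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (explicit Python loops, direct
formula transcription) and independent of the vectorized library code they
check.
"""

from __future__ import annotations

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def glcm_bruteforce(levels: np.ndarray, mask: np.ndarray, ng: int, dr: int, dc: int):
    """Reference GLCM: explicit double loop over all pixel pairs.

    Returns (p, n_pairs) with symmetric accumulation, or (None, 0) when no
    valid pair exists.
    """
    h, w = levels.shape
    counts = np.zeros((ng, ng), dtype=float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = levels[r, c], levels[r2, c2]
                counts[i, j] += 1
                counts[j, i] += 1
    total = counts.sum()
    if total == 0:
        return None, 0
    return counts / total, int(total)


def features_bruteforce(p: np.ndarray) -> dict:
    """Reference feature evaluator: explicit loops over (i, j) and k."""
    ng = p.shape[0]
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum(i * px[i] for i in range(ng))
    mu_y = sum(j * py[j] for j in range(ng))
    sig_x = (sum(i * i * px[i] for i in range(ng)) - mu_x**2) ** 0.5
    sig_y = (sum(j * j * py[j] for j in range(ng)) - mu_y**2) ** 0.5
    p_sum = [0.0] * (2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j] += p[i, j]

    def srt(f):
        return sum(f(i, j) * p[i, j] for i in range(ng) for j in range(ng))

    out = {
        "contrast": srt(lambda i, j: (i - j) ** 2),
        "cluster_shade": srt(lambda i, j: (i + j - mu_x - mu_y) ** 3),
        "cluster_prominence": srt(lambda i, j: (i + j - mu_x - mu_y) ** 4),
        "entropy": -sum(
            p[i, j] * np.log2(p[i, j])
            for i in range(ng)
            for j in range(ng)
            if p[i, j] > 0
        ),
        "variance": srt(lambda i, j: (i - mu_x) ** 2),
        "mean": (mu_x + mu_y) / 2,
        "correlation": (
            srt(lambda i, j: (i - mu_x) * (j - mu_y)) / (sig_x * sig_y)
            if sig_x > 0 and sig_y > 0
            else float("nan")
        ),
        "energy": srt(lambda i, j: p[i, j]),
        "homogeneity": srt(lambda i, j: 1.0 / (1 + (i - j) ** 2)),
        "mean_sum": sum(k * p_sum[k] for k in range(len(p_sum))),
        "entropy_sum": -sum(q * np.log2(q) for q in p_sum if q > 0),
    }
    out["variance_sum"] = sum(
        (k - out["mean_sum"]) ** 2 * p_sum[k] for k in range(len(p_sum))
    )
    return out


def random_symmetric_glcm(rng: np.random.Generator, ng: int) -> np.ndarray:
    """A random normalized exactly-symmetric matrix."""
    a = rng.random((ng, ng))
    a = a + a.T
    return a / a.sum()


def point_in_polygon_oracle(r: float, c: float, verts) -> bool:
    """Scalar even-odd test with boundary counted inside."""
    n = len(verts)
    # boundary
    for k in range(n):
        (r1, c1), (r2, c2) = verts[k], verts[(k + 1) % n]
        cross = (r2 - r1) * (c - c1) - (c2 - c1) * (r - r1)
        if abs(cross) < 1e-9 and min(r1, r2) - 1e-9 <= r <= max(r1, r2) + 1e-9 \
                and min(c1, c2) - 1e-9 <= c <= max(c1, c2) + 1e-9:
            return True
    inside = False
    for k in range(n):
        (r1, c1), (r2, c2) = verts[k], verts[(k + 1) % n]
        if (r1 > r) != (r2 > r):
            c_at = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_at:
                inside = not inside
    return inside


@pytest.fixture
def make_dicom(tmp_path):
    """Factory writing a minimal 8-bit DICOM file from a pixel array."""

    def _make(pixels: np.ndarray, photometric: str = "MONOCHROME2",
              name: str = "clip.dcm"):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        pixels = np.asarray(pixels, dtype=np.uint8)
        multi = pixels.ndim == 3

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.UID(
            "1.2.840.10008.5.1.4.1.1.6.1"  # ultrasound image storage
        )
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Rows = pixels.shape[-2]
        ds.Columns = pixels.shape[-1]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = photometric
        ds.BitsAllocated = 8
        ds.BitsStored = 8
        ds.HighBit = 7
        ds.PixelRepresentation = 0
        if multi:
            ds.NumberOfFrames = pixels.shape[0]
        ds.PixelData = pixels.tobytes()
        path = tmp_path / name
        ds.save_as(path, enforce_file_format=True)
        return path

    return _make
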