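"""Bubble photographs -> radius measurements.

Each time-resolved photograph shows one bubble as a dark region against
bright illumination.  Frames are segmented by 2-class k-means on pixel
intensity (deterministic min/max center initialization), the darker
class is taken as the bubble, the largest connected component is kept
with holes filled, and an equivalent radius is computed from the pixel
area assuming a circular cross-section:

    R_eq = scale * sqrt(area / pi).

A synthetic frame renderer (blurred dark disk plus additive noise)
makes the stage testable without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans

from .inversion import RadiusTimeDataset

__all__ = [
    "Frame",
    "SegmentationResult",
    "segment_frame",
    "build_series",
    "render_synthetic_frame",
    "read_frame",
    "read_manifest",
    "segment_manifest",
]


@dataclass
class Frame:
    """One grayscale photograph with its acquisition metadata."""

    image: np.ndarray  # 2-d float intensities
    scale_um_per_px: float
    delay: float = 0.0  # s
    replicate_id: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("frame image must be 2-d grayscale")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("frame intensities must be finite")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale must be positive")


@dataclass
class SegmentationResult:
    mask: np.ndarray
    area_px: int
    equivalent_radius: float  # m
    no_bubble: bool = False
    touching_border: bool = False
    multiple_components: bool = False


def _equivalent_radius_m(area_px: int, scale_um_per_px: float) -> float:
    return scale_um_per_px * 1e-6 * np.sqrt(area_px / np.pi)


def segment_frame(
    frame: Frame,
    dark_bubble: bool = True,
    min_contrast: float = 0.1,
    fill_holes: bool = True,
) -> SegmentationResult:
    """Segment one frame into bubble/background by 2-class k-means.

    ``dark_bubble`` selects the lower-intensity class as the bubble
    (the instrument geometry: shadow against dye-cell illumination).
    ``min_contrast`` is the minimum class-center separation relative to
    the intensity range below which a no-bubble result (radius 0,
    flagged) is returned instead of a spurious mask.
    """
    img = frame.image
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return SegmentationResult(
            mask=np.zeros(img.shape, dtype=bool),
            area_px=0,
            equivalent_radius=0.0,
            no_bubble=True,
        )
    km = KMeans(
        n_clusters=2, init=np.array([[lo], [hi]]), n_init=1, max_iter=100
    ).fit(img.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    if abs(centers[1] - centers[0]) < min_contrast * (hi - lo):
        return SegmentationResult(
            mask=np.zeros(img.shape, dtype=bool),
            area_px=0,
            equivalent_radius=0.0,
            no_bubble=True,
        )
    bubble_class = int(np.argmin(centers) if dark_bubble else np.argmax(centers))
    mask = (km.labels_ == bubble_class).reshape(img.shape)

    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return SegmentationResult(
            mask=mask, area_px=0, equivalent_radius=0.0, no_bubble=True
        )
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    area = int(mask.sum())
    border = bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    return SegmentationResult(
        mask=mask,
        area_px=area,
        equivalent_radius=_equivalent_radius_m(area, frame.scale_um_per_px),
        touching_border=border,
        multiple_components=n_comp > 1,
    )


def build_series(
    frames: Sequence[Frame],
    exclude_border_touching: bool = True,
    include_no_bubble: bool = False,
    **segment_options,
) -> RadiusTimeDataset:
    """Segment a stack of frames into one radius-time dataset.

    One row per frame (no averaging), sorted by delay then replicate.
    Frames flagged as touching the image border underestimate the
    radius and are excluded by default.
    """
    if len(frames) == 0:
        raise ValueError("no frames given")
    sample_ids = {f.sample_id for f in frames}
    scales = {f.scale_um_per_px for f in frames}
    if len(sample_ids) > 1:
        raise ValueError(f"frames mix sample_ids {sorted(sample_ids)}")
    if len(scales) > 1:
        raise ValueError(f"frames mix pixel scales {sorted(scales)}")
    rows = []
    for f in frames:
        seg = segment_frame(f, **segment_options)
        if seg.no_bubble and not include_no_bubble:
            continue
        if seg.touching_border and exclude_border_touching:
            continue
        rows.append((f.delay, seg.equivalent_radius, f.replicate_id))
    if not rows:
        raise ValueError("no usable frames after segmentation filtering")
    points = (
        pd.DataFrame(rows, columns=["time_s", "radius_m", "replicate_id"])
        .sort_values(["time_s", "replicate_id"], kind="stable")
        .reset_index(drop=True)
    )
    return RadiusTimeDataset(sample_id=next(iter(sample_ids)), points=points)


def render_synthetic_frame(
    radius: float,
    scale_um_per_px: float = 1.0,
    shape: tuple[int, int] = (256, 256),
    blur_px: float = 1.5,
    noise_sigma: float = 0.03,
    center: Optional[tuple[float, float]] = None,
    center_jitter_px: float = 0.0,
    background: float = 0.9,
    foreground: float = 0.1,
    seed: int = 0,
    delay: float = 0.0,
    replicate_id: int = 0,
    sample_id: str = "synthetic",
) -> Frame:
    """Render a dark disk of the given physical radius (m).

    Gaussian edge blur and additive Gaussian intensity noise emulate
    optical blur and camera noise; deterministic for a fixed seed.
    A zero radius renders a blank (background) frame.
    """
    radius_px = radius / (scale_um_per_px * 1e-6)
    ny, nx = shape
    if radius_px >= min(ny, nx) / 2.0:
        raise ValueError(
            f"disk radius {radius_px:.1f} px does not fit a {shape} frame"
        )
    rng = np.random.default_rng(seed)
    if center is None:
        center = (ny / 2.0, nx / 2.0)
    if center_jitter_px > 0:
        center = tuple(np.asarray(center) + center_jitter_px * rng.standard_normal(2))
    yy, xx = np.mgrid[0:ny, 0:nx]
    dist = np.hypot(yy - center[0], xx - center[1])
    if radius_px > 0:
        img = np.where(dist <= radius_px, foreground, background).astype(float)
    else:
        img = np.full(shape, background, dtype=float)
    if blur_px > 0 and radius_px > 0:
        img = ndimage.gaussian_filter(img, blur_px)
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape)
    return Frame(
        image=img,
        scale_um_per_px=scale_um_per_px,
        delay=delay,
        replicate_id=replicate_id,
        sample_id=sample_id,
    )


def read_frame(
    path,
    scale_um_per_px: float,
    delay: float = 0.0,
    replicate_id: int = 0,
    sample_id: str = "",
) -> Frame:
    """Load a single-frame TIFF or PNG as a grayscale Frame."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse color channels
        img = img.mean(axis=-1)
    return Frame(
        image=img,
        scale_um_per_px=scale_um_per_px,
        delay=delay,
        replicate_id=replicate_id,
        sample_id=sample_id,
    )


_MANIFEST_COLUMNS = ("path", "delay_us", "replicate_id", "sample_id", "um_per_px")


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, comment="#")
    missing = set(_MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    return manifest


def segment_manifest(manifest_path, **build_options) -> RadiusTimeDataset:
    """Drive build_series from a manifest file (paths relative to the
    manifest's directory)."""
    manifest = read_manifest(manifest_path)
    root = Path(manifest_path).parent
    frames = [
        read_frame(
            root / row["path"],
            scale_um_per_px=float(row["um_per_px"]),
            delay=float(row["delay_us"]) * 1e-6,
            replicate_id=int(row["replicate_id"]),
            sample_id=str(row["sample_id"]),
        )
        for _, row in manifest.iterrows()
    ]
    return build_series(frames, **build_options)
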