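"""ROI detection and import.

Regions of interest (usually single cell bodies) are stored as lists of
linear row-major pixel indices over the frame grid — the same
connected-components region structure common in image-processing
toolboxes, so segmentations produced elsewhere drop straight in.

Two detection pipelines are provided.  ``find_cells_g`` seeks intensity
peaks in channel 1, suited to indicators that brightly label somata or
nuclei; ``find_cells_gr`` first subtracts channel 2 from channel 1,
suppressing structures (vessels, neuropil counterstains such as
sulforhodamine) present in both channels.  Both share the same operator
chain: mean projection of processed frames, Gaussian smoothing, robust
thresholding in MAD-based s.d. units above the median, greedy
non-maximum suppression with a minimum peak separation, and a disc ROI
stamped at each accepted peak.

ImageJ ``.roi`` files (and ``.zip`` archives of them) can be imported;
rectangle, oval, polygon and freehand types are rasterized with the
pixel-center-inside rule.
"""

from __future__ import annotations

import io
import json
import struct
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiSet",
    "DetectConfig",
    "RoiFormatError",
    "find_cells_g",
    "find_cells_gr",
    "import_imagej",
    "rasterize_polygon",
    "rasterize_ellipse",
]

# ImageJ .roi type codes
_IJ_POLYGON = 0
_IJ_RECT = 1
_IJ_OVAL = 2
_IJ_FREEHAND = 7
_IJ_TYPE_NAMES = {
    0: "polygon", 1: "rectangle", 2: "oval", 3: "line", 4: "freeline",
    5: "polyline", 6: "noroi", 7: "freehand", 8: "traced", 9: "angle",
    10: "point",
}


class RoiFormatError(ValueError):
    """Corrupt or unrecognized ImageJ ROI data."""


@dataclass
class RoiSet:
    """Connected regions over a fixed frame grid.

    ``regions[k]`` is an array of unique linear (row-major) pixel indices;
    regions are non-empty and all indices lie inside ``image_dims``.
    """

    image_dims: tuple[int, int]
    regions: list = field(default_factory=list)
    labels: list | None = None

    def __post_init__(self) -> None:
        nr, nc = self.image_dims
        cleaned = []
        for k, reg in enumerate(self.regions):
            reg = np.unique(np.asarray(reg, dtype=np.intp))
            if reg.size == 0:
                raise ValueError(f"region {k} is empty")
            if reg.min() < 0 or reg.max() >= nr * nc:
                raise ValueError(f"region {k} has indices outside {nr} x {nc}")
            cleaned.append(reg)
        self.regions = cleaned

    def __len__(self) -> int:
        return len(self.regions)

    def mask(self, k: int) -> np.ndarray:
        m = np.zeros(self.image_dims, dtype=bool)
        m.ravel()[self.regions[k]] = True
        return m

    def centroids(self) -> np.ndarray:
        """(n_regions, 2) array of (row, col) centroids."""
        out = np.empty((len(self.regions), 2))
        for k, reg in enumerate(self.regions):
            r, c = np.unravel_index(reg, self.image_dims)
            out[k] = (r.mean(), c.mean())
        return out

    def to_json(self, path: str) -> None:
        doc = {
            "image_dims": list(self.image_dims),
            "regions": [reg.tolist() for reg in self.regions],
        }
        if self.labels is not None:
            doc["labels"] = list(self.labels)
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str) -> "RoiSet":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            tuple(doc["image_dims"]), doc["regions"], doc.get("labels")
        )


@dataclass
class DetectConfig:
    """Parameters of the peak-based cell detectors.

    Defaults suit 128 x 128 frames with ~6 px cell radii: smooth at the
    scale of a soma, require peaks 4 robust s.d. above the image median,
    and keep peaks at least one cell diameter apart.
    """

    smooth_sigma: float = 2.0
    cell_radius: float = 6.0
    min_separation: float | None = None  # default 2 * cell_radius
    threshold_z: float = 4.0

    def __post_init__(self) -> None:
        if self.min_separation is None:
            self.min_separation = 2.0 * self.cell_radius
        if min(self.smooth_sigma, self.cell_radius, self.min_separation,
               self.threshold_z) <= 0:
            raise ValueError("all detection parameters must be > 0")


def _disc_indices(center: tuple[float, float], radius: float,
                  dims: tuple[int, int]) -> np.ndarray:
    cy, cx = center
    nr, nc = dims
    r0, r1 = max(0, int(np.floor(cy - radius))), min(nr, int(np.ceil(cy + radius)) + 1)
    c0, c1 = max(0, int(np.floor(cx - radius))), min(nc, int(np.ceil(cx + radius)) + 1)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    inside = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    return (rr[inside] * nc + cc[inside]).astype(np.intp)


def detect_peaks_image(image: np.ndarray, cfg: DetectConfig) -> RoiSet:
    """Run the smooth / threshold / NMS / disc chain on a detection image."""
    img = np.asarray(image, dtype=float)
    img = np.where(np.isfinite(img), img, np.nanmedian(img))
    sm = ndimage.gaussian_filter(img, cfg.smooth_sigma)
    med = np.median(sm)
    mad = np.median(np.abs(sm - med))
    robust_sd = 1.4826 * mad
    thresh = med + cfg.threshold_z * robust_sd
    local_max = sm == ndimage.maximum_filter(sm, size=3, mode="nearest")
    cand = np.argwhere(local_max & (sm > thresh))
    if robust_sd == 0:
        # flat background: demand strictly positive prominence too
        cand = cand[sm[cand[:, 0], cand[:, 1]] > med] if cand.size else cand
    order = np.argsort(sm[cand[:, 0], cand[:, 1]])[::-1] if cand.size else []
    accepted: list[np.ndarray] = []
    for i in order:
        p = cand[i].astype(float)
        if all(np.hypot(*(p - q)) >= cfg.min_separation for q in accepted):
            accepted.append(p)
    regions = [
        _disc_indices((p[0], p[1]), cfg.cell_radius, img.shape) for p in accepted
    ]
    return RoiSet(img.shape, regions)


def _mean_projection(stack, channel: int, frame_range: Sequence[int],
                     chunk: int = 128) -> np.ndarray:
    frames = np.asarray(frame_range, dtype=int)
    if frames.size == 0:
        raise ValueError("frame_range is empty")
    acc = np.zeros((stack.shape[0], stack.shape[1]))
    count = np.zeros_like(acc)
    for lo in range(0, frames.size, chunk):
        block = stack.get_frames(frames[lo:lo + chunk], channel=channel,
                                 processed=True)
        finite = np.isfinite(block)
        acc += np.where(finite, block, 0.0).sum(axis=2)
        count += finite.sum(axis=2)
    with np.errstate(invalid="ignore"):
        return acc / count


def find_cells_g(stack, cfg: DetectConfig | None = None,
                 frame_range: Sequence[int] | None = None) -> RoiSet:
    """Detect cells as intensity peaks in channel 1.

    The detection image is the mean of the processed (re-registered,
    black-subtracted) frames in ``frame_range`` (default: whole stack).
    """
    cfg = cfg if cfg is not None else DetectConfig()
    if frame_range is None:
        frame_range = np.arange(stack.n_frames)
    return detect_peaks_image(_mean_projection(stack, 0, frame_range), cfg)


def find_cells_gr(stack, cfg: DetectConfig | None = None,
                  frame_range: Sequence[int] | None = None) -> RoiSet:
    """Detect cells on the channel-1 minus channel-2 difference image.

    Structures present in both channels (vessels, a neuron-excluding
    counterstain) cancel; cell-specific channel-1 signal survives.
    """
    if stack.n_channels < 2:
        raise ValueError("find_cells_gr requires a 2-channel stack")
    cfg = cfg if cfg is not None else DetectConfig()
    if frame_range is None:
        frame_range = np.arange(stack.n_frames)
    diff = (_mean_projection(stack, 0, frame_range)
            - _mean_projection(stack, 1, frame_range))
    return detect_peaks_image(diff, cfg)


# ------------------------------------------------------------- rasterization


def rasterize_polygon(xs: np.ndarray, ys: np.ndarray,
                      dims: tuple[int, int]) -> np.ndarray:
    """Linear indices of pixels whose centers fall inside the polygon.

    Vertices are in ImageJ coordinates (origin at the top-left pixel
    corner, x = column, y = row); pixel (r, c) has center (c+0.5, r+0.5).
    Even-odd (ray casting) rule.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    nr, nc = dims
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    px = cc.ravel() + 0.5
    py = rr.ravel() + 0.5
    inside = np.zeros(px.size, dtype=bool)
    n = len(xs)
    j = n - 1
    for i in range(n):
        xi, yi, xj, yj = xs[i], ys[i], xs[j], ys[j]
        crosses = (yi > py) != (yj > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = (xj - xi) * (py - yi) / (yj - yi) + xi
        inside ^= crosses & (px < x_at)
        j = i
    return np.flatnonzero(inside).astype(np.intp)


def rasterize_ellipse(top: float, left: float, bottom: float, right: float,
                      dims: tuple[int, int]) -> np.ndarray:
    """Linear indices of pixel centers inside the axis-aligned ellipse
    inscribed in the bounding box (ImageJ oval semantics)."""
    nr, nc = dims
    cy, cx = (top + bottom) / 2.0, (left + right) / 2.0
    ay, ax = (bottom - top) / 2.0, (right - left) / 2.0
    if ay <= 0 or ax <= 0:
        return np.empty(0, dtype=np.intp)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    py = rr + 0.5
    px = cc + 0.5
    inside = ((py - cy) / ay) ** 2 + ((px - cx) / ax) ** 2 <= 1.0
    return np.flatnonzero(inside.ravel()).astype(np.intp)


# ------------------------------------------------------------ ImageJ import


def _parse_roi_bytes(data: bytes, dims: tuple[int, int],
                     name: str = "<roi>") -> np.ndarray | None:
    """Decode one .roi payload to pixel indices; None for skipped types."""
    if len(data) < 64 or data[:4] != b"Iout":
        raise RoiFormatError(f"{name}: not an ImageJ ROI (bad magic bytes)")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n_coords = struct.unpack(">h", data[16:18])[0]
    nr, nc = dims
    if roi_type == _IJ_RECT:
        rr, cc = np.meshgrid(
            np.arange(max(0, top), min(nr, bottom)),
            np.arange(max(0, left), min(nc, right)),
            indexing="ij",
        )
        return (rr.ravel() * nc + cc.ravel()).astype(np.intp)
    if roi_type == _IJ_OVAL:
        return rasterize_ellipse(top, left, bottom, right, dims)
    if roi_type in (_IJ_POLYGON, _IJ_FREEHAND):
        end = 64 + 4 * n_coords
        if len(data) < end:
            raise RoiFormatError(f"{name}: truncated coordinate list")
        rel = np.frombuffer(data[64:end], dtype=">i2")
        xs = rel[:n_coords].astype(float) + left
        ys = rel[n_coords:2 * n_coords].astype(float) + top
        return rasterize_polygon(xs, ys, dims)
    warnings.warn(
        f"{name}: unsupported ROI type "
        f"{_IJ_TYPE_NAMES.get(roi_type, roi_type)!r}; skipped",
        RuntimeWarning,
        stacklevel=3,
    )
    return None


def import_imagej(path: str, image_dims: tuple[int, int]) -> RoiSet:
    """Import ImageJ ROIs from a ``.roi`` file or a ``.zip`` of them.

    Rectangle, oval, polygon and freehand ROIs are rasterized onto the
    given frame grid (pixel included iff its center lies inside the
    shape); unsupported types are skipped with a warning.
    """
    regions, labels = [], []
    if str(path).lower().endswith(".zip"):
        with zipfile.ZipFile(path) as zf:
            for member in sorted(zf.namelist()):
                if not member.lower().endswith(".roi"):
                    continue
                idx = _parse_roi_bytes(zf.read(member), image_dims, member)
                if idx is not None and idx.size:
                    regions.append(idx)
                    labels.append(member[:-4])
    else:
        with open(path, "rb") as fh:
            idx = _parse_roi_bytes(fh.read(), image_dims, str(path))
        if idx is not None and idx.size:
            regions.append(idx)
            labels.append(str(path))
    return RoiSet(image_dims, regions, labels or None)
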