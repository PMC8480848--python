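"""Otolith outline extraction from backlit silhouette images.

An otolith photographed against strong backlighting is a solid dark shape on a
light background.  The functions here binarize such an image, keep the single
largest connected blob (filled), trace its boundary at sub-pixel resolution and
express it as a closed polygon in millimetres, together with the maximum Feret
diameter (the longest distance between any two boundary points) that downstream
shape normalization uses as the size measure.

Coordinate convention: image (row, col) maps to Cartesian (x, y) with the
origin at the lower-left pixel corner, so outlines live in a right-handed
frame and are stored counter-clockwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu


class ExtractionError(ValueError):
    """Raised when an image contains no usable otolith silhouette."""


@dataclass
class Outline:
    """Closed planar polygon (first point not repeated; closure is implied).

    Parameters
    ----------
    points
        ``(n, 2)`` array of ``(x, y)`` vertices in mm, counter-clockwise.
    side
        Which otolith of the pair the outline came from (``left`` outlines
        are expected to have been mirrored before description).
    """

    points: np.ndarray
    side: str = "unknown"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("outline needs an (n, 2) array with n >= 3")
        # canonical counter-clockwise orientation
        if _signed_area(pts) < 0:
            pts = pts[::-1]
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        """Area centroid of the polygon (mm)."""
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        a = cross.sum() / 2.0
        if abs(a) < 1e-300:
            return self.points.mean(axis=0)
        cx = ((x + xn) * cross).sum() / (6.0 * a)
        cy = ((y + yn) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    @property
    def area(self) -> float:
        return abs(_signed_area(self.points))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def feret(self) -> float:
        return feret_diameter(self.points)

    def mirrored(self) -> "Outline":
        """Reflection about the vertical axis (used for left otoliths)."""
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        return Outline(pts[::-1], side=self.side)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x_mm,y_mm",
                   comments="")

    @classmethod
    def from_csv(cls, path, side: str = "unknown") -> "Outline":
        pts = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(pts, side=side)


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return float((x * np.roll(y, -1) - np.roll(x, -1) * y).sum() / 2.0)


def binarize(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Segment the dark otolith from a light background.

    Pixels at or below ``threshold`` (global Otsu when not supplied) are
    foreground.  Only the largest connected foreground component is kept, and
    its holes are filled: a backlit otolith is a solid silhouette, so interior
    light spots are imaging artefacts.

    Returns a boolean mask (True = otolith).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if threshold is None:
        if img.min() == img.max():
            raise ExtractionError("image is uniform; no foreground to segment")
        threshold = threshold_otsu(img)
    mask = img <= threshold
    if not mask.any():
        raise ExtractionError("no foreground pixels below threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def flip_if_left(image: np.ndarray, side: str) -> np.ndarray:
    """Mirror left-otolith images horizontally so all shapes share chirality."""
    if side == "left":
        return image[:, ::-1]
    if side == "right":
        return image
    raise ValueError(f"otolith side must be 'left' or 'right', got {side!r}")


def trace_outline(binary: np.ndarray, pixels_per_mm: float,
                  side: str = "unknown") -> Outline:
    """Trace the boundary of a single filled component as an Outline in mm.

    Uses sub-pixel marching-squares contouring at the 0.5 level, so the traced
    boundary runs midway between foreground and background pixel centres.
    A component touching the image border is rejected: a truncated silhouette
    would corrupt every downstream descriptor.
    """
    mask = np.asarray(binary).astype(bool)
    if not mask.any():
        raise ExtractionError("empty binary image")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ExtractionError("foreground touches the image border (truncated shape)")
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ExtractionError("no contour found")
    contour = max(contours, key=len)
    if len(contours) > 1:
        warnings.warn("multiple contours found; tracing the longest")
    if len(contour) < 32:
        raise ExtractionError("traced contour has fewer than 32 points")
    # drop duplicated closing vertex, convert (row, col) -> (x, y) mm
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    h = mask.shape[0]
    pts = np.empty((len(contour), 2))
    pts[:, 0] = contour[:, 1] / pixels_per_mm
    pts[:, 1] = (h - 1 - contour[:, 0]) / pixels_per_mm
    return Outline(pts, side=side)


def _max_pairwise(pts: np.ndarray) -> tuple[float, int, int]:
    """Exact maximum squared pairwise distance, chunked to bound memory.

    Returns (max squared distance, i, j) with the lexicographically smallest
    maximizing index pair, i < j.
    """
    n = len(pts)
    best = (-1.0, 0, 0)
    chunk = max(1, 2 ** 22 // max(n, 1))
    sq = (pts ** 2).sum(axis=1)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (pts[lo:hi] @ pts.T)
        k = int(np.argmax(d2))
        i, j = divmod(k, n)
        val = float(d2[i, j])
        if val > best[0] + 1e-15:
            ii, jj = lo + i, j
            if ii > jj:
                ii, jj = jj, ii
            best = (val, ii, jj)
    return best


def feret_diameter(points: np.ndarray) -> float:
    """Maximum Feret diameter: the largest pairwise distance between outline
    points.

    Accelerated through the convex hull (the diameter of a point set is
    attained between hull vertices), which makes it exactly equal to the
    brute-force O(n^2) maximum.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points for a Feret diameter")
    if pts.shape[0] > 4:
        try:
            hull = ConvexHull(pts)
            pts = pts[np.sort(hull.vertices)]
        except Exception:  # degenerate (collinear) input: fall through
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1) \
        if len(pts) <= 2048 else None
    if d2 is not None:
        return float(np.sqrt(d2.max()))
    return float(np.sqrt(_max_pairwise(pts)[0]))


def read_image(path) -> np.ndarray:
    """Load a PNG/TIFF otolith photograph as a single-channel 8-bit array.

    Colour images are converted with the usual luminance weights.
    """
    import imageio.v3 as iio
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.dtype != np.uint8:
        lo, hi = float(img.min()), float(img.max())
        img = np.zeros_like(img, dtype=np.uint8) if hi == lo else \
            np.round(255.0 * (img - lo) / (hi - lo)).astype(np.uint8)
    return img


def write_outline(outline: Outline, prefix) -> None:
    """Point list as ``<prefix>.csv`` plus a JSON sidecar with centroid,
    Feret diameter and otolith side."""
    import json
    from pathlib import Path
    prefix = Path(prefix)
    outline.to_csv(prefix.with_suffix(".csv"))
    meta = {"centroid_mm": list(map(float, outline.centroid)),
            "feret_mm": float(outline.feret), "side": outline.side,
            "n_points": outline.n_points}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_outline(prefix) -> Outline:
    import json
    from pathlib import Path
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return Outline.from_csv(prefix.with_suffix(".csv"), side=meta.get("side", "unknown"))


def feret_endpoints(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The pair of outline points realizing the Feret diameter.

    Deterministic: among maximizing pairs the lexicographically smallest index
    pair is returned, ordered so the first endpoint has the smaller index.
    """
    pts = np.asarray(points, dtype=float)
    idx = np.arange(len(pts))
    if len(pts) > 4:
        try:
            hull = ConvexHull(pts)
            idx = np.sort(hull.vertices)
        except Exception:
            pass
    sub = pts[idx]
    if len(sub) <= 2048:
        d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
        i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    else:
        _, i, j = _max_pairwise(sub)
    i, j = int(idx[i]), int(idx[j])
    if i > j:
        i, j = j, i
    return pts[i].copy(), pts[j].copy()
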