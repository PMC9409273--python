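"""Proximity and colocalization statistics for two-channel patch images.

Workflow mirrored from the imaging analysis: threshold each channel at a
fraction of its within-cell maximum, extract connected-component patches
with areas/centroids/equivalent diameters, measure nearest-centroid
distances with an isolation cutoff (twice the mean reference-patch
diameter), compare against a null of uniformly re-positioned circular
masks, and compute Pearson and Manders M1/M2 coefficients per ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "ChannelImage",
    "Patch",
    "ProximityResult",
    "ColocResult",
    "RandomMaskNull",
    "threshold_mask",
    "label_patches",
    "nearest_centroid_distances",
    "isolation_cutoff",
    "random_mask_null",
    "pearson_coefficient",
    "manders_coefficients",
    "distance_histogram",
]


@dataclass
class ChannelImage:
    """Single-channel 2D intensity image with physical pixel size."""

    data: np.ndarray
    pixel_size: float              # µm / px
    channel: str = ""              # e.g. "red" (receptor) or "green" (marker)
    cell_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
            if self.cell_mask.shape != self.data.shape:
                raise ValueError("cell mask shape mismatch")


@dataclass(frozen=True)
class Patch:
    """Connected pixel patch with physical measurements."""

    pixels: tuple                   # (rows, cols) index arrays
    area: float                     # µm^2
    centroid: tuple[float, float]   # (x, y) µm
    equivalent_diameter: float      # µm
    channel: str = ""
    patch_id: int = -1

    @classmethod
    def from_pixels(cls, rows: np.ndarray, cols: np.ndarray, pixel_size: float,
                    channel: str = "", patch_id: int = -1) -> "Patch":
        area = rows.size * pixel_size**2
        # pixel-center convention: pixel (r, c) is centered at (c+0.5, r+0.5)
        cx = (float(cols.mean()) + 0.5) * pixel_size
        cy = (float(rows.mean()) + 0.5) * pixel_size
        return cls((rows, cols), area, (cx, cy),
                   2.0 * math.sqrt(area / math.pi), channel, patch_id)

    @classmethod
    def from_diameter(cls, diameter: float, center=(0.0, 0.0),
                      channel: str = "") -> "Patch":
        """Synthetic patch carrying a prescribed equivalent diameter."""
        area = math.pi * (diameter / 2.0) ** 2
        return cls((np.array([]), np.array([])), area,
                   (float(center[0]), float(center[1])), float(diameter),
                   channel)


@dataclass
class ProximityResult:
    """Nearest-centroid distances of reference patches to query patches."""

    distances: np.ndarray           # µm, one per reference patch (NaN if no query)
    nearest_query: np.ndarray       # index into the query list, -1 if none
    isolated: np.ndarray            # bool, distance > cutoff (or no query)
    cutoff: float                   # µm

    @property
    def retained(self) -> np.ndarray:
        return self.distances[~self.isolated]

    @property
    def n_retained(self) -> int:
        return int((~self.isolated).sum())

    @property
    def n_isolated(self) -> int:
        return int(self.isolated.sum())

    @property
    def mean_distance(self) -> float:
        r = self.retained
        return float(r.mean()) if r.size else float("nan")

    @property
    def sem_distance(self) -> float:
        r = self.retained
        if r.size < 2:
            return float("nan")
        return float(r.std(ddof=1) / math.sqrt(r.size))


@dataclass
class ColocResult:
    """Pearson and Manders coefficients for one ROI (NaN when undefined)."""

    pearson: float
    m1: float
    m2: float
    roi_id: int = -1


@dataclass
class RandomMaskNull:
    """Uniformly re-positioned circular masks inside the cell region."""

    centers: np.ndarray             # (n, 2) µm, (x, y)
    diameter: float                 # µm
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.centers)

    def as_patches(self) -> list[Patch]:
        return [
            Patch((np.array([]), np.array([])),
                  math.pi * (self.diameter / 2) ** 2,
                  (float(x), float(y)), self.diameter, "null", i)
            for i, (x, y) in enumerate(self.centers)
        ]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def threshold_mask(img: ChannelImage, fraction: float = 0.5,
                   reference: str = "max") -> np.ndarray:
    """Binary mask of pixels >= ``fraction`` of the channel's reference level.

    ``reference="max"`` uses the maximum intensity inside the cell mask (the
    default reading of a "50% threshold"); ``reference="range"`` uses
    min + fraction * (max - min) inside the cell mask instead.
    """
    if img.data.size == 0:
        raise ValueError("empty image")
    region = img.cell_mask if img.cell_mask is not None else np.ones_like(
        img.data, dtype=bool)
    vals = img.data[region]
    if vals.size == 0:
        raise ValueError("cell mask excludes every pixel")
    hi = float(vals.max())
    if hi == 0.0:
        return np.zeros_like(img.data, dtype=bool)
    if reference == "max":
        level = fraction * hi
    elif reference == "range":
        lo = float(vals.min())
        level = lo + fraction * (hi - lo)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return (img.data >= level) & region


def label_patches(mask: np.ndarray, pixel_size: float, min_pixels: int = 4,
                  channel: str = "") -> list[Patch]:
    """Extract 8-connected patches of at least ``min_pixels`` pixels."""
    mask = np.asarray(mask, dtype=bool)
    lab = sk_label(mask, connectivity=2)
    out = []
    for prop in regionprops(lab):
        if prop.num_pixels < min_pixels:
            continue
        rows, cols = prop.coords[:, 0], prop.coords[:, 1]
        out.append(Patch.from_pixels(rows, cols, pixel_size, channel,
                                     patch_id=len(out)))
    return out


def isolation_cutoff(reference_patches: list[Patch],
                     override: float | None = None,
                     convention: str = "mean_diameter") -> float:
    """Twice the mean equivalent diameter of the reference patches (µm).

    ``convention="mean_diameter"`` averages per-patch equivalent diameters;
    ``convention="diameter_of_mean_area"`` converts the mean area instead.
    ``override`` short-circuits with a fixed cutoff.
    """
    if override is not None:
        if override <= 0:
            raise ValueError("override cutoff must be positive")
        return float(override)
    if not reference_patches:
        raise ValueError("need at least one reference patch")
    if convention == "mean_diameter":
        mean_d = float(np.mean([p.equivalent_diameter for p in reference_patches]))
    elif convention == "diameter_of_mean_area":
        mean_a = float(np.mean([p.area for p in reference_patches]))
        mean_d = 2.0 * math.sqrt(mean_a / math.pi)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return 2.0 * mean_d


def nearest_centroid_distances(ref: list[Patch], query: list[Patch],
                               cutoff: float) -> ProximityResult:
    """Per reference patch, XY distance to the nearest query centroid.

    Distances above ``cutoff`` are flagged isolated and excluded from the
    summary mean; with an empty query list every reference is isolated.
    """
    if not ref:
        raise ValueError("need at least one reference patch")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(ref)
    if not query:
        return ProximityResult(np.full(n, np.nan), np.full(n, -1),
                               np.ones(n, dtype=bool), cutoff)
    rpts = np.array([p.centroid for p in ref])
    qpts = np.array([p.centroid for p in query])
    tree = cKDTree(qpts)
    d, idx = tree.query(rpts)
    isolated = d > cutoff
    return ProximityResult(d, idx, isolated, cutoff)


def random_mask_null(cell_mask: np.ndarray, n: int, pixel_size: float,
                     diameter: float = 0.397, seed=None,
                     max_iter: int = 10_000_000) -> RandomMaskNull:
    """Draw ``n`` circular-mask centers uniformly over the cell region.

    Centers are continuous coordinates: a uniformly chosen cell-mask pixel
    plus uniform sub-pixel jitter.  Masks may overlap each other; only the
    centroids matter for the distance analysis.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if n < 1:
        raise ValueError("n must be >= 1")
    pix = np.flatnonzero(cell_mask)
    if pix.size == 0:
        raise ValueError("cell mask is empty")
    if n > max_iter:
        raise ValueError("n exceeds the iteration cap")
    rng = np.random.default_rng(seed)
    chosen = rng.integers(0, pix.size, n)
    rows, cols = np.unravel_index(pix[chosen], cell_mask.shape)
    x = (cols + rng.random(n)) * pixel_size
    y = (rows + rng.random(n)) * pixel_size
    return RandomMaskNull(np.column_stack([x, y]), diameter, seed)


def pearson_coefficient(red_roi: np.ndarray, green_roi: np.ndarray) -> float:
    """Pixel-intensity Pearson correlation over an ROI (NaN if constant)."""
    r = np.asarray(red_roi, dtype=float).ravel()
    g = np.asarray(green_roi, dtype=float).ravel()
    if r.shape != g.shape:
        raise ValueError("ROIs must have the same shape")
    if r.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(r) == 0 or np.ptp(g) == 0:
        return float("nan")
    rc = r - r.mean()
    gc = g - g.mean()
    return float((rc * gc).sum() / math.sqrt((rc**2).sum() * (gc**2).sum()))


def manders_coefficients(red_roi: np.ndarray, green_roi: np.ndarray,
                         red_mask: np.ndarray, green_mask: np.ndarray,
                         ) -> tuple[float, float]:
    """Manders M1/M2 overlap coefficients.

    M1: fraction of red intensity (over the red mask) lying in green-mask
    pixels; M2 symmetric.  NaN when the corresponding denominator is zero.
    """
    r = np.asarray(red_roi, dtype=float)
    g = np.asarray(green_roi, dtype=float)
    rm = np.asarray(red_mask, dtype=bool)
    gm = np.asarray(green_mask, dtype=bool)
    if not (r.shape == g.shape == rm.shape == gm.shape):
        raise ValueError("ROIs and masks must share a shape")
    r_tot = r[rm].sum()
    g_tot = g[gm].sum()
    m1 = float(r[rm & gm].sum() / r_tot) if r_tot > 0 else float("nan")
    m2 = float(g[gm & rm].sum() / g_tot) if g_tot > 0 else float("nan")
    return m1, m2


def distance_histogram(results, bin_width: float = 0.05,
                       max_distance: float | None = None):
    """Binned counts of retained distances, bins ``[k*w, (k+1)*w)``.

    ``results`` is a ProximityResult or a list of them; returns a pandas
    DataFrame with bin edges and counts.
    """
    import pandas as pd

    if isinstance(results, ProximityResult):
        results = [results]
    if not results:
        raise ValueError("no results given")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    d = np.concatenate([r.retained for r in results])
    if max_distance is None:
        max_distance = float(d.max()) + bin_width if d.size else bin_width
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "bin_left_um": edges[:-1],
        "bin_right_um": edges[1:],
        "count": counts,
    })
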