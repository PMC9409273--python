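"""Ground-truth-known synthetic inputs.

Two generators: (1) two-channel cortical-plane images — green marker
patches and red receptor patches displaced from them by a controlled 2D
Gaussian, plus unpaired ("isolated") red patches and imaging noise — with
the full ground truth returned next to the image; (2) paired simulator
configurations (random vs. colocalized) sharing channel-placement seeds so
geometry is the only difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .spatial_stats import ChannelImage
from .secretion_sim import SimConfig

__all__ = [
    "ImageScenario",
    "GroundTruth",
    "generate_cell_image",
    "generate_proximity_series",
    "generate_sim_scenarios",
]


@dataclass(frozen=True)
class ImageScenario:
    """Parameters of one synthetic two-channel cell image."""

    size_px: int = 256
    pixel_size: float = 0.07          # µm / px
    cell_radius: float = 7.0          # µm
    n_green: int = 14
    n_red: int = 14
    green_diameter: float = 0.378     # µm, mean
    green_diameter_sd: float = 0.02
    red_diameter: float = 0.397       # µm, mean
    red_diameter_sd: float = 0.02
    sigma: float = 0.2                # µm, green->red displacement scale
    unpaired_fraction: float = 0.0    # fraction of red patches with no partner
    isolation_margin: float = 0.756   # µm, min unpaired-red to green distance
    min_separation: float = 0.9       # µm, same-channel center separation
    psf_sigma: float = 0.0            # µm, Gaussian blur
    noise_sd: float = 0.0             # additive Gaussian noise (intensity units)
    poisson_photons: float = 0.0      # >0 enables Poisson noise at this scale
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_green, self.n_red) < 0 or self.size_px <= 0:
            raise ValueError("counts and size must be non-negative")
        if not 0.0 <= self.unpaired_fraction <= 1.0:
            raise ValueError("unpaired_fraction must lie in [0, 1]")
        if self.cell_radius * 2 >= self.size_px * self.pixel_size:
            raise ValueError("cell does not fit in the image")


@dataclass
class GroundTruth:
    """True patch geometry and pairing behind a synthetic image."""

    green_centers: np.ndarray         # (Ng, 2) µm
    green_diameters: np.ndarray
    red_centers: np.ndarray           # (Nr, 2) µm
    red_diameters: np.ndarray
    pairing: np.ndarray               # (Nr,) index of partner green, -1 if none
    displacements: np.ndarray         # (Nr, 2) µm, NaN rows for unpaired

    @property
    def paired_distance(self) -> np.ndarray:
        ok = self.pairing >= 0
        return np.linalg.norm(self.displacements[ok], axis=1)


def _sample_centers(rng, n, cell_center, max_r, min_sep, existing=None,
                    min_dist_to=None, min_dist=0.0, max_tries=20_000):
    centers = [] if existing is None else list(existing)
    start = len(centers)
    for _ in range(max_tries):
        if len(centers) - start >= n:
            break
        rr = max_r * math.sqrt(rng.random())
        th = 2 * math.pi * rng.random()
        p = (cell_center[0] + rr * math.cos(th), cell_center[1] + rr * math.sin(th))
        if centers and min_sep > 0:
            d = np.linalg.norm(np.asarray(centers) - p, axis=1)
            if d.min() < min_sep:
                continue
        if min_dist_to is not None and len(min_dist_to):
            d = np.linalg.norm(np.asarray(min_dist_to) - p, axis=1)
            if d.min() < min_dist:
                continue
        centers.append(p)
    if len(centers) - start < n:
        raise ValueError("could not place patches: cell too small/crowded")
    return np.asarray(centers[start:])


def _render_disks(img: np.ndarray, centers_um, diameters_um, pixel_size,
                  subsample: int = 4) -> None:
    """Add unit-amplitude disks with sub-pixel coverage anti-aliasing."""
    sub = (np.arange(subsample) + 0.5) / subsample
    ox, oy = np.meshgrid(sub, sub)
    for (cx, cy), d in zip(centers_um, diameters_um):
        r_px = d / 2.0 / pixel_size
        cx_px, cy_px = cx / pixel_size, cy / pixel_size
        x0 = max(0, int(math.floor(cx_px - r_px - 1)))
        x1 = min(img.shape[1], int(math.ceil(cx_px + r_px + 1)))
        y0 = max(0, int(math.floor(cy_px - r_px - 1)))
        y1 = min(img.shape[0], int(math.ceil(cy_px + r_px + 1)))
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = xs[None, :, None, None] + ox[None, None, :, :]
        gy = ys[:, None, None, None] + oy[None, None, :, :]
        inside = (gx - cx_px) ** 2 + (gy - cy_px) ** 2 <= r_px**2
        cov = inside.mean(axis=(2, 3))
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], cov)


def generate_cell_image(
    scenario: ImageScenario,
) -> tuple[ChannelImage, ChannelImage, GroundTruth]:
    """Render one synthetic cell; returns (green, red, ground truth)."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    ps = sc.pixel_size
    extent = sc.size_px * ps
    cc = (extent / 2.0, extent / 2.0)

    # cell mask (disk)
    yy, xx = np.mgrid[0:sc.size_px, 0:sc.size_px]
    cx_px = (xx + 0.5) * ps - cc[0]
    cy_px = (yy + 0.5) * ps - cc[1]
    cell_mask = cx_px**2 + cy_px**2 <= sc.cell_radius**2

    margin = (max(sc.green_diameter, sc.red_diameter) / 2.0
              + 3.0 * max(sc.green_diameter_sd, sc.red_diameter_sd))
    max_r = sc.cell_radius - margin
    if max_r <= 0:
        raise ValueError("cell radius too small for the patch sizes")

    green_centers = _sample_centers(rng, sc.n_green, cc, max_r,
                                    sc.min_separation)
    green_diams = np.maximum(
        rng.normal(sc.green_diameter, sc.green_diameter_sd, sc.n_green),
        2.0 * ps)

    n_unpaired = int(round(sc.n_red * sc.unpaired_fraction))
    n_paired = sc.n_red - n_unpaired
    if n_paired > sc.n_green:
        raise ValueError("more paired red patches than green partners")
    partners = rng.choice(sc.n_green, size=n_paired, replace=False)

    red_centers = np.empty((sc.n_red, 2))
    pairing = np.full(sc.n_red, -1, dtype=np.int64)
    displacements = np.full((sc.n_red, 2), np.nan)
    for i, j in enumerate(partners):
        for _ in range(10_000):
            dxy = rng.normal(0.0, sc.sigma, 2) if sc.sigma > 0 else np.zeros(2)
            p = green_centers[j] + dxy
            if (p[0] - cc[0]) ** 2 + (p[1] - cc[1]) ** 2 <= max_r**2:
                break
        else:
            raise ValueError("could not place a displaced red patch")
        red_centers[i] = p
        pairing[i] = j
        displacements[i] = dxy
    if n_unpaired:
        red_centers[n_paired:] = _sample_centers(
            rng, n_unpaired, cc, max_r, sc.min_separation,
            min_dist_to=green_centers, min_dist=sc.isolation_margin)
    red_diams = np.maximum(
        rng.normal(sc.red_diameter, sc.red_diameter_sd, sc.n_red), 2.0 * ps)

    green = np.zeros((sc.size_px, sc.size_px))
    red = np.zeros((sc.size_px, sc.size_px))
    _render_disks(green, green_centers, green_diams, ps)
    _render_disks(red, red_centers, red_diams, ps)

    if sc.psf_sigma > 0:
        s = sc.psf_sigma / ps
        green = gaussian_filter(green, s)
        red = gaussian_filter(red, s)
    if sc.poisson_photons > 0:
        green = rng.poisson(green * sc.poisson_photons) / sc.poisson_photons
        red = rng.poisson(red * sc.poisson_photons) / sc.poisson_photons
    if sc.noise_sd > 0:
        green = green + rng.normal(0.0, sc.noise_sd, green.shape)
        red = red + rng.normal(0.0, sc.noise_sd, red.shape)
    green = np.clip(green, 0.0, None)
    red = np.clip(red, 0.0, None)

    gt = GroundTruth(green_centers, green_diams, red_centers, red_diams,
                     pairing, displacements)
    return (
        ChannelImage(green, ps, "green", cell_mask),
        ChannelImage(red, ps, "red", cell_mask),
        gt,
    )


def generate_proximity_series(sigmas: list[float], reps: int,
                              base: ImageScenario | None = None,
                              ) -> list[ImageScenario]:
    """Scenario batch varying only sigma; seeds repeat across sigmas so the
    rep-k scenarios form matched pairs."""
    if list(sigmas) != sorted(sigmas):
        raise ValueError("sigmas must be sorted ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = base if base is not None else ImageScenario()
    return [replace(base, sigma=float(s), seed=base.seed + rep)
            for s in sigmas for rep in range(reps)]


def generate_sim_scenarios(base: SimConfig, modes=("random", "colocalized"),
                           seeds=None) -> list[SimConfig]:
    """Paired simulator configs; each seed appears once per mode.

    Channel placement inside ``run_pulse`` derives its RNG stream from the
    seed alone (not the mode), so paired configs share channel geometry.
    """
    for m in modes:
        if m not in ("random", "colocalized"):
            raise ValueError(f"unknown mode {m!r}")
    if seeds is None:
        seeds = [base.seed]
    return [replace(base, mode=m, seed=int(s)) for s in seeds for m in modes]
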