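"""SRS image processing: Huang masking, ratio images, droplet detection.

Mirrors the single-channel SRS quantification pipeline: a cell mask from
Huang fuzzy-entropy thresholding of the CH3 (protein) channel, the per-pixel
CH2/CH3 lipid-to-protein ratio image restricted to the mask, the lipid
channel as the linear combination 5*CH2 - 0.4*CH3, bright sub-micron lipid
droplets segmented from the CH2 channel, and per-region spectra extracted
from hyperspectral stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import perimeter as _perimeter
from skimage.segmentation import flood

from ramanmet.spectra import Spectrum


@dataclass
class ImageChannel:
    """Single-wavenumber SRS image (nonnegative intensities)."""

    pixels: np.ndarray
    wavenumber: float = 0.0
    pixel_size: float = 1.0  # um / px

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D array")
        if not np.all(np.isfinite(self.pixels)) or (self.pixels < 0).any():
            raise ValueError("pixel intensities must be finite and nonnegative")

    @property
    def shape(self):
        return self.pixels.shape

    @classmethod
    def from_tiff(cls, path, wavenumber: float = 0.0, pixel_size: float = 1.0):
        return cls(tifffile.imread(path).astype(float), wavenumber, pixel_size)

    def to_tiff(self, path):
        tifffile.imwrite(path, self.pixels.astype(np.float32))


@dataclass
class CellMask:
    """Binary mask of cell pixels with the threshold that produced it."""

    pixels: np.ndarray
    threshold_value: float

    def __post_init__(self):
        self.pixels = (np.asarray(self.pixels) != 0).astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DropletRegion:
    centroid: tuple[float, float]
    radius: float  # equivalent radius, px
    pixels: np.ndarray  # boolean array, full frame


@dataclass
class DropletSet:
    regions: list[DropletRegion] = field(default_factory=list)
    source: str = ""

    def __len__(self):
        return len(self.regions)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([r.centroid for r in self.regions]).reshape(-1, 2)


def huang_fuzziness(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Huang–Wang fuzziness of every candidate threshold.

    The image is min–max rescaled onto ``n_bins`` histogram bins.  For a
    threshold t the membership of bin g to its side's mean is
    mu = 1 / (1 + |g - m_side| / C) with C the full gray range, and the
    fuzziness is the histogram-weighted Shannon entropy
    -mu*ln(mu) - (1-mu)*ln(1-mu).  Returns the fuzziness for thresholds
    t = 0 .. n_bins-2 (foreground = bins strictly above t).
    """
    x = np.asarray(image, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("no separable histogram: image is constant")
    g = np.minimum((x - lo) / (hi - lo) * n_bins, n_bins - 1).astype(int)
    hist = np.bincount(g, minlength=n_bins).astype(float)
    levels = np.arange(n_bins, dtype=float)

    w = hist * levels
    cum_h = np.cumsum(hist)
    cum_w = np.cumsum(w)
    tot_h, tot_w = cum_h[-1], cum_w[-1]

    fuzz = np.full(n_bins - 1, np.inf)
    C = float(n_bins - 1)
    for t in range(n_bins - 1):
        h0, h1 = cum_h[t], tot_h - cum_h[t]
        if h0 == 0 or h1 == 0:
            continue
        m0 = cum_w[t] / h0
        m1 = (tot_w - cum_w[t]) / h1
        mu = np.empty(n_bins)
        mu[: t + 1] = 1.0 / (1.0 + np.abs(levels[: t + 1] - m0) / C)
        mu[t + 1 :] = 1.0 / (1.0 + np.abs(levels[t + 1 :] - m1) / C)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        S = -mu * np.log(mu) - (1 - mu) * np.log(1 - mu)
        fuzz[t] = float(np.sum(hist * S))
    return fuzz


def huang_threshold_mask(image: ImageChannel, n_bins: int = 256) -> CellMask:
    """Cell mask by Huang fuzzy-entropy thresholding (exhaustive search).

    The threshold minimizing the fuzziness is mapped back to intensity
    units; foreground pixels (strictly above threshold) are set to one.
    """
    px = image.pixels
    fuzz = huang_fuzziness(px, n_bins)
    t_bin = int(np.argmin(fuzz))
    lo, hi = float(px.min()), float(px.max())
    # upper edge of bin t_bin on the original intensity scale
    thresh = lo + (t_bin + 1) / n_bins * (hi - lo)
    return CellMask(pixels=px > thresh, threshold_value=thresh)


def ratio_image(ch2: ImageChannel, ch3: ImageChannel, mask: CellMask) -> np.ndarray:
    """Per-pixel CH2/CH3 ratio inside the mask; zero outside and where CH3=0.

    Stored values are unclamped; any display range (e.g. 0–0.5) is a
    rendering choice, not applied here.
    """
    if ch2.shape != ch3.shape or ch2.shape != mask.shape:
        raise ValueError("channel/mask shapes differ")
    out = np.zeros(ch2.shape, dtype=float)
    ok = (mask.pixels != 0) & (ch3.pixels > 0)
    out[ok] = ch2.pixels[ok] / ch3.pixels[ok]
    return out


def lipid_channel_image(ch2: ImageChannel, ch3: ImageChannel) -> ImageChannel:
    """Lipid (C-H) channel as 5*CH2 - 0.4*CH3, negatives clipped to zero."""
    if ch2.shape != ch3.shape:
        raise ValueError("channel shapes differ")
    vals = np.clip(5.0 * ch2.pixels - 0.4 * ch3.pixels, 0.0, None)
    return ImageChannel(pixels=vals, wavenumber=ch2.wavenumber, pixel_size=ch2.pixel_size)


def region_mean(image, region: np.ndarray, reference_group_mean: float | None = None) -> float:
    """Mean intensity over a pixel region, optionally normalized to a reference.

    ``region`` is a boolean array; ``image`` an :class:`ImageChannel` or a
    plain 2-D array (e.g. a ratio image).  Passing the reference group's
    mean maps that group to 1, as in relative C-D signal quantification.
    """
    px = image.pixels if isinstance(image, ImageChannel) else np.asarray(image, dtype=float)
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    m = float(px[region].mean())
    if reference_group_mean is not None:
        if reference_group_mean == 0:
            raise ValueError("zero reference mean")
        m /= reference_group_mean
    return m


def detect_lipid_droplets(
    ch2: ImageChannel,
    mask: CellMask,
    min_radius: float = 1.5,
    max_radius: float = 8.0,
    sigma: float = 1.0,
    prominence_sd: float = 2.0,
    min_circularity: float = 0.7,
) -> DropletSet:
    """Detect bright, round lipid droplets in the CH2 channel.

    Pipeline: Gaussian smoothing (``sigma`` px), local maxima above the
    in-mask mean + ``prominence_sd`` standard deviations, region growth to
    the half-maximum isophote around each peak, then radius and circularity
    filters.  Returns disjoint regions inside the mask.
    """
    if mask.n_pixels == 0:
        raise ValueError("empty cell mask")
    sm = gaussian(ch2.pixels, sigma=sigma, preserve_range=True)
    inmask = sm[mask.pixels != 0]
    thr = float(inmask.mean() + prominence_sd * inmask.std())
    peaks = peak_local_max(
        sm,
        min_distance=max(1, int(round(min_radius))),
        threshold_abs=thr,
        labels=mask.pixels,
    )
    claimed = np.zeros(sm.shape, dtype=bool)
    regions: list[DropletRegion] = []
    # brightest first so overlapping half-max basins resolve deterministically
    for r, c in sorted(map(tuple, peaks), key=lambda rc: (-sm[rc], rc)):
        if claimed[r, c]:
            continue
        half = sm[r, c] / 2.0
        grown = flood(sm, (r, c), tolerance=sm[r, c] - half)
        grown &= (mask.pixels != 0) & ~claimed
        area = int(grown.sum())
        if area == 0:
            continue
        radius = float(np.sqrt(area / np.pi))
        if not (min_radius <= radius <= max_radius):
            continue
        perim = _perimeter(grown, neighborhood=4)
        circ = 4 * np.pi * area / perim**2 if perim > 0 else 1.0
        if circ < min_circularity:
            continue
        claimed |= grown
        rr, cc = np.nonzero(grown)
        regions.append(
            DropletRegion(centroid=(float(rr.mean()), float(cc.mean())), radius=radius, pixels=grown)
        )
    return DropletSet(regions=regions)


def label_cells(mask: CellMask) -> np.ndarray:
    """Connected-component labels of the cell mask (8-connectivity)."""
    labels, _ = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    return labels


def extract_region_spectrum(stack: np.ndarray, wavenumbers, region: np.ndarray, label: str = "") -> Spectrum:
    """Per-wavenumber mean over a pixel region of a hyperspectral stack.

    ``stack`` has shape (n_wavenumbers, rows, cols); the result is ready for
    :func:`ramanmet.spectra.normalize_to_anchor`.
    """
    stack = np.asarray(stack, dtype=float)
    region = np.asarray(region, dtype=bool)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (wavenumber, row, col)")
    if region.shape != stack.shape[1:]:
        raise ValueError("region shape does not match frames")
    if not region.any():
        raise ValueError("empty region")
    vals = stack[:, region].mean(axis=1)
    return Spectrum(wavenumbers=np.asarray(wavenumbers, dtype=float), intensities=vals, label=label)
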