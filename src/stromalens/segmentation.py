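"""Stromal-fraction estimation from H&E-style RGB images.

The segmentation pipeline follows the classical recipe for separating
eosinophilic stroma from haematoxylin-dominant carcinoma in brightfield
histology:

1. an entropy filter on the grayscale image marks textured (tissue) pixels
   and removes the flat background;
2. the RGB image is converted to optical density (Beer-Lambert) and colour
   deconvolution with the Ruifrok H&E stain basis recovers per-stain
   concentration channels;
3. the haematoxylin channel is subtracted from the eosin channel, leaving a
   raw stromal signal (eosinophilic stroma positive);
4. Otsu's threshold, computed over tissue pixels only, splits stroma from
   tumour, and morphological smoothing removes speckle;
5. the stromal fraction is the stroma area divided by the tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters.rank import entropy as _rank_entropy
from skimage.morphology import closing as _closing, disk, opening as _opening
from skimage.filters import median as _median_filter

__all__ = [
    "StainBasis",
    "SegmentationConfig",
    "SegmentationResult",
    "RUIFROK_HE",
    "rgb_to_od",
    "od_to_rgb",
    "entropy_tissue_mask",
    "colour_deconvolve",
    "stromal_signal",
    "otsu_threshold",
    "smooth_mask",
    "segment_slide",
]

#: Luminance weights used to grayscale RGB images for the entropy filter.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class StainBasis:
    """Stain vectors in optical-density space, one unit 3-vector per stain.

    For a two-stain basis the residual third vector is completed by the
    cross product of the first two, so the 3x3 system is always invertible
    for linearly independent stains.
    """

    vectors: np.ndarray  # (n_stains, 3), unit rows
    names: tuple[str, ...]

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if v.shape[0] not in (2, 3) or v.shape[1] != 3:
            raise ValueError("stain basis must hold 2 or 3 OD 3-vectors")
        if np.any(v < 0):
            raise ValueError("stain OD components must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero stain vector")
        v = v / norms[:, None]
        names = tuple(self.names)
        if v.shape[0] == 2:
            residual = np.cross(v[0], v[1])
            n = np.linalg.norm(residual)
            if n < 1e-12:
                raise ValueError("stain vectors are collinear")
            v = np.vstack([v, np.abs(residual) / n])
            names = names + ("residual",)
        if abs(np.linalg.det(v)) < 1e-8:
            raise ValueError("stain basis is singular")
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "names", names)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix whose *columns* are the stain vectors (od = M @ c)."""
        return self.vectors.T


#: Published Ruifrok & Johnston H&E stain vectors (unit-normalised), with the
#: residual channel completed by cross product.
RUIFROK_HE = StainBasis(
    vectors=np.array([[0.650, 0.704, 0.286], [0.072, 0.990, 0.105]]),
    names=("haematoxylin", "eosin"),
)


def _check_rgb(image) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {image.shape}")
    if image.shape[0] < 32 or image.shape[1] < 32:
        raise ValueError("image smaller than the 32 px minimum")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("RGB intensities must lie in [0, 255]")
    return image


def rgb_to_od(image, background_intensity=255) -> np.ndarray:
    """Convert RGB intensities to base-10 optical densities.

    ``od = -log10(max(I, 1) / I0)`` per channel, where I0 is the incident
    (background) intensity. Intensities are clipped below at 1 so fully
    opaque pixels map to a finite OD.
    """
    image = _check_rgb(image)
    i0 = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,))
    if np.any(i0 <= 0) or np.any(i0 > 255):
        raise ValueError("background_intensity must lie in [1, 255]")
    intensity = np.maximum(image.astype(float), 1.0)
    return -np.log10(intensity / i0)


def od_to_rgb(od, background_intensity=255) -> np.ndarray:
    """Inverse Beer-Lambert transform, quantised to 8-bit RGB."""
    od = np.asarray(od, dtype=float)
    i0 = np.broadcast_to(np.asarray(background_intensity, dtype=float), (3,))
    rgb = i0 * np.power(10.0, -od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def entropy_tissue_mask(image, window_radius=5, threshold_mode="otsu",
                        fixed_threshold=4.0) -> np.ndarray:
    """Mask textured (tissue) pixels by local grayscale entropy.

    Local Shannon entropy (bits) of the 256-level luminance image is
    computed in a disk window; pixels above the threshold — Otsu on the
    entropy map, or a fixed value in bits — are called tissue.
    """
    image = _check_rgb(image)
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    if min(image.shape[:2]) < 2 * window_radius + 1:
        raise ValueError("image smaller than the entropy window")
    gray = np.clip(np.round(image.astype(float) @ LUMA_WEIGHTS), 0, 255).astype(np.uint8)
    ent = _rank_entropy(gray, disk(window_radius))
    if threshold_mode == "fixed":
        return ent > fixed_threshold
    if threshold_mode != "otsu":
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    flat = ent.ravel()
    if np.unique(flat).size < 2:
        # constant entropy map: no texture contrast anywhere -> no tissue
        return np.zeros(ent.shape, dtype=bool)
    return ent > otsu_threshold(flat)


def colour_deconvolve(od, basis: StainBasis = RUIFROK_HE):
    """Unmix an OD image into per-stain concentration channels.

    Solves ``basis.matrix @ c = od`` per pixel. Returns ``(concentrations,
    residual)`` where concentrations has one channel per stain (H x W x 3)
    and residual is the per-pixel Euclidean reconstruction error (zero for
    an exactly 3-stain mixture).
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("OD image must be H x W x 3")
    if not np.all(np.isfinite(od)) or np.any(od < 0):
        raise ValueError("OD values must be finite and non-negative")
    m = basis.matrix
    inv = np.linalg.inv(m)
    conc = od @ inv.T
    recon = conc @ m.T
    residual = np.linalg.norm(recon - od, axis=2)
    return conc, residual


def stromal_signal(h_channel, e_channel) -> np.ndarray:
    """Raw stromal signal: eosin minus haematoxylin concentration per pixel."""
    h = np.asarray(h_channel, dtype=float)
    e = np.asarray(e_channel, dtype=float)
    if h.shape != e.shape:
        raise ValueError(f"channel shapes differ: {h.shape} vs {e.shape}")
    return e - h


def otsu_threshold(values, n_bins=256) -> float:
    """Otsu's threshold: the histogram bin edge maximising between-class variance.

    ``values`` is typically the stromal signal restricted to tissue pixels.
    The threshold is chosen among the interior edges of an ``n_bins``-bin
    histogram spanning the data range; ties go to the lowest edge.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values to threshold")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise ValueError("all values identical: threshold undefined")
    edges = np.linspace(lo, hi, n_bins + 1)[1:-1]   # interior bin edges
    order = np.sort(values)
    n = order.size
    cum = np.concatenate([[0.0], np.cumsum(order)])
    # class 0 at edge t holds the k values strictly below t
    k = np.searchsorted(order, edges, side="left")
    valid = (k > 0) & (k < n)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum[k] / k
        mu1 = (cum[n] - cum[k]) / (n - k)
        w0 = k / n
        sigma_b = w0 * (1 - w0) * (mu0 - mu1) ** 2
    sigma_b = np.where(valid, sigma_b, -np.inf)
    if not np.any(np.isfinite(sigma_b)):
        raise ValueError("no valid split among histogram bin edges")
    return float(edges[int(np.argmax(sigma_b))])


def smooth_mask(mask, radius=2) -> np.ndarray:
    """Morphological opening then closing with a disk footprint; radius 0 is identity."""
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return mask.copy()
    footprint = disk(radius)
    return _closing(_opening(mask, footprint), footprint).astype(bool)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the stromal segmentation pipeline."""

    basis: StainBasis = RUIFROK_HE
    background_intensity: float = 255.0
    entropy_radius: int = 5
    entropy_threshold_mode: str = "otsu"   # or "fixed"
    entropy_fixed_threshold: float = 4.0   # bits, used in fixed mode
    smoothing_radius: int = 2              # post-threshold mask smoothing
    median_radius: int = 0                 # optional pre-threshold signal median filter
    otsu_bins: int = 256
    min_tissue_pixels: int = 64            # below this the fraction is undefined


@dataclass
class SegmentationResult:
    """Tissue/stroma masks plus the stromal fraction of one image."""

    tissue_mask: np.ndarray
    stroma_mask: np.ndarray
    stromal_fraction: float | None
    stromal_signal: np.ndarray
    threshold: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def no_tissue(self) -> bool:
        return self.stromal_fraction is None


def segment_slide(image, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Estimate the stromal fraction of one H&E-style RGB image.

    Applies entropy tissue masking, Ruifrok colour deconvolution, the
    eosin-minus-haematoxylin stromal signal, Otsu thresholding within
    tissue, and morphological smoothing. When too little tissue is found
    the fraction is returned as None with a ``no-tissue`` flag rather than
    a silent zero. Deterministic given the config.
    """
    cfg = config or SegmentationConfig()
    image = _check_rgb(image)

    tissue = entropy_tissue_mask(
        image,
        window_radius=cfg.entropy_radius,
        threshold_mode=cfg.entropy_threshold_mode,
        fixed_threshold=cfg.entropy_fixed_threshold,
    )
    od = rgb_to_od(image, cfg.background_intensity)
    conc, _ = colour_deconvolve(od, cfg.basis)
    signal = stromal_signal(conc[..., 0], conc[..., 1])
    if cfg.median_radius > 0:
        signal = _median_filter(signal, disk(cfg.median_radius))

    empty = np.zeros(tissue.shape, dtype=bool)
    if tissue.sum() < cfg.min_tissue_pixels:
        return SegmentationResult(tissue, empty, None, signal, None, ("no-tissue",))

    in_tissue = signal[tissue]
    if np.unique(in_tissue).size < 2:
        return SegmentationResult(tissue, empty, None, signal, None,
                                  ("degenerate-signal",))
    thr = otsu_threshold(in_tissue, n_bins=cfg.otsu_bins)
    stroma = (signal > thr) & tissue
    stroma = smooth_mask(stroma, cfg.smoothing_radius) & tissue
    frac = float(stroma.sum() / tissue.sum())
    return SegmentationResult(tissue, stroma, frac, signal, thr)
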