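"""Reflectance calibration, seed segmentation, and mean-spectrum extraction.

The processing chain, applied to one raw scene:

1. calibrate raw counts to relative reflectance against white and dark
   reference frames: ``R = (S0 - Sb) / (Sw - Sb)``;
2. binarize a single working band (the seeds show their sharpest outline
   near 640 nm) with Otsu's threshold;
3. clean the foreground with a morphological opening (disk element);
4. extract the specular "hot spot" at each seed's center with a second
   per-seed threshold pass, and the dim rim by erosion;
5. average the reflectance spectrum over each seed's remaining region of
   interest (ROI), one spectrum per seed.

Seeds are roughly spherical, so their images carry a bright specular core
and a dark rim; both bias the mean spectrum and are removed before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, erosion as _gray_erosion, opening as _gray_opening

from .io_formats import HyperCube, ReferenceFrame, SeedspecError, SpectraTable

__all__ = [
    "SeedMask",
    "SegmentationConfig",
    "DegenerateReferenceError",
    "DegenerateImageError",
    "SegmentationError",
    "correct_reflectance",
    "otsu_threshold",
    "segment_seeds",
    "extract_hotspot",
    "build_roi",
    "extract_mean_spectra",
    "segment_scene",
    "process_scene",
]


class DegenerateReferenceError(SeedspecError):
    """White and dark references coincide somewhere they are used."""


class DegenerateImageError(SeedspecError):
    """An image whose histogram cannot support a threshold (constant)."""


class SegmentationError(SeedspecError):
    """Segmentation produced no usable foreground."""


@dataclass
class SeedMask:
    """A 2-D boolean mask at one of the pipeline stages.

    ``stage`` is ``binarized`` (raw Otsu foreground), ``opened`` (after
    morphological opening) or ``roi`` (after rim erosion and hot-spot
    removal).  ``dropped`` lists 1-based component indices of seeds whose
    ROI fell below the minimum pixel count and were discarded.
    """

    mask: np.ndarray
    stage: str = "binarized"
    dropped: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.stage not in ("binarized", "opened", "roi"):
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation stage.

    segmentation_wavelength_nm : working band for binarization (default
        640.08 nm, where seed outlines are sharpest against the dark tray).
    opening_radius_px : disk radius of the morphological opening.
    edge_erosion_px : width of the dim rim stripped from each seed.
    hotspot_method : ``second_otsu`` (a second Otsu pass inside each seed,
        parameter-free) or ``quantile`` (pixels above ``hotspot_quantile``).
    min_roi_px : seeds whose ROI retains fewer pixels are dropped.
    keep_border : whether components touching the image border are kept.
    """

    segmentation_wavelength_nm: float = 640.08
    opening_radius_px: int = 2
    edge_erosion_px: int = 2
    hotspot_method: str = "second_otsu"
    hotspot_quantile: float = 0.9
    min_roi_px: int = 10
    keep_border: bool = True

    def __post_init__(self) -> None:
        if self.opening_radius_px < 1:
            raise ValueError("opening_radius_px must be >= 1")
        if self.edge_erosion_px < 0:
            raise ValueError("edge_erosion_px must be >= 0")
        if self.hotspot_method not in ("second_otsu", "quantile"):
            raise ValueError(f"unknown hotspot_method {self.hotspot_method!r}")
        if not 0.0 < self.hotspot_quantile < 1.0:
            raise ValueError("hotspot_quantile must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def correct_reflectance(
    raw: HyperCube, white: ReferenceFrame, dark: ReferenceFrame
) -> HyperCube:
    """Convert raw detector counts to relative reflectance.

    ``R = (S0 - Sb) / (Sw - Sb)`` element-wise, where S0 is the raw cube,
    Sw the white-standard frame and Sb the dark (lens-capped) frame.  The
    references may be full cubes or anything broadcastable to the cube.
    """
    s0 = raw.data.astype(float)
    sw = np.broadcast_to(white.data, s0.shape)
    sb = np.broadcast_to(dark.data, s0.shape)
    denom = sw - sb
    bad = denom == 0
    if np.any(bad):
        pos = tuple(int(i) for i in np.argwhere(bad)[0])
        raise DegenerateReferenceError(
            f"white equals dark at (row, col, band) = {pos}; cannot calibrate"
        )
    return HyperCube((s0 - sb) / denom, raw.wavelengths, kind="reflectance")


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the image range.

    Returns the gray level maximizing the between-class variance; the
    value lies strictly between the image minimum and maximum.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if image.min() == image.max():
        raise DegenerateImageError(
            "constant image: histogram has a single occupied bin"
        )
    return float(threshold_otsu(image, nbins=256))


def segment_seeds(band_image: np.ndarray, config: SegmentationConfig) -> SeedMask:
    """Binarize the working band with Otsu's method and clean the mask.

    The foreground is opened with a disk of ``opening_radius_px``; residual
    specks smaller than the structuring element's area are removed.  Each
    connected component of the result is one seed candidate.
    """
    band_image = np.asarray(band_image, dtype=float)
    fg = band_image > otsu_threshold(band_image)
    elem = disk(config.opening_radius_px)
    opened = _gray_opening(fg, elem).astype(bool)
    # drop residual specks smaller than the structuring element
    lab = cc_label(opened)
    areas = np.bincount(lab.ravel())
    small = np.flatnonzero(areas < int(elem.sum()))
    opened &= ~np.isin(lab, small[small > 0])
    if not config.keep_border:
        lab = cc_label(opened)
        border_ids = np.unique(
            np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
        )
        opened &= ~np.isin(lab, border_ids[border_ids > 0])
    if not opened.any():
        raise SegmentationError("no seeds found after opening")
    return SeedMask(opened, stage="opened")


def extract_hotspot(
    band_image: np.ndarray, mask: SeedMask, config: SegmentationConfig
) -> np.ndarray:
    """Bright specular core of each seed, as a boolean array inside ``mask``.

    With ``second_otsu`` a second Otsu threshold is computed over the pixels
    of each connected component; with ``quantile`` the per-component
    ``hotspot_quantile`` is used.  A component of constant intensity has an
    empty hot spot.
    """
    band_image = np.asarray(band_image, dtype=float)
    if not mask.mask.any():
        raise SegmentationError("empty mask: nothing to extract a hot spot from")
    hot = np.zeros_like(mask.mask)
    lab = cc_label(mask.mask)
    for comp_id in range(1, lab.max() + 1):
        comp = lab == comp_id
        vals = band_image[comp]
        # near-constant (to float precision) counts as uniform: no core
        if np.ptp(vals) <= 1e-9 * max(1.0, abs(float(vals.max()))):
            continue
        if config.hotspot_method == "second_otsu":
            thr = float(threshold_otsu(vals, nbins=256))
        else:
            thr = float(np.quantile(vals, config.hotspot_quantile))
        hot |= comp & (band_image > thr)
    return hot


def build_roi(
    opened: SeedMask, hotspot: np.ndarray, config: SegmentationConfig
) -> SeedMask:
    """Strip each seed's rim (erosion) and hot spot to form the ROI.

    ``roi = erode(opened, edge_erosion_px) AND NOT hotspot``.  Components
    left with fewer than ``min_roi_px`` pixels are dropped (their 1-based
    component index is recorded on the returned mask).
    """
    hotspot = np.asarray(hotspot, dtype=bool)
    if hotspot.shape != opened.mask.shape:
        raise ValueError("hotspot and mask shapes differ")
    if config.edge_erosion_px > 0:
        eroded = _gray_erosion(opened.mask, disk(config.edge_erosion_px)).astype(bool)
    else:
        eroded = opened.mask.copy()
    roi = eroded & ~hotspot
    lab = cc_label(opened.mask)
    dropped = []
    for comp_id in range(1, lab.max() + 1):
        comp = lab == comp_id
        if (roi & comp).sum() < config.min_roi_px:
            roi &= ~comp
            dropped.append(comp_id)
    if not roi.any():
        raise SegmentationError("every seed's ROI is empty after cleanup")
    if dropped:
        warnings.warn(
            f"{len(dropped)} seed(s) dropped: ROI below {config.min_roi_px} px",
            stacklevel=2,
        )
    return SeedMask(roi, stage="roi", dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# Spectrum extraction
# ---------------------------------------------------------------------------

def extract_mean_spectra(
    cube: HyperCube,
    roi: SeedMask,
    labels: np.ndarray | list | None = None,
    scene_id: str = "scene",
) -> SpectraTable:
    """Average the reflectance spectrum over each ROI component.

    One row per connected component, in deterministic raster-scan order of
    first-encountered pixel.  ``labels`` optionally assigns a variety label
    per component (same order); otherwise rows are labeled ``unlabeled``.
    """
    if cube.kind != "reflectance":
        raise ValueError("extract_mean_spectra expects a reflectance cube")
    if cube.shape[:2] != roi.mask.shape:
        raise ValueError("cube and ROI are not spatially aligned")
    if not roi.mask.any():
        raise SegmentationError("empty ROI")
    lab = cc_label(roi.mask)
    n_comp = int(lab.max())
    if labels is not None and len(labels) != n_comp:
        raise ValueError(
            f"{len(labels)} labels supplied for {n_comp} ROI components"
        )
    spectra = np.empty((n_comp, cube.n_bands), dtype=float)
    for comp_id in range(1, n_comp + 1):
        spectra[comp_id - 1] = cube.data[lab == comp_id].mean(axis=0)
    row_labels = (
        np.asarray(labels)
        if labels is not None
        else np.array(["unlabeled"] * n_comp, dtype=object)
    )
    seed_ids = [f"{scene_id}:{i}" for i in range(1, n_comp + 1)]
    return SpectraTable(spectra, row_labels, cube.wavelengths, seed_ids)


def segment_scene(
    band_image: np.ndarray, config: SegmentationConfig | None = None
) -> SeedMask:
    """Full segmentation of one working-band image down to the ROI mask.

    The dim rim would dominate a per-seed threshold pass, so the hot spot is
    located on the rim-eroded mask; since hot ⊆ eroded ⊆ opened, the ROI
    formula erode(opened) AND NOT hotspot is unchanged.
    """
    config = config or SegmentationConfig()
    opened = segment_seeds(band_image, config)
    if config.edge_erosion_px > 0:
        eroded = SeedMask(
            _gray_erosion(opened.mask, disk(config.edge_erosion_px)).astype(bool),
            stage="opened",
        )
    else:
        eroded = opened
    hot = extract_hotspot(band_image, eroded, config)
    return build_roi(opened, hot, config)


def process_scene(
    raw: HyperCube,
    white: ReferenceFrame,
    dark: ReferenceFrame,
    config: SegmentationConfig | None = None,
    labels: np.ndarray | list | None = None,
    scene_id: str = "scene",
) -> tuple[SpectraTable, SeedMask]:
    """Run the full chain on one scene: calibrate, segment, build the ROI
    and extract per-seed mean spectra.  Returns the table and the ROI mask."""
    config = config or SegmentationConfig()
    refl = correct_reflectance(raw, white, dark)
    band = refl.data[:, :, refl.band_nearest(config.segmentation_wavelength_nm)]
    roi = segment_scene(band, config)
    if labels is not None and roi.dropped:
        labels = [l for i, l in enumerate(labels, start=1) if i not in roi.dropped]
    table = extract_mean_spectra(refl, roi, labels=labels, scene_id=scene_id)
    return table, roi
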