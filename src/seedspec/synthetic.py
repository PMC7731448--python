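"""Synthetic hyperspectral phantoms: class spectra, seed tables, and scenes.

The generator emulates the statistical structure of visible/NIR reflectance
spectra of seed varieties, so every stage of the pipeline (calibration,
segmentation, band selection, classification) can be exercised with known
ground truth:

* class mean curves are smooth — a logistic rise toward the NIR plus a
  chlorophyll-like Gaussian absorption valley centered between 600 and
  700 nm — with all reflectance values kept at or below 0.6;
* per-seed spectra add zero-mean Gaussian noise whose correlation is
  block-diagonal: within a contiguous band block every pair of bands shares
  correlation ``rho``, between blocks the noise is independent.  This
  mimics the bright diagonal blocks of the band correlation matrix that
  motivate block-stratified band selection;
* rendered scenes place elliptical seeds on a dark tray, add a bright
  specular "hot spot" disk at each seed center and a dim rim ring, and
  convert reflectance to raw counts through a smooth white-reference field
  and a constant dark level, so reflectance calibration recovers the body
  spectrum exactly where uncontaminated.

All randomness flows from a single integer seed; child streams are derived
with fixed offsets so modules can be exercised independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .band_selection import BandBlocks, default_blocks
from .io_formats import HyperCube, ReferenceFrame, SeedspecError, SpectraTable

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_class_spectra",
    "sample_spectra_table",
    "render_scene",
]

# fixed offsets for child RNG streams
_STREAM_CLASS = 1
_STREAM_NOISE = 2
_STREAM_SCENE = 3


@dataclass
class PhantomConfig:
    """Parameters of the phantom generator.

    Spectral defaults match the instrument layout the pipeline targets:
    462 bands over 400–1000 nm, 25 varieties of ~50 seeds, reflectance
    below 0.6 with an absorption valley in 600–700 nm, and noise whose
    correlation follows the default four band blocks.
    """

    n_varieties: int = 25
    seeds_per_variety: int = 50
    n_bands: int = 462
    wavelength_min_nm: float = 400.0
    wavelength_max_nm: float = 1000.0
    # class-curve family
    valley_center_nm: float = 650.0
    valley_width_nm: float = 30.0
    valley_depth: float = 0.08
    max_reflectance: float = 0.6
    separation: float = 1.0  # scale of between-class curve differences
    noise_sd: float = 0.01  # within-class spectral noise (reflectance units)
    noise_rho: float = 0.9  # within-block noise correlation
    blocks: BandBlocks | None = None  # None -> four-block default when B=462
    # scene geometry (pixels)
    scene_seeds: int = 15
    seed_axes_px: tuple[int, int] = (10, 8)
    hotspot_radius_px: int = 3
    hotspot_boost: float = 0.4  # relative brightening of the specular core
    rim_width_px: int = 2
    rim_drop: float = 0.35  # relative dimming of the rim ring
    background_reflectance: float = 0.02
    white_dn: float = 3500.0
    dark_dn: float = 80.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_varieties, self.seeds_per_variety, self.n_bands) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.noise_rho < 1.0:
            raise ValueError("noise_rho must lie in [0, 1)")
        if not 0.0 < self.max_reflectance <= 0.6:
            raise ValueError("max_reflectance must lie in (0, 0.6]")
        if self.blocks is None and self.n_bands == 462:
            self.blocks = default_blocks()

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(
            self.wavelength_min_nm, self.wavelength_max_nm, self.n_bands
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence((self.rng_seed, stream))
        )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom table or scene."""

    labels: np.ndarray  # per-seed variety label
    true_spectra: np.ndarray  # per-seed body spectrum, (n, B)
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # body/hotspot/rim


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_class_spectra(config: PhantomConfig) -> np.ndarray:
    """Smooth per-variety mean reflectance curves, (n_varieties, n_bands).

    Base shape: low reflectance in the blue, a logistic rise toward the
    NIR plateau, and a Gaussian absorption valley at ``valley_center_nm``.
    Class-specific offsets, slope tweaks and valley-depth jitter are scaled
    by ``separation``; at separation 0 every class curve is identical.
    Values are clipped into (0, max_reflectance] with a warning if the
    family parameters push any curve outside.
    """
    wl = config.wavelengths
    rng = config._rng(_STREAM_CLASS)
    # seed bodies stay clearly brighter than the light-absorbing tray even
    # inside the absorption valley, as in reflectance imagery of real seeds
    base = 0.14 + 0.36 * _logistic((wl - 700.0) / 60.0)
    valley = config.valley_depth * np.exp(
        -(((wl - config.valley_center_nm) / config.valley_width_nm) ** 2)
    )
    curves = np.empty((config.n_varieties, config.n_bands))
    for v in range(config.n_varieties):
        offset = config.separation * rng.normal(0.0, 0.012)
        slope = config.separation * rng.normal(0.0, 0.012)
        depth_jit = 1.0 + config.separation * rng.normal(0.0, 0.1)
        curves[v] = (
            base
            - depth_jit * valley
            + offset
            + slope * (wl - 700.0) / 300.0
        )
    lo, hi = 1e-3, config.max_reflectance
    if curves.min() < lo or curves.max() > hi:
        warnings.warn(
            "class curves exceeded the valid reflectance range and were clipped",
            stacklevel=2,
        )
        curves = np.clip(curves, lo, hi)
    return curves


def _block_noise(
    rng: np.random.Generator, n: int, config: PhantomConfig
) -> np.ndarray:
    """Zero-mean noise (n, B): equicorrelation rho within each block, zero
    between blocks; marginal sd = noise_sd."""
    B = config.n_bands
    rho = config.noise_rho
    noise = np.empty((n, B))
    if config.blocks is not None:
        intervals = [(s - 1, e) for s, e in config.blocks.blocks]
        # bands outside the declared blocks (if any) are independent
        covered = np.zeros(B, dtype=bool)
        for s, e in intervals:
            covered[s:e] = True
        extra = np.flatnonzero(~covered)
    else:
        intervals = [(0, B)]
        extra = np.array([], dtype=int)
    for s, e in intervals:
        size = e - s
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, size))
        noise[:, s:e] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep
    if extra.size:
        noise[:, extra] = rng.standard_normal((n, extra.size))
    return config.noise_sd * noise


def sample_spectra_table(
    config: PhantomConfig,
) -> tuple[SpectraTable, PhantomTruth]:
    """Draw per-seed spectra: class curve + block-correlated noise.

    Returns the table (labels ``V01``, ``V02``, ...) and the ground truth
    holding each seed's noiseless class curve.
    """
    curves = make_class_spectra(config)
    rng = config._rng(_STREAM_NOISE)
    n = config.n_varieties * config.seeds_per_variety
    labels = np.repeat(
        [f"V{v + 1:02d}" for v in range(config.n_varieties)],
        config.seeds_per_variety,
    )
    clean = np.repeat(curves, config.seeds_per_variety, axis=0)
    spectra = clean + _block_noise(rng, n, config)
    table = SpectraTable(spectra, labels, config.wavelengths)
    return table, PhantomTruth(labels=labels, true_spectra=clean)


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(
    shape: tuple[int, int], center: tuple[int, int], axes: tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def render_scene(
    config: PhantomConfig,
) -> tuple[HyperCube, ReferenceFrame, ReferenceFrame, PhantomTruth]:
    """Render a raw-count scene of elliptical seeds plus reference frames.

    Seeds are laid out on a regular grid (placement fails if the implied
    grid cannot hold them disjointly, which cannot happen with the
    auto-sized canvas used here).  Each seed's pixels carry its true
    spectrum; the central hot-spot disk is brightened by ``hotspot_boost``
    and the rim ring dimmed by ``rim_drop``.  Raw counts follow
    ``DN = dark + R * (white - dark)`` with a smooth spatial white field,
    so calibration recovers body reflectance exactly (to float precision)
    outside the contaminated regions.
    """
    n_seeds = config.scene_seeds
    a, b = config.seed_axes_px
    if config.rim_width_px >= min(a, b) or config.hotspot_radius_px >= min(a, b):
        raise SeedspecError("rim/hot-spot geometry exceeds the seed axes")
    margin = 4
    cell = 2 * max(a, b) + 2 * margin
    n_cols = int(np.ceil(np.sqrt(n_seeds)))
    n_rows = int(np.ceil(n_seeds / n_cols))
    shape = (n_rows * cell, n_cols * cell)

    # per-seed spectra: cycle varieties across seeds
    table_cfg = config
    curves = make_class_spectra(table_cfg)
    rng = config._rng(_STREAM_SCENE)
    var_of_seed = np.arange(n_seeds) % config.n_varieties
    labels = np.array([f"V{v + 1:02d}" for v in var_of_seed])
    seed_noise = _block_noise(rng, n_seeds, config)
    true_spectra = np.clip(
        curves[var_of_seed] + seed_noise, 1e-3, config.max_reflectance
    )

    B = config.n_bands
    refl = np.full(shape + (B,), config.background_reflectance)
    body = np.zeros(shape, dtype=bool)
    hotspot = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    for s in range(n_seeds):
        r0 = (s // n_cols) * cell + cell // 2
        c0 = (s % n_cols) * cell + cell // 2
        outer = _ellipse_mask(shape, (r0, c0), (a, b))
        inner = _ellipse_mask(
            shape, (r0, c0), (a - config.rim_width_px, b - config.rim_width_px)
        )
        hot = (
            _ellipse_mask(
                shape, (r0, c0),
                (config.hotspot_radius_px, config.hotspot_radius_px),
            )
            & inner
        )
        seed_rim = outer & ~inner
        seed_body = inner & ~hot
        refl[outer] = true_spectra[s]
        refl[hot] *= 1.0 + config.hotspot_boost
        refl[seed_rim] *= 1.0 - config.rim_drop
        body |= seed_body
        hotspot |= hot
        rim |= seed_rim

    wl = config.wavelengths
    # smooth spatial gain field times a gentle lamp spectrum
    rr = np.linspace(0.0, np.pi, shape[0])[:, None]
    cc = np.linspace(0.0, np.pi, shape[1])[None, :]
    gain = 1.0 + 0.1 * np.sin(rr) * np.sin(cc)
    lamp = 0.8 + 0.2 * np.exp(-(((wl - 750.0) / 250.0) ** 2))
    white = config.dark_dn + (config.white_dn - config.dark_dn) * (
        gain[:, :, None] * lamp[None, None, :]
    )
    dark = np.full(shape + (B,), config.dark_dn)
    raw = dark + refl * (white - dark)

    truth = PhantomTruth(
        labels=labels,
        true_spectra=true_spectra,
        masks={"body": body, "hotspot": hotspot, "rim": rim},
    )
    return (
        HyperCube(raw, wl, kind="raw"),
        ReferenceFrame(white, role="white"),
        ReferenceFrame(dark, role="dark"),
        truth,
    )
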