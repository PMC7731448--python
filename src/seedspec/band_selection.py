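"""Correlation-matrix band blocks and equal-interval band selection.

Adjacent bands of a visible/NIR hyperspectral cube are strongly redundant:
the band-by-band Pearson correlation matrix (CCM) of seed spectra shows
bright diagonal blocks of mutually correlated bands.  Those blocks are used
as strata for feature selection — within each block, bands are picked at
regular intervals, so every spectral region contributes features without
flooding the classifier with near-duplicates.

For the 462-band (400–1000 nm) instrument layout the default partition is
the four blocks covering bands 1–90, 91–190, 191–225 and 226–462 (1-based).
The third block holds only 35 bands, so per-block requests above 35 are
capped there; requests of 10/20/30/40/50 per block yield selections of
40/80/120/155/185 bands in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SeedspecError, SpectraTable

__all__ = [
    "BandBlocks",
    "BandSelection",
    "UndefinedCorrelationError",
    "default_blocks",
    "correlation_matrix",
    "block_mean_correlation",
    "select_bands_equal_interval",
]


class UndefinedCorrelationError(SeedspecError):
    """A band column is constant, so its Pearson correlation is undefined."""


@dataclass(frozen=True)
class BandBlocks:
    """Ordered, non-overlapping inclusive 1-based band-index intervals."""

    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block required")
        prev_end = 0
        for start, end in self.blocks:
            if start < 1 or end < start:
                raise ValueError(f"invalid block ({start}, {end})")
            if start <= prev_end:
                raise ValueError("blocks must be ascending and non-overlapping")
            prev_end = end

    @property
    def sizes(self) -> list[int]:
        return [end - start + 1 for start, end in self.blocks]

    @property
    def max_band(self) -> int:
        return self.blocks[-1][1]


def default_blocks() -> BandBlocks:
    """The four-block partition of the 462-band spectral axis."""
    return BandBlocks(((1, 90), (91, 190), (191, 225), (226, 462)))


@dataclass
class BandSelection:
    """A sorted, unique set of selected 1-based band indices.

    ``per_block_request`` is the number of bands asked of every block;
    ``per_block_taken`` records what each block could actually supply
    (capped at the block size).
    """

    indices: np.ndarray
    per_block_request: int
    per_block_taken: list[int]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) != len(np.unique(self.indices)):
            raise ValueError("selected indices must be unique")
        if len(self.indices) != sum(self.per_block_taken):
            raise ValueError("index count disagrees with per-block tallies")

    def __len__(self) -> int:
        return len(self.indices)

    def to_zero_based(self) -> np.ndarray:
        return self.indices - 1

    def to_dataframe(self, wavelengths: np.ndarray | None = None) -> pd.DataFrame:
        """Selection as a table of 1-based band numbers (and wavelengths)."""
        df = pd.DataFrame({"band": self.indices})
        if wavelengths is not None:
            df["wavelength_nm"] = np.asarray(wavelengths)[self.indices - 1]
        return df


def correlation_matrix(table: SpectraTable) -> np.ndarray:
    """Pearson correlation between every pair of band columns.

    Needs at least 3 rows; a constant band column makes its correlations
    undefined and raises, naming the first offending band (1-based).
    """
    X = table.spectra
    if X.shape[0] < 3:
        raise ValueError("correlation matrix needs at least 3 spectra")
    spread = np.ptp(X, axis=0)
    if np.any(spread == 0):
        band = int(np.flatnonzero(spread == 0)[0]) + 1
        raise UndefinedCorrelationError(
            f"band {band} is constant across samples; correlation undefined"
        )
    ccm = np.corrcoef(X, rowvar=False)
    # guard against tiny numeric excursions outside [-1, 1]
    np.clip(ccm, -1.0, 1.0, out=ccm)
    np.fill_diagonal(ccm, 1.0)
    return ccm


def block_mean_correlation(ccm: np.ndarray, blocks: BandBlocks) -> list[float]:
    """Mean of each diagonal block of the CCM (diagonal entries included)."""
    B = ccm.shape[0]
    if blocks.max_band > B:
        raise ValueError(f"blocks extend to band {blocks.max_band} but CCM has {B}")
    means = []
    for start, end in blocks.blocks:
        sub = ccm[start - 1 : end, start - 1 : end]
        means.append(float(sub.mean()))
    return means


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # positions are always positive here
    return np.floor(x + 0.5).astype(int)


def select_bands_equal_interval(blocks: BandBlocks, k: int) -> BandSelection:
    """Pick ``min(k, block size)`` bands per block at regular intervals.

    Positions are the ``m`` evenly spaced points from the block start to the
    block end inclusive (``m = 1`` takes the block start), rounded half away
    from zero; a rounding collision shifts to the nearest unused index
    within the block (ties toward the lower index).
    """
    if k < 1:
        raise ValueError("per-block request k must be >= 1")
    chosen: list[int] = []
    per_block_taken: list[int] = []
    for start, end in blocks.blocks:
        size = end - start + 1
        m = min(k, size)
        per_block_taken.append(m)
        if m == 1:
            ideal = np.array([float(start)])
        else:
            ideal = start + (size - 1) * np.arange(m) / (m - 1)
        used: set[int] = set()
        for pos in _round_half_away(ideal):
            idx = int(pos)
            if idx in used:
                for offset in range(1, size):
                    lo, hi = idx - offset, idx + offset
                    if start <= lo <= end and lo not in used:
                        idx = lo
                        break
                    if start <= hi <= end and hi not in used:
                        idx = hi
                        break
            used.add(idx)
        chosen.extend(sorted(used))
    return BandSelection(
        indices=np.array(chosen, dtype=int),
        per_block_request=k,
        per_block_taken=per_block_taken,
    )
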