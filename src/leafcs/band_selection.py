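"""Optimal-band selection via the spatial/spectral decorrelation criterion.

SSDC scores each band's noise level by regressing it on its two spectral
neighbours within small spatial blocks and averaging the residual standard
deviation; the band with the minimal score is the cleanest and is used for
ROI mask extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import HyperCube

__all__ = ["SSDCCurve", "compute_ssdc_curve", "select_optimal_band"]

_MIN_BLOCK_PIXELS = 8  # residual sd needs count-3 dof; merge tiny edge blocks


@dataclass
class SSDCCurve:
    """Per-band SSDC scores (DN units). ``valid`` is False for the two
    boundary bands, which lack a spectral neighbour on one side."""

    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same length")
        if np.any(self.values[self.valid] < 0):
            raise ValueError("SSDC values must be non-negative where valid")


def _block_edges(size: int, block: int) -> list[tuple[int, int]]:
    """Partition [0, size) into runs of length `block`; the remainder is
    absorbed by the last block (and a single short block is kept whole)."""
    if size <= block:
        return [(0, size)]
    n_full = size // block
    edges = [(i * block, (i + 1) * block) for i in range(n_full)]
    rem = size - n_full * block
    if rem:
        lo, _ = edges[-1]
        edges[-1] = (lo, size)
    return edges


def compute_ssdc_curve(
    cube: HyperCube,
    block_rows: int = 8,
    block_cols: int = 8,
    spatial_regressor: bool = False,
) -> SSDCCurve:
    """Score every band with SSDC.

    For each interior band ``k`` and each spatial block, fit by least squares

        x(i, j, k) ~ a + b * x(i, j, k-1) + c * x(i, j, k+1)

    over the block's pixels and take the residual standard deviation with
    the degrees-of-freedom-corrected divisor (pixel count minus the number
    of fitted coefficients).  ``SSDC(k)`` is the mean over blocks.  With
    ``spatial_regressor=True`` the left spatial neighbour ``x(i, j-1, k)``
    is added as a third regressor (first image column dropped).

    The two boundary bands have no two-sided neighbourhood and are marked
    invalid.  Spatial blocks default to 8x8; image-edge remainders are
    merged into the last block, and blocks would never fall below 8 pixels.
    """
    rows, cols, bands = cube.shape
    if bands < 3:
        raise ValueError(f"SSDC needs >= 3 bands, got {bands}")
    if block_rows < 4 or block_cols < 4:
        raise ValueError("block dimensions must be >= 4x4")

    data = cube.data.astype(float)
    col0 = 1 if spatial_regressor else 0
    row_edges = _block_edges(rows, block_rows)
    col_edges = _block_edges(cols - col0, block_cols)

    values = np.zeros(bands)
    valid = np.zeros(bands, dtype=bool)
    n_coef = 4 if spatial_regressor else 3

    for k in range(1, bands - 1):
        block_sds = []
        for r0, r1 in row_edges:
            for c0, c1 in col_edges:
                c0s, c1s = c0 + col0, c1 + col0
                y = data[r0:r1, c0s:c1s, k].ravel()
                count = y.size
                if count < n_coef + 1:
                    continue
                regs = [
                    np.ones(count),
                    data[r0:r1, c0s:c1s, k - 1].ravel(),
                    data[r0:r1, c0s:c1s, k + 1].ravel(),
                ]
                if spatial_regressor:
                    regs.append(data[r0:r1, c0s - 1 : c1s - 1, k].ravel())
                design = np.column_stack(regs)
                coef, *_ = np.linalg.lstsq(design, y, rcond=None)
                resid = y - design @ coef
                block_sds.append(np.sqrt(resid @ resid / (count - n_coef)))
        values[k] = float(np.mean(block_sds))
        valid[k] = True

    return SSDCCurve(values=values, valid=valid)


def select_optimal_band(curve: SSDCCurve) -> int:
    """Index of the minimal-SSDC band among valid bands; ties break to the
    smallest index."""
    if not curve.valid.any():
        raise ValueError("no valid band in SSDC curve")
    masked = np.where(curve.valid, curve.values, np.inf)
    return int(np.argmin(masked))
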