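"""End-to-end ROI-aware compression and reconstruction, per-ROI rate
allocation, and the SSCS / BCS baseline codecs.

Two rate-plan modes exist.  In whole-rate mode a single target rate ``p``
for the full image is concentrated on the leaf regions: every ROI is coded
at ``Ratio_p = (Area_image / Area_ROIs) * p`` (capped at 0.99), the rate the
background's discarded budget buys.  In per-ROI mode each ROI ``i`` carries
its own ``p(i)`` and the realized whole rate is the area-weighted mean
``Ratio_whole = sum(Area_ROI(i) * p(i)) / Area_ROIs``.

The baselines reuse the identical block/expand/measure/StOMP machinery:
BCS applies it to every 2x2 block of the full frame (background included,
single measurement matrix); SSCS compresses each pixel's spectral vector
independently with no spatial blocking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cs_core import (
    StompParams,
    compose_sensing,
    expand_block,
    inverse_expand_block,
    make_dct_basis,
    make_gaussian_matrix,
    measurements_count,
    partition_roi_blocks,
    stomp_recover,
)
from .hsi_io import CompressedScene, HyperCube, RoiCode
from .roi_mask import RoiAreas, roi_areas

__all__ = [
    "RatePlan",
    "effective_roi_rate",
    "whole_rate",
    "hcsmaroi_compress",
    "hcsmaroi_reconstruct",
    "run_bcs_baseline",
    "run_sscs_baseline",
]

RATE_CAP = 0.99


@dataclass
class RatePlan:
    """Sampling-rate allocation.

    mode="whole-rate": one target rate ``p`` for the whole image,
    concentrated on the ROIs. mode="per-roi": explicit ``roi_rates``
    mapping each ROI id to its own rate.
    """

    mode: str = "whole-rate"
    p: float | None = None
    roi_rates: dict[int, float] = field(default_factory=dict)
    literal_area_whole: bool = False  # rate boost denominator reading, see below

    def __post_init__(self) -> None:
        if self.mode not in ("whole-rate", "per-roi"):
            raise ValueError(f"unknown rate-plan mode {self.mode!r}")
        if self.mode == "whole-rate":
            if self.p is None or not 0 < self.p < 1:
                raise ValueError("whole-rate mode needs p in (0, 1)")
        else:
            if not self.roi_rates:
                raise ValueError("per-roi mode needs roi_rates")
            for rid, r in self.roi_rates.items():
                if not 0 < r < 1:
                    raise ValueError(f"ROI {rid} rate {r} outside (0, 1)")

    def rate_for(self, roi_id: int, areas: RoiAreas) -> float:
        if self.mode == "whole-rate":
            return effective_roi_rate(
                self.p, areas, literal_area_whole=self.literal_area_whole
            )
        try:
            return self.roi_rates[roi_id]
        except KeyError:
            raise ValueError(f"no sampling rate given for ROI {roi_id}") from None


def effective_roi_rate(
    p: float, areas: RoiAreas, literal_area_whole: bool = False
) -> float:
    """ROI sampling rate bought by a whole-image target rate ``p``:
    ``Ratio_p = (Area_image / Area_ROIs) * p``, capped at 0.99.

    ``literal_area_whole=True`` selects the alternative reading in which the
    numerator is the total ROI area itself, collapsing ``Ratio_p`` to ``p``
    (no background-budget reallocation).
    """
    if not 0 < p < 1:
        raise ValueError(f"whole rate must be in (0, 1), got {p}")
    if areas.total == 0:
        raise ValueError("no ROIs: cannot allocate rate")
    numerator = areas.total if literal_area_whole else areas.image
    ratio = numerator / areas.total * p
    if ratio > RATE_CAP:
        warnings.warn(
            f"effective ROI rate {ratio:.3f} exceeds {RATE_CAP}; capping",
            stacklevel=2,
        )
        ratio = RATE_CAP
    return ratio


def whole_rate(roi_rates: dict[int, float], areas: RoiAreas) -> float:
    """Realized whole rate of a per-ROI plan: the area-weighted mean
    ``sum(Area_ROI(i) * p(i)) / Area_ROIs``."""
    missing = set(areas.per_roi) - set(roi_rates)
    if missing:
        raise ValueError(f"no sampling rate given for ROIs {sorted(missing)}")
    num = sum(areas.per_roi[i] * roi_rates[i] for i in areas.per_roi)
    return num / areas.total


def _roi_seed(seed: int, roi_id: int) -> int:
    return (seed ^ roi_id) & 0x7FFFFFFF


def hcsmaroi_compress(
    cube: HyperCube,
    labels: np.ndarray,
    plan: RatePlan,
    seed: int = 0,
    fill_rule: str = "mean",
) -> CompressedScene:
    """Compress the ROIs of a cube, discarding the background.

    Each ROI is tiled by 2x2 blocks, every block expanded to a vector of
    length N = 4 * bands, and measured with that ROI's seeded Gaussian
    matrix at its allocated rate (M = ceil(rate * N)).  The returned scene
    header carries everything reconstruction needs: mask, per-ROI rates,
    M, and matrix seeds.
    """
    labels = np.asarray(labels)
    if labels.shape != cube.shape[:2]:
        raise ValueError("labeled mask shape does not match cube")
    areas = roi_areas(labels)
    bands = cube.shape[2]
    n = 4 * bands

    rois: dict[int, RoiCode] = {}
    for rid in sorted(areas.per_roi):
        rate = plan.rate_for(rid, areas)
        # ceil can reach N when the capped rate approaches 1; keep M < N
        m = min(measurements_count(rate, n), n - 1)
        blocks = partition_roi_blocks(labels, rid)
        phi = make_gaussian_matrix(m, n, _roi_seed(seed, rid))
        meas = np.empty((blocks.n_blocks, m), dtype=np.float32)
        for b in range(blocks.n_blocks):
            x = expand_block(cube, tuple(blocks.anchors[b]), blocks.valid[b], fill_rule)
            meas[b] = phi.phi @ x
        rois[rid] = RoiCode(
            roi_id=rid,
            rate=rate,
            m=m,
            n=n,
            seed=_roi_seed(seed, rid),
            measurements=meas,
        )

    return CompressedScene(
        rows=cube.shape[0],
        cols=cube.shape[1],
        bands=bands,
        wavelengths=cube.wavelengths,
        bit_depth=cube.bit_depth,
        labels=labels,
        rois=rois,
        fill_rule=fill_rule,
    )


def hcsmaroi_reconstruct(
    scene: CompressedScene,
    params: StompParams | None = None,
    fill_value: int = 0,
) -> HyperCube:
    """Reconstruct a compressed scene.

    Each block's expansion vector is recovered by StOMP in the DCT basis
    and inverse-expanded into an output cube initialized to ``fill_value``;
    only ROI pixels are written, rounded and clipped to the bit depth.
    """
    dtype = np.uint16 if scene.bit_depth <= 16 else np.uint32
    out = HyperCube(
        data=np.full((scene.rows, scene.cols, scene.bands), fill_value, dtype=dtype),
        wavelengths=scene.wavelengths,
        bit_depth=scene.bit_depth,
    )
    n = 4 * scene.bands
    # synthesis operator: atoms are the columns of the inverse (transposed)
    # DCT matrix — smooth expansion vectors are sparse in their DCT coefficients
    psi_syn = make_dct_basis(n).T
    for rid in sorted(scene.rois):
        roi = scene.rois[rid]
        if roi.n != n:
            raise ValueError(
                f"ROI {rid} header N={roi.n} inconsistent with {scene.bands} bands"
            )
        blocks = partition_roi_blocks(scene.labels, rid)
        if blocks.n_blocks != roi.measurements.shape[0]:
            raise ValueError(
                f"ROI {rid}: mask implies {blocks.n_blocks} blocks but payload "
                f"holds {roi.measurements.shape[0]}"
            )
        phi = make_gaussian_matrix(roi.m, n, roi.seed)
        a = compose_sensing(phi, psi_syn)
        for b in range(blocks.n_blocks):
            s, _ = stomp_recover(a, roi.measurements[b].astype(float), params)
            inverse_expand_block(
                psi_syn @ s, tuple(blocks.anchors[b]), blocks.valid[b], out
            )
    return out


# ---------------------------------------------------------------------------
# Baselines


def run_bcs_baseline(
    cube: HyperCube,
    rate: float,
    seed: int = 0,
    params: StompParams | None = None,
) -> HyperCube:
    """Blocking compressive sensing: the identical 2x2-block codec applied
    to every block of the full frame (background included), one shared
    measurement matrix, uniform rate.  Odd-dimension remainders become
    partial blocks with mean fill."""
    if not 0 < rate < 1:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    rows, cols, bands = cube.shape
    # a single full-frame ROI exercises the same machinery with no mask
    labels = np.ones((rows, cols), dtype=np.int32)
    plan = RatePlan(mode="per-roi", roi_rates={1: rate})
    scene = hcsmaroi_compress(cube, labels, plan, seed=seed)
    return hcsmaroi_reconstruct(scene, params)


def run_sscs_baseline(
    cube: HyperCube,
    rate: float,
    seed: int = 0,
    params: StompParams | None = None,
) -> HyperCube:
    """Single spectral compressive sensing: each pixel's spectral vector
    (length = bands) compressed independently with a shared Gaussian matrix
    and a bands-sized DCT basis; no spatial blocking."""
    if not 0 < rate < 1:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    rows, cols, bands = cube.shape
    m = measurements_count(rate, bands)
    if m >= bands:
        raise ValueError(f"rate {rate} gives M={m} >= bands={bands}")
    phi = make_gaussian_matrix(m, bands, seed)
    psi_syn = make_dct_basis(bands).T
    a = compose_sensing(phi, psi_syn)

    out = HyperCube(
        data=np.zeros_like(cube.data),
        wavelengths=cube.wavelengths,
        bit_depth=cube.bit_depth,
    )
    spectra = cube.data.reshape(-1, bands).astype(float)
    recon = np.empty_like(spectra)
    for i in range(spectra.shape[0]):
        y = phi.phi @ spectra[i]
        s, _ = stomp_recover(a, y, params)
        recon[i] = psi_syn @ s
    out.data = (
        np.clip(np.rint(recon), 0, cube.full_scale)
        .astype(cube.data.dtype)
        .reshape(rows, cols, bands)
    )
    return out
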