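"""Reconstruction quality metrics.

Spatial domain: per-ROI MSE over (ROI pixels x all bands) and
PSNR = 10*log10((2^n - 1)^2 / MSE) with n the cube's bit depth.
Spectral domain: mean ROI spectra and the red-edge vegetation indices

    TVI = 0.5 * [120 * (R750 - R550) - 200 * (R670 - R550)]
    DD  = (R750 - R720) - (R700 - R670)

where Rx is the reflectance at the band nearest x nm (DN divided by the
full scale 2^n - 1, standing in for reflectance calibration), together with
the RMSE of a per-pixel index between original and reconstruction.
"""

from __future__ import annotations

import math

import numpy as np

from .hsi_io import HyperCube, nearest_band

__all__ = [
    "psnr_roi",
    "mean_spectrum",
    "spectral_index",
    "index_rmse",
    "INDEX_ANCHORS",
]

INDEX_ANCHORS = {
    "TVI": (750.0, 550.0, 670.0),
    "DD": (750.0, 720.0, 700.0, 670.0),
}


def _check_pair(orig: HyperCube, recon: HyperCube) -> None:
    if orig.shape != recon.shape:
        raise ValueError(f"shape mismatch: {orig.shape} vs {recon.shape}")
    if orig.bit_depth != recon.bit_depth:
        raise ValueError(
            f"bit depth mismatch: {orig.bit_depth} vs {recon.bit_depth}"
        )


def psnr_roi(
    orig: HyperCube,
    recon: HyperCube,
    labels: np.ndarray,
    roi_id: int,
) -> tuple[float, float]:
    """Per-ROI (MSE, PSNR).  MSE averages the squared error over every
    (pixel, band) sample of the ROI; identical inputs report PSNR = +inf."""
    _check_pair(orig, recon)
    member = np.asarray(labels) == roi_id
    if not member.any():
        raise ValueError(f"ROI {roi_id} is empty")
    diff = orig.data[member].astype(float) - recon.data[member].astype(float)
    mse = float(np.mean(diff**2))
    if mse == 0:
        return 0.0, math.inf
    psnr = 10.0 * math.log10(orig.full_scale**2 / mse)
    return mse, psnr


def mean_spectrum(
    cube: HyperCube, labels: np.ndarray, roi_id: int | None = None
) -> np.ndarray:
    """Per-band mean over one ROI (``roi_id``) or over all ROI pixels
    (``roi_id=None``)."""
    labels = np.asarray(labels)
    member = labels > 0 if roi_id is None else labels == roi_id
    if not member.any():
        raise ValueError("empty pixel selection")
    return cube.data[member].astype(float).mean(axis=0)


def spectral_index(
    spectrum: np.ndarray,
    wavelengths: np.ndarray,
    index: str,
    scale: float = 1.0,
) -> float:
    """Evaluate TVI or DD on one spectrum.

    ``scale`` maps DN to reflectance (pass the cube's full scale 2^n - 1
    for raw counts; 1.0 if the spectrum is already in [0, 1]).  Errors if
    any required anchor wavelength is farther than 10 nm from every band.
    """
    if index not in INDEX_ANCHORS:
        raise ValueError(f"unknown spectral index {index!r}")
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)

    def rx(nm: float) -> float:
        k = nearest_band(wavelengths, nm)
        if abs(wavelengths[k] - nm) > 10.0:
            raise ValueError(
                f"no band within 10 nm of required {nm} nm anchor "
                f"(nearest is {wavelengths[k]:.1f} nm)"
            )
        return spectrum[k] / scale

    if index == "TVI":
        return 0.5 * (120.0 * (rx(750) - rx(550)) - 200.0 * (rx(670) - rx(550)))
    return (rx(750) - rx(720)) - (rx(700) - rx(670))


def index_rmse(
    orig: HyperCube,
    recon: HyperCube,
    labels: np.ndarray,
    index: str,
    roi_id: int | None = None,
    per_pixel: bool = True,
) -> float:
    """RMSE of a spectral index between original and reconstruction.

    Default is the per-pixel convention: the index is evaluated on each
    selected pixel's spectrum in both cubes and the RMSE of the per-pixel
    differences is returned (the stricter choice; it reduces to the
    mean-spectrum convention when the ROI is homogeneous).
    ``per_pixel=False`` compares indices of the ROI mean spectra instead.
    """
    _check_pair(orig, recon)
    labels = np.asarray(labels)
    member = labels > 0 if roi_id is None else labels == roi_id
    if not member.any():
        raise ValueError("empty pixel selection")
    scale = float(orig.full_scale)
    wl = orig.wavelengths

    if not per_pixel:
        a = spectral_index(mean_spectrum(orig, labels, roi_id), wl, index, scale)
        b = spectral_index(mean_spectrum(recon, labels, roi_id), wl, index, scale)
        return abs(a - b)

    # vectorized per-pixel evaluation
    anchors = INDEX_ANCHORS[index]
    idx = {}
    for nm in anchors:
        k = nearest_band(wl, nm)
        if abs(wl[k] - nm) > 10.0:
            raise ValueError(
                f"no band within 10 nm of required {nm} nm anchor"
            )
        idx[nm] = k

    def evaluate(cube: HyperCube) -> np.ndarray:
        px = cube.data[member].astype(float) / scale
        r = {nm: px[:, k] for nm, k in idx.items()}
        if index == "TVI":
            return 0.5 * (
                120.0 * (r[750.0] - r[550.0]) - 200.0 * (r[670.0] - r[550.0])
            )
        return (r[750.0] - r[720.0]) - (r[700.0] - r[670.0])

    diff = evaluate(orig) - evaluate(recon)
    return float(np.sqrt(np.mean(diff**2)))
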