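"""Synthetic leaf-scene generator.

Emulates line-scan captures of detached plant leaves on a dark, spectrally
flat stage: several non-overlapping elliptical "leaves", each filled with a
vegetation-like reflectance spectrum (green bump near 550 nm, chlorophyll
absorption trough near 670 nm, logistic red-edge rise to a NIR plateau),
quantized to 12 or 16 bits with additive Gaussian sensor noise.  The
generator returns the ground-truth labeled mask alongside the cube so every
downstream stage (band selection, masking, coding, metrics) can be tested
against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hsi_io import HyperCube

__all__ = ["SceneParams", "vegetation_spectrum", "generate_leaf_scene"]


@dataclass
class SceneParams:
    """Parameters of a synthetic leaf scene.

    Defaults model a small benchtop frame: 64x64 pixels, 32 bands across the
    visible/NIR (450-950 nm), three leaves covering a minority of the frame
    on a dark background (2% of full scale), 16-bit samples, and mild sensor
    noise (sd 40 DN, about 0.06% of full scale, far below the
    leaf/background contrast).
    """

    rows: int = 64
    cols: int = 64
    bands: int = 32
    wavelength_start: float = 450.0
    wavelength_end: float = 950.0
    n_leaves: int = 3
    background_level: float = 0.02
    noise_sigma: float = 40.0
    bit_depth: int = 16
    rng_seed: int = 0
    # reflectance-spectrum shape; per-leaf jitter is applied around these
    peak_nir: float = 0.55
    trough_vis: float = 0.08
    red_edge_center: float = 715.0
    red_edge_width: float = 12.0
    boundary_wobble: float = 0.0  # sinusoidal radius perturbation, fraction of radius
    max_placement_tries: int = 200
    per_band_noise_sigma: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.background_level < 1):
            raise ValueError("background_level must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.bands)


def vegetation_spectrum(
    wavelengths: np.ndarray,
    peak_nir: float = 0.55,
    trough_vis: float = 0.08,
    red_edge_center: float = 715.0,
    red_edge_width: float = 12.0,
    green_bump: float = 0.06,
) -> np.ndarray:
    """Vegetation-like reflectance in [0, 1].

    A logistic red edge,
    ``refl = trough + (peak - trough) * sigmoid((lam - center) / width)``,
    plus a Gaussian green bump centred at 550 nm (sd 30 nm).  This places
    meaningful reflectance values at the 550/670/700/720/750 nm anchors of
    the TVI and DD indices: a low chlorophyll-absorption trough at 670 nm, a
    steep rise through 700-720 nm, and a NIR plateau at 750 nm.
    """
    if not (0 <= trough_vis < peak_nir <= 1):
        raise ValueError(
            f"need 0 <= trough_vis < peak_nir <= 1, got {trough_vis}, {peak_nir}"
        )
    lam = np.asarray(wavelengths, dtype=float)
    if red_edge_width == 0:
        sig = (lam >= red_edge_center).astype(float)
        sig[lam == red_edge_center] = 0.5
    else:
        sig = 1.0 / (1.0 + np.exp(-(lam - red_edge_center) / red_edge_width))
    refl = trough_vis + (peak_nir - trough_vis) * sig
    refl = refl + green_bump * np.exp(-0.5 * ((lam - 550.0) / 30.0) ** 2)
    return np.clip(refl, 0.0, 1.0)


def _ellipse_mask(
    rows: int,
    cols: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    theta: float,
    wobble: float,
    phase: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    radius = np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)
    if wobble > 0:
        ang = np.arctan2(v, u)
        radius = radius / (1.0 + wobble * np.sin(4 * ang + phase))
    return radius <= 1.0


def generate_leaf_scene(params: SceneParams) -> tuple[HyperCube, np.ndarray]:
    """Generate a leaf scene and its ground-truth labeled mask.

    Leaves are rotated ellipses (optionally with a sinusoidal boundary
    perturbation making them non-convex), placed without overlap and fully
    inside the frame; each leaf's spectrum gets mild multiplicative jitter.
    The returned mask labels leaves 1..n in row-major first-occurrence order
    (left to right, top to bottom), the same order the mask pipeline uses.
    """
    rng = np.random.default_rng(params.rng_seed)
    rows, cols, bands = params.rows, params.cols, params.bands
    wavelengths = params.wavelengths
    full_scale = (1 << params.bit_depth) - 1

    leaf_masks: list[np.ndarray] = []
    occupied = np.zeros((rows, cols), dtype=bool)
    for _ in range(params.n_leaves):
        placed = False
        for _try in range(params.max_placement_tries):
            a = rng.uniform(0.13, 0.19) * min(rows, cols)
            b = rng.uniform(0.6, 0.9) * a
            theta = rng.uniform(0, np.pi)
            margin = a + 2
            if 2 * margin >= min(rows, cols):
                continue
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            mask = _ellipse_mask(
                rows, cols, (cr, cc), (a, b), theta,
                params.boundary_wobble, rng.uniform(0, 2 * np.pi),
            )
            # one-pixel dilation gap keeps leaves 8-disconnected from each other
            grown = np.zeros_like(mask)
            grown[:, :] = mask
            pad = np.pad(mask, 1)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    grown |= pad[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
            if mask.sum() >= 16 and not (grown & occupied).any():
                leaf_masks.append(mask)
                occupied |= grown
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {params.n_leaves} non-overlapping leaves in a "
                f"{rows}x{cols} frame after {params.max_placement_tries} tries"
            )

    # label in row-major first-occurrence order
    order = np.argsort([int(np.flatnonzero(m.ravel())[0]) for m in leaf_masks])
    labels = np.zeros((rows, cols), dtype=np.int32)
    for new_id, k in enumerate(order, start=1):
        labels[leaf_masks[k]] = new_id

    scene = np.full(
        (rows, cols, bands), params.background_level * full_scale, dtype=float
    )
    for new_id, k in enumerate(order, start=1):
        jitter = rng.uniform(0.92, 1.08)
        refl = vegetation_spectrum(
            wavelengths,
            peak_nir=min(params.peak_nir * jitter, 1.0),
            trough_vis=params.trough_vis * rng.uniform(0.85, 1.15),
            red_edge_center=params.red_edge_center + rng.uniform(-5, 5),
            red_edge_width=params.red_edge_width,
        )
        scene[leaf_masks[k]] = refl * full_scale

    if params.per_band_noise_sigma is not None:
        sig = np.asarray(params.per_band_noise_sigma, dtype=float)
        if sig.shape != (bands,):
            raise ValueError("per_band_noise_sigma length must equal band count")
        scene += rng.standard_normal(scene.shape) * sig
    elif params.noise_sigma > 0:
        scene += rng.standard_normal(scene.shape) * params.noise_sigma

    data = np.clip(np.rint(scene), 0, full_scale).astype(
        np.uint16 if params.bit_depth <= 16 else np.uint32
    )
    cube = HyperCube(data=data, wavelengths=wavelengths, bit_depth=params.bit_depth)
    return cube, labels
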