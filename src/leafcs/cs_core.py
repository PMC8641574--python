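"""Compressive-sensing core: ROI block partition, zigzag expansion, Gaussian
measurement, DCT sparse basis, sensing-matrix composition, and staged
orthogonal matching pursuit (StOMP) recovery.

Each arbitrary-shape ROI is tiled by 2x2 spatial blocks anchored to an even
grid at the ROI's bounding-box origin.  A block's samples across all bands
are expanded into one vector of length N = 4 * bands (zigzag within the
block, band by band), measured as Y = Phi @ x with an iid Gaussian matrix
Phi of shape M x N, M = ceil(R * N) for sampling rate R = M/N, and recovered
by StOMP against the sensing matrix A = Phi @ Psi where Psi is the
orthonormal DCT basis.  Non-ROI pixels inside a boundary block are mean-filled
before measurement and never written back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hsi_io import HyperCube

__all__ = [
    "RoiBlockSet",
    "MeasurementOp",
    "StompParams",
    "partition_roi_blocks",
    "expand_block",
    "inverse_expand_block",
    "make_gaussian_matrix",
    "measurements_count",
    "make_dct_basis",
    "compose_sensing",
    "measure",
    "stomp_recover",
]

BLOCK_SIZE = 2
# zigzag visiting order of a 2x2 block: (0,0),(0,1),(1,0),(1,1)
_ZIGZAG = [(0, 0), (0, 1), (1, 0), (1, 1)]


@dataclass
class RoiBlockSet:
    """The 2x2 spatial tiling of one ROI.

    ``anchors[b]`` is the (row, col) of block b's top-left pixel;
    ``valid[b]`` holds four booleans in zigzag order marking which of the
    block's pixels belong to the ROI (pixels outside the image frame are
    invalid too).  Every ROI pixel is covered by exactly one block and every
    block has at least one valid pixel.
    """

    roi_id: int
    anchors: np.ndarray  # (n_blocks, 2) int
    valid: np.ndarray  # (n_blocks, 4) bool
    block_size: int = BLOCK_SIZE

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=int).reshape(-1, 2)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1, 4)
        if len(self.anchors) != len(self.valid):
            raise ValueError("anchors and valid flags must align")
        if len(self.valid) and not self.valid.any(axis=1).all():
            raise ValueError("every block must contain at least one ROI pixel")

    @property
    def n_blocks(self) -> int:
        return len(self.anchors)


@dataclass
class MeasurementOp:
    """Gaussian measurement operator Phi (M x N, iid N(0, 1/M) entries)."""

    phi: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        m, n = self.phi.shape
        if not 0 < m < n:
            raise ValueError(f"need 0 < M < N, got M={m}, N={n}")

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.phi.shape[1]

    @property
    def rate(self) -> float:
        """Realized sampling rate R = M/N."""
        return self.m / self.n


@dataclass
class StompParams:
    """StOMP tuning: threshold multiplier t, max stages S, relative residual
    tolerance.  Defaults follow the algorithm's recommended range."""

    threshold: float = 2.5
    max_stages: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold multiplier must be > 0")
        if self.max_stages < 1:
            raise ValueError("max_stages must be >= 1")


def partition_roi_blocks(labels: np.ndarray, roi_id: int) -> RoiBlockSet:
    """Tile one ROI with 2x2 blocks.

    Blocks are cells of the even grid anchored at the ROI's bounding-box
    origin; cells containing at least one ROI pixel are kept, with valid
    flags marking ROI membership in zigzag order.
    """
    labels = np.asarray(labels)
    member = labels == roi_id
    if not member.any():
        raise ValueError(f"ROI id {roi_id} not present in labeled mask")
    rows_idx, cols_idx = np.nonzero(member)
    r0, c0 = rows_idx.min(), cols_idx.min()
    nrows, ncols = labels.shape

    anchors = []
    valid = []
    for ar in range(r0, rows_idx.max() + 1, BLOCK_SIZE):
        for ac in range(c0, cols_idx.max() + 1, BLOCK_SIZE):
            flags = []
            for dr, dc in _ZIGZAG:
                rr, cc = ar + dr, ac + dc
                flags.append(
                    rr < nrows and cc < ncols and bool(member[rr, cc])
                )
            if any(flags):
                anchors.append((ar, ac))
                valid.append(flags)
    return RoiBlockSet(roi_id=roi_id, anchors=np.array(anchors), valid=np.array(valid))


def expand_block(
    cube: HyperCube,
    anchor: tuple[int, int],
    valid: np.ndarray,
    fill_rule: str = "mean",
) -> np.ndarray:
    """Expand one 2x2 block into a 1-D vector of length 4 * bands.

    For each band in ascending order the block's four pixels are emitted in
    zigzag order; invalid (non-ROI or out-of-frame) slots are filled with
    the mean of the block's valid pixels in that band (``fill_rule="mean"``)
    or with zero (``"zero"``).
    """
    if fill_rule not in ("mean", "zero"):
        raise ValueError(f"unknown fill rule {fill_rule!r}")
    valid = np.asarray(valid, dtype=bool)
    rows, cols, bands = cube.shape
    ar, ac = anchor
    vec = np.zeros(4 * bands)
    vals = np.zeros((4, bands))
    for slot, (dr, dc) in enumerate(_ZIGZAG):
        rr, cc = ar + dr, ac + dc
        if valid[slot]:
            vals[slot] = cube.data[rr, cc, :]
    if fill_rule == "mean" and not valid.all():
        band_means = vals[valid].mean(axis=0)
        vals[~valid] = band_means
    vec = vals.T.ravel()  # band-major: 4 zigzag slots per band
    return vec


def inverse_expand_block(
    vec: np.ndarray,
    anchor: tuple[int, int],
    valid: np.ndarray,
    cube_out: HyperCube,
) -> None:
    """Write a recovered expansion vector back into ``cube_out`` in place.

    Only valid pixels are written; values are rounded to the nearest integer
    and clipped to the cube's [0, 2**n - 1] range.
    """
    vec = np.asarray(vec, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    bands = cube_out.shape[2]
    if vec.size != 4 * bands:
        raise ValueError(
            f"expansion vector length {vec.size} != 4 x {bands} bands"
        )
    vals = vec.reshape(bands, 4).T  # (slot, band)
    clipped = np.clip(np.rint(vals), 0, cube_out.full_scale)
    ar, ac = anchor
    for slot, (dr, dc) in enumerate(_ZIGZAG):
        if valid[slot]:
            cube_out.data[ar + dr, ac + dc, :] = clipped[slot].astype(
                cube_out.data.dtype
            )


def make_gaussian_matrix(m: int, n: int, seed: int) -> MeasurementOp:
    """Seeded random Gaussian measurement matrix, entries iid N(0, 1/M)."""
    if not 0 < m < n:
        raise ValueError(f"need 0 < M < N, got M={m}, N={n}")
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((m, n)) / math.sqrt(m)
    return MeasurementOp(phi=phi, seed=seed)


def measurements_count(rate: float, n: int) -> int:
    """M = ceil(R * N), at least 1, for sampling rate R in (0, 1)."""
    if not 0 < rate < 1:
        raise ValueError(f"sampling rate must be in (0, 1), got {rate}")
    return max(1, math.ceil(rate * n))


def make_dct_basis(n: int) -> np.ndarray:
    """Orthonormal N x N DCT-II matrix Psi.

    Row 0 is 1/sqrt(N); row r >= 1, column c is
    sqrt(2/N) * cos((2c + 1) * r * pi / (2N)).
    """
    if n < 1:
        raise ValueError(f"basis size must be >= 1, got {n}")
    r = np.arange(n)[:, None]
    c = np.arange(n)[None, :]
    psi = math.sqrt(2.0 / n) * np.cos((2 * c + 1) * r * np.pi / (2 * n))
    psi[0, :] = 1.0 / math.sqrt(n)
    return psi


def compose_sensing(phi: MeasurementOp | np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Sensing matrix A = Phi @ Psi."""
    mat = phi.phi if isinstance(phi, MeasurementOp) else np.asarray(phi)
    if mat.shape[1] != psi.shape[0]:
        raise ValueError(
            f"cannot compose {mat.shape} measurement with {psi.shape} basis"
        )
    return mat @ psi


def measure(phi: MeasurementOp | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Sample an expansion vector: Y = Phi @ x."""
    mat = phi.phi if isinstance(phi, MeasurementOp) else np.asarray(phi)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != mat.shape[1]:
        raise ValueError(f"vector length {x.size} != N = {mat.shape[1]}")
    return mat @ x


def stomp_recover(
    a: np.ndarray,
    y: np.ndarray,
    params: StompParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Staged orthogonal matching pursuit.

    At each stage the residual is correlated against the (internally
    column-normalized) sensing matrix; every atom whose correlation
    magnitude exceeds ``t * sigma`` with ``sigma = ||r|| / sqrt(M)`` joins
    the support, the coefficients on the support are refit by least
    squares, and the residual is updated.  Stops when a stage selects
    nothing new, the relative residual falls below tolerance, the support
    reaches M atoms (a batch that would overshoot is truncated to its
    strongest atoms), or the stage budget S is exhausted.

    The threshold is deliberately conservative: an atom can only be
    selected if its correlation exceeds ``t / sqrt(M)`` of the residual
    norm, so for very small M (below about t**2 measurements) no atom can
    ever qualify and the recovery is the zero vector.

    Returns ``(s, y_hat)``: the sparse coefficient vector (zeros off the
    support) and its image ``A @ s`` for residual inspection.  The signal
    estimate is ``Psi @ s``, formed by the caller who holds the basis.
    """
    if params is None:
        params = StompParams()
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, n = a.shape
    if y.size != m:
        raise ValueError(f"measurement length {y.size} != M = {m}")

    s = np.zeros(n)
    ynorm = np.linalg.norm(y)
    if ynorm == 0:
        return s, np.zeros(m)

    col_norms = np.linalg.norm(a, axis=0)
    col_norms[col_norms == 0] = 1.0
    a_unit = a / col_norms

    support: list[int] = []
    in_support = np.zeros(n, dtype=bool)
    r = y.copy()
    coef = np.zeros(0)

    for _stage in range(params.max_stages):
        c = a_unit.T @ r
        sigma = np.linalg.norm(r) / math.sqrt(m)
        new = np.flatnonzero((np.abs(c) > params.threshold * sigma) & ~in_support)
        if new.size == 0:
            break
        room = m - len(support)
        if room <= 0:
            break
        if new.size > room:
            new = new[np.argsort(np.abs(c[new]))[::-1][:room]]
        support.extend(int(j) for j in new)
        in_support[new] = True
        sub = a[:, support]
        coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
        r = y - sub @ coef
        if np.linalg.norm(r) / ynorm < params.tol:
            break
        if len(support) >= m:
            break

    if support:
        s[support] = coef
        # prune numerically-zero coefficients left by the least-squares refit
        tiny = 1e-10 * np.max(np.abs(s))
        s[np.abs(s) <= tiny] = 0.0
    return s, a @ s
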