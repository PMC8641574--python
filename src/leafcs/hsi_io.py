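"""Hyperspectral cube I/O: ENVI header/raster pairs, the ``.hcs`` compressed
container, and false-color composites.

A cube is stored as an ENVI text header (``*.hdr``) next to a raw binary
raster.  Only unsigned-integer sample types are supported; 12-bit data are
stored in 16-bit words with the logical depth carried in a ``bit depth``
header key.  The compressed container is a single file holding a JSON text
header (dimensions, wavelengths, run-length-encoded labeled mask, per-ROI
sampling parameters and measurement-matrix seeds) followed by raw
little-endian float32 measurement vectors, so the compressed size is
directly auditable.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperCube",
    "RoiCode",
    "CompressedScene",
    "read_envi_cube",
    "write_envi_cube",
    "read_compressed",
    "write_compressed",
    "false_color",
    "nearest_band",
    "mask_to_rle",
    "rle_to_mask",
]

# ENVI numeric data-type codes for unsigned integers -> numpy dtypes
_ENVI_UINT_DTYPES = {1: np.uint8, 12: np.uint16, 13: np.uint32}
_DTYPE_TO_ENVI = {np.dtype(v).name: k for k, v in _ENVI_UINT_DTYPES.items()}

_HCS_MAGIC = b"HCSLEAF1"


@dataclass
class HyperCube:
    """A hyperspectral image: ``data[row, col, band]`` of unsigned integers.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Raw digital numbers (DN), non-negative integers.
    wavelengths : ndarray, shape (bands,)
        Band-center wavelengths in nanometres, strictly increasing.
    bit_depth : int
        Bits per sample ``n``; all values must lie in ``[0, 2**n - 1]``.
        May be smaller than the storage word (e.g. 12-bit data in uint16).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        rows, cols, bands = self.data.shape
        if min(rows, cols, bands) < 1:
            raise ValueError("cube dimensions must all be >= 1")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"cube data must be integer, got {self.data.dtype}")
        if self.wavelengths.shape != (bands,):
            raise ValueError(
                f"wavelength count {self.wavelengths.size} != band count {bands}"
            )
        if bands > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        full_scale = (1 << self.bit_depth) - 1
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < 0 or hi > full_scale:
            raise ValueError(
                f"data range [{lo}, {hi}] outside [0, {full_scale}] "
                f"for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def full_scale(self) -> int:
        """Largest representable DN, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1


@dataclass
class RoiCode:
    """Compressed representation of one ROI.

    ``measurements`` holds one length-``m`` vector per block, in the
    deterministic block-partition order of :func:`leafcs.cs_core.partition_roi_blocks`.
    """

    roi_id: int
    rate: float
    m: int
    n: int
    seed: int
    measurements: np.ndarray  # (n_blocks, m) float32

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=np.float32)
        if self.measurements.ndim != 2 or self.measurements.shape[1] != self.m:
            raise ValueError(
                f"ROI {self.roi_id}: measurement block shape "
                f"{self.measurements.shape} inconsistent with M={self.m}"
            )


@dataclass
class CompressedScene:
    """Everything needed to reconstruct: header metadata plus per-ROI payload."""

    rows: int
    cols: int
    bands: int
    wavelengths: np.ndarray
    bit_depth: int
    labels: np.ndarray  # labeled mask, 0 = background
    rois: dict[int, RoiCode] = field(default_factory=dict)
    block_size: int = 2
    expansion_order: str = "zigzag-band-major"
    fill_rule: str = "mean"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.rows, self.cols):
            raise ValueError("labeled mask shape does not match scene dimensions")
        for rid in self.rois:
            if not np.any(self.labels == rid):
                raise ValueError(f"payload ROI {rid} absent from labeled mask")

    @property
    def n_measurements(self) -> int:
        return sum(r.measurements.size for r in self.rois.values())


# ---------------------------------------------------------------------------
# ENVI reader / writer


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI's ``key = value`` header grammar, including {...} lists."""
    fields: dict[str, str] = {}
    # strip the leading "ENVI" magic line if present
    body = text
    key = None
    buf = ""
    in_braces = False
    for raw in body.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI" or line.startswith(";"):
            continue
        if in_braces:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and "}" not in value:
            buf = value
            in_braces = True
        else:
            fields[key] = value
    return fields


def _parse_brace_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/raster pair into a :class:`HyperCube`.

    Supports BSQ, BIL and BIP interleaves and unsigned-integer sample types
    (ENVI data types 1, 12, 13).  Wavelengths must be present in the header.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required key: {exc.args[0]!r}") from None

    if dtype_code not in _ENVI_UINT_DTYPES:
        raise ValueError(
            f"unsupported ENVI data type {dtype_code}; only unsigned integer "
            f"types {sorted(_ENVI_UINT_DTYPES)} are supported"
        )
    dtype = np.dtype(_ENVI_UINT_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) != 0:
        dtype = dtype.newbyteorder(">")

    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required key: 'wavelength'")
    wavelengths = np.array(_parse_brace_list(fields["wavelength"]))
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )

    interleave = fields.get("interleave", "bsq").lower()
    data_path = header_path.with_suffix("")
    if not data_path.exists():
        data_path = header_path.with_suffix(".img")
    if not data_path.exists():
        raise FileNotFoundError(f"raster file for {header_path} not found")

    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"raster holds {raw.size} samples, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    bit_depth = int(fields.get("bit depth", dtype.itemsize * 8))
    return HyperCube(
        data=np.ascontiguousarray(data.astype(dtype.newbyteorder("="))),
        wavelengths=wavelengths,
        bit_depth=bit_depth,
    )


def write_envi_cube(cube: HyperCube, header_path: str | Path) -> Path:
    """Write a cube as a BSQ ENVI pair; returns the header path.

    Round-trips bit-exactly with :func:`read_envi_cube`.
    """
    cube.validate()
    header_path = Path(header_path)
    data_path = header_path.with_suffix(".img")

    storage = np.uint8 if cube.bit_depth <= 8 else (
        np.uint16 if cube.bit_depth <= 16 else np.uint32
    )
    data = cube.data.astype(storage)
    rows, cols, bands = data.shape
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[np.dtype(storage).name]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"bit depth = {cube.bit_depth}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    header_path.write_text(header)
    data.transpose(2, 0, 1).tofile(data_path)
    return header_path


# ---------------------------------------------------------------------------
# Compressed container (.hcs)


def mask_to_rle(labels: np.ndarray) -> list[list[int]]:
    """Row-major run-length encoding: list of ``[label, run]`` pairs."""
    flat = np.asarray(labels).ravel()
    if flat.size == 0:
        return []
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [flat.size]))
    return [[int(flat[s]), int(e - s)] for s, e in zip(starts, ends)]


def rle_to_mask(rle: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    total = shape[0] * shape[1]
    out = np.empty(total, dtype=np.int32)
    pos = 0
    for label, run in rle:
        out[pos : pos + run] = label
        pos += run
    if pos != total:
        raise ValueError(f"RLE decodes to {pos} pixels, expected {total}")
    return out.reshape(shape)


def write_compressed(scene: CompressedScene, path: str | Path) -> Path:
    """Serialize a :class:`CompressedScene` to a single ``.hcs`` file."""
    path = Path(path)
    roi_meta = []
    payload_parts = []
    for rid in sorted(scene.rois):
        roi = scene.rois[rid]
        roi_meta.append(
            {
                "roi_id": roi.roi_id,
                "rate": roi.rate,
                "m": roi.m,
                "n": roi.n,
                "seed": roi.seed,
                "n_blocks": int(roi.measurements.shape[0]),
            }
        )
        payload_parts.append(
            np.ascontiguousarray(roi.measurements, dtype="<f4").tobytes()
        )
    header = {
        "rows": scene.rows,
        "cols": scene.cols,
        "bands": scene.bands,
        "wavelengths": [float(w) for w in scene.wavelengths],
        "bit_depth": scene.bit_depth,
        "block_size": scene.block_size,
        "expansion_order": scene.expansion_order,
        "fill_rule": scene.fill_rule,
        "mask_rle": mask_to_rle(scene.labels),
        "rois": roi_meta,
    }
    header_bytes = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_HCS_MAGIC)
        fh.write(struct.pack("<I", len(header_bytes)))
        fh.write(header_bytes)
        for part in payload_parts:
            fh.write(part)
    return path


def read_compressed(path: str | Path) -> CompressedScene:
    """Read a ``.hcs`` file back into a :class:`CompressedScene`."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_HCS_MAGIC))
        if magic != _HCS_MAGIC:
            raise ValueError(f"{path}: not an .hcs container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode())
        rois: dict[int, RoiCode] = {}
        for meta in header["rois"]:
            count = meta["n_blocks"] * meta["m"]
            raw = fh.read(count * 4)
            if len(raw) != count * 4:
                raise ValueError(
                    f"truncated payload for ROI {meta['roi_id']}: expected "
                    f"{count} float32 values ({meta['n_blocks']} blocks x M="
                    f"{meta['m']}), got {len(raw) // 4}"
                )
            meas = np.frombuffer(raw, dtype="<f4").reshape(meta["n_blocks"], meta["m"])
            rois[meta["roi_id"]] = RoiCode(
                roi_id=meta["roi_id"],
                rate=meta["rate"],
                m=meta["m"],
                n=meta["n"],
                seed=meta["seed"],
                measurements=meas,
            )
        trailing = fh.read(1)
        if trailing:
            raise ValueError("trailing bytes after declared payload")
    labels = rle_to_mask(header["mask_rle"], (header["rows"], header["cols"]))
    return CompressedScene(
        rows=header["rows"],
        cols=header["cols"],
        bands=header["bands"],
        wavelengths=np.array(header["wavelengths"]),
        bit_depth=header["bit_depth"],
        labels=labels,
        rois=rois,
        block_size=header["block_size"],
        expansion_order=header["expansion_order"],
        fill_rule=header["fill_rule"],
    )


# ---------------------------------------------------------------------------
# False color


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties break to the lower wavelength."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    dist = np.abs(wavelengths - target_nm)
    return int(np.argmin(dist))  # argmin returns first (lower-λ) index on ties


def false_color(
    cube: HyperCube, r_nm: float, g_nm: float, b_nm: float
) -> np.ndarray:
    """Build an RGB composite from the nearest bands to the requested
    wavelengths, each channel rescaled to [0, 1] by the cube's full scale."""
    lo, hi = cube.wavelengths[0], cube.wavelengths[-1]
    for nm in (r_nm, g_nm, b_nm):
        if not (lo <= nm <= hi):
            raise ValueError(
                f"requested wavelength {nm} nm outside cube range [{lo}, {hi}] nm"
            )
    idx = [nearest_band(cube.wavelengths, nm) for nm in (r_nm, g_nm, b_nm)]
    img = cube.data[:, :, idx].astype(float) / cube.full_scale
    return img
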