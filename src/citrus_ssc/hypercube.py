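"""Hyperspectral cube data model, reflectance calibration, and ENVI-style I/O.

A line-scan VNIR camera produces a cube of raw intensities with axes
(scan line, cross-track pixel, spectral band).  Raw counts are converted to
relative reflectance against a diffuse white standard and a shutter-closed
dark frame:

    R_i = (I_s,i - D_i) / (I_w,i - D_i)

per band i, where I_s is the sample image, I_w the white-reference image and
D the dark-current image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "ReferenceFrame",
    "make_wavelength_grid",
    "calibrate_reflectance",
    "write_envi",
    "read_envi",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform band-center grid on the half-open interval [start_nm, stop_nm)."""

    start_nm: float
    stop_nm: float
    step_nm: float
    centers: np.ndarray

    def __len__(self) -> int:
        return len(self.centers)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))

    def __eq__(self, other) -> bool:  # dataclass eq chokes on arrays
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.stop_nm == other.stop_nm
            and self.step_nm == other.step_nm
            and np.array_equal(self.centers, other.centers)
        )


def make_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform wavelength grid; e.g. (400, 1000, 2) gives 300 bands.

    The range must divide evenly by the step (half-open convention: the stop
    wavelength itself is not a band center).
    """
    if stop_nm <= start_nm:
        raise ValueError(f"stop_nm ({stop_nm}) must exceed start_nm ({start_nm})")
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    span = stop_nm - start_nm
    n_float = span / step_nm
    n = round(n_float)
    if abs(n_float - n) > 1e-9 * max(1.0, abs(n_float)):
        raise ValueError(
            f"wavelength span {span} nm is not divisible by step {step_nm} nm "
            f"({n_float} bands is not an integer)"
        )
    centers = start_nm + step_nm * np.arange(n, dtype=float)
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), centers)


@dataclass
class HyperCube:
    """3-D spectral image with axes (line, cross-track pixel, band), 0-based.

    ``kind`` distinguishes raw camera counts from calibrated relative
    reflectance.  Reflectance cubes are finite and clipped to [0, clip_max].
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D (lines, pixels, bands), got {self.values.ndim}-D")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis length {self.values.shape[2]} does not match "
                f"grid length {len(self.grid)}"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def crop(self, lines: slice, pixels: slice) -> "HyperCube":
        """Spatial crop; the band axis is never cropped here."""
        return HyperCube(self.values[lines, pixels, :], self.grid, self.kind, dict(self.metadata))


@dataclass
class ReferenceFrame:
    """White-standard and dark-current images used in reflectance calibration.

    Frames may be 2-D (one line of (pixel, band) values, broadcast along the
    scan axis — the line-scan convention) or full 3-D cubes matching the raw
    data.  The white frame must exceed the dark frame almost everywhere.
    """

    white: np.ndarray
    dark: np.ndarray
    min_valid_fraction: float = 0.99

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError(
                f"white shape {self.white.shape} != dark shape {self.dark.shape}"
            )
        if self.white.ndim not in (2, 3):
            raise ValueError("reference frames must be 2-D (pixel, band) or 3-D cubes")
        if not np.any(self.white):
            raise ValueError("white reference frame is all zeros")
        frac = np.mean(self.white > self.dark)
        if frac < self.min_valid_fraction:
            raise ValueError(
                f"white exceeds dark on only {frac:.1%} of entries "
                f"(required {self.min_valid_fraction:.0%}) — references look swapped or corrupt"
            )


def calibrate_reflectance(
    raw: HyperCube,
    refs: ReferenceFrame,
    epsilon: float = 1e-6,
    clip_max: float = 2.0,
) -> HyperCube:
    """Convert raw counts to relative reflectance: R = (I_s - D) / (I_w - D).

    Near-zero denominators (dead pixels, |I_w - D| < epsilon in white-normalized
    units) are replaced by epsilon with sign preserved so the output stays
    finite.  Output is clipped to [0, clip_max]; specular glints can exceed 1
    but unbounded values destabilize downstream preprocessing.
    """
    if raw.kind != "raw":
        raise ValueError(f"expected a raw-kind cube, got kind={raw.kind!r}")
    white, dark = refs.white, refs.dark
    if white.ndim == 2:
        white = white[np.newaxis, :, :]
        dark = dark[np.newaxis, :, :]
    try:
        np.broadcast_shapes(raw.values.shape, white.shape)
    except ValueError as exc:
        raise ValueError(
            f"reference shape {refs.white.shape} not broadcastable to cube "
            f"shape {raw.values.shape}"
        ) from exc

    denom = white - dark
    # sign-preserving floor; exact zeros get +epsilon
    sign = np.where(denom >= 0, 1.0, -1.0)
    denom = np.where(np.abs(denom) < epsilon, sign * epsilon, denom)
    refl = (raw.values.astype(float) - dark) / denom
    refl = np.clip(refl, 0.0, clip_max)
    meta = dict(raw.metadata)
    meta["calibration"] = {"epsilon": epsilon, "clip_max": clip_max}
    return HyperCube(refl, raw.grid, kind="reflectance", metadata=meta)


# ---------------------------------------------------------------------------
# ENVI-style I/O: ASCII header + flat binary.  BIL is the line-scan default.
# ---------------------------------------------------------------------------

_DTYPE_TO_ENVI = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}

_INTERLEAVES = ("bil", "bip", "bsq")


def _to_disk_order(values: np.ndarray, interleave: str) -> np.ndarray:
    # in-memory axis order is (line, pixel, band)
    if interleave == "bip":
        return values
    if interleave == "bil":
        return values.transpose(0, 2, 1)  # (line, band, pixel)
    if interleave == "bsq":
        return values.transpose(2, 0, 1)  # (band, line, pixel)
    raise ValueError(f"unknown interleave {interleave!r}; expected one of {_INTERLEAVES}")


def _from_disk_order(flat: np.ndarray, lines: int, samples: int, bands: int, interleave: str) -> np.ndarray:
    if interleave == "bip":
        return flat.reshape(lines, samples, bands)
    if interleave == "bil":
        return flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    if interleave == "bsq":
        return flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    raise ValueError(f"unknown interleave {interleave!r}; expected one of {_INTERLEAVES}")


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bil") -> Path:
    """Write ``cube`` as ENVI-style flat binary plus ``<path>.hdr`` header.

    Reflectance cubes are stored as float32 (adequate for relative reflectance);
    raw cubes keep their recorded dtype (12-bit cameras record into uint16).
    Returns the binary path.
    """
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unknown interleave {interleave!r}; expected one of {_INTERLEAVES}")
    path = Path(path)
    values = cube.values
    if cube.kind == "reflectance":
        values = values.astype(np.float32)
    dtype = values.dtype
    if dtype not in _DTYPE_TO_ENVI:
        values = values.astype(np.float64)
        dtype = values.dtype
    lines, samples, bands = values.shape
    wl = ", ".join(f"{w:g}" for w in cube.grid.centers)
    header = (
        "ENVI\n"
        f"description = {{citrus-ssc cube, kind={cube.kind}}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength step = {cube.grid.step_nm:g}\n"
        f"wavelength stop = {cube.grid.stop_nm:g}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    Path(str(path) + ".hdr").write_text(header)
    _to_disk_order(values, interleave).astype(dtype).tofile(path)
    return path


def _parse_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # collapse {...} blocks that may span lines
    text = text.replace("\r\n", "\n")
    i = 0
    lines_out = []
    buf = ""
    in_brace = False
    for ch in text:
        if ch == "{":
            in_brace = True
        elif ch == "}":
            in_brace = False
        if ch == "\n" and in_brace:
            buf += " "
        else:
            buf += ch
    for line in buf.split("\n"):
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI-style cube written by :func:`write_envi`.

    The header's dimensions are validated against the binary size; a mismatch
    or an unknown interleave is rejected.
    """
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        data_type = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} missing required field {exc}") from exc
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unknown interleave {interleave!r}; expected one of {_INTERLEAVES}")
    if data_type not in _ENVI_TO_DTYPE:
        raise ValueError(f"unsupported ENVI data type {data_type}")
    dtype = _ENVI_TO_DTYPE[data_type]
    flat = np.fromfile(path, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise ValueError(
            f"binary {path} holds {flat.size} values but header declares "
            f"{lines}x{samples}x{bands} = {expected}"
        )
    values = _from_disk_order(flat, lines, samples, bands, interleave)

    wl_field = fields.get("wavelength", "")
    wl = np.array(
        [float(tok) for tok in wl_field.strip("{}").split(",") if tok.strip()], dtype=float
    )
    if wl.size != bands:
        raise ValueError(f"header lists {wl.size} wavelengths for {bands} bands")
    step = float(fields.get("wavelength step", wl[1] - wl[0] if wl.size > 1 else 1.0))
    stop = float(fields.get("wavelength stop", wl[-1] + step))
    grid = WavelengthGrid(float(wl[0]), stop, step, wl)
    kind = fields.get("cube kind", "raw")
    meta = {}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{}").strip()
    return HyperCube(values, grid, kind=kind, metadata=meta)
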