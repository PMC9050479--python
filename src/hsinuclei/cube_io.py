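"""Hyperspectral cube container, ENVI I/O, and transmittance calibration.

A transmitted-light hyperspectral microscope records, per pixel, the
intensity of light passing through the stained section at each of (by
default) 87 wavelength bands between 470 and 720 nm.  Raw detector counts
are converted to normalized transmittance with a white reference (blank
area of the slide) and a dark reference (blocked light path):

    T(p, lam) = (I_raw(p, lam) - I_dark(p, lam)) / (I_white(p, lam) - I_dark(p, lam))

Cubes are stored on disk in the ENVI convention: a plain-text ``.hdr``
file next to a raw binary with BSQ/BIL/BIP interleave.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_WAVELENGTHS",
    "HyperCube",
    "ReferencePair",
    "CalibrationError",
    "EnviFormatError",
    "read_envi_cube",
    "write_envi_cube",
    "calibrate_transmittance",
]

#: Band centers of the instrument emulated throughout the package:
#: 87 bands evenly spanning 470-720 nm.
DEFAULT_WAVELENGTHS = np.linspace(470.0, 720.0, 87)

#: Transmittance slightly above 1 occurs in blank regions through noise;
#: values are retained up to this ceiling, then clipped.
DEFAULT_CLIP_MAX = 1.5

# ENVI data type codes <-> numpy dtypes (the subset we read/write).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Header/binary inconsistency or unsupported ENVI dialect."""


class CalibrationError(ValueError):
    """Reference images unusable for transmittance calibration."""


@dataclass
class HyperCube:
    """A hyperspectral image cube: rows x cols x bands plus band centers.

    ``units`` is ``"raw_dn"`` for detector counts and ``"transmittance"``
    after white/dark calibration.  ``valid_mask`` (2-D bool) marks pixels
    whose calibration denominator was well defined; ``None`` means all
    pixels are valid.
    """

    data: np.ndarray
    wavelengths: np.ndarray = None  # type: ignore[assignment]
    units: str = "raw_dn"
    meta: dict = field(default_factory=dict)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) == 0:
            raise ValueError("zero-size cube")
        if self.wavelengths is None:
            if self.data.shape[2] == DEFAULT_WAVELENGTHS.size:
                self.wavelengths = DEFAULT_WAVELENGTHS.copy()
            else:
                raise ValueError("wavelengths required for non-default band count")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths for {self.data.shape[2]} bands"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.units not in ("raw_dn", "transmittance"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    def mean_spectrum(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-band mean over all (or masked) valid pixels."""
        sel = np.ones(self.data.shape[:2], dtype=bool) if mask is None else np.asarray(mask, bool)
        if self.valid_mask is not None:
            sel = sel & self.valid_mask
        if not sel.any():
            raise ValueError("empty selection")
        return self.data[sel].mean(axis=0)


@dataclass
class ReferencePair:
    """White (blank slide) and dark (blocked path) reference cubes."""

    white: HyperCube
    dark: HyperCube

    def __post_init__(self) -> None:
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references differ in shape")
        if not np.allclose(self.white.wavelengths, self.dark.wavelengths):
            raise ValueError("white and dark references differ in wavelengths")


# ---------------------------------------------------------------------------
# ENVI reading / writing
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse `key = value` lines; `{...}` values may span lines."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("missing ENVI magic line")
    body = text.split("\n", 1)[1] if "\n" in text else ""
    fields: dict[str, str] = {}
    # Brace-delimited values can contain newlines; scan manually.
    i = 0
    lines = body.split("\n")
    while i < len(lines):
        line = lines[i]
        if "=" not in line:
            i += 1
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            parts = [val]
            while i + 1 < len(lines):
                i += 1
                parts.append(lines[i])
                if "}" in lines[i]:
                    break
            val = "\n".join(parts)
        fields[key] = val.strip()
        i += 1
    return fields


def _brace_list(value: str) -> list[str]:
    inner = value.strip()
    if inner.startswith("{"):
        inner = inner[1:]
    if inner.endswith("}"):
        inner = inner[:-1]
    return [tok.strip() for tok in inner.replace("\n", ",").split(",") if tok.strip()]


def read_envi_cube(header_path: str | Path) -> HyperCube:
    """Read an ENVI ``.hdr`` + companion raw binary into a :class:`HyperCube`.

    The companion binary is the header path without its ``.hdr`` suffix,
    or with ``.raw``/``.img`` substituted.  Wavelengths are taken from the
    header (assumed nm when unlabeled); units default to ``raw_dn`` unless
    the header carries a ``units`` entry.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise EnviFormatError(f"header missing {key!r}")
    samples = int(fields["samples"])  # columns
    lines = int(fields["lines"])  # rows
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    interleave = fields["interleave"].strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise EnviFormatError(f"unsupported interleave {interleave!r}")
    byte_order = int(fields.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", "0"))

    binary = _companion_binary(header_path)
    expected = samples * lines * bands * dtype.itemsize + offset
    actual = binary.stat().st_size
    if actual != expected:
        raise EnviFormatError(
            f"binary {binary.name}: {actual} bytes, header implies {expected} "
            f"({lines}x{samples}x{bands} {dtype})"
        )
    flat = np.fromfile(binary, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)

    if "wavelength" in fields:
        wavelengths = np.array([float(v) for v in _brace_list(fields["wavelength"])])
        if wavelengths.size != bands:
            raise EnviFormatError(
                f"header lists {wavelengths.size} wavelengths for {bands} bands"
            )
    elif bands == DEFAULT_WAVELENGTHS.size:
        wavelengths = DEFAULT_WAVELENGTHS.copy()
    else:
        raise EnviFormatError("header lists no wavelengths")

    units = fields.get("units", "raw_dn").strip()
    meta = {
        k: v
        for k, v in fields.items()
        if k
        not in {
            "samples", "lines", "bands", "data type", "interleave",
            "byte order", "header offset", "wavelength", "units",
        }
    }
    valid_mask = None
    sidecar = header_path.with_suffix(".mask.json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        invalid = np.array(payload.get("invalid_pixels", []), dtype=int)
        valid_mask = np.ones((lines, samples), dtype=bool)
        if invalid.size:
            valid_mask[invalid[:, 0], invalid[:, 1]] = False
    return HyperCube(np.ascontiguousarray(data), wavelengths, units, meta, valid_mask)


def _companion_binary(header_path: Path) -> Path:
    candidates = [
        header_path.with_suffix(""),
        header_path.with_suffix(".raw"),
        header_path.with_suffix(".img"),
        header_path.with_suffix(".dat"),
    ]
    for cand in candidates:
        if cand != header_path and cand.exists():
            return cand
    raise FileNotFoundError(f"no companion binary for {header_path}")


def write_envi_cube(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> Path:
    """Write ``cube`` as ENVI header + raw binary; returns the header path.

    ``path`` may be the header path (``*.hdr``) or its stem; the binary is
    written beside it with a ``.raw`` suffix.  Round-trips are bit-exact
    for integer (raw_dn) cubes and exact to float precision otherwise.
    A non-trivial ``valid_mask`` is stored in a JSON sidecar.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    header_path = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    binary_path = header_path.with_suffix(".raw")

    data = cube.data
    dtype = np.dtype(data.dtype)
    if dtype not in _DTYPE_CODES:
        data = data.astype(np.float64)
        dtype = np.dtype(np.float64)
    rows, cols, bands = data.shape
    if interleave == "bsq":
        out = np.ascontiguousarray(data.transpose(2, 0, 1))
    elif interleave == "bil":
        out = np.ascontiguousarray(data.transpose(0, 2, 1))
    else:
        out = np.ascontiguousarray(data)
    out.astype(dtype.newbyteorder("<")).tofile(binary_path)

    lines = [
        "ENVI",
        "description = {hsinuclei hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"units = {cube.units}",
        "wavelength = {",
        ",\n".join(f" {w:.6f}" for w in cube.wavelengths),
        "}",
    ]
    header_path.write_text("\n".join(lines) + "\n")

    if cube.valid_mask is not None and not cube.valid_mask.all():
        invalid = np.argwhere(~cube.valid_mask)
        sidecar = {
            "invalid_pixels": invalid.tolist(),
            "reason": "calibration denominator white == dark",
        }
        header_path.with_suffix(".mask.json").write_text(json.dumps(sidecar))
    return header_path


# ---------------------------------------------------------------------------
# Transmittance calibration
# ---------------------------------------------------------------------------

def calibrate_transmittance(
    raw: HyperCube,
    refs: ReferencePair,
    clip_max: float = DEFAULT_CLIP_MAX,
) -> HyperCube:
    """White/dark-calibrate a raw cube to normalized transmittance.

    Per pixel p and band lam::

        T = (I_raw - I_dark) / (I_white - I_dark)

    The result is clipped to ``[0, clip_max]``.  Pixels where the white and
    dark references coincide at any band have no defined transmittance and
    are flagged invalid in ``valid_mask`` (their values are set to 0);
    downstream operations skip them.  The transform is invariant to any
    affine rescaling ``a*I + b`` (a > 0) of the detector response.
    """
    if raw.shape != refs.white.shape:
        raise ValueError(
            f"raw shape {raw.shape} does not match reference shape {refs.white.shape}"
        )
    white = refs.white.data.astype(np.float64)
    dark = refs.dark.data.astype(np.float64)
    denom = white - dark
    bad = denom == 0
    if bad.all():
        raise CalibrationError("white and dark references are identical everywhere")
    valid = ~bad.any(axis=2)
    t = (raw.data.astype(np.float64) - dark) / np.where(bad, 1.0, denom)
    t = np.clip(t, 0.0, clip_max)
    t[~valid, :] = 0.0
    if raw.valid_mask is not None:
        valid = valid & raw.valid_mask
    meta = dict(raw.meta)
    meta["calibration"] = {"clip_max": clip_max}
    return HyperCube(t, raw.wavelengths.copy(), "transmittance", meta, valid)
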