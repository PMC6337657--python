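"""Hypercube container, ENVI-style I/O, and reflectance correction.

A hyperspectral line-scan acquisition is an ``H x W x B`` array of intensities
bound to a monotone wavelength axis (nm).  Raw counts are converted to relative
reflectance with the standard black/white correction

    R = (raw - dark) / (white - dark)

applied per pixel and per band, where *white* is a reference panel scan and
*dark* is the dark-current frame (lens capped, light off).  White and dark
references may be full frames or a single scan line replicated along the
motion axis, as line-scan systems commonly store them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthAxis",
    "Hypercube",
    "ReferenceFrames",
    "read_cube",
    "write_cube",
    "reflectance_correct",
    "nearest_band",
]

# ENVI data-type codes <-> numpy dtypes (little-endian only).
_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("<i2"),
    3: np.dtype("<i4"),
    4: np.dtype("<f4"),
    5: np.dtype("<f8"),
    12: np.dtype("<u2"),
}
_DTYPE_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("wavelength axis must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if v.size > 1 and not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def nearest(self, target_nm: float) -> int:
        return nearest_band(self, target_nm)

    @classmethod
    def uniform(cls, lo: float = 400.0, hi: float = 1000.0, n: int = 477) -> "WavelengthAxis":
        return cls(np.linspace(lo, hi, n))


def nearest_band(axis: WavelengthAxis, target_nm: float) -> int:
    """Index of the band closest to ``target_nm``; ties go to the lower index."""
    # np.argmin returns the first minimum, which is the lower index on a tie.
    return int(np.argmin(np.abs(axis.values - float(target_nm))))


@dataclass
class Hypercube:
    """``H x W x B`` intensity or reflectance array bound to a wavelength axis."""

    data: np.ndarray
    axis: WavelengthAxis
    corrected: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (H, W, B); got shape {self.data.shape}")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis has {len(self.axis)}"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def band_image(self, target_nm: float) -> np.ndarray:
        """The single-band image at the band nearest ``target_nm``."""
        return self.data[:, :, nearest_band(self.axis, target_nm)]


@dataclass
class ReferenceFrames:
    """White-panel and dark-current reference frames.

    Either full ``H x W x B`` frames, or a single ``W x B`` scan line that is
    broadcast along the motion (row) axis.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        for name, a in (("white", self.white), ("dark", self.dark)):
            if a.ndim not in (2, 3):
                raise ValueError(f"{name} frame must be 2-D (line) or 3-D (frame)")
        if self.white.shape[-2:] != self.dark.shape[-2:]:
            raise ValueError("white and dark frames disagree on (W, B) shape")

    def broadcast_to(self, shape: tuple) -> tuple:
        """Return (white, dark) broadcast against a raw cube shape ``(H, W, B)``."""
        out = []
        for name, a in (("white", self.white), ("dark", self.dark)):
            if a.ndim == 2:
                if a.shape != shape[1:]:
                    raise ValueError(
                        f"line {name} frame {a.shape} incompatible with cube {shape}"
                    )
                out.append(np.broadcast_to(a[None, :, :], shape))
            else:
                if a.shape != shape:
                    raise ValueError(
                        f"{name} frame {a.shape} incompatible with cube {shape}"
                    )
                out.append(a)
        return tuple(out)


def reflectance_correct(
    raw: Hypercube,
    refs: ReferenceFrames,
    *,
    clip_negative: bool = True,
    white_dark_epsilon: float | None = None,
) -> Hypercube:
    """Black/white correction ``R = (raw - dark) / (white - dark)``.

    Positions where ``white == dark`` are an error (the correction is
    undefined there) unless ``white_dark_epsilon`` is given, in which case the
    denominator is floored at that value.  Negative results (sensor noise with
    raw < dark) are clipped to 0 by default and the clip count logged; values
    above 1 (specular pixels) are kept and flagged in the log.
    """
    white, dark = refs.broadcast_to(raw.shape)
    denom = white.astype(np.float64) - dark.astype(np.float64)
    bad = denom <= 0
    if bad.any():
        if white_dark_epsilon is None:
            bands = np.unique(np.nonzero(bad)[2]) + 1  # 1-based for reporting
            raise ValueError(
                "white <= dark at some positions; offending band(s) "
                f"(1-based): {bands.tolist()[:20]}"
            )
        denom = np.maximum(denom, float(white_dark_epsilon))
    out = (raw.data.astype(np.float64) - dark) / denom
    n_clipped = 0
    if clip_negative:
        neg = out < 0
        n_clipped = int(neg.sum())
        if n_clipped:
            out[neg] = 0.0
            logger.info("reflectance_correct: clipped %d negative values to 0", n_clipped)
    n_over = int((out > 1).sum())
    if n_over:
        logger.info("reflectance_correct: %d values > 1 kept (specular pixels)", n_over)
    cube = Hypercube(out.astype(np.float32), raw.axis, corrected=True)
    cube.clip_count = n_clipped
    cube.over_unity_count = n_over
    return cube


# ---------------------------------------------------------------------------
# Minimal ENVI header + flat-binary I/O (BIL / BIP / BSQ, little-endian)
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    """Parse `key = value` pairs; `{...}` values may span lines."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict = {}
    # Strip the magic line, then match either braced or scalar values.
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            items = [s.strip() for s in val[1:-1].replace("\n", " ").split(",")]
            fields[key] = [s for s in items if s]
        else:
            fields[key] = val
    return fields


def read_cube(header_path, data_path=None) -> Hypercube:
    """Read an ENVI-style cube (header + flat binary) into a :class:`Hypercube`.

    The header must declare ``samples``, ``lines``, ``bands``, ``data type``,
    ``interleave`` and a ``wavelength`` list whose length equals ``bands``.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = str(fields["interleave"]).strip().lower()
    except KeyError as e:
        raise ValueError(f"ENVI header missing required field: {e}") from None
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength list")
    wavelengths = np.array([float(w) for w in fields["wavelength"]])
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but {wavelengths.size} wavelengths"
        )
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order = 0) is supported")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]

    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    data_path = Path(data_path)
    expected = samples * lines * bands * dtype.itemsize
    actual = data_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"data file size {actual} B does not match header "
            f"({lines}x{samples}x{bands} {dtype.name} = {expected} B)"
        )
    flat = np.fromfile(data_path, dtype=dtype)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    return Hypercube(np.ascontiguousarray(data), WavelengthAxis(wavelengths))


def write_cube(cube: Hypercube, header_path, data_path=None, interleave: str = "bsq") -> None:
    """Write a :class:`Hypercube` as an ENVI header + flat little-endian binary."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    data = np.asarray(cube.data)
    dtype = data.dtype.newbyteorder("<")
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype("<f4")
    H, W, B = data.shape
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out, dtype=dtype).tofile(data_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.axis.values)
    header_path.write_text(
        "ENVI\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
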