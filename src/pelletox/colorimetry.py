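"""sRGB decoding, CIE XYZ conversion and the ASTM E313 yellowness index.

The yellowness index (YI) quantifies the departure of a color from a
neutral white toward yellow (positive) or blue (negative):

    YI = 100 * (Cx * X - Cz * Z) / Y

where (X, Y, Z) are CIE tristimulus values on the 0-100 scale and the
coefficients Cx, Cz depend on the illuminant and standard observer.  The
coefficients are constructed so that the reference white of the matched
illuminant/observer pair scores exactly zero; YI is homogeneous of degree
zero in (X, Y, Z), i.e. invariant to overall luminance scaling.

Input colors are 8-bit sRGB (the encoding of consumer-camera JPEG/PNG
photographs); they are linearized with the IEC 61966-2-1 transfer function
and mapped to XYZ through the matrix derived from the sRGB primaries and
the chosen white point, so that RGB white maps exactly onto the reference
white.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "RGB8Color",
    "XYZTristimulus",
    "IlluminantObserver",
    "get_illuminant_observer",
    "ILLUMINANT_OBSERVERS",
    "decode_srgb_component",
    "linearize_rgb",
    "rgb_to_xyz",
    "yellowness_index",
    "yellowness_of_rgb",
    "YI_STANDARD_NAME",
]

#: Name of the colorimetric standard whose index formula is implemented;
#: recorded in all tabular outputs.
YI_STANDARD_NAME = "ASTM E313"

# sRGB primary chromaticities (IEC 61966-2-1 / ITU-R BT.709).
_SRGB_PRIMARIES_XY = np.array(
    [[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]], dtype=float
)


@dataclass(frozen=True)
class RGB8Color:
    """An 8-bit sRGB color; each channel an integer in [0, 255]."""

    r: int
    g: int
    b: int

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 255):
                raise ValueError(
                    f"channel {name}={v!r} must be an integer in [0, 255]"
                )

    def as_tuple(self) -> tuple[int, int, int]:
        return (int(self.r), int(self.g), int(self.b))


@dataclass(frozen=True)
class XYZTristimulus:
    """CIE 1931 tristimulus values on the 0-100 scale (Y=100 = reference white)."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0 or self.Z < 0:
            raise ValueError("tristimulus values must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)


@dataclass(frozen=True)
class IlluminantObserver:
    """An illuminant/observer pair with its white point and YI coefficients.

    The coefficients must neutralize the reference white:
    |Cx*Xw - Cz*Zw| / Yw < 1e-3, so neutral grays score ~0.
    """

    name: str
    white_point: XYZTristimulus
    c_x: float
    c_z: float

    def __post_init__(self) -> None:
        w = self.white_point
        residual = abs(self.c_x * w.X - self.c_z * w.Z) / w.Y
        if residual >= 1e-3:
            raise ValueError(
                f"{self.name}: coefficients do not neutralize the reference "
                f"white (residual {residual:.2e} >= 1e-3)"
            )


# White points from the CIE standard illuminant tables (0-100 scale) and
# Cx/Cz from the ASTM E313 coefficient table.
ILLUMINANT_OBSERVERS: dict[str, IlluminantObserver] = {
    "D65/2": IlluminantObserver(
        "D65/2", XYZTristimulus(95.047, 100.0, 108.883), 1.2985, 1.1335
    ),
    "D65/10": IlluminantObserver(
        "D65/10", XYZTristimulus(94.811, 100.0, 107.304), 1.3013, 1.1498
    ),
    "C/2": IlluminantObserver(
        "C/2", XYZTristimulus(98.074, 100.0, 118.232), 1.2769, 1.0592
    ),
    "C/10": IlluminantObserver(
        "C/10", XYZTristimulus(97.285, 100.0, 116.145), 1.2871, 1.0781
    ),
}

#: Package-wide default pair (consumer photography assumes D65 daylight).
DEFAULT_ILLUMINANT_OBSERVER = ILLUMINANT_OBSERVERS["D65/2"]


def get_illuminant_observer(name: str) -> IlluminantObserver:
    """Look up a supported illuminant/observer pair by name.

    Accepts "D65/2", "D65/2°", "d65/2" etc.
    """
    key = name.replace("°", "").replace(" ", "").upper()
    try:
        return ILLUMINANT_OBSERVERS[key]
    except KeyError:
        raise KeyError(
            f"unsupported illuminant/observer {name!r}; supported: "
            f"{sorted(ILLUMINANT_OBSERVERS)}"
        ) from None


def decode_srgb_component(u: int) -> float:
    """Linearize one 8-bit sRGB channel to reflectance in [0, 1].

    Applies the IEC 61966-2-1 transfer function; monotone, with 0 -> 0.0
    and 255 -> 1.0 exactly.
    """
    if not (isinstance(u, (int, np.integer)) and 0 <= u <= 255):
        raise ValueError(f"channel value {u!r} must be an integer in [0, 255]")
    v = u / 255.0
    if v <= 0.04045:
        return v / 12.92
    return float(((v + 0.055) / 1.055) ** 2.4)


def linearize_rgb(rgb: np.ndarray) -> np.ndarray:
    """Vectorized sRGB linearization of values on the 0-255 scale.

    Accepts float input (e.g. unrounded cluster centroids); values are
    clipped to [0, 255] before decoding.
    """
    v = np.clip(np.asarray(rgb, dtype=float), 0.0, 255.0) / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


@lru_cache(maxsize=None)
def _rgb_to_xyz_matrix(io_name: str) -> np.ndarray:
    """RGB->XYZ matrix from the sRGB primaries and the pair's white point.

    Column-scaled so that linear RGB (1,1,1) maps exactly onto the
    reference white; for D65/2 this reproduces the standard sRGB matrix.
    """
    io = ILLUMINANT_OBSERVERS[io_name]
    x, y = _SRGB_PRIMARIES_XY[:, 0], _SRGB_PRIMARIES_XY[:, 1]
    # Columns: primaries' XYZ at unit luminance.
    prim = np.stack([x / y, np.ones(3), (1.0 - x - y) / y], axis=0)
    white = io.white_point.as_array() / io.white_point.Y
    scale = np.linalg.solve(prim, white)
    return prim * scale


def xyz_from_linear_rgb(linear_rgb: np.ndarray, io: IlluminantObserver) -> np.ndarray:
    """Map linear RGB in [0,1] (last axis length 3) to XYZ on the 0-100 scale."""
    m = _rgb_to_xyz_matrix(io.name)
    return 100.0 * np.asarray(linear_rgb, dtype=float) @ m.T


def rgb_to_xyz(
    c: RGB8Color | tuple[int, int, int],
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
) -> XYZTristimulus:
    """Convert an 8-bit sRGB color to CIE XYZ under the given pair."""
    if not isinstance(c, RGB8Color):
        c = RGB8Color(*c)
    lin = np.array([decode_srgb_component(u) for u in c.as_tuple()])
    xyz = xyz_from_linear_rgb(lin, io)
    # Tiny negative values can arise from floating rounding at black.
    xyz = np.where(np.abs(xyz) < 1e-12, 0.0, xyz)
    return XYZTristimulus(*np.maximum(xyz, 0.0))


def yellowness_index(
    t: XYZTristimulus,
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
) -> float:
    """ASTM E313 yellowness index, YI = 100 (Cx X - Cz Z) / Y.

    Raises ValueError for Y = 0 (YI is undefined at zero luminance).
    """
    if t.Y <= 0:
        raise ValueError("yellowness index undefined for Y <= 0")
    return 100.0 * (io.c_x * t.X - io.c_z * t.Z) / t.Y


def yellowness_of_rgb(
    c: RGB8Color | tuple[int, int, int],
    io: IlluminantObserver = DEFAULT_ILLUMINANT_OBSERVER,
) -> float:
    """Closed-form YI of a single sRGB color (black is undefined)."""
    return yellowness_index(rgb_to_xyz(c, io), io)
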