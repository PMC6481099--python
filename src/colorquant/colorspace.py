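"""Deterministic color separations of 8-bit RGB assay images.

One scanned RGB image is decomposed into single-channel 8-bit grayscale
images ("channels"): the raw R, G, B components, a CMYK ink separation,
and CIE L*a*b*.  Every pixel of every channel is an integer digital
number between 0 (black) and 255 (white), matching what image editors
display when a separation is viewed as a grayscale picture.

Conventions
-----------
CMYK uses the naive gray-component-replacement formula (no ICC profile),
with intensity encoded as ``255 * (1 - ink coverage)`` so paper-white
(zero ink) reads 255.  L*a*b* is computed for sRGB input: linearize with
the standard sRGB gamma, convert to XYZ under D65, Bradford-adapt to
D50, then evaluate CIE L*a*b* against the D50 white point.  L* is scaled
from [0, 100] onto [0, 255]; a* and b* are offset by +128 and clipped,
mimicking the common image-editor encoding of Lab channels.

All rounding is round-half-up, fixed explicitly because exact .5 cases
occur (e.g. merging 255 and 0 gives 127.5 -> 128).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ImageFormatError, ShapeMismatchError

__all__ = [
    "ChannelImage",
    "split_rgb",
    "rgb_to_cmyk_channels",
    "rgb_to_lab_channels",
    "invert_channel",
    "merge_channels",
    "as_rgb_array",
]

# sRGB primaries (IEC 61966-2-1), linear RGB -> XYZ under D65.
_SRGB_TO_XYZ_D65 = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Bradford chromatic adaptation, D65 -> D50 (ICC PCS convention).
_BRADFORD_D65_TO_D50 = np.array(
    [
        [1.0478112, 0.0228866, -0.0501270],
        [0.0295424, 0.9904844, -0.0170491],
        [-0.0092345, 0.0150436, 0.7521316],
    ]
)

# D50 reference white.
_WHITE_D50 = np.array([0.96422, 1.0, 0.82521])


@dataclass(frozen=True)
class ChannelImage:
    """A named single-channel 8-bit grayscale image.

    Parameters
    ----------
    name
        Canonical channel label, e.g. ``"R"``, ``"L*"`` or ``"-cRGB a*"``.
    pixels
        ``(H, W)`` array of ``uint8`` digital numbers, 0 = black.
    provenance
        ``(source image id, recipe id or "base", component label)``.
    """

    name: str
    pixels: np.ndarray
    provenance: tuple[str, str, str] = field(default=("image", "base", ""))

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ImageFormatError(
                f"channel {self.name!r}: expected a 2-D array, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if not (np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255):
                raise ImageFormatError(
                    f"channel {self.name!r}: values must be integers in [0, 255]"
                )
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.name:
            raise ValueError("channel name must be nonempty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the channel math needs half-up.
    return np.floor(x + 0.5)


def as_rgb_array(image: object) -> np.ndarray:
    """Validate and normalize an RGB image to an ``(H, W, 3) uint8`` array.

    Accepts ``uint8`` directly; 16-bit input is downscaled to 8 bits with
    rounding.  Anything that is not an ``H x W x 3`` integer raster is
    rejected with :class:`ImageFormatError`.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"expected an H x W x 3 RGB image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ImageFormatError("image must contain at least one pixel")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return _round_half_up(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise ImageFormatError("integer RGB components must lie in [0, 255]")
        return arr.astype(np.uint8)
    raise ImageFormatError(f"unsupported image dtype {arr.dtype} (need 8- or 16-bit)")


def split_rgb(image: object, source_id: str = "image") -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Split an RGB image into its R, G and B component channels."""
    arr = as_rgb_array(image)
    return tuple(
        ChannelImage(name, arr[:, :, i].copy(), (source_id, "base", name))
        for i, name in enumerate(("R", "G", "B"))
    )  # type: ignore[return-value]


def rgb_to_cmyk_channels(
    image: object, source_id: str = "image", recipe_id: str = "base"
) -> tuple[ChannelImage, ChannelImage, ChannelImage, ChannelImage]:
    """Separate an RGB image into C, M, Y and K channels.

    Naive gray-component replacement: with ``r', g', b'`` in [0, 1],
    ``K = 1 - max(r', g', b')`` and, away from pure black,
    ``C = (1 - r' - K) / (1 - K)`` (M, Y analogous).  Channels encode
    ``255 * (1 - coverage)`` so zero ink displays as white.
    """
    arr = as_rgb_array(image).astype(np.float64) / 255.0
    k_cov = 1.0 - arr.max(axis=2)
    denom = 1.0 - k_cov
    with np.errstate(divide="ignore", invalid="ignore"):
        cmy = (1.0 - arr - k_cov[:, :, None]) / denom[:, :, None]
    cmy[denom == 0.0] = 0.0  # pure black: all chromatic coverage zero
    coverages = (cmy[:, :, 0], cmy[:, :, 1], cmy[:, :, 2], k_cov)
    out = []
    for name, cov in zip(("C", "M", "Y", "K"), coverages):
        enc = _round_half_up(255.0 * (1.0 - cov)).astype(np.uint8)
        out.append(ChannelImage(name, enc, (source_id, recipe_id, name)))
    return tuple(out)  # type: ignore[return-value]


def _srgb_to_linear(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3.0 * delta**2) + 4.0 / 29.0)


def rgb_to_lab_channels(
    image: object, source_id: str = "image", recipe_id: str = "base"
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Convert an RGB image to encoded L*, a* and b* channels.

    Pipeline: sRGB gamma expansion -> XYZ (D65) -> Bradford adaptation to
    D50 -> CIE L*a*b* against the D50 white.  Encoding:
    ``L* -> round(255 * L*/100)``; ``a*, b* -> round(v) + 128`` clipped
    to [0, 255].
    """
    arr = as_rgb_array(image).astype(np.float64) / 255.0
    linear = _srgb_to_linear(arr)
    xyz = linear @ _SRGB_TO_XYZ_D65.T
    xyz = xyz @ _BRADFORD_D65_TO_D50.T
    f = _lab_f(xyz / _WHITE_D50)
    lightness = 116.0 * f[:, :, 1] - 16.0
    a_star = 500.0 * (f[:, :, 0] - f[:, :, 1])
    b_star = 200.0 * (f[:, :, 1] - f[:, :, 2])

    enc_l = np.clip(_round_half_up(255.0 * lightness / 100.0), 0, 255).astype(np.uint8)
    enc_a = np.clip(_round_half_up(a_star) + 128.0, 0, 255).astype(np.uint8)
    enc_b = np.clip(_round_half_up(b_star) + 128.0, 0, 255).astype(np.uint8)
    return (
        ChannelImage("L*", enc_l, (source_id, recipe_id, "L*")),
        ChannelImage("a*", enc_a, (source_id, recipe_id, "a*")),
        ChannelImage("b*", enc_b, (source_id, recipe_id, "b*")),
    )


def invert_channel(ch: ChannelImage) -> ChannelImage:
    """Black-white inversion: every pixel ``v`` becomes ``255 - v``."""
    src, recipe, comp = ch.provenance
    return ChannelImage(
        ch.name if ch.name.startswith("-") else f"-{ch.name}",
        (255 - ch.pixels.astype(np.int16)).astype(np.uint8),
        (src, recipe, f"invert({comp or ch.name})"),
    )


def merge_channels(ch1: ChannelImage, ch2: ChannelImage, name: str | None = None) -> ChannelImage:
    """Equal-weight merge: per-pixel mean of two channels, rounded half-up."""
    if ch1.shape != ch2.shape:
        raise ShapeMismatchError(
            f"cannot merge {ch1.name!r} {ch1.shape} with {ch2.name!r} {ch2.shape}"
        )
    # integer half-up: (a + b + 1) // 2
    merged = ((ch1.pixels.astype(np.uint16) + ch2.pixels + 1) // 2).astype(np.uint8)
    src = ch1.provenance[0]
    label = name or f"merge({ch1.name},{ch2.name})"
    return ChannelImage(label, merged, (src, "base", f"merge({ch1.name},{ch2.name})"))
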