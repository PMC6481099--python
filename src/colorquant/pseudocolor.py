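"""Pseudocolor images and the 83-channel grayscale set.

A pseudocolor image is built by substituting one or more slots of an RGB
image with hybrid grayscale channels — the equal-weight merges
RGB yellow = (R+G)/2, RGB cyan = (G+B)/2, RGB magenta = (R+B)/2 — either
directly or black-white inverted.  Ten canonical substitution recipes
are used.  Re-separating each pseudocolor image into C, M, Y, K, L*, a*
and b* yields 70 additional channels; together with the ten base
channels and the three hybrids this gives the full 83-channel set.

Recipe names follow the slot notation used throughout the package:
lowercase ``c``/``m``/``y`` marks a hybrid occupying the neighbouring
slot, and a leading ``-`` marks inversion (e.g. ``RG-yB`` is R, G and
the inverted yellow hybrid; ``cRmGyB`` has hybrids in all three slots).
Derived channels are named ``"<recipe> <component>"``, e.g.
``"-cRGB a*"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import (
    ChannelImage,
    as_rgb_array,
    invert_channel,
    merge_channels,
    rgb_to_cmyk_channels,
    rgb_to_lab_channels,
    split_rgb,
)
from .exceptions import ConfigError, ShapeMismatchError

__all__ = [
    "SlotSpec",
    "PseudocolorRecipe",
    "ChannelSet",
    "BASE10_NAMES",
    "HYBRID_NAMES",
    "DERIVED_COMPONENTS",
    "hybrid_channels",
    "canonical_recipes",
    "assemble_pseudocolor",
    "derive_channel_set",
    "full83_names",
]

BASE10_NAMES = ("R", "G", "B", "C", "M", "Y", "K", "L*", "a*", "b*")
HYBRID_NAMES = ("RGB cyan", "RGB magenta", "RGB yellow")
DERIVED_COMPONENTS = ("C", "M", "Y", "K", "L*", "a*", "b*")

# Which hybrid may occupy which slot: cyan replaces R, magenta replaces G,
# yellow replaces B (a hybrid substitutes the component it complements).
_SLOT_HYBRID = {0: "RGB cyan", 1: "RGB magenta", 2: "RGB yellow"}
_IDENTITY = {0: "R", 1: "G", 2: "B"}


@dataclass(frozen=True)
class SlotSpec:
    """One slot of a pseudocolor recipe: a source channel plus inversion flag."""

    source: str  # "R", "G", "B", "RGB cyan", "RGB magenta" or "RGB yellow"
    invert: bool = False


@dataclass(frozen=True)
class PseudocolorRecipe:
    """Declarative mapping of the three color slots to channels."""

    id: str
    slots: tuple[SlotSpec, SlotSpec, SlotSpec]

    def __post_init__(self) -> None:
        if len(self.slots) != 3:
            raise ConfigError(f"recipe {self.id!r}: exactly three slots required")
        for pos, slot in enumerate(self.slots):
            allowed = {_IDENTITY[pos], _SLOT_HYBRID[pos]}
            if slot.source not in allowed:
                raise ConfigError(
                    f"recipe {self.id!r}: slot {pos} cannot hold {slot.source!r}"
                )
            if slot.invert and "-" not in self.id:
                raise ConfigError(
                    f"recipe {self.id!r}: inversion without '-' in the name"
                )


def canonical_recipes() -> list[PseudocolorRecipe]:
    """The ten canonical pseudocolor recipes, in registry order."""
    s = SlotSpec
    return [
        PseudocolorRecipe("RGyB", (s("R"), s("G"), s("RGB yellow"))),
        PseudocolorRecipe("RG-yB", (s("R"), s("G"), s("RGB yellow", invert=True))),
        PseudocolorRecipe("RmGB", (s("R"), s("RGB magenta"), s("B"))),
        PseudocolorRecipe("R-mGB", (s("R"), s("RGB magenta", invert=True), s("B"))),
        PseudocolorRecipe("cRGB", (s("RGB cyan"), s("G"), s("B"))),
        PseudocolorRecipe("-cRGB", (s("RGB cyan", invert=True), s("G"), s("B"))),
        PseudocolorRecipe("RmGyB", (s("R"), s("RGB magenta"), s("RGB yellow"))),
        PseudocolorRecipe("cRGyB", (s("RGB cyan"), s("G"), s("RGB yellow"))),
        PseudocolorRecipe("cRmGB", (s("RGB cyan"), s("RGB magenta"), s("B"))),
        PseudocolorRecipe("cRmGyB", (s("RGB cyan"), s("RGB magenta"), s("RGB yellow"))),
    ]


def hybrid_channels(
    r: ChannelImage, g: ChannelImage, b: ChannelImage
) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Build the RGB cyan, RGB magenta and RGB yellow hybrid channels.

    cyan = merge(G, B); magenta = merge(R, B); yellow = merge(R, G).
    """
    if not (r.shape == g.shape == b.shape):
        raise ShapeMismatchError("R, G, B channels must share dimensions")
    cyan = merge_channels(g, b, name="RGB cyan")
    magenta = merge_channels(r, b, name="RGB magenta")
    yellow = merge_channels(r, g, name="RGB yellow")
    return cyan, magenta, yellow


def assemble_pseudocolor(
    recipe: PseudocolorRecipe, channels: dict[str, ChannelImage]
) -> np.ndarray:
    """Assemble a pseudocolor RGB image from base and hybrid channels.

    ``channels`` must map every source name the recipe references
    (``"R"``, ``"G"``, ``"B"``, ``"RGB cyan"``, ...) to a
    :class:`ChannelImage`.  Returns an ``(H, W, 3) uint8`` array whose
    slots hold the mapped, possibly inverted, channels.
    """
    planes = []
    for slot in recipe.slots:
        if slot.source not in channels:
            raise ConfigError(
                f"recipe {recipe.id!r}: channel {slot.source!r} not in registry"
            )
        ch = channels[slot.source]
        if slot.invert:
            ch = invert_channel(ch)
        planes.append(ch.pixels)
    if not (planes[0].shape == planes[1].shape == planes[2].shape):
        raise ShapeMismatchError(f"recipe {recipe.id!r}: slot dimensions differ")
    return np.stack(planes, axis=2)


class ChannelSet:
    """Ordered registry of named grayscale channels from one source image.

    Supports mapping-style access by canonical channel name and preserves
    the registry order (base channels, hybrids, then recipe-derived
    channels).
    """

    def __init__(self, source_id: str, mode: str, channels: dict[str, ChannelImage]):
        if mode not in ("base10", "full83"):
            raise ConfigError(f"unknown channel-set mode {mode!r}")
        expected = 10 if mode == "base10" else 83
        if len(channels) != expected:
            raise ConfigError(
                f"mode {mode!r} requires {expected} channels, got {len(channels)}"
            )
        self.source_id = source_id
        self.mode = mode
        self._channels = dict(channels)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._channels)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self._channels.values()))
        return first.shape

    def __getitem__(self, name: str) -> ChannelImage:
        return self._channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self._channels

    def __len__(self) -> int:
        return len(self._channels)

    def __iter__(self):
        return iter(self._channels.values())

    def stack(self) -> np.ndarray:
        """All channels as an ``(H, W, n_channels) uint8`` array in registry order."""
        return np.stack([ch.pixels for ch in self], axis=2)


def full83_names() -> tuple[str, ...]:
    """Canonical ordering of the 83 channel names."""
    names = list(BASE10_NAMES) + list(HYBRID_NAMES)
    for recipe in canonical_recipes():
        names.extend(f"{recipe.id} {comp}" for comp in DERIVED_COMPONENTS)
    return tuple(names)


def derive_channel_set(image: object, mode: str = "full83", source_id: str = "image") -> ChannelSet:
    """Derive the base-10 or full-83 channel set from one RGB image.

    The base set is R, G, B plus the CMYK and L*a*b* separations of the
    source image.  The full set adds the three hybrids and, for each of
    the ten canonical pseudocolor images, its seven CMYK/Lab channels
    (the raw slot channels of a pseudocolor image duplicate base or
    hybrid channels and are not re-extracted).
    """
    arr = as_rgb_array(image)
    r, g, b = split_rgb(arr, source_id)
    c, m, y, k = rgb_to_cmyk_channels(arr, source_id)
    l_star, a_star, b_star = rgb_to_lab_channels(arr, source_id)
    channels: dict[str, ChannelImage] = {
        ch.name: ch for ch in (r, g, b, c, m, y, k, l_star, a_star, b_star)
    }
    if mode == "base10":
        return ChannelSet(source_id, "base10", channels)
    if mode != "full83":
        raise ConfigError(f"unknown channel-set mode {mode!r}")

    cyan, magenta, yellow = hybrid_channels(r, g, b)
    for ch in (cyan, magenta, yellow):
        channels[ch.name] = ch

    slot_sources = {
        "R": r, "G": g, "B": b,
        "RGB cyan": cyan, "RGB magenta": magenta, "RGB yellow": yellow,
    }
    for recipe in canonical_recipes():
        pseudo = assemble_pseudocolor(recipe, slot_sources)
        derived = rgb_to_cmyk_channels(pseudo, source_id, recipe.id)
        derived += rgb_to_lab_channels(pseudo, source_id, recipe.id)
        for ch in derived:
            name = f"{recipe.id} {ch.name}"
            channels[name] = ChannelImage(name, ch.pixels, (source_id, recipe.id, ch.name))
    return ChannelSet(source_id, "full83", channels)
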