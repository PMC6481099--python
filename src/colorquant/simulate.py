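"""Synthetic colorimetric assay studies.

Generates scanner-like pack images whose R, G and B responses to
analyte concentration are smooth, partly nonmonotonic curves — as real
pack colorations are — perturbed by a between-pack gain (pack-to-glass
attachment and scan-to-scan differences act mainly as a brightness
change common to the pack) and independent within-pack pixel noise,
then quantized to 8 bits.  Only the three base channels are simulated;
all 83 grayscale channels inherit their structure through the actual
pseudocolor pipeline, so an end-to-end run exercises the real channel
math rather than a shortcut.

Default noise levels: between-pack coefficient of variation 3% (the
scale of scanner repeatability observed for printed reference colors)
and within-pack pixel CV 0.5% (replication pixels come from the most
uniform image region, so their spread is well below the between-pack
spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import ConfigError, ContractError
from .pseudocolor import ChannelSet, derive_channel_set
from .sampling import (
    AssayDesign,
    FeatureTable,
    PixelSelection,
    assemble_dataset,
    extract_features,
    select_pixels,
)

__all__ = [
    "NoiseModel",
    "ResponseLibrary",
    "SyntheticStudy",
    "make_response_library",
    "simulate_pack_image",
    "simulate_study",
    "scanner_repeatability",
    "glucose_to_cod",
]

# Full oxidation of glucose: C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O.
_GLUCOSE_MOLAR_MASS = 180.16  # g/mol
_O2_MOLAR_MASS = 32.00  # g/mol


@dataclass(frozen=True)
class NoiseModel:
    """Coefficients of variation of the simulated noise sources."""

    within_pack_cv: float = 0.005
    between_pack_cv: float = 0.03
    between_scan_cv: float = 0.03

    def __post_init__(self) -> None:
        if min(self.within_pack_cv, self.between_pack_cv, self.between_scan_cv) < 0:
            raise ConfigError("noise CVs must be >= 0")


@dataclass(frozen=True)
class ResponseLibrary:
    """Per-channel concentration-response curves plus the noise model.

    ``curves`` maps each base channel name to a callable taking a
    concentration and returning the mean digital number, clipped to
    [0, 255].  At least one default curve is nonmonotonic over the
    calibrated range, reflecting the complex color changes of real
    reacted packs.
    """

    curves: dict[str, Callable[[np.ndarray], np.ndarray]]
    noise: NoiseModel
    level_max: float
    seed: int

    def mean_rgb(self, level: float) -> np.ndarray:
        """Noise-free mean (R, G, B) at a concentration."""
        c = np.asarray(level, dtype=np.float64)
        vals = [self.curves[name](c) for name in ("R", "G", "B")]
        return np.clip(np.stack(vals, axis=-1), 0.0, 255.0)


def make_response_library(
    seed: int = 0,
    noise: NoiseModel | None = None,
    level_max: float = 100.0,
) -> ResponseLibrary:
    """Build a seeded response library over concentrations [0, level_max].

    R falls and B rises steeply and monotonically with concentration
    (each combining a linear trend with a saturating component so the
    low-concentration end stays well resolved), while G carries a
    Gaussian bump that guarantees an interior extremum — i.e. a
    nonmonotonic response — within the calibrated range.  Curve
    parameters are jittered around these templates by the seed.
    """
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)

    def jitter(v: float, rel: float = 0.08) -> float:
        return float(v * (1.0 + rel * rng.uniform(-1.0, 1.0)))

    r_hi = jitter(225.0)
    r_span = jitter(165.0)
    r_k = jitter(0.12)
    b_lo = jitter(55.0)
    b_span = jitter(150.0)
    b_k = jitter(0.15)
    g_mid = jitter(115.0)
    g_amp = jitter(55.0)
    g_mu = jitter(0.40)
    g_sigma = jitter(0.18)
    g_slope = jitter(18.0)

    def curve_r(c: np.ndarray) -> np.ndarray:
        u = np.asarray(c, dtype=np.float64) / level_max
        return r_hi - r_span * (0.55 * u + 0.45 * u / (u + r_k))

    def curve_g(c: np.ndarray) -> np.ndarray:
        u = np.asarray(c, dtype=np.float64) / level_max
        return g_mid + g_amp * np.exp(-((u - g_mu) ** 2) / (2.0 * g_sigma**2)) - g_slope * u

    def curve_b(c: np.ndarray) -> np.ndarray:
        u = np.asarray(c, dtype=np.float64) / level_max
        return b_lo + b_span * (0.55 * u + 0.45 * u / (u + b_k))

    return ResponseLibrary(
        curves={"R": curve_r, "G": curve_g, "B": curve_b},
        noise=noise,
        level_max=level_max,
        seed=seed,
    )


def _quantize(pixels: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(pixels, 0.0, 255.0) + 0.5).astype(np.uint8)


def simulate_pack_image(
    library: ResponseLibrary,
    level: float,
    pack_seed: int,
    shape: tuple[int, int] = (16, 16),
) -> np.ndarray:
    """Simulate the scanned image area of one reacted pack.

    A single multiplicative gain (between-pack CV) shifts the whole
    pack, then every pixel and channel receives independent
    multiplicative noise (within-pack CV); the result is quantized to
    8 bits.  Returns an ``(H, W, 3) uint8`` array.
    """
    if not (0.0 <= level <= library.level_max):
        raise ContractError(
            f"level {level} outside calibrated range [0, {library.level_max}]"
        )
    rng = np.random.default_rng(pack_seed)
    gain = 1.0 + library.noise.between_pack_cv * rng.standard_normal()
    gain = max(gain, 0.2)
    mean = library.mean_rgb(level) * gain
    h, w = shape
    pixel_noise = 1.0 + library.noise.within_pack_cv * rng.standard_normal((h, w, 3))
    return _quantize(mean[None, None, :] * pixel_noise)


@dataclass
class SyntheticStudy:
    """A complete simulated study with ground truth attached."""

    design: AssayDesign
    library: ResponseLibrary
    seed: int
    train: FeatureTable
    validation: FeatureTable
    selections: list[PixelSelection] = field(default_factory=list)
    images: dict[str, np.ndarray] = field(default_factory=dict)
    channel_sets: dict[str, ChannelSet] = field(default_factory=dict)


def simulate_study(
    library: ResponseLibrary,
    design: AssayDesign,
    seed: int = 0,
    mode: str = "full83",
    image_shape: tuple[int, int] = (16, 16),
    keep_images: bool = False,
) -> SyntheticStudy:
    """Simulate every pack of a design and assemble scaled feature tables.

    Each pack image is pushed through the real channel pipeline
    (:func:`~colorquant.pseudocolor.derive_channel_set`), replication
    pixels are selected by the low-variance rule over the whole pack
    area, and per-pack tables are concatenated into /255-scaled
    train/validation tables.  Fully deterministic for a fixed seed.
    """
    if design.levels[-1] > library.level_max:
        raise ContractError("design levels exceed the library's calibrated range")
    master = np.random.default_rng(seed)
    n_packs = len(design.levels) * design.packs_per_level
    pack_seeds = master.integers(0, 2**31 - 1, size=n_packs)
    select_seeds = master.integers(0, 2**31 - 1, size=n_packs)

    tables: list[FeatureTable] = []
    selections: list[PixelSelection] = []
    images: dict[str, np.ndarray] = {}
    channel_sets: dict[str, ChannelSet] = {}
    idx = 0
    for level in design.levels:
        for rep in range(design.packs_per_level):
            pack_id = f"{design.analyte}_L{level:g}_P{rep + 1}"
            img = simulate_pack_image(library, level, int(pack_seeds[idx]), image_shape)
            cset = derive_channel_set(img, mode=mode, source_id=pack_id)
            sel = select_pixels(
                cset,
                n_train=design.train_pixels_per_pack,
                n_val=design.val_pixels_per_pack,
                seed=int(select_seeds[idx]),
                pack_id=pack_id,
            )
            tables.append(extract_features(cset, sel, level))
            selections.append(sel)
            if keep_images:
                images[pack_id] = img
                channel_sets[pack_id] = cset
            idx += 1
    train, validation = assemble_dataset(tables, design, scale=True)
    return SyntheticStudy(
        design=design,
        library=library,
        seed=seed,
        train=train,
        validation=validation,
        selections=selections,
        images=images,
        channel_sets=channel_sets,
    )


def scanner_repeatability(
    image: np.ndarray,
    n_reads: int = 8,
    read_cv: float = 0.03,
    seed: int = 0,
) -> list[np.ndarray]:
    """Replicate scans of one image with per-read multiplicative noise.

    Each read applies an independent gain per color channel drawn with
    coefficient of variation ``read_cv``, then requantizes; feeding the
    per-channel means of the replicates to
    :func:`~colorquant.evalstats.coefficient_of_variation` recovers
    ``read_cv`` up to sampling error.
    """
    if n_reads < 2:
        raise ContractError("need at least 2 reads")
    base = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_reads):
        gains = 1.0 + read_cv * rng.standard_normal(3)
        reads.append(_quantize(base * gains[None, None, :]))
    return reads


def glucose_to_cod(glucose_mg_per_l: float) -> float:
    """Theoretical oxygen demand of a glucose standard, in mg O2/L.

    Full oxidation consumes 6 mol O2 per mol glucose, so
    COD = glucose * (6 * 32.00) / 180.16.
    """
    g = np.asarray(glucose_mg_per_l, dtype=np.float64)
    if np.any(g < 0):
        raise ContractError("glucose concentration must be >= 0")
    out = g * (6.0 * _O2_MOLAR_MASS) / _GLUCOSE_MOLAR_MASS
    return float(out) if out.ndim == 0 else out
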