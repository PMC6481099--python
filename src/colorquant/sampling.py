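"""Pixel selection and feature-table assembly.

Per reacted pack, a handful of replication pixels is selected from the
scanned image — by default ten training and five validation pixels from
the most uniform region — and their digital numbers are read across a
:class:`~colorquant.pseudocolor.ChannelSet`.  Per-pack tables are then
concatenated into train/validation feature tables for a whole standard
series, optionally scaled to [0, 1] by dividing by 255.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import (
    CapacityError,
    ConfigError,
    ContractError,
    DesignMismatchError,
    InputError,
)
from .pseudocolor import BASE10_NAMES, ChannelSet

__all__ = [
    "AssayDesign",
    "PixelSelection",
    "FeatureTable",
    "META_COLUMNS",
    "cod_design",
    "ammonium_design",
    "phosphate_design",
    "select_pixels",
    "extract_features",
    "assemble_dataset",
]

META_COLUMNS = ("pack_id", "level", "role")


@dataclass(frozen=True)
class AssayDesign:
    """Standard-series layout of a colorimetric assay study.

    ``levels`` are the analyte concentrations of the standard solutions,
    strictly increasing; each level is replicated over
    ``packs_per_level`` single-use packs, and each pack contributes
    ``train_pixels_per_pack`` training and ``val_pixels_per_pack``
    validation pixels.
    """

    analyte: str
    unit: str
    levels: tuple[float, ...]
    packs_per_level: int
    train_pixels_per_pack: int = 10
    val_pixels_per_pack: int = 5

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ConfigError("design needs at least one level")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ConfigError("levels must be strictly increasing")
        if min(self.packs_per_level, self.train_pixels_per_pack, self.val_pixels_per_pack) < 1:
            raise ConfigError("pack and pixel counts must be >= 1")

    @property
    def has_reference_level(self) -> bool:
        """True when a zero-concentration reference level is included."""
        return self.levels[0] == 0.0

    @property
    def n_train_rows(self) -> int:
        return len(self.levels) * self.packs_per_level * self.train_pixels_per_pack

    @property
    def n_val_rows(self) -> int:
        return len(self.levels) * self.packs_per_level * self.val_pixels_per_pack

    @property
    def level_range(self) -> float:
        return self.levels[-1] - self.levels[0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__ | {"levels": list(self.levels)}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AssayDesign":
        raw = json.loads(Path(path).read_text())
        raw["levels"] = tuple(raw["levels"])
        return cls(**raw)


def cod_design() -> AssayDesign:
    """Chemical oxygen demand series: 8 levels (0–100 mg O2/L), 5 packs each."""
    return AssayDesign(
        analyte="COD",
        unit="mg/L",
        levels=(0.0, 1.56, 3.13, 6.25, 12.5, 25.0, 50.0, 100.0),
        packs_per_level=5,
    )


def ammonium_design() -> AssayDesign:
    """Ammonium series: reagent-blank plus 35–556 µM, 3 packs per level."""
    return AssayDesign(
        analyte="NH4+",
        unit="uM",
        levels=(0.0, 35.0, 69.0, 139.0, 278.0, 556.0),
        packs_per_level=3,
    )


def phosphate_design() -> AssayDesign:
    """Phosphate series: 0–105 µM in five levels, 3 packs per level."""
    return AssayDesign(
        analyte="PO43-",
        unit="uM",
        levels=(0.0, 13.0, 26.0, 53.0, 105.0),
        packs_per_level=3,
    )


@dataclass(frozen=True)
class PixelSelection:
    """Selected pixel coordinates for one pack, with train/validation roles."""

    pack_id: str
    coordinates: tuple[tuple[int, int], ...]
    roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.coordinates) != len(self.roles):
            raise ContractError("coordinates and roles must have equal length")
        if any(role not in ("train", "validation") for role in self.roles):
            raise ContractError("roles must be 'train' or 'validation'")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ContractError("pixel coordinates must be distinct")

    def by_role(self, role: str) -> tuple[tuple[int, int], ...]:
        return tuple(c for c, r in zip(self.coordinates, self.roles) if r == role)


def _local_variance_score(channel_set: ChannelSet) -> np.ndarray:
    """Per-pixel 3x3 local intensity variance summed over the base channels."""
    base = BASE10_NAMES if channel_set.mode == "full83" else channel_set.names
    score = np.zeros(channel_set.shape, dtype=np.float64)
    for name in base:
        px = channel_set[name].pixels.astype(np.float64)
        mean = ndimage.uniform_filter(px, size=3, mode="reflect")
        mean_sq = ndimage.uniform_filter(px * px, size=3, mode="reflect")
        score += np.maximum(mean_sq - mean * mean, 0.0)
    return score


def select_pixels(
    channel_set: ChannelSet,
    roi: tuple[int, int, int, int] | None = None,
    n_train: int = 10,
    n_val: int = 5,
    strategy: str = "low-variance",
    seed: int = 0,
    pack_id: str = "pack",
    coordinates: Sequence[tuple[int, int]] | None = None,
    roles: Sequence[str] | None = None,
) -> PixelSelection:
    """Select training and validation pixels inside a region of interest.

    ``roi`` is ``(row, col, height, width)``; ``None`` means the whole
    image.  Strategy ``"low-variance"`` ranks ROI pixels by their local
    3x3 intensity variance summed over the base channels (a reproducible
    surrogate for "least diffuse reflection"), takes the
    ``n_train + n_val`` least-variable pixels with seeded tie-breaking,
    and alternates ranks between the train and validation roles.
    Strategy ``"manual"`` returns user-supplied coordinates verbatim.
    """
    h, w = channel_set.shape
    if roi is None:
        roi = (0, 0, h, w)
    r0, c0, rh, rw = roi
    if r0 < 0 or c0 < 0 or r0 + rh > h or c0 + rw > w or rh < 1 or rw < 1:
        raise InputError(f"roi {roi} outside image of shape {(h, w)}")

    if strategy == "manual":
        if coordinates is None:
            raise ContractError("manual strategy requires explicit coordinates")
        coords = tuple((int(r), int(c)) for r, c in coordinates)
        for r, c in coords:
            if not (r0 <= r < r0 + rh and c0 <= c < c0 + rw):
                raise InputError(f"coordinate {(r, c)} outside roi {roi}")
        if roles is None:
            roles = ("train",) * n_train + ("validation",) * (len(coords) - n_train)
        return PixelSelection(pack_id, coords, tuple(roles))

    if strategy != "low-variance":
        raise ConfigError(f"unknown selection strategy {strategy!r}")
    n_total = n_train + n_val
    if n_total > rh * rw:
        raise CapacityError(
            f"roi holds {rh * rw} pixels; cannot select {n_total}"
        )
    score = _local_variance_score(channel_set)[r0 : r0 + rh, c0 : c0 + rw]
    flat = score.ravel()
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(flat.size)
    order = np.lexsort((tiebreak, flat))[:n_total]
    rows, cols = np.unravel_index(order, score.shape)
    coords = tuple((int(r + r0), int(c + c0)) for r, c in zip(rows, cols))
    # Alternate ranks between roles until each quota fills, so both roles
    # sample the same variance stratum.
    role_list: list[str] = []
    taken = {"train": 0, "validation": 0}
    for rank in range(n_total):
        want = "train" if rank % 2 == 0 else "validation"
        if want == "train" and taken["train"] >= n_train:
            want = "validation"
        elif want == "validation" and taken["validation"] >= n_val:
            want = "train"
        role_list.append(want)
        taken[want] += 1
    return PixelSelection(pack_id, coords, tuple(role_list))


@dataclass(frozen=True)
class FeatureTable:
    """Pixels-by-channels intensity table with pack, level and role metadata.

    ``data`` holds the metadata columns ``pack_id``, ``level``, ``role``
    followed by one column per channel name.  ``scaled`` is False for
    raw 0–255 digital numbers and True after division by 255.
    """

    data: pd.DataFrame
    mode: str
    scaled: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ContractError(f"feature table lacks metadata columns {missing}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in META_COLUMNS)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def features(self) -> np.ndarray:
        """Feature matrix in table units (raw 0–255 or scaled [0, 1])."""
        return self.data[list(self.channel_names)].to_numpy(dtype=np.float64)

    def raw_features(self) -> np.ndarray:
        """Feature matrix on the raw 0–255 scale regardless of ``scaled``."""
        x = self.features()
        return x * 255.0 if self.scaled else x

    @property
    def levels(self) -> np.ndarray:
        return self.data["level"].to_numpy(dtype=np.float64)

    def subset(self, role: str) -> "FeatureTable":
        return replace(self, data=self.data[self.data["role"] == role].reset_index(drop=True))

    def scale(self) -> "FeatureTable":
        """Divide intensities by 255 so features lie in [0, 1]."""
        if self.scaled:
            return self
        out = self.data.copy()
        cols = list(self.channel_names)
        out[cols] = out[cols].astype(np.float64) / 255.0
        return replace(self, data=out, scaled=True)

    def unscale(self) -> "FeatureTable":
        if not self.scaled:
            return self
        out = self.data.copy()
        cols = list(self.channel_names)
        out[cols] = out[cols].astype(np.float64) * 255.0
        return replace(self, data=out, scaled=False)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mode: str, scaled: bool = False) -> "FeatureTable":
        return cls(pd.read_csv(path), mode=mode, scaled=scaled)


def extract_features(
    channel_set: ChannelSet, selection: PixelSelection, level: float
) -> FeatureTable:
    """Read the selected pixels' intensities across all channels of a set."""
    h, w = channel_set.shape
    for r, c in selection.coordinates:
        if not (0 <= r < h and 0 <= c < w):
            raise InputError(f"pixel {(r, c)} out of bounds for image {(h, w)}")
    rows = np.array([r for r, _ in selection.coordinates])
    cols = np.array([c for _, c in selection.coordinates])
    stack = channel_set.stack()  # (H, W, n)
    values = stack[rows, cols, :].astype(np.int64)
    df = pd.DataFrame(values, columns=list(channel_set.names))
    df.insert(0, "role", selection.roles)
    df.insert(0, "level", float(level))
    df.insert(0, "pack_id", selection.pack_id)
    return FeatureTable(df, mode=channel_set.mode)


def assemble_dataset(
    tables: Iterable[FeatureTable],
    design: AssayDesign,
    scale: bool = True,
) -> tuple[FeatureTable, FeatureTable]:
    """Concatenate per-pack tables and split them into train/validation.

    Validates the result against the design (one table per pack, level
    values drawn from the design grid, expected row counts per role) and
    optionally scales intensities to [0, 1].
    """
    tables = list(tables)
    expected_packs = len(design.levels) * design.packs_per_level
    if len(tables) != expected_packs:
        raise DesignMismatchError(
            f"design expects {expected_packs} packs, got {len(tables)} tables"
        )
    modes = {t.mode for t in tables}
    if len(modes) != 1:
        raise DesignMismatchError(f"mixed table modes {modes}")
    if any(t.scaled for t in tables):
        raise ContractError("per-pack tables must be raw; scaling happens here")
    combined = pd.concat([t.data for t in tables], ignore_index=True)
    level_grid = set(design.levels)
    bad = set(combined["level"].unique()) - level_grid
    if bad:
        raise DesignMismatchError(f"levels {sorted(bad)} not in the design grid")
    full = FeatureTable(combined, mode=modes.pop())
    train = full.subset("train")
    val = full.subset("validation")
    if train.n_rows != design.n_train_rows or val.n_rows != design.n_val_rows:
        raise DesignMismatchError(
            f"row counts {train.n_rows}/{val.n_rows} do not match design "
            f"{design.n_train_rows}/{design.n_val_rows}"
        )
    if scale:
        train, val = train.scale(), val.scale()
    return train, val
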