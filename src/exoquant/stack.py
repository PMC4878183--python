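"""Core containers for co-registered multi-channel images and binary masks.

Conventions used throughout the package: arrays are indexed ``(row, col)``,
0-based, pixel-center; intensities are non-negative floats in arbitrary
fluorescence units (AFU); all channels of a stack share one pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np


class ExoquantError(Exception):
    """Base class for package errors."""


class ContractError(ExoquantError, ValueError):
    """A documented precondition was violated."""


class DegenerateInputError(ExoquantError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant image
    passed to an Otsu threshold)."""


class NoCellsError(ExoquantError, ValueError):
    """A per-cell quantity was requested but no cells were found."""


@dataclass
class ChannelStack:
    """Co-registered multi-channel 2D image with named channels.

    Parameters
    ----------
    channels
        Mapping of channel name -> 2D float array (AFU). Insertion order is
        the channel order used when writing multi-page TIFF.
    pixel_size_um
        Physical pixel size in micrometres per pixel (isotropic).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ContractError("ChannelStack requires at least one channel")
        self.channels = {str(k): np.asarray(v, dtype=float) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ContractError(f"channels have inconsistent shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ContractError(f"channels must be 2D, got shape {shape}")
        for name, arr in self.channels.items():
            if not np.all(np.isfinite(arr)):
                raise ContractError(f"channel {name!r} contains non-finite values")
            if (arr < 0).any():
                raise ContractError(f"channel {name!r} contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ContractError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ContractError(
                f"unknown channel {name!r}; stack has {list(self.channels)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def with_channel(self, name: str, pixels: np.ndarray) -> "ChannelStack":
        """Return a new stack with one channel added or replaced."""
        new = dict(self.channels)
        new[name] = pixels
        return ChannelStack(new, pixel_size_um=self.pixel_size_um)

    def renamed(self, mapping: Mapping[str, str]) -> "ChannelStack":
        new = {mapping.get(k, k): v for k, v in self.channels.items()}
        if len(new) != len(self.channels):
            raise ContractError("channel rename produced duplicate names")
        return ChannelStack(new, pixel_size_um=self.pixel_size_um)


@dataclass
class BinaryMask:
    """Boolean image mask with provenance of how it was made."""

    pixels: np.ndarray
    source_channel: str | None = None
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ContractError("BinaryMask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __invert__(self) -> "BinaryMask":
        return BinaryMask(
            ~self.pixels,
            source_channel=f"not({self.source_channel})" if self.source_channel else None,
            threshold_used=self.threshold_used,
        )

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        if self.shape != other.shape:
            raise ContractError(f"mask shape mismatch: {self.shape} vs {other.shape}")
        return BinaryMask(
            self.pixels & other.pixels,
            source_channel=f"and({self.source_channel},{other.source_channel})",
        )

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CellLabelMap:
    """Integer-labelled cell segmentation; 0 is background, labels are
    contiguous positive integers in scan order."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ContractError("CellLabelMap must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ContractError("labels must be integer")
        if (self.labels < 0).any():
            raise ContractError("labels must be non-negative")

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape
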