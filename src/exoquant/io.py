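"""TIFF / CSV / YAML input-output.

2D multi-channel images travel as multi-page TIFF, one page per channel,
with channel names and pixel size in a JSON image description (fallback:
ordered names supplied by the caller). 3D EM volumes travel as TIFF stacks
with a YAML sidecar carrying ``voxel_size_nm`` (dz, dy, dx) and optional
phase levels. Measurement tables are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .em3d import EMVolume
from .stack import ChannelStack, ContractError

DESC_KEY = "exoquant"


def write_stack(stack: ChannelStack, path: str | Path) -> None:
    """Write a multi-page TIFF (one page per channel, names in metadata)."""
    pages = np.stack([stack[name] for name in stack.channel_names])
    desc = json.dumps(
        {DESC_KEY: {"channel_names": list(stack.channel_names), "pixel_size_um": stack.pixel_size_um}}
    )
    tifffile.imwrite(path, pages.astype(np.float32), description=desc, photometric="minisblack")


def read_stack(path: str | Path, channel_names: Sequence[str] | None = None) -> ChannelStack:
    """Read a multi-page TIFF into a :class:`ChannelStack`.

    Channel names come from the embedded metadata; if absent, the
    ``channel_names`` fallback is applied in page order.
    """
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description or ""
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ContractError(f"expected a stack of 2D pages, got shape {pages.shape}")
    meta = {}
    try:
        meta = json.loads(desc).get(DESC_KEY, {})
    except (json.JSONDecodeError, AttributeError):
        pass
    names = meta.get("channel_names") or list(channel_names or [])
    if not names:
        names = [f"ch{i}" for i in range(pages.shape[0])]
    if len(names) != pages.shape[0]:
        raise ContractError(
            f"{len(names)} channel names for {pages.shape[0]} pages in {path}"
        )
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    return ChannelStack(
        {str(n): pages[i].astype(float) for i, n in enumerate(names)},
        pixel_size_um=pixel_size,
    )


def write_volume(volume: EMVolume, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write a 3D TIFF stack plus a YAML sidecar with voxel metadata."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensity.astype(np.float32), photometric="minisblack")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"voxel_size_nm": list(volume.voxel_size_nm)}, fh)


def read_volume(
    path: str | Path,
    sidecar: str | Path | None = None,
    voxel_size_nm: tuple[float, float, float] | None = None,
) -> EMVolume:
    """Read a 3D TIFF stack; voxel size from the YAML sidecar unless given."""
    path = Path(path)
    intensity = tifffile.imread(path).astype(float)
    if voxel_size_nm is None:
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        voxel_size_nm = tuple(meta.get("voxel_size_nm", (1.0, 1.0, 1.0)))
    return EMVolume(intensity=intensity, voxel_size_nm=voxel_size_nm)


MEASUREMENT_COLUMNS = ["image_id", "cell_id", "metric", "value", "condition", "day"]


def measurement_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble a MeasurementTable with the canonical column order."""
    df = pd.DataFrame(list(rows))
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    return df[MEASUREMENT_COLUMNS + extra]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
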