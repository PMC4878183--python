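"""Per-cell quantification in the macrophage–adipocyte culture model.

Cell boundaries come from a plasma-membrane stain (Alexa488-CtB); each
cell's readout is its *fluorescence power* — the sum of all raw pixel
intensities within the cell boundary — computed for internalized adipocyte
label (uptake), LipidTOX (foam-cell formation), or surface LAMP-1
immunostain. Uptake-style assays gate on contact: a macrophage is only
scored when it touches an adipocyte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .maskquant import EIGHT, gaussian_smooth, threshold_mask
from .stack import (
    BinaryMask,
    CellLabelMap,
    ChannelStack,
    ContractError,
    DegenerateInputError,
)


def label_cells_from_ctb(
    ctb_channel: np.ndarray,
    kernel_px: int = 5,
    threshold: float | None = None,
    min_area_px: int = 50,
    fill_holes: bool = True,
    exclude_border: bool = True,
) -> CellLabelMap:
    """Label cells from a surface (ring) stain.

    Pipeline: smooth → threshold (Otsu unless fixed) → fill enclosed
    interiors → 8-connected components → drop components smaller than
    ``min_area_px`` and, by default, components touching the image border
    (partial cells bias power). Two cells sharing a boundary arc merge into
    one label. A blank channel yields an empty map with a warning.
    """
    ctb = np.asarray(ctb_channel, dtype=float)
    smoothed = gaussian_smooth(ctb, kernel_px)
    try:
        mask = threshold_mask(
            smoothed,
            method="otsu" if threshold is None else "fixed",
            threshold=threshold,
        )
    except DegenerateInputError:
        warnings.warn("constant boundary channel: no cells labelled")
        return CellLabelMap(np.zeros(ctb.shape, np.int32), {"threshold": None})
    filled = ndimage.binary_fill_holes(mask.pixels) if fill_holes else mask.pixels
    labels, n = ndimage.label(filled, structure=EIGHT)
    if n == 0:
        warnings.warn("no cells found in boundary channel")
        return CellLabelMap(labels.astype(np.int32), {"threshold": mask.threshold_used})
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= min_area_px
    if exclude_border:
        border = np.zeros(labels.shape, bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        on_border = np.unique(labels[border])
        keep[on_border[on_border > 0] - 1] = False
    keep_ids = np.flatnonzero(keep) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep_ids] = np.arange(1, keep_ids.size + 1)
    return CellLabelMap(
        remap[labels],
        provenance={
            "threshold": mask.threshold_used,
            "kernel_px": kernel_px,
            "min_area_px": min_area_px,
            "fill_holes": fill_holes,
            "exclude_border": exclude_border,
        },
    )


def contact_filter(
    cells: CellLabelMap, adipocyte_mask: BinaryMask | np.ndarray, radius_px: int = 1
) -> np.ndarray:
    """Per-cell boolean: does the cell touch the adipocyte within ``radius_px``?

    A cell is in contact iff its label, dilated by ``radius_px`` (Euclidean),
    intersects the adipocyte mask — equivalently, iff the minimum distance
    from any of its pixels to the mask is ≤ ``radius_px``. Radius 0 requires
    direct overlap; the default radius 1 is direct adjacency. Monotone in
    the radius.
    """
    if radius_px < 0:
        raise ContractError("radius_px must be >= 0")
    mask = adipocyte_mask.pixels if isinstance(adipocyte_mask, BinaryMask) else np.asarray(adipocyte_mask, bool)
    if mask.shape != cells.shape:
        raise ContractError("adipocyte mask shape mismatch")
    n = cells.n_cells
    if n == 0:
        return np.zeros(0, dtype=bool)
    if not mask.any():
        return np.zeros(n, dtype=bool)
    dist = ndimage.distance_transform_edt(~mask)
    dmin = ndimage.minimum(dist, cells.labels, index=np.arange(1, n + 1))
    return np.asarray(dmin) <= radius_px


def cell_power(cells: CellLabelMap, signal_channel: np.ndarray) -> np.ndarray:
    """Fluorescence power per cell: exact sum of the *raw* (unsmoothed)
    signal over each label's pixels; background (label 0) excluded."""
    signal = np.asarray(signal_channel, dtype=float)
    if signal.shape != cells.shape:
        raise ContractError("signal channel shape mismatch")
    if cells.n_cells == 0:
        return np.zeros(0, dtype=float)
    sums = ndimage.sum_labels(signal, cells.labels, index=cells.ids)
    return np.asarray(sums, dtype=float)


def region_power(roi_mask: BinaryMask | np.ndarray, signal_channel: np.ndarray) -> float:
    """Sum of the signal within a region of interest (deposition readouts)."""
    mask = roi_mask.pixels if isinstance(roi_mask, BinaryMask) else np.asarray(roi_mask, bool)
    signal = np.asarray(signal_channel, dtype=float)
    if mask.shape != signal.shape:
        raise ContractError("ROI mask shape mismatch")
    if not mask.any():
        warnings.warn("empty ROI: region power is 0")
        return 0.0
    return float(signal[mask].sum())


@dataclass
class PositivityResult:
    flags: np.ndarray
    fraction: float
    threshold: float
    rule: str


def positivity(
    powers: np.ndarray,
    rule: str = "fixed",
    threshold: float | None = None,
    control_powers: np.ndarray | None = None,
    k: float = 3.0,
) -> PositivityResult:
    """Classify cells as positive (e.g. foam cells) against a power threshold.

    ``rule='fixed'`` uses an explicit ``threshold``. ``rule='mad'`` sets the
    threshold adaptively at ``median(control) + k·MAD(control)`` (raw median
    absolute deviation, unscaled; k defaults to 3) from a control
    population. A cell is positive iff power > threshold.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ContractError("positivity requires >= 1 measurement")
    if rule == "fixed":
        if threshold is None:
            raise ContractError("rule='fixed' requires threshold=")
        t = float(threshold)
    elif rule == "mad":
        if control_powers is None or len(control_powers) == 0:
            raise ContractError("rule='mad' requires a non-empty control set")
        control = np.asarray(control_powers, dtype=float)
        med = float(np.median(control))
        mad = float(np.median(np.abs(control - med)))
        t = med + k * mad
    else:
        raise ContractError(f"unknown positivity rule {rule!r}")
    flags = powers > t
    return PositivityResult(flags=flags, fraction=float(flags.mean()), threshold=t, rule=rule)


def surface_lamp1_culture(
    stack: ChannelStack,
    boundary_channel: str = "CtB",
    signal_channel: str = "LAMP1",
    **label_params,
) -> tuple[CellLabelMap, np.ndarray]:
    """Per-cell surface LAMP-1 in the culture model: label cells from the
    membrane stain, then sum the LAMP-1 immunostain within each boundary."""
    cells = label_cells_from_ctb(stack[boundary_channel], **label_params)
    return cells, cell_power(cells, stack[signal_channel])


def adipocyte_mask_from_channel(
    channel: np.ndarray,
    kernel_px: int = 5,
    threshold: float | None = None,
    largest_only: bool = True,
) -> BinaryMask:
    """Adipocyte body mask from the labelled-adipocyte channel: smooth,
    threshold, and (by default) keep only the largest connected component."""
    smoothed = gaussian_smooth(np.asarray(channel, dtype=float), kernel_px)
    try:
        mask = threshold_mask(
            smoothed,
            method="otsu" if threshold is None else "fixed",
            threshold=threshold,
        )
    except DegenerateInputError:
        return BinaryMask(np.zeros(np.asarray(channel).shape, bool))
    if not largest_only:
        return mask
    labels, n = ndimage.label(mask.pixels, structure=EIGHT)
    if n <= 1:
        return mask
    areas = np.bincount(labels.ravel())[1:]
    return BinaryMask(labels == (int(np.argmax(areas)) + 1), mask.source_channel, mask.threshold_used)
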