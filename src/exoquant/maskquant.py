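"""Tissue immunofluorescence quantification by channel-mask algebra.

The workflow mirrors a standard crown-like-structure (CLS) analysis of white
adipose tissue: every channel is pre-filtered with a small normalized
Gaussian, the macrophage marker (F4/80, FITC) is thresholded to a binary
mask, permeabilized cells flagged by extracellular calnexin access (Cy5) are
removed by multiplying with the inverted calnexin mask, the combined mask is
applied to the LAMP-1 channel (Cy3), and the surviving LAMP-1 signal is
normalized by the number of nuclei (DAPI) to give an average surface LAMP-1
per cell. The lysosomal variant (permeabilized tissue) is identical without
the calnexin exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack import (
    BinaryMask,
    ChannelStack,
    ContractError,
    DegenerateInputError,
    NoCellsError,
)

EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element

DEFAULT_CHANNELS = {"fitc": "FITC", "cy3": "Cy3", "cy5": "Cy5", "dapi": "DAPI"}


def binomial_taps(kernel_px: int) -> np.ndarray:
    """Normalized binomial filter taps of odd length ``kernel_px``.

    The length-5 taps are [1,4,6,4,1]/16 and length-7 are
    [1,6,15,20,15,6,1]/64 — the standard discrete approximation of an
    ``N x N`` Gaussian used by microscopy analysis software.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ContractError(f"kernel_px must be a positive odd integer, got {kernel_px}")
    row = np.array([1.0])
    for _ in range(kernel_px - 1):
        row = np.convolve(row, [1.0, 1.0])
    return row / row.sum()


def gaussian_taps(kernel_px: int, sigma: float) -> np.ndarray:
    """Sampled-Gaussian taps of odd length ``kernel_px``, normalized to 1."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ContractError(f"kernel_px must be a positive odd integer, got {kernel_px}")
    if sigma <= 0:
        raise ContractError("sigma must be positive")
    x = np.arange(kernel_px) - kernel_px // 2
    taps = np.exp(-0.5 * (x / sigma) ** 2)
    return taps / taps.sum()


def gaussian_smooth(image: np.ndarray, kernel_px: int = 5, sigma: float | None = None) -> np.ndarray:
    """Separable N×N Gaussian smoothing with reflective boundary.

    Uses normalized binomial taps by default; an explicit ``sigma`` switches
    to sampled-Gaussian taps truncated to the same window. The kernel sums to
    one, so a constant image is unchanged and total intensity of
    interior-supported signals is conserved.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ContractError("image must be finite")
    taps = gaussian_taps(kernel_px, sigma) if sigma is not None else binomial_taps(kernel_px)
    out = ndimage.convolve1d(image, taps, axis=0, mode="reflect")
    out = ndimage.convolve1d(out, taps, axis=1, mode="reflect")
    return out


def threshold_mask(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    q: float | None = None,
    source_channel: str | None = None,
) -> BinaryMask:
    """Binary mask of pixels strictly above a threshold.

    ``method`` is ``"otsu"`` (automatic, requires a non-constant image),
    ``"fixed"`` (requires ``threshold``) or ``"quantile"`` (requires ``q``).
    The threshold actually used is recorded on the mask.
    """
    image = np.asarray(image, dtype=float)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateInputError(
                "constant image: Otsu threshold is undefined; use method='fixed'"
            )
        t = float(threshold_otsu(image))
    elif method == "fixed":
        if threshold is None:
            raise ContractError("method='fixed' requires threshold=")
        t = float(threshold)
    elif method == "quantile":
        if q is None or not 0.0 <= q <= 1.0:
            raise ContractError("method='quantile' requires q in [0, 1]")
        t = float(np.quantile(image, q))
    else:
        raise ContractError(f"unknown threshold method {method!r}")
    return BinaryMask(image > t, source_channel=source_channel, threshold_used=t)


def mask_invert(mask: BinaryMask) -> BinaryMask:
    """Boolean complement (the 'inverted binary mask' of the CLS pipeline)."""
    return ~mask


def mask_and(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Boolean conjunction, i.e. pixel-wise mask multiplication."""
    return a & b


def _nucleus_labels(
    dapi: np.ndarray,
    min_area_px: int = 1,
    kernel_px: int = 5,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei: smooth, threshold, 8-connected components, area filter.

    Returns a relabelled map with small components removed. A blank or
    constant DAPI channel yields an all-zero map.
    """
    if min_area_px < 1:
        raise ContractError("min_area_px must be >= 1")
    smoothed = gaussian_smooth(dapi, kernel_px)
    try:
        mask = threshold_mask(
            smoothed,
            method="otsu" if threshold is None else "fixed",
            threshold=threshold,
        )
    except DegenerateInputError:
        return np.zeros(np.asarray(dapi).shape, dtype=np.int32)
    labels, n = ndimage.label(mask.pixels, structure=EIGHT)
    if n == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area_px) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def count_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 1,
    kernel_px: int = 5,
    threshold: float | None = None,
) -> int:
    """Count nuclei as 8-connected DAPI components of at least ``min_area_px``
    pixels after smoothing and thresholding.

    Touching nuclei merged by a bridge count as one component (no watershed
    split). Returns 0 on a blank image.
    """
    return int(_nucleus_labels(dapi, min_area_px, kernel_px, threshold).max())


@dataclass
class PerCellResult:
    """Per-field quantification: total masked signal over nucleus count."""

    total_signal: float
    cell_count: int
    signal_per_cell: float
    gating: dict = field(default_factory=dict)


def _background_estimate(signal: np.ndarray, cell_mask: np.ndarray) -> float:
    """Median signal outside the cell mask; 0 if the mask covers everything."""
    outside = signal[~cell_mask]
    return float(np.median(outside)) if outside.size else 0.0


def _lamp1_pipeline(
    stack: ChannelStack,
    exclude_permeable: bool,
    kernel_px: int = 5,
    fitc_threshold: float | None = None,
    cy5_threshold: float | None = None,
    dapi_threshold: float | None = None,
    min_nucleus_area_px: int = 5,
    nucleus_denominator: str = "fitc",
    background_subtract: bool = True,
    channel_map: dict[str, str] | None = None,
) -> tuple[PerCellResult, np.ndarray, BinaryMask]:
    names = {**DEFAULT_CHANNELS, **(channel_map or {})}
    fitc = gaussian_smooth(stack[names["fitc"]], kernel_px)
    cy3 = gaussian_smooth(stack[names["cy3"]], kernel_px)
    fitc_mask = threshold_mask(
        fitc,
        method="otsu" if fitc_threshold is None else "fixed",
        threshold=fitc_threshold,
        source_channel=names["fitc"],
    )
    combined = fitc_mask
    cy5_mask = None
    if exclude_permeable:
        cy5 = gaussian_smooth(stack[names["cy5"]], kernel_px)
        if np.ptp(cy5) == 0 and cy5_threshold is None:
            # blank calnexin channel: nothing to exclude
            cy5_mask = BinaryMask(np.zeros(stack.shape, bool), names["cy5"], None)
        else:
            cy5_mask = threshold_mask(
                cy5,
                method="otsu" if cy5_threshold is None else "fixed",
                threshold=cy5_threshold,
                source_channel=names["cy5"],
            )
        combined = mask_and(fitc_mask, mask_invert(cy5_mask))

    background = _background_estimate(cy3, fitc_mask.pixels) if background_subtract else 0.0
    total = float(np.sum(cy3[combined.pixels] - background))
    total = max(total, 0.0)

    nuclei = _nucleus_labels(
        stack[names["dapi"]], min_nucleus_area_px, kernel_px, dapi_threshold
    )
    if nucleus_denominator == "fitc":
        inside = np.unique(nuclei[fitc_mask.pixels])
        cell_count = int(np.count_nonzero(inside))
    elif nucleus_denominator == "all":
        cell_count = int(nuclei.max())
    else:
        raise ContractError("nucleus_denominator must be 'fitc' or 'all'")
    if cell_count == 0:
        raise NoCellsError("no nuclei found in field; cannot normalize per cell")

    gating = {
        "kernel_px": kernel_px,
        "threshold_fitc": fitc_mask.threshold_used,
        "threshold_cy5": cy5_mask.threshold_used if cy5_mask is not None else None,
        "background_cy3": background,
        "nucleus_denominator": nucleus_denominator,
        "exclude_permeable": exclude_permeable,
        "fitc_mask": fitc_mask,
        "cy5_mask": cy5_mask,
        "combined_mask": combined,
    }
    result = PerCellResult(
        total_signal=total,
        cell_count=cell_count,
        signal_per_cell=total / cell_count,
        gating=gating,
    )
    return result, cy3, fitc_mask


def surface_lamp1_per_cell(stack: ChannelStack, **params) -> PerCellResult:
    """Average plasma-membrane LAMP-1 per cell for a non-permeabilized field.

    Pipeline: smooth all channels (5×5 default) → FITC mask ∧ ¬Cy5 mask →
    sum the Cy3 (LAMP-1) signal within the combined mask → divide by the
    nucleus count. By default nuclei are counted only where they overlap the
    F4/80 mask (``nucleus_denominator='fitc'``; ``'all'`` counts every
    nucleus in the field) and a field background (median Cy3 outside the
    FITC mask) is subtracted per masked pixel.
    """
    result, _, _ = _lamp1_pipeline(stack, exclude_permeable=True, **params)
    return result


def lysosomal_lamp1_per_cell(stack: ChannelStack, **params) -> PerCellResult:
    """As :func:`surface_lamp1_per_cell` but without the calnexin exclusion
    (permeabilized tissue: total lysosomal LAMP-1 per macrophage)."""
    result, _, _ = _lamp1_pipeline(stack, exclude_permeable=False, **params)
    return result


def surface_lamp1_per_region(stack: ChannelStack, **params) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell surface LAMP-1 using F4/80 connected components as cells.

    Applies exactly the surface mask algebra, then aggregates the masked,
    background-subtracted Cy3 signal within each 8-connected component of
    the FITC mask instead of averaging over the whole field. Returns
    ``(labels, per_cell_signal)`` where ``labels`` is the component label
    map. Useful when macrophages are spatially separated (culture models,
    synthetic scenes) and a per-cell distribution is wanted.
    """
    params.setdefault("min_nucleus_area_px", 5)
    result, cy3, fitc_mask = _lamp1_pipeline(stack, exclude_permeable=True, **params)
    labels, n = ndimage.label(fitc_mask.pixels, structure=EIGHT)
    if n == 0:
        raise NoCellsError("no F4/80-positive components found")
    masked = np.where(result.gating["combined_mask"].pixels, cy3 - result.gating["background_cy3"], 0.0)
    sums = ndimage.sum_labels(masked, labels, index=np.arange(1, n + 1))
    return labels, np.maximum(np.asarray(sums, dtype=float), 0.0)


@dataclass
class PermeabilityResult:
    """Per-cell permeability calls from the calnexin (Cy5) channel."""

    flags: np.ndarray
    fraction: float
    labels: np.ndarray
    threshold: float


def classify_permeable(
    stack: ChannelStack,
    kernel_px: int = 5,
    fitc_threshold: float | None = None,
    cy5_threshold: float | None = None,
    channel_map: dict[str, str] | None = None,
) -> PermeabilityResult:
    """Flag permeabilized macrophages by calnexin accessibility.

    Cells are the 8-connected components of the smoothed, thresholded F4/80
    mask. A cell is permeable when its mean smoothed Cy5 intensity exceeds
    the threshold; by default the threshold is twice the whole-image median
    Cy5 (a robust background estimate), overridable with ``cy5_threshold``.
    Returns per-cell flags in label order plus the permeable fraction.
    """
    names = {**DEFAULT_CHANNELS, **(channel_map or {})}
    fitc = gaussian_smooth(stack[names["fitc"]], kernel_px)
    fitc_mask = threshold_mask(
        fitc,
        method="otsu" if fitc_threshold is None else "fixed",
        threshold=fitc_threshold,
    )
    labels, n = ndimage.label(fitc_mask.pixels, structure=EIGHT)
    if n == 0:
        raise NoCellsError("no F4/80-positive cells found")
    cy5 = gaussian_smooth(stack[names["cy5"]], kernel_px)
    if cy5_threshold is None:
        cy5_threshold = 2.0 * float(np.median(cy5))
    means = np.asarray(ndimage.mean(cy5, labels, index=np.arange(1, n + 1)), dtype=float)
    flags = means > cy5_threshold
    return PermeabilityResult(
        flags=flags,
        fraction=float(flags.mean()),
        labels=labels,
        threshold=float(cy5_threshold),
    )
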