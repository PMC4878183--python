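"""Ratiometric extracellular pH mapping from a dual-fluorophore pair.

A pH-sensitive fluorophore (CypHer 5E, brighter at acidic pH) and a
pH-insensitive one (Alexa488) are imaged together; the per-pixel
CypHer/Alexa ratio is converted to pH through a calibration curve built
from buffer standards of known pH. The ratio is strictly decreasing in pH,
so the curve is invertible. Both channels are smoothed (7×7 by default) and
background is removed by thresholding the pH-insensitive channel before the
ratio is formed; nuclear regions are excluded from calibration because the
two dyes accumulate in nuclei at different rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .maskquant import gaussian_smooth, threshold_mask
from .stack import BinaryMask, ChannelStack, ContractError, DegenerateInputError

PH_CHANNELS = {"cypher": "CypHer", "alexa": "Alexa488"}


@dataclass
class FourParamLogistic:
    """Strictly decreasing 4-parameter logistic ratio→pH response.

    ``ratio(pH) = low + (high - low) / (1 + exp(steepness * (pH - mid_ph)))``

    ``high`` is the acidic-end ratio asymptote, ``low`` the basic-end
    asymptote, ``mid_ph`` the inflection (the apparent pKa of the pH probe)
    and ``steepness`` (> 0) the transition sharpness in 1/pH-unit.
    """

    high: float = 4.0
    low: float = 0.1
    mid_ph: float = 6.1
    steepness: float = 1.4

    def __post_init__(self) -> None:
        if not (self.high > self.low and self.steepness > 0):
            raise ContractError(
                "response must be strictly decreasing: require high > low and steepness > 0"
            )

    def __call__(self, ph: np.ndarray | float) -> np.ndarray | float:
        ph = np.asarray(ph, dtype=float)
        out = self.low + (self.high - self.low) / (1.0 + np.exp(self.steepness * (ph - self.mid_ph)))
        return out if out.ndim else float(out)

    def inverse(self, ratio: np.ndarray | float) -> np.ndarray | float:
        """Analytic pH from ratio; valid for ratio strictly inside (low, high)."""
        r = np.asarray(ratio, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.mid_ph + np.log((self.high - self.low) / (r - self.low) - 1.0) / self.steepness
        return out if out.ndim else float(out)


def ratio_image(
    stack: ChannelStack,
    kernel_px: int = 7,
    alexa_threshold: float | None = None,
    channel_map: dict[str, str] | None = None,
) -> tuple[np.ndarray, BinaryMask]:
    """Background-masked CypHer/Alexa ratio image.

    Both channels are smoothed with a ``kernel_px`` Gaussian, a background
    mask is made by thresholding the smoothed Alexa channel (Otsu unless an
    explicit threshold is given), and the ratio is formed on masked-in
    pixels only. Pixels outside the mask — and any masked-in pixel with a
    zero denominator — are NaN (undefined).
    """
    names = {**PH_CHANNELS, **(channel_map or {})}
    cypher = gaussian_smooth(stack[names["cypher"]], kernel_px)
    alexa = gaussian_smooth(stack[names["alexa"]], kernel_px)
    try:
        mask = threshold_mask(
            alexa,
            method="otsu" if alexa_threshold is None else "fixed",
            threshold=alexa_threshold,
            source_channel=names["alexa"],
        )
    except DegenerateInputError:
        mask = BinaryMask(np.zeros(stack.shape, bool), names["alexa"], None)
    ratio = np.full(stack.shape, np.nan)
    valid = mask.pixels & (alexa > 0)
    ratio[valid] = cypher[valid] / alexa[valid]
    n_zero = int(mask.pixels.sum() - valid.sum())
    if n_zero:
        warnings.warn(f"{n_zero} masked-in pixels had zero denominator; flagged undefined")
    return ratio, mask


@dataclass
class CalibrationCurve:
    """Monotone ratio→pH mapping built from buffer standards.

    ``standards`` holds (pH, mean ratio) pairs sorted by pH with ratio
    strictly decreasing. ``model`` is ``"piecewise"`` (linear interpolation
    between standards, the assumption-free default) or ``"4pl"`` (fitted
    :class:`FourParamLogistic`, available with ≥ 4 standards).
    """

    ph_values: np.ndarray
    ratios: np.ndarray
    model: str = "piecewise"
    params: FourParamLogistic | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ph_values = np.asarray(self.ph_values, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ph_values.size < 3:
            raise ContractError("calibration requires >= 3 standards")
        order = np.argsort(self.ph_values)
        self.ph_values = self.ph_values[order]
        self.ratios = self.ratios[order]
        diffs = np.diff(self.ratios)
        if not (diffs < 0).all():
            i = int(np.argmax(diffs >= 0))
            raise ContractError(
                "standards are not strictly decreasing in ratio: "
                f"pH {self.ph_values[i]:g} (ratio {self.ratios[i]:g}) vs "
                f"pH {self.ph_values[i + 1]:g} (ratio {self.ratios[i + 1]:g})"
            )

    @property
    def ratio_range(self) -> tuple[float, float]:
        return float(self.ratios.min()), float(self.ratios.max())

    def ph_from_ratio(self, ratio: np.ndarray | float, clamp: bool = True) -> np.ndarray:
        """Invert the calibration model; out-of-range ratios are clamped to
        the domain ends (NaN propagates)."""
        r = np.atleast_1d(np.asarray(ratio, dtype=float))
        lo, hi = self.ratio_range
        if clamp:
            r = np.clip(r, lo, hi)
        if self.model == "piecewise":
            # ratio decreasing in pH -> sort by ratio ascending for interp
            out = np.interp(r, self.ratios[::-1], self.ph_values[::-1])
        else:
            assert self.params is not None
            eps = 1e-12 * (self.params.high - self.params.low)
            out = self.params.inverse(
                np.clip(r, self.params.low + eps, self.params.high - eps)
            )
        out = np.where(np.isnan(np.atleast_1d(ratio)), np.nan, out)
        return out if np.ndim(ratio) else float(out[0])

    def ratio_from_ph(self, ph: np.ndarray | float) -> np.ndarray | float:
        if self.model == "piecewise":
            return np.interp(ph, self.ph_values, self.ratios)
        assert self.params is not None
        return self.params(ph)


def fit_calibration(
    buffer_images: Sequence[tuple[float, ChannelStack]],
    nuclear_masks: Sequence[np.ndarray | None] | None = None,
    model: str = "piecewise",
    kernel_px: int = 7,
    alexa_threshold: float | None = None,
    channel_map: dict[str, str] | None = None,
) -> CalibrationCurve:
    """Build a calibration curve from (pH, image) buffer standards.

    Each buffer's mean masked ratio is computed with nuclear pixels excluded
    (nuclear masks optional). Standards must be strictly monotone (ratio
    decreasing with pH) or fitting fails naming the offending pair.
    ``model='4pl'`` fits a four-parameter logistic (needs ≥ 4 standards);
    the default is exact piecewise-linear interpolation through the means.
    """
    if len(buffer_images) < 3:
        raise ContractError("calibration requires >= 3 buffer standards")
    phs = [ph for ph, _ in buffer_images]
    if len(set(phs)) != len(phs):
        raise ContractError("calibration standards must have distinct pH values")
    if nuclear_masks is None:
        nuclear_masks = [None] * len(buffer_images)
    means = []
    for (ph, stack), nuc in zip(buffer_images, nuclear_masks):
        ratio, _ = ratio_image(stack, kernel_px, alexa_threshold, channel_map)
        valid = np.isfinite(ratio)
        if nuc is not None:
            valid &= ~np.asarray(nuc, dtype=bool)
        if not valid.any():
            raise ContractError(f"buffer at pH {ph:g} has no defined ratio pixels")
        means.append(float(ratio[valid].mean()))
    ph_arr = np.asarray(phs, dtype=float)
    ratio_arr = np.asarray(means, dtype=float)
    curve = CalibrationCurve(ph_arr, ratio_arr)  # validates monotonicity
    if model == "piecewise":
        return curve
    if model == "4pl":
        if ph_arr.size < 4:
            raise ContractError("4PL model requires >= 4 standards")
        order = np.argsort(ph_arr)
        x, y = ph_arr[order], ratio_arr[order]

        def f(ph, high, low, mid, steep):
            return low + (high - low) / (1.0 + np.exp(steep * (ph - mid)))

        p0 = (y.max(), y.min(), float(x[np.argmin(np.abs(y - y.mean()))]), 1.0)
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20000)
        params = FourParamLogistic(*popt)
        return CalibrationCurve(
            ph_arr, ratio_arr, model="4pl", params=params, residuals=y - f(x, *popt)
        )
    raise ContractError(f"unknown calibration model {model!r}")


@dataclass
class PHMap:
    """Per-pixel pH with undefined pixels as NaN plus provenance."""

    ph: np.ndarray
    clamp_fraction: float
    background_mask: BinaryMask | None = None
    nuclear_mask: np.ndarray | None = None
    gating: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.ph)

    def mean_ph(self) -> float:
        d = self.defined()
        return float(self.ph[d].mean()) if d.any() else float("nan")


def ph_map(
    ratio: np.ndarray,
    curve: CalibrationCurve,
    nuclear_mask: np.ndarray | None = None,
    background_mask: BinaryMask | None = None,
) -> PHMap:
    """Per-pixel pH map by inverting the calibration model.

    Nuclear pixels are set undefined; NaN (background) ratios propagate as
    undefined pH; ratios outside the calibration domain are clamped to the
    domain ends and counted in ``clamp_fraction``.
    """
    ratio = np.asarray(ratio, dtype=float)
    if nuclear_mask is not None:
        nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
        if nuclear_mask.shape != ratio.shape:
            raise ContractError("nuclear mask shape mismatch")
        ratio = np.where(nuclear_mask, np.nan, ratio)
    lo, hi = curve.ratio_range
    finite = np.isfinite(ratio)
    n_clamped = int(((ratio < lo) | (ratio > hi))[finite].sum())
    ph = np.full(ratio.shape, np.nan)
    ph[finite] = curve.ph_from_ratio(ratio[finite], clamp=True)
    clamp_fraction = n_clamped / max(int(finite.sum()), 1)
    return PHMap(
        ph=ph,
        clamp_fraction=float(clamp_fraction),
        background_mask=background_mask,
        nuclear_mask=nuclear_mask,
        gating={"model": curve.model, "ratio_range": curve.ratio_range},
    )
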