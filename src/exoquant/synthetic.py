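"""Seeded synthetic scenes with complete ground truth.

Every quantification stage in this package is exercised on synthetic data
that emulates the statistical structure of the corresponding experiment:

* **CLS scenes** — crown-like (macrophages ringing an adipocyte) or
  dispersed (resident) geometry; macrophages carry a cytoplasmic F4/80
  (FITC) fill, plasma-membrane LAMP-1 (Cy3) rings and/or punctate
  lysosomal LAMP-1, one DAPI nucleus each, and a calnexin (Cy5) fill for a
  Bernoulli-sampled permeable subpopulation.
* **pH scenes** — a known pH field imaged through a strictly decreasing
  ratio→pH response as a CypHer/Alexa488 channel pair.
* **Uptake scenes** — CtB-outlined macrophages with internalized puncta
  summing to a prescribed per-cell total, next to an adipocyte body, with
  known contact flags.
* **EM volumes** — two cell phases meeting at an interface with lumenal
  cavities that are sealed or opened to a volume face by construction.

Cells are simple primitives (discs, rings, boxes, ellipsoids): adequate to
exercise mask algebra and flood fill, with no claim of morphological
realism. All painting is conservative — ground truth records every painted
quantity before background and noise are added — and each scene uses one
explicit RNG stream, so regeneration with the same spec and seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .em3d import PHASES, EMVolume, extract_compartments
from .phmap import FourParamLogistic
from .stack import ChannelStack, ContractError, ExoquantError


class PlacementError(ExoquantError, RuntimeError):
    """Non-overlapping cell placement failed after bounded retries."""


class GeometryError(ExoquantError, ValueError):
    """A requested primitive does not fit the volume/image."""


# --------------------------------------------------------------------------
# small raster helpers


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ring(
    shape: tuple[int, int], center: tuple[float, float], radius: float, thickness: float = 2.0
) -> np.ndarray:
    return _disk(shape, center, radius) & ~_disk(shape, center, radius - thickness)


def _apply_noise(
    channels: dict[str, np.ndarray],
    background_level: float,
    noise_sd: float,
    rng: np.random.Generator,
    noise_model: str = "gaussian",
) -> dict[str, np.ndarray]:
    out = {}
    for name, img in channels.items():
        img = img + background_level
        if noise_model == "gaussian":
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, img.shape)
        elif noise_model == "poisson":
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        else:
            raise ContractError(f"unknown noise model {noise_model!r}")
        out[name] = np.clip(img, 0.0, None)
    return out


# --------------------------------------------------------------------------
# CLS (tissue) scenes


@dataclass
class SceneSpec:
    """Parameters of a synthetic crown-like-structure scene.

    Signal levels are arbitrary fluorescence units (AFU):
    ``membrane_signal_mean`` per membrane-ring pixel, ``lysosomal_signal_mean``
    per punctum. ``signal_cv`` adds lognormal cell-to-cell heterogeneity of
    the membrane signal (macrophage responses are heterogeneous).
    ``permeable_fraction`` of macrophages are calnexin-accessible (Cy5
    filled). Noise is additive Gaussian (sd ``noise_sd``) clipped at zero on
    top of ``background_level``; a Poisson mode is available.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.3
    n_adipocytes: int = 4
    n_macrophages: int = 12
    geometry: str = "crown"
    membrane_signal_mean: float = 100.0
    lysosomal_signal_mean: float = 0.0
    permeable_fraction: float = 0.0
    background_level: float = 20.0
    noise_sd: float = 10.0
    seed: int = 0
    # rendering knobs
    signal_cv: float = 0.25
    adipocyte_radius_px: float = 26.0
    macrophage_radius_px: float = 7.0
    nucleus_radius_px: float = 3.0
    fitc_level: float = 150.0
    dapi_level: float = 200.0
    cy5_level: float = 150.0
    n_puncta: int = 4
    noise_model: str = "gaussian"
    max_retries: int = 500

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise ContractError("image dimensions must be >= 64x64")
        if not 0.0 <= self.permeable_fraction <= 1.0:
            raise ContractError("permeable_fraction must be in [0, 1]")
        if self.n_adipocytes < 0 or self.n_macrophages < 0 or self.n_puncta < 0:
            raise ContractError("counts must be >= 0")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ContractError("noise_sd and background_level must be >= 0")
        if self.geometry not in ("crown", "dispersed"):
            raise ContractError("geometry must be 'crown' or 'dispersed'")
        if self.signal_cv < 0:
            raise ContractError("signal_cv must be >= 0")


@dataclass
class SceneGroundTruth:
    """Everything painted into a CLS scene, recorded before noise."""

    macrophage_centers: np.ndarray  # (n, 2) row/col
    nucleus_mask: np.ndarray
    permeable_flags: np.ndarray
    true_surface_signal: np.ndarray
    true_lysosomal_signal: np.ndarray
    adipocyte_mask: np.ndarray
    contact_flags: np.ndarray


def _adipocyte_centers(spec: SceneSpec) -> list[tuple[float, float]]:
    h, w = spec.image_shape
    n = spec.n_adipocytes
    if n == 0:
        return []
    grid = int(np.ceil(np.sqrt(n)))
    centers = []
    for i in range(n):
        gy, gx = divmod(i, grid)
        cy = (gy + 0.5) * h / grid
        cx = (gx + 0.5) * w / grid
        centers.append((cy, cx))
    return centers


def _place_crown(spec: SceneSpec, adip_centers, rng) -> np.ndarray:
    h, w = spec.image_shape
    r_m = spec.macrophage_radius_px
    ring_r = spec.adipocyte_radius_px + r_m + 1.0
    min_sep = 2 * r_m + 4.0  # keep neighbouring cells from merging after smoothing
    if not adip_centers:
        raise ContractError("crown geometry requires n_adipocytes >= 1")
    per = [spec.n_macrophages // len(adip_centers)] * len(adip_centers)
    for i in range(spec.n_macrophages % len(adip_centers)):
        per[i] += 1
    capacity = int(2 * np.pi * ring_r / min_sep)
    if max(per) > capacity:
        raise PlacementError(
            f"cannot place {max(per)} macrophages on one crown (capacity {capacity}); "
            f"seed={spec.seed}"
        )
    centers: list[tuple[float, float]] = []
    for (cy, cx), k in zip(adip_centers, per):
        for attempt in range(spec.max_retries):
            phase = rng.uniform(0, 2 * np.pi)
            angles = phase + 2 * np.pi * np.arange(k) / max(k, 1)
            cand = [(cy + ring_r * np.sin(a), cx + ring_r * np.cos(a)) for a in angles]
            ok = all(
                r_m + 1 <= y <= h - r_m - 2 and r_m + 1 <= x <= w - r_m - 2 for y, x in cand
            )
            if ok and centers:
                prev = np.asarray(centers)
                for y, x in cand:
                    if np.min(np.hypot(prev[:, 0] - y, prev[:, 1] - x)) < min_sep:
                        ok = False
                        break
            if ok:
                centers.extend(cand)
                break
        else:
            raise PlacementError(
                f"crown placement failed after {spec.max_retries} retries; seed={spec.seed}"
            )
    return np.asarray(centers, dtype=float)


def _place_dispersed(spec: SceneSpec, adip_centers, rng) -> np.ndarray:
    h, w = spec.image_shape
    r_m = spec.macrophage_radius_px
    keep_out = spec.adipocyte_radius_px + r_m + 3.0
    min_sep = 2 * r_m + 4.0
    centers: list[tuple[float, float]] = []
    for _ in range(spec.n_macrophages):
        for attempt in range(spec.max_retries):
            y = rng.uniform(r_m + 1, h - r_m - 2)
            x = rng.uniform(r_m + 1, w - r_m - 2)
            if adip_centers and any(
                np.hypot(cy - y, cx - x) < keep_out for cy, cx in adip_centers
            ):
                continue
            if centers:
                prev = np.asarray(centers)
                if np.min(np.hypot(prev[:, 0] - y, prev[:, 1] - x)) < min_sep:
                    continue
            centers.append((y, x))
            break
        else:
            raise PlacementError(
                f"dispersed placement failed after {spec.max_retries} retries; seed={spec.seed}"
            )
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def generate_cls_scene(spec: SceneSpec) -> tuple[ChannelStack, SceneGroundTruth]:
    """Render a 4-channel CLS scene (FITC, Cy3, DAPI, Cy5) with ground truth.

    The Cy3 membrane ring of each macrophage carries its per-cell
    heterogeneity factor; puncta carry ``lysosomal_signal_mean`` each.
    Ground truth records painted totals exactly (before background/noise).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    adip_centers = _adipocyte_centers(spec)
    if spec.geometry == "crown":
        centers = _place_crown(spec, adip_centers, rng)
    else:
        centers = _place_dispersed(spec, adip_centers, rng)
    n = centers.shape[0]

    adipocyte_mask = np.zeros(shape, bool)
    for c in adip_centers:
        adipocyte_mask |= _disk(shape, c, spec.adipocyte_radius_px)

    permeable = rng.random(n) < spec.permeable_fraction
    cell_factor = (
        rng.lognormal(mean=-0.5 * np.log1p(spec.signal_cv**2), sigma=np.sqrt(np.log1p(spec.signal_cv**2)), size=n)
        if spec.signal_cv > 0
        else np.ones(n)
    )

    fitc = np.zeros(shape)
    cy3 = np.zeros(shape)
    dapi = np.zeros(shape)
    cy5 = np.zeros(shape)
    nucleus_mask = np.zeros(shape, bool)
    true_surface = np.zeros(n)
    true_lyso = np.zeros(n)

    r_m = spec.macrophage_radius_px
    for i, (cy_, cx_) in enumerate(centers):
        body = _disk(shape, (cy_, cx_), r_m)
        fitc[body] += spec.fitc_level
        if spec.membrane_signal_mean > 0:
            # ring sits one pixel inside the cell boundary so the smoothed
            # membrane signal stays within the smoothed F4/80 footprint
            ring = _ring(shape, (cy_, cx_), r_m - 1.0, thickness=2.0)
            per_px = spec.membrane_signal_mean * cell_factor[i]
            cy3[ring] += per_px
            true_surface[i] = per_px * int(ring.sum())
        if spec.lysosomal_signal_mean > 0 and spec.n_puncta > 0:
            for _ in range(spec.n_puncta):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max(r_m - 3.0, 0.5))
                py = int(round(cy_ + rad * np.sin(ang)))
                px = int(round(cx_ + rad * np.cos(ang)))
                cy3[py, px] += spec.lysosomal_signal_mean
                true_lyso[i] += spec.lysosomal_signal_mean
        nuc = _disk(shape, (cy_, cx_), spec.nucleus_radius_px)
        dapi[nuc] += spec.dapi_level
        nucleus_mask |= nuc
        if permeable[i]:
            cy5[body] += spec.cy5_level

    contact = np.zeros(n, bool)
    if adip_centers:
        ac = np.asarray(adip_centers)
        d = np.hypot(
            centers[:, 0:1] - ac[None, :, 0], centers[:, 1:2] - ac[None, :, 1]
        ).min(axis=1)
        contact = d <= spec.adipocyte_radius_px + r_m + 1.5

    channels = _apply_noise(
        {"FITC": fitc, "Cy3": cy3, "DAPI": dapi, "Cy5": cy5},
        spec.background_level,
        spec.noise_sd,
        rng,
        spec.noise_model,
    )
    stack = ChannelStack(channels, pixel_size_um=spec.pixel_size_um)
    truth = SceneGroundTruth(
        macrophage_centers=centers,
        nucleus_mask=nucleus_mask,
        permeable_flags=permeable,
        true_surface_signal=true_surface,
        true_lysosomal_signal=true_lyso,
        adipocyte_mask=adipocyte_mask,
        contact_flags=contact,
    )
    return stack, truth


# --------------------------------------------------------------------------
# pH scenes


@dataclass
class PhSceneSpec:
    """Synthetic ratiometric pH scene: a pH field in [3, 9] imaged through a
    strictly decreasing ratio→pH response. The noise-free per-pixel
    CypHer/Alexa ratio equals ``response(ph_field)`` exactly."""

    ph_field: np.ndarray
    response: FourParamLogistic = field(default_factory=FourParamLogistic)
    alexa_level: float = 1000.0
    noise_sd: float = 0.0
    nuclear_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.ph_field = np.asarray(self.ph_field, dtype=float)
        if self.ph_field.ndim != 2:
            raise ContractError("ph_field must be 2D")
        if self.ph_field.min() < 3.0 or self.ph_field.max() > 9.0:
            raise ContractError("ph_field values must lie in [3, 9]")
        if self.alexa_level <= 0 or self.noise_sd < 0:
            raise ContractError("alexa_level must be > 0 and noise_sd >= 0")
        if self.nuclear_mask is not None:
            self.nuclear_mask = np.asarray(self.nuclear_mask, dtype=bool)
            if self.nuclear_mask.shape != self.ph_field.shape:
                raise ContractError("nuclear_mask shape mismatch")


@dataclass
class PhGroundTruth:
    ph_field: np.ndarray
    response: FourParamLogistic
    nuclear_mask: np.ndarray | None


def generate_ph_scene(spec: PhSceneSpec) -> tuple[ChannelStack, PhGroundTruth]:
    """Render the CypHer/Alexa488 pair for a known pH field."""
    rng = np.random.default_rng(spec.seed)
    ratio = np.asarray(spec.response(spec.ph_field), dtype=float)
    channels = _apply_noise(
        {"CypHer": spec.alexa_level * ratio, "Alexa488": np.full(spec.ph_field.shape, spec.alexa_level)},
        background_level=0.0,
        noise_sd=spec.noise_sd,
        rng=rng,
    )
    stack = ChannelStack(channels)
    return stack, PhGroundTruth(spec.ph_field.copy(), spec.response, spec.nuclear_mask)


def acidic_pocket_field(
    shape: tuple[int, int] = (128, 128),
    base_ph: float = 7.2,
    pockets: Sequence[tuple[float, float, float, float]] = ((64, 64, 14.0, 2.5),),
) -> np.ndarray:
    """Smooth pH field: a neutral background with Gaussian acidic pockets.

    Each pocket is (row, col, sigma_px, depth_pH); mimics acidified
    extracellular compartments at a macrophage–adipocyte interface.
    """
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    ph = np.full(shape, float(base_ph))
    for cy, cx, sigma, depth in pockets:
        ph -= depth * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma**2))
    return np.clip(ph, 3.0, 9.0)


def generate_calibration_buffers(
    ph_values: Sequence[float],
    response: FourParamLogistic | None = None,
    alexa_level: float = 1000.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> list[tuple[float, ChannelStack]]:
    """Uniform-pH buffer images for calibration-curve fitting."""
    response = response or FourParamLogistic()
    out = []
    for i, ph in enumerate(ph_values):
        spec = PhSceneSpec(
            ph_field=np.full(shape, float(ph)),
            response=response,
            alexa_level=alexa_level,
            noise_sd=noise_sd,
            seed=seed + i,
        )
        stack, _ = generate_ph_scene(spec)
        out.append((float(ph), stack))
    return out


# --------------------------------------------------------------------------
# uptake / foam-cell scenes


@dataclass
class UptakeGroundTruth:
    macrophage_centers: np.ndarray
    true_power: np.ndarray
    contact_flags: np.ndarray
    adipocyte_mask: np.ndarray


@dataclass
class UptakeSceneSpec:
    """Layout knobs for :func:`generate_uptake_scene`."""

    image_shape: tuple[int, int] = (192, 192)
    cell_radius_px: float = 10.0
    adipocyte_center: tuple[float, float] = (52.0, 44.0)
    adipocyte_radius_px: float = 28.0
    ctb_level: float = 150.0
    adipocyte_level: float = 200.0
    background_level: float = 0.0
    noise_sd: float = 0.0
    n_puncta: int = 4
    # contacting cells leave a small gap so their segmented footprint (the
    # painted ring plus its smoothing halo) never overlaps the adipocyte
    # body; non-contact cells are kept far outside the contact radius
    contact_gap_px: float = 2.0
    noncontact_gap_px: float = 12.0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 64 or w < 64:
            raise ContractError("image dimensions must be >= 64x64")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ContractError("noise_sd and background_level must be >= 0")


def generate_uptake_scene(
    per_cell_truth: Sequence[float],
    contact_pattern: Sequence[bool],
    seed: int = 0,
    spec: UptakeSceneSpec | None = None,
) -> tuple[ChannelStack, UptakeGroundTruth]:
    """Render a CtB + Alexa546 uptake scene with prescribed per-cell totals.

    Each macrophage is drawn as a CtB surface ring; its internalized signal
    is ``n_puncta`` equal-valued puncta in the cell interior summing to its
    entry of ``per_cell_truth`` (painting is conservative: ground truth
    stores the painted sum). Cells flagged in ``contact_pattern`` are placed
    tangent to the adipocyte body (painted into the Alexa546 channel); the
    rest are kept well clear of it. LipidTOX foam-cell scenes use the same
    generator with the signal channel read as LipidTOX.
    """
    spec = spec or UptakeSceneSpec()
    truths = np.asarray(per_cell_truth, dtype=float)
    contact = np.asarray(contact_pattern, dtype=bool)
    if truths.shape != contact.shape:
        raise ContractError("per_cell_truth and contact_pattern lengths differ")
    if (truths < 0).any():
        raise ContractError("per-cell truth values must be >= 0")
    rng = np.random.default_rng(seed)
    shape = spec.image_shape
    h, w = shape
    r = spec.cell_radius_px
    acy, acx = spec.adipocyte_center
    ar = spec.adipocyte_radius_px
    adipocyte_mask = _disk(shape, (acy, acx), ar)

    # contacting cells: just off the adipocyte perimeter
    centers = np.zeros((truths.size, 2))
    placed: list[tuple[float, float]] = []
    # ring + 2-px smoothing halo per cell: keep halos from touching
    min_sep = 2 * r + 6.0
    for i in np.flatnonzero(contact):
        for _ in range(spec.max_retries):
            ang = rng.uniform(0, 2 * np.pi)
            y = acy + (ar + r + spec.contact_gap_px) * np.sin(ang)
            x = acx + (ar + r + spec.contact_gap_px) * np.cos(ang)
            if not (r + 1 <= y <= h - r - 2 and r + 1 <= x <= w - r - 2):
                continue
            if placed and min(np.hypot(py - y, px - x) for py, px in placed) < min_sep:
                continue
            placed.append((y, x))
            centers[i] = (y, x)
            break
        else:
            raise PlacementError(f"contact placement failed; seed={seed}")
    # non-contact cells: jittered grid, kept clear of the adipocyte
    keep_out = ar + r + spec.noncontact_gap_px
    grid_step = max(min_sep + 4.0, 24.0)
    gys = np.arange(r + 4, h - r - 4, grid_step)
    gxs = np.arange(r + 4, w - r - 4, grid_step)
    sites = [
        (gy, gx)
        for gy in gys
        for gx in gxs
        if np.hypot(gy - acy, gx - acx) >= keep_out + 4.0
        and all(np.hypot(gy - py, gx - px) >= min_sep + 3.0 for py, px in placed)
    ]
    rng.shuffle(sites)
    free = list(np.flatnonzero(~contact))
    if len(free) > len(sites):
        raise PlacementError(
            f"not enough free sites for {len(free)} non-contact cells; seed={seed}"
        )
    for i, (gy, gx) in zip(free, sites):
        y = gy + rng.uniform(-3, 3)
        x = gx + rng.uniform(-3, 3)
        centers[i] = (y, x)

    ctb = np.zeros(shape)
    signal = np.zeros(shape)
    signal[adipocyte_mask] += spec.adipocyte_level
    true_power = np.zeros(truths.size)
    for i, (cy_, cx_) in enumerate(centers):
        ctb[_ring(shape, (cy_, cx_), r, thickness=2.0)] += spec.ctb_level
        if truths[i] > 0 and spec.n_puncta > 0:
            part = truths[i] / spec.n_puncta
            for _ in range(spec.n_puncta):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, max(r - 4.0, 0.5))
                py = int(round(cy_ + rad * np.sin(ang)))
                px = int(round(cx_ + rad * np.cos(ang)))
                signal[py, px] += part
                true_power[i] += part

    channels = _apply_noise(
        {"CtB": ctb, "Alexa546": signal},
        spec.background_level,
        spec.noise_sd,
        rng,
    )
    stack = ChannelStack(channels)
    return stack, UptakeGroundTruth(
        macrophage_centers=centers,
        true_power=true_power,
        contact_flags=contact,
        adipocyte_mask=adipocyte_mask,
    )


# --------------------------------------------------------------------------
# EM volumes


@dataclass
class CavitySpec:
    """One lumenal cavity primitive.

    ``size`` is the full extent per axis for a box, or the semi-axes for an
    ellipsoid, in voxels. ``sealed=False`` opens a one-voxel lumen channel
    from the cavity to the +y volume face.
    """

    shape: str = "box"
    center: tuple[int, int, int] = (0, 0, 0)
    size: tuple[int, int, int] = (10, 10, 10)
    sealed: bool = True

    def __post_init__(self) -> None:
        if self.shape not in ("box", "ellipsoid"):
            raise ContractError("cavity shape must be 'box' or 'ellipsoid'")


@dataclass
class VolumeSpec:
    """Synthetic EM volume: macrophage and adipocyte half-spaces meeting at
    a z interface, wrapped in a background border, with lumenal cavities.

    ``density_levels`` set the mean intensity per phase; defaults are
    ordered background < lumen < macrophage < adipocyte so threshold
    banding can recover the phases.
    """

    volume_shape: tuple[int, int, int] = (48, 64, 64)
    voxel_size_nm: tuple[float, float, float] = (20.0, 10.0, 10.0)
    cavities: list[CavitySpec] = field(default_factory=list)
    density_levels: dict[str, float] = field(
        default_factory=lambda: {
            "background": 20.0,
            "lumen": 90.0,
            "macrophage": 160.0,
            "adipocyte": 230.0,
        }
    )
    noise_sd: float = 0.0
    background_border: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ContractError("volume_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ContractError("voxel sizes must be positive")
        if set(self.density_levels) != set(PHASES):
            raise ContractError(f"density_levels must name exactly {sorted(PHASES)}")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")


@dataclass
class CompartmentGroundTruth:
    """Per-cavity ground truth: actual carved lumen voxels and sealedness."""

    voxel_counts: np.ndarray
    volumes_nm3: np.ndarray
    sealed: np.ndarray


def _cavity_mask(cav: CavitySpec, shape: tuple[int, int, int]) -> np.ndarray:
    cz, cy, cx = cav.center
    if cav.shape == "box":
        sz, sy, sx = cav.size
        lo = (cz - sz // 2, cy - sy // 2, cx - sx // 2)
        hi = (lo[0] + sz, lo[1] + sy, lo[2] + sx)
        if min(lo) < 0 or any(h > d for h, d in zip(hi, shape)):
            raise GeometryError(f"cavity {cav} extends beyond volume bounds {shape}")
        m = np.zeros(shape, bool)
        m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return m
    az, ay, ax = cav.size
    if (
        cz - az < 0
        or cz + az >= shape[0]
        or cy - ay < 0
        or cy + ay >= shape[1]
        or cx - ax < 0
        or cx + ax >= shape[2]
    ):
        raise GeometryError(f"cavity {cav} extends beyond volume bounds {shape}")
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_em_volume(spec: VolumeSpec) -> tuple[EMVolume, CompartmentGroundTruth]:
    """Render a phase-labelled + intensity EM volume with known cavities.

    The returned :class:`EMVolume` carries both the intensity (phase levels
    plus optional Gaussian noise) and the generating phase labels. Before
    returning, sealed/open flags are re-derived by flood fill
    (:func:`exoquant.em3d.extract_compartments`) and checked against the
    spec — a self-consistency guarantee that the ground truth is honest.
    """
    shape = spec.volume_shape
    b = spec.background_border
    phases = np.full(shape, PHASES["background"], dtype=np.int8)
    z_mid = shape[0] // 2
    interior = (slice(b, shape[0] - b), slice(b, shape[1] - b), slice(b, shape[2] - b))
    phases[b:z_mid, b : shape[1] - b, b : shape[2] - b] = PHASES["macrophage"]
    phases[z_mid : shape[0] - b, b : shape[1] - b, b : shape[2] - b] = PHASES["adipocyte"]

    masks = []
    lumen_total = np.zeros(shape, bool)
    for cav in spec.cavities:
        m = _cavity_mask(cav, shape)
        if (phases[m] == PHASES["background"]).any():
            raise GeometryError(f"cavity {cav} overlaps the background border")
        if not cav.sealed:
            cz, cy, cx = cav.center
            channel = np.zeros(shape, bool)
            channel[cz, cy:, cx] = True
            m = m | channel
        if (m & lumen_total).any():
            raise GeometryError("cavities overlap; ground truth would be ambiguous")
        lumen_total |= m
        masks.append(m)
    phases[lumen_total] = PHASES["lumen"]

    rng = np.random.default_rng(spec.seed)
    levels = np.array(
        [spec.density_levels[name] for name, code in sorted(PHASES.items(), key=lambda kv: kv[1])]
    )
    intensity = levels[phases]
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, shape)

    counts = np.array([int(m.sum()) for m in masks])
    dz, dy, dx = spec.voxel_size_nm
    truth = CompartmentGroundTruth(
        voxel_counts=counts,
        volumes_nm3=counts * dz * dy * dx,
        sealed=np.array([c.sealed for c in spec.cavities], dtype=bool),
    )

    # self-consistency: flood-fill verification of the sealed flags
    comp = extract_compartments(phases, spec.voxel_size_nm)
    found = {c.id: c for c in comp.compartments}
    for m, cav in zip(masks, spec.cavities):
        ids = np.unique(comp.label_volume[m])
        ids = ids[ids > 0]
        if ids.size != 1:
            raise GeometryError(f"cavity {cav} did not form a single lumen component")
        if found[int(ids[0])].sealed != cav.sealed:
            raise GeometryError(
                f"flood-fill sealedness of cavity {cav} contradicts its sealed flag"
            )

    volume = EMVolume(intensity=intensity, voxel_size_nm=spec.voxel_size_nm, phases=phases)
    return volume, truth


def default_em_thresholds(density_levels: dict[str, float]) -> tuple[float, float, float]:
    """Midpoint thresholds between the sorted phase density levels."""
    lv = sorted(density_levels.values())
    return tuple((a + b) / 2.0 for a, b in zip(lv, lv[1:]))
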