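"""End-to-end seeded in-silico experiments.

Each function reproduces one experimental design on synthetic scenes with
known ground truth: generate the scenes, quantify them with the package's
pipeline, and test the comparison — exactly the generate → quantify → test
loop a study would run on real images. All randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import cellquant, maskquant, phmap, stats, synthetic
from .phmap import FourParamLogistic
from .synthetic import (
    PhSceneSpec,
    SceneSpec,
    UptakeSceneSpec,
    VolumeSpec,
    CavitySpec,
)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n independent 31-bit scene seeds from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def lamp1_fold_experiment(
    seed: int,
    fold: float = 2.2,
    n_cells: int = 40,
    snr: float = 10.0,
    base_membrane: float = 100.0,
    image_shape: tuple[int, int] = (256, 256),
) -> dict:
    """Crown (CLS-like) vs dispersed (resident-like) surface LAMP-1.

    Generates one scene per arm with ``n_cells`` macrophages, the crown arm
    carrying a ``fold``-times higher membrane LAMP-1 signal, at
    signal-to-noise ratio ``snr`` (membrane AFU per pixel over noise sd).
    Quantifies per-cell surface LAMP-1 with the mask-algebra pipeline and
    compares arms with the rank-sum test. Returns the recovered fold change
    (ratio of arm means) and the two-sided p-value.
    """
    s_crown, s_disp = _sub_seeds(seed, 2)
    noise_sd = base_membrane / snr
    common = dict(
        image_shape=image_shape,
        n_adipocytes=4,
        n_macrophages=n_cells,
        permeable_fraction=0.0,
        noise_sd=noise_sd,
    )
    crown_spec = SceneSpec(
        geometry="crown", membrane_signal_mean=base_membrane * fold, seed=int(s_crown), **common
    )
    disp_spec = SceneSpec(
        geometry="dispersed", membrane_signal_mean=base_membrane, seed=int(s_disp), **common
    )
    per_cell = {}
    for arm, spec in (("cls", crown_spec), ("resident", disp_spec)):
        stack, _ = synthetic.generate_cls_scene(spec)
        _, values = maskquant.surface_lamp1_per_region(stack)
        per_cell[arm] = values
    fold_est = float(per_cell["cls"].mean() / per_cell["resident"].mean())
    test = stats.rank_sum_test(per_cell["cls"], per_cell["resident"])
    return {
        "fold_estimate": fold_est,
        "p_value": test.p_value,
        "per_cell": per_cell,
        "true_fold": fold,
    }


def ph_recovery_experiment(
    seed: int,
    snr: float | None = None,
    image_shape: tuple[int, int] = (128, 128),
    buffer_ph: tuple[float, ...] = (4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5),
    edge_margin: int = 8,
) -> dict:
    """Round-trip pH recovery on a smooth acidified-pocket field.

    A known pH field (neutral background, Gaussian acidic pockets) is imaged
    through the default probe response at signal-to-noise ratio ``snr``
    (``None`` = noise-free), calibrated against noise-free buffer standards,
    and inverted back to pH. Returns the RMSE between recovered and true pH
    over defined pixels away from the image edges.
    """
    field = synthetic.acidic_pocket_field(
        image_shape,
        base_ph=7.2,
        pockets=(
            (image_shape[0] * 0.38, image_shape[1] * 0.42, 13.0, 2.6),
            (image_shape[0] * 0.66, image_shape[1] * 0.64, 10.0, 1.8),
        ),
    )
    response = FourParamLogistic()
    alexa_level = 1000.0
    noise_sd = 0.0 if snr is None else alexa_level / snr
    stack, truth = synthetic.generate_ph_scene(
        PhSceneSpec(ph_field=field, response=response, alexa_level=alexa_level, noise_sd=noise_sd, seed=seed)
    )
    buffers = synthetic.generate_calibration_buffers(buffer_ph, response, alexa_level)
    curve = phmap.fit_calibration(buffers, alexa_threshold=alexa_level / 2.0)
    ratio, mask = phmap.ratio_image(stack, alexa_threshold=alexa_level / 2.0)
    result = phmap.ph_map(ratio, curve)
    interior = np.zeros(image_shape, bool)
    interior[edge_margin:-edge_margin, edge_margin:-edge_margin] = True
    sel = result.defined() & interior
    err = result.ph[sel] - truth.ph_field[sel]
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "n_pixels": int(sel.sum()),
        "clamp_fraction": result.clamp_fraction,
        "ph_map": result,
        "true_field": truth.ph_field,
    }


def uptake_experiment(
    seed: int,
    truths_a: np.ndarray,
    truths_b: np.ndarray,
    noise_sd: float = 0.0,
    background_level: float = 0.0,
    contact: bool = False,
) -> dict:
    """Quantify two uptake arms (e.g. untreated vs bafilomycin) end to end.

    Each arm is one scene whose cells carry the given per-cell true totals;
    per-cell fluorescence power is measured from the labelled CtB boundaries
    and the arms compared by rank-sum. ``contact=True`` places cells tangent
    to the adipocyte and gates measurements on the contact filter.
    """
    s_a, s_b = _sub_seeds(seed, 2)
    n_max = max(len(truths_a), len(truths_b))
    side = 192 if n_max <= 20 else 256  # enough placement sites per arm
    spec = UptakeSceneSpec(
        image_shape=(side, side), noise_sd=noise_sd, background_level=background_level
    )
    powers = {}
    for arm, truths, s in (("a", truths_a, s_a), ("b", truths_b, s_b)):
        pattern = np.full(len(truths), bool(contact))
        stack, truth = synthetic.generate_uptake_scene(truths, pattern, seed=int(s), spec=spec)
        cells = cellquant.label_cells_from_ctb(stack["CtB"])
        p = cellquant.cell_power(cells, stack["Alexa546"])
        if contact:
            adip = cellquant.adipocyte_mask_from_channel(stack["Alexa546"])
            p = p[cellquant.contact_filter(cells, adip, radius_px=3)]
        powers[arm] = p
    test = stats.rank_sum_test(powers["a"], powers["b"])
    return {"powers": powers, "p_value": test.p_value, "statistic": test.statistic}


def null_uptake_replicate(seed: int, n_cells: int = 20) -> float:
    """One null replicate: both arms drawn from the same heterogeneous
    per-cell uptake distribution, full scene → quantify → test loop.
    Returns the rank-sum p-value."""
    rng = np.random.default_rng(seed)
    truths_a = rng.lognormal(mean=np.log(200.0), sigma=0.6, size=n_cells)
    truths_b = rng.lognormal(mean=np.log(200.0), sigma=0.6, size=n_cells)
    sub = int(rng.integers(0, 2**31 - 1))
    res = uptake_experiment(sub, truths_a, truths_b, noise_sd=5.0, background_level=10.0)
    return res["p_value"]


def type_i_error_rate(seed: int, n_reps: int = 2000, n_cells: int = 20, alpha: float = 0.05) -> float:
    """Rejection rate at level alpha across seeded null replicates."""
    seeds = _sub_seeds(seed, n_reps)
    rejections = sum(null_uptake_replicate(int(s), n_cells) < alpha for s in seeds)
    return rejections / n_reps


def em_compartment_experiment(seed: int = 0, noise_sd: float = 0.0) -> dict:
    """Detect sealed compartments in a synthetic volume: 2 sealed + 1 open.

    Generates the volume, classifies phases from intensity by threshold
    banding, extracts lumen components, and compares against ground truth.
    """
    spec = VolumeSpec(
        volume_shape=(48, 64, 96),
        cavities=[
            CavitySpec(shape="box", center=(24, 24, 24), size=(10, 10, 10), sealed=True),
            CavitySpec(shape="box", center=(24, 40, 64), size=(7, 7, 7), sealed=True),
            CavitySpec(shape="ellipsoid", center=(24, 20, 70), size=(5, 6, 7), sealed=False),
        ],
        noise_sd=noise_sd,
        seed=seed,
    )
    volume, truth = synthetic.generate_em_volume(spec)
    from .em3d import analyze_volume
    from .synthetic import default_em_thresholds

    comps = analyze_volume(volume, default_em_thresholds(spec.density_levels))
    return {"compartments": comps, "truth": truth, "volume": volume, "spec": spec}
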