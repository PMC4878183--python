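# Methods

This note records the models, parameter choices and numerical decisions
behind `exoquant`, and what the synthetic benchmarks do and do not
establish about real microscopy.

## Image model and conventions

All 2D images are `(row, col)`, 0-based, pixel-centred, non-negative
floats in arbitrary fluorescence units (AFU); channels of a
`ChannelStack` share one grid and a single isotropic pixel size (µm).
3D EM volumes are `(z, y, x)` with anisotropic voxel sizes in nm
(default 20 × 10 × 10 — typical for ion-abrasion serial imaging at
10 nm/pixel with 20 nm slices). Stack registration is assumed done
upstream; `exoquant` never aligns images.

## Gaussian pre-filter

The "N×N Gaussian" filters of interactive microscopy packages are not
published as kernels. We use separable normalized binomial taps
([1,4,6,4,1]/16 for 5×5; [1,6,15,20,15,6,1]/64 for 7×7) — the standard
discrete Gaussian — with reflective boundaries, and expose a sampled-
Gaussian `sigma` override. The kernel sums to one, so constant images are
fixed points and totals of interior-supported signals are conserved; the
test suite checks the impulse response against a dense 2D convolution.

## Surface / lysosomal LAMP-1 per cell

Pipeline: smooth every channel (5×5) → threshold F4/80 (Otsu per channel
by default; every threshold actually applied is recorded in the gating
provenance) → for the surface variant, multiply by the inverted calnexin
mask → sum LAMP-1 within the combined mask → divide by the nucleus count.
Decisions that were genuinely open:

* **Background subtraction.** The per-cell sum of a masked channel grows
  with mask area, so any nonzero camera/background offset contaminates the
  readout and destroys fold-change recovery. We subtract the median LAMP-1
  intensity outside the F4/80 mask from every masked-in pixel (clamped at
  zero). This is the package's choice; the quantification description this
  mirrors is silent on offsets.
* **Denominator.** "Number of cells in the field" can mean all nuclei or
  only macrophage nuclei. Both are implemented
  (`nucleus_denominator='all' | 'fitc'`); the default counts nuclei
  overlapping the F4/80 mask, since the measured signal is macrophage-
  restricted by construction.
* **Nucleus counting** is smoothing → Otsu → 8-connected components →
  area filter (default ≥ 5 px). Nuclei merged by a bridge count once; no
  watershed split (simplicity as the tie-break; a split would add a
  parameter the benchmarks cannot calibrate).
* **Per-cell variant.** `surface_lamp1_per_region` aggregates the same
  masked signal per F4/80 connected component instead of per field. It
  exists because distribution-level comparisons (rank-sum across cells)
  need per-cell samples; in tissue with confluent macrophages the
  per-field average is the honest readout.
* **Permeability gating** (`classify_permeable`) flags a cell when its
  mean smoothed Cy5 exceeds twice the whole-image median Cy5 — a robust
  background multiple chosen so a blank channel yields fraction 0 and a
  filled channel fraction 1 without tuning; an explicit threshold can be
  supplied.

## Ratiometric pH

The probe response is modelled as a strictly decreasing 4-parameter
logistic `r(pH) = low + (high − low)/(1 + exp(s·(pH − pH₀)))` with
defaults high = 4.0, low = 0.1, pH₀ = 6.1, s = 1.4 /pH — an apparent pKa
near 6.1, matching a cyanine-based acidotropic probe. Calibration uses
buffer standards (defaults 4.0–7.5 in 0.5 steps, a conventional buffer
series); the curve is piecewise-linear interpolation through per-buffer
mean ratios (assumption-free, exact at the standards) with a 4PL fit
offered when ≥ 4 standards are available. Out-of-range ratios are clamped
to the domain ends and counted in a `clamp_fraction` rather than dropped —
dropping would bias spatial means acid-ward. Nuclear exclusion is an
explicit mask input; no automatic nuclear detection is attempted. Division
is guarded by the background mask; masked-in zero denominators are flagged
undefined with a warning. Frames of a time series are treated
independently.

## Per-cell power and gating

Cell boundaries: smooth → threshold → fill enclosed interiors →
8-connected components → area filter; border-touching cells are dropped by
default (partial cells bias power; toggleable). Power is the **raw**
(unsmoothed) pixel sum per label — smoothing would redistribute signal
across boundaries. Contact gating uses the Euclidean distance transform:
a cell is in contact when the minimum distance from its pixels to the
adipocyte mask is ≤ radius (default 1 px = direct adjacency), which is
monotone in the radius by construction. The adipocyte mask is derived
from the labelled-adipocyte channel by threshold + largest component.
Foam-cell positivity is power > threshold, fixed or adaptively
median + k·MAD (raw, unscaled MAD; k = 3) of a control population.

## 3D sealed compartments

Phase classification is intensity banding at 2–3 ordered thresholds, with
optional denoising first. The median filter is the preferred denoiser:
linear smoothing interpolates across a dark/bright cell interface straight
through the intermediate lumen band and manufactures spurious lumen
voxels, while the median preserves edges (the test suite demonstrates
≥ 99% voxel agreement at SNR 10 with a 3³ median). Sealedness is the
strictest test consistent with a "no gap at imaging resolution" criterion:
lumen components are 26-connected, a component is sealed iff it has no
voxel on a volume face and no 26-contact with background, and cell
adjacency uses the 6-neighbourhood. All components are reported with
flags; candidates are sealed ∧ adjacent to both cells. Volumes are
`voxels × dz·dy·dx`, reported in nm³ and µm³. Interactive (manual)
segmentation of real EM is replaced by threshold banding — adequate for
synthetic benchmarks, a simplification for real volumes.

## Statistics

Per-day normalization divides every value by that day's control median
(per metric), failing loudly when a control median is missing or zero.
The rank-sum test uses midranks; for n ≤ 12 the two-sided p is exact by
full enumeration of all C(n, n_a) rank assignments conditioned on the
observed ties, using the symmetric-tail definition
p = P(|W′ − μ| ≥ |W − μ|) (the permutation distribution of W is symmetric
about μ = n_a(n+1)/2, also under ties). Larger samples use the normal
approximation with tie-corrected variance and a 0.5 continuity
correction, which agrees with the exact p to < 0.02 at n = 8 + 8 and is
slightly conservative (attained level ≈ 0.049 at 20 + 20). The t-test is
the pooled-variance two-sample form; degenerate zero-variance inputs give
p = 1 (equal means) or p → 0 with a warning. All tests are two-sided; no
multiple-testing correction is applied (single planned comparisons).

## Synthetic scenes: what they emulate, and what they do not

Cells are simple primitives — discs for macrophage bodies and adipocytes,
2-px rings for membranes, single-pixel puncta for lysosomes/uptake, boxes
and ellipsoids for 3D cavities. Painting is conservative: ground truth
records every painted AFU before background and noise, so noise-free
recovery can be asserted exactly. One `numpy` Generator per scene, seeded
explicitly; regeneration is bit-identical. Noise is additive Gaussian
clipped at zero over a constant background (a Poisson mode is available);
SNR in the experiment helpers means signal level / noise sd.

Generator defaults are the study conditions of the benchmarks: membrane
signal 100 AFU/px with 25% lognormal cell-to-cell heterogeneity
(macrophage responses are heterogeneous), background 20, noise 10
(SNR 10); crown scenes ring 4 adipocytes, dispersed scenes keep cells off
the adipocytes; the permeable subpopulation is Bernoulli-sampled. The
layout enforces inter-cell spacing such that smoothed footprints do not
merge, membrane rings sit one pixel inside the cell boundary so the
smoothed ring stays within the smoothed F4/80 footprint, and uptake
scenes leave a 2-px gap between contacting cells and the adipocyte so the
segmented cell never swallows adipocyte pixels (contact gating then uses
radius 3). EM volumes wrap two cell slabs in a 2-voxel background border;
unsealed cavities get a one-voxel lumen channel to the +y face, and the
sealed/open flags are re-verified by flood fill before the ground truth
is returned.

These scenes exercise mask algebra, calibration inversion, labelling,
flood fill and the statistics under known truth. They do **not** model
point-spread functions, illumination fields, chromatic misregistration,
morphological variability, or touching-cell segmentation — passing
benchmarks here demonstrates the correctness of the quantification
algebra, not robustness to those real-data effects.

## Benchmark problem sizes

Chosen as the package's standard study scale: LAMP-1 oracle equivalence on
20 randomized 64×64 stacks; fold-change recovery with 40 cells/arm on
256×256 scenes over 50 seeds; pH round trips on 128×128 fields calibrated
with 8 buffers; EM detection on a 48×64×96 volume with two sealed and one
open cavity; the null-calibration study runs 2000 replicates of a
20-cell-per-arm uptake comparison on 192×192 scenes (the rank-sum
normal approximation's attained level at that size, ≈ 0.049 by rank-level
computation, sits inside the 0.05 ± 0.01 acceptance band with margin for
Monte-Carlo error).
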