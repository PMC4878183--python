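# exoquant

Quantitative image analysis of **macrophage exophagy** — the process by
which macrophages digest dead adipocytes that are far too large to
phagocytose, by sealing an acidified, hydrolase-filled extracellular
compartment (a *lysosomal synapse*) against the adipocyte surface.

`exoquant` re-implements, as a tested and reusable Python library, the
measurements such a study rests on:

| capability | module | readout |
| --- | --- | --- |
| surface / lysosomal LAMP-1 per cell in tissue | `exoquant.maskquant` | channel-mask algebra: Σ Cy3 within (F4/80 mask ∧ ¬calnexin mask) / nucleus count |
| ratiometric extracellular pH maps | `exoquant.phmap` | CypHer 5E / Alexa488 ratio inverted through a buffer calibration curve |
| per-macrophage uptake, dextran deposition, foam cells | `exoquant.cellquant` | fluorescence power: Σ pixel intensities within the CtB cell boundary, contact-gated |
| sealed compartments in 3D EM volumes | `exoquant.em3d` | 26-connected lumen components with flood-fill sealedness and dual-cell adjacency, volume = voxels × dz·dy·dx |
| statistics | `exoquant.stats` | per-day control-median normalization, exact/approximate Wilcoxon rank-sum, pooled t, SEM |
| synthetic ground truth | `exoquant.synthetic` | seeded 2D scenes and 3D volumes where every painted quantity is known |

Because the original microscopy is not redistributable, every pipeline
stage is exercisable end-to-end on synthetic scenes whose ground truth is
known exactly: crown-like structures (CLS) vs dispersed macrophages with a
prescribed LAMP-1 fold change, pH fields imaged through a known monotone
probe response, per-cell uptake totals painted as puncta, and 3D volumes
with cavities that are sealed or opened by construction.

## The core measurements

**Surface LAMP-1 (lysosome exocytosis marker).** Each channel is smoothed
with a normalized 5×5 binomial (Gaussian) kernel. A binary mask from the
F4/80 (FITC) channel selects macrophages; it is multiplied by the inverted
calnexin (Cy5) mask so permeabilized cells — whose intracellular LAMP-1
would masquerade as surface signal — are excluded. The resulting mask is
applied to the LAMP-1 (Cy3) channel and the surviving, background-corrected
signal is divided by the DAPI nucleus count:

```
S = Σ_{p ∈ M_FITC ∧ ¬M_Cy5} (Cy3(p) − bg) / N_nuclei
```

**Ratiometric pH.** With a pH-sensitive (CypHer, brighter when acidic) and
a pH-insensitive (Alexa488) label on the same target, the smoothed (7×7),
background-masked ratio R = CypHer/Alexa is a strictly decreasing function
of pH. Buffer standards of known pH give the calibration curve (piecewise
linear by default, 4-parameter logistic optionally), which is inverted
pixel-wise; nuclear pixels are excluded because the two dyes accumulate
there at different rates.

**Fluorescence power.** A cell's uptake (or LipidTOX, or surface LAMP-1
immunostain) is the exact sum of raw pixel intensities within its boundary,
labelled from the CtB membrane stain; uptake is only scored in cells in
contact with an adipocyte.

**Sealed compartments.** In a phase-classified EM volume, a lumen component
is *sealed* when no voxel lies on a volume face and none touches the
background phase (26-connectivity — one diagonal leak counts as open). A
sealed component adjacent to both macrophage and adipocyte is a
lysosomal-synapse candidate; its physical volume is `voxels × dz·dy·dx`
(anisotropic voxels, e.g. 20 × 10 × 10 nm).

## Worked example

`examples/02_lamp1_tissue.py` generates one crown-geometry scene (40
macrophages ringing adipocytes, 2.2× membrane LAMP-1) and one dispersed
scene (40 resident-like macrophages), quantifies per-cell surface LAMP-1
through the full mask-algebra pipeline, and tests the difference:

```
generated fold change: 2.2x (CLS over resident)
recovered fold change: 2.22x
rank-sum p (40 cells/arm): 2.08e-12

single field: 12 cells, surface LAMP-1 per cell = 3764 AFU
permeable (calnexin+) fraction: 0.33 (truth 0.33) — these cells are
excluded so lysosomal LAMP-1 cannot masquerade as surface signal
```

The recovered fold (2.22× vs the generated 2.2×) shows the masking,
background correction and per-cell aggregation are conservative; the tiny
rank-sum p mirrors the tissue finding that CLS macrophages carry roughly
double the plasma-membrane LAMP-1 of resident macrophages. The other
examples cover scene generation (`01`), pH mapping (`03`), uptake and
foam-cell positivity (`04`), EM compartments (`05`) and the statistics
layer (`06`); each prints the numbers it computes with a note on what they
mean.

## Scope

The package consumes already-registered images (multi-page TIFF with
channel metadata; 3D TIFF + YAML voxel sidecar) and quantifies them. It
does not align stacks, trace membranes, render 3D surfaces, model optics,
or score viability assays.
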