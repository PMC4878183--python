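"""Tissue-style surface LAMP-1 quantification by channel-mask algebra.

Reproduces the crown (inflamed, CLS) vs dispersed (resident) comparison:
per-cell plasma-membrane LAMP-1 is the Cy3 signal inside the F4/80 mask
with calnexin-positive (permeable) cells excluded, normalized per nucleus.
"""

from exoquant import SceneSpec, classify_permeable, generate_cls_scene, surface_lamp1_per_cell
from exoquant.experiments import lamp1_fold_experiment

res = lamp1_fold_experiment(seed=1, fold=2.2, n_cells=40, snr=10.0)
print(f"generated fold change: {res['true_fold']}x (CLS over resident)")
print(f"recovered fold change: {res['fold_estimate']:.2f}x")
print(f"rank-sum p (40 cells/arm): {res['p_value']:.2e}")
# The recovered fold is the ratio of arm means of per-cell surface LAMP-1;
# p < 0.05 mirrors the in-tissue finding that CLS macrophages carry more
# plasma-membrane LAMP-1 (lysosome exocytosis) than resident macrophages.

stack, truth = generate_cls_scene(SceneSpec(n_macrophages=12, permeable_fraction=0.3, seed=5))
field = surface_lamp1_per_cell(stack)
perm = classify_permeable(stack)
print(f"\nsingle field: {field.cell_count} cells, "
      f"surface LAMP-1 per cell = {field.signal_per_cell:.0f} AFU")
print(f"permeable (calnexin+) fraction: {perm.fraction:.2f} "
      f"(truth {truth.permeable_flags.mean():.2f}) — these cells are "
      f"excluded so lysosomal LAMP-1 cannot masquerade as surface signal")
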