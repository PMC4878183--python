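"""Ratiometric pH mapping of acidified extracellular pockets.

A pH field with two acidic pockets is imaged through the CypHer/Alexa488
response, calibrated against buffer standards, and inverted back to pH.
"""

import numpy as np

from exoquant.experiments import ph_recovery_experiment

res = ph_recovery_experiment(seed=3, snr=20.0)
ph = res["ph_map"]
true_field = res["true_field"]
print(f"pH recovery at SNR 20 over {res['n_pixels']} pixels:")
print(f"  RMSE vs true field : {res['rmse']:.3f} pH units")
print(f"  mean recovered pH  : {ph.mean_ph():.2f} (true {true_field.mean():.2f})")
print(f"  clamped pixels     : {100 * ph.clamp_fraction:.2f}%")
d = ph.defined()
print(f"  most acidic pixel  : {np.nanmin(ph.ph[d]):.2f} "
      f"(true minimum {true_field.min():.2f})")
# RMSE well under 0.1 pH units means the calibration curve plus ratio
# imaging resolves the acidified pockets a macrophage forms against the
# neutral extracellular background.
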