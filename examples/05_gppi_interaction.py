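"""Generalized PPI: recover a planted task-dependent connectivity change.

Builds a six-condition event schedule, a random seed-ROI time course, and
a target series whose coupling to the seed exists only during
related-picture trials (beta 0.8).  The gPPI model (psychological +
interaction + seed + drift regressors) should return ~0.8 for the planted
condition and ~0 elsewhere.
"""

import numpy as np
import pandas as pd

from gistmem.glm import ROITimeSeries, build_gppi_model, fit_gppi

rng = np.random.default_rng(5)
conds = [f"{pt}_{emo}" for pt in ("old", "related", "novel")
         for emo in ("negative", "neutral")]
rows, onset = [], 8.0
for i in range(60):
    rows.append({"onset": onset, "duration": 3.5, "condition": conds[i % 6],
                 "trial_id": f"t{i}"})
    onset += 3.5 + 5.0 + 4.0 * rng.random()
events = pd.DataFrame(rows)

n_scans, tr = 400, 2.5
seed = ROITimeSeries(samples=rng.standard_normal(n_scans), tr=tr, roi_label="aHC")
model = build_gppi_model(seed, events, n_scans=n_scans)
planted = model.design.column("ppi_related_negative")
target = ROITimeSeries(samples=0.8 * planted + 0.5 * rng.standard_normal(n_scans),
                       tr=tr, roi_label="amygdala")

betas = fit_gppi(target, model)
print(betas.round(3).to_string(index=False))
print("\nOnly the related_negative interaction carries signal (planted 0.8);")
print("the other betas estimate the null and should hover near zero.")
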