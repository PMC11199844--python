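"""Fit the hierarchical beta GAM to a synthetic hourly grunt series.

Generates 2,000 individual-hours with a known dominance effect (+1.5 on
the logit scale), fits the model, and prints the recovered status
contrast, fit quality, and the dominant/subdominant rank-sum comparison.
"""

import numpy as np

from rutvox import BehaviourParams, fit_hgam, predict_smooths, status_contrast_test
from rutvox.hgam import HGAMSpec
from rutvox.synth import synth_behaviour_series

params = BehaviourParams(seed=11, status_effect=1.5, n_individuals=8)
records = synth_behaviour_series(params, n_records=2000)

fit = fit_hgam(records, HGAMSpec())
s = fit.summary()
print(f"status contrast (dominant - subdominant, logit): "
      f"{s['status_contrast']:+.3f} +- {s['status_se']:.3f}  (truth {params.status_effect:+.1f})")
print(f"beta precision theta: {s['theta']:.2f}   deviance explained: "
      f"{s['deviance_explained']:.1%}   adjusted r2: {s['adjusted_r2']:.3f}")

curves = predict_smooths(fit)["hour"]
pop = curves.groupby("x").estimate.mean()
print(f"diel smooth: minimum at {pop.idxmin():.1f} h, maximum at {pop.idxmax():.1f} h")

wil = status_contrast_test(records)
print(f"Wilcoxon rank sum: W = {wil['W']:.0f}, p = {wil['p']:.2e}; "
      f"mean proportion dominant {wil['mean_dominant']:.3f} vs "
      f"subdominant {wil['mean_subdominant']:.3f}")
# A positive contrast near +1.5 and a diel minimum in the pre-dawn hours
# mean the model recovered both effects the generator embedded.
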