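"""Score a synthetic sample against the real data with JS divergence and FID.

JS (0..1, per-feature histograms, base-2 logs) measures marginal overlap;
FID (>= 0, Gaussian moment distance on z-scored features) is sensitive to
mean/covariance mismatch and mode collapse.  Lower is better for both.
"""

import vitalgan as vg

real = vg.generate_cohort(43, seed=7)
model, _ = vg.train_cgan(real, vg.GanConfig(epochs=2000, seed=1))
synthetic = vg.sample_synthetic(model, 1000, real.prevalence_high(), seed=2)

print(f"JS real-fake:        {vg.js_divergence(real, synthetic):.3f}")
print(f"JS between classes:  {vg.js_between_classes(synthetic):.3f}")
print(f"FID:                 {vg.fid_score(real, synthetic):.3f}")

# Reference points computed on the spot:
print(f"JS(real, real):      {vg.js_divergence(real, real):.3f}   (identical -> 0)")
print(f"FID(real, real):     {vg.fid_score(real, real):.3f}   (identical -> 0)")

# JS real-fake near 0 means the synthetic marginals overlap the real ones;
# JS between classes > 0 means the two conditioned classes stayed distinct.
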