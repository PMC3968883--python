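"""Build a combined left+right shape model and inspect its variance spectrum.

A combined 130-point model can represent *relative* left-right patterns;
its leading modes mix anatomy (mirror-symmetric) with positioning
artefacts (mirror-opposed).
"""

import numpy as np

from femsym import (SyntheticConfig, build_model, generalized_procrustes,
                    generate_dataset, mode_shape, save_model)

contours, _ = generate_dataset(SyntheticConfig(n_subjects=100, seed=0))
gpa = generalized_procrustes(np.stack([c.points for c in contours]))
print(f"Procrustes alignment converged in {gpa.iterations} iterations")

model = build_model(gpa.aligned, variance_threshold=0.95)
frac = model.variances / model.total_variance
print(f"{model.k} modes retained for "
      f"{model.explained_variance_fraction():.1%} of total variance")
for j in range(min(5, model.k)):
    print(f"  mode {j + 1}: variance {model.variances[j]:8.1f} mm^2 "
          f"({frac[j]:.1%} of total)")

# the conventional rendering of a mode spans the mean +/- 2.5 SD
extremes = mode_shape(model, 1, 2.5) - mode_shape(model, 1, -2.5)
print(f"mode 1 max landmark excursion over +/-2.5 SD: "
      f"{np.linalg.norm(extremes, axis=1).max():.1f} mm")
save_model(model, "scratch/combined_model.ssm")
print("model written to scratch/combined_model.ssm (ssm-v1 JSON)")
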