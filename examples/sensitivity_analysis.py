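"""RBD-FAST first-order sensitivity indices.

Validates the estimator on the Ishigami function (closed-form indices
exist) and shows the single-design economy of the method: d factors cost N
model runs, not d*N.
"""

import numpy as np

from soilplant import build_design, estimate_s1

a, b = 7.0, 0.1
bounds = np.tile([-np.pi, np.pi], (3, 1))
design = build_design(3000, bounds, seed=0)
x = design.samples
y = np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2 \
    + b * x[:, 2] ** 4 * np.sin(x[:, 0])

res = estimate_s1(y, design)
analytic = (0.3139, 0.4424, 0.0)
print(f"N = {design.n} model runs for d = {design.d} factors")
for f in range(3):
    print(f"  x{f + 1}: S1 = {res.s1[f]:+.3f}   (analytic "
          f"{analytic[f]:.3f})")
print("\nS1 is the fraction of output variance a factor explains alone;")
print("x3 acts only through its interaction with x1, so its first-order")
print("index is ~0 even though the model depends on it.")
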