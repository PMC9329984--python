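"""The Gaussian-process surrogate and Expected Improvement.

Fits the Matérn 5/2 GP to five observations of sin(2 pi x), prints the
posterior against the true function, and scores Expected Improvement —
the quantity the optimizer maximizes to pick its next evaluation.
"""

import numpy as np

from smearopt import expected_improvement, gp_fit

X = np.array([[0.0], [0.25], [0.5], [0.75], [1.0]])
y = np.sin(2 * np.pi * X[:, 0])
model = gp_fit(X, y, rng=0)

print("  x    truth   posterior mean   sd      EI")
f_best = y.min()
for x in np.linspace(0, 1, 9):
    mean, sd = model.predict([[x]])
    ei = expected_improvement(float(mean[0]), float(sd[0]), f_best)
    print(f"{x:5.3f} {np.sin(2 * np.pi * x):7.3f} {mean[0]:12.3f} "
          f"{sd[0]:8.3f} {ei:8.4f}")

print()
print("the posterior interpolates the observations (sd near 0 there);")
print("EI is zero at evaluated points and positive only between them,")
print("where residual uncertainty leaves room to beat the incumbent.")
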