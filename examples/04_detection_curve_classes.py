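"""Compare the two monotone detection-curve classes.

Fits the same gene with the I-spline curve (smooth, default) and the
bounded-isotonic curve (step function), and shows the fitted detection
probabilities across the coverage range.
"""

import numpy as np

from happi import HappiConfig, SimulationConfig, fit_happi, simulate_dataset

data = simulate_dataset(SimulationConfig(n=100, beta=(0.0, 1.0), sigma_x=0.5,
                                         seed=21))
grid = np.linspace(10, 40, 7)

for f_class in ("ispline", "isotone"):
    cfg = HappiConfig(epsilon=0.0, delta=0.01, f_class=f_class)
    fit = fit_happi(data.Y, data.X, data.M, cfg)
    probs = fit.params.curve.eval_prob(grid)
    print(f"{f_class:8s} beta = {np.round(fit.params.beta, 3)}  "
          f"f(M) on 10..40x: {np.round(probs, 3)}")

print()
print("Both curves are monotone non-decreasing in coverage; the I-spline")
print("class is smooth and usually estimates the presence effect (beta_1)")
print("with lower mean squared error, which is why it is the default.")
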