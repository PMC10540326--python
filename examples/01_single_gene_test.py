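"""Test one gene for differential presence, adjusting for genome quality.

Builds a small synthetic cohort of genomes where the gene is genuinely
more common in one group, fits the hierarchical model, and contrasts the
quality-adjusted likelihood-ratio test with a quality-naive logistic test.
"""

import numpy as np

from happi import HappiConfig, SimulationConfig, TestSpec, glm_lrt, simulate_dataset
from happi.em import test_gene

# 60 genomes; the covariate of interest has a true log-odds effect of 2 on
# latent presence, and coverage (10-40x) governs detection of present genes
data = simulate_dataset(SimulationConfig(n=60, beta=(0.0, 2.0), sigma_x=0.5,
                                         seed=4))

config = HappiConfig(epsilon=0.0, t_max=1000, delta=0.01)
spec = TestSpec.coefficients([1], p=2)  # H0: beta_1 = 0

res = test_gene(data.Y, data.X, data.M, config, spec)
base = glm_lrt(data.Y, data.X, spec)

print(f"quality-adjusted LRT: Q = {res.Q_lrt:.3f}, p = {res.p_value:.4f}")
print(f"  beta estimate: {np.round(res.fit_alt.params.beta, 3)}")
print(f"quality-naive GLM-LRT: Q = {base.Q_lrt:.3f}, p = {base.p_value:.4f}")
print()
print("The adjusted test models non-detection in low-coverage genomes as")
print("possible missingness rather than absence; beta_1 estimates the")
print("log-odds difference in true gene presence between covariate groups.")
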