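"""Type-1 error comparison at small sample size.

Simulates null data (no covariate effect on presence) in which coverage is
correlated with the covariate of interest, then measures how often each
test falsely rejects at the 5% level.  Scaled down (40 replicates, 99
permutations, ~1-2 minutes); the full-scale study uses 500 replicates and
B=1000.
"""

from happi import HappiConfig, run_type1_study

config = HappiConfig(epsilon=0.0, t_max=1000, delta=0.1, min_iter=16)
table = run_type1_study(ns=[30], sigma_xs=[0.5],
                        methods=["happi-np", "happi-a", "glm-lrt"],
                        n_sim=40, B=99, seed=1, happi_config=config)
print(table.to_string(index=False))
print()
print("rate = fraction of null datasets rejected at alpha = 0.05 with a 95%")
print("Wald binomial CI; at this reduced scale the intervals are wide, so")
print("treat the rates as illustrative. In the 500-replicate study the")
print("asymptotic chi-square calibration and the quality-naive GLM-LRT both")
print("exceed the nominal 5% at n=30 (~9%), while the permutation test")
print("(happi-np) recalibrates the same statistic and holds the level --")
print("which is why it is the recommended test for small cohorts.")
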