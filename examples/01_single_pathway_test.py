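"""Test one pathway for differential co-expression.

Simulates a 10-gene pathway (n=300) in which the correlation between genes
increases with a binary risk factor (tau ~ U(0.1, 0.2)), then runs the kernel
test with the default linear/projection/Gaussian kernels and B=1000
permutations.
"""

import numpy as np
import pandas as pd

from kdca import DesignInputs, MvnSimConfig, kdca_test, simulate_mvn_pathway

data = simulate_mvn_pathway(MvnSimConfig(sign_scheme="mixed", delta_max=0.1, seed=7))
design = DesignInputs(
    Y=data.Y,
    X=pd.DataFrame({"exposure": data.X[:, 0]}),
    C=pd.DataFrame({"age": data.C}),
    categorical=("exposure",),
)

result = kdca_test(design, B=1000, seed=11, include_eigengene=True)

print(f"simulated effect size tau = {data.tau:.3f} (mixed signs across pairs)")
for pk in result.per_kernel:
    print(f"  {pk.kernel_name:>10} kernel: T = {pk.T_obs:8.3f}  p = {pk.p_empirical:.4f}")
print(f"  combined (Fisher):  T' = {result.T_prime_obs:6.3f}  p = {result.p_combined:.4f}")
print(f"  eigengene baseline:           p = {result.eigengene.p_empirical:.4f}")
print()
print("Small combined p: the co-expression structure of the pathway depends")
print("on the exposure. The eigengene baseline misses dispersed (mixed-sign)")
print("signals that the kernel statistics aggregate across all gene pairs.")
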