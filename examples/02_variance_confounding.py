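"""Why variance adjustment matters.

Simulates a *null* pathway (no differential co-expression) in which a
continuous risk factor nonetheless scales the variance of each gene
(log Var = 1 + delta_k X, delta_k ~ U(0, 0.5)).  Without variance
adjustment the cross products inherit this effect and the test rejects far
too often; the double-GLM adjustment restores calibration.
"""

import numpy as np
import pandas as pd

from kdca import DesignInputs, MvnSimConfig, kdca_test, simulate_mvn_pathway

rng = np.random.default_rng(3)
cfg = MvnSimConfig(risk="continuous", tau_range=(0.0, 0.0), delta_max=0.5)

n_rej_adj = n_rej_raw = 0
R = 40
for _ in range(R):
    d = simulate_mvn_pathway(cfg, rng)
    design = DesignInputs(
        Y=d.Y, X=pd.DataFrame({"x": d.X[:, 0]}), C=pd.DataFrame({"c": d.C})
    )
    seed = int(rng.integers(2**31))
    n_rej_adj += kdca_test(design, B=300, seed=seed).p_combined <= 0.05
    n_rej_raw += (
        kdca_test(design, B=300, seed=seed, variance_mode="constant").p_combined
        <= 0.05
    )

print(f"null pathways tested: {R} (tau = 0, variance effect delta' = 0.5)")
print(f"rejections at 5% with double-GLM variance adjustment: {n_rej_adj} "
      f"({n_rej_adj / R:.0%})")
print(f"rejections at 5% without variance adjustment:          {n_rej_raw} "
      f"({n_rej_raw / R:.0%})")
print()
print("A pure variance effect is not differential co-expression; failing to")
print("model it turns into false discoveries, while the adjusted test stays")
print("near the nominal 5% level.")
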