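"""RNA-seq counts: transformation, library size, and a hidden pitfall.

Simulates negative-binomial counts in which each gene carries a latent
interaction with the risk factor that is NOT shared across genes — so the
pathway is a true differential co-expression null, yet the log transform
induces a risk-factor variance effect.  The pipeline log2(count+2) +
log-library-size covariate + double-GLM adjustment keeps p-values honest.
"""

import numpy as np
import pandas as pd

from kdca import (
    DesignInputs,
    NbSimConfig,
    kdca_test,
    pathway_blocks,
    simulate_nb_counts,
    transform_counts,
)

rng = np.random.default_rng(8)
nb = simulate_nb_counts(NbSimConfig(n_genes=200), rng)
print(f"simulated counts: {nb.counts.shape[0]} samples x {nb.counts.shape[1]} genes, "
      f"library sizes {sorted(int(v) for v in set(nb.library_sizes))}")

logY, log_lib = transform_counts(nb.counts)

ps = []
for blk in pathway_blocks(200, 10):
    design = DesignInputs(
        Y=logY[:, blk],
        X=pd.DataFrame({"x": nb.X}),
        C=pd.DataFrame({"c": nb.C, "log_lib": log_lib}),
    )
    res = kdca_test(design, B=300, seed=int(rng.integers(2**31)))
    ps.append(res.p_combined)

ps = np.array(ps)
print(f"pathways tested: {ps.size} (all true nulls for co-expression)")
print(f"combined p-values: min {ps.min():.3f}, median {np.median(ps):.3f}")
print(f"rejections at 5%: {(ps <= 0.05).sum()}")
print()
print("Counts in, calibrated p-values out: the latent interactions create")
print("variance (not co-expression) effects after the log transform, and the")
print("double GLM absorbs them.")
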