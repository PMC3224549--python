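"""Rank a suite of gene selectors by cross-validated prediction error.

Simulates a paired experiment (500 genes, 6 replicates, 90% of genes
equivalently expressed), runs leave-one-out cross validation for each
selector, and reports total error relative to the t-statistic local-FDR
base model.  Ratios above 1 mean worse predictions than the base.
"""

import warnings

import numpy as np

import dexval as dx

warnings.simplefilter("ignore")

cfg = dx.SimulationConfig(m=500, n=6, n_prime=6, pi0=0.9, paired=True, seed=7)
data, truth = dx.generate(cfg)
print(f"simulated {cfg.m} genes, n = {cfg.n} pairs, "
      f"{truth.is_null.mean():.0%} truly equivalent\n")

suite = ["t_locfdr", "modt_locfdr", "fc_shrinkage", "bayes_factor", "bic",
         "fc_gt_2", "all_nulls_true", "all_nulls_false"]
tables = {lab: dx.loocv(data, dx.get_selector(lab)) for lab in suite}
base = tables["t_locfdr"]

print(f"{'selector':<18}{'total error':>12}{'vs base':>10}")
for lab in sorted(suite, key=lambda l: np.nansum(tables[l].errors)):
    s = dx.summarize_errors(tables[lab], base)
    print(f"{lab:<18}{np.nansum(tables[lab].errors):>12.1f}"
          f"{s.absolute_ratio:>10.3f}")

print("\nhierarchical selectors (local FDR, moderated t) should sit at the"
      "\ntop: they exploit the high proportion of equivalent genes that the"
      "\nfold-change and per-gene model-selection rules ignore")
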