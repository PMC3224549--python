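"""Score selectors without holding out data: posterior predictive loss.

Simulates an unpaired two-group experiment, fits the gold-standard model
(t-statistic local FDR, theoretical null), builds the per-gene mixture
predictive -- closed-form t predictive under differential expression,
Gibbs-sampled predictive under the common-mean/unequal-variance null --
and reports each selector's total posterior predictive expected squared
error relative to the gold standard.
"""

import warnings

import numpy as np

import dexval as dx

warnings.simplefilter("ignore")

cfg = dx.SimulationConfig(m=800, n=6, n_prime=6, pi0=0.9, paired=False, seed=21)
data, _ = dx.generate(cfg)

gold, pi0 = dx.gold_standard_pi(data)
print(f"gold-standard estimated proportion of equivalent genes: {pi0:.2f}")

mcmc = dx.MCMCConfig(chains=10, burnin=20, keep=100, seed=22)
null = dx.gibbs_null_unpaired(data, mcmc)
print(f"null predictive variance: median {np.median(null.variance):.3f}, "
      f"median MC standard error {np.median(null.mc_se):.4f} "
      f"({mcmc.total_draws} draws/gene)")

mix = dx.mixture_moments(gold.pi, null, dx.unpaired_alt_predictive(data))

suite = ["t_locfdr", "modt_locfdr", "fc_shrinkage", "bayes_factor",
         "fc_gt_2", "all_nulls_true", "all_nulls_false"]
totals = {}
for lab in suite:
    tab = dx.ppese(data, dx.get_selector(lab), gold, mixture=mix)
    totals[lab] = float(np.nansum(tab.errors))

base = totals["t_locfdr"]
print(f"\n{'selector':<18}{'total PPESE':>12}{'vs gold':>10}")
for lab in sorted(suite, key=totals.get):
    print(f"{lab:<18}{totals[lab]:>12.1f}{totals[lab] / base:>10.3f}")

print("\nthe gold standard is exactly 1 by construction; a ratio near 1"
      "\nmeans the selector's shrunken estimates sit close to the posterior"
      "\nmean, the irreducible floor being the predictive variance")
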