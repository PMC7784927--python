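"""Fit the ratio-genotype G-BLUP model and score held-out predictions.

Builds G = ZZ'/h from continuous genotypes, fits y = mu + g + e by Gibbs
sampling on a training set, and evaluates predictive ability (Pearson r with
the adjusted phenotypes) and accuracy (r with the true genetic values) on a
held-out test set.
"""

import numpy as np

import tetragp as tg

data = tg.simulate_study(n_founders=24, n_families=20, family_size=12,
                         n_chrom=6, markers_per_chrom=100, seed=11)
trait = "polygenic"
y = data.phenotypes[trait]

m = tg.ratio_genotypes(data.rc)
G = tg.build_g(m)
print(f"G: {G.n_individuals} individuals from {G.n_markers} markers, "
      f"scale h = {G.h:.2f}; trace = {np.trace(G.g):.2f} (= n-1)")

(test,) = tg.make_test_sets(list(data.individual_ids), size=50, n_reps=1, seed=12)
train = np.setdiff1d(data.individual_ids, test)

fit = tg.fit_gibbs(y, G, train, n_iter=4000, burn_in=1000, thin=5, seed=13)
h2_est = fit.sigma2_a / (fit.sigma2_a + fit.sigma2_e)
print(f"posterior means: sigma_a^2 = {fit.sigma2_a:.3f}, "
      f"sigma_e^2 = {fit.sigma2_e:.3f}  (h2 ~ {h2_est:.2f})")

pred = tg.predict(fit, list(test))
r = tg.predictive_ability(pred.to_numpy(), y.reindex(list(test)).to_numpy())
acc = tg.predictive_ability(pred.to_numpy(),
                            data.truth[trait].reindex(list(test)).to_numpy())
err = tg.mse(pred.to_numpy(), y.reindex(list(test)).to_numpy())
print(f"test set: predictive ability r = {r:.3f}, accuracy vs truth = {acc:.3f}, "
      f"MSE = {err:.3f}")
# Accuracy against the (noise-free) true genetic values exceeds predictive
# ability against phenotypes, which carry residual error.
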