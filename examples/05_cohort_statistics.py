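"""Effect sizes and group comparisons on per-cell activity metrics.

Bootstraps the difference in mean activity between two simulated cell
groups and runs the standard group tests (Kolmogorov-Smirnov,
Kruskal-Wallis with Dunn's post hoc).
"""

import numpy as np

from pcdrift import bootstrap_diff_ci, group_tests

rng = np.random.default_rng(8)
# per-cell mean activity of persistently active vs sometimes-silent cells
persistently_active = rng.lognormal(mean=0.5, sigma=0.6, size=120)
sometimes_silent = rng.lognormal(mean=0.0, sigma=0.6, size=150)

ci = bootstrap_diff_ci(persistently_active, sometimes_silent,
                       statistic="mean", n=5000, seed=9)
print(f"mean-activity difference: {ci.observed:.3f} "
      f"[95% bootstrap CI {ci.ci_low:.3f}, {ci.ci_high:.3f}] "
      f"({ci.n_resamples} resamples)")

rep = group_tests({"persistently_active": persistently_active,
                   "sometimes_silent": sometimes_silent})
ks = rep["kolmogorov_smirnov"]
print(f"KS test: D = {ks['statistic']:.3f}, p = {ks['p']:.2e}")
kw = rep["kruskal_wallis"]
print(f"Kruskal-Wallis: H = {kw['statistic']:.2f}, p = {kw['p']:.2e}")
for pair, res in rep["dunn"].items():
    print(f"Dunn {pair}: p = {res['p']:.2e}")
# A CI excluding 0 and small test p-values indicate persistently
# active cells carry genuinely higher activity, not sampling noise.
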