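"""Copula MI between continuous variables: accuracy, rank invariance, limits.

Draws correlated Gaussian pairs, compares the rank-based copula MI estimate
with the analytic value -0.5*log2(1-r^2), and shows the two defining
behaviours: bit-exact invariance under monotone marginal transforms, and the
zero result on a symmetric (zero-Gaussian-copula) dependence, where the
estimator's lower-bound character is visible.
"""

import numpy as np

from copulainfo import gcmi_cc
from copulainfo.simulate import gen_bivariate_gaussian

for r in (0.2, 0.5, 0.8):
    x, y = gen_bivariate_gaussian(r, 10_000, seed=1)
    est = gcmi_cc(x, y)
    true = -0.5 * np.log2(1 - r * r)
    print(f"r={r}:  copula MI = {est.bits:.4f} bits   analytic = {true:.4f} bits")

x, y = gen_bivariate_gaussian(0.6, 2_000, seed=2)
print("\nmonotone marginal transforms leave the estimate bit-identical:")
print(f"  raw data      : {gcmi_cc(x, y).bits:.15f}")
print(f"  exp(x), y**3  : {gcmi_cc(np.exp(x), y**3).bits:.15f}")

rng = np.random.default_rng(3)
x = rng.standard_normal(10_000)
y = np.abs(x) + 0.1 * rng.standard_normal(10_000)
print("\nsymmetric dependence y=|x|+noise has zero Gaussian-copula correlation:")
print(f"  copula MI = {gcmi_cc(x, y).bits:.4f} bits  (true MI is large; the")
print("  estimate is a lower bound and reports only copula dependence)")
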