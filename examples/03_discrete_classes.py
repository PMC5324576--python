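"""MI between a continuous response and discrete classes; group decomposition.

A two-class response with a mean shift carries class information readable by
the mixed discrete-continuous copula estimator.  The group decomposition
then shows its use for multi-participant inference: participants with
opposite-signed effects cancel when pooled, but the total (per-participant)
term keeps the effect and the heterogeneity term flags the inconsistency.
"""

import numpy as np

from copulainfo import gcmi_cd, group_decomposition

rng = np.random.default_rng(7)
n = 1000
y = rng.integers(0, 2, n)
x = rng.standard_normal(n) + 1.0 * y
print(f"two-class mean shift of 1 s.d.: MI = {gcmi_cd(x, y).bits:.4f} bits")
print(f"shuffled labels (null)        : MI = "
      f"{gcmi_cd(x, rng.permutation(y)).bits:.4f} bits\n")

# two participants, equal-magnitude opposite-sign effects
xs, ys, ps = [], [], []
for p, sign in enumerate((+1.5, -1.5)):
    yy = rng.integers(0, 2, 2000)
    xs.append(rng.standard_normal(2000) + sign * yy)
    ys.append(yy)
    ps.append(np.full(2000, p))
out = group_decomposition(np.concatenate(xs), np.concatenate(ys), np.concatenate(ps))
print("opposite-signed effects in two participants:")
for key in ("pooled", "total", "heterogeneity"):
    print(f"  {key:13s} = {out[key].bits:.4f} bits")
print("pooling cancels the effect; the total/heterogeneity terms reveal it.")
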