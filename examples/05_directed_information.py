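"""Directed information and its stimulus-specific part on a relay model.

x carries a stimulus series; y receives x after a 4-sample delay.  Directed
information (transfer entropy) detects the x->y communication and its
asymmetry; directed feature information shows how much of that communication
is about the stimulus, vanishing when the relayed activity is
stimulus-independent noise.
"""

import numpy as np

from copulainfo import directed_feature_information, directed_information

rng = np.random.default_rng(19)
t, d = 6000, 4
s = rng.standard_normal(t)
x = s + 0.4 * rng.standard_normal(t)
y = np.zeros(t)
y[d:] = x[:-d]
y += 0.4 * rng.standard_normal(t)

print(f"relay model (x -> y at lag {d}):")
print(f"  DI(x->y)  = {directed_information(x, y, d).bits:.4f} bits")
print(f"  DI(y->x)  = {directed_information(y, x, d).bits:.4f} bits  (no reverse flow)")
print(f"  DFI(x->y | stimulus) = {directed_feature_information(x, y, s, d).bits:.4f} bits")

x2 = rng.standard_normal(t)  # stimulus-independent source, same wiring
y2 = np.zeros(t)
y2[d:] = x2[:-d]
y2 += 0.4 * rng.standard_normal(t)
print("\nsame wiring, stimulus-independent source:")
print(f"  DI(x->y)  = {directed_information(x2, y2, d).bits:.4f} bits  (still communicates)")
print(f"  DFI       = {directed_feature_information(x2, y2, s, d).bits:.4f} bits  "
      "(but nothing about the stimulus)")
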