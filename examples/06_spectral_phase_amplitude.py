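"""Phase/amplitude dissociation for complex spectral data.

Complex coefficients are split into an amplitude channel (row norms) and a
direction channel (unit-normalized 2-D vectors, avoiding circular-variable
issues).  A phase-coded class difference appears only in the direction
channel; an amplitude-coded one only in the amplitude channel.
"""

from copulainfo import amplitude, direction, gcmi_cd
from copulainfo.simulate import gen_spectral_classes

for mode in ("phase", "amplitude"):
    z, labels = gen_spectral_classes(mode, 4000, seed=51)
    mi_full = gcmi_cd(z, labels).bits
    mi_amp = gcmi_cd(amplitude(z), labels).bits
    mi_dir = gcmi_cd(direction(z), labels).bits
    print(f"{mode}-coded classes:")
    print(f"  full 2-D vector : {mi_full:.4f} bits")
    print(f"  amplitude only  : {mi_amp:.4f} bits")
    print(f"  direction only  : {mi_dir:.4f} bits")
print("each coding scheme lights up only its own channel.")
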