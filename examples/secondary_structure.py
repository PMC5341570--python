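"""Secondary-structure assignment on ideal fixtures.

Assigns the 8-class alphabet (H, G, I, E, B, T, S, C) to an ideal helix, a
two-strand antiparallel sheet and an extended coil, using the classical
electrostatic hydrogen-bond definition.
"""

from rindyn.secstruct import assign_ss
from rindyn.synth import gen_ideal_secondary

for kind, n in (("alpha_helix", 12), ("antiparallel_sheet", 6),
                ("extended_coil", 10)):
    top, traj = gen_ideal_secondary(kind, n)
    classes = "".join(assign_ss(traj.frame(0), top).classes)
    print(f"{kind:20s} -> {classes}")
print("H = alpha helix, E = beta sheet, C = coil; chain termini stay C")
print("because the terminal residues lack the flanking hydrogen bonds.")
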