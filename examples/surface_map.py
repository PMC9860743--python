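"""Map where a mineral surface can hydrogen-bond with adsorbed molecules.

Builds a small slab whose left half carries hydroxyl groups (donor oxygens)
and whose right half exposes bare oxygens (acceptors), assigns fictitious
+-1 charges, and evaluates the inverse-square-distance weighted-average
potential on a probe grid 1.4 Å above the surface.
"""

import numpy as np

from prepolymer import annotate, potential_map
from prepolymer.system import AtomRecord, Configuration

atoms = []
for i in range(8):
    for j in range(6):
        x, y = 2.5 * i, 2.5 * j
        atoms.append(AtomRecord(len(atoms), "OS", "O", 0, "MIN", "substrate", np.array([x, y, 0.0])))
        if i < 4:  # hydroxylated (donor) half
            atoms.append(AtomRecord(len(atoms), "HS", "H", 0, "MIN", "substrate", np.array([x, y, 0.96])))
config = Configuration(atoms=atoms)

pm = potential_map(config, annotate(config), mode="donor_acceptor", grid_spacing=1.0)
left = pm.values[:, pm.x < 7.5].mean()
right = pm.values[:, pm.x > 12.5].mean()
print(f"grid: {pm.values.shape[1]} x {pm.values.shape[0]} vertices at z = {pm.z:.2f} A")
print(f"mean potential over the hydroxylated half : {left:+.2f}")
print(f"mean potential over the bare-oxygen half  : {right:+.2f}")
print(f"value range: {pm.values.min():+.2f} .. {pm.values.max():+.2f}")
print()
print("+1 marks hydrogen-bond-donor surface, -1 acceptor surface; the sign")
print("flips across the strip boundary, showing which side can donate to a")
print("nucleotide's phosphate versus accept from its hydroxyls or base.")
# pm.save_png("surface_map.png")  # optional heatmap
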