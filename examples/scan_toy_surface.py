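"""Scan a toy rock-salt surface with a polar diatomic adsorbate.

Builds a two-layer NaCl-type slab, assigns oxidation-state formal
charges, enumerates a coarse site × orientation grid, lowers every pose
to first contact and prints the per-site minimum adsorption energies.
More negative E_a = more stable adsorption.
"""

from slabdock import (
    EnergyModel,
    assign_surface_charges,
    detect_surface_atoms,
    enumerate_rotations,
    generate_grid,
    scan_surface,
)
from slabdock.fixtures import make_rocksalt_slab, make_toy_adsorbate

slab = make_rocksalt_slab("Na", "Cl", a0=5.64, nx=1, ny=1, nlayers=2)
assign_surface_charges(slab)          # Na -> +1, Cl -> -1, neutral cell
detect_surface_atoms(slab)            # top layer only
ads = make_toy_adsorbate("polar_diatomic")   # C(+0.4) O(-0.4), 1.2 Å

grid = generate_grid(slab, spacing=1.6)      # 4 x 4 = 16 sites
rotations = enumerate_rotations(90)          # 3^3 = 27 orientations

reps = scan_surface(slab, ads, grid, rotations, EnergyModel())
contact = [r for r in reps if r is not None]

print(f"sites scanned:          {len(grid)}")
print(f"sites with contact:     {len(contact)}")
best = min(contact, key=lambda r: r.energy.e_a)
u, v = grid.sites[best.site_index]
print(f"global minimum E_a:     {best.energy.e_a:.4f} eV "
      f"(V_C {best.energy.v_coulomb:.4f}, V_LJ {best.energy.v_lj:.4f})")
print(f"  at site (u, v) =      ({u:.3f}, {v:.3f}), "
      f"Euler {best.rotation.as_tuple()}")
# The Coulomb term dominates: the positive C end points at surface Cl-,
# the negative O end at surface Na+.
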