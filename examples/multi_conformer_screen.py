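"""Multi-conformer screening on a CdS-like slab.

Screens an ensemble of rigid conformers of the same molecule in one
scan: at every site all conformers compete and the lowest-E_a contact
pose wins, so the map simultaneously reports the best site and the best
conformation per site — the workflow used for flexible adsorbates whose
conformers come from a chemical database.
"""

from slabdock import (
    Adsorbate,
    EnergyModel,
    assign_surface_charges,
    classify_denticity,
    detect_surface_atoms,
    enumerate_rotations,
    generate_grid,
    scan_surface,
)
from slabdock.fixtures import make_rocksalt_slab, make_toy_adsorbate

slab = make_rocksalt_slab("Cd", "S", a0=5.8, nx=1, ny=1, nlayers=2)
assign_surface_charges(slab)          # Cd -> +2, S -> -2
detect_surface_atoms(slab)

planar = make_toy_adsorbate("planar_4atom")
# a second rigid conformer: same composition, different geometry
bent = Adsorbate(symbols=list(planar.symbols),
                 positions=planar.positions[:, [0, 2, 1]].copy(),
                 partial_charges=planar.partial_charges.copy(),
                 net_charge=planar.net_charge,
                 conformer_id="planar_4atom_alt")

grid = generate_grid(slab, spacing=2.0)
reps = scan_surface(slab, [planar, bent], grid, enumerate_rotations(120),
                    EnergyModel())

contact = [r for r in reps if r is not None]
winners = {c: sum(r.conformer_id == c for r in contact)
           for c in (planar.conformer_id, bent.conformer_id)}
print(f"sites with contact: {len(contact)} / {len(grid)}")
print(f"per-site winning conformer counts: {winners}")
best = min(contact, key=lambda r: r.energy.e_a)
print(f"most stable: {best.conformer_id}  E_a {best.energy.e_a:.4f} eV  "
      f"denticity {classify_denticity(best)}")
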