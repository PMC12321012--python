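"""Heatmap construction and configuration filtering after a scan.

Scans a small ionic slab, reduces the per-site minima to an adsorption
energy heatmap (CSV + PNG), filters energy-equivalent configurations
with a 0.1 eV window, and classifies the binding mode (denticity) of
each surviving configuration.
"""

from pathlib import Path

from slabdock import (
    EnergyModel,
    assign_surface_charges,
    build_heatmap,
    classify_denticity,
    detect_surface_atoms,
    enumerate_rotations,
    filter_equivalent,
    generate_grid,
    make_map,
    scan_surface,
)
from slabdock.fixtures import make_rocksalt_slab, make_toy_adsorbate

slab = make_rocksalt_slab("Mg", "O", a0=4.2, nx=1, ny=1, nlayers=2)
assign_surface_charges(slab)          # Mg -> +2, O -> -2
detect_surface_atoms(slab)
ads = make_toy_adsorbate("planar_4atom")     # formaldehyde-like H2CO

grid = generate_grid(slab, spacing=1.4)
reps = scan_surface(slab, ads, grid, enumerate_rotations(120), EnergyModel())

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)
matrix = build_heatmap(make_map(grid, reps), csv_path=out / "heatmap.csv",
                       png_path=out / "heatmap.png")
print(f"heatmap shape:  {matrix.shape}  (n_a x n_b site grid)")
print(f"E_a range:      [{matrix.min():.4f}, {matrix.max():.4f}] eV")

kept = filter_equivalent(reps, window=0.1)
print(f"contact sites:  {sum(r is not None for r in reps)}")
print(f"distinct configurations (0.1 eV window): {len(kept.kept)}")
for pose in kept.kept:
    print(f"  E_a {pose.energy.e_a:8.4f} eV   denticity "
          f"{classify_denticity(pose)}   site {pose.site_index}")
# Denticity counts the distinct adsorbate atoms touching the surface:
# 1 = monodentate (e.g. O-down), 2+ = multidentate anchoring.
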