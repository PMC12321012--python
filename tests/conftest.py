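import numpy as np
import pytest

from slabdock import (
    EnergyModel,
    RadiiTable,
    assign_surface_charges,
    detect_surface_atoms,
)
from slabdock.fixtures import make_rocksalt_slab, make_toy_adsorbate


@pytest.fixture(scope="session")
def radii():
    return RadiiTable.default()


@pytest.fixture()
def rocksalt():
    """Charged, surface-masked 1x1 two-layer rock-salt slab."""
    slab = make_rocksalt_slab("Na", "Cl", 5.64, 1, 1, 2)
    assign_surface_charges(slab)
    detect_surface_atoms(slab)
    return slab


@pytest.fixture()
def flat_layer():
    slab = make_rocksalt_slab("Na", "Cl", 5.64, 1, 1, 1)
    assign_surface_charges(slab)
    detect_surface_atoms(slab)
    return slab


@pytest.fixture()
def polar_diatomic():
    return make_toy_adsorbate("polar_diatomic")


@pytest.fixture()
def model():
    return EnergyModel()


def brute_force_energies(slab, coords, charges, symbols, model):
    """Naive O(N^2) pair-sum reference for Coulomb and LJ energies.

    Independent of the vectorized implementation: explicit Python loops,
    explicit 3x3 in-plane image search.
    """
    import math

    v_c = 0.0
    v_lj = 0.0
    for i in range(len(slab)):
        for j in range(len(coords)):
            d = np.asarray(coords[j]) - slab.positions[i]
            if model.min_image:
                best = math.inf
                inv = np.linalg.inv(slab.lattice)
                f = d @ inv
                f0 = f.copy()
                f0[0] -= round(f0[0])
                f0[1] -= round(f0[1])
                base = f0 @ slab.lattice
                for p in (-1, 0, 1):
                    for q in (-1, 0, 1):
                        cand = base + p * slab.lattice[0] + q * slab.lattice[1]
                        best = min(best, math.sqrt(float(cand @ cand)))
                r = best
            else:
                r = math.sqrt(float(d @ d))
            v_c += model.k_e * slab.formal_charges[i] * charges[j] / r
            sigma = model.radii.vdw(slab.symbols[i]) + model.radii.vdw(symbols[j])
            v_lj += 4 * model.epsilon * ((sigma / r) ** 12 - (sigma / r) ** 6)
    return v_c, v_lj
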