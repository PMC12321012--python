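"""Synthetic slabs, toy adsorbates, and calibration sets.

Every stage of the pipeline is testable offline: rock-salt-type slabs
stand in for ionic surfaces, small rigid molecules with hand-set charges
stand in for adsorbates, and the calibration generator produces
(V_Coulomb, V_LJ, E_ref) triples with a known ground-truth divisor.
Stochastic fixtures use numpy's PCG64 generator, so a seed fixes the
output bit-for-bit across platforms.
"""

from __future__ import annotations

import numpy as np

from .calibrate import EPSILON_REF, CalibrationSet
from .errors import ValidationError
from .structures import Adsorbate, Slab

__all__ = [
    "make_rocksalt_slab",
    "make_flat_layer",
    "make_toy_adsorbate",
    "make_calibration_set",
]

#: Vacuum padding above/below the slab along c (Å).
VACUUM = 15.0


def make_rocksalt_slab(cation: str = "Na", anion: str = "Cl", a0: float = 5.64,
                       nx: int = 1, ny: int = 1, nlayers: int = 2) -> Slab:
    """A (001)-type rock-salt slab: checkerboard layers of ± ions.

    Each 1×1 layer holds 2 cations + 2 anions on the conventional-cell
    face (lattice constant ``a0``); successive layers are a0/2 apart
    with the two sublattices swapped, as in the rock-salt structure.
    Stoichiometric and charge-neutral by construction.
    """
    if a0 <= 0 or nx < 1 or ny < 1 or nlayers < 1:
        raise ValidationError("a0 must be > 0 and counts >= 1")
    symbols: list[str] = []
    positions: list[list[float]] = []
    # fractional (u, v) of the two sublattices within the 1x1 face
    sub_a = [(0.0, 0.0), (0.5, 0.5)]
    sub_b = [(0.5, 0.0), (0.0, 0.5)]
    for layer in range(nlayers):
        z = layer * a0 / 2.0
        first, second = (cation, anion) if layer % 2 == 0 else (anion, cation)
        for ix in range(nx):
            for iy in range(ny):
                for u, v in sub_a:
                    symbols.append(first)
                    positions.append([(ix + u) * a0, (iy + v) * a0, z])
                for u, v in sub_b:
                    symbols.append(second)
                    positions.append([(ix + u) * a0, (iy + v) * a0, z])
    lattice = np.array([
        [nx * a0, 0.0, 0.0],
        [0.0, ny * a0, 0.0],
        [0.0, 0.0, (nlayers - 1) * a0 / 2.0 + VACUUM],
    ])
    return Slab(lattice=lattice, symbols=symbols, positions=np.array(positions))


def make_flat_layer(element_pair: tuple[str, str] = ("Na", "Cl"),
                    a0: float = 5.64, nx: int = 1, ny: int = 1) -> Slab:
    """Single checkerboard monolayer; every atom is a surface atom."""
    return make_rocksalt_slab(element_pair[0], element_pair[1], a0, nx, ny, nlayers=1)


def make_toy_adsorbate(kind: str = "polar_diatomic") -> Adsorbate:
    """Small rigid molecules with fixed geometries and charges.

    neutral_diatomic  N2-like: two N at 1.10 Å, charges 0.
    polar_diatomic    CO-like dipole: C/O at 1.20 Å, charges ±0.4 e.
    planar_4atom      formaldehyde-like H2CO, net 0.
    """
    if kind == "neutral_diatomic":
        return Adsorbate(
            symbols=["N", "N"],
            positions=[[0.0, 0.0, 0.0], [0.0, 0.0, 1.10]],
            partial_charges=[0.0, 0.0],
            net_charge=0.0,
            conformer_id="neutral_diatomic",
        )
    if kind == "polar_diatomic":
        return Adsorbate(
            symbols=["C", "O"],
            positions=[[0.0, 0.0, 0.0], [0.0, 0.0, 1.20]],
            partial_charges=[0.4, -0.4],
            net_charge=0.0,
            conformer_id="polar_diatomic",
        )
    if kind == "planar_4atom":
        # formaldehyde-like geometry, all atoms in the y-z plane
        return Adsorbate(
            symbols=["C", "O", "H", "H"],
            positions=[
                [0.0, 0.000, 0.000],
                [0.0, 0.000, 1.210],
                [0.0, 0.943, -0.587],
                [0.0, -0.943, -0.587],
            ],
            partial_charges=[0.30, -0.40, 0.05, 0.05],
            net_charge=0.0,
            conformer_id="planar_4atom",
        )
    raise ValidationError(f"unknown toy adsorbate kind {kind!r}")


def make_calibration_set(
    n_true: int = 37,
    slope: float = 1.3,
    intercept: float = 0.2,
    noise_sd: float = 0.02,
    n_samples: int = 60,
    seed: int = 1,
    epsilon_ref: float = EPSILON_REF,
) -> CalibrationSet:
    """Synthetic calibration data with a known ground-truth divisor.

    V_Coulomb ~ U(−1.5, 0.2) eV and V_LJ(ε_ref) ~ U(−3, 0) eV are drawn
    independently (non-collinear with probability 1), and

        E_ref = slope · (V_Coulomb + V_LJ/n_true) + intercept + N(0, noise_sd).

    Reproducible bit-for-bit from the seed.
    """
    if n_true < 1:
        raise ValidationError("n_true must be >= 1")
    if n_samples < 10:
        raise ValidationError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    v_c = rng.uniform(-1.5, 0.2, n_samples)
    v_lj = rng.uniform(-3.0, 0.0, n_samples)
    e_ref = slope * (v_c + v_lj / n_true) + intercept
    if noise_sd > 0:
        e_ref = e_ref + rng.normal(0.0, noise_sd, n_samples)
    return CalibrationSet(v_coulomb=v_c, v_lj_ref=v_lj, e_ref=e_ref,
                          epsilon_ref=epsilon_ref)
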