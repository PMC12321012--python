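"""Pairwise Coulomb + Lennard-Jones adsorption energy.

The potential adsorption energy of a rigid pose is

    E_a = V_Coulomb + V_LJ
    V_Coulomb = k_e * sum_s sum_a  q_s q_a / r_sa
    V_LJ      = sum_s sum_a  4 eps [ (sigma_sa / r_sa)^12 - (sigma_sa / r_sa)^6 ]

summed over ALL slab atoms s (not just the surface layer) and all
adsorbate atoms a.  sigma_sa is the sum of the two van der Waals radii
(the zero-crossing distance); eps is the single tunable well depth.
Units: eV, Å, elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AtomOverlapError, ValidationError
from .structures import Adsorbate, RadiiTable, Slab, min_image_distance_matrix

__all__ = [
    "K_E",
    "EnergyModel",
    "EnergyBreakdown",
    "pair_sigma",
    "coulomb_energy",
    "lj_energy",
    "adsorption_energy",
]

#: Coulomb prefactor e^2 / (4 pi eps_0) in eV·Å (CODATA).
K_E = 14.3996

#: Production Lennard-Jones well depth in eV.
#: Note: the calibration chain 0.005 eV / 37 gives 1.35e-4 eV, which is not
#: identical to this production value; both are available as configuration
#: (see docs/methods.md).
DEFAULT_EPSILON = 1.49e-4

# Poses with any pair closer than this are upstream bugs, not physics.
_MIN_PAIR_DISTANCE = 0.1


@dataclass
class EnergyModel:
    """Parameters of the pairwise energy.

    epsilon   LJ well depth in eV (default the calibrated production value).
    radii     vdW radii providing sigma = r_vdw(s) + r_vdw(a).
    min_image use in-plane minimum-image distances over the periodic cell.
    cutoff    optional real-space cutoff in Å; pairs beyond it contribute 0.
    """

    epsilon: float = DEFAULT_EPSILON
    radii: RadiiTable = field(default_factory=RadiiTable.default)
    min_image: bool = True
    cutoff: float | None = None
    k_e: float = field(default=K_E, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValidationError("cutoff must be positive when set")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposed pose energy in eV; e_a is the sum by construction."""

    v_coulomb: float
    v_lj: float
    e_a: float

    def __post_init__(self) -> None:
        assert abs(self.e_a - (self.v_coulomb + self.v_lj)) < 1e-12


def pair_sigma(element_s: str, element_a: str, radii: RadiiTable) -> float:
    """LJ zero-crossing distance: sum of the two vdW radii (Å)."""
    return radii.vdw(element_s) + radii.vdw(element_a)


def _pair_distances(slab: Slab, adsorbate_positions: np.ndarray,
                    model: EnergyModel) -> np.ndarray:
    r = min_image_distance_matrix(
        slab.lattice, slab.positions, np.atleast_2d(adsorbate_positions),
        in_plane=model.min_image,
    )
    if r.min() < _MIN_PAIR_DISTANCE:
        raise AtomOverlapError(
            f"pair distance {r.min():.4f} Å below {_MIN_PAIR_DISTANCE} Å guard"
        )
    return r


def coulomb_energy(slab: Slab, adsorbate_positions, adsorbate_charges,
                   model: EnergyModel) -> float:
    """Coulomb sum k_e * Σ q_s q_a / r over all slab × adsorbate pairs (eV)."""
    if slab.formal_charges is None:
        raise ValidationError("slab has no formal charges; run the charging step")
    q_a = np.asarray(adsorbate_charges, dtype=float)
    r = _pair_distances(slab, adsorbate_positions, model)
    contrib = model.k_e * np.outer(slab.formal_charges, q_a) / r
    if model.cutoff is not None:
        contrib = np.where(r <= model.cutoff, contrib, 0.0)
    return float(contrib.sum())


def _sigma_matrix(slab_symbols, ads_symbols, radii: RadiiTable) -> np.ndarray:
    r_s = np.array([radii.vdw(s) for s in slab_symbols])
    r_a = np.array([radii.vdw(s) for s in ads_symbols])
    return r_s[:, None] + r_a[None, :]


def lj_energy(slab: Slab, adsorbate_positions, adsorbate_symbols,
              model: EnergyModel) -> float:
    """Lennard-Jones sum 4ε[(σ/r)^12 − (σ/r)^6] over the same pairs (eV)."""
    r = _pair_distances(slab, adsorbate_positions, model)
    sigma = _sigma_matrix(slab.symbols, adsorbate_symbols, model.radii)
    x6 = (sigma / r) ** 6
    contrib = 4.0 * model.epsilon * (x6 * x6 - x6)
    if model.cutoff is not None:
        contrib = np.where(r <= model.cutoff, contrib, 0.0)
    return float(contrib.sum())


def adsorption_energy(slab: Slab, pose_coords, adsorbate: Adsorbate,
                      model: EnergyModel) -> EnergyBreakdown:
    """Score one rigid pose: E_a = V_Coulomb + V_LJ (pure function)."""
    if adsorbate.partial_charges is None:
        raise ValidationError("adsorbate has no partial charges")
    coords = np.asarray(pose_coords, dtype=float)
    v_c = coulomb_energy(slab, coords, adsorbate.partial_charges, model)
    v_lj = lj_energy(slab, coords, adsorbate.symbols, model)
    return EnergyBreakdown(v_coulomb=v_c, v_lj=v_lj, e_a=v_c + v_lj)
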