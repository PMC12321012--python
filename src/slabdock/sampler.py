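"""Exhaustive rigid-body pose sampling over a lattice-aligned site grid.

For every grid site the adsorbate is placed above the surface at each
enumerated Euler orientation and lowered in fixed steps until the first
adsorbate–surface contact appears in the covalent-radius connectivity
test; that first-contact geometry is scored with the pairwise potential.
The scan is exhaustive and deterministic: identical results for any
worker count.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .errors import ValidationError
from .potential import EnergyBreakdown, EnergyModel, adsorption_energy
from .structures import Adsorbate, RadiiTable, Slab, min_image_distance_matrix

__all__ = [
    "SiteGrid",
    "Rotation",
    "Pose",
    "generate_grid",
    "enumerate_rotations",
    "place_adsorbate",
    "build_connectivity",
    "approach",
    "scan_surface",
]

#: Default multiplier on the sum of covalent radii in the contact test.
DEFAULT_CONNECTIVITY_SCALE = 1.1
#: Default extra height (Å) of the adsorbate's lowest atom above the
#: topmost surface atom at the start of the descent.
DEFAULT_HEADROOM = 4.0


@dataclass(frozen=True, order=True)
class Rotation:
    """Euler angles in degrees, intrinsic Z-Y-Z, applied about the COM."""

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", float(self.phi) % 360.0)
        object.__setattr__(self, "theta", float(self.theta) % 360.0)
        object.__setattr__(self, "psi", float(self.psi) % 360.0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)

    def matrix(self) -> np.ndarray:
        return ScipyRotation.from_euler(
            "ZYZ", [self.phi, self.theta, self.psi], degrees=True
        ).as_matrix()


@dataclass
class SiteGrid:
    """Equidistant fractional (u, v) sites along the a and b vectors."""

    spacing: float
    n_a: int
    n_b: int
    sites: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.sites)

    def cartesian(self, slab: Slab) -> np.ndarray:
        uv = np.array(self.sites)
        return uv[:, 0, None] * slab.lattice[0] + uv[:, 1, None] * slab.lattice[1]


@dataclass
class Pose:
    """One site × rotation × conformer placement at its stopping geometry.

    ``contacts`` holds (slab_atom_index, adsorbate_atom_index) pairs at
    the stopping geometry; empty when the descent ended without contact.
    """

    site_index: int
    conformer_id: str
    rotation: Rotation
    coords: np.ndarray
    contact: bool
    n_steps: int
    energy: EnergyBreakdown | None = None
    contacts: frozenset = field(default_factory=frozenset)


def generate_grid(slab: Slab, spacing: float) -> SiteGrid:
    """Lay out ceil(|v|/spacing) equidistant sites along each lattice vector.

    Fractional sites are k/n for k = 0..n-1 — the endpoint is excluded
    because it is the periodic image of the origin.
    """
    if spacing <= 0:
        raise ValidationError("grid spacing must be positive")
    la = float(np.linalg.norm(slab.lattice[0]))
    lb = float(np.linalg.norm(slab.lattice[1]))
    if spacing > la and spacing > lb:
        warnings.warn("grid spacing exceeds both lattice vectors; single-site grid",
                      stacklevel=2)
    n_a = max(1, math.ceil(la / spacing))
    n_b = max(1, math.ceil(lb / spacing))
    sites = [(k / n_a, l / n_b) for k in range(n_a) for l in range(n_b)]
    return SiteGrid(spacing=spacing, n_a=n_a, n_b=n_b, sites=sites)


def enumerate_rotations(step_deg: float) -> list[Rotation]:
    """Cartesian product of Euler angles k·step for k = 0 .. 360/step − 2.

    Each angle takes 360/step − 1 values (17 at a 20° step, hence
    17³ = 4913 orientations per site), in lexicographic (φ, θ, ψ) order.
    """
    if step_deg <= 0 or 360.0 % step_deg != 0:
        raise ValidationError(f"angle step {step_deg}° must divide 360°")
    n = int(360.0 / step_deg) - 1
    values = [k * step_deg for k in range(n)]
    return [Rotation(phi, theta, psi)
            for phi, theta, psi in itertools.product(values, repeat=3)]


def place_adsorbate(
    adsorbate: Adsorbate,
    slab: Slab,
    site: tuple[float, float],
    rotation: Rotation,
    clearance: float | None = None,
) -> np.ndarray:
    """Rotate about the COM, then set the COM above the site.

    The COM's lateral (x, y) position becomes the site's Cartesian
    position u·a + v·b; its height becomes z_top + clearance where z_top
    is the topmost surface atom.  The default clearance puts the lowest
    adsorbate atom a fixed headroom above z_top, guaranteeing no contact
    at the first step.
    """
    com = adsorbate.center_of_mass
    rotated = (adsorbate.positions - com) @ rotation.matrix().T
    if clearance is None:
        clearance = -rotated[:, 2].min() + DEFAULT_HEADROOM
    u, v = site
    site_cart = u * slab.lattice[0] + v * slab.lattice[1]
    target = np.array([site_cart[0], site_cart[1], slab.top_z() + clearance])
    return rotated + target


def build_connectivity(
    slab: Slab,
    coords: np.ndarray,
    adsorbate_symbols: list[str],
    radii: RadiiTable,
    scale: float = DEFAULT_CONNECTIVITY_SCALE,
) -> frozenset[tuple[int, int]]:
    """Adsorbate–surface contact pairs under the covalent-radius cutoff.

    Pair (s, a) is a contact iff r_sa < scale · (r_cov(s) + r_cov(a)),
    with the in-plane minimum image.  Only surface-masked slab atoms
    participate; slab indices refer to the full atom list.
    """
    if slab.surface_mask is None:
        raise ValidationError("surface mask not computed; run detect_surface_atoms")
    surf_idx = np.flatnonzero(slab.surface_mask)
    if len(surf_idx) == 0:
        return frozenset()
    r = min_image_distance_matrix(
        slab.lattice, slab.positions[surf_idx], np.atleast_2d(coords), in_plane=True
    )
    cov_s = np.array([radii.covalent(slab.symbols[i]) for i in surf_idx])
    cov_a = np.array([radii.covalent(s) for s in adsorbate_symbols])
    cutoff = scale * (cov_s[:, None] + cov_a[None, :])
    pairs = np.argwhere(r < cutoff)
    return frozenset((int(surf_idx[i]), int(j)) for i, j in pairs)


def approach(
    slab: Slab,
    adsorbate: Adsorbate,
    site: tuple[float, float],
    rotation: Rotation,
    model: EnergyModel,
    site_index: int = 0,
    step: float = 0.5,
    clearance: float | None = None,
    connectivity_scale: float = DEFAULT_CONNECTIVITY_SCALE,
    max_steps: int | None = None,
) -> Pose:
    """Lower the pose by ``step`` Å until the connectivity matrix diverges.

    The first non-empty contact set interrupts the descent; the pose is
    scored at that first-contact geometry.  If the COM drops below the
    lowest surface atom (or ``max_steps`` is exhausted) without any
    contact the pose is returned flagged ``contact=False`` and unscored.
    """
    if step <= 0:
        raise ValidationError("approach step must be positive")
    start = place_adsorbate(adsorbate, slab, site, rotation, clearance=clearance)
    surf_idx = np.flatnonzero(slab.surface_mask) if slab.surface_mask is not None else None
    if surf_idx is None or len(surf_idx) == 0:
        raise ValidationError("surface mask not computed; run detect_surface_atoms")
    z_floor = float(slab.positions[surf_idx, 2].min())
    com_z0 = float(
        adsorbate.masses @ start[:, 2] / adsorbate.masses.sum()
    )
    if max_steps is None:
        max_steps = int(math.ceil((com_z0 - z_floor) / step)) + 2
    for k in range(max_steps + 1):
        coords = start - np.array([0.0, 0.0, k * step])
        contacts = build_connectivity(
            slab, coords, adsorbate.symbols, model.radii, scale=connectivity_scale
        )
        if contacts:
            energy = adsorption_energy(slab, coords, adsorbate, model)
            return Pose(site_index=site_index, conformer_id=adsorbate.conformer_id,
                        rotation=rotation, coords=coords, contact=True,
                        n_steps=k, energy=energy, contacts=contacts)
        if com_z0 - k * step < z_floor:
            break
    return Pose(site_index=site_index, conformer_id=adsorbate.conformer_id,
                rotation=rotation, coords=coords, contact=False,
                n_steps=k, energy=None, contacts=frozenset())


def _pose_rank(pose: Pose) -> tuple:
    # minimum E_a; ties broken by conformer label then rotation order
    return (pose.energy.e_a, pose.conformer_id, pose.rotation.as_tuple())


def _scan_site(slab: Slab, conformers, site_index: int, site, rotations,
               model: EnergyModel, step: float, clearance,
               connectivity_scale: float, keep_all: bool):
    best: Pose | None = None
    all_poses: list[Pose] = []
    for adsorbate in conformers:
        for rotation in rotations:
            pose = approach(
                slab, adsorbate, site, rotation, model,
                site_index=site_index, step=step, clearance=clearance,
                connectivity_scale=connectivity_scale,
            )
            if not pose.contact:
                continue
            if keep_all:
                all_poses.append(pose)
            if best is None or _pose_rank(pose) < _pose_rank(best):
                best = pose
    return site_index, best, all_poses


def scan_surface(
    slab: Slab,
    conformers,
    grid: SiteGrid,
    rotations,
    model: EnergyModel,
    step: float = 0.5,
    clearance: float | None = None,
    connectivity_scale: float = DEFAULT_CONNECTIVITY_SCALE,
    workers: int = 1,
    keep_all: bool = False,
    progress_callback=None,
) -> list[Pose | None] | tuple[list[Pose | None], list[Pose]]:
    """Exhaustively approach every conformer × rotation on every site.

    Returns the per-site representatives — the minimum-E_a contact pose
    of each site, or ``None`` for a site where nothing made contact.
    With ``keep_all=True`` also returns every contact pose.  Work is
    partitioned by site and merged in site order, so the result is
    identical for any ``workers`` count.
    """
    if isinstance(conformers, Adsorbate):
        conformers = [conformers]
    conformers = sorted(conformers, key=lambda a: a.conformer_id)
    rotations = list(rotations)
    args = [
        (slab, conformers, i, site, rotations, model, step, clearance,
         connectivity_scale, keep_all)
        for i, site in enumerate(grid.sites)
    ]
    if workers == 1:
        results = [_scan_site(*a) for a in args]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(_scan_site)(*a) for a in args)
    results.sort(key=lambda r: r[0])  # deterministic ordered merge
    representatives: list[Pose | None] = [r[1] for r in results]
    if progress_callback is not None:
        for i, rep in enumerate(representatives):
            progress_callback(i, rep)
    if keep_all:
        all_poses = [p for r in results for p in r[2]]
        return representatives, all_poses
    return representatives
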