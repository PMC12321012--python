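"""Periodic slab models and rigid molecular adsorbates.

A :class:`Slab` is a crystal surface: a few atomic layers periodic along
the in-plane lattice vectors ``a`` and ``b``, with vacuum along the
out-of-plane direction (approximately ``z``).  An :class:`Adsorbate` is a
rigid conformer carrying per-atom partial charges.  Units are Å and
elementary charges throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import ATOMIC_MASSES, load_covalent_radii, load_vdw_radii
from .errors import (
    ChargeMismatchError,
    InputFileError,
    MissingElementError,
    ValidationError,
)

__all__ = [
    "Slab",
    "Adsorbate",
    "RadiiTable",
    "read_structure",
    "make_supercell",
    "detect_surface_atoms",
    "min_image_distance_matrix",
]

# Minimum believable interatomic distance inside an adsorbate (Å).
_MIN_INTRAMOLECULAR = 0.3


@dataclass
class RadiiTable:
    """Per-element van der Waals and covalent radii in Å.

    ``vdw_radius`` feeds the Lennard-Jones zero-crossing σ and the default
    surface-atom burial test; ``covalent_radius`` feeds the contact
    (connectivity) cutoff.
    """

    vdw_radius: dict[str, float]
    covalent_radius: dict[str, float]
    provenance: str = "Alvarez-2013 vdW / Cordero-2008 covalent"

    def __post_init__(self) -> None:
        for table in (self.vdw_radius, self.covalent_radius):
            for element, r in table.items():
                if r <= 0:
                    raise ValidationError(f"non-positive radius for {element}: {r}")

    @classmethod
    def default(cls) -> "RadiiTable":
        return cls(vdw_radius=load_vdw_radii(), covalent_radius=load_covalent_radii())

    def vdw(self, element: str) -> float:
        try:
            return self.vdw_radius[element]
        except KeyError:
            raise MissingElementError(f"no van der Waals radius for {element!r}") from None

    def covalent(self, element: str) -> float:
        try:
            return self.covalent_radius[element]
        except KeyError:
            raise MissingElementError(f"no covalent radius for {element!r}") from None

    def check_elements(self, symbols) -> None:
        for s in set(symbols):
            self.vdw(s)
            self.covalent(s)


@dataclass
class Slab:
    """A periodic slab surface.

    ``lattice`` rows are the cell vectors ``a``, ``b``, ``c`` in Å;
    ``a`` and ``b`` are the periodic in-plane directions and ``c`` carries
    the vacuum.  ``positions`` are Cartesian Å.  ``formal_charges`` (e)
    and ``surface_mask`` are absent until assigned/computed.
    """

    lattice: np.ndarray
    symbols: list[str]
    positions: np.ndarray
    formal_charges: np.ndarray | None = None
    surface_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.symbols = list(self.symbols)
        if self.formal_charges is not None:
            self.formal_charges = np.asarray(self.formal_charges, dtype=float)
        if self.surface_mask is not None:
            self.surface_mask = np.asarray(self.surface_mask, dtype=bool)
        self.validate()
        self.wrap_in_plane()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.symbols)
        if n == 0:
            raise ValidationError("slab has no atoms")
        if self.positions.shape != (n, 3):
            raise ValidationError("symbols/positions count mismatch")
        vol = abs(np.linalg.det(self.lattice))
        if vol < 1e-9:
            raise ValidationError("degenerate lattice (zero cell volume)")
        for name, arr in (("formal_charges", self.formal_charges),
                          ("surface_mask", self.surface_mask)):
            if arr is not None and len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != atom count {n}")
        c_hat = self.lattice[2] / np.linalg.norm(self.lattice[2])
        if abs(c_hat[2]) <= 0.5:
            raise ValidationError(
                "surface normal must be approximately along z (|c_hat . z_hat| > 0.5)"
            )
        z = self.positions[:, 2]
        if z.max() - z.min() >= abs(self.lattice[2][2]):
            raise ValidationError("atom z-spread exceeds out-of-plane cell length; "
                                  "vacuum direction is ambiguous")

    def wrap_in_plane(self) -> None:
        """Wrap fractional a/b coordinates into [0, 1); z untouched."""
        frac = self.positions @ np.linalg.inv(self.lattice)
        frac[:, :2] %= 1.0
        # guard against 1.0 from floating-point roundup of -1e-17 % 1
        frac[:, :2][frac[:, :2] >= 1.0] = 0.0
        self.positions = frac @ self.lattice

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def fractional(self) -> np.ndarray:
        return self.positions @ np.linalg.inv(self.lattice)

    def copy(self) -> "Slab":
        return Slab(
            lattice=self.lattice.copy(),
            symbols=list(self.symbols),
            positions=self.positions.copy(),
            formal_charges=None if self.formal_charges is None else self.formal_charges.copy(),
            surface_mask=None if self.surface_mask is None else self.surface_mask.copy(),
        )

    def top_z(self) -> float:
        """Highest z among surface atoms (whole slab if mask not set)."""
        if self.surface_mask is not None and self.surface_mask.any():
            return float(self.positions[self.surface_mask, 2].max())
        return float(self.positions[:, 2].max())


@dataclass
class Adsorbate:
    """A rigid molecular conformer with per-atom partial charges (e)."""

    symbols: list[str]
    positions: np.ndarray
    partial_charges: np.ndarray | None = None
    net_charge: float = 0.0
    conformer_id: str = "conf0"
    masses: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.symbols = list(self.symbols)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
        try:
            self.masses = np.array([ATOMIC_MASSES[s] for s in self.symbols])
        except KeyError as exc:
            raise MissingElementError(f"no atomic mass for {exc.args[0]!r}") from None
        self.validate()

    def validate(self) -> None:
        n = len(self.symbols)
        if n == 0:
            raise ValidationError("adsorbate has no atoms")
        if self.positions.shape != (n, 3):
            raise ValidationError("symbols/positions count mismatch")
        if n > 1:
            d = np.linalg.norm(
                self.positions[:, None, :] - self.positions[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            if d.min() <= _MIN_INTRAMOLECULAR:
                raise ValidationError(
                    f"interatomic distance {d.min():.3f} Å <= {_MIN_INTRAMOLECULAR} Å"
                )
        if self.partial_charges is not None:
            if len(self.partial_charges) != n:
                raise ChargeMismatchError(
                    f"{len(self.partial_charges)} charges for {n} atoms"
                )
            total = float(self.partial_charges.sum())
            if abs(total - self.net_charge) > 0.01:
                raise ChargeMismatchError(
                    f"charges sum to {total:+.4f} e but net charge is "
                    f"{self.net_charge:+.4f} e"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.positions / self.masses.sum()

    def with_charges(self, charges, net_charge: float | None = None) -> "Adsorbate":
        return Adsorbate(
            symbols=list(self.symbols),
            positions=self.positions.copy(),
            partial_charges=np.asarray(charges, dtype=float),
            net_charge=self.net_charge if net_charge is None else float(net_charge),
            conformer_id=self.conformer_id,
        )

    def copy(self) -> "Adsorbate":
        return dataclasses.replace(
            self,
            symbols=list(self.symbols),
            positions=self.positions.copy(),
            partial_charges=None if self.partial_charges is None
            else self.partial_charges.copy(),
        )


# -- periodic geometry --------------------------------------------------

def min_image_distance_matrix(
    lattice: np.ndarray,
    points_a: np.ndarray,
    points_b: np.ndarray,
    in_plane: bool = True,
) -> np.ndarray:
    """Pairwise distances with the in-plane minimum-image convention.

    Each separation vector is reduced by integer combinations of the
    ``a`` and ``b`` cell vectors so the nearest periodic copy is used;
    the out-of-plane direction is not imaged (slab geometry).  With
    ``in_plane=False`` plain Euclidean distances are returned.
    """
    pa = np.atleast_2d(points_a)
    pb = np.atleast_2d(points_b)
    delta = pa[:, None, :] - pb[None, :, :]
    if not in_plane:
        return np.linalg.norm(delta, axis=-1)
    inv = np.linalg.inv(lattice)
    frac = delta @ inv
    frac[..., 0] -= np.round(frac[..., 0])
    frac[..., 1] -= np.round(frac[..., 1])
    base = frac @ lattice
    # nearest-rounding can miss the true image in strongly skewed cells;
    # refine over the 3x3 neighbour shifts
    best = np.full(base.shape[:-1], np.inf)
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            shift = i * lattice[0] + j * lattice[1]
            d = np.linalg.norm(base + shift, axis=-1)
            np.minimum(best, d, out=best)
    return best


# -- operations ---------------------------------------------------------

def make_supercell(slab: Slab, na: int, nb: int) -> Slab:
    """Replicate the slab ``na`` times along ``a`` and ``nb`` along ``b``."""
    if not (isinstance(na, (int, np.integer)) and isinstance(nb, (int, np.integer))):
        raise ValidationError("supercell multipliers must be integers")
    if na < 1 or nb < 1:
        raise ValidationError("supercell multipliers must be >= 1")
    a, b, c = slab.lattice
    positions = []
    symbols: list[str] = []
    charges = [] if slab.formal_charges is not None else None
    mask = [] if slab.surface_mask is not None else None
    for i in range(na):
        for j in range(nb):
            shift = i * a + j * b
            positions.append(slab.positions + shift)
            symbols.extend(slab.symbols)
            if charges is not None:
                charges.append(slab.formal_charges)
            if mask is not None:
                mask.append(slab.surface_mask)
    return Slab(
        lattice=np.array([na * a, nb * b, c]),
        symbols=symbols,
        positions=np.concatenate(positions),
        formal_charges=None if charges is None else np.concatenate(charges),
        surface_mask=None if mask is None else np.concatenate(mask),
    )


def detect_surface_atoms(
    slab: Slab,
    radii: RadiiTable | None = None,
    radius_set: str = "vdw",
) -> np.ndarray:
    """Mark the outermost-layer (surface) atoms of a slab.

    An atom is buried when its centre falls inside the in-plane disc of
    radius ``r_j`` around any atom ``j`` lying strictly higher along z;
    atoms that are never buried form the surface.  ``radius_set`` selects
    which radius the disc uses ("vdw", the default, or "covalent").
    The mask is stored on the slab and returned.
    """
    radii = radii or RadiiTable.default()
    if radius_set == "vdw":
        r = np.array([radii.vdw(s) for s in slab.symbols])
    elif radius_set == "covalent":
        r = np.array([radii.covalent(s) for s in slab.symbols])
    else:
        raise ValidationError(f"unknown radius set {radius_set!r}")
    z = slab.positions[:, 2]
    # in-plane (xy) minimum-image distances between atom centres
    flat = slab.positions.copy()
    flat[:, 2] = 0.0
    d_xy = min_image_distance_matrix(slab.lattice, flat, flat, in_plane=True)
    higher = z[None, :] > z[:, None] + 1e-9   # j strictly above i
    buried = (d_xy < r[None, :]) & higher
    mask = ~buried.any(axis=1)
    slab.surface_mask = mask
    return mask


# -- file I/O -----------------------------------------------------------

def _read_sidecar_charges(path: Path) -> np.ndarray:
    values = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            values.append(float(line))
    return np.array(values)


def _read_cif(path: Path) -> Slab:
    import gemmi

    try:
        st = gemmi.read_small_structure(str(path))
    except Exception as exc:
        raise InputFileError(f"cannot parse CIF {path}: {exc}") from exc
    if not st.sites:
        raise InputFileError(f"CIF {path} contains no atom sites")
    cell = st.cell
    lattice = np.array(cell.orth.mat.tolist()).T  # rows a, b, c
    frac = np.array([[s.fract.x, s.fract.y, s.fract.z] for s in st.sites])
    symbols = [s.element.name for s in st.sites]
    return Slab(lattice=lattice, symbols=symbols, positions=frac @ lattice)


def _read_xyz(path: Path) -> tuple[list[str], np.ndarray, dict, np.ndarray | None]:
    """Plain or extended XYZ.  Returns (symbols, positions, info, charges)."""
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise InputFileError(f"{path}: truncated XYZ")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise InputFileError(f"{path}: bad XYZ atom count line") from None
    comment = lines[1]
    info: dict[str, str] = {}
    columns = ["species", "pos"]
    for token in _split_extxyz_comment(comment):
        if "=" in token:
            key, value = token.split("=", 1)
            info[key] = value.strip('"')
    if "Properties" in info:
        columns = _parse_extxyz_properties(info["Properties"])
    body = lines[2:2 + natoms]
    if len(body) < natoms:
        raise InputFileError(f"{path}: fewer atom lines than declared")
    symbols, positions, charges = [], [], []
    has_charge = "charge" in columns
    charge_col = None
    if has_charge:
        # column offsets: species=1 field, pos=3 fields, others 1 each
        offset = 0
        for name in columns:
            width = 3 if name == "pos" else 1
            if name == "charge":
                charge_col = offset
                break
            offset += width
    for line in body:
        parts = line.split()
        symbols.append(parts[0])
        positions.append([float(x) for x in parts[1:4]])
        if has_charge:
            charges.append(float(parts[charge_col]))
    return symbols, np.array(positions), info, (np.array(charges) if has_charge else None)


def _split_extxyz_comment(comment: str) -> list[str]:
    """Split key=value tokens, keeping quoted values intact."""
    tokens, current, in_quote = [], "", False
    for ch in comment:
        if ch == '"':
            in_quote = not in_quote
            current += ch
        elif ch == " " and not in_quote:
            if current:
                tokens.append(current)
            current = ""
        else:
            current += ch
    if current:
        tokens.append(current)
    return tokens


def _parse_extxyz_properties(spec: str) -> list[str]:
    parts = spec.split(":")
    return [parts[i] for i in range(0, len(parts), 3)]


def _read_sdf(path: Path) -> Adsorbate:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next(iter(supplier), None)
    if mol is None:
        raise InputFileError(f"cannot parse SDF {path}")
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    positions = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
    )
    charges = None
    if mol.HasProp("PARTIAL_CHARGES"):
        charges = np.array([float(x) for x in mol.GetProp("PARTIAL_CHARGES").split()])
        if len(charges) != len(symbols):
            raise ChargeMismatchError(
                f"{len(charges)} charges in PARTIAL_CHARGES for {len(symbols)} atoms"
            )
    net = float(mol.GetProp("NET_CHARGE")) if mol.HasProp("NET_CHARGE") else (
        float(charges.sum().round()) if charges is not None else 0.0
    )
    name = mol.GetProp("_Name") if mol.HasProp("_Name") else path.stem
    return Adsorbate(symbols=symbols, positions=positions, partial_charges=charges,
                     net_charge=net, conformer_id=name or path.stem)


def read_structure(
    path,
    format: str | None = None,
    charges=None,
    net_charge: float | None = None,
) -> Slab | Adsorbate:
    """Read a slab (CIF) or adsorbate (XYZ / extended-XYZ / SDF).

    ``charges`` may be a path to a sidecar file (one float per atom,
    ``#`` comments allowed) or an explicit sequence; it applies to
    adsorbates only.  Formal charges found in a CIF are deliberately
    ignored — surface charges always come from the charging step.
    """
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"no such file: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "cif":
        return _read_cif(path)
    if fmt in ("xyz", "extxyz"):
        symbols, positions, info, file_charges = _read_xyz(path)
        ads = Adsorbate(symbols=symbols, positions=positions,
                        conformer_id=info.get("conformer_id", path.stem))
        charge_values = file_charges
        if charges is not None:
            charge_values = (_read_sidecar_charges(Path(charges))
                             if isinstance(charges, (str, Path))
                             else np.asarray(charges, dtype=float))
        if charge_values is not None:
            declared = net_charge
            if declared is None:
                declared = float(info.get("net_charge", round(float(charge_values.sum()))))
            if len(charge_values) != len(ads):
                raise ChargeMismatchError(
                    f"{len(charge_values)} charges for {len(ads)} atoms"
                )
            ads = ads.with_charges(charge_values, net_charge=declared)
        return ads
    if fmt == "sdf":
        return _read_sdf(path)
    raise InputFileError(f"unsupported format {fmt!r}")


def write_xyz(path, obj: Slab | Adsorbate, append: bool = False,
              comment_extra: dict | None = None) -> None:
    """Write one extended-XYZ frame with charge / surface-mask columns."""
    path = Path(path)
    lines = [str(len(obj))]
    fields = ["species:S:1", "pos:R:3"]
    info: dict[str, object] = dict(comment_extra or {})
    if isinstance(obj, Slab):
        cell = " ".join(f"{x:.10f}" for x in obj.lattice.ravel())
        info["Lattice"] = f'"{cell}"'
        charges = obj.formal_charges
        mask = obj.surface_mask
        if mask is not None:
            fields.append("surface:I:1")
    else:
        charges = obj.partial_charges
        mask = None
        info.setdefault("conformer_id", obj.conformer_id)
        info.setdefault("net_charge", obj.net_charge)
    if charges is not None:
        fields.insert(2, "charge:R:1")
    info["Properties"] = ":".join(fields)
    lines.append(" ".join(f"{k}={v}" for k, v in info.items()))
    for i, (s, p) in enumerate(zip(obj.symbols, obj.positions)):
        row = f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}"
        if charges is not None:
            row += f" {charges[i]:.10f}"
        if mask is not None:
            row += f" {int(mask[i])}"
        lines.append(row)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_slab_xyz(path) -> Slab:
    """Read a slab written by :func:`write_xyz` (extended-XYZ with Lattice)."""
    symbols, positions, info, charges = _read_xyz(Path(path))
    if "Lattice" not in info:
        raise InputFileError(f"{path}: extended-XYZ slab requires a Lattice entry")
    lattice = np.array([float(x) for x in info["Lattice"].split()]).reshape(3, 3)
    return Slab(lattice=lattice, symbols=symbols, positions=positions,
                formal_charges=charges)


def write_cif(path, slab: Slab) -> None:
    """Write a P1 CIF of the slab."""
    frac = slab.fractional
    a, b, c = (np.linalg.norm(v) for v in slab.lattice)
    la, lb, lc = slab.lattice

    def angle(u, v):
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))

    lines = [
        "data_slab",
        "_symmetry_space_group_name_H-M   'P 1'",
        "_symmetry_Int_Tables_number      1",
        f"_cell_length_a     {a:.6f}",
        f"_cell_length_b     {b:.6f}",
        f"_cell_length_c     {c:.6f}",
        f"_cell_angle_alpha  {angle(lb, lc):.6f}",
        f"_cell_angle_beta   {angle(la, lc):.6f}",
        f"_cell_angle_gamma  {angle(la, lb):.6f}",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, (s, f) in enumerate(zip(slab.symbols, frac)):
        lines.append(f"{s}{i + 1} {s} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")
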