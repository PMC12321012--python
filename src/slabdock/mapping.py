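"""Reduction of scan output: heatmaps, distinct configurations, binding modes.

The per-site minima from a scan form an adsorption-energy map over the
(u, v) site grid.  An energy-window filter collapses poses that are
equivalent by cell symmetry or proximity, and denticity classification
counts how many adsorbate atoms anchor the surface in each pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import Pose, SiteGrid

__all__ = [
    "AdsorptionMap",
    "ConfigurationSet",
    "make_map",
    "filter_equivalent",
    "discard_implausible",
    "build_heatmap",
    "classify_denticity",
    "poses_to_table",
]

#: Energy window (eV) below which two poses count as the same configuration.
DEFAULT_WINDOW = 0.1


@dataclass
class AdsorptionMap:
    """Per-site minimum adsorption energies on the (n_a, n_b) grid.

    ``energies[i, j]`` is the minimum E_a (eV) at site (u_i, v_j), NaN
    where no pose made contact; ``representatives`` maps site index to
    the minimum-energy pose.
    """

    grid: SiteGrid
    energies: np.ndarray
    representatives: list[Pose | None]


def make_map(grid: SiteGrid, representatives: list[Pose | None]) -> AdsorptionMap:
    energies = np.full((grid.n_a, grid.n_b), np.nan)
    for idx, pose in enumerate(representatives):
        i, j = divmod(idx, grid.n_b)
        if pose is not None and pose.contact:
            energies[i, j] = pose.energy.e_a
    return AdsorptionMap(grid=grid, energies=energies,
                         representatives=list(representatives))


@dataclass
class ConfigurationSet:
    """Energy-distinct poses, ascending in E_a."""

    kept: list[Pose]
    window: float


def filter_equivalent(poses, window: float = DEFAULT_WINDOW) -> ConfigurationSet:
    """Collapse poses closer than ``window`` eV into one configuration.

    Greedy pass over poses sorted ascending by E_a (ties by site index):
    a pose survives iff its E_a differs by at least ``window`` from the
    most recently kept pose.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    scored = [p for p in poses if p is not None and p.contact]
    scored.sort(key=lambda p: (p.energy.e_a, p.site_index))
    kept: list[Pose] = []
    for pose in scored:
        if not kept or pose.energy.e_a - kept[-1].energy.e_a >= window:
            kept.append(pose)
    return ConfigurationSet(kept=kept, window=window)


def _is_h_down(pose: Pose, adsorbate_symbols: list[str]) -> bool:
    contact_atoms = {a for _, a in pose.contacts}
    return bool(contact_atoms) and all(
        adsorbate_symbols[a] == "H" for a in contact_atoms
    )


def discard_implausible(poses, adsorbate_symbols: list[str],
                        rule: str = "h_down") -> list[Pose]:
    """Drop poses matching a curation rule (calibration-set hygiene).

    The bundled ``h_down`` rule discards a pose iff every surface contact
    goes through an adsorbate hydrogen; mixed H + heavy-atom anchoring is
    kept.
    """
    if rule != "h_down":
        raise ValueError(f"unknown curation rule {rule!r}")
    return [p for p in poses if not _is_h_down(p, adsorbate_symbols)]


def build_heatmap(ads_map: AdsorptionMap, csv_path=None, png_path=None) -> np.ndarray:
    """The (n_a, n_b) matrix of per-site minimum E_a, with optional exports.

    CSV rows are (u, v, e_a) with full-precision floats so re-reading
    reproduces the matrix exactly; no-contact sites export as empty
    values.  The raster uses a blue-to-red scale: blue = low E_a = most
    stable, red = high E_a = least stable; no-contact sites are blank.
    """
    matrix = ads_map.energies
    grid = ads_map.grid
    if csv_path is not None:
        rows = []
        for idx, (u, v) in enumerate(grid.sites):
            i, j = divmod(idx, grid.n_b)
            rows.append((u, v, matrix[i, j]))
        pd.DataFrame(rows, columns=["u", "v", "e_a"]).to_csv(
            csv_path, index=False, float_format="%.17g")  # exact round-trip
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(matrix.T, origin="lower", cmap="coolwarm", aspect="auto",
                       extent=(0, 1, 0, 1))
        fig.colorbar(im, ax=ax, label=r"$E_a$ (eV)")
        ax.set_xlabel("u (fractional along a)")
        ax.set_ylabel("v (fractional along b)")
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
    return matrix


def read_heatmap_csv(path) -> np.ndarray:
    """Rebuild the heatmap matrix from its CSV export."""
    df = pd.read_csv(path, float_precision="round_trip")
    n = len(df)
    n_b = df["v"].nunique()
    n_a = n // n_b
    return df["e_a"].to_numpy().reshape(n_a, n_b)


def classify_denticity(pose: Pose) -> int:
    """Number of distinct adsorbate atoms in surface contact (0 = none)."""
    return len({a for _, a in pose.contacts})


def poses_to_table(poses, grid: SiteGrid) -> pd.DataFrame:
    """Flat results table: site coordinates, angles, energies, denticity."""
    rows = []
    for pose in poses:
        if pose is None:
            continue
        u, v = grid.sites[pose.site_index]
        e = pose.energy
        rows.append({
            "site_index": pose.site_index, "u": u, "v": v,
            "conformer": pose.conformer_id,
            "phi": pose.rotation.phi, "theta": pose.rotation.theta,
            "psi": pose.rotation.psi, "n_steps": pose.n_steps,
            "contact": pose.contact,
            "v_coulomb": e.v_coulomb if e else np.nan,
            "v_lj": e.v_lj if e else np.nan,
            "e_a": e.e_a if e else np.nan,
            "denticity": classify_denticity(pose),
        })
    return pd.DataFrame(rows)
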