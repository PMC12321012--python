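"""Point-charge assignment.

Surface atoms get integer formal charges from their most probable
oxidation states, chosen so the formula unit is charge neutral (the
point charges q_s of the Coulomb term).  Adsorbate partial charges
(q_a) come from a sidecar file, an SDF property block, or a registered
external-charge adapter; they are user data, never guessed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .data import DATA_VERSION, OXIDATION_STATES
from .errors import AdapterError, ChargeAssignmentError, ChargeMismatchError
from .structures import Adsorbate, Slab, _read_sidecar_charges

__all__ = [
    "ChargeAssignment",
    "guess_formal_charges",
    "assign_surface_charges",
    "load_partial_charges",
    "register_charge_adapter",
]


@dataclass(frozen=True)
class ChargeAssignment:
    """One formal charge per element, neutral over the formula unit."""

    element_to_charge: dict[str, int]
    provenance: str

    def validate_neutral(self, composition: dict[str, int]) -> None:
        total = sum(self.element_to_charge[e] * n for e, n in composition.items())
        if total != 0:
            raise ChargeAssignmentError(
                f"assignment {self.element_to_charge} not neutral for {composition}"
            )


def guess_formal_charges(composition: dict[str, int]) -> ChargeAssignment:
    """Pick one common oxidation state per element so the formula is neutral.

    Candidate states come from a static table ordered by how common each
    state is.  Among neutral combinations the one whose states rank
    highest in that preference order wins (smallest total preference
    index; ties broken lexicographically over alphabetically sorted
    elements), so the result is deterministic and scale invariant.
    """
    if not composition:
        raise ChargeAssignmentError("empty composition")
    elements = sorted(composition)
    counts = [int(composition[e]) for e in elements]
    if any(c <= 0 for c in counts):
        raise ChargeAssignmentError("composition counts must be positive integers")
    candidates = []
    for e in elements:
        if e not in OXIDATION_STATES:
            raise ChargeAssignmentError(f"element {e!r} not in oxidation-state table")
        candidates.append(OXIDATION_STATES[e])
    best: tuple | None = None
    best_states: tuple[int, ...] | None = None
    for index_combo in itertools.product(*(range(len(c)) for c in candidates)):
        states = tuple(candidates[i][k] for i, k in enumerate(index_combo))
        if sum(n * q for n, q in zip(counts, states)) != 0:
            continue
        key = (sum(index_combo), index_combo)
        if best is None or key < best:
            best, best_states = key, states
    if best_states is None:
        raise ChargeAssignmentError(
            f"no charge-neutral oxidation-state combination for {composition}"
        )
    return ChargeAssignment(
        element_to_charge=dict(zip(elements, best_states)),
        provenance=f"oxidation-state-guess (table {DATA_VERSION})",
    )


def assign_surface_charges(
    slab: Slab, assignment: ChargeAssignment | None = None
) -> Slab:
    """Attach per-atom formal charges to a slab, in place.

    Without an explicit assignment the composition of the slab is reduced
    and :func:`guess_formal_charges` is used.
    """
    if assignment is None:
        composition: dict[str, int] = {}
        for s in slab.symbols:
            composition[s] = composition.get(s, 0) + 1
        assignment = guess_formal_charges(composition)
    slab.formal_charges = np.array(
        [float(assignment.element_to_charge[s]) for s in slab.symbols]
    )
    return slab


# -- adsorbate partial charges -----------------------------------------

ChargeAdapter = Callable[[list[str], np.ndarray, float], np.ndarray]
_ADAPTERS: dict[str, ChargeAdapter] = {}


def register_charge_adapter(name: str, fn: ChargeAdapter) -> None:
    """Register an external partial-charge backend.

    The adapter takes ``(symbols, positions, net_charge)`` and returns one
    charge per atom; e.g. a semi-empirical single-point wrapper.  None is
    bundled — adapters are optional plug-ins.
    """
    _ADAPTERS[name] = fn


def load_partial_charges(
    adsorbate: Adsorbate,
    source,
    net_charge: float | None = None,
) -> Adsorbate:
    """Attach partial charges from a sidecar file, sequence, or adapter.

    ``source`` is a path to a one-float-per-line text file, an explicit
    sequence of charges, or the name of a registered adapter.  The sum of
    charges must match the declared net charge within 0.01 e; adapter
    failures raise :class:`AdapterError` rather than yielding zeros.
    """
    declared = adsorbate.net_charge if net_charge is None else float(net_charge)
    if isinstance(source, str) and source in _ADAPTERS:
        try:
            charges = np.asarray(
                _ADAPTERS[source](adsorbate.symbols, adsorbate.positions, declared),
                dtype=float,
            )
        except Exception as exc:
            raise AdapterError(f"charge adapter {source!r} failed: {exc}") from exc
    elif isinstance(source, (str, Path)):
        charges = _read_sidecar_charges(Path(source))
    else:
        charges = np.asarray(source, dtype=float)
    if len(charges) != len(adsorbate):
        raise ChargeMismatchError(
            f"{len(charges)} charges for {len(adsorbate)}-atom adsorbate"
        )
    return adsorbate.with_charges(charges, net_charge=declared)
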