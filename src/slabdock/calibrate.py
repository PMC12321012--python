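"""Calibration of the Lennard-Jones well depth against reference energies.

The well depth ε is the single tunable parameter of the pairwise score.
Because V_LJ is exactly linear in ε at fixed geometry, a set of poses
scored once at a reference ε can be re-scored at ε/n for any integer
divisor n without recomputing geometry.  The divisor is chosen by
ordinary least squares of the reference binding energies on the
re-scored E_a, maximising the coefficient of determination R².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputFileError, ValidationError

__all__ = [
    "CalibrationSet",
    "CalibrationResult",
    "rescore",
    "fit_divisor",
    "read_calibration_csv",
    "write_calibration_csv",
]

#: Reference well depth (eV) at which calibration sets are scored before
#: the divisor scan.
EPSILON_REF = 0.005

#: Default divisor search range.
DEFAULT_N_RANGE = range(1, 201)


@dataclass
class CalibrationSet:
    """Pose energies at a reference ε paired with reference binding energies.

    entries columns (eV): v_coulomb, v_lj_ref (at epsilon_ref), e_ref.
    """

    v_coulomb: np.ndarray
    v_lj_ref: np.ndarray
    e_ref: np.ndarray
    epsilon_ref: float = EPSILON_REF

    def __post_init__(self) -> None:
        self.v_coulomb = np.asarray(self.v_coulomb, dtype=float)
        self.v_lj_ref = np.asarray(self.v_lj_ref, dtype=float)
        self.e_ref = np.asarray(self.e_ref, dtype=float)
        n = len(self.v_coulomb)
        if not (len(self.v_lj_ref) == len(self.e_ref) == n):
            raise ValidationError("calibration columns have unequal lengths")
        if n < 3:
            raise ValidationError("calibration set needs at least 3 entries")
        if np.ptp(self.v_lj_ref) == 0:
            raise ValidationError("all v_lj_ref identical; divisor scan ill-posed")
        if self.epsilon_ref <= 0:
            raise ValidationError("epsilon_ref must be positive")

    def __len__(self) -> int:
        return len(self.v_coulomb)


@dataclass(frozen=True)
class CalibrationResult:
    """Chosen integer divisor and the regression at that divisor."""

    n: int
    epsilon_eff: float
    slope: float
    intercept: float
    r2: float
    curve: pd.DataFrame  # columns n, slope, intercept, r2

    def __post_init__(self) -> None:
        assert self.epsilon_eff > 0
        assert -1e-12 <= self.r2 <= 1 + 1e-12


def rescore(cal: CalibrationSet, n: int) -> np.ndarray:
    """E_a at ε_ref/n: V_Coulomb + V_LJ(ε_ref)/n, exact by linearity in ε."""
    if n < 1:
        raise ValidationError("divisor n must be >= 1")
    return cal.v_coulomb + cal.v_lj_ref / n


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of y regressed on x; R²=0 when x is degenerate."""
    sxx = float(np.var(x))
    if sxx == 0.0:
        return 0.0, float(np.mean(y)), 0.0
    slope = float(np.cov(x, y, bias=True)[0, 1] / sxx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return slope, intercept, 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return slope, intercept, r2


def fit_divisor(cal: CalibrationSet, n_range=DEFAULT_N_RANGE) -> CalibrationResult:
    """Scan integer divisors of ε_ref and keep the one maximising R².

    For each n, E_ref is regressed on the re-scored E_a by ordinary least
    squares; ties in R² break toward smaller n.  The full (n, R²) curve
    is retained for export.
    """
    n_values = sorted(int(n) for n in n_range)
    if not n_values:
        raise ValidationError("empty divisor range")
    if n_values[0] < 1:
        raise ValidationError("divisors must be >= 1")
    rows = []
    for n in n_values:
        e_a = rescore(cal, n)
        slope, intercept, r2 = _ols(e_a, cal.e_ref)
        rows.append((n, slope, intercept, r2))
    curve = pd.DataFrame(rows, columns=["n", "slope", "intercept", "r2"])
    if np.all(curve["r2"].to_numpy() == 0.0) and np.ptp(cal.e_ref) == 0:
        raise ValidationError("degenerate calibration set: constant reference energies")
    best_idx = int(curve["r2"].to_numpy().argmax())  # first max -> smallest n
    best = curve.iloc[best_idx]
    return CalibrationResult(
        n=int(best["n"]),
        epsilon_eff=cal.epsilon_ref / int(best["n"]),
        slope=float(best["slope"]),
        intercept=float(best["intercept"]),
        r2=float(best["r2"]),
        curve=curve,
    )


def read_calibration_csv(path) -> CalibrationSet:
    """Read a calibration CSV (columns v_coulomb, v_lj_ref, e_ref).

    An optional ``# epsilon_ref = <value>`` header line records the ε the
    LJ column was computed at; absent, the module default applies.
    """
    epsilon_ref = EPSILON_REF
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines += 1
                if "epsilon_ref" in line:
                    epsilon_ref = float(line.split("=", 1)[1])
            else:
                break
    try:
        df = pd.read_csv(path, skiprows=header_lines)
        return CalibrationSet(
            v_coulomb=df["v_coulomb"].to_numpy(),
            v_lj_ref=df["v_lj_ref"].to_numpy(),
            e_ref=df["e_ref"].to_numpy(),
            epsilon_ref=epsilon_ref,
        )
    except (KeyError, ValueError, pd.errors.ParserError) as exc:
        raise InputFileError(f"malformed calibration CSV {path}: {exc}") from exc


def write_calibration_csv(path, cal: CalibrationSet) -> None:
    df = pd.DataFrame(
        {"v_coulomb": cal.v_coulomb, "v_lj_ref": cal.v_lj_ref, "e_ref": cal.e_ref}
    )
    with open(path, "w") as fh:
        fh.write(f"# epsilon_ref = {cal.epsilon_ref}\n")
        df.to_csv(fh, index=False)
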