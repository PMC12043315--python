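"""Mass arithmetic and peak assignment for native MS of lipid-bound oligomers.

Native spectra of ~100 kDa membrane-protein complexes show each charge
state as a series of peaks spaced by ``adduct_mass / z`` — one peak per
bound lipid.  For 16:0 cardiolipin the adduct mass is ~1.35 kDa, so the
series is a characteristic 1.4 kDa mass shift.  This module builds the
theoretical (species, charge, n-adduct) m/z tables and matches observed
peaks to them within a ppm tolerance.

Formula and sequence masses are computed with pyteomics (IUPAC average
weights or principal-isotope monoisotopic masses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError

__all__ = [
    "PROTON_MASS",
    "CDL_FORMULA",
    "CDL_AVERAGE_MASS",
    "SpeciesModel",
    "PeakAssignment",
    "formula_mass",
    "sequence_mass",
    "mz",
    "expected_peak_table",
    "assign_peaks",
]

#: mass of a proton in Da; positive-mode charging is by proton adduction
PROTON_MASS = 1.007276

#: tetrapalmitoyl (16:0) cardiolipin, free acid
CDL_FORMULA = "C73H142O17P2"

MassMode = Literal["average", "monoisotopic"]


def formula_mass(formula: str, mode: MassMode = "average") -> float:
    """Mass in Da of a Hill-notation molecular formula.

    ``average`` sums IUPAC standard atomic weights; ``monoisotopic`` sums
    principal-isotope masses.
    """
    if mode not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass mode: {mode!r}")
    try:
        return float(_ptmass.calculate_mass(formula=formula, average=(mode == "average")))
    except (PyteomicsError, KeyError) as exc:
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc


#: average mass of the default cardiolipin adduct (1.4 kDa at one decimal)
CDL_AVERAGE_MASS = formula_mass(CDL_FORMULA, "average")

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


def sequence_mass(sequence: str, mode: MassMode = "average") -> float:
    """Neutral mass of a protein sequence (residue masses + one water)."""
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - _CANONICAL)
    if bad:
        raise ValueError(f"non-canonical residue letters: {bad}")
    if not seq:
        return formula_mass("H2O", mode)
    return float(_ptmass.calculate_mass(sequence=seq, average=(mode == "average")))


def mz(mass_da: float, z: int) -> float:
    """Positive-ion m/z: (M + z * m_proton) / z."""
    if z <= 0:
        raise ValueError(f"charge must be a positive integer, got {z}")
    return (mass_da + z * PROTON_MASS) / z


@dataclass(frozen=True)
class SpeciesModel:
    """A protein species and the lipid-adduct series it can carry.

    ``base_mass`` is the mass of the bare (apo) species — for an oligomer,
    the whole complex. ``n_max_adducts`` bounds the adduct series; in the
    native spectra this emulates, a maximum of three cardiolipin adducts can
    be assigned unambiguously on a tetramer.
    """

    name: str
    base_mass: float
    charge_states: tuple
    oligomer_order: int = 1
    n_max_adducts: int = 0
    adduct_mass: float = CDL_AVERAGE_MASS

    def __post_init__(self):
        object.__setattr__(self, "charge_states", tuple(int(z) for z in self.charge_states))
        if self.base_mass <= 0:
            raise ValueError("base_mass must be positive")
        if not self.charge_states or any(z < 1 for z in self.charge_states):
            raise ValueError("charge states must be positive integers")
        if self.n_max_adducts < 0 or self.oligomer_order < 1:
            raise ValueError("n_max_adducts must be >= 0 and oligomer_order >= 1")

    def mass_with_adducts(self, n: int) -> float:
        return self.base_mass + n * self.adduct_mass


@dataclass(frozen=True)
class PeakAssignment:
    """One observed peak matched to a theoretical (species, z, n) triple."""

    observed_mz: float
    species: str
    charge: int
    n_adducts: int
    theoretical_mz: float
    error_ppm: float
    ambiguous: bool = False
    peak_index: int | None = None


def expected_peak_table(species: SpeciesModel | Sequence[SpeciesModel]) -> pd.DataFrame:
    """Theoretical m/z for every (species, charge, adduct count), sorted by m/z.

    Adjacent adduct peaks of one charge state are spaced adduct_mass / z.
    """
    if isinstance(species, SpeciesModel):
        species = [species]
    rows = []
    for sp in species:
        for z in sp.charge_states:
            for n in range(sp.n_max_adducts + 1):
                rows.append({
                    "species": sp.name,
                    "charge": z,
                    "n_adducts": n,
                    "mz": mz(sp.mass_with_adducts(n), z),
                })
    table = pd.DataFrame(rows, columns=["species", "charge", "n_adducts", "mz"])
    return table.sort_values("mz", kind="stable", ignore_index=True)


def assign_peaks(observed_mz: Sequence[float],
                 expected: pd.DataFrame,
                 tolerance_ppm: float = 50.0) -> tuple[list[PeakAssignment], list[int]]:
    """Match observed peaks to the nearest theoretical m/z within tolerance.

    Each observed peak receives at most one assignment, resolved by smallest
    relative error; a peak with two or more candidates inside the tolerance
    is flagged ambiguous.  Returns (assignments, indices of unassigned peaks).
    The default 50 ppm stays far below the adduct spacing of a ~1.35 kDa
    lipid at the charge states of a 100 kDa complex (~80 m/z units at 17+).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    theo = expected["mz"].to_numpy(dtype=float)
    assignments: list[PeakAssignment] = []
    unassigned: list[int] = []
    for i, obs in enumerate(observed_mz):
        err_ppm = (obs - theo) / theo * 1e6
        inside = np.flatnonzero(np.abs(err_ppm) <= tolerance_ppm)
        if inside.size == 0:
            unassigned.append(i)
            continue
        best = inside[np.argmin(np.abs(err_ppm[inside]))]
        row = expected.iloc[int(best)]
        assignments.append(PeakAssignment(
            observed_mz=float(obs),
            species=str(row["species"]),
            charge=int(row["charge"]),
            n_adducts=int(row["n_adducts"]),
            theoretical_mz=float(row["mz"]),
            error_ppm=float(err_ppm[best]),
            ambiguous=inside.size > 1,
            peak_index=i,
        ))
    return assignments, unassigned


def kda_shift(mass_da: float) -> float:
    """Mass in kDa rounded to one decimal, half away from zero (for reporting)."""
    import decimal
    return float(decimal.Decimal(mass_da / 1000.0).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))
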