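"""Molecular formulas, monoisotopic [M+H]+ m/z values and ppm mass windows.

Targeted quantification needs exact theoretical m/z values for the light
(all-``12C``) and heavy (uniformly ``13C``-labelled) form of each analyte, plus a
narrow relative tolerance window (default +/- 10 ppm) for chromatogram
extraction. Atomic masses are hardcoded NIST monoisotopic values; the proton
mass (not the hydrogen atom mass) is used for the protonated adduct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "MASS_13C",
    "PROTON_MASS",
    "FormulaError",
    "MolecularSpecies",
    "MzWindow",
    "parse_formula",
    "theoretical_mz",
    "ppm_window",
    "load_targets",
]

#: Monoisotopic atomic masses (Da), NIST, truncated to 6 decimals.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.007825,
    "C": 12.0,
    "N": 14.003074,
    "O": 15.994915,
    "P": 30.973762,
    "S": 31.972071,
    "Na": 22.989769,
    "K": 38.963706,
    "Cl": 34.968853,
    "F": 18.998403,
}

MASS_13C = 13.003355
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formula input."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula like ``"C5H14N4"`` into element counts.

    An omitted count means 1. Unknown element symbols and empty input raise
    :class:`FormulaError`.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {text!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise FormulaError(f"unparseable formula {text!r} at position {pos}")
    return counts


@dataclass(frozen=True)
class MolecularSpecies:
    """An analyte or internal-standard species, possibly uniformly 13C-labelled.

    Parameters
    ----------
    name:
        Display name (e.g. ``"agmatine"`` or ``"[U-13C]agmatine"``).
    formula:
        Element -> count map of the *unlabelled* molecule.
    n_labeled_13C:
        Number of carbons replaced by 13C (0 for the light form; equal to the
        carbon count for a uniformly labelled standard).
    charge:
        Positive integer charge; only +1 is supported for now.
    adduct:
        Only the protonated adduct ``"[M+H]+"`` is supported.
    """

    name: str
    formula: dict[str, int] = field(hash=False)
    n_labeled_13C: int = 0
    charge: int = 1
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        for element, count in self.formula.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol {element!r}")
            if count < 0:
                raise FormulaError(f"negative count for {element!r}")
        if self.n_labeled_13C < 0:
            raise FormulaError("n_labeled_13C must be >= 0")
        if self.n_labeled_13C > self.formula.get("C", 0):
            raise FormulaError(
                f"{self.name}: {self.n_labeled_13C} 13C labels exceed "
                f"{self.formula.get('C', 0)} carbons"
            )
        if self.charge < 1:
            raise FormulaError("charge must be >= 1")
        if self.adduct != "[M+H]+":
            raise FormulaError(f"unsupported adduct {self.adduct!r}")

    @classmethod
    def from_formula(
        cls, name: str, formula: str, n_labeled_13C: int = 0
    ) -> "MolecularSpecies":
        return cls(name=name, formula=parse_formula(formula), n_labeled_13C=n_labeled_13C)


def theoretical_mz(species: MolecularSpecies) -> float:
    """Theoretical monoisotopic m/z of the protonated species, in Th.

    The neutral monoisotopic mass is the sum of atomic masses with
    ``n_labeled_13C`` carbons at the 13C mass; the proton mass is added and the
    total divided by the charge.
    """
    mass = 0.0
    for element, count in species.formula.items():
        mass += count * MONOISOTOPIC_MASS[element]
    mass += species.n_labeled_13C * (MASS_13C - MONOISOTOPIC_MASS["C"])
    return (mass + species.charge * PROTON_MASS) / species.charge


@dataclass(frozen=True)
class MzWindow:
    """A symmetric relative (ppm) mass window around a target m/z."""

    center: float
    tolerance_ppm: float
    lo: float
    hi: float

    def contains(self, mz: float) -> bool:
        return self.lo <= mz <= self.hi


def ppm_window(center: float, tolerance_ppm: float) -> MzWindow:
    """Build the closed interval ``center * (1 -/+ tolerance_ppm * 1e-6)``."""
    if center <= 0:
        raise ValueError(f"m/z center must be positive, got {center}")
    if tolerance_ppm <= 0:
        raise ValueError(f"tolerance_ppm must be positive, got {tolerance_ppm}")
    rel = tolerance_ppm * 1e-6
    return MzWindow(
        center=center,
        tolerance_ppm=tolerance_ppm,
        lo=center * (1.0 - rel),
        hi=center * (1.0 + rel),
    )


_TARGET_COLUMNS = ["name", "formula", "n_labeled_13C", "role", "pair_id", "is_concentration_nM"]


def load_targets(path: str | Path) -> pd.DataFrame:
    """Load a target table (CSV or YAML) of analyte / internal-standard pairs.

    Expected columns: ``name, formula, n_labeled_13C, role, pair_id,
    is_concentration_nM`` where ``role`` is ``analyte`` or ``internal_standard``
    and ``pair_id`` links the light analyte with its labelled standard. A
    ``mz`` column with the theoretical [M+H]+ value is appended.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            records = yaml.safe_load(fh)
        table = pd.DataFrame(records)
    else:
        table = pd.read_csv(path)
    missing = set(_TARGET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"target table {path} missing columns: {sorted(missing)}")
    bad_roles = set(table["role"]) - {"analyte", "internal_standard"}
    if bad_roles:
        raise ValueError(f"unknown roles in target table: {sorted(bad_roles)}")
    table["mz"] = [
        theoretical_mz(
            MolecularSpecies.from_formula(row["name"], row["formula"], int(row["n_labeled_13C"]))
        )
        for _, row in table.iterrows()
    ]
    return table
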