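"""Physicochemical peptide descriptors.

Elemental formula, average/monoisotopic mass, net charge (a simple counting
mode and a Henderson-Hasselbalch pH-dependent mode), isoelectric point,
GRAVY hydrophobicity and the helical hydrophobic moment (amphipathicity).

Two charge conventions are provided deliberately. The *integer counting*
mode scores K and R as +1 and D and E as -1, ignoring histidine and the
termini: this is the convention peptide-synthesis vendors quote ("+5,
cationic") and the mode used throughout the mining pipeline. The
Henderson-Hasselbalch mode is the physically graded alternative and drives
the isoelectric-point solver.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from . import _tables
from .seqio import validate_peptide

__all__ = [
    "ElementalFormula",
    "PropertyReport",
    "elemental_formula",
    "average_mass",
    "net_charge_integer",
    "net_charge_hh",
    "isoelectric_point",
    "gravy",
    "hydrophobic_moment",
    "property_report",
]


@dataclass(frozen=True)
class ElementalFormula:
    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(self.C + other.C, self.H + other.H,
                                self.N + other.N, self.O + other.O, self.S + other.S)

    def __str__(self) -> str:
        # Hill-style formula string; unit counts are left implicit (C2H5NO2)
        parts = []
        for el in ("C", "H", "N", "O", "S"):
            n = getattr(self, el)
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)


# IUPAC 2021 standard atomic weights, for formula/mass cross-checks
ATOMIC_AVERAGE_MASS = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}


def elemental_formula(peptide: str) -> ElementalFormula:
    """Elemental composition of the free peptide (residue sum plus one water)."""
    pep = validate_peptide(peptide)
    tables = _tables.residue_formulas()
    tot = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}  # start from H2O
    for aa in pep:
        for el, n in tables[aa].items():
            tot[el] += n
    return ElementalFormula(**tot)


def average_mass(peptide: str, kind: str = "average") -> float:
    """Free-peptide mass in Da (``average`` by default, ``monoisotopic`` optional)."""
    pep = validate_peptide(peptide)
    masses = _tables.residue_masses(kind)
    water = _tables.WATER_AVERAGE if kind == "average" else _tables.WATER_MONO
    return sum(masses[aa] for aa in pep) + water


def net_charge_integer(peptide: str) -> int:
    """Formal side-chain charge: (#K + #R) - (#D + #E); H and termini excluded."""
    pep = validate_peptide(peptide)
    return pep.count("K") + pep.count("R") - pep.count("D") - pep.count("E")


def net_charge_hh(peptide: str, pH: float, pka_set: str = "emboss",
                  include_termini: bool = True) -> float:
    """Henderson-Hasselbalch net charge at a given pH.

    Basic groups (K, R, H and the N-terminus) contribute
    ``+1/(1+10^(pH-pKa))``; acidic groups (D, E, C, Y and the C-terminus)
    contribute ``-1/(1+10^(pKa-pH))``.
    """
    pep = validate_peptide(peptide)
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    pkas = _tables.load_pka_set(pka_set)
    charge = 0.0
    groups: list[str] = [aa for aa in pep if aa in ("D", "E", "C", "Y", "H", "K", "R")]
    if include_termini:
        groups += ["nterm", "cterm"]
    for g in groups:
        pka, kind = pkas[g]
        if kind == "basic":
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(peptide: str, pka_set: str = "emboss",
                      include_termini: bool = True, tol: float = 1e-3) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero (bisection).

    Raises ``ValueError`` when the peptide has no ionizable groups (e.g.
    "AAA" with ``include_termini=False``).
    """
    pep = validate_peptide(peptide)
    has_groups = include_termini or any(aa in "DECYHKR" for aa in pep)
    if not has_groups:
        raise ValueError("peptide has no ionizable groups; pI undefined")
    f = lambda ph: net_charge_hh(pep, ph, pka_set, include_termini)
    c0, c14 = f(0.0), f(14.0)
    if c0 <= 0:
        return 0.0 if abs(c0) < tol else _raise_no_root(c0, c14)
    if c14 >= 0:
        return 14.0 if abs(c14) < tol else _raise_no_root(c0, c14)
    pI = brentq(f, 0.0, 14.0, xtol=1e-6)
    assert abs(f(pI)) < tol
    return float(pI)


def _raise_no_root(c0: float, c14: float) -> float:
    raise ValueError(f"net charge does not change sign on [0,14] (f(0)={c0:.3g}, f(14)={c14:.3g})")


def gravy(peptide: str, scale: str = "kyte_doolittle") -> float:
    """Grand average of hydropathy: mean per-residue scale value."""
    pep = validate_peptide(peptide)
    s = _tables.load_scale(scale)
    return float(np.mean([s[aa] for aa in pep]))


def hydrophobic_moment(peptide: str, scale: str = "eisenberg",
                       delta_deg: float = 100.0) -> float:
    """Helical hydrophobic moment |muH|.

    Magnitude of the vector sum of per-residue hydrophobicities placed at
    successive angles of ``delta_deg`` (100 deg/residue for an alpha helix;
    use 160 for a beta strand).
    """
    pep = validate_peptide(peptide)
    s = _tables.load_scale(scale)
    vals = np.array([s[aa] for aa in pep])
    angles = np.deg2rad(delta_deg) * np.arange(len(pep))
    return float(math.hypot(float(np.sum(vals * np.cos(angles))),
                            float(np.sum(vals * np.sin(angles)))))


@dataclass(frozen=True)
class PropertyReport:
    """Descriptor panel for one peptide; pure data, serializable."""

    peptide: str
    length: int
    formula: str
    average_mass: float
    net_charge_integer: int
    net_charge_at_pH7: float
    pI: float
    gravy: float
    hydrophobic_moment: float
    moment_per_residue: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_text(self) -> str:
        """Flat key-value serialization (one ``key\\tvalue`` pair per line)."""
        out = []
        for k, v in self.to_dict().items():
            out.append(f"{k}\t{v:.6f}" if isinstance(v, float) else f"{k}\t{v}")
        return "\n".join(out) + "\n"

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def property_report(peptide: str, gravy_scale: str = "kyte_doolittle",
                    moment_scale: str = "eisenberg", pka_set: str = "emboss",
                    delta_deg: float = 100.0) -> PropertyReport:
    """Compute the full descriptor panel for one peptide."""
    pep = validate_peptide(peptide)
    mu = hydrophobic_moment(pep, moment_scale, delta_deg)
    return PropertyReport(
        peptide=pep,
        length=len(pep),
        formula=str(elemental_formula(pep)),
        average_mass=average_mass(pep),
        net_charge_integer=net_charge_integer(pep),
        net_charge_at_pH7=net_charge_hh(pep, 7.0, pka_set),
        pI=isoelectric_point(pep, pka_set),
        gravy=gravy(pep, gravy_scale),
        hydrophobic_moment=mu,
        moment_per_residue=mu / len(pep),
    )
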