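"""Peptide mass and m/z arithmetic for glycation screening.

Monoisotopic masses are computed by residue summation over a hard-coded
constants table (IUPAC/Unimod values); nominal (integer) masses use integer
atomic mass numbers so that, e.g., the glycation adduct C6H10O5 is exactly
162 Da by construction. Only protonation is modelled for charging.
"""

from __future__ import annotations

from dataclasses import dataclass

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Monoisotopic residue masses, Da (Unimod/IUPAC 2021 atomic masses).
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

#: Nominal (integer) residue masses, Da.
NOMINAL_RESIDUE_MASS: dict[str, int] = {
    "G": 57, "A": 71, "S": 87, "P": 97, "V": 99, "T": 101, "C": 103,
    "L": 113, "I": 113, "N": 114, "D": 115, "Q": 128, "K": 128,
    "E": 129, "M": 131, "H": 137, "F": 147, "R": 156, "Y": 163, "W": 186,
}

WATER_MONOISOTOPIC = 18.010565
WATER_NOMINAL = 18
PROTON_MASS = 1.007276

#: Monoisotopic masses of the elements appearing in adduct compositions.
MONOISOTOPIC_ATOM_MASS: dict[str, float] = {
    "C": 12.0, "H": 1.00782503, "N": 14.00307401, "O": 15.99491462,
    "S": 31.97207117,
}
#: Integer mass numbers of the most abundant isotopes.
NOMINAL_ATOM_MASS: dict[str, int] = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

#: Glycation (Amadori ketoamine) adduct composition: one anhydroglucose unit.
GLYCATION_COMPOSITION: dict[str, int] = {"C": 6, "H": 10, "O": 5}


def composition_monoisotopic(composition: dict[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, Da."""
    return sum(MONOISOTOPIC_ATOM_MASS[el] * n for el, n in composition.items())


def composition_nominal(composition: dict[str, int]) -> int:
    """Nominal (integer) mass of an elemental composition, Da."""
    return sum(NOMINAL_ATOM_MASS[el] * n for el, n in composition.items())


@dataclass(frozen=True)
class ModificationSpec:
    """A covalent modification with its mass deltas and admissible targets.

    ``targets`` holds residue letters plus the terminus designator
    ``"protein-n-terminus"`` where applicable. ``fixed`` modifications apply
    to every target residue; variable ones are enumerated per site.
    """

    name: str
    delta_monoisotopic: float
    delta_nominal: int
    targets: frozenset[str]
    fixed: bool = False


#: Amadori glycation: +162 Da nominal, on lysine side chains or the protein
#: N-terminal amine. Variable modification.
GLYCATION = ModificationSpec(
    name="glycation",
    delta_monoisotopic=round(composition_monoisotopic(GLYCATION_COMPOSITION), 5),
    delta_nominal=composition_nominal(GLYCATION_COMPOSITION),
    targets=frozenset({"K", "protein-n-terminus"}),
    fixed=False,
)

#: Iodoacetamide alkylation of cysteine, applied as a fixed modification.
CARBAMIDOMETHYL = ModificationSpec(
    name="carbamidomethyl",
    delta_monoisotopic=57.02146,
    delta_nominal=57,
    targets=frozenset({"C"}),
    fixed=True,
)


@dataclass(frozen=True)
class MassResult:
    monoisotopic_mass: float
    nominal_mass: int
    composition_note: str = ""

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("mass must be positive")


def peptide_mass(sequence: str, mods: list[ModificationSpec] | None = None) -> MassResult:
    """Monoisotopic and nominal mass of a peptide with applied modifications.

    Each entry in ``mods`` is one applied modification event; pass the same
    spec twice for a doubly modified peptide. A modification whose targets
    are absent from the sequence (and which is not terminal) raises
    ``ValueError``.
    """
    mods = mods or []
    bad = sorted(set(sequence) - CANONICAL_RESIDUES)
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad} in sequence")
    if not sequence:
        raise ValueError("empty sequence")
    mono = sum(MONOISOTOPIC_RESIDUE_MASS[r] for r in sequence) + WATER_MONOISOTOPIC
    nominal = sum(NOMINAL_RESIDUE_MASS[r] for r in sequence) + WATER_NOMINAL
    notes = [f"{len(sequence)} residues + H2O"]
    for mod in mods:
        residue_targets = mod.targets & CANONICAL_RESIDUES
        if residue_targets and not (residue_targets & set(sequence)):
            if "protein-n-terminus" not in mod.targets:
                raise ValueError(
                    f"modification {mod.name!r} targets {sorted(residue_targets)} "
                    f"absent from sequence"
                )
        mono += mod.delta_monoisotopic
        nominal += mod.delta_nominal
        notes.append(f"+{mod.name}")
    return MassResult(mono, nominal, "; ".join(notes))


def apply_fixed_modifications(
    sequence: str, specs: tuple[ModificationSpec, ...] | list = (CARBAMIDOMETHYL,)
) -> list[ModificationSpec]:
    """Expand fixed modifications into one applied event per target residue."""
    applied: list[ModificationSpec] = []
    for spec in specs:
        if not spec.fixed:
            continue
        n = sum(sequence.count(r) for r in spec.targets & CANONICAL_RESIDUES)
        applied.extend([spec] * n)
    return applied


def mz(mass: float, charge: int) -> float:
    """m/z of a protonated ion: (M + z * m_proton) / z."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def ppm_window(center_mz: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric ±tol ppm window about a centre m/z."""
    if center_mz <= 0:
        raise ValueError("centre m/z must be positive")
    if tol_ppm <= 0:
        raise ValueError("ppm tolerance must be positive")
    half = center_mz * tol_ppm / 1e6
    return (center_mz - half, center_mz + half)


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6
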