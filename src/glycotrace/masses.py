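"""Monoisotopic mass arithmetic for peptides, modifications, glycans and ions.

All m/z bookkeeping in the pipeline flows through this module: residue and
monosaccharide mass tables, modification deltas, charged-ion m/z conversion,
and ppm/mmu tolerance matching.  Masses are monoisotopic throughout; average
masses and isotope envelopes are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Mapping, Sequence

WATER = 18.010565
"""Monoisotopic mass of H2O (Da), added once per peptide chain."""

PROTON = 1.007276
"""Monoisotopic mass of a proton (Da), added once per charge."""

#: Monoisotopic residue masses of the four monosaccharide classes (Da).
MONOSACCHARIDE_MASSES: Mapping[str, float] = MappingProxyType(
    {
        "HexNAc": 203.07937,
        "Hex": 162.05282,
        "Fuc": 146.05791,
        "NeuAc": 291.09542,
    }
)


def _load_residue_masses() -> Mapping[str, float]:
    text = (
        resources.files("glycotrace.data").joinpath("residue_masses.tsv").read_text()
    )
    table: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        letter, mass = line.split("\t")
        table[letter] = float(mass)
    return MappingProxyType(table)


#: Monoisotopic residue (chain) masses of the 20 canonical amino acids (Da).
RESIDUE_MASSES: Mapping[str, float] = _load_residue_masses()

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed-mass post-translational or chemical modification.

    The annotation convention used throughout the pipeline writes a modified
    residue as the lowercase form of its one-letter code (``n`` = deamidated
    Asn, ``c`` = carbamidomethyl Cys, ...).
    """

    name: str
    targets: frozenset[str]
    delta: float

    def __post_init__(self) -> None:
        if not self.delta == self.delta or self.delta in (float("inf"), float("-inf")):
            raise ValueError(f"modification delta must be finite, got {self.delta}")

    def allows(self, residue: str) -> bool:
        return residue in self.targets


# Deamidation is defined from the residue table itself (D − N) so the
# pipeline's N→D bookkeeping is exactly self-consistent.
DEAMIDATION_DELTA = RESIDUE_MASSES["D"] - RESIDUE_MASSES["N"]

CARBAMIDOMETHYL = ModificationSpec("carbamidomethyl", frozenset("C"), 57.02146372)
DEAMIDATION = ModificationSpec("deamidation", frozenset("NQ"), DEAMIDATION_DELTA)
OXIDATION = ModificationSpec("oxidation", frozenset("M"), 15.99491462)

BUILTIN_MODIFICATIONS: Mapping[str, ModificationSpec] = MappingProxyType(
    {m.name: m for m in (CARBAMIDOMETHYL, DEAMIDATION, OXIDATION)}
)

_COMPOSITION_RE = re.compile(r"(HexNAc|Hex|Fuc|NeuAc)(\d*)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Integer monosaccharide counts of an N-glycan (topology-unaware)."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_fuc: int = 0
    n_neuac: int = 0

    def __post_init__(self) -> None:
        for field, count in self.as_dict().items():
            if count < 0:
                raise ValueError(f"negative monosaccharide count: {field}={count}")

    def as_dict(self) -> dict[str, int]:
        return {
            "HexNAc": self.n_hexnac,
            "Hex": self.n_hex,
            "Fuc": self.n_fuc,
            "NeuAc": self.n_neuac,
        }

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_hexnac, self.n_hex, self.n_fuc, self.n_neuac)

    @property
    def mass(self) -> float:
        return sum(
            count * MONOSACCHARIDE_MASSES[name]
            for name, count in self.as_dict().items()
        )

    def contains(self, other: "GlycanComposition") -> bool:
        """True if ``other`` is a componentwise sub-composition of self."""
        return all(o <= s for o, s in zip(other.as_tuple(), self.as_tuple()))

    def __str__(self) -> str:
        parts = []
        for name, count in self.as_dict().items():
            if count:
                parts.append(f"{name}{count}")
        return "".join(parts) or "Empty"

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse e.g. ``"HexNAc5Hex3Fuc1"`` into a composition."""
        counts = {"HexNAc": 0, "Hex": 0, "Fuc": 0, "NeuAc": 0}
        pos = 0
        for match in _COMPOSITION_RE.finditer(text):
            if match.start() != pos:
                raise ValueError(f"unparseable glycan composition: {text!r}")
            counts[match.group(1)] += int(match.group(2) or 1)
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"unparseable glycan composition: {text!r}")
        return cls(counts["HexNAc"], counts["Hex"], counts["Fuc"], counts["NeuAc"])


@dataclass(frozen=True)
class IonSpec:
    """A charged ion: neutral mass, positive charge, and derived m/z."""

    neutral_mass: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")

    @property
    def mz(self) -> float:
        return mz(self.neutral_mass, self.charge)


def peptide_mass(
    sequence: str,
    mods: Sequence[tuple[int, ModificationSpec]] = (),
) -> float:
    """Neutral monoisotopic mass of a peptide with positioned modifications.

    Parameters
    ----------
    sequence:
        Uppercase canonical residue string.
    mods:
        ``(position, spec)`` pairs; positions are 1-based within the peptide
        and must fall on a residue the modification targets.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    total = WATER
    for letter in sequence:
        try:
            total += RESIDUE_MASSES[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r} in {sequence!r}") from None
    for position, spec in mods:
        if not 1 <= position <= len(sequence):
            raise ValueError(
                f"modification position {position} outside peptide of length {len(sequence)}"
            )
        residue = sequence[position - 1]
        if not spec.allows(residue):
            raise ValueError(
                f"{spec.name} not allowed on residue {residue!r} at position {position}"
            )
        total += spec.delta
    return total


def glycan_mass(composition: GlycanComposition) -> float:
    """Neutral monoisotopic mass of a glycan composition (0 for empty)."""
    return composition.mass


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of ``[M + zH]^z+``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(observed_mz: float, charge: int) -> float:
    """Inverse of :func:`mz`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return observed_mz * charge - charge * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error in parts per million."""
    return (observed - theoretical) / theoretical * 1e6


def mmu_error(observed: float, theoretical: float) -> float:
    """Signed absolute error in milli-mass-units (mDa)."""
    return (observed - theoretical) * 1e3


def within_tolerance(
    observed: float,
    theoretical: float,
    tol: float,
    unit: str = "ppm",
) -> tuple[bool, float]:
    """Tolerance match with a signed error, boundary inclusive.

    Returns ``(matched, error)`` where the error is in the requested unit
    (ppm or mmu) with the sign convention observed − theoretical.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("observed and theoretical m/z must be positive")
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    if unit == "ppm":
        error = ppm_error(observed, theoretical)
    elif unit == "mmu":
        error = mmu_error(observed, theoretical)
    else:
        raise ValueError(f"unknown tolerance unit {unit!r} (expected 'ppm' or 'mmu')")
    return abs(error) <= tol, error
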