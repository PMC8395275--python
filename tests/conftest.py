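"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings as hypothesis_settings

from glycotrace.digest import ProteinRecord

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")
from glycotrace.io import load_table1

# ---------------------------------------------------------------------------
# Independent elemental-composition mass oracle.
#
# Built only from atomic monoisotopic masses and residue elemental formulas:
# masses accumulate element by element, a completely different path from the
# packaged residue-mass table.  Standard NIST atomic masses.
# ---------------------------------------------------------------------------

ATOM = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048, "O": 15.9949146196, "S": 31.97207100}

#: residue formulas as (C, H, N, O, S) counts
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

#: modification element deltas as (C, H, N, O, S)
MOD_FORMULA = {
    "carbamidomethyl": (2, 3, 1, 1, 0),
    "deamidation": (0, -1, -1, 1, 0),
    "oxidation": (0, 0, 0, 1, 0),
}


def elemental_peptide_mass(sequence: str, mod_names: list[tuple[int, str]] = ()) -> float:
    """Oracle: accumulate element counts, then multiply by atomic masses."""
    counts = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}  # start from water
    for letter in sequence:
        c, h, n, o, s = RESIDUE_FORMULA[letter]
        counts["C"] += c
        counts["H"] += h
        counts["N"] += n
        counts["O"] += o
        counts["S"] += s
    for _, name in mod_names:
        c, h, n, o, s = MOD_FORMULA[name]
        counts["C"] += c
        counts["H"] += h
        counts["N"] += n
        counts["O"] += o
        counts["S"] += s
    return sum(ATOM[element] * count for element, count in counts.items())


def random_protein(rng: random.Random, length: int, accession: str = "P1") -> ProteinRecord:
    seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
    return ProteinRecord(accession=accession, name=accession, sequence=seq)


@pytest.fixture(scope="session")
def table1_records():
    return load_table1()
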