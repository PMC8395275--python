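"""In-silico tryptic digestion and N-glycosylation sequon detection.

The sequon rule is Asn-Xaa-Ser/Thr with Xaa != Pro.  Because tryptic
peptides can end before the residue that completes a sequon, validity is
resolved against the full protein sequence whenever the protein is known;
peptide-only mode marks such boundary asparagines "unresolved".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .masses import CANONICAL_RESIDUES


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession}: empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.accession}: non-canonical residue(s) {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideSpan:
    """A peptide located on a protein; coordinates are 1-based inclusive."""

    accession: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("span end before start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("span length does not match sequence")


class SequonValidity(str, Enum):
    VALID = "valid"
    INVALID = "invalid"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class SequonSite:
    accession: str
    asn_position: int  # 1-based position of the Asn in the protein
    triplet: str
    valid: bool


def _is_sequon(triplet: str) -> bool:
    return (
        len(triplet) == 3
        and triplet[0] == "N"
        and triplet[1] != "P"
        and triplet[2] in "ST"
    )


def tryptic_digest(protein: ProteinRecord, max_missed: int = 1) -> list[PeptideSpan]:
    """All tryptic peptides with 0..max_missed internal missed cleavages.

    Trypsin cleaves C-terminal to K or R, except when the next residue is P.
    At ``max_missed=0`` the returned spans tile the protein.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    # cut points after each cleavable K/R (0-based index of the cut)
    cuts = [0]
    for i, letter in enumerate(seq[:-1]):
        if letter in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    spans: list[PeptideSpan] = []
    for i in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            spans.append(
                PeptideSpan(
                    accession=protein.accession,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=missed,
                )
            )
    return spans


def find_sequons(protein: ProteinRecord) -> list[SequonSite]:
    """One :class:`SequonSite` per Asn in the protein, in position order."""
    sites = []
    seq = protein.sequence
    for i, letter in enumerate(seq):
        if letter != "N":
            continue
        triplet = seq[i : i + 3]
        sites.append(
            SequonSite(
                accession=protein.accession,
                asn_position=i + 1,
                triplet=triplet,
                valid=_is_sequon(triplet),
            )
        )
    return sites


def resolve_boundary_sequon(
    peptide: PeptideSpan, protein: ProteinRecord
) -> dict[int, SequonValidity]:
    """Sequon validity for every Asn in a peptide, using protein context.

    Keys are 1-based positions within the peptide.  An Asn within two
    residues of the protein C-terminus with no completing Ser/Thr is invalid.
    """
    if protein.sequence[peptide.start - 1 : peptide.end] != peptide.sequence:
        raise ValueError(
            f"peptide {peptide.sequence!r} does not match protein "
            f"{protein.accession} at {peptide.start}-{peptide.end}"
        )
    out: dict[int, SequonValidity] = {}
    for k, letter in enumerate(peptide.sequence):
        if letter != "N":
            continue
        prot_idx = peptide.start - 1 + k  # 0-based index in protein
        triplet = protein.sequence[prot_idx : prot_idx + 3]
        out[k + 1] = SequonValidity.VALID if _is_sequon(triplet) else SequonValidity.INVALID
    return out


def peptide_only_sequons(sequence: str) -> dict[int, SequonValidity]:
    """Sequon validity from the peptide string alone.

    Asparagines whose sequon window runs past the peptide C-terminus cannot
    be judged and come back ``UNRESOLVED``.
    """
    out: dict[int, SequonValidity] = {}
    for k, letter in enumerate(sequence):
        if letter != "N":
            continue
        triplet = sequence[k : k + 3]
        if len(triplet) == 3:
            out[k + 1] = (
                SequonValidity.VALID if _is_sequon(triplet) else SequonValidity.INVALID
            )
        elif len(triplet) == 2 and triplet[1] == "P":
            # X = P invalidates regardless of what follows the peptide
            out[k + 1] = SequonValidity.INVALID
        else:
            out[k + 1] = SequonValidity.UNRESOLVED
    return out
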