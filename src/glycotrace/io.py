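"""File formats: peptide tables, FASTA proteomes, and spectra.

Peptide tables are TSV with the annotated-peptide dialect in the
``peptide`` column; spectra travel as JSON-lines (one spectrum per line)
with MGF export for MS2.  FASTA goes through Biopython; MGF through
pyteomics.  All readers/writers round-trip losslessly.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as pyteomics_mgf

from .digest import ProteinRecord
from .sites import AnnotatedPeptide, parse_annotated_peptide
from .spectra import Peak, Spectrum

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_REQUIRED_COLUMNS = ("peptide", "protein_name", "ratio")


def read_peptide_table(path: PathLike) -> list[AnnotatedPeptide]:
    """Read an identified-peptide TSV into annotated records.

    Required columns: ``peptide``, ``protein_name``, ``ratio`` (numeric or
    the literals "WT only"/"KO only").  Optional columns ``intensity_wt``
    and ``intensity_ko`` carry per-condition intensities.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"ratio": str})
    if frame.empty:
        raise ValueError(f"{path}: empty peptide table")
    for column in _REQUIRED_COLUMNS:
        if column not in frame.columns:
            raise ValueError(f"{path}: missing required column {column!r}")
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                parse_annotated_peptide(
                    row.peptide,
                    protein_name=row.protein_name,
                    intensity_wt=_optional_float(getattr(row, "intensity_wt", None)),
                    intensity_ko=_optional_float(getattr(row, "intensity_ko", None)),
                    ratio_text=None if pd.isna(row.ratio) else str(row.ratio),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_number}: {exc}") from exc
    logger.info("read %d peptide records from %s", len(records), path)
    return records


def _optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def write_peptide_table(records: Sequence[AnnotatedPeptide], path: PathLike) -> None:
    frame = pd.DataFrame(
        {
            "peptide": [r.raw for r in records],
            "protein_name": [r.protein_name for r in records],
            "ratio": [r.ratio_text for r in records],
            "intensity_wt": [r.intensity_wt for r in records],
            "intensity_ko": [r.intensity_ko for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def load_table1() -> list[AnnotatedPeptide]:
    """The packaged 32-row identified-peptide fixture."""
    with resources.as_file(
        resources.files("glycotrace.data").joinpath("table1.tsv")
    ) as path:
        return read_peptide_table(path)


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """FASTA proteome; duplicate accessions are rejected."""
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate accession {entry.id!r}")
        seen.add(entry.id)
        description = entry.description
        name = description[len(entry.id) :].strip() or entry.id
        records.append(
            ProteinRecord(accession=entry.id, name=name, sequence=str(entry.seq))
        )
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path: PathLike) -> None:
    entries = [
        SeqRecord(Seq(p.sequence), id=p.accession, description=p.name)
        for p in proteins
    ]
    SeqIO.write(entries, str(path), "fasta")


def _spectrum_to_dict(spectrum: Spectrum) -> dict:
    record = {
        "ms_level": spectrum.ms_level,
        "rt": spectrum.retention_time,
        "peaks": [[p.mz, p.intensity] for p in spectrum.peaks],
    }
    if spectrum.ms_level == 2:
        record["precursor"] = {
            "mz": spectrum.precursor_mz,
            "charge": spectrum.precursor_charge,
        }
    return record


def _spectrum_from_dict(record: dict) -> Spectrum:
    peaks = [Peak(mz=m, intensity=i) for m, i in record["peaks"]]
    mzs = [p.mz for p in peaks]
    if mzs != sorted(mzs):
        logger.warning("unsorted peak list at rt %.3f; sorting", record["rt"])
        peaks = sorted(peaks, key=lambda p: p.mz)
    precursor = record.get("precursor") or {}
    return Spectrum(
        ms_level=record["ms_level"],
        retention_time=record["rt"],
        peaks=tuple(peaks),
        precursor_mz=precursor.get("mz"),
        precursor_charge=precursor.get("charge"),
    )


def write_spectra(spectra: Sequence[Spectrum], path: PathLike) -> None:
    """JSON-lines: one spectrum object per line."""
    with open(path, "w") as handle:
        for spectrum in spectra:
            handle.write(json.dumps(_spectrum_to_dict(spectrum)) + "\n")


def read_spectra(path: PathLike) -> list[Spectrum]:
    """Read JSON-lines spectra, returned sorted by retention time."""
    spectra = []
    with open(path) as handle:
        for line in handle:
            if line.strip():
                spectra.append(_spectrum_from_dict(json.loads(line)))
    return sorted(spectra, key=lambda s: s.retention_time)


def export_mgf(spectra: Sequence[Spectrum], path: PathLike) -> None:
    """Export MS2 spectra to MGF (BEGIN IONS / PEPMASS / CHARGE blocks)."""
    entries = []
    for index, spectrum in enumerate(spectra):
        if spectrum.ms_level != 2:
            continue
        entries.append(
            {
                "m/z array": [p.mz for p in spectrum.peaks],
                "intensity array": [p.intensity for p in spectrum.peaks],
                "params": {
                    "title": f"spectrum_{index}",
                    "pepmass": spectrum.precursor_mz,
                    "charge": f"{spectrum.precursor_charge}+",
                    "rtinseconds": spectrum.retention_time * 60.0,
                },
            }
        )
    pyteomics_mgf.write(entries, output=str(path), file_mode="w")
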