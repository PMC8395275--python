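"""Glycopeptide spectral verification.

Given a candidate peptide and glycan composition, this module computes the
theoretical precursor m/z across charge states, extracts ion chromatograms
from an MS1 run, averages spectra over a retention-time window, enumerates
the Y-ion ladder (peptide + glycan remnant) and oxonium ions, and annotates
an MS2 spectrum against those templates.  Fragment enumeration is
composition-based: glycan topology is not mass-resolvable, so every
componentwise sub-composition of the parent glycan is a Y-ion candidate.
Peaks are monoisotopic; no isotope envelopes or deconvolution.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .masses import (
    PROTON,
    GlycanComposition,
    IonSpec,
    MONOSACCHARIDE_MASSES,
    mmu_error,
    mz,
    ppm_error,
)

DEFAULT_CHARGES = frozenset({2, 3, 4, 5})


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """A peak list at one retention time; MS2 spectra carry their precursor."""

    ms_level: int
    retention_time: float  # minutes
    peaks: tuple[Peak, ...]
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            raise ValueError("peaks must be sorted ascending by m/z")

    @staticmethod
    def sorted_peaks(peaks: Iterable[Peak]) -> tuple[Peak, ...]:
        return tuple(sorted(peaks, key=lambda p: p.mz))


@dataclass(frozen=True)
class ExtractedIonChromatogram:
    target_mz: float
    tolerance_ppm: float
    points: tuple[tuple[float, float], ...]  # (retention time, summed intensity)

    def apex(self) -> tuple[float, float]:
        """(retention time, intensity) of the most intense point."""
        if not self.points:
            raise ValueError("empty chromatogram")
        return max(self.points, key=lambda pt: pt[1])


@dataclass(frozen=True)
class FragmentAnnotation:
    kind: str  # "Y" or "oxonium"
    glycan: GlycanComposition
    charge: int
    theoretical_mz: float
    matched_peak: Optional[Peak] = None
    error_ppm: Optional[float] = None
    error_mmu: Optional[float] = None

    @property
    def matched(self) -> bool:
        return self.matched_peak is not None


def theoretical_precursors(
    peptide_mass: float,
    glycan: GlycanComposition,
    charges: Iterable[int] = DEFAULT_CHARGES,
) -> list[IonSpec]:
    """Precursor ions of the intact glycopeptide, one per charge state."""
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    charges = sorted(set(charges))
    if not charges:
        raise ValueError("at least one charge state required")
    neutral = peptide_mass + glycan.mass
    return [IonSpec(neutral_mass=neutral, charge=z) for z in charges]


def extract_eic(
    spectra: Sequence[Spectrum],
    target_mz: float,
    tol_ppm: float = 6.0,
) -> ExtractedIonChromatogram:
    """Summed intensity of peaks within tolerance of a target, per MS1 scan.

    Zero-intensity points are retained so the trace stays dense over the run.
    """
    if any(s.ms_level != 1 for s in spectra):
        raise ValueError("EIC extraction takes MS1 spectra only")
    half_width = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half_width, target_mz + half_width
    points = []
    for spectrum in sorted(spectra, key=lambda s: s.retention_time):
        mzs = [p.mz for p in spectrum.peaks]
        i, j = bisect_left(mzs, lo), bisect_right(mzs, hi)
        points.append(
            (spectrum.retention_time, sum(p.intensity for p in spectrum.peaks[i:j]))
        )
    return ExtractedIonChromatogram(
        target_mz=target_mz, tolerance_ppm=tol_ppm, points=tuple(points)
    )


def average_spectrum(
    spectra: Sequence[Spectrum],
    rt_lo: float,
    rt_hi: float,
    tol_ppm: float = 6.0,
) -> Spectrum:
    """Average the MS1 spectra in an RT window, merging peaks within tolerance.

    Peaks closer than the tolerance (relative to the running bin centroid)
    are pooled; the pooled intensity is divided by the number of spectra in
    the window, so a peak present in every scan keeps its mean intensity.
    """
    if not rt_lo < rt_hi:
        raise ValueError(f"invalid RT window [{rt_lo}, {rt_hi}]")
    window = [
        s for s in spectra if s.ms_level == 1 and rt_lo <= s.retention_time <= rt_hi
    ]
    if not window:
        raise ValueError(f"no MS1 spectra in RT window [{rt_lo}, {rt_hi}]")
    n = len(window)
    all_peaks = sorted(
        (p for s in window for p in s.peaks), key=lambda p: p.mz
    )
    merged: list[Peak] = []
    bin_mzs: list[float] = []
    bin_intensity = 0.0
    for peak in all_peaks:
        if bin_mzs and abs(ppm_error(peak.mz, bin_mzs[0])) > tol_ppm:
            centroid = sum(bin_mzs) / len(bin_mzs)
            merged.append(Peak(mz=centroid, intensity=bin_intensity / n))
            bin_mzs, bin_intensity = [], 0.0
        bin_mzs.append(peak.mz)
        bin_intensity += peak.intensity
    if bin_mzs:
        centroid = sum(bin_mzs) / len(bin_mzs)
        merged.append(Peak(mz=centroid, intensity=bin_intensity / n))
    rt = sum(s.retention_time for s in window) / n
    return Spectrum(ms_level=1, retention_time=rt, peaks=tuple(merged))


def enumerate_y_ions(
    peptide_mass: float,
    glycan: GlycanComposition,
    charges: Iterable[int] = (1,),
) -> list[FragmentAnnotation]:
    """Y-ion templates for every sub-composition of the parent glycan.

    Includes Y0 (the bare peptide) and the intact glycopeptide; the count is
    the product of (count_i + 1) over monosaccharide classes, per charge.
    """
    if peptide_mass <= 0:
        raise ValueError("peptide mass must be positive")
    charges = sorted(set(charges))
    if not charges:
        raise ValueError("at least one charge state required")
    templates = []
    ranges = [range(c + 1) for c in glycan.as_tuple()]
    for counts in itertools.product(*ranges):
        sub = GlycanComposition(*counts)
        neutral = peptide_mass + sub.mass
        for z in charges:
            templates.append(
                FragmentAnnotation(
                    kind="Y", glycan=sub, charge=z, theoretical_mz=mz(neutral, z)
                )
            )
    return templates


# Singly charged glycan B-type ions: single residues and common pairs.
_OXONIUM_COMBOS: tuple[tuple[int, int, int, int], ...] = (
    (1, 0, 0, 0),  # HexNAc
    (0, 1, 0, 0),  # Hex
    (0, 0, 0, 1),  # NeuAc
    (1, 1, 0, 0),  # HexNAc + Hex
    (2, 0, 0, 0),  # HexNAc2
    (1, 0, 1, 0),  # HexNAc + Fuc
    (0, 0, 1, 1),  # NeuAc + Fuc (rare; only if both present)
)


def oxonium_ions(glycan: GlycanComposition) -> list[FragmentAnnotation]:
    """Singly charged oxonium (B-type) ion templates present in the glycan."""
    templates = []
    for counts in _OXONIUM_COMBOS:
        sub = GlycanComposition(*counts)
        if glycan.contains(sub) and sub.mass > 0:
            templates.append(
                FragmentAnnotation(
                    kind="oxonium",
                    glycan=sub,
                    charge=1,
                    theoretical_mz=sub.mass + PROTON,
                )
            )
    return templates


def annotate_ms2(
    spectrum: Spectrum,
    templates: Sequence[FragmentAnnotation],
    tol_mmu: float = 20.0,
) -> list[FragmentAnnotation]:
    """Greedy nearest-match of fragment templates to MS2 peaks.

    Each peak is used at most once.  Candidate (template, peak) pairs within
    tolerance are assigned in order of increasing |mmu| error, ties broken by
    lower charge.  Unmatched templates are returned with no peak.  The
    result is independent of the input peak order.
    """
    if spectrum.ms_level != 2:
        raise ValueError("annotate_ms2 takes an MS2 spectrum")
    peaks = sorted(spectrum.peaks, key=lambda p: (p.mz, -p.intensity))
    mzs = [p.mz for p in peaks]
    candidates = []
    for t_idx, template in enumerate(templates):
        lo = template.theoretical_mz - tol_mmu * 1e-3
        hi = template.theoretical_mz + tol_mmu * 1e-3
        for p_idx in range(bisect_left(mzs, lo), bisect_right(mzs, hi)):
            err = mmu_error(peaks[p_idx].mz, template.theoretical_mz)
            candidates.append((abs(err), template.charge, t_idx, p_idx, err))
    candidates.sort()
    used_peaks: set[int] = set()
    assigned: dict[int, tuple[int, float]] = {}
    for _, _, t_idx, p_idx, err in candidates:
        if t_idx in assigned or p_idx in used_peaks:
            continue
        assigned[t_idx] = (p_idx, err)
        used_peaks.add(p_idx)
    annotated = []
    for t_idx, template in enumerate(templates):
        if t_idx in assigned:
            p_idx, err = assigned[t_idx]
            peak = peaks[p_idx]
            annotated.append(
                FragmentAnnotation(
                    kind=template.kind,
                    glycan=template.glycan,
                    charge=template.charge,
                    theoretical_mz=template.theoretical_mz,
                    matched_peak=peak,
                    error_ppm=ppm_error(peak.mz, template.theoretical_mz),
                    error_mmu=err,
                )
            )
        else:
            annotated.append(template)
    return annotated


def bisecting_diagnostic_flag(
    annotations: Sequence[FragmentAnnotation],
    min_hexnac: int = 3,
    max_hex: int = 1,
) -> bool:
    """Operational bisecting-GlcNAc screen over annotated Y-ions.

    A Y-ion remnant retaining at least ``min_hexnac`` HexNAc on at most
    ``max_hex`` Hex is taken as evidence of a core GlcNAc beyond the
    chitobiose stubs, the mass signature a bisected core leaves after
    antenna losses.  Thresholds are configurable because the flag is a
    heuristic, not a topology proof.
    """
    return any(
        a.kind == "Y"
        and a.matched
        and a.glycan.n_hexnac >= min_hexnac
        and a.glycan.n_hex <= max_hex
        for a in annotations
    )


def screen_diagnostic_mz(
    templates: Sequence[FragmentAnnotation],
    target_mz: float,
    tol_ppm: float = 6.0,
) -> list[FragmentAnnotation]:
    """Templates whose theoretical m/z lies within ppm tolerance of a target.

    Used to ask which candidate ladder entries could explain a reported
    diagnostic ion.
    """
    return [
        t
        for t in templates
        if abs(ppm_error(target_mz, t.theoretical_mz)) <= tol_ppm
    ]
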