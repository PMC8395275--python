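"""Seeded synthetic two-condition lectin-enrichment glycoproteome.

The generator emulates the study design the pipeline is built for: a
wild-type (WT) and a glycosyltransferase-knockout (KO) brain membrane
digest, enriched with a lectin that prefers the bisected glycan, then
deglycosylated so every glycosylated Asn is read out as a deamidation.
It produces (i) a proteome with planted sequons, (ii) WT/KO identified-
peptide tables with log-normal intensities, strong KO suppression of
bisected peptides, contaminant leak-through, and spontaneous-deamidation
noise, and (iii) MS1/MS2 spectra of the intact glycopeptides — together
with the exact ground truth, so every pipeline stage can be scored.

Bisection is assigned per glycopeptide (all glycosylated sites of one
tryptic peptide share it): the enrichment step selects whole peptides, so
peptide-level coherence is the resolution the assay can actually report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .digest import ProteinRecord, SequonSite, find_sequons, tryptic_digest
from .masses import CARBAMIDOMETHYL, GlycanComposition, peptide_mass
from .quant import RatioClass, RatioThresholds, DEFAULT_THRESHOLDS
from .sites import AnnotatedPeptide, SiteCallResult
from .spectra import (
    Peak,
    Spectrum,
    enumerate_y_ions,
    oxonium_ions,
    theoretical_precursors,
)

DEFAULT_GLYCAN = GlycanComposition(n_hexnac=5, n_hex=3, n_fuc=1)
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic glycoproteome.

    Intensities are log-normal on the natural-log scale (location ``mu``,
    scale ``sigma``); ``ko_suppression`` multiplies the KO intensity of
    bisected peptides; ``ratio_noise_sigma`` is the technical ln-ratio noise
    between conditions for the same peptide; ``contaminant_survival`` is the
    probability that a peptide without the bisected glycan leaks through the
    lectin pulldown.
    """

    seed: int = 1
    n_proteins: int = 30
    protein_length_range: tuple[int, int] = (200, 400)
    fraction_sequons_glycosylated: float = 0.5
    fraction_glycopeptides_bisected: float = 0.5
    log_intensity_mu: float = 14.0
    log_intensity_sigma: float = 1.0
    ko_suppression: float = 0.02
    ratio_noise_sigma: float = 0.3
    detection_limit: Optional[float] = None  # None → 5th percentile of KO draws
    spontaneous_deamidation_rate: float = 0.005
    contaminant_survival: float = 0.2
    noise_peaks: int = 20
    ppm_jitter: float = 0.0  # planted peaks shifted uniformly within ±jitter ppm
    glycan: GlycanComposition = DEFAULT_GLYCAN

    def __post_init__(self) -> None:
        for name in (
            "fraction_sequons_glycosylated",
            "fraction_glycopeptides_bisected",
            "spontaneous_deamidation_rate",
            "contaminant_survival",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.ko_suppression < 0:
            raise ValueError("ko_suppression must be >= 0")
        if self.log_intensity_sigma <= 0:
            raise ValueError("log_intensity_sigma must be > 0")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if not 5 <= lo <= hi:
            raise ValueError(f"bad protein length range ({lo}, {hi})")

    @classmethod
    def noise_free(cls, seed: int = 1) -> "SimulationConfig":
        """All stochastic nuisance processes off; suppression total."""
        return cls(
            seed=seed,
            ko_suppression=0.0,
            ratio_noise_sigma=0.0,
            detection_limit=1.0,
            spontaneous_deamidation_rate=0.0,
            contaminant_survival=0.0,
            noise_peaks=0,
            ppm_jitter=0.0,
        )


@dataclass(frozen=True)
class SimulatedGlycopeptide:
    """An intact glycopeptide planted into the simulated LC-MS run."""

    accession: str
    sequence: str
    glycan: GlycanComposition
    retention_time: float
    abundance: float
    charges: tuple[int, ...] = (2, 3)

    @property
    def peptide_mass(self) -> float:
        mods = [
            (i + 1, CARBAMIDOMETHYL)
            for i, aa in enumerate(self.sequence)
            if aa == "C"
        ]
        return peptide_mass(self.sequence, mods)


@dataclass
class GroundTruth:
    """Everything the generator planted, for scoring the pipeline."""

    bisected_sites: set[tuple[str, int]] = field(default_factory=set)
    glycosylated_sites: set[tuple[str, int]] = field(default_factory=set)
    spontaneous_sites: set[tuple[str, int]] = field(default_factory=set)
    detection_limit: float = 0.0
    wt_intensity: dict[str, float] = field(default_factory=dict)  # raw, pre-limit
    ko_intensity: dict[str, float] = field(default_factory=dict)
    planted_ms1_peaks: list[tuple[float, float]] = field(default_factory=list)
    planted_ms2_fragments: dict[int, list[float]] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    proteome: list[ProteinRecord]
    records: list[AnnotatedPeptide]
    truth: GroundTruth
    glycopeptides: list[SimulatedGlycopeptide]


def generate_proteome(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], list[SequonSite]]:
    """Random proteome with planted sequons; every protein has >= 1 valid one."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    proteins = []
    letters = np.array(list(_ALPHABET))
    non_p = np.array([a for a in _ALPHABET if a != "P"])
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(letters, size=length)
        n_plant = int(rng.integers(1, 4))
        for _ in range(n_plant):
            pos = int(rng.integers(0, length - 2))
            seq[pos] = "N"
            seq[pos + 1] = rng.choice(non_p)
            seq[pos + 2] = "S" if rng.random() < 0.5 else "T"
        record = ProteinRecord(
            accession=f"SYN{i + 1:04d}",
            name=f"synthetic protein {i + 1}",
            sequence="".join(seq),
        )
        assert any(s.valid for s in find_sequons(record))
        proteins.append(record)
    inventory = [s for p in proteins for s in find_sequons(p)]
    return proteins, inventory


def simulate_study(
    config: SimulationConfig,
    proteome: Optional[Sequence[ProteinRecord]] = None,
) -> SimulatedStudy:
    """Full synthetic study: proteome, WT/KO peptide table, ground truth.

    Tryptic peptides (no missed cleavages, so sites partition uniquely) are
    glycosylated at their valid sequons, bisected per glycopeptide, passed
    through a leaky lectin enrichment, deglycosylated (glycosylated Asn →
    deamidated), intensity-sampled and thresholded at the detection limit.
    """
    rng = np.random.default_rng(config.seed)
    if proteome is None:
        proteome, _ = generate_proteome(
            replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        )
    truth = GroundTruth()

    # 1. choose glycosylated sites per protein, then bisection per peptide
    glyco_by_protein: dict[str, set[int]] = {}
    for protein in proteome:
        valid = [s.asn_position for s in find_sequons(protein) if s.valid]
        chosen = {
            pos for pos in valid if rng.random() < config.fraction_sequons_glycosylated
        }
        glyco_by_protein[protein.accession] = chosen
        truth.glycosylated_sites.update((protein.accession, p) for p in chosen)

    rows = []  # (protein, span, glyco_positions_in_peptide, bisected)
    for protein in proteome:
        for span in tryptic_digest(protein, max_missed=0):
            glyco = [
                pos - span.start + 1
                for pos in glyco_by_protein[protein.accession]
                if span.start <= pos <= span.end
            ]
            bisected = bool(glyco) and (
                rng.random() < config.fraction_glycopeptides_bisected
            )
            if bisected:
                truth.bisected_sites.update(
                    (protein.accession, span.start + p - 1) for p in glyco
                )
            rows.append((protein, span, glyco, bisected))

    # 2. lectin enrichment: bisected peptides always survive; others leak
    surviving = [
        row
        for row in rows
        if row[3] or rng.random() < config.contaminant_survival
    ]

    # 3. intensities
    wt_raw = np.exp(
        rng.normal(config.log_intensity_mu, config.log_intensity_sigma, len(surviving))
    )
    ratio_noise = np.exp(rng.normal(0.0, config.ratio_noise_sigma, len(surviving)))
    ko_raw = np.array(
        [
            wt * noise * (config.ko_suppression if row[3] else 1.0)
            for row, wt, noise in zip(surviving, wt_raw, ratio_noise)
        ]
    )
    limit = (
        config.detection_limit
        if config.detection_limit is not None
        else float(np.percentile(ko_raw, 5.0))
    )
    truth.detection_limit = limit

    # 4. deamidation annotation + record assembly
    records = []
    glycopeptides = []
    for (protein, span, glyco, bisected), wt, ko in zip(surviving, wt_raw, ko_raw):
        chars = list(span.sequence)
        for p in glyco:  # enzymatic deglycosylation converts every glyco-Asn
            chars[p - 1] = "n"
        for i, ch in enumerate(chars):
            if ch == "N" and rng.random() < config.spontaneous_deamidation_rate:
                chars[i] = "n"
                truth.spontaneous_sites.add((protein.accession, span.start + i))
            elif ch == "C":
                chars[i] = "c"  # alkylation is a static modification
        raw = "".join(chars)
        key = f"{protein.accession}:{span.start}-{span.end}"
        truth.wt_intensity[key] = float(wt)
        truth.ko_intensity[key] = float(ko)
        wt_obs = float(wt) if wt >= limit else None
        ko_obs = float(ko) if ko >= limit else None
        if wt_obs is None and ko_obs is None:
            continue
        records.append(
            AnnotatedPeptide(
                raw=raw,
                clean=span.sequence,
                deamidated_n=tuple(
                    i + 1 for i, ch in enumerate(raw) if ch == "n"
                ),
                carbamidomethyl_c=tuple(
                    i + 1 for i, ch in enumerate(raw) if ch == "c"
                ),
                protein_name=protein.accession,
                intensity_wt=wt_obs,
                intensity_ko=ko_obs,
            )
        )
        if bisected and wt_obs is not None:
            glycopeptides.append(
                SimulatedGlycopeptide(
                    accession=protein.accession,
                    sequence=span.sequence,
                    glycan=config.glycan,
                    retention_time=float(rng.uniform(10.0, 50.0)),
                    abundance=float(wt),
                )
            )
    return SimulatedStudy(
        proteome=list(proteome),
        records=records,
        truth=truth,
        glycopeptides=glycopeptides,
    )


def _jitter(rng: np.random.Generator, mz_value: float, ppm: float) -> float:
    if ppm <= 0:
        return mz_value
    return mz_value * (1.0 + rng.uniform(-ppm, ppm) * 1e-6)


def simulate_spectra(
    glycopeptides: Sequence[SimulatedGlycopeptide],
    config: SimulationConfig,
    rt_step: float = 0.1,
    rt_sigma: float = 0.15,
    truth: Optional[GroundTruth] = None,
) -> tuple[list[Spectrum], list[Spectrum]]:
    """MS1 run plus one MS2 spectrum per glycopeptide.

    MS1 precursors trace a Gaussian elution profile around the planted
    retention time; the MS2 at the apex carries the full singly charged
    Y-ion ladder and the oxonium ions, plus uniform-random noise peaks.
    Planted peaks sit at exact theoretical m/z unless ``ppm_jitter`` is on.
    """
    if not glycopeptides:
        raise ValueError("at least one glycopeptide required")
    rng = np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = GroundTruth()
    rt_min = min(g.retention_time for g in glycopeptides) - 1.0
    rt_max = max(g.retention_time for g in glycopeptides) + 1.0
    grid = np.arange(rt_min, rt_max + rt_step / 2, rt_step)

    ms1 = []
    for rt in grid:
        peaks = []
        for g in glycopeptides:
            profile = math.exp(-0.5 * ((rt - g.retention_time) / rt_sigma) ** 2)
            if profile < 1e-4:
                continue
            for ion in theoretical_precursors(g.peptide_mass, g.glycan, g.charges):
                mz_value = _jitter(rng, ion.mz, config.ppm_jitter)
                peaks.append(Peak(mz=mz_value, intensity=g.abundance * profile))
                truth.planted_ms1_peaks.append((float(rt), mz_value))
        for _ in range(config.noise_peaks):
            peaks.append(
                Peak(
                    mz=float(rng.uniform(300.0, 2000.0)),
                    intensity=float(rng.uniform(1.0, 100.0)),
                )
            )
        ms1.append(
            Spectrum(
                ms_level=1,
                retention_time=float(rt),
                peaks=Spectrum.sorted_peaks(peaks),
            )
        )

    ms2 = []
    for idx, g in enumerate(glycopeptides):
        templates = enumerate_y_ions(g.peptide_mass, g.glycan, charges=(1,))
        templates += oxonium_ions(g.glycan)
        planted = []
        peaks = []
        for template in templates:
            mz_value = _jitter(rng, template.theoretical_mz, config.ppm_jitter)
            peaks.append(Peak(mz=mz_value, intensity=float(rng.uniform(100.0, 1000.0))))
            planted.append(mz_value)
        for _ in range(config.noise_peaks):
            peaks.append(
                Peak(
                    mz=float(rng.uniform(150.0, 3000.0)),
                    intensity=float(rng.uniform(1.0, 50.0)),
                )
            )
        precursor = theoretical_precursors(g.peptide_mass, g.glycan, (3,))[0]
        ms2.append(
            Spectrum(
                ms_level=2,
                retention_time=g.retention_time,
                peaks=Spectrum.sorted_peaks(peaks),
                precursor_mz=precursor.mz,
                precursor_charge=3,
            )
        )
        truth.planted_ms2_fragments[idx] = planted
    return ms1, ms2


@dataclass(frozen=True)
class RecoveryReport:
    sensitivity: float
    precision: float
    n_true: int
    n_predicted: int
    n_correct: int


def evaluate_recovery(
    result: SiteCallResult,
    truth: GroundTruth,
    thresholds: RatioThresholds = DEFAULT_THRESHOLDS,
) -> RecoveryReport:
    """Score called bisected sites against the planted ground truth.

    A call counts as a predicted bisected site when it survived the sequon
    filter and its WT/KO evidence is WT-only or above the high-ratio
    threshold — the same reading the comparative analysis applies to real
    tables.
    """
    predicted = {
        (call.accession, call.position)
        for call in result.calls
        if call.ratio_class in (RatioClass.WT_ONLY, RatioClass.HIGH)
    }
    correct = predicted & truth.bisected_sites
    sensitivity = (
        len(correct) / len(truth.bisected_sites) if truth.bisected_sites else 1.0
    )
    precision = len(correct) / len(predicted) if predicted else 1.0
    return RecoveryReport(
        sensitivity=sensitivity,
        precision=precision,
        n_true=len(truth.bisected_sites),
        n_predicted=len(predicted),
        n_correct=len(correct),
    )
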