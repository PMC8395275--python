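"""Glycosite calling from case-annotated identified-peptide records.

Enzymatic deglycosylation (PNGase F) converts a glycosylated Asn to Asp,
so a deamidated Asn in an identified peptide marks a candidate
N-glycosylation site.  This module parses the lowercase annotation dialect
(``n`` = deamidated Asn, ``q`` = deamidated Gln, ``c`` = carbamidomethyl
Cys, ``m`` = oxidized Met), maps peptides onto a proteome, and converts
deamidated-Asn evidence into sequon-validated site calls.  Spontaneous
deamidation outside a sequon is the principal confounder; such calls are
kept in a side channel but excluded from the default report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

from .digest import (
    PeptideSpan,
    ProteinRecord,
    SequonValidity,
    peptide_only_sequons,
    resolve_boundary_sequon,
)
from .quant import (
    DEFAULT_THRESHOLDS,
    RatioClass,
    RatioThresholds,
    RatioValue,
    classify_ratio,
    compute_ratio,
)

logger = logging.getLogger(__name__)

_MOD_KINDS = {
    "n": ("deamidated_n", "N"),
    "q": ("deamidated_q", "Q"),
    "c": ("carbamidomethyl_c", "C"),
    "m": ("oxidized_m", "M"),
}


@dataclass(frozen=True)
class AnnotatedPeptide:
    """One identified-peptide record with case-encoded modifications."""

    raw: str
    clean: str
    deamidated_n: tuple[int, ...] = ()
    deamidated_q: tuple[int, ...] = ()
    carbamidomethyl_c: tuple[int, ...] = ()
    oxidized_m: tuple[int, ...] = ()
    protein_name: Optional[str] = None
    intensity_wt: Optional[float] = None
    intensity_ko: Optional[float] = None
    ratio_text: Optional[str] = None

    def ratio_value(self, detection_limit: float = 0.0) -> Optional[RatioValue]:
        """Numeric WT/KO ratio or single-condition flag for this record.

        Intensities take precedence; otherwise the textual ratio column
        ("4.14", "WT only", "KO only") is interpreted.
        """
        if self.intensity_wt is not None or self.intensity_ko is not None:
            return compute_ratio(self.intensity_wt, self.intensity_ko, detection_limit)
        if self.ratio_text is None:
            return None
        text = self.ratio_text.strip()
        lowered = text.lower()
        if lowered == "wt only":
            return RatioClass.WT_ONLY
        if lowered == "ko only":
            return RatioClass.KO_ONLY
        return float(text)


def parse_annotated_peptide(
    text: str,
    protein_name: Optional[str] = None,
    intensity_wt: Optional[float] = None,
    intensity_ko: Optional[float] = None,
    ratio_text: Optional[str] = None,
) -> AnnotatedPeptide:
    """Parse a mixed-case peptide string into an :class:`AnnotatedPeptide`.

    Positions are 1-based within the peptide.  Lowercase letters other than
    n/q/c/m, or a lowercase letter on the wrong residue (there are none —
    the letter itself names the residue), are rejected.
    """
    if not text:
        raise ValueError("empty peptide annotation")
    positions: dict[str, list[int]] = {name: [] for name, _ in _MOD_KINDS.values()}
    clean_chars = []
    for i, ch in enumerate(text, start=1):
        if ch.islower():
            if ch not in _MOD_KINDS:
                raise ValueError(
                    f"unsupported lowercase annotation {ch!r} at position {i} in {text!r}"
                )
            attr, _ = _MOD_KINDS[ch]
            positions[attr].append(i)
            clean_chars.append(ch.upper())
        elif ch.isupper():
            clean_chars.append(ch)
        else:
            raise ValueError(f"invalid character {ch!r} in peptide annotation {text!r}")
    return AnnotatedPeptide(
        raw=text,
        clean="".join(clean_chars),
        deamidated_n=tuple(positions["deamidated_n"]),
        deamidated_q=tuple(positions["deamidated_q"]),
        carbamidomethyl_c=tuple(positions["carbamidomethyl_c"]),
        oxidized_m=tuple(positions["oxidized_m"]),
        protein_name=protein_name,
        intensity_wt=intensity_wt,
        intensity_ko=intensity_ko,
        ratio_text=ratio_text,
    )


def map_peptide(
    peptide: AnnotatedPeptide, proteome: Sequence[ProteinRecord]
) -> list[PeptideSpan]:
    """All exact-substring placements of a peptide in a proteome.

    Multiple placements (within or across proteins) are all returned; zero
    placements yield an empty list, reported but not fatal.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    spans: list[PeptideSpan] = []
    for protein in proteome:
        start = protein.sequence.find(peptide.clean)
        while start != -1:
            spans.append(
                PeptideSpan(
                    accession=protein.accession,
                    start=start + 1,
                    end=start + len(peptide.clean),
                    sequence=peptide.clean,
                )
            )
            start = protein.sequence.find(peptide.clean, start + 1)
    if not spans:
        logger.info("unmapped peptide: %s", peptide.raw)
    return spans


@dataclass(frozen=True)
class GlycoSiteCall:
    """A protein position asserted to carry an N-glycan, with provenance."""

    accession: Optional[str]
    protein_name: Optional[str]
    position: int  # protein coordinate when mapped, peptide coordinate otherwise
    validity: SequonValidity
    ratio_class: Optional[RatioClass]
    evidence: tuple[AnnotatedPeptide, ...]
    ambiguous: bool = False
    mapped: bool = True


@dataclass
class SiteCallResult:
    """Default report (``calls``) plus side channels."""

    calls: list[GlycoSiteCall] = field(default_factory=list)
    invalid_sequon: list[GlycoSiteCall] = field(default_factory=list)
    unmapped: list[AnnotatedPeptide] = field(default_factory=list)

    @property
    def all_calls(self) -> list[GlycoSiteCall]:
        return self.calls + self.invalid_sequon


def _evidence_class(
    evidence: Sequence[AnnotatedPeptide],
    thresholds: RatioThresholds,
    detection_limit: float,
) -> Optional[RatioClass]:
    # Class of the maximum-evidence (highest WT intensity) record.
    best = None
    best_wt = -1.0
    for record in evidence:
        wt = record.intensity_wt if record.intensity_wt is not None else 0.0
        if best is None or wt > best_wt:
            value = record.ratio_value(detection_limit)
            if value is not None:
                best = value
                best_wt = wt
    if best is None:
        return None
    return classify_ratio(best, thresholds)


def call_glycosites(
    records: Sequence[AnnotatedPeptide],
    proteome: Optional[Sequence[ProteinRecord]] = None,
    thresholds: RatioThresholds = DEFAULT_THRESHOLDS,
    detection_limit: float = 0.0,
) -> SiteCallResult:
    """Convert deamidated-Asn evidence into sequon-validated site calls.

    With a proteome, peptides are placed by exact match, sequons are
    resolved against protein context, and records hitting the same
    (protein, position) merge into one call.  Without a proteome each
    deamidated Asn yields a peptide-coordinate call and boundary
    asparagines come back ``UNRESOLVED``.  Deamidated Gln never produces a
    call.  Calls outside a valid sequon go to the ``invalid_sequon`` side
    channel.
    """
    result = SiteCallResult()
    if proteome is None:
        for record in records:
            validity = peptide_only_sequons(record.clean)
            ratio_class = _evidence_class([record], thresholds, detection_limit)
            for pos in record.deamidated_n:
                call = GlycoSiteCall(
                    accession=None,
                    protein_name=record.protein_name,
                    position=pos,
                    validity=validity[pos],
                    ratio_class=ratio_class,
                    evidence=(record,),
                    mapped=False,
                )
                if call.validity is SequonValidity.INVALID:
                    result.invalid_sequon.append(call)
                else:
                    result.calls.append(call)
        _log_result(result)
        return result

    by_accession = {p.accession: p for p in proteome}
    grouped: dict[tuple[str, int], dict] = {}
    for record in records:
        spans = map_peptide(record, proteome)
        if not spans:
            result.unmapped.append(record)
            continue
        ambiguous = len(spans) > 1
        for span in spans:
            protein = by_accession[span.accession]
            validity = resolve_boundary_sequon(span, protein)
            for pos in record.deamidated_n:
                key = (span.accession, span.start + pos - 1)
                entry = grouped.setdefault(
                    key,
                    {
                        "validity": validity[pos],
                        "evidence": [],
                        "ambiguous": False,
                        "name": protein.name,
                    },
                )
                entry["evidence"].append(record)
                entry["ambiguous"] = entry["ambiguous"] or ambiguous
    for (accession, position), entry in sorted(grouped.items()):
        call = GlycoSiteCall(
            accession=accession,
            protein_name=entry["name"],
            position=position,
            validity=entry["validity"],
            ratio_class=_evidence_class(entry["evidence"], thresholds, detection_limit),
            evidence=tuple(dict.fromkeys(entry["evidence"])),
            ambiguous=entry["ambiguous"],
        )
        if call.validity is SequonValidity.INVALID:
            result.invalid_sequon.append(call)
        else:
            result.calls.append(call)
    _log_result(result)
    return result


def _log_result(result: SiteCallResult) -> None:
    logger.info(
        "site calling: %d calls, %d invalid-sequon, %d unmapped",
        len(result.calls),
        len(result.invalid_sequon),
        len(result.unmapped),
    )
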