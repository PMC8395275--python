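"""WT/KO label-free ratio computation and enrichment classification.

Peptides enriched for bisected N-glycans from a wild-type sample are
compared against the knockout control: a peptide detected only in WT, or
strongly enriched in WT, is evidence that its glycan carried the
knockout-dependent modification.  Bins follow strict inequalities — a
ratio above ``t_high`` is HIGH, between ``t_low`` (exclusive) and
``t_high`` (inclusive) MODERATE, at or below ``t_low`` UNCHANGED.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Union


class RatioClass(str, Enum):
    WT_ONLY = "WT_ONLY"
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    UNCHANGED = "UNCHANGED"
    KO_ONLY = "KO_ONLY"


@dataclass(frozen=True)
class RatioThresholds:
    t_high: float = 4.0
    t_low: float = 1.0

    def __post_init__(self) -> None:
        if not self.t_high > self.t_low > 0:
            raise ValueError(
                f"need t_high > t_low > 0, got {self.t_high}, {self.t_low}"
            )


DEFAULT_THRESHOLDS = RatioThresholds()

RatioValue = Union[float, RatioClass]  # numeric ratio or WT_ONLY / KO_ONLY flag


def compute_ratio(
    intensity_wt: Optional[float],
    intensity_ko: Optional[float],
    detection_limit: float = 0.0,
) -> Optional[RatioValue]:
    """WT/KO intensity ratio, or a single-condition flag.

    Intensities below the detection limit (or absent) count as undetected.
    Returns ``None`` when neither condition is detected.
    """
    for value in (intensity_wt, intensity_ko):
        if value is not None and value < 0:
            raise ValueError(f"negative intensity: {value}")

    def detected(value: Optional[float]) -> bool:
        return value is not None and value > 0 and value >= detection_limit

    wt_seen = detected(intensity_wt)
    ko_seen = detected(intensity_ko)
    if wt_seen and ko_seen:
        return intensity_wt / intensity_ko
    if wt_seen:
        return RatioClass.WT_ONLY
    if ko_seen:
        return RatioClass.KO_ONLY
    return None


def classify_ratio(
    value: RatioValue,
    thresholds: RatioThresholds = DEFAULT_THRESHOLDS,
) -> RatioClass:
    """Bin a ratio (or pass through a single-condition flag)."""
    if isinstance(value, RatioClass):
        if value in (RatioClass.WT_ONLY, RatioClass.KO_ONLY):
            return value
        raise ValueError(f"not a single-condition flag: {value}")
    if value <= 0:
        raise ValueError(f"ratio must be positive, got {value}")
    if value > thresholds.t_high:
        return RatioClass.HIGH
    if value > thresholds.t_low:
        return RatioClass.MODERATE
    return RatioClass.UNCHANGED


def summarize(classes: Iterable[RatioClass]) -> Mapping[RatioClass, int]:
    """Counts per class in a stable, report-friendly order."""
    counts = Counter(classes)
    return {cls: counts.get(cls, 0) for cls in RatioClass}
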