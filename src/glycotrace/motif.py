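"""Sequon-centered motif analysis.

Windows of residues around called glycosylation sites are stacked into a
position frequency matrix; per-offset information content (the sequence-logo
height, bits) measures how far each position departs from a uniform
background; and a permutation test asks whether any offset is more
concentrated than residue-composition chance allows.  The sequon's forced
positions (the Asn itself at offset 0 and the Ser/Thr at +2) are excluded
from the verdict by default, since they are conditioned on, not discovered.

The null model pools every non-padding residue across windows and scored
offsets, reshuffles the pool, and redeals it into the same slots, so each
offset keeps its effective sample size while losing any positional signal.
Per-offset empirical p-values are Bonferroni-adjusted across scored offsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .digest import ProteinRecord
from .sites import GlycoSiteCall

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
PAD = "-"
LOG2_20 = float(np.log2(20.0))


@dataclass(frozen=True)
class SiteWindow:
    """Residues at offsets −k..+k around a glycosylated Asn."""

    residues: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) % 2 != 1:
            raise ValueError("window length must be odd (2k+1)")
        center = self.residues[len(self.residues) // 2]
        if center != "N":
            raise ValueError(f"window center must be N, got {center!r}")

    @property
    def k(self) -> int:
        return len(self.residues) // 2


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-offset residue frequencies; padding excluded from denominators."""

    offsets: tuple[int, ...]
    counts: np.ndarray  # (n_offsets, 20) integer counts
    n_eff: np.ndarray  # (n_offsets,) non-pad observations per offset

    @property
    def frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_eff[:, None] > 0, self.counts / self.n_eff[:, None], np.nan
            )


@dataclass(frozen=True)
class LogoProfile:
    """Information content (bits) and letter heights per offset."""

    offsets: tuple[int, ...]
    information: np.ndarray  # (n_offsets,) bits; NaN where n_eff == 0
    heights: np.ndarray  # (n_offsets, 20) frequency × IC


@dataclass(frozen=True)
class MotifScanResult:
    offsets: tuple[int, ...]  # scored offsets only
    observed_ic: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    alpha: float
    verdict: str  # "motif" or "no motif"

    def flagged_offsets(self) -> list[int]:
        return [
            off
            for off, p in zip(self.offsets, self.p_adjusted)
            if p <= self.alpha
        ]


def extract_windows(
    calls: Sequence[GlycoSiteCall],
    proteome: Optional[Sequence[ProteinRecord]] = None,
    k: int = 5,
) -> list[SiteWindow]:
    """One ±k window per site call, centered on the glycosylated Asn.

    Mapped calls use protein context; unmapped (peptide-only) calls use the
    evidence peptide, clipped with padding.  Flanks running past either end
    are padded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_accession = {p.accession: p for p in proteome} if proteome else {}
    windows = []
    for call in calls:
        if call.mapped and call.accession in by_accession:
            context = by_accession[call.accession].sequence
            center = call.position  # 1-based in protein
            source = f"{call.accession}:{call.position}"
        else:
            context = call.evidence[0].clean
            center = call.position  # 1-based in peptide
            source = f"peptide:{call.evidence[0].raw}:{call.position}"
        if context[center - 1] != "N":
            raise ValueError(
                f"site {source} does not point at an Asn (found {context[center - 1]!r})"
            )
        residues = tuple(
            context[center - 1 + off] if 0 <= center - 1 + off < len(context) else PAD
            for off in range(-k, k + 1)
        )
        windows.append(SiteWindow(residues=residues, source=source))
    return windows


def _encode(windows: Sequence[SiteWindow]) -> np.ndarray:
    """Integer matrix (n_windows, 2k+1); padding encoded as −1."""
    if not windows:
        raise ValueError("at least one window required")
    k = windows[0].k
    if any(w.k != k for w in windows):
        raise ValueError("windows must share the same half-width k")
    return np.array(
        [[_RESIDUE_INDEX.get(r, -1) for r in w.residues] for w in windows],
        dtype=np.int64,
    )


def build_pfm(windows: Sequence[SiteWindow]) -> PositionFrequencyMatrix:
    encoded = _encode(windows)
    k = windows[0].k
    offsets = tuple(range(-k, k + 1))
    counts = np.zeros((len(offsets), 20), dtype=np.int64)
    for j in range(encoded.shape[1]):
        col = encoded[:, j]
        col = col[col >= 0]
        counts[j] = np.bincount(col, minlength=20)
    return PositionFrequencyMatrix(
        offsets=offsets, counts=counts, n_eff=counts.sum(axis=1)
    )


def _ic_from_counts(counts: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    """IC in bits per offset; NaN where n_eff is 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = counts / n_eff[..., None]
        logf = np.where(freq > 0, np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
        entropy = -(freq * logf).sum(axis=-1)
    ic = LOG2_20 - entropy
    return np.where(n_eff > 0, ic, np.nan)


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> LogoProfile:
    """Sequence-logo profile: IC = log2(20) − Shannon entropy per offset.

    With the small-sample correction on, the bias term
    e_n = 19 / (2 ln 2 · n_eff) is subtracted and the result floored at 0.
    """
    ic = _ic_from_counts(pfm.counts.astype(float), pfm.n_eff.astype(float))
    if small_sample_correction:
        with np.errstate(divide="ignore"):
            correction = np.where(
                pfm.n_eff > 0, 19.0 / (2.0 * np.log(2.0) * pfm.n_eff), 0.0
            )
        ic = np.maximum(ic - correction, 0.0)
        ic = np.where(pfm.n_eff > 0, ic, np.nan)
    heights = pfm.frequencies * ic[:, None]
    return LogoProfile(offsets=pfm.offsets, information=ic, heights=heights)


def motif_scan(
    windows: Sequence[SiteWindow],
    excluded_offsets: Sequence[int] = (0, 2),
    n_permutations: int = 1000,
    seed: int = 1,
    alpha: float = 0.05,
) -> MotifScanResult:
    """Permutation test for positional residue concentration.

    Residues at scored offsets are pooled, shuffled, and redealt
    ``n_permutations`` times.  The null statistic per permutation is the
    maximum bias-corrected IC over scored offsets, so each observed offset
    is compared against the best concentration chance produces anywhere in
    the window; per-offset p-values are then Bonferroni-adjusted across
    scored offsets.  The small-sample correction puts offsets with unequal
    effective sample sizes (padding) on the same scale.  The verdict is
    "motif" when the smallest adjusted p-value is at or below ``alpha``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if len(windows) < 5:
        raise ValueError(
            f"motif scan needs at least 5 windows, got {len(windows)}"
        )
    encoded = _encode(windows)
    k = windows[0].k
    all_offsets = list(range(-k, k + 1))
    scored_cols = [
        j for j, off in enumerate(all_offsets) if off not in set(excluded_offsets)
    ]
    sub = encoded[:, scored_cols]
    slot_mask = sub >= 0
    pool = sub[slot_mask]
    col_of_slot = np.nonzero(slot_mask)[1]
    n_cols = len(scored_cols)
    n_eff = np.bincount(col_of_slot, minlength=n_cols).astype(float)
    scored = n_eff > 0
    with np.errstate(divide="ignore"):
        bias = np.where(scored, 19.0 / (2.0 * np.log(2.0) * n_eff), 0.0)

    # observed bias-corrected IC per scored offset
    obs_counts = np.zeros((n_cols, 20))
    np.add.at(obs_counts, (col_of_slot, pool), 1.0)
    observed_ic = np.maximum(_ic_from_counts(obs_counts, n_eff) - bias, 0.0)
    observed_ic = np.where(scored, observed_ic, np.nan)

    rng = np.random.default_rng(seed)
    # sort the pool so the null stream depends only on residue composition,
    # not on the order the windows were supplied in
    perms = rng.permuted(
        np.tile(np.sort(pool), (n_permutations, 1)), axis=1
    )  # (n_perm, n_slots)
    flat = (
        np.arange(n_permutations)[:, None] * (n_cols * 20)
        + col_of_slot[None, :] * 20
        + perms
    )
    null_counts = np.bincount(
        flat.ravel(), minlength=n_permutations * n_cols * 20
    ).reshape(n_permutations, n_cols, 20)
    null_ic = _ic_from_counts(
        null_counts.astype(float), np.broadcast_to(n_eff, (n_permutations, n_cols))
    )
    null_ic = np.maximum(null_ic - bias[None, :], 0.0)
    null_max = np.nanmax(
        np.where(scored[None, :], null_ic, -np.inf), axis=1
    )  # (n_perm,)
    with np.errstate(invalid="ignore"):
        exceed = (null_max[:, None] >= observed_ic[None, :]).sum(axis=0)
    p = np.where(scored, (1.0 + exceed) / (n_permutations + 1.0), np.nan)
    n_scored = int(scored.sum())
    p_adj = np.where(scored, np.minimum(1.0, p * n_scored), np.nan)
    min_adj = np.nanmin(p_adj) if n_scored else np.nan
    verdict = "motif" if (n_scored and min_adj <= alpha) else "no motif"
    return MotifScanResult(
        offsets=tuple(all_offsets[j] for j in scored_cols),
        observed_ic=observed_ic,
        p_values=p,
        p_adjusted=p_adj,
        alpha=alpha,
        verdict=verdict,
    )


def plot_logo(profile: LogoProfile, path: str) -> None:
    """Write a simple information-content bar plot (one bar per offset)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(profile.offsets) * 0.6), 3))
    ic = np.nan_to_num(profile.information, nan=0.0)
    ax.bar(profile.offsets, ic, color="#3b6ea5")
    for off, height, row in zip(profile.offsets, ic, profile.heights):
        if height > 0 and not np.all(np.isnan(row)):
            top = ALPHABET[int(np.nanargmax(row))]
            ax.text(off, height, top, ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("offset from glycosylated Asn")
    ax.set_ylabel("information content (bits)")
    ax.set_ylim(0, LOG2_20)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
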