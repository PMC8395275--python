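"""End-to-end flows shared by the command line and the reports.

Each function runs one complete analysis path — classify a peptide table,
reproduce the packaged-fixture report, or score a full synthetic study —
and returns plain dictionaries that the CLI prints and the scripts dump
as JSON.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

from .config import RunConfig
from .io import load_table1
from .motif import extract_windows, motif_scan
from .quant import RatioClass, classify_ratio, summarize
from .simulate import (
    SimulationConfig,
    evaluate_recovery,
    simulate_spectra,
    simulate_study,
)
from .sites import AnnotatedPeptide, call_glycosites
from .spectra import annotate_ms2, enumerate_y_ions, extract_eic, oxonium_ions, theoretical_precursors

logger = logging.getLogger(__name__)


def classify_records(
    records: Sequence[AnnotatedPeptide], run: Optional[RunConfig] = None
) -> tuple[list[RatioClass], dict[RatioClass, int]]:
    """Per-record enrichment classes and their summary counts."""
    run = run or RunConfig()
    classes = []
    for record in records:
        value = record.ratio_value(run.detection_limit)
        if value is None:
            continue
        classes.append(classify_ratio(value, run.thresholds))
    return classes, dict(summarize(classes))


def table1_report(run: Optional[RunConfig] = None) -> dict:
    """Parse the packaged fixture, classify, and scan for a sequon motif."""
    run = run or RunConfig()
    records = load_table1()
    classes, counts = classify_records(records, run)
    result = call_glycosites(records, proteome=None, thresholds=run.thresholds)
    windows = extract_windows(result.all_calls, proteome=None, k=run.motif_k)
    scan = motif_scan(
        windows,
        excluded_offsets=run.motif_excluded_offsets,
        n_permutations=run.motif_permutations,
        seed=run.seed,
        alpha=run.motif_alpha,
    )
    return {
        "n_records": len(records),
        "class_counts": {cls.value: n for cls, n in counts.items()},
        "n_site_calls": len(result.all_calls),
        "n_windows": len(windows),
        "motif_verdict": scan.verdict,
        "motif_min_adjusted_p": float(min(p for p in scan.p_adjusted if p == p)),
    }


def run_synthetic_study(
    sim: Optional[SimulationConfig] = None,
    run: Optional[RunConfig] = None,
    with_spectra: bool = True,
) -> dict:
    """Simulate a study, run the pipeline on it, and score the recovery."""
    sim = sim or SimulationConfig()
    run = run or RunConfig()
    study = simulate_study(sim)
    result = call_glycosites(
        study.records,
        proteome=study.proteome,
        thresholds=run.thresholds,
        detection_limit=study.truth.detection_limit,
    )
    recovery = evaluate_recovery(result, study.truth, run.thresholds)
    report = {
        "n_proteins": len(study.proteome),
        "n_peptide_records": len(study.records),
        "n_site_calls": len(result.calls),
        "n_invalid_sequon": len(result.invalid_sequon),
        "n_planted_bisected_sites": recovery.n_true,
        "n_predicted_bisected_sites": recovery.n_predicted,
        "sensitivity": recovery.sensitivity,
        "precision": recovery.precision,
    }
    if with_spectra and study.glycopeptides:
        ms1, ms2 = simulate_spectra(study.glycopeptides, sim, truth=study.truth)
        glycopeptide = study.glycopeptides[0]
        precursors = theoretical_precursors(
            glycopeptide.peptide_mass, glycopeptide.glycan, (2, 3)
        )
        eic = extract_eic(ms1, precursors[0].mz, run.ms1_tolerance_ppm)
        apex_rt, _ = eic.apex()
        templates = enumerate_y_ions(
            glycopeptide.peptide_mass, glycopeptide.glycan, (1,)
        ) + oxonium_ions(glycopeptide.glycan)
        annotations = annotate_ms2(ms2[0], templates, run.ms2_tolerance_mmu)
        matched = sum(a.matched for a in annotations)
        report.update(
            {
                "n_glycopeptides": len(study.glycopeptides),
                "eic_apex_rt": apex_rt,
                "eic_apex_rt_error": abs(apex_rt - glycopeptide.retention_time),
                "ms2_fragment_match_rate": matched / len(templates),
            }
        )
    logger.info("synthetic study report: %s", report)
    return report
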