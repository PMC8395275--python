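"""The synthetic study generator: determinism, intensity model, spectra."""

import pytest

from glycotrace.digest import find_sequons
from glycotrace.masses import GlycanComposition
from glycotrace.pipeline import run_synthetic_study
from glycotrace.quant import RatioClass
from glycotrace.simulate import (
    SimulationConfig,
    SimulatedGlycopeptide,
    evaluate_recovery,
    generate_proteome,
    simulate_spectra,
    simulate_study,
)
from glycotrace.sites import call_glycosites
from glycotrace.spectra import (
    annotate_ms2,
    enumerate_y_ions,
    extract_eic,
    oxonium_ions,
    theoretical_precursors,
)


class TestGenerateProteome:
    def test_deterministic_given_seed(self):
        config = SimulationConfig(seed=1, n_proteins=10)
        first, _ = generate_proteome(config)
        second, _ = generate_proteome(config)
        assert [(p.accession, p.sequence) for p in first] == [
            (p.accession, p.sequence) for p in second
        ]

    def test_every_protein_has_a_valid_sequon(self):
        config = SimulationConfig(seed=3, n_proteins=50, protein_length_range=(200, 400))
        proteins, _ = generate_proteome(config)
        assert len(proteins) == 50
        for protein in proteins:
            assert 200 <= len(protein.sequence) <= 400
            assert any(s.valid for s in find_sequons(protein))

    def test_inventory_matches_sequon_finder(self):
        proteins, inventory = generate_proteome(SimulationConfig(seed=5, n_proteins=5))
        rebuilt = [s for p in proteins for s in find_sequons(p)]
        assert inventory == rebuilt

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_proteins=0)
        with pytest.raises(ValueError):
            SimulationConfig(fraction_sequons_glycosylated=1.5)


class TestSimulateStudy:
    def test_total_suppression_makes_every_bisected_peptide_wt_only(self):
        config = SimulationConfig(
            seed=2, ko_suppression=0.0, detection_limit=1.0
        )
        study = simulate_study(config)
        bisected = [r for r in study.records if r.deamidated_n]
        result = call_glycosites(
            bisected, study.proteome, detection_limit=config.detection_limit
        )
        for call in result.calls:
            if (call.accession, call.position) in study.truth.bisected_sites:
                assert call.ratio_class is RatioClass.WT_ONLY

    def test_no_suppression_keeps_ratios_near_unity(self):
        """With the knockout effect off, essentially nothing is enriched."""
        config = SimulationConfig(
            seed=1,
            n_proteins=60,
            ko_suppression=1.0,
            contaminant_survival=1.0,
            detection_limit=1.0,
        )
        study = simulate_study(config)
        classes = [
            r.ratio_value(config.detection_limit) for r in study.records
        ]
        n_high = sum(
            1
            for value in classes
            if isinstance(value, float) and value > 4.0
        )
        assert len(study.records) > 500
        assert n_high <= 0.01 * len(study.records)

    def test_default_conditions_enrich_bisected_peptides(self):
        study = simulate_study(SimulationConfig(seed=1))
        limit = study.truth.detection_limit
        outcomes = [
            record.ratio_value(limit)
            for record in study.records
            if record.deamidated_n
        ]
        bisected_like = [
            v
            for v in outcomes
            if v is RatioClass.WT_ONLY or (isinstance(v, float) and v > 4.0)
        ]
        assert len(bisected_like) >= 0.8 * len(study.truth.bisected_sites)

    def test_glycosylated_asn_always_emitted_deamidated(self):
        study = simulate_study(SimulationConfig.noise_free(4))
        called = call_glycosites(study.records, study.proteome)
        positions = {(c.accession, c.position) for c in called.calls}
        assert study.truth.bisected_sites <= positions

    def test_deterministic_records(self):
        a = simulate_study(SimulationConfig(seed=6))
        b = simulate_study(SimulationConfig(seed=6))
        assert [r.raw for r in a.records] == [r.raw for r in b.records]
        assert a.truth.bisected_sites == b.truth.bisected_sites


class TestRecovery:
    def test_noise_free_recovery_is_exact(self):
        config = SimulationConfig.noise_free(1)
        study = simulate_study(config)
        result = call_glycosites(
            study.records, study.proteome, detection_limit=config.detection_limit
        )
        report = evaluate_recovery(result, study.truth)
        assert report.sensitivity == 1.0
        assert report.precision == 1.0
        called = {(c.accession, c.position) for c in result.calls}
        assert called == study.truth.bisected_sites

    def test_default_noise_recovery_meets_frozen_bounds(self):
        report = run_synthetic_study(SimulationConfig(seed=1), with_spectra=False)
        assert report["sensitivity"] >= 0.9
        assert report["precision"] >= 0.95


class TestSimulateSpectra:
    def _one_glycopeptide(self):
        return SimulatedGlycopeptide(
            accession="SYN0001",
            sequence="LSVECANK",
            glycan=GlycanComposition(5, 3, 1, 0),
            retention_time=27.3,
            abundance=1000.0,
        )

    def test_zero_noise_eic_apex_at_planted_rt(self):
        config = SimulationConfig.noise_free(1)
        g = self._one_glycopeptide()
        ms1, _ = simulate_spectra([g], config)
        target = theoretical_precursors(g.peptide_mass, g.glycan, (2,))[0].mz
        eic = extract_eic(ms1, target, 6.0)
        rt, intensity = eic.apex()
        assert intensity > 0
        assert abs(rt - g.retention_time) <= 0.1  # within one scan interval

    def test_zero_noise_ms2_fully_annotated(self):
        config = SimulationConfig.noise_free(1)
        g = self._one_glycopeptide()
        _, ms2 = simulate_spectra([g], config)
        templates = enumerate_y_ions(g.peptide_mass, g.glycan, (1,)) + oxonium_ions(
            g.glycan
        )
        annotated = annotate_ms2(ms2[0], templates, 20.0)
        assert all(a.matched for a in annotated)
        assert all(abs(a.error_mmu) < 1e-9 for a in annotated)

    def test_ppm_jitter_within_tolerance_still_recovered(self):
        config = SimulationConfig(seed=1, ppm_jitter=3.0, noise_peaks=0)
        g = self._one_glycopeptide()
        ms1, _ = simulate_spectra([g], config)
        target = theoretical_precursors(g.peptide_mass, g.glycan, (2,))[0].mz
        eic = extract_eic(ms1, target, 6.0)
        nonzero = [i for _, i in eic.points if i > 0]
        # the elution profile spans ~±3 sigma around the apex
        assert len(nonzero) >= 5

    def test_requires_at_least_one_glycopeptide(self):
        with pytest.raises(ValueError):
            simulate_spectra([], SimulationConfig(seed=1))
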