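"""Glycopeptide spectral verification: precursors, EIC, fragments, annotation."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotrace.masses import CARBAMIDOMETHYL, GlycanComposition, peptide_mass
from glycotrace.spectra import (
    Peak,
    Spectrum,
    annotate_ms2,
    average_spectrum,
    bisecting_diagnostic_flag,
    enumerate_y_ions,
    extract_eic,
    oxonium_ions,
    screen_diagnostic_mz,
    theoretical_precursors,
)

LSVECANK_CAM = peptide_mass("LSVECANK", [(5, CARBAMIDOMETHYL)])
BISECTED = GlycanComposition(5, 3, 1, 0)


def _ms1(rt, peaks):
    return Spectrum(ms_level=1, retention_time=rt, peaks=Spectrum.sorted_peaks(peaks))


class TestTheoreticalPrecursors:
    def test_glycopeptide_charge_states(self):
        ions = theoretical_precursors(LSVECANK_CAM, BISECTED, {2, 3})
        assert ions[0].mz == pytest.approx(1284.5355, abs=1e-4)
        assert ions[1].mz == pytest.approx(856.6928, abs=1e-4)

    def test_empty_glycan_gives_bare_peptide_mh(self):
        (ion,) = theoretical_precursors(LSVECANK_CAM, GlycanComposition(), {1})
        assert ion.mz == pytest.approx(920.4506, abs=1e-4)

    def test_mz_decreases_with_charge(self):
        ions = theoretical_precursors(LSVECANK_CAM, BISECTED, {1, 2})
        assert ions[1].mz < ions[0].mz

    def test_empty_charge_set_rejected(self):
        with pytest.raises(ValueError):
            theoretical_precursors(LSVECANK_CAM, BISECTED, set())


class TestExtractEic:
    def test_single_matching_peak(self):
        spectra = [_ms1(10.0, [Peak(500.0, 100.0)])]
        eic = extract_eic(spectra, 500.0, 6.0)
        assert eic.points == ((10.0, 100.0),)

    def test_peak_outside_tolerance_gives_zero_point(self):
        spectra = [_ms1(10.0, [Peak(500.0 * (1 + 10e-6), 100.0)])]
        eic = extract_eic(spectra, 500.0, 6.0)
        assert eic.points == ((10.0, 0.0),)

    def test_in_tolerance_peaks_summed(self):
        spectra = [
            _ms1(10.0, [Peak(500.0, 50.0), Peak(500.001, 70.0), Peak(600.0, 5.0)])
        ]
        eic = extract_eic(spectra, 500.0, 6.0)
        assert eic.points == ((10.0, 120.0),)

    def test_rejects_ms2_input(self):
        ms2 = Spectrum(
            ms_level=2, retention_time=1.0, peaks=(), precursor_mz=500.0
        )
        with pytest.raises(ValueError):
            extract_eic([ms2], 500.0)

    def test_eic_conserves_total_signal(self):
        rng = random.Random(3)
        spectra = [
            _ms1(
                float(rt),
                [
                    Peak(rng.uniform(300, 2000), rng.uniform(0, 100))
                    for _ in range(20)
                ],
            )
            for rt in range(5)
        ]
        eic = extract_eic(spectra, 1000.0, 50.0)
        total = sum(p.intensity for s in spectra for p in s.peaks)
        assert sum(i for _, i in eic.points) <= total


class TestAverageSpectrum:
    def test_same_peak_intensity_averaged(self):
        spectra = [
            _ms1(27.1, [Peak(1000.0, 10.0)]),
            _ms1(27.2, [Peak(1000.0, 20.0)]),
        ]
        averaged = average_spectrum(spectra, 27.0, 27.5)
        assert len(averaged.peaks) == 1
        assert averaged.peaks[0].intensity == pytest.approx(15.0)

    def test_single_spectrum_is_identity(self):
        spectrum = _ms1(27.1, [Peak(800.0, 5.0), Peak(900.0, 7.0)])
        averaged = average_spectrum([spectrum], 27.0, 27.5)
        assert [(p.mz, p.intensity) for p in averaged.peaks] == [
            (800.0, 5.0),
            (900.0, 7.0),
        ]

    def test_peaks_within_tolerance_merge(self):
        spectra = [
            _ms1(27.1, [Peak(1000.000, 10.0)]),
            _ms1(27.2, [Peak(1000.003, 20.0)]),  # 3 ppm apart
        ]
        averaged = average_spectrum(spectra, 27.0, 27.5, tol_ppm=6.0)
        assert len(averaged.peaks) == 1
        assert averaged.peaks[0].mz == pytest.approx(1000.0015)

    def test_empty_window_rejected_with_bounds(self):
        with pytest.raises(ValueError, match="27.0"):
            average_spectrum([_ms1(10.0, [])], 27.0, 27.5)


class TestFragmentEnumeration:
    @pytest.mark.parametrize(
        "glycan, expected",
        [
            (GlycanComposition(2, 3, 0, 0), 12),
            (GlycanComposition(5, 3, 1, 0), 48),
        ],
    )
    def test_subcomposition_counts(self, glycan, expected):
        assert len(enumerate_y_ions(1000.0, glycan, (1,))) == expected

    def test_y0_is_bare_peptide(self):
        templates = enumerate_y_ions(LSVECANK_CAM, BISECTED, (1,))
        y0 = [t for t in templates if t.glycan == GlycanComposition()]
        assert len(y0) == 1
        assert y0[0].theoretical_mz == pytest.approx(920.4506, abs=1e-4)

    @given(
        a=st.integers(0, 4),
        b=st.integers(0, 4),
        c=st.integers(0, 2),
        d=st.integers(0, 2),
        n_charges=st.integers(1, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_count_formula(self, a, b, c, d, n_charges):
        glycan = GlycanComposition(a, b, c, d)
        charges = tuple(range(1, n_charges + 1))
        expected = (a + 1) * (b + 1) * (c + 1) * (d + 1) * n_charges
        assert len(enumerate_y_ions(1000.0, glycan, charges)) == expected

    def test_oxonium_examples(self):
        ions = {str(t.glycan): t.theoretical_mz for t in oxonium_ions(BISECTED)}
        assert ions["HexNAc1"] == pytest.approx(204.0867, abs=1e-4)
        assert ions["HexNAc1Hex1"] == pytest.approx(366.1395, abs=1e-4)
        assert not any("NeuAc" in key for key in ions)


class TestAnnotateMs2:
    def _spectrum(self, peaks, precursor=900.0):
        return Spectrum(
            ms_level=2,
            retention_time=27.0,
            peaks=Spectrum.sorted_peaks(peaks),
            precursor_mz=precursor,
            precursor_charge=3,
        )

    def test_planted_peak_matches_with_zero_error(self):
        templates = enumerate_y_ions(LSVECANK_CAM, GlycanComposition(1, 0, 0, 0), (1,))
        y1 = [t for t in templates if t.glycan.n_hexnac == 1][0]
        spectrum = self._spectrum([Peak(y1.theoretical_mz, 500.0)])
        annotated = annotate_ms2(spectrum, [y1], 20.0)
        assert annotated[0].matched
        assert annotated[0].error_mmu == pytest.approx(0.0, abs=1e-9)

    def test_peak_beyond_tolerance_unmatched(self):
        templates = enumerate_y_ions(1000.0, GlycanComposition(), (1,))
        spectrum = self._spectrum([Peak(templates[0].theoretical_mz + 0.025, 10.0)])
        annotated = annotate_ms2(spectrum, templates, 20.0)
        assert not annotated[0].matched

    def test_each_peak_used_at_most_once(self):
        template = enumerate_y_ions(1000.0, GlycanComposition(), (1,))[0]
        near_twin = enumerate_y_ions(1000.000001, GlycanComposition(), (1,))[0]
        spectrum = self._spectrum([Peak(template.theoretical_mz, 10.0)])
        annotated = annotate_ms2(spectrum, [template, near_twin], 20.0)
        assert sum(a.matched for a in annotated) == 1

    def test_stable_under_peak_permutation(self):
        rng = random.Random(9)
        templates = enumerate_y_ions(LSVECANK_CAM, BISECTED, (1,))
        peaks = [Peak(t.theoretical_mz, rng.uniform(10, 100)) for t in templates[:20]]
        shuffled = peaks[:]
        rng.shuffle(shuffled)
        first = annotate_ms2(self._spectrum(peaks), templates, 20.0)
        second = annotate_ms2(self._spectrum(shuffled), templates, 20.0)
        matches_a = [(a.theoretical_mz, a.matched_peak.mz if a.matched else None) for a in first]
        matches_b = [(a.theoretical_mz, a.matched_peak.mz if a.matched else None) for a in second]
        assert matches_a == matches_b

    def test_rejects_ms1_input(self):
        with pytest.raises(ValueError):
            annotate_ms2(_ms1(1.0, []), [], 20.0)

    def test_diagnostic_flag_on_heavy_hexnac_remnant(self):
        templates = enumerate_y_ions(LSVECANK_CAM, BISECTED, (1,))
        target = [
            t for t in templates if t.glycan.n_hexnac == 3 and t.glycan.n_hex == 1
        ][0]
        spectrum = self._spectrum([Peak(target.theoretical_mz, 100.0)])
        annotated = annotate_ms2(spectrum, templates, 20.0)
        assert bisecting_diagnostic_flag(annotated)

    def test_diagnostic_screen_filters_by_ppm(self):
        templates = enumerate_y_ions(LSVECANK_CAM, BISECTED, (1, 2, 3))
        hits = screen_diagnostic_mz(templates, 918.923, tol_ppm=6.0)
        for hit in hits:
            assert abs(hit.theoretical_mz - 918.923) / 918.923 * 1e6 <= 6.0
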