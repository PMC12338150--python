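"""MS1 matching, MS2 confirmation, double peaks, peak-table IO."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bilescreen import ms_screen
from bilescreen.ms_screen import (EVIDENCE_MS1, EVIDENCE_MS1_MS2, Ms2Spectrum,
                                  detect_double_peaks, match_ms1, confirm_ms2,
                                  ppm_error, read_peak_table)


def feature_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "rt_min", "mz", "intensity"])


GLYCO_DCA_MZ = 448.30685


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(GLYCO_DCA_MZ, GLYCO_DCA_MZ) == 0.0

    def test_signed_evaluation(self):
        assert ppm_error(448.30752, GLYCO_DCA_MZ) == pytest.approx(1.49, abs=0.01)

    def test_boundary_value_fails_strict_gate(self, conjugate_lib):
        err = ppm_error(448.30775, GLYCO_DCA_MZ)
        assert err == pytest.approx(2.01, abs=0.01)
        feats = feature_frame([("s1", 10.0, 448.30775, 1e4)])
        m = match_ms1(feats, conjugate_lib, tol_ppm=2.0)
        assert not (m["mz_theo"].sub(GLYCO_DCA_MZ).abs() < 1e-4).any()

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


class TestMatchMs1:
    def test_glyco_dca_feature_matches_its_isobaric_group(self, conjugate_lib):
        """A 448.30685 feature hits exactly the glycine conjugates of the
        C24H40O4 cores (CDCA/DCA/UDCA/HDCA are positional isomers)."""
        feats = feature_frame([("s1", 10.0, GLYCO_DCA_MZ, 1e5)])
        m = match_ms1(feats, conjugate_lib, tol_ppm=2.0)
        assert set(m["species_id"]) == {"CDCA-Gly", "DCA-Gly", "UDCA-Gly",
                                        "HDCA-Gly"}
        assert (m["isobaric_n"] == 4).all()
        assert (m["ppm"].abs() < 2.0).all()

    def test_standards_rt_gating(self, conjugate_lib):
        feats = feature_frame([("s1", 20.0, GLYCO_DCA_MZ, 1e5)])
        m = match_ms1(feats, conjugate_lib, tol_ppm=2.0,
                      standards_rt={"DCA-Gly": 20.1, "CDCA-Gly": 28.0},
                      rt_window=0.5)
        # DCA-Gly passes its RT window, CDCA-Gly is gated out,
        # species without standards are matched on mass alone
        assert set(m["species_id"]) == {"DCA-Gly", "UDCA-Gly", "HDCA-Gly"}

    def test_out_of_range_feature_matches_nothing(self, conjugate_lib):
        feats = feature_frame([("s1", 5.0, 290.0, 1e4)])
        assert match_ms1(feats, conjugate_lib, tol_ppm=2.0).empty

    def test_empty_library_warns(self, caplog):
        feats = feature_frame([("s1", 5.0, 400.0, 1e4)])
        with caplog.at_level(logging.WARNING):
            m = match_ms1(feats, pd.DataFrame(columns=conjugate_columns()), 2.0)
        assert m.empty
        assert "empty library" in caplog.text

    @given(st.lists(st.floats(min_value=300, max_value=700), min_size=1,
                    max_size=20),
           st.floats(min_value=0.1, max_value=1.9))
    def test_tolerance_monotonicity(self, mzs, small_tol):
        from bilescreen import bile_chem
        lib = bile_chem.library_frame(bile_chem.enumerate_conjugates())
        feats = feature_frame([("s", 1.0, mz, 1.0) for mz in mzs])
        narrow = match_ms1(feats, lib, tol_ppm=small_tol)
        wide = match_ms1(feats, lib, tol_ppm=2.0)
        narrow_keys = set(zip(narrow["feature_idx"], narrow["species_id"]))
        wide_keys = set(zip(wide["feature_idx"], wide["species_id"]))
        assert narrow_keys <= wide_keys

    def test_all_outputs_respect_tolerance(self, conjugate_lib):
        rng = np.random.default_rng(5)
        mzs = rng.uniform(350, 650, size=300)
        feats = feature_frame([("s", 1.0, mz, 1.0) for mz in mzs])
        m = match_ms1(feats, conjugate_lib, tol_ppm=2.0)
        assert (m["ppm"].abs() < 2.0).all()


def conjugate_columns():
    return ["species_id", "mz_M_minus_H", "isobaric_group"]


class TestConfirmMs2:
    @pytest.fixture
    def glyco_dca_match(self, conjugate_lib):
        feats = feature_frame([("s1", 10.0, GLYCO_DCA_MZ, 1e5)])
        m = match_ms1(feats, conjugate_lib, tol_ppm=2.0)
        return m[m["species_id"] == "DCA-Gly"].reset_index(drop=True)

    def test_two_of_three_fragments_upgrade(self, glyco_dca_match, conjugate_lib):
        spec = Ms2Spectrum("s1", 10.1, 446.0, 40.0,
                           np.array([[74.02475, 1e4], [391.28538, 2e4]]))
        out = confirm_ms2(glyco_dca_match, [spec], conjugate_lib)
        assert out.loc[0, "evidence"] == EVIDENCE_MS1_MS2
        assert out.loc[0, "fragments_found"] == "aa_anion,aa_loss"

    def test_unrelated_peaks_stay_ms1_only(self, glyco_dca_match, conjugate_lib):
        spec = Ms2Spectrum("s1", 10.0, 446.0, 40.0,
                           np.array([[100.0, 1e4], [200.0, 1e4]]))
        out = confirm_ms2(glyco_dca_match, [spec], conjugate_lib)
        assert out.loc[0, "evidence"] == EVIDENCE_MS1

    def test_wrong_precursor_window_not_searched(self, glyco_dca_match,
                                                 conjugate_lib):
        """448.31 lives in the 446-centered window (426-466), not the 370 one."""
        spec = Ms2Spectrum("s1", 10.0, 370.0, 40.0,
                           np.array([[74.02475, 1e4], [391.28538, 2e4]]))
        out = confirm_ms2(glyco_dca_match, [spec], conjugate_lib)
        assert out.loc[0, "evidence"] == EVIDENCE_MS1

    def test_rt_window_gates_spectra(self, glyco_dca_match, conjugate_lib):
        spec = Ms2Spectrum("s1", 12.0, 446.0, 40.0,
                           np.array([[74.02475, 1e4], [391.28538, 2e4]]))
        out = confirm_ms2(glyco_dca_match, [spec], conjugate_lib, rt_window=0.5)
        assert out.loc[0, "evidence"] == EVIDENCE_MS1

    def test_three_of_three_rule(self, glyco_dca_match, conjugate_lib):
        spec = Ms2Spectrum("s1", 10.0, 446.0, 40.0,
                           np.array([[74.02475, 1e4], [391.28538, 2e4]]))
        out = confirm_ms2(glyco_dca_match, [spec], conjugate_lib, min_fragments=3)
        assert out.loc[0, "evidence"] == EVIDENCE_MS1

    def test_shrinking_frag_tol_never_upgrades(self, glyco_dca_match,
                                               conjugate_lib):
        # fragment peaks placed ~8 ppm off: found at 10 ppm, lost at 1 ppm
        spec = Ms2Spectrum("s1", 10.0, 446.0, 40.0, np.array(
            [[74.02475 * (1 + 8e-6), 1e4], [391.28538 * (1 + 8e-6), 2e4]]))
        wide = confirm_ms2(glyco_dca_match, [spec], conjugate_lib,
                           frag_tol_ppm=10.0)
        narrow = confirm_ms2(glyco_dca_match, [spec], conjugate_lib,
                             frag_tol_ppm=1.0)
        assert wide.loc[0, "evidence"] == EVIDENCE_MS1_MS2
        assert narrow.loc[0, "evidence"] == EVIDENCE_MS1


class TestDoublePeaks:
    def match_rows(self, rts, species="CDCA-Ala"):
        return pd.DataFrame({"sample_id": "s1", "species_id": species,
                             "rt_min": rts})

    def test_simple_pair(self):
        pairs = detect_double_peaks(self.match_rows([12.1, 13.0]), min_sep=0.3)
        assert len(pairs) == 1
        assert pairs.loc[0, "delta_rt"] == pytest.approx(0.9)

    def test_single_feature_no_pair(self):
        assert detect_double_peaks(self.match_rows([12.1]), min_sep=0.3).empty

    def test_subthreshold_adjacent_pair_suppressed(self):
        pairs = detect_double_peaks(self.match_rows([10.0, 10.1, 12.0]),
                                    min_sep=0.3)
        assert len(pairs) == 1
        assert (pairs.loc[0, "rt_first"], pairs.loc[0, "rt_second"]) == (10.1, 12.0)


class TestPeakTableIO:
    HEADER = "sample_id,ms_level,rt_min,mz,intensity,precursor_center,isolation_width\n"

    def test_well_formed_file(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(self.HEADER
                     + "s1,1,10.0,448.3,100,,\n"
                     + "s1,1,11.0,500.1,200,,\n"
                     + "s1,1,12.0,390.2,300,,\n")
        features, spectra = read_peak_table(p)
        assert len(features) == 3 and spectra == []

    def test_malformed_rows_dropped_and_logged(self, tmp_path, caplog):
        p = tmp_path / "peaks.csv"
        p.write_text(self.HEADER
                     + "s1,1,10.0,448.3,100,,\n"
                     + "s1,1,11.0,500.1,-5,,\n")   # negative intensity
        with caplog.at_level(logging.WARNING):
            features, _ = read_peak_table(p)
        assert len(features) == 1
        assert "line(s) [3]" in caplog.text

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("sample_id,ms_level,rt_min,mz,precursor_center,isolation_width\n")
        with pytest.raises(ValueError, match="intensity"):
            read_peak_table(p)

    def test_header_only_warns_empty(self, tmp_path, caplog):
        p = tmp_path / "peaks.csv"
        p.write_text(self.HEADER)
        with caplog.at_level(logging.WARNING):
            features, spectra = read_peak_table(p)
        assert features.empty and spectra == []
        assert "no rows" in caplog.text

    def test_ms2_rows_group_into_spectra(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text(self.HEADER
                     + "s1,2,10.0,74.02,100,446,40\n"
                     + "s1,2,10.0,391.28,200,446,40\n"
                     + "s1,2,12.0,164.07,150,522,40\n")
        _, spectra = read_peak_table(p)
        assert len(spectra) == 2
        first = next(s for s in spectra if s.rt_min == 10.0)
        assert first.peaks.shape == (2, 2)
        assert first.covers(448.3) and not first.covers(370.0)
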