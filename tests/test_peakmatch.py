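"""Peak-list parsing, proteoform matching, window screening, oxoforms."""

import numpy as np
import pytest

from crpforge import (
    MassOptions,
    PeakList,
    SimConfig,
    TC1_SEQUENCE,
    enumerate_oxoforms,
    match_peaks,
    mz,
    oxidation_fraction,
    peptide_mass,
    read_peaklist,
    screen_window,
    simulate_peaklist,
)

TC1_MZ1 = mz(peptide_mass(TC1_SEQUENCE, MassOptions(n_disulfides=4)), 1)  # ~3369.135


class TestReadPeaklist:
    def test_two_column_whitespace(self, tmp_path):
        p = tmp_path / "peaks.txt"
        p.write_text("3369.1 1000\n2000.0 50\n")
        pl = read_peaklist(p)
        assert len(pl) == 2
        assert pl.peaks[0][0] == 2000.0  # sorted ascending

    def test_comma_delimited_with_header_and_comments(self, tmp_path):
        p = tmp_path / "peaks.csv"
        p.write_text("mz,intensity\n# calibrant\n3369.1,1000\n\n2000.0,50\n")
        assert len(read_peaklist(p)) == 2

    def test_non_numeric_field_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("3369.1 1000\noops here\n")
        with pytest.raises(ValueError, match=":2"):
            read_peaklist(p)

    def test_empty_file_warns_and_returns_empty(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert len(read_peaklist(p)) == 0

    def test_synthetic_peak_count_matches_truth(self, tmp_path):
        cfg = SimConfig(seed=2, n_noise_peaks=10)
        pl, truth = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
        p = tmp_path / "sim.txt"
        p.write_text("".join(f"{m:.6f}\t{i:.3f}\n" for m, i in pl.peaks))
        assert len(read_peaklist(p)) == len(truth)


class TestEnumerateOxoforms:
    def test_tc1_three_met_gives_four_forms_16da_apart(self):
        forms = enumerate_oxoforms(TC1_SEQUENCE, n_disulfides=4)
        assert len(forms) == 4
        masses = [f.mass for f in forms]
        assert all(b - a == pytest.approx(15.9949, abs=1e-4)
                   for a, b in zip(masses, masses[1:]))

    def test_met_free_peptide_single_form(self):
        assert len(enumerate_oxoforms("CGGACGGAC")) == 1

    def test_max_ox_zero(self):
        assert len(enumerate_oxoforms(TC1_SEQUENCE, max_ox=0)) == 1

    def test_alkylated_form_carries_carbamidomethyl_mass(self):
        plain = enumerate_oxoforms(TC1_SEQUENCE, n_disulfides=0, max_ox=0)[0]
        alk = enumerate_oxoforms(TC1_SEQUENCE, n_disulfides=0, max_ox=0, alkylated=True)[0]
        assert alk.mass - plain.mass == pytest.approx(8 * 57.021464, abs=1e-4)


class TestMatchPeaks:
    def test_tc1_peak_within_half_dalton(self):
        pl = PeakList(peaks=[(3369.14, 1000.0)])
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4, max_ox=0)
        (hit,) = match_peaks(pl, forms, tol_da=0.5)
        assert hit.error_da == pytest.approx(3369.14 - TC1_MZ1, abs=1e-6)
        assert abs(hit.error_da) < 0.01

    def test_no_peak_in_tolerance(self):
        pl = PeakList(peaks=[(3000.0, 10.0)])
        forms = enumerate_oxoforms(TC1_SEQUENCE, n_disulfides=4, max_ox=0)
        assert match_peaks(pl, forms) == []

    def test_tie_breaks_to_higher_intensity(self):
        target = TC1_MZ1
        pl = PeakList(peaks=[(target - 0.1, 10.0), (target + 0.1, 500.0)])
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="t", n_disulfides=4, max_ox=0)
        (hit,) = match_peaks(pl, forms, tol_da=0.5)
        assert hit.peak_intensity == 500.0

    def test_planted_base_and_satellite_matched(self):
        cfg = SimConfig(seed=4, mass_noise_ppm=30, ox_fraction=0.27, n_noise_peaks=20)
        pl, _ = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4)
        hits = match_peaks(pl, forms)
        assert {h.proteoform.n_met_ox for h in hits} >= {0, 1}

    def test_recovery_under_low_mass_noise(self):
        """Planted proteoforms are recovered across seeds when the mass
        noise sigma is well inside the matching tolerance."""
        recovered = 0
        for seed in range(30):
            cfg = SimConfig(seed=seed, mass_noise_ppm=30, ox_fraction=0.27, n_noise_peaks=5)
            pl, _ = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
            forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4)
            hits = match_peaks(pl, forms)
            if {h.proteoform.n_met_ox for h in hits} >= {0, 1}:
                recovered += 1
        assert recovered == 30


class TestScreenWindow:
    def test_keeps_only_in_window_peak(self):
        pl = PeakList(peaks=[(1500.0, 10.0), (3369.1, 100.0), (6000.0, 10.0)])
        kept = screen_window(pl, 2000, 5000)
        assert [m for m, _ in kept.peaks] == [3369.1]

    def test_zero_threshold_keeps_all_in_window(self):
        pl = PeakList(peaks=[(2500.0, 1.0), (3369.1, 100.0)])
        assert len(screen_window(pl, 2000, 5000, min_rel_intensity=0.0)) == 2

    def test_relative_intensity_threshold(self):
        pl = PeakList(peaks=[(2500.0, 1.0), (3369.1, 100.0)])
        kept = screen_window(pl, 2000, 5000, min_rel_intensity=0.05)
        assert [m for m, _ in kept.peaks] == [3369.1]

    def test_synthetic_noise_removed_planted_kept(self):
        cfg = SimConfig(seed=6, n_noise_peaks=50, noise_rel_intensity=0.01)
        pl, truth = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
        kept = screen_window(pl, 2000, 5000, min_rel_intensity=0.05)
        assert len(kept) == len(truth[truth.base_id != "noise"])

    def test_commutes_with_matching(self):
        cfg = SimConfig(seed=8, n_noise_peaks=25)
        pl, _ = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4)
        direct = match_peaks(screen_window(pl, 2000, 5000), forms)
        full = [
            h for h in match_peaks(pl, forms)
            if 2000 <= h.peak_mz - 1.007276 <= 5000
        ]
        assert [(h.peak_mz, h.proteoform.n_met_ox) for h in direct] == [
            (h.peak_mz, h.proteoform.n_met_ox) for h in full
        ]


class TestOxidationFraction:
    def test_73_27_intensity_split(self):
        pl = PeakList(peaks=[(TC1_MZ1, 73.0), (TC1_MZ1 + 15.9949, 27.0)])
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4, max_ox=1)
        frac = oxidation_fraction(match_peaks(pl, forms))
        assert frac[1] == pytest.approx(0.27)
        assert frac[0] == pytest.approx(0.73)

    def test_single_form_is_unit_fraction(self):
        pl = PeakList(peaks=[(TC1_MZ1, 50.0)])
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4, max_ox=0)
        assert oxidation_fraction(match_peaks(pl, forms)) == {0: 1.0}

    def test_fractions_sum_to_one(self):
        cfg = SimConfig(seed=9, ox_fraction=0.27)
        pl, _ = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
        forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4)
        frac = oxidation_fraction(match_peaks(pl, forms))
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_mixed_base_ids_rejected(self):
        pl = PeakList(peaks=[(TC1_MZ1, 50.0)])
        a = match_peaks(pl, enumerate_oxoforms(TC1_SEQUENCE, base_id="a", n_disulfides=4, max_ox=0))
        b = match_peaks(pl, enumerate_oxoforms(TC1_SEQUENCE, base_id="b", n_disulfides=4, max_ox=0))
        with pytest.raises(ValueError):
            oxidation_fraction(a + b)

    def test_monte_carlo_recovers_planted_fraction(self):
        """Across 20 replicate synthetic spectra with 5% intensity CV the
        mean estimated 1-ox fraction stays within 0.03 of the planted 0.27."""
        rng = np.random.default_rng(123)
        estimates = []
        for rep in range(20):
            cfg = SimConfig(seed=1000 + rep, ox_fraction=0.27, mass_noise_ppm=50)
            pl, _ = simulate_peaklist([("tC1", TC1_SEQUENCE)], cfg)
            jittered = PeakList(
                peaks=[(m, i * max(rng.normal(1.0, 0.05), 0.0)) for m, i in pl.peaks],
                source=pl.source,
            )
            forms = enumerate_oxoforms(TC1_SEQUENCE, base_id="tC1", n_disulfides=4)
            frac = oxidation_fraction(match_peaks(jittered, forms))
            estimates.append(frac.get(1, 0.0))
        assert abs(float(np.mean(estimates)) - 0.27) < 0.03
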