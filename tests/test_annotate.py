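"""Annotation at ±2 ppm, isotopic-interference flags and class profiles."""

import numpy as np
import pytest

import kmdprint as kp
from kmdprint.annotate import (
    TYPE2_GAP_DA,
    AnnotatedPeak,
    annotate_peaks,
    class_intensity_profile,
    flag_type2_interference,
    split_bimodal_profile,
)
from kmdprint.chem import C13_C12_DELTA
from kmdprint.spectra import PeakList


def _peaklist(mzs, intensities=None):
    mzs = np.asarray(sorted(mzs), dtype=float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return PeakList(mz=mzs, intensity=np.asarray(intensities, dtype=float))


class TestAssignment:
    def test_within_tolerance_assigned(self, targets):
        mz0 = 433.380472  # sodiated squalene
        peaks = _peaklist([mz0 * (1 + 1e-6)])
        [ann] = annotate_peaks(peaks, targets)
        assert ann.assigned
        assert ann.target.composition.formula() == "C30H50Na"
        assert ann.ppm_error == pytest.approx(1.0, abs=0.05)

    def test_outside_tolerance_unassigned(self, targets):
        peaks = _peaklist([433.380472 * (1 + 3e-6)])
        [ann] = annotate_peaks(peaks, targets)
        assert not ann.assigned

    def test_order_independent(self, targets, day7_sample):
        peaks = day7_sample.peaks
        ann = annotate_peaks(peaks, targets)
        shuffled = sorted(targets, key=lambda t: t.label)
        ann2 = annotate_peaks(peaks, shuffled)
        assert [
            a.target.composition if a.assigned else None for a in ann
        ] == [a.target.composition if a.assigned else None for a in ann2]

    def test_sodium_wins_tie_against_potassium(self, targets):
        # Place a peak exactly between a Na target and a hypothetical K
        # interpretation: at the Na target's own m/z the Na entry must win
        # even though the K twin of a lighter species could be in range.
        na = next(t for t in targets if t.composition.formula() == "C30H50Na")
        [ann] = annotate_peaks(_peaklist([na.mz]), targets)
        assert ann.target.n_K == 0

    def test_empty_peaklist(self, targets):
        assert annotate_peaks(_peaklist([]), targets) == []

    def test_recovery_on_simulated_spectra(self, timecourse_samples, targets):
        """>=99% of interference-free ground-truth peaks are annotated with
        the correct composition (<=1 ppm-scale jitter, +-2 ppm search)."""
        tmz = np.array([t.mz for t in targets])
        by_formula = {t.composition.formula(): t for t in targets}
        ok = bad = 0
        for sample in timecourse_samples[:6]:
            ann = annotate_peaks(sample.peaks, targets)
            ann_by_mz = dict(zip(np.round(sample.peaks.mz, 9), ann))
            for pmz, grp in sample.truth.groupby("peak_mz"):
                formulas = set(grp.formula)
                if len(formulas) != 1:
                    continue  # co-merged events: not interference-free
                row = grp.iloc[0]
                if not row.annotatable or row.isotope != 0:
                    continue
                target = by_formula.get(row.formula)
                assert target is not None, f"simulated ion {row.formula} not in list"
                ppm_gap = np.sort(np.abs(tmz - target.mz) / target.mz * 1e6)[1]
                if ppm_gap <= 4.0:
                    continue  # another theoretical ion too close
                result = ann_by_mz[round(pmz, 9)]
                if (
                    result.assigned
                    and result.target.composition.formula() == row.formula
                ):
                    ok += 1
                else:
                    bad += 1
        assert ok + bad > 500
        assert ok / (ok + bad) >= 0.99


class TestType2Flag:
    def test_closed_form_gap(self):
        # Second 13C isotopologue vs one-more-saturation monoisotopic ion.
        assert round(TYPE2_GAP_DA, 4) == 0.0089
        h2 = 2 * 1.00782503207
        assert abs(2 * C13_C12_DELTA - h2) == pytest.approx(0.0089, abs=5e-5)

    def test_lone_peak_unflagged(self, targets):
        ann = annotate_peaks(_peaklist([433.380472]), targets)
        flagged = flag_type2_interference(ann)
        assert "type2_isotope_risk" not in flagged[0].flags

    def test_intense_unsaturated_neighbor_flags(self, targets):
        # A TG 50:1 ion accompanied by a 10x more intense ion two 13C units
        # lighter: the neighbor's expected M+2 (binomial, ~C53) exceeds 20%
        # of the assigned peak -> flag.
        tg50_1 = kp.ion_mz(kp.ElementalComposition.from_formula("C53H100O6Na"))
        neighbor = tg50_1 - 2 * C13_C12_DELTA
        peaks = _peaklist([neighbor, tg50_1], [10.0, 1.0])
        ann = annotate_peaks(peaks, targets)
        flagged = flag_type2_interference(ann)
        target_peak = [a for a in flagged if abs(a.mz - tg50_1) < 1e-6][0]
        assert target_peak.assigned
        assert "type2_isotope_risk" in target_peak.flags

    def test_weak_neighbor_not_flagged(self, targets):
        tg50_1 = kp.ion_mz(kp.ElementalComposition.from_formula("C53H100O6Na"))
        neighbor = tg50_1 - 2 * C13_C12_DELTA
        peaks = _peaklist([neighbor, tg50_1], [0.5, 1.0])
        flagged = flag_type2_interference(annotate_peaks(peaks, targets))
        target_peak = [a for a in flagged if abs(a.mz - tg50_1) < 1e-6][0]
        assert "type2_isotope_risk" not in target_peak.flags


class TestClassProfiles:
    def test_absent_class_gives_empty_profile(self, targets):
        ann = annotate_peaks(_peaklist([433.380472]), targets)
        profile = class_intensity_profile(ann, n_O=8, dbe=9)
        assert len(profile) == 0

    def test_invalid_class_parameters_rejected(self):
        with pytest.raises(ValueError):
            class_intensity_profile([], n_O=-1, dbe=3)

    def test_day7_o7_profile_is_bimodal(self, day7_sample, targets):
        """Day-7 O7/DBE-4 class splits into an ozonolysis-aldehyde mode
        (m/z 650-730) and an epoxide mode (m/z 780-870)."""
        ann = annotate_peaks(day7_sample.peaks, targets)
        profile = class_intensity_profile(ann, n_O=7, dbe=4)
        split = split_bimodal_profile(profile)
        assert split.is_bimodal
        low, high = split.modes
        low_peak = low.mz[np.argmax(low.intensity)]
        high_peak = high.mz[np.argmax(high.intensity)]
        assert 650 <= low_peak <= 730
        assert 780 <= high_peak <= 870
        # separated by the ~10-carbon omega-cleavage offset
        low_c = low.carbon_numbers[np.argmax(low.intensity)]
        high_c = high.carbon_numbers[np.argmax(high.intensity)]
        assert high_c - low_c >= 8

    def test_fresh_o6_profile_is_unimodal(self, day0_sample, targets):
        ann = annotate_peaks(day0_sample.peaks, targets)
        profile = class_intensity_profile(ann, n_O=6, dbe=4)
        split = split_bimodal_profile(profile)
        assert not split.is_bimodal


class TestBimodalSplit:
    @staticmethod
    def _profile_from(carbons, intensities):
        carbons = np.asarray(carbons, dtype=int)
        return kp.ClassProfile(
            n_O=7, dbe=4, n_Na=1, n_K=0,
            carbon_numbers=carbons,
            mz=14.0 * carbons + 100.0,
            intensity=np.asarray(intensities, dtype=float),
        )

    def test_two_gaussians_split_at_true_valley(self):
        carbons = np.arange(30, 61)
        low = 100.0 * np.exp(-0.5 * ((carbons - 38) / 2.5) ** 2)
        high = 80.0 * np.exp(-0.5 * ((carbons - 52) / 2.5) ** 2)
        split = split_bimodal_profile(self._profile_from(carbons, low + high))
        assert split.is_bimodal
        assert abs(split.valley_carbon - 45) <= 1
        assert split.modes[0].carbon_numbers.max() <= split.valley_carbon

    def test_strictly_unimodal_returns_single_mode(self):
        carbons = np.arange(40, 55)
        single = 50.0 * np.exp(-0.5 * ((carbons - 47) / 3.0) ** 2)
        split = split_bimodal_profile(self._profile_from(carbons, single))
        assert len(split.modes) == 1
        assert split.valley_carbon is None

    def test_short_profile_not_split(self):
        split = split_bimodal_profile(
            self._profile_from([40, 41, 42], [1.0, 5.0, 1.0])
        )
        assert len(split.modes) == 1


class TestFlags:
    def test_potassium_adduct_flag(self, targets):
        k_target = next(t for t in targets if t.composition.formula() == "C30H50K")
        ann = annotate_peaks(_peaklist([k_target.mz]), targets)
        assert "potassium_adduct" in ann[0].flags

    def test_shared_composition_flagged_ambiguous(self, targets):
        shared = next(
            t for t in targets if t.composition.formula() == "C40H74O7Na"
        )
        ann = annotate_peaks(_peaklist([shared.mz]), targets)
        assert "multi_class_ambiguous" in ann[0].flags
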