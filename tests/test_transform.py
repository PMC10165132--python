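"""Noise-removal and augmentation transforms."""

import numpy as np
import pytest

from specnoise import (
    JitterModel,
    MatchConfig,
    NoiseConfig,
    Peak,
    Peptide,
    Spectrum,
    UnknownPeakModel,
    add_predicted_missing_peaks,
    augment_predicted,
    classify_spectrum,
    enumerate_backbone_ions,
    match_ions,
    predict_spectrum,
    remove_non_backbone,
    replace_intensity,
    shuffle_non_backbone,
    snap_mz,
)
from specnoise.transform import apply_jitter


class TestSnapMz:
    def test_exact_spectrum_is_fixed_point(self, clean_spectrum):
        out = snap_mz(clean_spectrum)
        assert [p.mz for p in out.peaks] == [p.mz for p in clean_spectrum.peaks]

    def test_offset_peak_moved_to_theoretical(self, peptide10):
        ions = enumerate_backbone_ions(peptide10, charges=(1,), losses=("none",))
        y3 = next(i for i in ions if i.series == "y" and i.index == 3)
        spec = Spectrum("t", 500.0, 2, [Peak(y3.mz + 0.03, 1.0)], peptide10)
        out = snap_mz(spec)
        assert out.peaks[0].mz == pytest.approx(y3.mz, abs=1e-9)

    def test_snap_then_rematch_zero_deltas(self, noisy_corpus):
        """Snapping is idempotent and puts every matched peak exactly on a
        theoretical m/z, so rematching finds zero-delta pairings."""
        from specnoise import enumerate_internal_fragments

        _, real = noisy_corpus
        config = MatchConfig()
        for spec in real[:8]:
            snapped = snap_mz(spec, config)
            assert snap_mz(snapped, config).peaks == snapped.peaks
            pep = spec.peptide
            grid = {round(i.mz, 9) for i in enumerate_backbone_ions(pep)}
            grid |= {round(f.mass, 9)
                     for f in enumerate_internal_fragments(pep, 1)}
            ions = enumerate_backbone_ions(pep)
            matched_before = {r.peak_index
                              for r in match_ions(spec, ions, config.tolerance)}
            on_grid = sum(1 for p in snapped.peaks if round(p.mz, 9) in grid)
            assert on_grid >= len(matched_before)
            after = match_ions(snapped, ions, config.tolerance)
            assert sum(1 for r in after if r.delta == 0) >= len(matched_before) * 0.9

    def test_unlabelled_rejected(self):
        with pytest.raises(ValueError):
            snap_mz(Spectrum("t", 500.0, 2, [Peak(100.0, 1.0)]))


class TestReplaceIntensity:
    def test_empty_prediction_is_identity(self, clean_spectrum, peptide10):
        empty = Spectrum("t", 500.0, 2, [], peptide10)
        out = replace_intensity(clean_spectrum, empty)
        assert out.peaks == clean_spectrum.peaks

    def test_full_prediction_replaces_all(self, clean_spectrum):
        doubled = clean_spectrum.with_peaks(
            [Peak(p.mz, p.intensity * 2) for p in clean_spectrum.peaks]
        )
        out = replace_intensity(doubled, clean_spectrum)
        for got, want in zip(out.peaks, clean_spectrum.peaks):
            assert got.intensity == pytest.approx(want.intensity)

    def test_partial_prediction_only_covered_ions(self, peptide10):
        ions = enumerate_backbone_ions(peptide10, charges=(1,), losses=("none",))
        y = sorted((i for i in ions if i.series == "y"), key=lambda i: i.index)
        observed = Spectrum("t", 500.0, 2,
                            [Peak(i.mz, 0.5) for i in y[:4]], peptide10)
        predicted = Spectrum("t", 500.0, 2,
                             [Peak(y[0].mz, 0.9), Peak(y[1].mz, 0.8)], peptide10)
        out = replace_intensity(observed, predicted)
        by_mz = {p.mz: p.intensity for p in out.peaks}
        assert by_mz[y[0].mz] == pytest.approx(0.9)
        assert by_mz[y[1].mz] == pytest.approx(0.8)
        assert by_mz[y[2].mz] == pytest.approx(0.5)

    def test_peptide_mismatch_rejected(self, clean_spectrum):
        other = predict_spectrum(Peptide("AAAAK"))
        with pytest.raises(ValueError):
            replace_intensity(clean_spectrum, other)


class TestRemoveNonBackbone:
    def test_pure_ladder_unchanged(self, clean_spectrum):
        out = remove_non_backbone(clean_spectrum)
        assert len(out.peaks) == len(clean_spectrum.peaks)

    def test_unknown_peaks_removed(self, clean_spectrum):
        noisy = clean_spectrum.with_peaks(
            list(clean_spectrum.peaks)
            + [Peak(3000.0, 0.1), Peak(3100.0, 0.1), Peak(3200.0, 0.1)]
        )
        out = remove_non_backbone(noisy)
        assert len(out.peaks) == len(clean_spectrum.peaks)

    def test_output_classifies_pure_backbone(self, noisy_corpus):
        _, real = noisy_corpus
        for spec in real[:5]:
            out = remove_non_backbone(spec)
            fr = classify_spectrum(out).fractions
            if out.peaks:
                assert fr["backbone_1plus"] + fr["backbone_2plus"] == pytest.approx(1.0)
                assert fr["unknown"] == 0.0


class TestShuffleNonBackbone:
    def test_single_spectrum_unchanged(self, noisy_corpus):
        _, real = noisy_corpus
        out = shuffle_non_backbone(real[:1], rng=0)
        assert [p.mz for p in out[0].peaks] == [p.mz for p in real[0].peaks]

    def test_bin_multiset_conserved(self, noisy_corpus):
        _, real = noisy_corpus
        out = shuffle_non_backbone(real, n_bins=5, rng=1)
        before = sorted(round(p.mz, 9) for s in real for p in s.peaks)
        after = sorted(round(p.mz, 9) for s in out for p in s.peaks)
        assert before == after

    def test_backbone_peaks_stay_home(self, noisy_corpus):
        _, real = noisy_corpus
        out = shuffle_non_backbone(real, n_bins=5, rng=2)
        for orig, shuf in zip(real, out):
            orig_backbone = {
                rec.peak_index
                for cat in ("backbone_1plus", "backbone_2plus")
                for rec in classify_spectrum(orig).records[cat]
            }
            orig_mzs = {orig.peaks[i].mz for i in orig_backbone}
            shuf_mzs = {p.mz for p in shuf.peaks}
            assert orig_mzs <= shuf_mzs


class TestAddPredictedMissing:
    def test_subset_prediction_unchanged(self, clean_spectrum):
        out = add_predicted_missing_peaks(clean_spectrum, clean_spectrum)
        assert len(out.peaks) == len(clean_spectrum.peaks)

    def test_missing_y3_inserted(self, peptide10, clean_spectrum):
        ions = enumerate_backbone_ions(peptide10, charges=(1,), losses=("none",))
        y3 = next(i for i in ions if i.series == "y" and i.index == 3)
        gutted = clean_spectrum.with_peaks(
            [p for p in clean_spectrum.peaks if abs(p.mz - y3.mz) > 0.01]
        )
        out = add_predicted_missing_peaks(gutted, clean_spectrum)
        assert any(abs(p.mz - y3.mz) < 1e-9 for p in out.peaks)
        assert len(out.peaks) == len(clean_spectrum.peaks)


class TestAugment:
    def test_all_off_is_identity(self, clean_spectrum):
        out = augment_predicted(clean_spectrum, NoiseConfig.all_off(), rng=0)
        assert out.peaks == clean_spectrum.peaks

    def test_rempeaks_count(self, peptide10, clean_spectrum):
        config = NoiseConfig(missing_peaks=True)
        out = augment_predicted(clean_spectrum, config, rng=0)
        # l=10 -> n=5 peaks removed
        assert len(out.peaks) == len(clean_spectrum.peaks) - 5

    def test_full_stack_deterministic(self, clean_spectrum):
        config = NoiseConfig(
            jitter=JitterModel(method=2),
            missing_peaks=True,
            unknown=UnknownPeakModel(method="combined"),
            unknown_count=20,
            seed=123,
        )
        a = augment_predicted(clean_spectrum, config)
        b = augment_predicted(clean_spectrum, config)
        assert a.peaks == b.peaks

    def test_output_sorted_positive(self, clean_spectrum):
        config = NoiseConfig(
            jitter=JitterModel(method=1),
            unknown=UnknownPeakModel(method="random_aa"),
            unknown_count=50,
        )
        out = augment_predicted(clean_spectrum, config, rng=3)
        mzs = [p.mz for p in out.peaks]
        assert mzs == sorted(mzs)
        assert all(m > 0 for m in mzs)

    def test_jitter_perturbs_every_peak(self, clean_spectrum):
        out = apply_jitter(clean_spectrum, JitterModel(method=1), rng=5)
        assert len(out.peaks) == len(clean_spectrum.peaks)
        moved = sum(
            1 for a, b in zip(sorted(p.mz for p in clean_spectrum.peaks),
                              sorted(p.mz for p in out.peaks))
            if a != b
        )
        assert moved == len(out.peaks)
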