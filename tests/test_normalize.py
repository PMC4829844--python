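"""Normalization chain: binning, total normalization, GC correction,
control reference and log2 ratios."""

import numpy as np
import pandas as pd
import pytest

import chordcna as cc
from chordcna.errors import DataError
from chordcna.normalize import (bin_counts, build_reference, correct_sample,
                                gc_correct, log2_ratio_profile,
                                normalize_sample, total_normalize)


class TestBinCounts:
    def test_half_open_bin_assignment(self, toy_genome, tmp_path):
        bed = tmp_path / "frags.bed"
        # start 0 -> bin 0; start exactly on the boundary -> right-hand bin
        bed.write_text("1\t0\t150\n1\t100000\t100150\n1\t99999\t100149\n")
        counts, skipped = bin_counts(bed, toy_genome)
        assert skipped == 0
        idx = toy_genome.chrom_bins("1")
        assert counts.counts[idx[0]] == 2
        assert counts.counts[idx[1]] == 1

    def test_counts_concentrate_in_one_bin(self, toy_genome, tmp_path):
        bed = tmp_path / "frags.bed"
        bed.write_text("".join("2\t500100\t500250\n" for _ in range(10)))
        counts, _ = bin_counts(bed, toy_genome)
        idx = toy_genome.chrom_bins("2")
        assert counts.counts[idx[5]] == 10
        assert counts.counts.sum() == 10

    def test_unknown_chromosome_skipped_and_counted(self, toy_genome, tmp_path):
        bed = tmp_path / "frags.bed"
        bed.write_text("1\t0\t150\nMT\t5\t155\n")
        counts, skipped = bin_counts(bed, toy_genome)
        assert skipped == 1
        assert counts.counts.sum() == 1

    def test_malformed_line_reports_position(self, toy_genome, tmp_path):
        bed = tmp_path / "frags.bed"
        bed.write_text("1\t0\t150\n1\tnot_a_number\t99\n")
        with pytest.raises(DataError, match="line 2"):
            bin_counts(bed, toy_genome)

    def test_empty_input_rejected(self, toy_genome, tmp_path):
        bed = tmp_path / "frags.bed"
        bed.write_text("")
        with pytest.raises(DataError):
            bin_counts(bed, toy_genome)


class TestTotalNormalize:
    def test_rates_sum_to_one(self):
        rates = total_normalize(np.array([2, 2]))
        assert np.allclose(rates, [0.5, 0.5])
        rng = np.random.default_rng(0)
        c = rng.integers(0, 100, size=50)
        assert total_normalize(c).sum() == pytest.approx(1.0)

    def test_masked_bin_excluded_from_denominator(self):
        mask = np.array([True, True, False])
        rates = total_normalize(np.array([2, 2, 100]), mask)
        assert np.allclose(rates, [0.5, 0.5, 0.0])

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            total_normalize(np.zeros(10))


class TestGCCorrect:
    def test_pure_gc_signal_flattened(self, toy_genome):
        """Rates that are exactly a smooth function of GC correct to ~1."""
        gc = toy_genome.bins["gc"].to_numpy()
        rates = 1.0 - 2.0 * (gc - 0.45) ** 2
        corrected = gc_correct(rates / rates.sum(), gc)
        dev = np.abs(corrected.rates[corrected.mask] - 1.0)
        assert dev.max() < 0.02

    def test_flat_rates_survive_unchanged(self, toy_genome):
        gc = toy_genome.bins["gc"].to_numpy()
        rates = np.full(len(gc), 1.0 / len(gc))
        corrected = gc_correct(rates, gc)
        assert np.allclose(corrected.rates[corrected.mask], 1.0, atol=1e-6)

    def test_correction_removes_gc_correlation(self, toy_genome):
        # monotone bias over the observed GC range -> strong raw correlation;
        # autosomes only, so haploid X/Y copy-number structure (which GC
        # correction must leave alone) does not enter the correlation
        from chordcna.genome import AUTOSOMES
        s = cc.simulate_sample(toy_genome, cc.balanced_spec(),
                               gc_bias=cc.GCBias(peak=0.25, amplitude=0.4,
                                                 span=0.4), seed=2)
        auto = toy_genome.bins["chrom"].isin(AUTOSOMES).to_numpy()
        mask = ~toy_genome.par_mask & auto
        gc = toy_genome.bins["gc"].to_numpy()
        raw = total_normalize(s, mask)
        raw_corr = np.corrcoef(raw[mask], gc[mask])[0, 1]
        assert abs(raw_corr) > 0.3
        corrected = gc_correct(raw, gc, mask)
        m = corrected.mask
        assert abs(np.corrcoef(corrected.rates[m], gc[m])[0, 1]) < 0.05

    def test_idempotent_up_to_tolerance(self, toy_genome):
        s = cc.simulate_sample(toy_genome, cc.balanced_spec(), seed=4)
        once = correct_sample(s, toy_genome)
        twice = gc_correct(once.rates, toy_genome.bins["gc"].to_numpy(), once.mask)
        m = once.mask & twice.mask
        rms = np.sqrt(np.mean((twice.rates[m] - once.rates[m]) ** 2))
        assert rms < 0.01

    def test_degenerate_gc_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            corrected = gc_correct(np.full(100, 0.01), np.full(100, 0.5))
        assert np.allclose(corrected.rates, 1.0)


class TestReference:
    def test_median_of_identical_controls(self, toy_genome, panel_corrected,
                                          control_panel):
        ref, mask = build_reference(control_panel, toy_genome,
                                    corrected=panel_corrected)
        stacked = np.stack([c.rates for c in panel_corrected])
        assert np.allclose(ref[mask], np.median(stacked, axis=0)[mask])

    def test_outlier_control_does_not_move_reference(self, toy_genome,
                                                     control_panel, reference):
        import copy
        from chordcna.normalize import correct_panel
        panel2 = cc.simulate_control_panel(toy_genome, 30, seed=3)
        # corrupt one control by doubling one chromosome
        idx = toy_genome.chrom_bins("5")
        panel2.samples[0].counts[idx] *= 2
        panel2.samples[0].total_reads = int(panel2.samples[0].counts.sum())
        ref2, _ = build_reference(panel2, toy_genome)
        other = np.setdiff1d(np.arange(toy_genome.n_bins), idx)
        ok = reference[1] & np.isin(np.arange(toy_genome.n_bins), other)
        assert np.abs(ref2[ok] - reference[0][ok]).max() < 0.05

    def test_par_bins_masked(self, toy_genome, reference):
        _, mask = reference
        assert not mask[toy_genome.par_mask].any()


class TestLog2Profile:
    def test_sample_equal_to_reference_gives_zero(self, toy_genome, reference):
        from chordcna.normalize import CorrectedCounts
        ref, mask = reference
        sample = CorrectedCounts("self", ref.copy(), mask.copy())
        prof = log2_ratio_profile(sample, ref, mask, toy_genome)
        assert np.abs(prof.log2[prof.mask]).max() < 1e-6

    def test_doubled_chromosome_is_one(self, toy_genome, reference):
        from chordcna.normalize import CorrectedCounts
        ref, mask = reference
        rates = ref.copy()
        idx = toy_genome.chrom_bins("4")
        rates[idx] *= 2
        prof = log2_ratio_profile(CorrectedCounts("x", rates, mask), ref,
                                  mask, toy_genome)
        sel = prof.mask[idx]
        assert np.allclose(prof.log2[idx][sel], 1.0, atol=1e-6)

    def test_balanced_sample_is_tight_around_zero(self, toy_genome,
                                                  control_panel, reference):
        s = cc.simulate_sample(toy_genome, cc.balanced_spec(), seed=21,
                               sample_id="lcl-like")
        prof = normalize_sample(s, control_panel, toy_genome, reference=reference)
        within = np.abs(prof.log2[prof.mask]) < 0.2
        assert within.mean() >= 0.99
        assert np.median(np.abs(prof.log2[prof.mask])) < 0.05

    def test_masking_is_monotone(self, toy_genome, control_panel, reference):
        s = cc.simulate_sample(toy_genome, cc.mug_cc1_spec(), seed=8)
        corrected = correct_sample(s, toy_genome)
        prof = log2_ratio_profile(corrected, reference[0], reference[1], toy_genome)
        # every bin masked upstream stays masked in the profile
        assert not prof.mask[~corrected.mask].any()
        assert not prof.mask[~reference[1]].any()

    def test_genome_mismatch_rejected(self, toy_genome, reference):
        from chordcna.normalize import CorrectedCounts
        short = CorrectedCounts("x", np.ones(10), np.ones(10, dtype=bool))
        with pytest.raises(DataError):
            log2_ratio_profile(short, reference[0], reference[1], toy_genome)


def test_profile_csv_round_trip(toy_genome, control_panel, reference, tmp_path):
    from chordcna.normalize import NormalizedProfile
    s = cc.simulate_sample(toy_genome, cc.balanced_spec(), seed=30)
    prof = normalize_sample(s, control_panel, toy_genome, reference=reference)
    path = tmp_path / "profile.csv"
    prof.to_csv(path)
    back = NormalizedProfile.from_csv(path, toy_genome)
    assert np.array_equal(back.mask, prof.mask)
    assert np.allclose(back.log2[back.mask], prof.log2[prof.mask], atol=1e-6)
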