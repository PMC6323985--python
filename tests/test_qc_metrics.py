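"""ENCODE library/signal metrics and the FNCM/FPCM peak-level controls."""

import math

import numpy as np
import pytest

from cistromeqc.io_formats import GenomicInterval, Peak, TagRecord
from cistromeqc.peak_merging import FrequencySpectrum, frequency_spectrum, merge_peaks
from cistromeqc.qc_metrics import (
    QCReport,
    cross_correlation,
    fncm,
    fpcm,
    frip,
    nrf,
    pbc,
    qc_report,
)
from cistromeqc.synthetic import SimulationConfig, simulate_peak_sets, simulate_tags


def tags_at(positions, strand="+", chrom="chr1"):
    return [TagRecord(chrom, p, strand) for p in positions]


class TestLibraryMetrics:
    def test_nrf_direct_count(self):
        tags = tags_at([1, 1, 2, 3, 4, 5, 6, 7, 8, 8])  # 10 tags, 8 distinct
        assert nrf(tags) == pytest.approx(0.8)

    def test_nrf_extremes(self):
        assert nrf(tags_at([1, 2, 3])) == 1.0
        assert nrf(tags_at([5] * 4)) == pytest.approx(0.25)

    def test_nrf_strand_distinguishes_positions(self):
        tags = tags_at([10], "+") + tags_at([10], "-")
        assert nrf(tags) == 1.0

    def test_pbc_direct_count(self):
        # position multiset {a x1, b x1, c x2, d x2, e x4}
        tags = tags_at([1] + [2] + [3] * 2 + [4] * 2 + [5] * 4)
        pbc1, pbc2 = pbc(tags)
        assert pbc1 == pytest.approx(0.4)
        assert pbc2 == pytest.approx(1.0)

    def test_pbc_all_singletons_flags_infinity(self):
        pbc1, pbc2 = pbc(tags_at([1, 2, 3]))
        assert pbc1 == 1.0
        assert math.isinf(pbc2)

    def test_pbc_all_doubled(self):
        pbc1, _ = pbc(tags_at([1, 1, 2, 2]))
        assert pbc1 == 0.0

    def test_empty_inputs_error(self):
        for fn in (nrf, pbc):
            with pytest.raises(ValueError):
                fn([])


class TestFrip:
    def peaks(self, *spans):
        return [
            Peak(interval=GenomicInterval("chr1", s, e), caller="MACS")
            for s, e in spans
        ]

    def test_direct_count(self):
        tags = tags_at([0, 5, 9, 10, 50, 60, 70, 80, 90, 99])
        # [0,10) contains 0,5,9; [95,100) contains 99 -> 4 of 10
        assert frip(tags, self.peaks((0, 10), (95, 100))) == pytest.approx(0.4)

    def test_no_peaks(self):
        assert frip(tags_at([1, 2]), []) == 0.0

    def test_everything_covered(self):
        assert frip(tags_at([1, 2, 3]), self.peaks((0, 100))) == 1.0

    def test_half_open_boundary(self):
        tags = tags_at([9, 10])
        assert frip(tags, self.peaks((0, 10))) == pytest.approx(0.5)


class TestCrossCorrelation:
    def test_fragment_length_recovered(self):
        config = SimulationConfig(
            seed=9, genome_length=200_000, n_true_sites=150,
            fragment_length=147, read_length=36, background_tags=6000,
        )
        rng = config.rng()
        sites, _ = simulate_peak_sets(config, rng)
        tags = simulate_tags(config, sites, rng)
        result = cross_correlation(tags, max_shift=300, read_length=36)
        assert abs(result.fragment_length - 147) <= 10
        assert result.nsc > 1.0
        assert result.rsc > 0.0

    def test_phantom_duplication_inflates_cc_read(self):
        rng = np.random.default_rng(3)
        positions = rng.integers(0, 5000, size=800)
        plus = tags_at(positions)
        minus = tags_at(positions + 36, "-")  # every + tag mirrored at read length
        background = tags_at(rng.integers(0, 5000, size=400), "-")
        with_phantom = cross_correlation(
            plus + minus + background, max_shift=200, read_length=36
        )
        assert with_phantom.cc_read > with_phantom.cc.mean()

    def test_signal_beats_no_signal(self):
        def run(frags):
            config = SimulationConfig(
                seed=17, genome_length=200_000, n_true_sites=120,
                frags_per_site=frags, background_tags=8000,
            )
            rng = config.rng()
            sites, _ = simulate_peak_sets(config, rng)
            tags = simulate_tags(config, sites, rng)
            return cross_correlation(tags, max_shift=300, read_length=36)

        signal, null = run(20), run(0)
        assert signal.nsc > null.nsc
        assert signal.rsc > null.rsc

    def test_profile_invariant_to_tag_and_chrom_order(self):
        rng = np.random.default_rng(5)
        tags = []
        for chrom in ("chr1", "chr2"):
            pos = rng.integers(0, 3000, size=500)
            tags += tags_at(pos, "+", chrom) + tags_at(pos + 100, "-", chrom)
        shuffled = [tags[i] for i in rng.permutation(len(tags))]
        a = cross_correlation(tags, max_shift=150, read_length=36)
        b = cross_correlation(shuffled, max_shift=150, read_length=36)
        np.testing.assert_allclose(a.cc, b.cc)

    def test_single_strand_errors(self):
        with pytest.raises(ValueError, match="both strands"):
            cross_correlation(tags_at([1, 2, 3]), max_shift=10, read_length=5)


class TestFNCM:
    def test_definitional_ratio(self):
        assert fncm(80, 100.0) == pytest.approx(0.8)
        assert fncm(100, 100.0) == 1.0

    def test_invalid_expected(self):
        with pytest.raises(ValueError):
            fncm(10, 0.0)

    @pytest.mark.parametrize("p", [0.5, 0.7, 0.9])
    def test_tracks_detection_probability(self, p):
        """With per-caller Bernoulli(p) detection and no noise the mean
        FNCM of a caller approaches p."""
        values = []
        for seed in range(25):
            config = SimulationConfig(
                seed=seed, genome_length=400_000, n_true_sites=400,
                capture_model="per_caller_bernoulli",
                detection_probs={c: p for c in SimulationConfig.callers},
            )
            rng = config.rng()
            _, peaks = simulate_peak_sets(config, rng)
            report_input = {c: peaks[c] for c in peaks}
            merged = merge_peaks(report_input)
            from cistromeqc.capture_recapture import expected_peak_count
            from cistromeqc.peak_merging import presence_counts

            spec = frequency_spectrum(merged)
            mean_N, _ = expected_peak_count(
                spec, presence_counts(merged, list(report_input))
            )
            values.append(len(peaks["MACS"]) / mean_N)
        assert np.mean(values) == pytest.approx(p, abs=0.05)


class TestFPCM:
    def test_hand_value(self):
        spec = FrequencySpectrum(f={1: 40, 2: 30, 3: 30})
        value = fpcm(spec, lambda_hat=1.0, N_hat=100.0)
        assert value == pytest.approx(40 / (100 * math.exp(-1)), rel=1e-6)

    def test_exact_expectation_gives_one(self):
        lam, N = 1.3, 200.0
        f1 = N * lam * math.exp(-lam)
        spec = FrequencySpectrum(f={1: f1, 2: 10})
        assert fpcm(spec, lam, N) == pytest.approx(1.0)

    def test_invalid_parameters(self):
        spec = FrequencySpectrum(f={1: 5})
        with pytest.raises(ValueError):
            fpcm(spec, 0.0, 10.0)

    def test_noise_free_near_one_and_monotone_in_noise(self):
        means = []
        for noise in (0.0, 0.1, 0.3):
            values = []
            for seed in range(25):
                config = SimulationConfig(
                    seed=seed, genome_length=400_000, n_true_sites=400,
                    capture_model="poisson", capture_lambda=1.5,
                    noise_rate=noise,
                )
                rng = config.rng()
                _, peaks = simulate_peak_sets(config, rng)
                merged = merge_peaks(dict(peaks))
                spec = frequency_spectrum(merged)
                from cistromeqc.capture_recapture import mle_ztp_estimate

                est = mle_ztp_estimate(spec)
                values.append(fpcm(spec, est.lambda_hat, est.N_hat))
            means.append(float(np.mean(values)))
        assert means[0] == pytest.approx(1.0, abs=0.1)
        assert means[0] < means[1] < means[2]


class TestQCReport:
    def _experiment(self, **kwargs):
        config = SimulationConfig(
            seed=21, genome_length=300_000, n_true_sites=200,
            noise_rate=0.05, duplicate_rate=0.1, **kwargs,
        )
        rng = config.rng()
        sites, peaks = simulate_peak_sets(config, rng)
        tags = simulate_tags(config, sites, rng)
        return tags, peaks

    def test_end_to_end_populates_all_metrics(self):
        tags, peaks = self._experiment()
        report = qc_report(tags, peaks, read_length=36, max_shift=300)
        assert 0 <= report.nrf <= 1
        assert 0 <= report.pbc1 <= 1
        assert report.pbc2 > 0
        assert 0 <= report.frip <= 1
        assert report.nsc is not None and report.rsc is not None
        assert set(report.fncm) == set(peaks)
        assert report.fpcm is not None
        assert report.expected_peak_count > 0

    def test_single_strand_partial_report(self):
        tags, peaks = self._experiment()
        plus_only = [t for t in tags if t.strand == "+"]
        report = qc_report(plus_only, peaks, read_length=36, max_shift=300)
        assert report.nsc is None and report.rsc is None
        assert report.nrf is not None
        assert any("cross-correlation" in w for w in report.warnings)

    def test_json_round_trip(self):
        tags, peaks = self._experiment()
        report = qc_report(tags, peaks, read_length=36, max_shift=300)
        back = QCReport.from_json(report.to_json())
        assert back.nrf == report.nrf
        assert back.fncm == report.fncm
        assert back.fpcm == report.fpcm
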