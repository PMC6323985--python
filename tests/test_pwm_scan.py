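"""PCM -> PWM conversion, exact p-value thresholds, and scanning."""

from itertools import product

import numpy as np
import pytest

from cistromeqc.io_formats import read_pcm
from cistromeqc.mappability import revcomp
from cistromeqc.pwm_scan import (
    PositionCountMatrix,
    pcm_to_pwm,
    scan,
    score_distribution,
    score_threshold,
)


def random_pcm(rng, L):
    return PositionCountMatrix(
        tf_name="T", counts=rng.integers(1, 60, size=(L, 4)).astype(float)
    )


def exhaustive_threshold(pwm, pvalue):
    """Independent oracle: enumerate all 4^L words, exact scores, uniform
    background; smallest achieved score whose tail probability <= pvalue.
    Tied scores count as one group (P(score >= t) includes every word at
    t). None when even the top score group is too probable."""
    L = len(pwm)
    scores = np.sort(
        np.array(
            [
                sum(pwm.weights[j, b] for j, b in enumerate(word))
                for word in product(range(4), repeat=L)
            ]
        )
    )[::-1]
    n = scores.size
    cum = 0.0
    last_ok = None
    i = 0
    while i < n:
        j = i
        while j < n and scores[i] - scores[j] <= 1e-9:
            j += 1
        cum += (j - i) / n
        if cum <= pvalue + 1e-12:
            last_ok = float(scores[i])
            i = j
        else:
            break
    return last_ok


class TestPcmToPwm:
    def test_uniform_counts_give_zero_weights(self):
        pcm = PositionCountMatrix("T", np.full((5, 4), 10.0))
        pwm = pcm_to_pwm(pcm)
        np.testing.assert_allclose(pwm.weights, 0.0, atol=1e-12)

    def test_dominant_base_sign(self):
        pcm = PositionCountMatrix("T", np.array([[100.0, 0.0, 0.0, 0.0]]))
        pwm = pcm_to_pwm(pcm)
        assert pwm.weights[0, 0] > 0
        assert (pwm.weights[0, 1:] < 0).all()

    def test_word_score_is_sum_of_weights(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 6))
        word = "ACGTAC"
        expected = sum(
            pwm.weights[j, "ACGT".index(b)] for j, b in enumerate(word)
        )
        assert pwm.score_word(word) == pytest.approx(expected)

    def test_invalid_pseudocount(self, rng):
        with pytest.raises(ValueError):
            pcm_to_pwm(random_pcm(rng, 3), pseudocount=0.0)


class TestScoreThreshold:
    def test_pvalue_one_gives_min_score(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 5))
        assert score_threshold(pwm, 1.0) == pytest.approx(
            pwm.min_score(), abs=1e-9
        )

    def test_invalid_pvalue(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 4))
        for p in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                score_threshold(pwm, p)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 9))
        pwm = pcm_to_pwm(random_pcm(rng, L))
        _, _, bin_width = score_distribution(pwm)
        for pvalue in (0.1, 0.01, 0.002):
            oracle = exhaustive_threshold(pwm, pvalue)
            got = score_threshold(pwm, pvalue)
            if oracle is None:
                assert got > pwm.max_score()
            else:
                # exact tail enumeration: agreement far inside one bin
                assert abs(got - oracle) <= min(bin_width, 1e-6)

    def test_distribution_sums_to_one(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 7))
        _, probs, _ = score_distribution(pwm)
        assert probs.sum() == pytest.approx(1.0)

    def test_monotone_in_pvalue(self, rng):
        for _ in range(5):
            pwm = pcm_to_pwm(random_pcm(rng, 6))
            thresholds = [
                score_threshold(pwm, p) for p in (0.2, 0.1, 0.05, 0.025, 0.0125)
            ]
            assert all(
                a <= b + 1e-12 for a, b in zip(thresholds, thresholds[1:])
            )


class TestScan:
    def consensus(self, pwm):
        return "".join("ACGT"[b] for b in np.argmax(pwm.weights, axis=1))

    def test_planted_site_found_on_both_strands(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 8))
        threshold = score_threshold(pwm, 0.001)
        site = self.consensus(pwm)
        background = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, 300)]
        )
        seq = background[:100] + site + background[100:200] + revcomp(site)
        hits = scan(seq, pwm, threshold)
        assert (100, "+") in {(h[0], h[1]) for h in hits}
        assert (208, "-") in {(h[0], h[1]) for h in hits}

    def test_strand_symmetry_under_revcomp(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 6))
        threshold = score_threshold(pwm, 0.01)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        fwd = scan(seq, pwm, threshold)
        rev = scan(revcomp(seq), pwm, threshold)
        L = len(pwm)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - pos - L, flip[strand], round(score, 9))
            for pos, strand, score in rev
        )
        assert mirrored == sorted(
            (pos, strand, round(score, 9)) for pos, strand, score in fwd
        )

    def test_all_n_sequence_and_short_sequence(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 5))
        threshold = score_threshold(pwm, 0.5)
        assert scan("N" * 50, pwm, threshold) == []
        assert scan("ACG", pwm, threshold) == []

    def test_windows_containing_n_skipped(self, rng):
        pwm = pcm_to_pwm(random_pcm(rng, 4))
        threshold = pwm.min_score()  # accept every clean window
        seq = "ACGTNACGT"
        hits = scan(seq, pwm, threshold)
        starts = {h[0] for h in hits}
        assert starts == {0, 5}  # windows 1..4 all contain the N

    def test_expected_hit_rate_on_background(self, rng):
        """Threshold semantics tie to the scan: on i.i.d. background the
        expected hit count is 2 * n_windows * pvalue (within 3 SE)."""
        pwm = pcm_to_pwm(random_pcm(rng, 8))
        pvalue = 0.005
        threshold = score_threshold(pwm, pvalue)
        n, reps = 20_000, 8
        total = 0
        for _ in range(reps):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            total += len(scan(seq, pwm, threshold))
        n_windows = n - len(pwm) + 1
        expected = 2 * n_windows * pvalue * reps
        assert abs(total - expected) <= 3 * np.sqrt(expected)


class TestPcmIO:
    def test_hocomoco_layout_round_trip(self, tmp_path):
        p = tmp_path / "m.pcm"
        p.write_text(
            ">MOTIF_A\n10 0 0 0\n0 10 0 0\n2 2 4 2\n"
            ">MOTIF_B\n1 2 3 4\n"
        )
        matrices = read_pcm(p)
        assert [m.tf_name for m in matrices] == ["MOTIF_A", "MOTIF_B"]
        assert matrices[0].counts.shape == (3, 4)
        np.testing.assert_allclose(matrices[1].counts, [[1, 2, 3, 4]])

    def test_bad_column_count(self, tmp_path):
        p = tmp_path / "m.pcm"
        p.write_text(">X\n1 2 3\n")
        with pytest.raises(ValueError, match="4 columns"):
            read_pcm(p)
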