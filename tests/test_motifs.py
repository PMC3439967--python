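import math

import numpy as np
import pytest

from peaknorm.motifs import (
    PWM,
    BackgroundModel,
    DegenerateMotifError,
    UNIFORM_BACKGROUND,
    cluster_m_with_motifs,
    consensus_score,
    encode_sequence,
    estimate_background,
    fisher_enrichment_filter,
    motif_norm_score,
    motif_raw_score,
    read_jaspar,
    score_sequences,
)

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def toy_ac_pwm(pseudo=1e-9) -> PWM:
    """Length-2 motif: A then C, essentially deterministic."""
    return PWM.from_probabilities(
        "AC", [[1, 0, 0, 0], [0, 1, 0, 0]], pseudo=pseudo
    )


def brute_force_raw(pwm: PWM, seq: str, background: BackgroundModel) -> float:
    """Exhaustive offset/strand enumeration oracle in pure Python."""
    best = -math.inf
    for candidate in (seq, revcomp(seq)):
        enc = encode_sequence(candidate)
        for off in range(len(candidate) - len(pwm) + 1):
            score = 0.0
            for i in range(len(pwm)):
                code = enc[off + i]
                if code == 4:
                    continue
                score += math.log2(pwm.matrix[i, code] / background.freq[code])
            best = max(best, score)
    return best


class TestBackground:
    def test_uniform_genome_gives_uniform_frequencies(self):
        seqs = {"chr1": "ACGT" * 5000}
        bg = estimate_background(seqs, n=50, length=1000, seed=1)
        assert bg.freq == pytest.approx([0.25] * 4, abs=1e-3)

    def test_all_a_genome_regularized(self):
        bg = estimate_background({"chr1": "A" * 5000}, n=20, length=1000, seed=1)
        assert bg.freq[0] > 0.99
        assert np.all(bg.freq > 0)
        assert bg.freq.sum() == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        seqs = {"chr1": "ACGTTGCA" * 2000, "chr2": "GGCC" * 3000}
        bg1 = estimate_background(seqs, n=30, length=500, seed=7)
        bg2 = estimate_background(seqs, n=30, length=500, seed=7)
        assert np.array_equal(bg1.freq, bg2.freq)

    def test_genome_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            estimate_background({"chr1": "ACGT" * 10}, n=5, length=1000)


class TestRawScore:
    def test_deterministic_motif_closed_form(self):
        # two positions of probability ~1 vs uniform background: 2*log2(4) = 4
        assert motif_raw_score(toy_ac_pwm(), "AC", UNIFORM_BACKGROUND) == pytest.approx(
            4.0, abs=1e-6
        )

    def test_reverse_strand_scanned(self):
        # "GT" is the reverse complement of "AC"
        assert motif_raw_score(toy_ac_pwm(), "GT", UNIFORM_BACKGROUND) == pytest.approx(
            4.0, abs=1e-6
        )

    def test_score_invariant_under_revcomp(self, rng):
        pwm = PWM.from_probabilities("m", rng.dirichlet(np.ones(4), size=6))
        seq = "".join(rng.choice(list("ACGT"), 80))
        s_fwd = motif_raw_score(pwm, seq, UNIFORM_BACKGROUND)
        s_rev = motif_raw_score(pwm, revcomp(seq), UNIFORM_BACKGROUND)
        assert s_fwd == pytest.approx(s_rev, abs=1e-12)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            motif_raw_score(toy_ac_pwm(), "A", UNIFORM_BACKGROUND)

    def test_matches_brute_force_oracle(self, rng):
        bg = BackgroundModel(np.array([0.3, 0.2, 0.2, 0.3]), 0)
        for _ in range(5):
            pwm = PWM.from_probabilities("m", rng.dirichlet(np.full(4, 0.5), size=8))
            seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            assert motif_raw_score(pwm, seq, bg) == pytest.approx(
                brute_force_raw(pwm, seq, bg), abs=1e-9
            )


class TestNormScore:
    def test_consensus_scores_one(self, rng):
        pwm = PWM.from_probabilities("m", rng.dirichlet(np.full(4, 0.5), size=8))
        seq = "TTT" + pwm.consensus + "GGG"
        assert motif_norm_score(pwm, seq, UNIFORM_BACKGROUND) == pytest.approx(1.0)

    def test_score_never_exceeds_one(self, rng):
        pwm = PWM.from_probabilities("m", rng.dirichlet(np.ones(4), size=6))
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 50))
            assert motif_norm_score(pwm, seq, UNIFORM_BACKGROUND) <= 1.0 + 1e-12

    def test_ratio_of_brute_force_scores(self, rng):
        bg = BackgroundModel(np.array([0.2, 0.3, 0.3, 0.2]), 0)
        pwm = PWM.from_probabilities("m", rng.dirichlet(np.full(4, 0.3), size=7))
        seq = "".join(rng.choice(list("ACGT"), 120))
        expected = brute_force_raw(pwm, seq, bg) / consensus_score(pwm, bg)
        assert motif_norm_score(pwm, seq, bg) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_motif_rejected(self):
        # uniform motif over uniform background: consensus log-odds = 0
        pwm = PWM("flat", np.full((4, 4), 0.25))
        with pytest.raises(DegenerateMotifError):
            motif_norm_score(pwm, "ACGTACGT", UNIFORM_BACKGROUND)


def test_read_jaspar_both_layouts(tmp_path):
    path = tmp_path / "motifs.pfm"
    path.write_text(
        ">M1 first\n"
        "A [ 10  0  5 ]\n"
        "C [  0 10  5 ]\n"
        "G [  0  0  5 ]\n"
        "T [  0  0  5 ]\n"
        ">M2\n"
        "8 0\n0 8\n0 0\n0 0\n"
    )
    pwms = read_jaspar(path)
    assert [p.id for p in pwms] == ["M1", "M2"]
    assert len(pwms[0]) == 3 and len(pwms[1]) == 2
    assert pwms[0].consensus[:2] == "AC"
    assert np.all(pwms[0].matrix > 0)
    assert pwms[0].matrix.sum(axis=1) == pytest.approx([1, 1, 1])


class TestFisherFilter:
    def test_enriched_motif_retained_with_hypergeom_oracle(self):
        # 90/100 peaks present vs 10/100 background regions
        peak_scores = np.array([[0.9]] * 90 + [[0.1]] * 10)
        bg_scores = np.array([[0.9]] * 10 + [[0.1]] * 90)
        (res,) = fisher_enrichment_filter(
            ["m"], peak_scores, bg_scores, presence_threshold=0.7
        )
        assert res.enrichment_score == pytest.approx(9.0)
        assert res.retained
        # exact one-sided hypergeometric tail: P(X >= 90) drawing 100 from
        # an urn with 100 "present" among 200
        total = math.comb(200, 100)
        tail = sum(
            math.comb(100, k) * math.comb(100, 100 - k) for k in range(90, 101)
        )
        assert res.p_value == pytest.approx(tail / total, rel=1e-9)

    def test_identical_rates_not_retained(self):
        scores = np.array([[0.9]] * 50 + [[0.1]] * 50)
        (res,) = fisher_enrichment_filter(["m"], scores, scores.copy())
        assert res.enrichment_score == pytest.approx(1.0)
        assert not res.retained

    def test_absent_everywhere_not_retained(self):
        scores = np.zeros((50, 1))
        (res,) = fisher_enrichment_filter(["m"], scores, scores.copy())
        assert not res.retained

    def test_zero_background_presence_uses_continuity(self, caplog):
        peak_scores = np.array([[0.9]] * 40 + [[0.1]] * 10)
        bg_scores = np.full((50, 1), 0.1)
        with caplog.at_level("WARNING"):
            (res,) = fisher_enrichment_filter(["m"], peak_scores, bg_scores)
        assert np.isfinite(res.enrichment_score)
        assert "continuity" in caplog.text

    def test_bonferroni_scales_with_motif_count(self):
        peak_scores = np.tile(np.array([[0.9]] * 30 + [[0.1]] * 20), (1, 5))
        bg_scores = np.tile(np.array([[0.9]] * 5 + [[0.1]] * 45), (1, 5))
        results = fisher_enrichment_filter(list("abcde"), peak_scores, bg_scores)
        for res in results:
            assert res.p_bonferroni == pytest.approx(min(1.0, res.p_value * 5))

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment_filter(["m"], np.zeros((2, 1)), np.zeros((2, 1)), 1.5)


def naive_ward(dist: np.ndarray) -> list[float]:
    """O(n^3) Lance-Williams Ward agglomeration oracle; returns merge heights."""
    n = dist.shape[0]
    d = dist.astype(float).copy()
    active = {i: 1 for i in range(n)}  # cluster id -> size
    heights = []
    while len(active) > 1:
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                if best is None or d[i, j] < best[0]:
                    best = (d[i, j], i, j)
        h, i, j = best
        heights.append(h)
        ni, nj = active[i], active[j]
        for k in active:
            if k in (i, j):
                continue
            nk = active[k]
            dik, djk, dij = d[i, k], d[j, k], d[i, j]
            new = math.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            d[i, k] = d[k, i] = new
        active[i] = ni + nj
        del active[j]
        d[j, :] = d[:, j] = math.inf
    return heights


class TestClustering:
    def test_identical_column_merges_first_with_m(self, rng):
        m = rng.normal(0, 1, 50)
        noise = rng.normal(0, 1, 50)
        scores = np.column_stack([m, noise, -m])
        result = cluster_m_with_motifs(m, scores, ["same", "noise", "anti"])
        assert result.correlations_with_m[0][0] == "same"
        assert result.correlations_with_m[0][1] == pytest.approx(1.0)
        assert result.correlations_with_m[-1][0] == "anti"
        assert result.correlations_with_m[-1][1] == pytest.approx(-1.0)
        # first merge joins M (leaf 0) and its copy (leaf 1) at height 0
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-7)

    def test_linkage_heights_match_naive_ward_oracle(self, rng):
        data = rng.normal(0, 1, size=(50, 4))
        data[:, 1] += 0.8 * data[:, 0]
        m = data[:, 0]
        result = cluster_m_with_motifs(m, data[:, 1:], ["a", "b", "c"])
        corr = np.corrcoef(np.column_stack([m, data[:, 1:]]), rowvar=False)
        heights = naive_ward(1.0 - corr)
        assert result.linkage[:, 2] == pytest.approx(heights, rel=1e-10)

    def test_zero_variance_variable_dropped(self, rng, caplog):
        m = rng.normal(0, 1, 30)
        scores = np.column_stack([np.full(30, 0.5), m + rng.normal(0, 0.5, 30)])
        with caplog.at_level("WARNING"):
            result = cluster_m_with_motifs(m, scores, ["flat", "ok"])
        assert result.labels == ["M", "ok"]

    def test_planted_motif_correlates_and_clusters_with_m(self, rng):
        """A motif planted with probability increasing in M outranks decoys
        and is M's nearest neighbor in the dendrogram."""
        planted = PWM.from_probabilities(
            "planted", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]] * 0.85 + 0.0375
        )
        decoys = [
            PWM.from_probabilities(f"decoy{k}", rng.dirichlet(np.full(4, 0.4), size=8))
            for k in range(3)
        ]
        m = rng.normal(0, 1.5, 150)
        seqs = []
        for mv in m:
            seq = list("".join(rng.choice(list("ACGT"), 60)))
            if rng.random() < 1 / (1 + math.exp(-2.0 * mv)):
                pos = int(rng.integers(0, 60 - 8))
                seq[pos : pos + 8] = planted.consensus
            seqs.append("".join(seq))
        pwms = [planted] + decoys
        scores = score_sequences(pwms, seqs, UNIFORM_BACKGROUND)
        result = cluster_m_with_motifs(m, scores, [p.id for p in pwms])
        assert result.correlations_with_m[0][0] == "planted"
        # M is leaf 0, planted is leaf 1: their first merges must be with
        # each other
        first_with_m = next(row for row in result.linkage if 0 in row[:2])
        assert {int(first_with_m[0]), int(first_with_m[1])} == {0, 1}
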