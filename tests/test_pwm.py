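import numpy as np
import pytest

from utreg import pwm as pw
from utreg.io import SequenceRecord

BRUNO = "URURURU"  # U(G/A)U(A/G)U(G/A)U
PUMILIO = "UGUAHAUA"  # UGUA(A/C/U)AUA

# heptamers printed as Bruno-element matches in the study's gene tables
TABLE7_HEPTAMERS = [
    "UGUGUAU",
    "UAUGUAU",
    "UGUGUAU",
    "UAUGUAU",
    "UAUGUAU",
    "UAUGUAU",
    "UAUGUAU",
    "UAUGUAU",
]


def indicator_pwm(word, name="w", eps=1e-3):
    mat = np.full((len(word), 4), eps)
    for i, c in enumerate(word):
        mat[i, "ACGT".index(c)] = 1.0
    mat /= mat.sum(axis=1, keepdims=True)
    return pw.PWM(name, mat)


class TestComparePwms:
    def test_self_match_identity(self, rng):
        mat = rng.dirichlet(np.ones(4) * 0.3, size=8)
        a = pw.PWM("a", mat)
        res = pw.compare_pwms(a, a, rng=1)
        assert res.offset == 0 and res.orientation == "fwd"
        assert res.score == pytest.approx(1.0)
        assert res.match

    def test_reverse_complement_symmetry(self, rng):
        mat = rng.dirichlet(np.ones(4) * 0.3, size=8)
        a = pw.PWM("a", mat)
        rc = a.reverse_complement()
        res = pw.compare_pwms(a, rc, rng=1)
        assert res.orientation == "rc"
        assert res.score == pytest.approx(1.0)
        assert res.match

    def test_match_decision_symmetric(self, rng):
        for trial in range(5):
            a = pw.PWM("a", rng.dirichlet(np.ones(4) * 0.5, size=8))
            b = pw.PWM("b", rng.dirichlet(np.ones(4) * 0.5, size=9))
            pool = np.random.default_rng(77).dirichlet(np.ones(4), size=4000)
            r1 = pw.compare_pwms(a, b, rng=5, column_pool=pool)
            r2 = pw.compare_pwms(b, a, rng=5, column_pool=pool)
            assert r1.match == r2.match

    def test_independent_background_pwms_rarely_match(self, rng):
        """PWMs sampled from the null column pool match at <= alpha rate."""
        matches = 0
        trials = 40
        for t in range(trials):
            local = np.random.default_rng(900 + t)
            a = pw.PWM("a", local.dirichlet(np.ones(4), size=8))
            b = pw.PWM("b", local.dirichlet(np.ones(4), size=8))
            res = pw.compare_pwms(a, b, n_null=2000, rng=local)
            matches += res.match
        # binomial(40, 0.05) 3-sigma upper bound
        assert matches <= 0.05 * trials + 3 * np.sqrt(trials * 0.05 * 0.95)

    def test_narrow_pwm_rejected(self, rng):
        a = pw.PWM("a", rng.dirichlet(np.ones(4), size=4))
        b = pw.PWM("b", rng.dirichlet(np.ones(4), size=8))
        with pytest.raises(ValueError):
            pw.compare_pwms(a, b, min_overlap=7)


class TestClusterAverage:
    def test_single_pwm_unchanged(self, rng):
        a = pw.PWM("a", rng.dirichlet(np.ones(4), size=8))
        clusters = pw.cluster_average([a])
        assert len(clusters) == 1
        assert clusters[0][1] is a

    def test_identical_pwms_average_to_member(self, rng):
        mat = rng.dirichlet(np.ones(4) * 0.3, size=8)
        a, b = pw.PWM("a", mat), pw.PWM("b", mat.copy())
        clusters = pw.cluster_average([a, b])
        assert len(clusters) == 1
        np.testing.assert_allclose(clusters[0][1].matrix, mat, atol=1e-9)

    def test_average_rows_normalized_and_idempotent(self, rng):
        """Re-clustering the cluster averages keeps the cluster count."""
        base1 = rng.dirichlet(np.ones(4) * 0.2, size=8)
        base2 = rng.dirichlet(np.ones(4) * 0.2, size=8)
        pwms = []
        for i in range(3):
            for j, base in enumerate((base1, base2)):
                noisy = base + rng.uniform(0, 0.02, size=base.shape)
                noisy /= noisy.sum(axis=1, keepdims=True)
                pwms.append(pw.PWM(f"m{j}_{i}", noisy))
        clusters = pw.cluster_average(pwms, rng=2)
        averages = [c[1] for c in clusters]
        for avg in averages:
            np.testing.assert_allclose(avg.matrix.sum(axis=1), 1.0, atol=1e-9)
        reclustered = pw.cluster_average(averages, rng=2)
        assert len(reclustered) == len(clusters)


class TestScanPwm:
    def test_exact_word_hit(self):
        p = indicator_pwm("TGTGTAT")
        seqs = [SequenceRecord("g", "AAAATGTGTATCCC", "utr3")]
        hits = pw.scan_pwm(p, seqs, score_threshold=0.9)
        assert hits == [("g", 5, "fwd", pytest.approx(hits[0][3]))]

    def test_threshold_one_only_consensus(self, rng):
        p = indicator_pwm("ACGTACG")
        seq = "".join(rng.choice(list("ACGT"), size=300)) + "ACGTACG"
        hits = pw.scan_pwm(p, [SequenceRecord("g", seq, "utr3")], score_threshold=1.0)
        windows = {seq[h[1] - 1 : h[1] + 6] for h in hits}
        assert windows == {"ACGTACG"}

    def test_matches_bruteforce_oracle(self, rng):
        mat = rng.dirichlet(np.ones(4), size=6)
        p = pw.PWM("p", mat)
        logodds = np.log2(np.maximum(mat, 1e-6) / 0.25)
        maxs = logodds.max(axis=1).sum()
        seq = "".join(rng.choice(list("ACGT"), size=200))
        expected = []
        for i in range(len(seq) - 5):
            s = sum(logodds[j, "ACGT".index(seq[i + j])] for j in range(6))
            if s >= 0.5 * maxs - 1e-9:
                expected.append((i + 1, s))
        hits = pw.scan_pwm(p, [SequenceRecord("g", seq, "utr3")], score_threshold=0.5)
        assert [(h[1], pytest.approx(h[3])) for h in hits] == [
            (i, pytest.approx(s)) for i, s in expected
        ]


class TestIupacScan:
    @pytest.mark.parametrize("heptamer", sorted(set(TABLE7_HEPTAMERS)))
    def test_printed_bruno_matches(self, heptamer):
        """Every heptamer printed as a Bruno-element match fits the
        degenerate pattern U(G/A)U(A/G)U(G/A)U."""
        assert pw.iupac_scan(BRUNO, heptamer) == [(1, "fwd")]

    def test_pumilio_h_excludes_g(self):
        assert pw.iupac_scan(PUMILIO, "UGUACAUA")
        assert not pw.iupac_scan(PUMILIO, "UGUAGAUA")

    def test_all_pumilio_consistent_octamers(self):
        for mid in "ACU":
            word = f"UGUA{mid}AUA"
            assert pw.iupac_scan(PUMILIO, word) == [(1, "fwd")]

    def test_reverse_complement_search(self):
        # DNA reverse complement of TAGGGTTT is AAACCCTA
        hits = pw.iupac_scan("UAGGGUUU", "GGAAACCCTAGG", search_rc=True)
        assert (3, "rc") in hits

    def test_overlapping_matches_reported(self):
        hits = pw.iupac_scan("AA", "AAAA")
        assert [h[0] for h in hits] == [1, 2, 3]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            pw.iupac_scan("AJG", "ACGT")


class TestInfoContent:
    def test_indicator_column_two_bits(self):
        p = pw.PWM("p", np.array([[1.0, 0, 0, 0]] * 4))
        np.testing.assert_allclose(pw.info_content(p), 2.0)

    def test_uniform_column_zero_bits(self):
        p = pw.PWM("p", np.full((5, 4), 0.25))
        np.testing.assert_allclose(pw.info_content(p), 0.0)

    def test_bounded_zero_two(self, rng):
        for _ in range(20):
            p = pw.PWM("p", rng.dirichlet(np.ones(4), size=8))
            ic = pw.info_content(p)
            assert np.all(ic >= 0) and np.all(ic <= 2 + 1e-12)


class TestPatternToPwm:
    def test_known_motif_matches_its_own_pwm(self):
        km = pw.KnownMotif("pumilio", PUMILIO)
        p = pw.pattern_to_pwm(km)
        assert p.width == 8
        res = pw.compare_pwms(p, p, min_overlap=7, rng=3)
        assert res.match and res.score == pytest.approx(1.0)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            pw.KnownMotif("bad", "AJJA")
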