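import numpy as np
import pytest

from utreg import seeder
from utreg.io import SequenceRecord
from utreg.simulate import simulate_background


def oracle_min_distance(seed_str, seq):
    """Independent brute-force best-match Hamming distance."""
    k = len(seed_str)
    if len(seq) < k:
        return k
    best = k
    for i in range(len(seq) - k + 1):
        d = sum(1 for a, b in zip(seed_str, seq[i : i + k]) if a != b)
        best = min(best, d)
    return best


class TestSeedEncoding:
    def test_roundtrip_all_seeds(self):
        for idx in range(4**3):
            s = seeder.seed_to_string(idx, 3)
            assert seeder.string_to_seed(s) == idx


class TestBackground:
    def test_ubiquitous_seed(self):
        bg = seeder.build_background(["AAAAAA"], 6)
        np.testing.assert_allclose(bg.pmf_for("AAAAAA"), [1, 0, 0, 0, 0, 0, 0])

    def test_maximally_distant_seed(self):
        bg = seeder.build_background(["AAAAAA"], 6)
        np.testing.assert_allclose(bg.pmf_for("TTTTTT"), [0, 0, 0, 0, 0, 0, 1])

    def test_pmfs_match_bruteforce(self, rng):
        """Per-seed pmfs equal brute-force enumeration on a 64-seed sample."""
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(100)]
        bg = seeder.build_background(seqs, 6)
        sample = rng.choice(4**6, size=64, replace=False)
        for idx in sample:
            s = seeder.seed_to_string(int(idx), 6)
            dists = [oracle_min_distance(s, t) for t in seqs]
            expected = np.bincount(dists, minlength=7) / len(seqs)
            np.testing.assert_allclose(bg.pmf_for(s), expected)

    def test_pmfs_sum_to_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(20)]
        bg = seeder.build_background(seqs, 6)
        np.testing.assert_allclose(bg.pmf.sum(axis=1), 1.0)

    def test_short_sequences_excluded(self):
        bg = seeder.build_background(["AAAAAA", "ACG"], 6)
        assert bg.n_background == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            seeder.build_background([], 6)

    def test_restricted_seed_set(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
        subset = [0, 100, 200]
        bg = seeder.build_background(seqs, 8, seeds=subset)
        assert list(bg.seeds) == subset
        s = seeder.seed_to_string(100, 8)
        dists = [oracle_min_distance(s, t) for t in seqs]
        expected = np.bincount(dists, minlength=9) / len(seqs)
        np.testing.assert_allclose(bg.pmf_for(100), expected)


class TestSubgroups:
    def _records(self, n):
        return [SequenceRecord(f"g{i}", "ACGTACGTAC", "utr3") for i in range(n)]

    def test_shape_and_no_replacement(self):
        groups = seeder.make_subgroups(
            self._records(85), seeder.SubgroupScheme(n_subgroups=500, subgroup_size=10, seed=1)
        )
        assert len(groups) == 500
        assert all(len(g) == 10 for g in groups)
        assert all(len({r.id for r in g}) == 10 for g in groups)

    def test_small_set_fallback(self):
        groups = seeder.make_subgroups(
            self._records(7), seeder.SubgroupScheme(n_subgroups=500, subgroup_size=10, seed=1)
        )
        assert len(groups) == 500 and all(len(g) == 7 for g in groups)

    def test_deterministic_under_seed(self):
        scheme = seeder.SubgroupScheme(n_subgroups=20, subgroup_size=5, seed=9)
        a = seeder.make_subgroups(self._records(30), scheme)
        b = seeder.make_subgroups(self._records(30), scheme)
        assert [[r.id for r in g] for g in a] == [[r.id for r in g] for g in b]


class TestSeedPvalue:
    def test_ubiquitous_seed_never_enriched(self):
        assert seeder.seed_pvalue(0, 5, np.array([1.0])) == 1.0

    def test_two_draw_enumeration(self):
        """pmf {0: .5, 1: .5}, m=2: P(S<=0) = 1/4 by enumerating outcomes."""
        p = seeder.seed_pvalue(0, 2, np.array([0.5, 0.5]))
        assert p == pytest.approx(0.25)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_monte_carlo(self, case):
        """Exact convolution agrees with 200k-draw Monte Carlo within 3 SE."""
        n_draws = 200_000
        rng = np.random.default_rng(6000 + case)
        support = int(rng.integers(2, 7))
        pmf = rng.dirichlet(np.ones(support))
        m = int(rng.integers(1, 6))
        draws = rng.choice(support, size=(n_draws, m), p=pmf).sum(axis=1)
        s = int(rng.integers(0, m * (support - 1) + 1))
        mc = (draws <= s).mean()
        exact = seeder.seed_pvalue(s, m, pmf)
        se = np.sqrt(max(exact * (1 - exact), 1e-12) / n_draws)
        assert abs(mc - exact) <= max(3 * se, 1e-6)

    def test_cdf_is_proper(self, rng):
        pmf = rng.dirichlet(np.ones(5))
        cdf = seeder.null_cdf(pmf, 4)
        assert np.all(np.diff(cdf) >= -1e-12)
        assert cdf[-1] == pytest.approx(1.0)


class TestDiscover:
    def test_null_subgroups_controlled(self, rng):
        """Background-distributed subgroups yield few (BH-controlled) hits."""
        bg_seqs = simulate_background(400, 150, seed=21)
        bg = seeder.build_background(bg_seqs, 6)
        fore = simulate_background(50, 150, seed=22)
        scheme = seeder.SubgroupScheme(n_subgroups=20, subgroup_size=10, seed=3)
        groups = seeder.make_subgroups(fore, scheme)
        motifs = seeder.discover(groups, bg, 0.05)
        # null data: expect approximately zero enriched seed families
        assert len(motifs) <= 10

    def test_planted_motif_detected(self):
        """A 6-mer present once per foreground sequence, rare in background,
        is reported at q <= 0.05 in >= 90% of subgroups."""
        motif = "TGTGTA"
        bg_seqs = simulate_background(1000, 150, seed=31)
        bg = seeder.build_background(bg_seqs, 6)
        rng = np.random.default_rng(32)
        fore = []
        for i in range(50):
            seq = list("".join(rng.choice(list("ACGT"), size=150,
                                          p=[0.325, 0.175, 0.175, 0.325])))
            pos = int(rng.integers(0, 145))
            seq[pos : pos + 6] = motif
            fore.append(SequenceRecord(f"f{i}", "".join(seq), "utr3"))
        scheme = seeder.SubgroupScheme(n_subgroups=100, subgroup_size=10, seed=33)
        groups = seeder.make_subgroups(fore, scheme)
        motifs = seeder.discover(groups, bg, 0.05)
        hit = [m for m in motifs if m.seed == motif]
        assert hit
        assert hit[0].n_subgroups_significant >= 90

    def test_zero_threshold_empty(self, rng):
        bg_seqs = simulate_background(50, 100, seed=41)
        bg = seeder.build_background(bg_seqs, 6)
        groups = seeder.make_subgroups(bg_seqs[:20], seeder.SubgroupScheme(5, 5, 1))
        assert seeder.discover(groups, bg, 1e-300) == []

    def test_deterministic(self):
        bg_seqs = simulate_background(100, 100, seed=51)
        bg = seeder.build_background(bg_seqs, 6)
        fore = simulate_background(30, 100, seed=52)
        scheme = seeder.SubgroupScheme(n_subgroups=10, subgroup_size=8, seed=53)
        a = seeder.discover(seeder.make_subgroups(fore, scheme), bg, 0.5)
        b = seeder.discover(seeder.make_subgroups(fore, scheme), bg, 0.5)
        assert [(m.seed, m.best_q, m.best_score) for m in a] == [
            (m.seed, m.best_q, m.best_score) for m in b
        ]


class TestExtendToPwm:
    def test_identical_sites_near_indicator(self):
        group = [SequenceRecord(f"g{i}", "AAAA" + "TGTGTA" + "CCCC", "utr3") for i in range(10)]
        pwm = seeder.extend_to_pwm("TGTGTA", group)
        consensus = "".join("ACGT"[j] for j in pwm.argmax(axis=1))
        assert consensus == "TGTGTA"
        assert pwm.max() > 0.9

    def test_mixture_position(self):
        group = [
            SequenceRecord("a", "TGTGTA", "utr3"),
            SequenceRecord("b", "TGAGTA", "utr3"),
        ]
        pwm = seeder.extend_to_pwm("TGTGTA", group)
        # position 3: one T, one A (plus pseudocounts)
        assert pwm[2, 0] == pytest.approx(pwm[2, 3])

    def test_rows_normalized(self, rng):
        group = [
            SequenceRecord(f"g{i}", "".join(rng.choice(list("ACGT"), size=40)), "utr3")
            for i in range(8)
        ]
        pwm = seeder.extend_to_pwm("ACGTAC", group)
        np.testing.assert_allclose(pwm.sum(axis=1), 1.0, atol=1e-9)
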