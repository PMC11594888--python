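import numpy as np
import pytest

from popsweep.annotate import GeneModel
from popsweep.sweep import (
    Window,
    fst_bins,
    joint_select,
    make_windows,
    site_pi,
    window_fst,
    window_pi,
    windows_to_genes,
)
from popsweep.variants import MISSING

from conftest import make_gm


class TestMakeWindows:
    def test_enumeration_250kb(self):
        wins = make_windows({"c": 250_000}, size=100_000, step=50_000)
        starts = [w.start for w in wins]
        assert starts == [1, 50_001, 100_001, 150_001, 200_001]
        assert wins[0].end == 100_000
        assert wins[-1].end == 250_000  # truncated at chromosome end

    def test_step_equals_size_tiles(self):
        wins = make_windows({"c": 300_000}, size=100_000, step=100_000)
        assert [(w.start, w.end) for w in wins] == [
            (1, 100_000),
            (100_001, 200_000),
            (200_001, 300_000),
        ]

    def test_count_closed_form(self):
        for L in (123_456, 100_000, 250_000, 1_000_001):
            wins = make_windows({"c": L}, size=100_000, step=50_000)
            assert len(wins) == (L - 1) // 50_000 + 1

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, size=0)
        with pytest.raises(ValueError):
            make_windows({"c": 100}, size=10, step=20)


def wc_oracle_site(counts1, counts2):
    """Literal per-site Weir & Cockerham (1984) components for two pops.

    counts = (n_homref, n_het, n_homalt).  Returns (a, b, c).
    """
    r = 2
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - 1.0
        / (nbar - 1)
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _counts_of(column):
    return (
        int(np.sum(column == 0)),
        int(np.sum(column == 1)),
        int(np.sum(column == 2)),
    )


class TestWindowFst:
    def test_opposite_fixation_is_one(self):
        calls = np.array([[0] * 5] * 3 + [[2] * 5] * 3, dtype=np.int8)
        g = make_gm(calls)
        wins = make_windows({"chr1": 1000}, size=1000, step=1000)
        fst = window_fst(g, ["s0", "s1", "s2"], ["s3", "s4", "s5"], wins)
        assert fst[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(6, 200), dtype=np.int8)
        calls = np.vstack([block, block])  # mirror-image populations
        g = make_gm(calls, positions=np.arange(1, 201))
        wins = make_windows({"chr1": 200}, size=200, step=200)
        pop1 = [f"s{i}" for i in range(6)]
        pop2 = [f"s{i}" for i in range(6, 12)]
        fst = window_fst(g, pop1, pop2, wins)
        assert fst[0] <= 1e-9  # estimator noise is non-positive here

    def test_five_snp_toy_matches_oracle(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(6, 5), dtype=np.int8)
        g = make_gm(calls)
        wins = make_windows({"chr1": 1000}, size=1000, step=1000)
        pop1 = [f"s{i}" for i in range(3)]
        pop2 = [f"s{i}" for i in range(3, 6)]
        fst = window_fst(g, pop1, pop2, wins)
        num = den = 0.0
        for k in range(5):
            a, b, c = wc_oracle_site(_counts_of(calls[:3, k]), _counts_of(calls[3:, k]))
            num += a
            den += a + b + c
        assert fst[0] == pytest.approx(num / den, abs=1e-10)

    def test_symmetric_in_population_labels(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(8, 50), dtype=np.int8)
        g = make_gm(calls)
        wins1 = make_windows({"chr1": 10_000}, size=10_000, step=10_000)
        wins2 = make_windows({"chr1": 10_000}, size=10_000, step=10_000)
        pop1 = [f"s{i}" for i in range(4)]
        pop2 = [f"s{i}" for i in range(4, 8)]
        f12 = window_fst(g, pop1, pop2, wins1)
        f21 = window_fst(g, pop2, pop1, wins2)
        np.testing.assert_allclose(f12, f21, atol=1e-12)

    def test_empty_population_rejected(self):
        g = make_gm([[0], [1]])
        with pytest.raises(ValueError):
            window_fst(g, [], ["s0"], make_windows({"chr1": 100}, 100, 100))

    def test_empty_window_undefined(self):
        g = make_gm([[0], [1]], positions=[10])
        wins = make_windows({"chr1": 1000}, size=500, step=500)
        fst = window_fst(g, ["s0"], ["s1"], wins)
        assert np.isnan(fst[1])


class TestWindowPi:
    def test_single_site_combinatorics(self):
        # hom-ref + hom-alt diploids: 2*2 ref-alt pairs / C(4,2) = 2/3 per site
        g = make_gm([[0], [2]], positions=[5])
        wins = [Window("chr1", 1, 10)]
        pi = window_pi(g, ["s0", "s1"], wins)
        assert pi[0] == pytest.approx((2.0 / 3.0) / 10.0)

    def test_fixed_population_zero(self):
        g = make_gm([[2, 2], [2, 2]])
        wins = [Window("chr1", 1, 1000)]
        assert window_pi(g, ["s0", "s1"], wins)[0] == 0.0

    def test_doubling_length_halves_pi(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(6, 20), dtype=np.int8)
        g = make_gm(calls, positions=np.arange(1, 21))
        pops = [f"s{i}" for i in range(6)]
        short = window_pi(g, pops, [Window("chr1", 1, 100)])
        long = window_pi(g, pops, [Window("chr1", 1, 200)])
        assert long[0] == pytest.approx(short[0] / 2.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(6, 30), dtype=np.int8)
        g = make_gm(calls)
        pops = [f"s{i}" for i in range(6)]
        w1 = window_pi(g, pops, [Window("chr1", 1, 5000)])
        w2 = window_pi(g, pops[::-1], [Window("chr1", 1, 5000)])
        np.testing.assert_allclose(w1, w2)

    def test_brute_force_pair_enumeration(self):
        """site pi equals explicit enumeration of chromosome pairs."""
        rng = np.random.default_rng(5)
        calls = rng.integers(-1, 3, size=(5, 12), dtype=np.int8)
        pi = site_pi(calls)
        for k in range(12):
            chroms = []
            for c in calls[:, k]:
                if c == MISSING:
                    continue
                chroms += [1] * int(c) + [0] * (2 - int(c))
            n = len(chroms)
            if n < 2:
                assert pi[k] == 0.0
                continue
            diff = sum(
                1
                for i in range(n)
                for j in range(i + 1, n)
                if chroms[i] != chroms[j]
            )
            assert pi[k] == pytest.approx(diff / (n * (n - 1) / 2), abs=1e-12)


class TestFstBins:
    def test_all_zero(self):
        wins = [Window("c", 1, 10, n_snps=1, fst=0.0) for _ in range(5)]
        assert fst_bins(wins) == (1.0, 0.0, 0.0)

    def test_constructed_fractions(self):
        wins = [Window("c", 1, 10, n_snps=1, fst=0.01) for _ in range(19)]
        wins.append(Window("c", 1, 10, n_snps=1, fst=0.1))
        lo, mid, hi = fst_bins(wins)
        assert (lo, mid, hi) == pytest.approx((0.95, 0.05, 0.0))

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        wins = [
            Window("c", 1, 10, n_snps=1, fst=f) for f in rng.uniform(-0.02, 0.5, 50)
        ]
        assert sum(fst_bins(wins)) == pytest.approx(1.0)

    def test_no_defined_fst_rejected(self):
        with pytest.raises(ValueError):
            fst_bins([Window("c", 1, 10)])


def _windows_with_stats(fst, pi_focal, pi_other, focal="SL", other="TL"):
    wins = []
    for f, pf, po in zip(fst, pi_focal, pi_other):
        w = Window("c", 1, 10, n_snps=10, fst=f)
        w.pi[focal] = pf
        w.pi[other] = po
        wins.append(w)
    return wins


class TestJointSelect:
    def test_argmax_window_selected(self):
        rng = np.random.default_rng(7)
        fst = rng.uniform(0, 0.1, 100)
        pi_f = rng.uniform(1e-4, 1e-3, 100)
        pi_o = rng.uniform(1e-4, 1e-3, 100)
        fst[17] = 0.9
        pi_f[17] = 1e-6  # depleted focal diversity
        wins = _windows_with_stats(fst, pi_f, pi_o)
        res = joint_select(wins, "SL")
        assert wins[17] in res.selected
        assert wins[17].selected_for == "SL"

    def test_quantile_one_selects_nothing(self):
        rng = np.random.default_rng(8)
        wins = _windows_with_stats(
            rng.uniform(0, 1, 50), rng.uniform(0, 1e-3, 50), rng.uniform(0, 1e-3, 50)
        )
        assert joint_select(wins, "SL", quantile=1.0).selected == []

    def test_quantile_zero_selects_everything(self):
        rng = np.random.default_rng(9)
        wins = _windows_with_stats(
            rng.uniform(0, 1, 50), rng.uniform(1e-4, 1e-3, 50), rng.uniform(1e-4, 1e-3, 50)
        )
        res = joint_select(wins, "SL", quantile=0.0)
        assert len(res.selected) == 50

    def test_independence_null_expectation(self):
        # independent uniform statistics: E[selected] ~ 400 * 0.05 * 0.05 = 1
        total = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            wins = _windows_with_stats(
                rng.uniform(0, 1, 400),
                rng.uniform(1e-4, 1e-3, 400),
                rng.uniform(1e-4, 1e-3, 400),
            )
            total += len(joint_select(wins, "SL").selected)
        mean = total / n_rep
        # binomial(400, 0.0025) mean 1, sd 1 -> generous Monte Carlo band
        assert 0.4 < mean < 2.0

    def test_raw_mode_ranks_low_focal_pi(self):
        rng = np.random.default_rng(10)
        fst = rng.uniform(0, 0.1, 100)
        pi_f = rng.uniform(1e-4, 1e-3, 100)
        pi_o = rng.uniform(1e-4, 1e-3, 100)
        fst[3] = 0.9
        pi_f[3] = 1e-7
        wins = _windows_with_stats(fst, pi_f, pi_o)
        res = joint_select(wins, "SL", pi_mode="raw")
        assert wins[3] in res.selected

    def test_zero_pi_pseudocount(self):
        rng = np.random.default_rng(11)
        fst = rng.uniform(0, 0.1, 30)
        pi_f = rng.uniform(1e-4, 1e-3, 30)
        pi_o = rng.uniform(1e-4, 1e-3, 30)
        pi_f[5] = 0.0
        fst[5] = 0.95
        wins = _windows_with_stats(fst, pi_f, pi_o)
        res = joint_select(wins, "SL")
        assert wins[5] in res.selected  # zero diversity = maximal statistic

    def test_too_few_windows_rejected(self):
        wins = _windows_with_stats([0.1] * 5, [1e-4] * 5, [1e-4] * 5)
        with pytest.raises(ValueError):
            joint_select(wins, "SL")


class TestWindowsToGenes:
    def _models(self):
        return [
            GeneModel("g1", "c", "+", 100, 200, [(100, 200)], []),
            GeneModel("g2", "c", "+", 950, 1200, [(950, 1200)], []),
            GeneModel("g3", "c", "-", 5000, 6000, [(5000, 6000)], []),
            GeneModel("g4", "x", "+", 100, 200, [(100, 200)], []),
        ]

    def test_gene_inside_window(self):
        wins = [Window("c", 1, 1000)]
        per, union = windows_to_genes(wins, self._models())
        assert per[0] == ["g1", "g2"]
        assert union == ["g1", "g2"]

    def test_gene_spanning_two_windows_counted_once(self):
        wins = [Window("c", 1, 1000), Window("c", 500, 1500)]
        _per, union = windows_to_genes(wins, self._models())
        assert union.count("g2") == 1

    def test_exact_overlap_lists(self):
        wins = [
            Window("c", 1, 90),  # nothing
            Window("c", 150, 1000),  # g1 partial, g2 partial
            Window("c", 5500, 5600),  # inside g3
            Window("x", 1, 300),  # g4 on other chromosome
            Window("c", 10_000, 11_000),  # nothing
        ]
        per, union = windows_to_genes(wins, self._models())
        assert per[0] == []
        assert per[1] == ["g1", "g2"]
        assert per[2] == ["g3"]
        assert per[3] == ["g4"]
        assert per[4] == []
        assert union == ["g1", "g2", "g3", "g4"]


class TestSweepRecoveryProperty:
    def test_planted_sweep_recovered(self, small_sim):
        cfg, sim = small_sim
        from popsweep.variants import filter_variants

        g, _ = filter_variants(sim.genotypes)
        wins = make_windows(cfg.chrom_lengths)
        tl = [s for s in g.samples if s.startswith("TL")]
        sl = [s for s in g.samples if s.startswith("SL")]
        window_fst(g, tl, sl, wins)
        window_pi(g, tl, wins, label="TL")
        window_pi(g, sl, wins, label="SL")
        res = joint_select(wins, "SL")
        region = cfg.sweep_regions[0]
        hit = any(
            w.chrom == region.chrom and w.start <= region.end and w.end >= region.start
            for w in res.selected
        )
        assert hit, "planted sweep region not recovered"
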