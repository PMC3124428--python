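"""Multi-locus profiling, epoch integration, and ranking."""

import numpy as np
import pytest

import phyloinform as pf
from phyloinform.io_phylo import ValidationError
from phyloinform.simulate import SimulationSpec, simulate_alignment, yule_tree


def const_vector(name, lam, n):
    return pf.SiteRateVector(name, np.full(n, float(lam)), np.zeros(n, bool))


class TestProfileLoci:
    def test_identical_rate_vectors_identical_curves(self):
        a = const_vector("a", 0.7, 50)
        b = const_vector("b", 0.7, 50)
        prof = pf.profile_loci([a, b], depth=2.0, n_points=100)
        na, pa = prof.curves["a"]
        nb, pb = prof.curves["b"]
        assert np.array_equal(na, nb) and np.array_equal(pa, pb)

    def test_single_site_curve_is_rho(self):
        v = pf.SiteRateVector("one", np.array([1.0]), np.array([False]))
        prof = pf.profile_loci([v], depth=2.0, n_points=2001)
        net, per = prof.curves["one"]
        assert per == pytest.approx(pf.rho(prof.grid, 1.0))
        # peak near t = 1/4
        assert prof.grid[int(np.argmax(per))] == pytest.approx(0.25, abs=2e-3)

    def test_partition_nets_sum_to_locus_net(self):
        tree = yule_tree(8, 1.0, 31)
        aln, _ = simulate_alignment(
            SimulationSpec(n_sites=60, seed=8, tree=tree, rate_model="gamma"))
        rng = np.random.default_rng(0)
        left = sorted(rng.choice(np.arange(1, 61), size=25, replace=False))
        right = sorted(set(range(1, 61)) - set(left))
        aln.partitions = {"p1": list(map(int, left)), "p2": right}
        prof = pf.profile_loci([aln], tree, n_points=50)
        assert set(prof.loci) == {"sim", "sim:p1", "sim:p2"}
        total = prof.curves["sim"][0]
        assert prof.curves["sim:p1"][0] + prof.curves["sim:p2"][0] == pytest.approx(
            total, rel=1e-10
        )

    def test_net_is_per_site_times_count(self):
        v = const_vector("x", 1.3, 37)
        prof = pf.profile_loci([v], depth=1.0, n_points=20)
        net, per = prof.curves["x"]
        assert net == pytest.approx(per * 37, rel=1e-12)

    def test_disjoint_taxa_error_names_locus(self, make_tree):
        tree = make_tree("(A:1,B:1);")
        aln = pf.Alignment("orphan", ["X", "Y"], ["AC", "AG"], "DNA")
        with pytest.raises(ValidationError, match="orphan"):
            pf.profile_loci([aln], tree)

    def test_alignment_without_tree_rejected(self):
        aln = pf.Alignment("x", ["A", "B"], ["AC", "AG"], "DNA")
        with pytest.raises(ValidationError, match="tree"):
            pf.profile_loci([aln])


class TestRankLoci:
    def setup_method(self):
        self.fast = const_vector("fast", 2.0, 300)
        self.slow = const_vector("slow", 0.1, 300)

    def test_deep_epoch_favors_slow_locus(self):
        rk = pf.rank_loci([self.fast, self.slow], pf.Epoch(2, 3), depth=3.0)
        assert [e.locus for e in rk.entries] == ["slow", "fast"]
        # closed-form oracle values (cross-checked by quadrature elsewhere)
        assert rk.entries[0].integral_per_site == pytest.approx(0.146165, abs=1e-4)
        assert rk.entries[1].integral_per_site == pytest.approx(1.91e-6, abs=1e-7)

    def test_shallow_epoch_favors_fast_locus(self):
        rk = pf.rank_loci([self.fast, self.slow], pf.Epoch(0, 0.2), depth=3.0)
        assert [e.locus for e in rk.entries] == ["fast", "slow"]

    def test_single_locus_ranks_first(self):
        rk = pf.rank_loci([self.fast], pf.Epoch(0, 1), depth=3.0)
        assert rk.entries[0].rank == 1

    def test_epoch_beyond_depth_rejected(self):
        with pytest.raises(ValidationError, match="allowed range"):
            pf.rank_loci([self.fast], pf.Epoch(2, 4), depth=3.0)

    def test_competition_ranking_for_ties(self):
        a = const_vector("a", 1.0, 10)
        b = const_vector("b", 1.0, 10)
        c = const_vector("c", 0.1, 10)
        rk = pf.rank_loci([c, b, a], pf.Epoch(0, 0.5), depth=1.0)
        assert [(e.locus, e.rank, e.tied) for e in rk.entries] == [
            ("a", 1, True), ("b", 1, True), ("c", 3, False)
        ]

    def test_net_basis_rewards_length(self):
        long = const_vector("long", 0.5, 1000)
        short = const_vector("short", 0.5, 10)
        rk_net = pf.rank_loci([short, long], pf.Epoch(0, 1), depth=1.0, basis="net")
        assert rk_net.entries[0].locus == "long"
        # per-site basis is invariant to duplicating columns
        rk_ps = pf.rank_loci([short, long], pf.Epoch(0, 1), depth=1.0)
        assert rk_ps.entries[0].integral_per_site == pytest.approx(
            rk_ps.entries[1].integral_per_site
        )

    def test_ranking_invariant_under_tree_rescaling(self):
        rng = np.random.default_rng(12)
        vecs = [
            pf.SiteRateVector(f"L{i}", rng.gamma(0.5, 1.0, 40),
                              np.zeros(40, bool))
            for i in range(5)
        ]
        rk = pf.rank_loci(vecs, pf.Epoch(0.2, 0.8), depth=1.0)
        c = 10.0
        scaled = [
            pf.SiteRateVector(v.locus_name, v.rates / c, v.faulty) for v in vecs
        ]
        rk_s = pf.rank_loci(scaled, pf.Epoch(0.2 * c, 0.8 * c), depth=c)
        assert [e.locus for e in rk.entries] == [e.locus for e in rk_s.entries]

    def test_shallow_epoch_prefers_faster_of_proportional_vectors(self):
        rng = np.random.default_rng(4)
        lam = rng.gamma(1.0, 0.5, 30)
        a = pf.SiteRateVector("base", lam, np.zeros(30, bool))
        b = pf.SiteRateVector("x3", 3 * lam, np.zeros(30, bool))
        rk = pf.rank_loci([a, b], pf.Epoch(0, 0.01), depth=1.0)
        assert rk.entries[0].locus == "x3"


class TestMultiEpoch:
    def test_epoch_partition_sums_to_total(self):
        rng = np.random.default_rng(9)
        v = pf.SiteRateVector("L", rng.gamma(0.5, 1.0, 80), np.zeros(80, bool))
        parts = pf.multi_epoch_report(
            [v], [pf.Epoch(0, 0.3), pf.Epoch(0.3, 0.7), pf.Epoch(0.7, 1.0)],
            depth=1.0)
        whole = pf.rank_loci([v], pf.Epoch(0, 1.0), depth=1.0)
        total = sum(rk.entries[0].integral_net for rk in parts)
        assert total == pytest.approx(whole.entries[0].integral_net, rel=1e-12)

    def test_duplicate_epochs_identical(self):
        v = const_vector("L", 1.0, 10)
        r1, r2 = pf.multi_epoch_report(
            [v], [pf.Epoch(0, 0.5), pf.Epoch(0, 0.5)], depth=1.0)
        assert r1.entries == r2.entries

    def test_empty_epoch_list_rejected(self):
        with pytest.raises(ValidationError):
            pf.multi_epoch_report([const_vector("L", 1, 5)], [], depth=1.0)

    def test_opposite_order_across_crossover(self):
        fast = const_vector("fast", 2.0, 30)
        slow = const_vector("slow", 0.3, 30)
        early, late = pf.multi_epoch_report(
            [fast, slow], [pf.Epoch(0, 0.2), pf.Epoch(1.5, 2.0)], depth=2.0)
        assert early.entries[0].locus == "fast"
        assert late.entries[0].locus == "slow"

    def test_combined_frame_shape(self):
        from phyloinform.profiler import combined_ranking_frame

        vecs = [const_vector(n, l, 10) for n, l in [("a", 1.0), ("b", 0.2)]]
        rks = pf.multi_epoch_report(
            vecs, [pf.Epoch(0, 0.5), pf.Epoch(0.5, 1.0)], depth=1.0)
        df = combined_ranking_frame(rks)
        assert df.shape == (2, 6)
        assert set(df.index) == {"a", "b"}
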