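import numpy as np
import pytest
from scipy.stats import chi2_contingency

from methvalley import (
    DmrCriteria,
    ValidationError,
    aggregate_window_counts,
    bh_adjust,
    call_dmrs,
    chisq_2x2,
    dmr_associated_genes,
    scan_dmr_windows,
    tile_windows,
)
from methvalley.io import GeneModel, GenomicInterval

from conftest import make_sample


class TestTiling:
    def test_partial_final_tile(self):
        tiles = tile_windows({"chr1": 500}, 200)
        assert [(t.start, t.end) for t in tiles] == [(0, 200), (200, 400), (400, 500)]

    def test_exact_fit_single_tile(self):
        assert len(tile_windows({"chr1": 200}, 200)) == 1

    def test_unit_windows(self):
        assert len(tile_windows({"chr1": 7}, 1)) == 7


class TestAggregation:
    def test_replicates_pool_reads_but_not_positions(self):
        a = make_sample([("chr1", 50, "+", "CG", 3, 1)], {"chr1": 200})
        b = make_sample([("chr1", 50, "+", "CG", 3, 1)], {"chr1": 200}, replicate=2)
        n, meth, total = aggregate_window_counts(
            [a, b], GenomicInterval("chr1", 0, 200), "CG"
        )
        assert (n, meth, total) == (1, 6, 8)

    def test_low_coverage_site_excluded_per_sample(self):
        a = make_sample([("chr1", 50, "+", "CG", 2, 1)], {"chr1": 200})
        n, meth, total = aggregate_window_counts(
            [a], GenomicInterval("chr1", 0, 200), "CG", min_site_cov=4
        )
        assert (n, meth, total) == (0, 0, 0)

    def test_empty_window(self):
        a = make_sample([("chr1", 50, "+", "CG", 3, 1)], {"chr1": 1000})
        assert aggregate_window_counts(
            [a], GenomicInterval("chr1", 500, 700), "CG"
        ) == (0, 0, 0)

    def test_all_c_pools_contexts(self):
        a = make_sample([
            ("chr1", 10, "+", "CG", 4, 0), ("chr1", 20, "+", "CHG", 0, 4),
            ("chr1", 30, "-", "CHH", 2, 2),
        ], {"chr1": 200})
        n, meth, total = aggregate_window_counts(
            [a], GenomicInterval("chr1", 0, 200), "ALL_C"
        )
        assert (n, meth, total) == (3, 6, 12)


class TestChiSquare:
    def test_identical_proportions(self):
        stat, p = chisq_2x2(50, 50, 50, 50)
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # expected counts all 50; sum (obs-exp)^2/exp = 4 * 1600/50 = 128
        stat, _ = chisq_2x2(90, 10, 10, 90)
        assert stat == pytest.approx(128.0)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(ValidationError, match="degenerate"):
            chisq_2x2(0, 10, 0, 10)

    @pytest.mark.parametrize("table", [
        (90, 10, 10, 90), (5, 15, 12, 8), (1, 99, 3, 97), (40, 1, 2, 39),
    ])
    def test_matches_scipy_without_correction(self, table):
        stat, p = chisq_2x2(*table)
        obs = np.array(table, dtype=float).reshape(2, 2)
        ref = chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_step_up_hand_computation(self):
        # q_i = min over j >= i of p_j * m / j
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_order_preserved_and_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.shape == p.shape


class TestCallDmrs:
    def _planted_groups(self):
        """6 CG positions in one window; group A ~90% methylated, B ~10%."""
        pos = [10, 30, 50, 70, 90, 110]
        rec_a = [("chr1", p, "+", "CG", 15, 2) for p in pos]  # 90/12 reads
        rec_b = [("chr1", p, "+", "CG", 2, 15) for p in pos]
        a = [make_sample(rec_a, {"chr1": 400})]
        b = [make_sample(rec_b, {"chr1": 400}, tissue="leaf")]
        return a, b

    def test_planted_window_called(self):
        a, b = self._planted_groups()
        dmrs = call_dmrs(a, b, DmrCriteria.for_context("CG"))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.interval.start, d.interval.end) == (0, 200)
        assert d.diff == pytest.approx(90 / 102 - 12 / 102)
        assert d.q <= 0.05 and abs(d.diff) >= 0.25 and d.n_sites >= 5

    def test_identical_groups_give_no_dmrs(self):
        a, _ = self._planted_groups()
        assert call_dmrs(a, a, DmrCriteria.for_context("CG")) == []

    def test_min_sites_required_in_both_groups(self):
        a, b = self._planted_groups()
        # drop group B to 4 positions: window must not be tested
        b4 = [make_sample([("chr1", p, "+", "CG", 2, 15) for p in (10, 30, 50, 70)],
                          {"chr1": 400}, tissue="leaf")]
        scan = scan_dmr_windows(a, b4, DmrCriteria.for_context("CG"))
        assert len(scan) == 0

    def test_empty_group_rejected(self):
        a, _ = self._planted_groups()
        with pytest.raises(ValidationError):
            call_dmrs(a, [], DmrCriteria.for_context("CG"))

    def test_every_reported_dmr_satisfies_all_criteria(self, study):
        crit = DmrCriteria.for_context("CG")
        dmrs = call_dmrs(study.samples_for("root"), study.samples_for("leaf"), crit)
        assert dmrs, "planted differential windows should be detected"
        for d in dmrs:
            assert abs(d.diff) >= crit.min_abs_diff
            assert d.q <= crit.q_max
            assert d.n_sites >= crit.min_sites

    def test_planted_chh_windows_recovered(self, study):
        dmrs = call_dmrs(
            study.samples_for("root"), study.samples_for("leaf"),
            DmrCriteria.for_context("CHH"),
        )
        found = {(d.interval.chrom, d.interval.start) for d in dmrs}
        planted = {
            (d.interval.chrom, d.interval.start)
            for d in study.truth.dmr_windows if d.context == "CHH"
        }
        assert len(found & planted) >= 0.9 * len(planted)


class TestDmrGeneAssociation:
    GENES = [
        GeneModel("near", GenomicInterval("chr1", 1500, 3000, "+"), "+"),
        GeneModel("far", GenomicInterval("chr1", 2300, 3000, "+"), "+"),
        GeneModel("hit", GenomicInterval("chr1", 50, 150, "-"), "-"),
    ]

    def _dmr(self):
        from methvalley.dmr import DmrRecord
        return [DmrRecord(GenomicInterval("chr1", 0, 200), "CG",
                          0.9, 0.1, 0.8, 6, 100.0, 1e-10, 1e-9)]

    def test_flank_rule(self):
        assoc = dmr_associated_genes(self._dmr(), self.GENES, flank=2000)
        assert assoc == {"near", "hit"}  # gap 1300 in, gap 2100 out, body overlap in

    def test_zero_flank(self):
        assoc = dmr_associated_genes(self._dmr(), self.GENES, flank=0)
        assert assoc == {"hit"}
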