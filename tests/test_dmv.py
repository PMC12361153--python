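import numpy as np
import pytest

from methvalley import (
    DmvParams,
    detect_dmvs,
    dmv_genes,
    dmv_tissue_overlap,
    sliding_windows,
    window_mean_level,
)
from methvalley.io import GeneModel, GenomicInterval
from methvalley.dmv import DmvRegion

from conftest import make_sample


def brute_force_dmvs(sample, params):
    """Independent enumerate-filter-merge oracle, one window at a time."""
    regions = []
    for chrom in sample.chrom_order():
        size = sample.chrom_sizes[chrom]
        qualifying = []
        start = 0
        while start + params.window_size <= size:
            win = GenomicInterval(chrom, start, start + params.window_size)
            mean, n = window_mean_level_slow(sample, win, params.min_site_cov)
            if n >= params.min_sites_per_window and mean is not None and mean < params.max_level:
                qualifying.append((start, start + params.window_size))
            start += params.step
        # merge by >= 1 bp overlap
        merged = []
        for s, e in qualifying:
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        regions += [(chrom, s, e) for s, e in merged]
    return regions


def window_mean_level_slow(sample, window, min_site_cov):
    """Per-site loop, no prefix sums."""
    levels = []
    for s in sample.iter_sites():
        if s.chrom != window.chrom:
            continue
        if s.coverage < max(min_site_cov, 1):
            continue
        if window.start <= s.pos - 1 < window.end:
            levels.append(s.meth_reads / s.coverage)
    if not levels:
        return None, 0
    return float(np.mean(levels)), len(levels)


def random_instance(rng, size):
    """Random methylome with alternating low/high blocks on one chromosome."""
    n_blocks = rng.integers(2, 8)
    bounds = np.sort(rng.choice(np.arange(200, size - 200, 100),
                                size=n_blocks - 1, replace=False))
    bounds = [0, *bounds.tolist(), size]
    records = []
    pos = 1
    for b0, b1, low in zip(bounds, bounds[1:], rng.integers(0, 2, size=n_blocks)):
        p = rng.uniform(0.0, 0.04) if low else rng.uniform(0.2, 0.9)
        step = int(rng.integers(15, 60))
        for pos in range(b0 + 1, b1 + 1, step):
            cov = int(rng.poisson(10))
            meth = int(rng.binomial(cov, p))
            ctx = ("CG", "CHG", "CHH")[rng.integers(3)]
            records.append(("chr1", pos, "+", ctx, meth, cov - meth))
    return make_sample(records, {"chr1": size})


class TestSlidingWindows:
    def test_step_windows_drop_partial_tail(self):
        wins = sliding_windows({"chr1": 1400}, 1000, 200)
        assert [w.start for w in wins] == [0, 200, 400]

    def test_too_short_chromosome(self):
        assert sliding_windows({"chr1": 999}, 1000, 200) == []

    def test_step_equal_to_window_tiles(self):
        wins = sliding_windows({"chr1": 3000}, 1000, 1000)
        assert [(w.start, w.end) for w in wins] == [(0, 1000), (1000, 2000), (2000, 3000)]


class TestWindowMean:
    def test_unweighted_site_mean(self):
        s = make_sample([("chr1", 10, "+", "CG", 0, 10), ("chr1", 20, "+", "CHH", 1, 9)],
                        {"chr1": 2000})
        mean, n = window_mean_level(s, GenomicInterval("chr1", 0, 1000), min_site_cov=4)
        assert (mean, n) == (pytest.approx(0.05), 2)

    def test_no_sites_is_missing(self):
        s = make_sample([("chr1", 10, "+", "CG", 0, 10)], {"chr1": 5000})
        mean, n = window_mean_level(s, GenomicInterval("chr1", 2000, 3000))
        assert (mean, n) == (None, 0)

    def test_single_site(self):
        s = make_sample([("chr1", 10, "+", "CG", 2, 8)], {"chr1": 2000})
        mean, _ = window_mean_level(s, GenomicInterval("chr1", 0, 1000))
        assert mean == pytest.approx(0.2)


class TestDetectDmvs:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            size = int(rng.integers(3_000, 30_000))
            sample = random_instance(rng, size)
            params = DmvParams(
                window_size=int(rng.choice([600, 1000])),
                step=int(rng.choice([200, 300])),
                max_level=float(rng.choice([0.05, 0.15])),
                min_site_cov=int(rng.choice([1, 4])),
                min_sites_per_window=int(rng.choice([1, 5])),
            )
            got = [(r.interval.chrom, r.interval.start, r.interval.end)
                   for r in detect_dmvs(sample, params)]
            assert got == brute_force_dmvs(sample, params)

    def test_fully_unmethylated_genome_is_one_region_per_chromosome(self):
        records = [(c, p, "+", "CG", 0, 10)
                   for c in ("chr1", "chr2") for p in range(1, 5001, 50)]
        s = make_sample(records, {"chr1": 5000, "chr2": 5000})
        regions = detect_dmvs(s, DmvParams())
        assert [(r.interval.chrom, r.interval.start, r.interval.end) for r in regions] == [
            ("chr1", 0, 5000), ("chr2", 0, 5000)
        ]

    def test_uniform_ten_percent_yields_nothing(self):
        records = [("chr1", p, "+", "CG", 1, 9) for p in range(1, 5001, 25)]
        s = make_sample(records, {"chr1": 5000})
        assert detect_dmvs(s, DmvParams()) == []

    def test_raising_max_level_never_shrinks_coverage(self):
        rng = np.random.default_rng(5)
        sample = random_instance(rng, 20_000)
        covered = []
        for max_level in (0.02, 0.05, 0.10, 0.3):
            params = DmvParams(max_level=max_level, min_sites_per_window=1)
            covered.append(sum(len(r.interval) for r in detect_dmvs(sample, params)))
        assert covered == sorted(covered)

    def test_reported_bp_only_from_qualifying_windows(self):
        rng = np.random.default_rng(17)
        sample = random_instance(rng, 15_000)
        params = DmvParams(min_sites_per_window=1)
        regions = detect_dmvs(sample, params)
        qualifying_bp = set()
        for win in sliding_windows(sample.chrom_sizes, params.window_size, params.step):
            mean, n = window_mean_level(sample, win, params.min_site_cov)
            if n >= params.min_sites_per_window and mean is not None and mean < params.max_level:
                qualifying_bp.update(range(win.start, win.end))
        for r in regions:
            assert set(range(r.interval.start, r.interval.end)) <= qualifying_bp


class TestDmvGenes:
    REGIONS = [DmvRegion(GenomicInterval("chr1", 1000, 3000), 5, 0.01)]

    @pytest.mark.parametrize("start,end,expected", [
        (1200, 2000, True),   # fully inside
        (0, 2000, False),     # 50% overlap
        (1400, 3500, False),  # 76% overlap
        (600, 3000, True),    # exactly 2000/2400 < 0.8? no: 2000/2400 = 0.833
    ])
    def test_gene_fraction_rule(self, start, end, expected):
        gene = GeneModel("g", GenomicInterval("chr1", start, end, "+"), "+")
        assert (dmv_genes(self.REGIONS, [gene], 0.8) == {"g"}) is expected

    def test_exact_boundary_is_inclusive(self):
        gene = GeneModel("g", GenomicInterval("chr1", 1000, 3500, "+"), "+")
        # overlap 2000 / length 2500 = 0.8 exactly
        assert dmv_genes(self.REGIONS, [gene], 0.8) == {"g"}

    def test_cumulative_overlap_across_regions(self):
        regions = [
            DmvRegion(GenomicInterval("chr1", 0, 1000), 1, 0.0),
            DmvRegion(GenomicInterval("chr1", 1500, 2500), 1, 0.0),
        ]
        gene = GeneModel("g", GenomicInterval("chr1", 200, 2400, "+"), "+")
        # overlap 800 + 900 = 1700 of 2200 -> 0.77 < 0.8; widen second region
        assert dmv_genes(regions, [gene], 0.8) == set()
        regions[1] = DmvRegion(GenomicInterval("chr1", 1400, 2500), 1, 0.0)
        assert dmv_genes(regions, [gene], 0.8) == {"g"}


class TestTissueOverlap:
    def test_counts(self):
        counts, inter, union = dmv_tissue_overlap(
            {"R": {"a", "b", "c"}, "L": {"b", "c", "d"}}
        )
        assert counts == {"R": 3, "L": 3}
        assert (inter, union) == (2, 4)

    def test_disjoint_and_identical(self):
        assert dmv_tissue_overlap({"R": {"a"}, "L": {"b"}})[1] == 0
        counts, inter, union = dmv_tissue_overlap({"R": {"a"}, "L": {"a"}})
        assert inter == union == 1


class TestPlantedValleyRecovery:
    def test_per_valley_jaccard(self, study, pooled):
        regions = detect_dmvs(pooled["root"], DmvParams())
        detected = [(r.interval.chrom, r.interval.start, r.interval.end) for r in regions]
        for valley in study.truth.valleys:
            best = 0.0
            for chrom, s, e in detected:
                if chrom != valley.chrom:
                    continue
                inter = max(0, min(e, valley.end) - max(s, valley.start))
                union = (e - s) + len(valley) - inter
                best = max(best, inter / union)
            assert best >= 0.9, f"valley {valley} poorly recovered (J={best:.2f})"

    def test_root_leaf_dmv_gene_jaccard(self, study, pooled):
        sets = {
            t: dmv_genes(detect_dmvs(pooled[t], DmvParams()), study.genes)
            for t in ("root", "leaf")
        }
        inter = len(sets["root"] & sets["leaf"])
        union = len(sets["root"] | sets["leaf"])
        assert union > 0 and inter / union >= 0.95
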