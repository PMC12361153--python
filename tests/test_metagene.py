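import numpy as np
import pytest

from methvalley import metagene_profile
from methvalley.io import GeneModel, GenomicInterval

from conftest import make_sample


def dense_sample(size, level_fn, step=7, chrom="chr1"):
    """Sites every `step` bp on both strands with 10 reads at level_fn(pos0)."""
    records = []
    for pos0 in range(0, size, step):
        lvl = level_fn(pos0)
        meth = int(round(10 * lvl))
        ctx = ("CG", "CHG", "CHH")[pos0 % 3]
        strand = "+" if pos0 % 2 == 0 else "-"
        records.append((chrom, pos0 + 1, strand, ctx, meth, 10 - meth))
    return make_sample(records, {chrom: size})


def brute_force_profile(sample, genes, flank, U, B, D):
    """Independent per-gene, per-site bin assignment by explicit loops."""
    n_bins = U + B + D
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)
    for g in genes:
        start, end = g.interval.start, g.interval.end
        L = end - start
        for s in sample.iter_sites():
            if s.chrom != g.interval.chrom:
                continue
            p = s.pos - 1
            if g.strand == "+":
                if start - flank <= p < start:
                    b = (p - (start - flank)) // (flank // U)
                elif start <= p < end:
                    b = U + min((p - start) * B // L, B - 1)
                elif end <= p < end + flank:
                    b = U + B + (p - end) // (flank // D)
                else:
                    continue
            else:
                if end <= p < end + flank:
                    b = (end + flank - 1 - p) // (flank // U)
                elif start <= p < end:
                    b = U + (B - 1) - min((p - start) * B // L, B - 1)
                elif start - flank <= p < start:
                    b = U + B + (start - 1 - p) // (flank // D)
                else:
                    continue
            meth[b] += s.meth_reads
            total[b] += s.coverage
    with np.errstate(invalid="ignore"):
        return np.where(total > 0, meth / total, np.nan)


class TestMetageneProfile:
    def test_uniform_methylome_is_flat(self):
        sample = dense_sample(20_000, lambda p: 0.5)
        genes = [GeneModel("g", GenomicInterval("chr1", 8000, 11_000, "+"), "+")]
        prof = metagene_profile(sample, genes)
        for ctx in ("C", "CG", "CHG", "CHH"):
            vals = prof.values[ctx].dropna()
            assert np.allclose(vals, 0.5)

    def test_body_valley_with_hot_flanks(self):
        start, end = 8000, 11_000
        sample = dense_sample(20_000, lambda p: 0.0 if start <= p < end else 0.8)
        genes = [GeneModel("g", GenomicInterval("chr1", start, end, "+"), "+")]
        prof = metagene_profile(sample, genes)
        body = prof.body_slice()["C"].dropna()
        assert np.allclose(body, 0.0)
        flank_up = prof.values["C"].iloc[:prof.upstream_bins].dropna()
        assert np.allclose(flank_up, 0.8)
        # matches the independent per-gene binning oracle
        oracle = brute_force_profile(sample, genes, 2000, 20, 60, 20)
        got = prof.values["C"].to_numpy()
        assert np.allclose(got, oracle, equal_nan=True)

    def test_minus_strand_signal_lands_downstream(self):
        # methylation only at coordinates above the gene: for a minus-strand
        # gene that region is the 5' upstream flank
        start, end = 8000, 10_000
        sample = dense_sample(14_000, lambda p: 0.9 if p >= end else 0.0)
        gene_minus = [GeneModel("g", GenomicInterval("chr1", start, end, "-"), "-")]
        prof = metagene_profile(sample, gene_minus)
        up = prof.values["C"].iloc[:prof.upstream_bins].dropna()
        down = prof.values["C"].iloc[-prof.downstream_bins:].dropna()
        assert (up > 0.8).all()
        assert np.allclose(down, 0.0)

    def test_strand_reversal_reverses_bins_exactly(self):
        rng = np.random.default_rng(3)
        sample = dense_sample(30_000, lambda p: float(rng.uniform(0, 1)), step=11)
        fwd = [GeneModel("a", GenomicInterval("chr1", 5000, 8321, "+"), "+"),
               GeneModel("b", GenomicInterval("chr1", 15_000, 19_777, "+"), "+")]
        rev = [GeneModel(g.gene_id, GenomicInterval("chr1", g.interval.start,
                                                    g.interval.end, "-"), "-")
               for g in fwd]
        p_fwd = metagene_profile(sample, fwd)
        p_rev = metagene_profile(sample, rev)
        for ctx in ("C", "CG"):
            a = p_fwd.values[ctx].to_numpy()
            b = p_rev.values[ctx].to_numpy()[::-1]
            assert np.allclose(a, b, equal_nan=True)

    def test_pooling_is_read_weighted_union(self):
        sample = dense_sample(40_000, lambda p: (p % 100) / 100, step=9)
        g1 = [GeneModel("a", GenomicInterval("chr1", 5000, 8000, "+"), "+")]
        g2 = [GeneModel("b", GenomicInterval("chr1", 25_000, 29_000, "+"), "+")]
        p1 = metagene_profile(sample, g1)
        p2 = metagene_profile(sample, g2)
        p12 = metagene_profile(sample, g1 + g2)
        m = (p1.values["C"] * p1.total_reads["C"]).fillna(0) + \
            (p2.values["C"] * p2.total_reads["C"]).fillna(0)
        t = p1.total_reads["C"] + p2.total_reads["C"]
        expected = np.where(t > 0, m / t, np.nan)
        assert np.allclose(p12.values["C"].to_numpy(), expected, equal_nan=True)

    def test_short_gene_skipped_with_warning(self, caplog):
        sample = dense_sample(5000, lambda p: 0.5)
        genes = [GeneModel("tiny", GenomicInterval("chr1", 100, 140, "+"), "+"),
                 GeneModel("ok", GenomicInterval("chr1", 1000, 3000, "+"), "+")]
        prof = metagene_profile(sample, genes)
        assert prof.n_genes == 1


class TestPlantedGeneBodyHypomethylation:
    def test_preferential_genes_lower_than_constitutive_in_body(self, study, pooled):
        truth = study.truth
        by_id = {g.gene_id: g for g in study.genes}
        pref = [by_id[g] for g, c in truth.gene_classes.items()
                if c.kind in ("exclusive", "preferential") and c.tissue == "root"
                and "vgene" in g]
        constitutive = [by_id[g] for g, c in truth.gene_classes.items()
                        if c.kind == "constitutive" and "vgene" not in g]
        p_pref = metagene_profile(pooled["root"], pref)
        p_const = metagene_profile(pooled["root"], constitutive)
        a = p_pref.body_slice()["CG"].to_numpy()
        b = p_const.body_slice()["CG"].to_numpy()
        ok = np.sum(a < b)
        assert ok >= 0.9 * len(a)
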