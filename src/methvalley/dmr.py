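"""Sliding-window differential methylation between two tissue groups.

The genome is tiled in non-overlapping 200-bp windows.  For each window and
sequence context, read counts are pooled across replicates within each group
(over sites whose per-sample coverage reaches ``min_site_cov``), and the
pooled 2x2 table (methylated/unmethylated x group) is tested with Pearson's
chi-square (1 df, no continuity correction).  P-values are Benjamini-Hochberg
adjusted across all tested windows, and a window is reported as a DMR when it
meets the context-specific criteria on site count, absolute methylation
difference and q-value simultaneously.

Context presets (min sites per window / min |difference| / max q):
CG 5/0.25/0.05, CHG 5/0.25/0.05, CHH 15/0.15/0.05, ALL_C 20/0.20/0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io import (
    ALL_CONTEXTS,
    CONTEXTS,
    GeneModel,
    GenomicInterval,
    MethylomeSample,
    ValidationError,
)

ALL_C = "ALL_C"  # pool the three contexts

_PRESETS = {
    # context: (min_sites, min_abs_diff, q_max)
    "CG": (5, 0.25, 0.05),
    "CHG": (5, 0.25, 0.05),
    "CHH": (15, 0.15, 0.05),
    ALL_C: (20, 0.20, 0.05),
}


@dataclass(frozen=True)
class DmrCriteria:
    context: str = "CG"
    min_sites: int = 5
    min_abs_diff: float = 0.25
    q_max: float = 0.05
    window_size: int = 200
    min_site_cov: int = 4

    def __post_init__(self) -> None:
        if self.context not in _PRESETS:
            raise ValidationError(f"context must be one of {list(_PRESETS)}")
        if self.min_sites < 1:
            raise ValidationError("min_sites must be >= 1")
        if not (0 < self.min_abs_diff < 1):
            raise ValidationError("min_abs_diff must be in (0, 1)")
        if not (0 < self.q_max < 1):
            raise ValidationError("q_max must be in (0, 1)")

    @classmethod
    def for_context(cls, context: str, **overrides) -> "DmrCriteria":
        """Standard criteria for a context; keyword overrides allowed."""
        if context not in _PRESETS:
            raise ValidationError(f"context must be one of {list(_PRESETS)}")
        min_sites, min_abs_diff, q_max = _PRESETS[context]
        crit = cls(context=context, min_sites=min_sites,
                   min_abs_diff=min_abs_diff, q_max=q_max)
        return replace(crit, **overrides) if overrides else crit


@dataclass(frozen=True)
class DmrRecord:
    interval: GenomicInterval
    context: str
    level_a: float
    level_b: float
    diff: float  # level_a - level_b
    n_sites: int  # qualifying positions (min over the two groups)
    chi2: float
    p: float
    q: float


def tile_windows(chrom_sizes: dict[str, int], window_size: int) -> list[GenomicInterval]:
    """Non-overlapping tiles from 0, final partial tile included."""
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    out = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, window_size):
            out.append(GenomicInterval(chrom, start, min(start + window_size, size)))
    return out


def _context_mask(ctx_col, context: str) -> np.ndarray:
    if context == ALL_C or context == ALL_CONTEXTS:
        return np.ones(len(ctx_col), dtype=bool)
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    return (ctx_col == context).to_numpy()


def _group_window_counts(
    group: list[MethylomeSample],
    chrom: str,
    n_windows: int,
    window_size: int,
    context: str,
    min_site_cov: int,
):
    """Pooled (n_sites, meth, total) per tile for one chromosome.

    n_sites counts distinct (pos, strand) qualifying in >= 1 sample;
    qualification (coverage >= min_site_cov) is per sample, so a position may
    contribute reads from one replicate and not another.
    """
    meth = np.zeros(n_windows)
    total = np.zeros(n_windows)
    seen_keys = []
    for s in group:
        df = s.sites
        sub = df[df["chrom"] == chrom]
        m = _context_mask(sub["context"], context)
        sm = sub["meth"].to_numpy()
        cov = sm + sub["unmeth"].to_numpy()
        m &= cov >= min_site_cov
        pos0 = sub["pos"].to_numpy()[m] - 1
        widx = pos0 // window_size
        meth += np.bincount(widx, weights=sm[m], minlength=n_windows)
        total += np.bincount(widx, weights=cov[m], minlength=n_windows)
        strand01 = (sub["strand"].to_numpy()[m] == "-").astype(np.int64)
        seen_keys.append(pos0 * 2 + strand01)
    if seen_keys:
        uniq = np.unique(np.concatenate(seen_keys))
        n_sites = np.bincount((uniq // 2) // window_size, minlength=n_windows)
    else:
        n_sites = np.zeros(n_windows, dtype=np.int64)
    return n_sites, meth, total


def aggregate_window_counts(
    group: list[MethylomeSample],
    window: GenomicInterval,
    context: str,
    min_site_cov: int = 4,
) -> tuple[int, int, int]:
    """(n_sites, meth_reads, total_reads) pooled across a group in one window."""
    if not group:
        raise ValidationError("empty sample group")
    n_sites = set()
    meth = total = 0
    for s in group:
        df = s.sites
        sub = df[df["chrom"] == window.chrom]
        m = _context_mask(sub["context"], context)
        sm = sub["meth"].to_numpy()
        cov = sm + sub["unmeth"].to_numpy()
        pos0 = sub["pos"].to_numpy() - 1
        m &= (cov >= min_site_cov) & (pos0 >= window.start) & (pos0 < window.end)
        meth += int(sm[m].sum())
        total += int(cov[m].sum())
        n_sites.update(zip(pos0[m].tolist(), sub["strand"].to_numpy()[m].tolist()))
    return len(n_sites), meth, total


def chisq_2x2(meth_a: float, unmeth_a: float, meth_b: float, unmeth_b: float) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    A table with a zero margin leaves the test undefined; such windows are
    skipped by the caller rather than given p = 1.
    """
    obs = np.array([[meth_a, unmeth_a], [meth_b, unmeth_b]], dtype=float)
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("degenerate 2x2 table (zero margin): test undefined")
    stat = _chisq_vec(*(np.asarray([v], dtype=float) for v in (meth_a, unmeth_a, meth_b, unmeth_b)))[0]
    return float(stat), float(chi2.sf(stat, df=1))


def _chisq_vec(ma, ua, mb, ub):
    """Vectorised Pearson chi-square statistic for 2x2 tables.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); callers must exclude
    zero-margin tables.
    """
    n = ma + ua + mb + ub
    num = n * (ma * ub - ua * mb) ** 2
    den = (ma + ua) * (mb + ub) * (ma + mb) * (ua + ub)
    return num / den


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan_dmr_windows(
    group_a: list[MethylomeSample],
    group_b: list[MethylomeSample],
    criteria: DmrCriteria,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Chi-square scan of every testable window; the full BH family.

    Returns one row per *tested* window (both groups reach
    ``criteria.min_sites`` qualifying positions and the pooled 2x2 table has
    no zero margin — degenerate windows are excluded from the BH family, not
    assigned p = 1) with columns chrom, start, end, n_sites, level_a,
    level_b, diff, chi2, p, q.  Levels are pooled read-weighted per group.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    if chrom_sizes is None:
        chrom_sizes = {}
        for s in group_a + group_b:
            for c, n in s.chrom_sizes.items():
                chrom_sizes[c] = max(chrom_sizes.get(c, 0), n)

    w = criteria.window_size
    rows = []  # (chrom, start, end, n_sites, chi2, p, level_a, level_b)
    for chrom, size in chrom_sizes.items():
        n_win = -(-size // w)
        na, ma, ta = _group_window_counts(group_a, chrom, n_win, w, criteria.context, criteria.min_site_cov)
        nb, mb, tb = _group_window_counts(group_b, chrom, n_win, w, criteria.context, criteria.min_site_cov)
        ua, ub = ta - ma, tb - mb
        testable = (
            (na >= criteria.min_sites)
            & (nb >= criteria.min_sites)
            & (ta > 0)
            & (tb > 0)
            & (ma + mb > 0)
            & (ua + ub > 0)
        )
        idx = np.nonzero(testable)[0]
        if idx.size == 0:
            continue
        stat = _chisq_vec(ma[idx], ua[idx], mb[idx], ub[idx])
        pvals = chi2.sf(stat, df=1)
        la, lb = ma[idx] / ta[idx], mb[idx] / tb[idx]
        for j, i in enumerate(idx):
            start = int(i) * w
            rows.append((
                chrom, start, min(start + w, size),
                int(min(na[i], nb[i])), float(stat[j]), float(pvals[j]),
                float(la[j]), float(lb[j]),
            ))
    cols = ["chrom", "start", "end", "n_sites", "chi2", "p", "level_a", "level_b"]
    scan = pd.DataFrame(rows, columns=cols)
    scan["diff"] = scan["level_a"] - scan["level_b"]
    scan["q"] = bh_adjust(scan["p"]) if len(scan) else scan["p"]
    return scan[["chrom", "start", "end", "n_sites", "level_a", "level_b",
                 "diff", "chi2", "p", "q"]]


def call_dmrs(
    group_a: list[MethylomeSample],
    group_b: list[MethylomeSample],
    criteria: DmrCriteria,
    chrom_sizes: dict[str, int] | None = None,
) -> list[DmrRecord]:
    """Genome-wide window DMRs: the scan filtered to windows meeting all
    three criteria (site count, |difference| >= min_abs_diff, q <= q_max)."""
    scan = scan_dmr_windows(group_a, group_b, criteria, chrom_sizes)
    out = []
    for row in scan.itertuples(index=False):
        if abs(row.diff) >= criteria.min_abs_diff and row.q <= criteria.q_max:
            out.append(DmrRecord(
                GenomicInterval(row.chrom, int(row.start), int(row.end)),
                criteria.context, float(row.level_a), float(row.level_b),
                float(row.diff), int(row.n_sites), float(row.chi2),
                float(row.p), float(row.q),
            ))
    return out


def dmrs_to_dataframe(dmrs: list[DmrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.interval.chrom, "start": d.interval.start,
                "end": d.interval.end, "context": d.context,
                "level_a": d.level_a, "level_b": d.level_b, "diff": d.diff,
                "n_sites": d.n_sites, "chi2": d.chi2, "p": d.p, "q": d.q,
            }
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "context", "level_a", "level_b",
                 "diff", "n_sites", "chi2", "p", "q"],
    )


def dmr_associated_genes(
    dmrs: list[DmrRecord],
    genes: list[GeneModel],
    flank: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> set[str]:
    """Genes whose 2-kb upstream, body or 2-kb downstream overlaps a DMR.

    Equivalent to intersecting each DMR with [gene_start - flank,
    gene_end + flank), clipped at chromosome bounds, by >= 1 bp.
    """
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    trees: dict[str, IntervalTree] = {}
    for d in dmrs:
        trees.setdefault(d.interval.chrom, IntervalTree()).addi(
            d.interval.start, d.interval.end
        )
    out = set()
    for g in genes:
        iv = g.interval
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_sizes and iv.chrom in chrom_sizes:
            end = min(end, chrom_sizes[iv.chrom])
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(start, end):
            out.add(g.gene_id)
    return out
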