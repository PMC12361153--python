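"""Genome-wide methylation summaries: weighted levels per context,
methylcytosine calling, context proportions and fixed-width chromosome
window tracks.

The "global methylation level" here is the read-weighted level
(sum of methylated reads / sum of all reads over qualifying cytosines),
the coverage-robust WGBS convention — not the mean of per-site levels.

Methylcytosine calling follows the Lister-style binomial convention: a site
with coverage >= min_cov is called methylated when the one-sided binomial
tail P(X >= meth_reads | n = coverage, p = error_rate), BH-adjusted across
all tested sites, falls below q_max.  The error rate models bisulfite
non-conversion plus sequencing error (default 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .io import (
    ALL_CONTEXTS,
    CONTEXTS,
    GenomicInterval,
    MethylomeSample,
    NoDataError,
    ValidationError,
)

SiteKey = tuple[str, int, str]  # (chrom, pos, strand)


@dataclass(frozen=True)
class GlobalMethylationSummary:
    weighted_level: dict[str, float]  # per context
    mc_count: dict[str, int]
    proportions: dict[str, float]  # per-context fraction of called mC


def _context_mask(context_col: pd.Series, context: str) -> np.ndarray:
    if context == ALL_CONTEXTS:
        return np.ones(len(context_col), dtype=bool)
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    return (context_col == context).to_numpy()


def weighted_methylation_level(
    sample: MethylomeSample,
    context: str = ALL_CONTEXTS,
    region: GenomicInterval | None = None,
    min_cov: int = 1,
) -> float:
    """Read-weighted methylation level over qualifying sites.

    Qualifying: context match, coverage >= min_cov, and inside ``region``
    (half-open, cytosine position converted to 0-based) when given.  Raises
    :class:`NoDataError` when nothing qualifies — never returns a silent 0.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    df = sample.sites
    mask = _context_mask(df["context"], context)
    cov = (df["meth"] + df["unmeth"]).to_numpy()
    mask &= cov >= min_cov
    if region is not None:
        pos0 = df["pos"].to_numpy() - 1
        mask &= (
            (df["chrom"] == region.chrom).to_numpy()
            & (pos0 >= region.start)
            & (pos0 < region.end)
        )
    total = int(cov[mask].sum())
    if total == 0:
        raise NoDataError(
            f"no qualifying {context} sites (min_cov={min_cov}"
            + (f", region={region.chrom}:{region.start}-{region.end}" if region else "")
            + ")"
        )
    meth = int(df["meth"].to_numpy()[mask].sum())
    return meth / total


def call_methylcytosines(
    sample: MethylomeSample,
    error_rate: float = 0.005,
    min_cov: int = 4,
    q_max: float = 0.05,
) -> set[SiteKey]:
    """Binomial-test methylcytosine calls, BH-corrected across tested sites."""
    if not (0 < error_rate < 1):
        raise ValidationError("error_rate must be in (0, 1)")
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    df = sample.sites
    cov = (df["meth"] + df["unmeth"]).to_numpy()
    tested = cov >= min_cov
    if not tested.any():
        return set()
    n = cov[tested]
    k = df["meth"].to_numpy()[tested]
    pvals = binom.sf(k - 1, n, error_rate)  # P(X >= k)
    rejected, _, _, _ = multipletests(pvals, alpha=q_max, method="fdr_bh")[:4]
    sub = df.loc[tested, ["chrom", "pos", "strand"]].to_numpy()
    return {
        (str(c), int(p), str(s))
        for (c, p, s), rej in zip(sub, rejected)
        if rej
    }


def context_proportions(called: set[SiteKey], sample: MethylomeSample) -> dict[str, float]:
    """Fraction of called methylcytosines in each context (sums to 1)."""
    if not called:
        raise NoDataError("no called methylcytosines")
    df = sample.sites
    keys = list(zip(df["chrom"], df["pos"].astype(int), df["strand"]))
    in_called = pd.Series([k in called for k in keys], index=df.index)
    if int(in_called.sum()) != len(called):
        raise ValidationError("called set contains keys absent from the sample")
    counts = df.loc[in_called, "context"].value_counts()
    total = int(counts.sum())
    return {c: int(counts.get(c, 0)) / total for c in CONTEXTS}


def global_summary(
    sample: MethylomeSample,
    error_rate: float = 0.005,
    mc_min_cov: int = 4,
    q_max: float = 0.05,
    level_min_cov: int = 1,
) -> GlobalMethylationSummary:
    """Convenience wrapper: per-context weighted levels + mC counts/proportions."""
    levels = {}
    for ctx in CONTEXTS:
        try:
            levels[ctx] = weighted_methylation_level(sample, ctx, min_cov=level_min_cov)
        except NoDataError:
            levels[ctx] = float("nan")
    called = call_methylcytosines(sample, error_rate, mc_min_cov, q_max)
    if called:
        props = context_proportions(called, sample)
        df = sample.sites
        keys = set(zip(df["chrom"], df["pos"].astype(int), df["strand"]))
        assert called <= keys
        counts = {c: 0 for c in CONTEXTS}
        ctx_by_key = dict(zip(zip(df["chrom"], df["pos"].astype(int), df["strand"]), df["context"]))
        for key in called:
            counts[ctx_by_key[key]] += 1
    else:
        props = {c: float("nan") for c in CONTEXTS}
        counts = {c: 0 for c in CONTEXTS}
    return GlobalMethylationSummary(levels, counts, props)


def chromosome_window_summary(
    sample: MethylomeSample,
    window_size: int = 100_000,
    genes=None,
    te_intervals=None,
) -> pd.DataFrame:
    """Per-context weighted levels (and optional gene/TE density) in
    non-overlapping fixed tiles along each chromosome.

    Tiles are [0, w), [w, 2w), ... per chromosome with the last tile
    truncated at the chromosome end.  A tile with no covered sites of a
    context gets NaN for that context — missing, not 0.  Density columns are
    the fraction of the tile covered by gene / TE intervals.
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    rows = []
    df = sample.sites
    for chrom in sample.chrom_order():
        size = sample.chrom_sizes.get(chrom)
        sub = df[df["chrom"] == chrom]
        if size is None:
            size = int(sub["pos"].max()) if len(sub) else 0
        if size == 0:
            continue
        n_tiles = -(-size // window_size)
        pos0 = sub["pos"].to_numpy() - 1
        tile_idx = pos0 // window_size
        meth = sub["meth"].to_numpy()
        cov = meth + sub["unmeth"].to_numpy()
        level_cols: dict[str, np.ndarray] = {}
        for ctx in list(CONTEXTS) + [ALL_CONTEXTS]:
            m = _context_mask(sub["context"], ctx) & (cov >= 1)
            msum = np.bincount(tile_idx[m], weights=meth[m], minlength=n_tiles)
            csum = np.bincount(tile_idx[m], weights=cov[m], minlength=n_tiles)
            with np.errstate(invalid="ignore", divide="ignore"):
                level_cols[ctx] = np.where(csum > 0, msum / csum, np.nan)
        for i in range(n_tiles):
            start, end = i * window_size, min((i + 1) * window_size, size)
            row = {"chrom": chrom, "start": start, "end": end}
            for ctx in list(CONTEXTS) + [ALL_CONTEXTS]:
                row[f"level_{ctx}"] = level_cols[ctx][i]
            if genes is not None:
                row["gene_density"] = _covered_fraction(chrom, start, end, genes)
            if te_intervals is not None:
                row["te_density"] = _covered_fraction(chrom, start, end, te_intervals)
            rows.append(row)
    return pd.DataFrame(rows)


def _covered_fraction(chrom: str, start: int, end: int, features) -> float:
    """Fraction of [start, end) covered by the union of features on chrom."""
    tile = GenomicInterval(chrom, start, end)
    spans = []
    for f in features:
        iv = f.interval if hasattr(f, "interval") else f
        if iv.chrom == chrom and iv.start < end and start < iv.end:
            spans.append((max(iv.start, start), min(iv.end, end)))
    if not spans:
        return 0.0
    spans.sort()
    covered, cur_s, cur_e = 0, *spans[0]
    for s, e in spans[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / len(tile)
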