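"""Strand-aware scaled metagene methylation profiles (TSS -> TES + flanks).

Each gene contributes its 2-kb flanks in fixed-width bins and its body in a
fixed number of equal *fractional* bins (the body is scaled, so genes of any
length align).  Minus-strand genes are reversed so that bin 0 is always the
5'-most upstream bin and the last bin the 3'-most downstream bin.  Per bin
and sequence context the profile value is the read-weighted level pooled
across all genes' sites in that bin (sum of methylated reads / sum of reads,
not a mean of per-gene means); bins with no reads are missing (NaN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTEXTS, GeneModel, MethylomeSample, ValidationError

logger = logging.getLogger(__name__)

PROFILE_CONTEXTS = ("C", "CG", "CHG", "CHH")  # "C" pools all three


@dataclass
class MetageneProfile:
    values: pd.DataFrame  # bin x context weighted levels (NaN where no reads)
    total_reads: pd.DataFrame  # bin x context pooled read counts
    upstream_bins: int
    body_bins: int
    downstream_bins: int
    flank: int
    n_genes: int

    @property
    def n_bins(self) -> int:
        return self.upstream_bins + self.body_bins + self.downstream_bins

    def body_slice(self) -> pd.DataFrame:
        return self.values.iloc[self.upstream_bins:self.upstream_bins + self.body_bins]


def metagene_profile(
    sample: MethylomeSample,
    genes: list[GeneModel],
    flank: int = 2000,
    upstream_bins: int = 20,
    body_bins: int = 60,
    downstream_bins: int = 20,
) -> MetageneProfile:
    """Pooled metagene profile of a gene set.

    Genes shorter than ``body_bins`` bp are skipped with a warning (each body
    bin must span >= 1 bp).  A cytosine belongs to the bin containing its
    0-based position; the body bin index is floor((pos - start) / length *
    body_bins), clamped to the last bin at the end coordinate.
    """
    if not genes:
        raise ValidationError("metagene_profile needs a non-empty gene set")
    if flank % upstream_bins or flank % downstream_bins:
        # integer bin widths keep the binning exact and mirror-symmetric
        raise ValidationError("flank must be divisible by upstream_bins and downstream_bins")
    n_bins = upstream_bins + body_bins + downstream_bins
    up_w = flank // upstream_bins
    down_w = flank // downstream_bins

    ctx_index = {c: i for i, c in enumerate(CONTEXTS)}
    meth_acc = np.zeros((len(CONTEXTS), n_bins))
    total_acc = np.zeros((len(CONTEXTS), n_bins))

    # per-chromosome site arrays, sorted by position
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    df = sample.sites
    for chrom, sub in df.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        per_chrom[chrom] = (
            pos0[order],
            sub["context"].map(ctx_index).to_numpy()[order],
            sub["meth"].to_numpy(dtype=float)[order],
            (sub["meth"] + sub["unmeth"]).to_numpy(dtype=float)[order],
        )

    n_used = 0
    for g in genes:
        L = len(g.interval)
        if L < body_bins:
            logger.warning("gene %s length %d < body_bins %d: skipped", g.gene_id, L, body_bins)
            continue
        if g.interval.chrom not in per_chrom:
            n_used += 1
            continue
        pos0, ctx, meth, cov = per_chrom[g.interval.chrom]
        start, end = g.interval.start, g.interval.end
        lo, hi = np.searchsorted(pos0, [start - flank, end + flank])
        p = pos0[lo:hi]
        if p.size == 0:
            n_used += 1
            continue
        if g.strand == "+":
            bins = np.where(
                p < start,
                (p - (start - flank)) // up_w,
                np.where(
                    p < end,
                    upstream_bins + np.minimum((p - start) * body_bins // L, body_bins - 1),
                    upstream_bins + body_bins + (p - end) // down_w,
                ),
            )
        else:
            # 5' end is `end`; flanks mirror by coordinate, the body by bin
            # index (exact mirror even when L is not a multiple of body_bins)
            bins = np.where(
                p >= end,
                (end + flank - 1 - p) // up_w,
                np.where(
                    p >= start,
                    upstream_bins + (body_bins - 1)
                    - np.minimum((p - start) * body_bins // L, body_bins - 1),
                    upstream_bins + body_bins + (start - 1 - p) // down_w,
                ),
            )
        valid = (bins >= 0) & (bins < n_bins)
        np.add.at(meth_acc, (ctx[lo:hi][valid], bins[valid].astype(int)), meth[lo:hi][valid])
        np.add.at(total_acc, (ctx[lo:hi][valid], bins[valid].astype(int)), cov[lo:hi][valid])
        n_used += 1

    if n_used == 0:
        raise ValidationError("no usable genes (all shorter than body_bins)")

    all_meth = meth_acc.sum(axis=0)
    all_total = total_acc.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        data = {"C": np.where(all_total > 0, all_meth / all_total, np.nan)}
        for c in CONTEXTS:
            i = ctx_index[c]
            data[c] = np.where(total_acc[i] > 0, meth_acc[i] / total_acc[i], np.nan)
    totals = {"C": all_total, **{c: total_acc[ctx_index[c]] for c in CONTEXTS}}
    values = pd.DataFrame(data, columns=list(PROFILE_CONTEXTS))
    total_reads = pd.DataFrame(totals, columns=list(PROFILE_CONTEXTS))
    return MetageneProfile(
        values, total_reads, upstream_bins, body_bins, downstream_bins, flank, n_used
    )
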