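"""DNA methylation valley (DMV) detection and DMV-gene classification.

A DMV is a merged run of low-methylation windows: the genome is scanned with
a 1-kb window advancing in 200-bp steps; a window qualifies when the
*unweighted mean* of per-site methylation levels over all cytosine contexts
(sites with coverage >= min_site_cov, at least min_sites_per_window of them)
is below 5%.  Overlapping qualifying windows are merged by union into maximal
regions.  A gene is a DMV gene when at least 80% of its gene body lies in the
DMV union (cumulative overlap, boundary inclusive).

The window mean is deliberately the per-site average ("average methylation
level of all C sites"), not the read-weighted level used for global
summaries: in a valley, the per-site view treats a deeply covered site and a
thinly covered one equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GeneModel, GenomicInterval, MethylomeSample, ValidationError


@dataclass(frozen=True)
class DmvParams:
    window_size: int = 1000
    step: int = 200
    max_level: float = 0.05
    min_site_cov: int = 4
    min_sites_per_window: int = 5
    gene_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.step < 1 or self.step > self.window_size:
            raise ValidationError("need 1 <= step <= window_size")
        if not (0 < self.max_level < 1):
            raise ValidationError("max_level must be in (0, 1)")
        if not (0 < self.gene_fraction <= 1):
            raise ValidationError("gene_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DmvRegion:
    interval: GenomicInterval
    n_windows_merged: int
    mean_level: float


def sliding_windows(
    chrom_sizes: dict[str, int], window_size: int, step: int
) -> list[GenomicInterval]:
    """Windows [k*step, k*step + window_size) with end <= chromosome length.

    Partial trailing windows are not emitted: a short window would change the
    meaning of the mean-level threshold.
    """
    if step < 1:
        raise ValidationError("step must be >= 1")
    out = []
    for chrom, size in chrom_sizes.items():
        start = 0
        while start + window_size <= size:
            out.append(GenomicInterval(chrom, start, start + window_size))
            start += step
    return out


def _site_levels(sample: MethylomeSample, chrom: str, min_site_cov: int):
    """Sorted 0-based positions and per-site levels of qualifying sites."""
    df = sample.sites
    sub = df[df["chrom"] == chrom]
    meth = sub["meth"].to_numpy(dtype=float)
    cov = meth + sub["unmeth"].to_numpy(dtype=float)
    m = cov >= max(min_site_cov, 1)
    pos0 = sub["pos"].to_numpy()[m] - 1
    levels = meth[m] / cov[m]
    order = np.argsort(pos0, kind="stable")
    return pos0[order], levels[order]


def window_mean_level(
    sample: MethylomeSample,
    window: GenomicInterval,
    min_site_cov: int = 4,
) -> tuple[float | None, int]:
    """(mean per-site level, n qualifying sites) in a window; mean is None
    when no site qualifies."""
    pos0, levels = _site_levels(sample, window.chrom, min_site_cov)
    i0, i1 = np.searchsorted(pos0, [window.start, window.end])
    n = int(i1 - i0)
    if n == 0:
        return None, 0
    return float(levels[i0:i1].mean()), n


def detect_dmvs(sample: MethylomeSample, params: DmvParams = DmvParams()) -> list[DmvRegion]:
    """Scan, filter and merge: the DMV caller.

    Qualifying windows (n_sites >= min_sites_per_window and mean level <
    max_level) that overlap by >= 1 bp are merged by union into maximal
    regions; each region reports the per-site mean level over its full span.
    """
    out: list[DmvRegion] = []
    for chrom in sample.chrom_order():
        size = sample.chrom_sizes.get(chrom)
        if size is None or size < params.window_size:
            continue
        pos0, levels = _site_levels(sample, chrom, params.min_site_cov)
        csum = np.concatenate([[0.0], np.cumsum(levels)])
        starts = np.arange(0, size - params.window_size + 1, params.step)
        i0 = np.searchsorted(pos0, starts)
        i1 = np.searchsorted(pos0, starts + params.window_size)
        n = i1 - i0
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, (csum[i1] - csum[i0]) / np.maximum(n, 1), np.nan)
        qual = (n >= params.min_sites_per_window) & (mean < params.max_level)
        qstarts = starts[qual]
        if qstarts.size == 0:
            continue
        # merge overlapping equal-length windows, sorted by start
        region_start = int(qstarts[0])
        region_end = region_start + params.window_size
        n_merged = 1
        for s in qstarts[1:]:
            s = int(s)
            if s < region_end:  # >= 1 bp overlap
                region_end = s + params.window_size
                n_merged += 1
            else:
                out.append(_make_region(chrom, region_start, region_end, n_merged, pos0, csum))
                region_start, region_end, n_merged = s, s + params.window_size, 1
        out.append(_make_region(chrom, region_start, region_end, n_merged, pos0, csum))
    return out


def _make_region(chrom, start, end, n_merged, pos0, csum) -> DmvRegion:
    i0, i1 = np.searchsorted(pos0, [start, end])
    mean = float((csum[i1] - csum[i0]) / (i1 - i0)) if i1 > i0 else float("nan")
    return DmvRegion(GenomicInterval(chrom, start, end), n_merged, mean)


def dmv_genes(
    dmvs: list[DmvRegion],
    genes: list[GeneModel],
    gene_fraction: float = 0.8,
) -> set[str]:
    """Genes with >= gene_fraction of their body inside the DMV union."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in dmvs:
        by_chrom.setdefault(r.interval.chrom, []).append((r.interval.start, r.interval.end))
    for spans in by_chrom.values():
        spans.sort()
    out = set()
    for g in genes:
        spans = by_chrom.get(g.interval.chrom, [])
        overlap = sum(
            max(0, min(e, g.interval.end) - max(s, g.interval.start))
            for s, e in spans
        )
        if overlap / len(g.interval) >= gene_fraction:
            out.add(g.gene_id)
    return out


def dmv_tissue_overlap(dmv_genes_by_tissue: dict[str, set[str]]):
    """Per-tissue DMV-gene counts plus intersection and union sizes."""
    if len(dmv_genes_by_tissue) < 2:
        raise ValidationError("need DMV gene sets for >= 2 tissues")
    sets = list(dmv_genes_by_tissue.values())
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return (
        {t: len(s) for t, s in dmv_genes_by_tissue.items()},
        len(inter),
        len(union),
    )
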