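"""Shared genomic data model and readers/writers for the formats the pipeline touches.

The atomic unit is a strand-resolved cytosine with methylated/unmethylated read
counts and a sequence context (CG, CHG or CHH — the three contexts of plant DNA
methylation).  A :class:`MethylomeSample` holds all cytosines of one
tissue/replicate as a columnar table for vectorised downstream work, while
:class:`CytosineSite` gives a per-site record view.

Coordinate conventions
----------------------
All intervals (windows, DMRs, DMVs, genes) are 0-based half-open, the BED
convention.  Cytosine positions are stored 1-based as in Bismark-style
cytosine (CX) reports and converted on the fly for interval queries.  CG sites
are *not* collapsed across strands: each strand's cytosine is an independent
site, as in the native CX representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
ALL_CONTEXTS = "ALL"

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


class MethvalleyError(Exception):
    """Base class for all package errors."""


class ParseError(MethvalleyError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MethvalleyError):
    """Input violated a contract (bounds, duplicates, negative values...)."""


class NoDataError(MethvalleyError):
    """A statistic was requested over a region/set with no qualifying data.

    Raised instead of silently returning 0: a methylation level of 0 is a
    real biological observation, absence of data is not.
    """


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class CytosineSite(NamedTuple):
    chrom: str
    pos: int  # 1-based, as in the CX report
    strand: str
    context: str
    meth_reads: int
    unmeth_reads: int

    @property
    def coverage(self) -> int:
        return self.meth_reads + self.unmeth_reads

    @property
    def level(self) -> float:
        """Per-site methylation level; undefined at zero coverage."""
        cov = self.coverage
        if cov == 0:
            raise NoDataError(f"site {self.chrom}:{self.pos} has zero coverage")
        return self.meth_reads / cov


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )


@dataclass
class MethylomeSample:
    """All cytosine sites of one sequenced sample (tissue x replicate).

    ``sites`` is a DataFrame with columns chrom, pos (1-based), strand,
    context, meth, unmeth, sorted by (chrom, pos) with chromosomes in
    ``chrom_sizes`` order.
    """

    sample_id: str
    tissue: str
    replicate: int
    sites: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sites table missing columns {missing}")
        if len(df):
            order = {c: i for i, c in enumerate(self.chrom_sizes)}
            fallback = {c: len(order) + i
                        for i, c in enumerate(sorted(set(df["chrom"]) - set(order)))}
            key = df["chrom"].map({**order, **fallback}).to_numpy()
            pos = df["pos"].to_numpy()
            in_order = bool(np.all(
                (key[1:] > key[:-1]) | ((key[1:] == key[:-1]) & (pos[1:] >= pos[:-1]))
            )) if len(df) > 1 else True
            if not in_order:
                df = df.take(np.lexsort((pos, key)))
            df = df.reset_index(drop=True)
            if (df["meth"].to_numpy() < 0).any() or (df["unmeth"].to_numpy() < 0).any():
                raise ValidationError("negative read counts")
            for chrom, pmax in df.groupby("chrom", sort=False)["pos"].max().items():
                size = self.chrom_sizes.get(chrom)
                if size is not None and int(pmax) > size:
                    raise ValidationError(
                        f"sample {self.sample_id}: position {int(pmax)} exceeds "
                        f"{chrom} length {size}"
                    )
        self.sites = df

    @classmethod
    def from_records(
        cls,
        records: Iterable[CytosineSite],
        sample_id: str = "sample",
        tissue: str = "tissue",
        replicate: int = 1,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> "MethylomeSample":
        rows = list(records)
        df = pd.DataFrame(rows, columns=SITE_COLUMNS) if rows else pd.DataFrame(
            {c: pd.Series(dtype="int64" if c in ("pos", "meth", "unmeth") else "object")
             for c in SITE_COLUMNS}
        )
        sizes = dict(chrom_sizes) if chrom_sizes else _infer_chrom_sizes(df)
        return cls(sample_id, tissue, replicate, df, sizes)

    def iter_sites(self) -> Iterator[CytosineSite]:
        for row in self.sites.itertuples(index=False):
            yield CytosineSite(row.chrom, int(row.pos), row.strand, row.context,
                               int(row.meth), int(row.unmeth))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def chrom_order(self) -> list[str]:
        if self.chrom_sizes:
            return list(self.chrom_sizes)
        return sorted(self.sites["chrom"].unique())


def _infer_chrom_sizes(df: pd.DataFrame) -> dict[str, int]:
    if df.empty:
        return {}
    return {c: int(g.max()) for c, g in df.groupby("chrom", sort=True)["pos"]}


def pool_samples(
    samples: Sequence[MethylomeSample],
    sample_id: str,
    tissue: str | None = None,
) -> MethylomeSample:
    """Pool replicates by summing read counts per (chrom, pos, strand, context).

    Used before DMV detection and metagene profiling, which operate on one
    methylome per tissue rather than per replicate.
    """
    if not samples:
        raise ValidationError("cannot pool an empty sample list")
    frames = [s.sites for s in samples]
    cat = pd.concat(frames, ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)[
            ["meth", "unmeth"]
        ].sum()
    )[SITE_COLUMNS]
    sizes: dict[str, int] = {}
    for s in samples:
        for c, n in s.chrom_sizes.items():
            sizes[c] = max(sizes.get(c, 0), n)
    return MethylomeSample(
        sample_id=sample_id,
        tissue=tissue if tissue is not None else samples[0].tissue,
        replicate=0,
        sites=pooled,
        chrom_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Cytosine report (CX) I/O
# ---------------------------------------------------------------------------

_CX_NAMES = ["chrom", "pos", "strand", "meth", "unmeth", "context", "trinucleotide"]


def read_cytosine_report(
    path: str | Path,
    sample_id: str,
    tissue: str,
    replicate: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> MethylomeSample:
    """Read a Bismark-style CX report (7-column TSV) into a MethylomeSample.

    Columns: chrom, 1-based position, strand, methylated count, unmethylated
    count, context (CG/CHG/CHH), trinucleotide.  Zero-coverage sites are
    retained (coverage filters are applied by each downstream statistic);
    lines with an unknown context are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_CX_NAMES, dtype=str,
            comment=None, skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({c: pd.Series(dtype=str) for c in _CX_NAMES})
    if df.isna().any(axis=None):
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise ParseError(f"{path}: line {bad}: expected 7 tab-separated fields")
    for col in ("pos", "meth", "unmeth"):
        num = pd.to_numeric(df[col], errors="coerce")
        if num.isna().any():
            bad = int(num.isna().idxmax()) + 1
            raise ParseError(f"{path}: line {bad}: non-integer value in column {col!r}")
        df[col] = num.astype("int64")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        bad = int(bad_ctx.idxmax()) + 1
        raise ParseError(
            f"{path}: line {bad}: unknown context {df['context'].iloc[bad - 1]!r} "
            f"(expected one of {CONTEXTS})"
        )
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        bad = int(bad_strand.idxmax()) + 1
        raise ParseError(f"{path}: line {bad}: strand must be + or -")
    sites = df[SITE_COLUMNS].copy()
    sizes = dict(chrom_sizes) if chrom_sizes else _infer_chrom_sizes(sites)
    return MethylomeSample(sample_id, tissue, replicate, sites, sizes)


def write_cytosine_report(sample: MethylomeSample, path: str | Path) -> None:
    """Write a MethylomeSample back out as a 7-column CX report."""
    df = sample.sites.copy()
    if "trinucleotide" not in df.columns:
        df["trinucleotide"] = df["context"]
    df[_CX_NAMES].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED6 / GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (0-based half-open) or GFF3 (1-based closed).

    The dialect is sniffed from the file; either way the returned GeneModels
    use the unified 0-based half-open convention.  Duplicate gene ids and
    empty intervals are rejected.
    """
    path = Path(path)
    if _looks_like_gff3(path):
        genes = _read_gff3_genes(path)
    else:
        genes = _read_bed6_genes(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _looks_like_gff3(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    if path.suffix.lower() == ".bed":
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            return len(fields) >= 9 and "=" in fields[8]
    return False


def _read_bed6_genes(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {i}: BED6 needs 6 fields")
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: non-integer coordinate") from exc
            if end_i <= start_i:
                raise ValidationError(f"{path}: line {i}: end <= start for {name}")
            genes.append(GeneModel(name, GenomicInterval(chrom, start_i, end_i, strand), strand))
    return genes


def _read_gff3_genes(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        start0, end = feat.start - 1, feat.end  # 1-based closed -> 0-based half-open
        if end <= start0:
            raise ValidationError(f"{path}: gene {feat.id}: end < start")
        genes.append(GeneModel(feat.id, GenomicInterval(feat.seqid, start0, end, feat.strand), feat.strand))
    return genes


# ---------------------------------------------------------------------------
# Interval (BED) I/O and expression table
# ---------------------------------------------------------------------------

def write_intervals_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
    chrom_order: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start).

    Chromosomes sort in ``chrom_order`` when given (an interval on an
    undeclared chromosome is an error), lexicographically otherwise.
    """
    if names is not None and len(names) != len(intervals):
        raise ValidationError("names length must match intervals")
    if scores is not None and len(scores) != len(intervals):
        raise ValidationError("scores length must match intervals")
    if chrom_order is not None:
        rank = {c: i for i, c in enumerate(chrom_order)}
        for iv in intervals:
            if iv.chrom not in rank:
                raise ValidationError(
                    f"chromosome {iv.chrom!r} not in declared order {list(chrom_order)}"
                )
        sort_key = lambda t: (rank[t[0].chrom], t[0].start)  # noqa: E731
    else:
        sort_key = lambda t: (t[0].chrom, t[0].start)  # noqa: E731

    rows = list(zip(
        intervals,
        names if names is not None else (f"region_{i}" for i in itertools.count(1)),
        scores if scores is not None else itertools.repeat(0),
    ))
    rows.sort(key=sort_key)
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file back into GenomicIntervals (first 3-6 columns used)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i}: BED needs >= 3 fields")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def read_expression_table(path: str | Path):
    """Read a gene x tissue abundance table (TSV, first column gene_id).

    Values are RPKM/FPKM-style non-negative abundances; missing cells,
    negative values and duplicated gene rows are rejected.  Returns an
    :class:`methvalley.expression.ExpressionMatrix`.
    """
    from .expression import ExpressionMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated gene rows: {dupes}")
    if df.isna().any(axis=None):
        raise ValidationError(f"{path}: missing values in expression table")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value") from exc
    if (values.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    return ExpressionMatrix(values)
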