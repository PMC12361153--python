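"""Synthetic WGBS + expression data with a ground-truth manifest.

The generator emulates the statistical structure the analysis assumes for a
plant methylome: a multi-chromosome genome partitioned into compartments —
hypermethylated TE-like blocks, gene regions, unmethylated valley regions
(with hot flanks) and background — plus planted tissue-differential windows,
a 3-replicates-per-tissue design at ~10x Poisson coverage, and an expression
table with planted tissue-specificity classes.

Per site and sample, the true methylation level is drawn from a Beta
distribution centred on the compartment x context probability
(beta-binomial site noise gives replicates realistic extra-binomial
variance; set ``beta_dispersion`` to None for pure binomial sampling),
coverage is Poisson, and methylated reads are binomial.  Everything is
seeded and byte-deterministic; the planted truth (valleys, differential
windows, expression classes with their exact TAU) is serialised alongside
the data so parameter-recovery tests can score the pipeline.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .io import (
    CONTEXTS,
    GeneModel,
    GenomicInterval,
    MethylomeSample,
    SITE_COLUMNS,
    ValidationError,
    write_cytosine_report,
    write_intervals_bed,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    interval: GenomicInterval
    cls: str  # TE_block | gene_region | valley | valley_flank | background


@dataclass(frozen=True)
class PlantedDmr:
    interval: GenomicInterval
    context: str  # CG | CHG | CHH | ALL
    probs: tuple[tuple[str, float], ...]  # (tissue, methylation probability)

    def prob_for(self, tissue: str) -> float | None:
        for t, p in self.probs:
            if t == tissue:
                return p
        return None

    @property
    def true_delta(self) -> float:
        ps = [p for _, p in self.probs]
        return max(ps) - min(ps)


DEFAULT_CLASS_PROBS = {
    # per-class per-context methylation probabilities
    "TE_block": {"CG": 0.95, "CHG": 0.80, "CHH": 0.15},
    "gene_region": {"CG": 0.60, "CHG": 0.15, "CHH": 0.05},
    "valley": {"CG": 0.005, "CHG": 0.005, "CHH": 0.005},
    "valley_flank": {"CG": 0.90, "CHG": 0.80, "CHH": 0.50},
    "background": {"CG": 0.90, "CHG": 0.65, "CHH": 0.12},
}


@dataclass
class LandscapePlan:
    chrom_sizes: dict[str, int]
    compartments: list[Compartment]
    class_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PROBS.items()}
    )
    planted_dmr_windows: list[PlantedDmr] = field(default_factory=list)
    tissues: tuple[str, ...] = ("root", "leaf")
    replicates: int = 3
    mean_coverage: float = 10.0
    beta_dispersion: float | None = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in self.compartments:
            iv = comp.interval
            if iv.chrom not in self.chrom_sizes or iv.end > self.chrom_sizes[iv.chrom]:
                raise ValidationError(f"compartment {iv} outside the genome")
            if comp.cls not in self.class_probs:
                raise ValidationError(f"no probabilities for compartment class {comp.cls!r}")
        for cls, probs in self.class_probs.items():
            for ctx, p in probs.items():
                if not (0 <= p <= 1):
                    raise ValidationError(f"{cls}/{ctx}: probability {p} outside [0, 1]")

    def valleys(self) -> list[GenomicInterval]:
        return [c.interval for c in self.compartments if c.cls == "valley"]


# ---------------------------------------------------------------------------
# Genome + cytosine catalog
# ---------------------------------------------------------------------------

def simulate_genome(plan: LandscapePlan) -> tuple[dict[str, str], pd.DataFrame]:
    """Random nucleotide sequences plus the derived cytosine catalog.

    Every cytosine on both strands with a complete trinucleotide is
    catalogued with the CX-report context convention: CG when followed by G,
    CHG for C-H-G, else CHH (H in {A, C, T}); on the minus strand the rule is
    applied to the reverse complement.  Cytosines within 2 bp of a
    chromosome end (incomplete trinucleotide) are omitted.
    """
    rng = np.random.default_rng([_norm_seed(plan.seed), 1])
    sequences: dict[str, str] = {}
    frames = []
    for chrom, size in plan.chrom_sizes.items():
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=size)])
        sequences[chrom] = seq
        frames.append(catalog_from_sequence(chrom, seq))
    catalog = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    catalog["compartment"] = _assign_compartments(catalog, plan)
    return sequences, catalog


def catalog_from_sequence(chrom: str, seq: str) -> pd.DataFrame:
    """Derive the per-cytosine context catalog from a nucleotide sequence."""
    arr = np.frombuffer(seq.encode(), dtype="S1")
    L = len(arr)
    rows = []
    # plus strand: C at i, context from i+1, i+2
    ci = np.nonzero(arr == b"C")[0]
    ci = ci[ci + 2 < L]
    if ci.size:
        nxt = arr[ci + 1]
        nxt2 = arr[ci + 2]
        ctx = np.where(nxt == b"G", "CG", np.where(nxt2 == b"G", "CHG", "CHH"))
        tri = np.char.add(np.char.add(
            arr[ci].astype("U1"), nxt.astype("U1")), nxt2.astype("U1"))
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": ci + 1, "strand": "+", "context": ctx,
            "trinucleotide": tri,
        }))
    # minus strand: G at i, context from i-1, i-2 (complemented)
    gi = np.nonzero(arr == b"G")[0]
    gi = gi[gi - 2 >= 0]
    if gi.size:
        prev = arr[gi - 1]
        prev2 = arr[gi - 2]
        ctx = np.where(prev == b"C", "CG", np.where(prev2 == b"C", "CHG", "CHH"))
        comp = np.zeros(256, dtype="U1")
        for a, b in zip(b"ACGT", "TGCA"):
            comp[a] = b
        tri = np.char.add(np.char.add(
            comp[arr[gi].view(np.uint8)],
            comp[arr[gi - 1].view(np.uint8)]),
            comp[arr[gi - 2].view(np.uint8)])
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": gi + 1, "strand": "-", "context": ctx,
            "trinucleotide": tri,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def _assign_compartments(catalog: pd.DataFrame, plan: LandscapePlan) -> pd.Series:
    """Compartment class per catalogued site; gaps default to background."""
    if catalog.empty:
        return pd.Series(dtype=object)
    out = np.full(len(catalog), "background", dtype=object)
    for chrom in plan.chrom_sizes:
        comps = sorted(
            (c for c in plan.compartments if c.interval.chrom == chrom),
            key=lambda c: c.interval.start,
        )
        for a, b in zip(comps, comps[1:]):
            if b.interval.start < a.interval.end:
                raise ValidationError(f"overlapping compartments on {chrom}")
        mask = (catalog["chrom"] == chrom).to_numpy()
        if not mask.any() or not comps:
            continue
        pos0 = catalog["pos"].to_numpy()[mask] - 1
        starts = np.array([c.interval.start for c in comps])
        ends = np.array([c.interval.end for c in comps])
        classes = np.array([c.cls for c in comps], dtype=object)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.maximum(idx, 0)])
        vals = np.full(pos0.shape, "background", dtype=object)
        vals[inside] = classes[idx[inside]]
        out[mask] = vals
    return pd.Series(out, index=catalog.index)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def _norm_seed(seed: int) -> int:
    return int(seed) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Methylome sampling
# ---------------------------------------------------------------------------

def sample_methylome(
    plan: LandscapePlan,
    catalog: pd.DataFrame,
    tissue: str,
    replicate: int,
) -> MethylomeSample:
    """Draw one sample's cytosine report from the plan.

    The generator is namespaced by (seed, tissue, replicate) so each sample
    is an independent but reproducible draw.  Zero-coverage sites are
    emitted (as a real CX report would) and filtered downstream.
    """
    rng = np.random.default_rng(
        [_norm_seed(plan.seed), 2, zlib.crc32(tissue.encode()) % (2**31), replicate]
    )
    n = len(catalog)
    comp_codes, comp_levels = pd.factorize(catalog["compartment"].to_numpy())
    ctx_codes, ctx_levels = pd.factorize(catalog["context"].to_numpy())
    chrom_codes, chrom_levels = pd.factorize(catalog["chrom"].to_numpy())
    table = np.empty((len(comp_levels), len(ctx_levels)))
    for i, cls in enumerate(comp_levels):
        for j, ctx in enumerate(ctx_levels):
            table[i, j] = plan.class_probs[cls][ctx]
    p = table[comp_codes, ctx_codes]
    pos0 = catalog["pos"].to_numpy() - 1
    chrom_code = {c: i for i, c in enumerate(chrom_levels)}
    ctx_code = {c: i for i, c in enumerate(ctx_levels)}
    for planted in plan.planted_dmr_windows:
        override = planted.prob_for(tissue)
        if override is None or planted.interval.chrom not in chrom_code:
            continue
        m = (
            (chrom_codes == chrom_code[planted.interval.chrom])
            & (pos0 >= planted.interval.start)
            & (pos0 < planted.interval.end)
        )
        if planted.context != "ALL":
            m &= ctx_codes == ctx_code.get(planted.context, -1)
        p[m] = override

    if plan.beta_dispersion is None:
        level = p
    else:
        c = plan.beta_dispersion
        interior = (p > 0) & (p < 1)
        level = p.copy()
        level[interior] = rng.beta(p[interior] * c, (1 - p[interior]) * c)
    cov = rng.poisson(plan.mean_coverage, size=n)
    meth = rng.binomial(cov, level)
    sites = pd.DataFrame({
        "chrom": catalog["chrom"].to_numpy(),
        "pos": catalog["pos"].to_numpy(),
        "strand": catalog["strand"].to_numpy(),
        "context": catalog["context"].to_numpy(),
        "meth": meth,
        "unmeth": cov - meth,
    })[SITE_COLUMNS]
    sites["trinucleotide"] = catalog["trinucleotide"].to_numpy()
    return MethylomeSample(
        sample_id=f"{tissue}_{replicate}",
        tissue=tissue,
        replicate=replicate,
        sites=sites,
        chrom_sizes=dict(plan.chrom_sizes),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionClass:
    """Planted specificity class of one gene.

    kind: "exclusive" (expressed in one tissue only, ratio 0), "preferential"
    (min/max = ratio, e.g. 0.005 -> tau 0.995) or "constitutive" (ratio drawn
    in [0.6, 1), tau <= 0.4).  ``tissue`` names the high tissue where
    applicable.
    """

    kind: str
    tissue: str | None = None
    ratio: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exclusive", "preferential", "constitutive"):
            raise ValidationError(f"unknown expression class {self.kind!r}")
        if self.kind != "constitutive" and self.tissue is None:
            raise ValidationError(f"{self.kind} class needs a tissue")
        if self.kind == "preferential" and not (0 <= (self.ratio or 0) < 1):
            raise ValidationError("preferential ratio must be in [0, 1)")


def simulate_expression(
    genes: list[GeneModel],
    classes: dict[str, ExpressionClass],
    seed: int,
    tissues: tuple[str, ...] = ("root", "leaf"),
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Expression matrix with exact planted cross-tissue ratios.

    Each gene gets a log-normal baseline abundance (median ~20 FPKM, clipped
    at 2 so every gene clears the default abundance floor) for its high
    tissue; the class fixes the low/high ratio exactly, so the planted TAU
    (1 - ratio for two tissues) is recorded without sampling error.
    """
    rng = np.random.default_rng([_norm_seed(seed), 3])
    rows = {}
    true_tau: dict[str, float] = {}
    for g in genes:
        cls = classes.get(g.gene_id)
        if cls is None:
            raise ValidationError(f"no expression class for gene {g.gene_id}")
        base = max(2.0, float(rng.lognormal(mean=np.log(20.0), sigma=0.8)))
        if cls.kind == "exclusive":
            high, ratio = cls.tissue, 0.0
        elif cls.kind == "preferential":
            high, ratio = cls.tissue, float(cls.ratio)
        else:
            high = tissues[int(rng.integers(len(tissues)))]
            ratio = float(rng.uniform(0.6, 1.0)) if cls.ratio is None else float(cls.ratio)
        low_val = base * ratio
        rows[g.gene_id] = {
            t: base if t == high else low_val for t in tissues
        }
        # tau over n tissues with one high and the rest at ratio*high
        true_tau[g.gene_id] = (len(tissues) - 1) * (1 - ratio) / (len(tissues) - 1)
    matrix = ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index")[list(tissues)])
    return matrix, true_tau


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    chrom_sizes: dict[str, int]
    valleys: list[GenomicInterval]
    dmr_windows: list[PlantedDmr]
    gene_ids: list[str]
    gene_classes: dict[str, ExpressionClass]
    true_tau: dict[str, float]
    compartment_probs: dict[str, dict[str, float]]
    seed: int

    def validate(self) -> None:
        known = set(self.gene_ids)
        unknown = set(self.gene_classes) - known
        if unknown:
            raise ValidationError(
                f"manifest references genes absent from the annotation: {sorted(unknown)[:10]}"
            )


def build_truth(
    plan: LandscapePlan,
    genes: list[GeneModel],
    classes: dict[str, ExpressionClass],
    true_tau: dict[str, float],
) -> TruthManifest:
    manifest = TruthManifest(
        chrom_sizes=dict(plan.chrom_sizes),
        valleys=plan.valleys(),
        dmr_windows=list(plan.planted_dmr_windows),
        gene_ids=[g.gene_id for g in genes],
        gene_classes=dict(classes),
        true_tau=dict(true_tau),
        compartment_probs={k: dict(v) for k, v in plan.class_probs.items()},
        seed=plan.seed,
    )
    manifest.validate()
    return manifest


def write_truth(manifest: TruthManifest, path: str | Path) -> None:
    manifest.validate()
    doc = {
        "chrom_sizes": manifest.chrom_sizes,
        "valleys": [asdict(v) for v in manifest.valleys],
        "dmr_windows": [
            {"interval": asdict(d.interval), "context": d.context,
             "probs": list(d.probs)}
            for d in manifest.dmr_windows
        ],
        "gene_ids": manifest.gene_ids,
        "gene_classes": {g: asdict(c) for g, c in manifest.gene_classes.items()},
        "true_tau": manifest.true_tau,
        "compartment_probs": manifest.compartment_probs,
        "seed": manifest.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_truth(path: str | Path) -> TruthManifest:
    with open(path) as fh:
        doc = json.load(fh)
    manifest = TruthManifest(
        chrom_sizes=dict(doc["chrom_sizes"]),
        valleys=[GenomicInterval(**v) for v in doc["valleys"]],
        dmr_windows=[
            PlantedDmr(GenomicInterval(**d["interval"]), d["context"],
                       tuple((t, p) for t, p in d["probs"]))
            for d in doc["dmr_windows"]
        ],
        gene_ids=list(doc["gene_ids"]),
        gene_classes={g: ExpressionClass(**c) for g, c in doc["gene_classes"].items()},
        true_tau={g: float(t) for g, t in doc["true_tau"].items()},
        compartment_probs=doc["compartment_probs"],
        seed=int(doc["seed"]),
    )
    manifest.validate()
    return manifest


# ---------------------------------------------------------------------------
# Default demo study
# ---------------------------------------------------------------------------

CHROM_KB = 200
N_CHROMS = 3


def default_plan(seed: int = 0) -> tuple[LandscapePlan, list[GeneModel], dict[str, ExpressionClass]]:
    """The demo study: 3 chromosomes x 200 kb, 2 tissues x 3 replicates, 10x.

    Per chromosome: two 30-kb TE blocks, two 24-kb gene regions holding 7
    genes each, six planted valleys (2-3.2 kb, aligned to the 200-bp scan
    grid, 1-kb hot flanks) each holding one gene fully inside, ten planted
    CG-differential 200-bp windows (root 0.9 vs leaf 0.4) and four planted
    CHH windows (0.45 vs 0.10) in background.  Expression classes are
    planted so root-preferential genes are strongly enriched among valley
    genes (12 of 18 valley genes root-preferential vs 6 of 42 others).
    """
    size = CHROM_KB * 1000
    chrom_sizes = {f"chr{i+1}": size for i in range(N_CHROMS)}
    compartments: list[Compartment] = []
    genes: list[GeneModel] = []
    classes: dict[str, ExpressionClass] = {}
    planted: list[PlantedDmr] = []

    valley_specs = [  # (start, length), grid-aligned
        (62000, 2000), (70000, 2400), (80000, 3200),
        (162000, 2000), (170000, 2400), (180000, 3200),
    ]
    gene_region_starts = (34000, 134000)
    strands = "+-"

    for ci, chrom in enumerate(chrom_sizes):
        compartments += [
            Compartment(GenomicInterval(chrom, 0, 30000), "TE_block"),
            Compartment(GenomicInterval(chrom, 100000, 130000), "TE_block"),
        ]
        # valleys with flanks, one gene fully inside each valley
        valley_classes = [
            ExpressionClass("exclusive", "root"),
            ExpressionClass("preferential", "root", 0.005),
            ExpressionClass("exclusive", "root"),
            ExpressionClass("preferential", "root", 0.005),
            ExpressionClass("constitutive"),
            ExpressionClass("exclusive", "leaf") if ci < 2 else ExpressionClass("constitutive"),
        ]
        for vi, (vstart, vlen) in enumerate(valley_specs):
            vend = vstart + vlen
            compartments += [
                Compartment(GenomicInterval(chrom, vstart - 1000, vstart), "valley_flank"),
                Compartment(GenomicInterval(chrom, vstart, vend), "valley"),
                Compartment(GenomicInterval(chrom, vend, vend + 1000), "valley_flank"),
            ]
            gid = f"{chrom}_vgene{vi+1}"
            strand = strands[vi % 2]
            genes.append(GeneModel(gid, GenomicInterval(chrom, vstart + 100, vend - 100, strand), strand))
            classes[gid] = valley_classes[vi]
        # gene regions with ordinary genes
        other_classes = [
            ExpressionClass("exclusive", "root"),
            ExpressionClass("preferential", "root", 0.005),
            ExpressionClass("exclusive", "leaf"),
            ExpressionClass("preferential", "leaf", 0.005),
        ] + [ExpressionClass("constitutive")] * 10
        oi = 0
        for rstart in gene_region_starts:
            compartments.append(Compartment(GenomicInterval(chrom, rstart, rstart + 24000), "gene_region"))
            for j in range(7):
                gstart = rstart + 400 + j * 3400
                gid = f"{chrom}_gene{oi+1}"
                strand = strands[(vi + j) % 2]
                genes.append(GeneModel(gid, GenomicInterval(chrom, gstart, gstart + 2000, strand), strand))
                classes[gid] = other_classes[oi]
                oi += 1
        # planted differential windows in background
        for j in range(10):
            s = 86000 + j * 1000
            planted.append(PlantedDmr(
                GenomicInterval(chrom, s, s + 200), "CG",
                (("root", 0.9), ("leaf", 0.4)),
            ))
        for j in range(4):
            s = 186000 + j * 2000
            planted.append(PlantedDmr(
                GenomicInterval(chrom, s, s + 200), "CHH",
                (("root", 0.45), ("leaf", 0.10)),
            ))

    plan = LandscapePlan(
        chrom_sizes=chrom_sizes,
        compartments=compartments,
        planted_dmr_windows=planted,
        seed=seed,
    )
    return plan, genes, classes


@dataclass
class SimulatedStudy:
    plan: LandscapePlan
    sequences: dict[str, str]
    catalog: pd.DataFrame
    samples: dict[tuple[str, int], MethylomeSample]
    genes: list[GeneModel]
    expression: ExpressionMatrix
    truth: TruthManifest

    def samples_for(self, tissue: str) -> list[MethylomeSample]:
        return [s for (t, _), s in sorted(self.samples.items()) if t == tissue]


def simulate_study(
    seed: int = 0,
    plan: LandscapePlan | None = None,
    genes: list[GeneModel] | None = None,
    classes: dict[str, ExpressionClass] | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedStudy:
    """Run the whole generator; optionally write every artefact to disk.

    Writes (when ``out_dir`` is given): genome.fa, one CX report per sample
    (<tissue>_<rep>.cx.tsv), genes.bed, expression.tsv and truth.json.
    """
    if plan is None:
        plan, genes, classes = default_plan(seed)
    if genes is None or classes is None:
        raise ValidationError("a custom plan needs explicit genes and classes")
    sequences, catalog = simulate_genome(plan)
    samples = {
        (tissue, rep): sample_methylome(plan, catalog, tissue, rep)
        for tissue in plan.tissues
        for rep in range(1, plan.replicates + 1)
    }
    expression, true_tau = simulate_expression(genes, classes, plan.seed, plan.tissues)
    truth = build_truth(plan, genes, classes, true_tau)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sequences, out / "genome.fa")
        for (tissue, rep), sample in samples.items():
            write_cytosine_report(sample, out / f"{tissue}_{rep}.cx.tsv")
        write_intervals_bed(
            [g.interval for g in genes], out / "genes.bed",
            names=[g.gene_id for g in genes],
            chrom_order=list(plan.chrom_sizes),
        )
        expression.values.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
        write_truth(truth, out / "truth.json")

    return SimulatedStudy(plan, sequences, catalog, samples, genes, expression, truth)
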