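"""End-to-end orchestration: global stats -> DMR -> DMV -> TAU -> enrichment
-> metagene, driven by a single YAML config.

Replicates are pooled per tissue (read counts summed per site) before DMV
detection and metagene profiling; the DMR stage receives the unpooled
replicates and pools internally per its own contract.  Every output is
stamped with the config hash and seed, and the run summary is recomputed
from the emitted gene lists (self-consistency is asserted, not assumed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import dmv as dmv_mod
from . import enrichment as enrich_mod
from . import expression as expr_mod
from . import global_stats, metagene
from .io import (
    GenomicInterval,
    MethylomeSample,
    MethvalleyError,
    ValidationError,
    pool_samples,
    read_cytosine_report,
    read_gene_annotation,
    read_expression_table,
    write_intervals_bed,
)

logger = logging.getLogger(__name__)


class PipelineError(MethvalleyError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class SampleEntry:
    path: str
    tissue: str
    replicate: int


@dataclass
class PipelineConfig:
    samples: list[SampleEntry]
    annotation: str
    expression: str
    out_dir: str
    seed: int = 0
    chrom_sizes: dict[str, int] | None = None
    dmr_contexts: tuple[str, ...] = ("CG", "CHG", "CHH")
    dmr_overrides: dict[str, dict] = field(default_factory=dict)
    dmv: dmv_mod.DmvParams = field(default_factory=dmv_mod.DmvParams)
    tau_min: float = 0.99
    min_max_abundance: float = 1.0
    fold_change_cutoff: float = 2.0
    enrichment_universe: str = "expressed"  # or "annotated"
    metagene_flank: int = 2000

    def __post_init__(self) -> None:
        if self.enrichment_universe not in ("expressed", "annotated"):
            raise ValidationError("enrichment_universe must be 'expressed' or 'annotated'")
        tissues = {s.tissue for s in self.samples}
        if len(tissues) < 2:
            raise ValidationError("need samples from >= 2 tissues")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.tissue not in seen:
                seen.append(s.tissue)
        return seen

    def config_hash(self) -> str:
        doc = {
            "samples": [[s.path, s.tissue, s.replicate] for s in self.samples],
            "annotation": self.annotation, "expression": self.expression,
            "seed": self.seed, "dmr_contexts": list(self.dmr_contexts),
            "dmr_overrides": self.dmr_overrides,
            "dmv": self.dmv.__dict__, "tau_min": self.tau_min,
            "min_max_abundance": self.min_max_abundance,
            "fold_change_cutoff": self.fold_change_cutoff,
            "enrichment_universe": self.enrichment_universe,
            "metagene_flank": self.metagene_flank,
        }
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; referenced paths must exist."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    def resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    samples = [
        SampleEntry(resolve(s["path"]), str(s["tissue"]), int(s.get("replicate", 1)))
        for s in doc["samples"]
    ]
    for s in samples:
        if not Path(s.path).exists():
            raise ValidationError(f"sample file not found: {s.path}")
    for key in ("annotation", "expression"):
        if not Path(resolve(doc[key])).exists():
            raise ValidationError(f"{key} file not found: {resolve(doc[key])}")
    kwargs: dict = {}
    if "dmv" in doc:
        kwargs["dmv"] = dmv_mod.DmvParams(**doc["dmv"])
    for key in ("seed", "chrom_sizes", "dmr_contexts", "dmr_overrides", "tau_min",
                "min_max_abundance", "fold_change_cutoff", "enrichment_universe",
                "metagene_flank"):
        if key in doc:
            kwargs[key] = doc[key]
    if "dmr_contexts" in kwargs:
        kwargs["dmr_contexts"] = tuple(kwargs["dmr_contexts"])
    return PipelineConfig(
        samples=samples,
        annotation=resolve(doc["annotation"]),
        expression=resolve(doc["expression"]),
        out_dir=resolve(doc.get("out_dir", "methvalley_out")),
        **kwargs,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run summary dict.

    Outputs land in ``config.out_dir``: per-tissue global stats, 100-kb
    window tracks, per-context DMR tables + BED, per-tissue DMV regions +
    gene lists, the TAU table, enrichment results, metagene profiles and
    ``summary.json``/``summary.tsv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}

    samples = _load_samples(config)
    genes = _load_genes(config)
    matrix = _load_expression(config)
    tissues = config.tissues
    expr_tissues = set(matrix.tissues)
    missing = [t for t in tissues if t not in expr_tissues]
    if missing:
        raise PipelineError(
            f"stage 'load' failed: tissues {missing} in the sample sheet are "
            f"absent from the expression table columns {matrix.tissues}"
        )

    pooled = {
        t: pool_samples([s for s in samples if s.tissue == t], f"{t}_pooled", t)
        for t in tissues
    }

    _write_global_stats(pooled, genes, out)
    dmr_counts, dmr_gene_counts = _run_dmr(config, samples, genes, out)
    dmv_windows, dmv_gene_sets = _run_dmv(config, pooled, genes, out)
    tau_df, preferential = _run_tau(config, matrix, out)
    enrich_results, overlap_counts = _run_enrichment(
        config, matrix, genes, preferential, dmv_gene_sets, out
    )
    _run_metagene(config, pooled, genes, tau_df, preferential, out)

    per_tissue_counts, shared, union = dmv_mod.dmv_tissue_overlap(dmv_gene_sets)
    n_pref = {t: len(preferential.get(t, set())) for t in tissues}
    all_pref = set().union(*preferential.values()) if preferential else set()
    all_dmv = set().union(*dmv_gene_sets.values()) if dmv_gene_sets else set()
    pref_dmv = all_pref & all_dmv
    total_pref, pct = preferential_dmv_summary(n_pref, len(pref_dmv))
    # self-consistency: the percentage must agree with the emitted gene lists
    assert total_pref == len(all_pref), "preferential sets overlap across tissues"
    assert pct == round(100 * len(pref_dmv) / total_pref, 1) if total_pref else pct == 0.0

    summary = {
        **stamp,
        "tissues": tissues,
        "dmv_windows_per_tissue": dmv_windows,
        "dmv_genes_per_tissue": per_tissue_counts,
        "dmv_genes_shared": shared,
        "dmv_genes_union": union,
        "dmr_counts_per_context": dmr_counts,
        "dmr_associated_genes_per_context": dmr_gene_counts,
        "preferential_genes_per_tissue": n_pref,
        "preferential_total": total_pref,
        "preferential_dmv_overlap": len(pref_dmv),
        "preferential_dmv_percent": pct,
        "enrichment": enrich_results,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    pd.DataFrame([
        {"key": k, "value": json.dumps(v) if isinstance(v, (dict, list)) else v}
        for k, v in summary.items()
    ]).to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary


def preferential_dmv_summary(
    n_preferential_by_tissue: Mapping[str, int], n_overlap: int
) -> tuple[int, float]:
    """Total tissue-preferential genes and the percentage of them that are
    DMV genes (1 decimal), from per-tissue counts and the overlap count."""
    total = int(sum(n_preferential_by_tissue.values()))
    if n_overlap > total:
        raise ValidationError("overlap cannot exceed the total preferential count")
    pct = round(100.0 * n_overlap / total, 1) if total else 0.0
    return total, pct


# --- stages ----------------------------------------------------------------

@_stage("load")
def _load_samples(config: PipelineConfig) -> list[MethylomeSample]:
    return [
        read_cytosine_report(s.path, f"{s.tissue}_{s.replicate}", s.tissue,
                             s.replicate, config.chrom_sizes)
        for s in config.samples
    ]


@_stage("load")
def _load_genes(config: PipelineConfig):
    return read_gene_annotation(config.annotation)


@_stage("load")
def _load_expression(config: PipelineConfig):
    return read_expression_table(config.expression)


@_stage("global_stats")
def _write_global_stats(pooled, genes, out: Path) -> None:
    rows = []
    for tissue, sample in pooled.items():
        summary = global_stats.global_summary(sample)
        for ctx in ("CG", "CHG", "CHH"):
            rows.append({
                "tissue": tissue, "context": ctx,
                "weighted_level": summary.weighted_level[ctx],
                "mc_count": summary.mc_count[ctx],
                "mc_proportion": summary.proportions[ctx],
            })
        track = global_stats.chromosome_window_summary(sample, genes=genes)
        track.to_csv(out / f"windows_100kb_{tissue}.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(out / "global_stats.tsv", sep="\t", index=False)


@_stage("dmr")
def _run_dmr(config: PipelineConfig, samples, genes, out: Path):
    tissues = config.tissues
    group_a = [s for s in samples if s.tissue == tissues[0]]
    group_b = [s for s in samples if s.tissue == tissues[1]]
    counts, gene_counts = {}, {}
    for ctx in config.dmr_contexts:
        criteria = dmr_mod.DmrCriteria.for_context(ctx, **config.dmr_overrides.get(ctx, {}))
        records = dmr_mod.call_dmrs(group_a, group_b, criteria, config.chrom_sizes)
        dmr_mod.dmrs_to_dataframe(records).to_csv(
            out / f"dmrs_{ctx}.tsv", sep="\t", index=False
        )
        write_intervals_bed(
            [d.interval for d in records], out / f"dmrs_{ctx}.bed",
            scores=[d.q for d in records],
        )
        assoc = dmr_mod.dmr_associated_genes(records, genes)
        (out / f"dmr_genes_{ctx}.txt").write_text("".join(f"{g}\n" for g in sorted(assoc)))
        counts[ctx] = len(records)
        gene_counts[ctx] = len(assoc)
    return counts, gene_counts


@_stage("dmv")
def _run_dmv(config: PipelineConfig, pooled, genes, out: Path):
    window_counts, gene_sets = {}, {}
    for tissue, sample in pooled.items():
        regions = dmv_mod.detect_dmvs(sample, config.dmv)
        write_intervals_bed(
            [r.interval for r in regions], out / f"dmv_{tissue}.bed",
            scores=[r.mean_level for r in regions],
        )
        gset = dmv_mod.dmv_genes(regions, genes, config.dmv.gene_fraction)
        (out / f"dmv_genes_{tissue}.txt").write_text("".join(f"{g}\n" for g in sorted(gset)))
        window_counts[tissue] = sum(r.n_windows_merged for r in regions)
        gene_sets[tissue] = gset
    return window_counts, gene_sets


@_stage("tau")
def _run_tau(config: PipelineConfig, matrix, out: Path):
    tau_df = expr_mod.tau_table(matrix)
    tau_df.rename_axis("gene_id").to_csv(out / "tau.tsv", sep="\t")
    preferential = expr_mod.preferential_genes(matrix, config.tau_min, config.min_max_abundance)
    for tissue, gset in preferential.items():
        (out / f"preferential_{tissue}.txt").write_text(
            "".join(f"{g}\n" for g in sorted(gset))
        )
    return tau_df, preferential


@_stage("enrichment")
def _run_enrichment(config: PipelineConfig, matrix, genes, preferential, dmv_gene_sets, out: Path):
    if config.enrichment_universe == "expressed":
        tau_df = expr_mod.tau_table(matrix)
        universe = set(tau_df.index[tau_df["tau"].notna()])
    else:
        universe = {g.gene_id for g in genes}
    results, overlaps = {}, {}
    rows = []
    for tissue, pref in preferential.items():
        dmv_set = dmv_gene_sets.get(tissue, set())
        res = enrich_mod.set_enrichment(pref & universe, dmv_set & universe, universe)
        results[tissue] = {"p_value": res.p_value, "fold_enrichment": res.fold_enrichment,
                           "overlap": res.overlap}
        overlaps[tissue] = res.overlap
        rows.append({"tissue": tissue, "universe": res.universe_size,
                     "preferential": res.set_a_size, "dmv_genes": res.set_b_size,
                     "overlap": res.overlap, "p_value": res.p_value,
                     "fold_enrichment": res.fold_enrichment})
    pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    return results, overlaps


@_stage("metagene")
def _run_metagene(config: PipelineConfig, pooled, genes, tau_df, preferential, out: Path):
    by_id = {g.gene_id: g for g in genes}
    pref_all = set().union(*preferential.values()) if preferential else set()
    constitutive = [
        by_id[g] for g in tau_df.index[tau_df["tau"].notna() & (tau_df["tau"] < config.tau_min)]
        if g in by_id and g not in pref_all
    ]
    gene_sets = {"preferential": [by_id[g] for g in pref_all if g in by_id],
                 "constitutive": constitutive}
    for tissue, sample in pooled.items():
        for label, gset in gene_sets.items():
            if not gset:
                continue
            profile = metagene.metagene_profile(sample, gset, flank=config.metagene_flank)
            df = profile.values.copy()
            df.insert(0, "bin", range(profile.n_bins))
            df.to_csv(out / f"metagene_{tissue}_{label}.tsv", sep="\t", index=False)
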