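"""TAU tissue-specificity index and tissue-preferential gene classification.

TAU summarises how concentrated a gene's expression is in one tissue:

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

over the n tissue abundances x_i.  tau = 0 for perfectly uniform expression,
tau = 1 for single-tissue expression; with two tissues it reduces to
1 - min/max.  Genes with tau >= 0.99 (and an abundance floor, see
:func:`preferential_genes`) are classed as tissue-preferentially expressed
and assigned to their highest-expressing tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NoDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Gene x tissue abundance table (RPKM/FPKM), non-negative, no missing cells."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any(axis=None):
            raise ValidationError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression matrix contains negative values")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float
    preferred_tissue: str
    max_value: float


def tau(values) -> float:
    """Tissue-specificity index over a vector of >= 2 abundances.

    Undefined (raises :class:`NoDataError`) for an all-zero vector: a gene
    expressed nowhere has no specificity, and treating it as tau = 0 would
    class it with constitutive genes.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("tau needs a 1-d vector of at least 2 abundances")
    if (x < 0).any():
        raise ValidationError("tau is defined for non-negative abundances")
    xmax = x.max()
    if xmax == 0:
        raise NoDataError("tau undefined for an all-zero expression vector")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def tau_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tau, preferred tissue and maximum abundance.

    All-zero genes get tau = NaN (excluded from classification); argmax ties
    get preferred_tissue = NaN.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise ValidationError("need >= 2 tissues")
    xmax = vals.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        taus = np.where(xmax > 0, (1.0 - vals / xmax[:, None]).sum(axis=1) / (n - 1), np.nan)
    argmax = vals.argmax(axis=1)
    tied = (vals == xmax[:, None]).sum(axis=1) > 1
    tissues = np.asarray(matrix.tissues, dtype=object)
    preferred = tissues[argmax].astype(object)
    preferred[tied] = np.nan
    return pd.DataFrame(
        {"tau": taus, "preferred_tissue": preferred, "max_value": xmax},
        index=matrix.values.index,
    )


def preferential_genes(
    matrix: ExpressionMatrix,
    tau_min: float = 0.99,
    min_max_abundance: float = 1.0,
) -> dict[str, set[str]]:
    """Tissue-preferentially expressed genes per tissue.

    A gene qualifies when its tau is defined and >= ``tau_min`` and its maximum
    abundance is >= ``min_max_abundance`` (a floor guarding against noise-only
    genes whose zero-vs-epsilon profile scores tau = 1; set it to 0 to
    disable).  Qualifying genes are assigned to their argmax tissue; argmax
    ties are excluded and logged.
    """
    table = tau_table(matrix)
    out: dict[str, set[str]] = {t: set() for t in matrix.tissues}
    qual = table[(table["tau"] >= tau_min) & (table["max_value"] >= min_max_abundance)]
    for gene_id, row in qual.iterrows():
        if not isinstance(row["preferred_tissue"], str):
            logger.warning("gene %s: tied argmax expression, excluded", gene_id)
            continue
        out[row["preferred_tissue"]].add(str(gene_id))
    return out


def fold_change_de(
    matrix: ExpressionMatrix,
    tissue_a: str,
    tissue_b: str,
    cutoff: float = 2.0,
    pseudocount: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Two-fold-change differential expression between two tissues.

    A gene is "up in a" iff (v_a + pseudocount) / (v_b + pseudocount) >= cutoff
    (boundary inclusive), and symmetrically for b.  The pseudocount keeps zero
    denominators finite.
    """
    if cutoff <= 1:
        raise ValidationError("fold-change cutoff must exceed 1")
    va = matrix.values[tissue_a].to_numpy(dtype=float) + pseudocount
    vb = matrix.values[tissue_b].to_numpy(dtype=float) + pseudocount
    genes = np.asarray(matrix.genes, dtype=object)
    up_a = set(genes[va / vb >= cutoff])
    up_b = set(genes[vb / va >= cutoff])
    return up_a, up_b
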