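"""Gene grouping, quality filtering and expression transforms.

Filtering operates on pre-transformation values; log/normalization transforms
are applied afterwards, in the order log first, normalization next.
All detection/expression criteria use strict ``>`` comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from cernanet.io_harmonize import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneGrouping:
    """Mapping gene symbol -> group label; each gene in exactly one group."""

    group_of: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, label in self.group_of.items():
            out.setdefault(label, []).append(g)
        return {k: sorted(v) for k, v in out.items()}

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def restrict(self, genes) -> "GeneGrouping":
        keep = set(genes)
        return GeneGrouping({g: l for g, l in self.group_of.items() if g in keep})


@dataclass
class FilterReport:
    """Record of what a filtering step measured, removed and retained."""

    sample_ratio_cerna: pd.Series | None = None
    sample_ratio_mirna: pd.Series | None = None
    gene_ratio: pd.Series | None = None
    removed_samples: list[str] = field(default_factory=list)
    retained_samples: list[str] = field(default_factory=list)
    removed_genes: dict[str, list[str]] = field(default_factory=dict)
    retained_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed_samples": self.removed_samples,
            "retained_samples": self.retained_samples,
            "removed_genes": self.removed_genes,
            "retained_genes": self.retained_genes,
        }


def assign_groups(
    annotation,
    attribute: str,
    rule: Mapping[str, str],
    default_group: str = "Other",
) -> GeneGrouping:
    """Assign each annotated gene to a group via an attribute-value rule.

    E.g. ``rule={"protein_coding": "Coding"}, default_group="Noncoding"``
    reproduces the coding/noncoding biotype split.
    """
    values = annotation.attribute(attribute) if attribute else None
    group_of = {}
    for gene in annotation.gene_symbols:
        if values is None:
            group_of[gene] = default_group
        else:
            group_of[gene] = rule.get(str(values.loc[gene]), default_group)
    return GeneGrouping(group_of)


def detected_ratio_per_sample(
    expr: ExpressionMatrix, detect_threshold: float
) -> pd.Series:
    """Fraction of genes with value strictly above the threshold, per sample."""
    return (expr.data > detect_threshold).mean(axis=0)


def expressing_sample_ratio(expr: ExpressionMatrix, min_expr: float) -> pd.Series:
    """Fraction of samples with value strictly above ``min_expr``, per gene."""
    return (expr.data > min_expr).mean(axis=1)


def filter_samples(
    cerna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    cerna_detect_threshold: float,
    mirna_detect_threshold: float,
    min_ratio: tuple[float, float] | None = None,
    drop_lowest: tuple[int, int] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, FilterReport]:
    """Remove low-quality samples from both matrices jointly.

    Exactly one of ``min_ratio`` (ceRNA, miRNA minimum detected ratios;
    sample kept iff ratio >= minimum in both) or ``drop_lowest`` (number of
    lowest-ratio samples to drop per matrix; the union is removed from both)
    must be given.  Both matrices end with the identical retained sample set.
    """
    if (min_ratio is None) == (drop_lowest is None):
        raise ValueError("specify exactly one of min_ratio or drop_lowest")
    samples = cerna_expr.sample_names
    if set(samples) != set(mirna_expr.sample_names):
        raise ValueError("matrices must share the same sample set")
    r_cerna = detected_ratio_per_sample(cerna_expr, cerna_detect_threshold)
    r_mirna = detected_ratio_per_sample(mirna_expr, mirna_detect_threshold)

    if min_ratio is not None:
        min_c, min_m = min_ratio
        removed = {
            s for s in samples if r_cerna[s] < min_c or r_mirna[s] < min_m
        }
    else:
        k_c, k_m = drop_lowest
        # stable tie-break by sample name so results are deterministic
        by_c = sorted(samples, key=lambda s: (r_cerna[s], s))
        by_m = sorted(samples, key=lambda s: (r_mirna[s], s))
        removed = set(by_c[:k_c]) | set(by_m[:k_m])

    retained = [s for s in samples if s not in removed]
    if not retained:
        raise ValueError("sample filtering removed all samples")
    report = FilterReport(
        sample_ratio_cerna=r_cerna,
        sample_ratio_mirna=r_mirna,
        removed_samples=sorted(removed),
        retained_samples=retained,
    )
    logger.info(
        "filter_samples: removed %d of %d samples", len(removed), len(samples)
    )
    return (
        cerna_expr.subset(samples=retained),
        mirna_expr.subset(samples=retained),
        report,
    )


def filter_genes(
    cerna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    grouping: GeneGrouping,
    group_thresholds: Mapping[str, tuple[float, float]],
    mirna_thresholds: tuple[float, float],
) -> tuple[ExpressionMatrix, ExpressionMatrix, FilterReport]:
    """Remove non-expressed RNAs per group and miRNAs by the same rule.

    A gene survives iff its expressing-sample ratio at its group's
    ``min_expr`` is strictly greater than the group's ``min_fraction``.
    Groups missing a threshold pair are an error; a group losing all genes
    only warns.
    """
    groups = grouping.groups
    missing = [g for g in groups if g not in group_thresholds]
    if missing:
        raise ValueError(f"no thresholds for group(s): {missing}")

    gene_ratio = pd.Series(dtype=float)
    removed: dict[str, list[str]] = {}
    retained: dict[str, list[str]] = {}
    keep_cerna: list[str] = []
    for label, genes in groups.items():
        genes = [g for g in genes if g in set(cerna_expr.gene_symbols)]
        min_expr, min_fraction = group_thresholds[label]
        sub = cerna_expr.subset(genes=genes)
        ratios = expressing_sample_ratio(sub, min_expr)
        gene_ratio = pd.concat([gene_ratio, ratios])
        kept = [g for g in genes if ratios[g] > min_fraction]
        removed[label] = sorted(set(genes) - set(kept))
        retained[label] = kept
        keep_cerna.extend(kept)
        if genes and not kept:
            logger.warning("filter_genes: group %r lost all its genes", label)

    m_expr, m_fraction = mirna_thresholds
    m_ratios = expressing_sample_ratio(mirna_expr, m_expr)
    keep_mirna = [g for g in mirna_expr.gene_symbols if m_ratios[g] > m_fraction]
    removed["miRNA"] = sorted(set(mirna_expr.gene_symbols) - set(keep_mirna))
    retained["miRNA"] = keep_mirna

    report = FilterReport(
        gene_ratio=gene_ratio, removed_genes=removed, retained_genes=retained
    )
    logger.info(
        "filter_genes: retained %s",
        {k: len(v) for k, v in retained.items()},
    )
    return (
        cerna_expr.subset(genes=keep_cerna),
        mirna_expr.subset(genes=keep_mirna),
        report,
    )


_LOG_FN = {2: np.log2, 10: np.log10, "e": np.log, math.e: np.log}


def log_transform(
    expr: ExpressionMatrix, base: float | str = 2, pseudocount: float = 0.0
) -> ExpressionMatrix:
    """value -> log_base(value + pseudocount); requires strictly positive args."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if base not in _LOG_FN:
        raise ValueError(f"unsupported log base {base!r} (use 2, 10 or 'e')")
    shifted = expr.data + pseudocount
    if (shifted <= 0).to_numpy().any():
        raise ValueError("log transform requires value + pseudocount > 0 everywhere")
    return ExpressionMatrix(_LOG_FN[base](shifted))


def normalize(
    expr: ExpressionMatrix,
    method: str | Callable[[np.ndarray], np.ndarray] = "minmax",
) -> ExpressionMatrix:
    """Row-wise normalization: ``minmax``, ``zscore`` or a custom row function.

    Constant rows map to zeros with a warning (both built-in methods).
    z-scores use sample standard deviation (N-1 denominator).
    """
    mat = expr.data.to_numpy(dtype=float)
    out = np.empty_like(mat)
    if callable(method):
        for i in range(mat.shape[0]):
            out[i] = np.asarray(method(mat[i]), dtype=float)
    elif method == "minmax":
        lo, hi = mat.min(axis=1, keepdims=True), mat.max(axis=1, keepdims=True)
        rng = hi - lo
        flat = (rng == 0).ravel()
        if flat.any():
            logger.warning("normalize: %d zero-range row(s) set to 0", flat.sum())
        rng[rng == 0] = 1.0
        out = (mat - lo) / rng
        out[flat] = 0.0
    elif method == "zscore":
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        flat = (sd == 0).ravel()
        if flat.any():
            logger.warning("normalize: %d zero-sd row(s) set to 0", flat.sum())
        sd[sd == 0] = 1.0
        out = (mat - mean) / sd
        out[flat] = 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)
    )


def histogram_table(values: pd.Series, bins: int = 20) -> pd.DataFrame:
    """Bin a ratio/metric vector into a (bin_left, bin_right, count) table."""
    counts, edges = np.histogram(values.to_numpy(dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
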