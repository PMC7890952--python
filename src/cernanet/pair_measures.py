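"""The five ceRNA pair measures and their shared building blocks.

MS    shared-miRNA enrichment significance: the hypergeometric upper-tail
      probability that two transcripts share at least their observed number
      of targeting miRNAs,
      MS = 1 - sum_{i=0}^{t-1} C(T1,i) C(Q-T1, T2-i) / C(Q,T2).
PCC   Pearson product-moment correlation of the two expression vectors.
MI    plug-in mutual information of the discretized expression vectors
      (natural log, 0*log 0 = 0).
CMI   plug-in conditional mutual information given the discretized sum of
      shared-miRNA expression.
LA    liquid association: (1/N) sum_i z_i(x) z_i(y) norm_i(m), z-scores with
      the N-1 denominator and norm the Van der Waerden normal scores of the
      shared-miRNA expression sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from cernanet.io_harmonize import ExpressionMatrix, InteractionTable

logger = logging.getLogger(__name__)

MEASURES = ("MS", "PCC", "MI", "CMI", "LA")

DiscretizeMethod = Literal["equal-frequency", "equal-width"]


def ms(t: int, T1: int, T2: int, Q: int) -> float:
    """Shared-miRNA enrichment significance P(X >= t).

    X ~ Hypergeometric(population Q, successes T1, draws T2).  t = 0 gives
    exactly 1.0 (empty sum).  Evaluated through the survival function for
    numerical safety.
    """
    if not (0 <= t <= min(T1, T2) and 0 <= T1 <= Q and 0 <= T2 <= Q):
        raise ValueError(
            f"invalid hypergeometric configuration t={t}, T1={T1}, T2={T2}, Q={Q}"
        )
    if t == 0:
        return 1.0
    return float(stats.hypergeom.sf(t - 1, Q, T1, T2))


def pcc(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation; ``None`` (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pcc: constant input vector, correlation undefined")
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass(frozen=True)
class DiscretizedVector:
    """Integer bin labels for one expression vector."""

    labels: np.ndarray
    n_bins: int
    method: DiscretizeMethod

    def __len__(self) -> int:
        return len(self.labels)


def default_n_bins(n_samples: int) -> int:
    """Plug-in bin count: max(2, floor(sqrt(N)))."""
    return max(2, int(np.sqrt(n_samples)))


def discretize(
    x: np.ndarray, n_bins: int, method: DiscretizeMethod = "equal-frequency"
) -> DiscretizedVector:
    """Bin a real vector into ``n_bins`` integer labels.

    equal-frequency: quantile cut on average ranks (ties share a bin);
    equal-width: uniform partition of [min, max], right-closed final bin.
    A constant vector collapses to a single occupied bin with a warning.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} observations, got {n}")
    if np.ptp(x) == 0:
        logger.warning("discretize: constant vector, single occupied bin")
        return DiscretizedVector(np.zeros(n, dtype=int), n_bins, method)
    if method == "equal-frequency":
        ranks = stats.rankdata(x, method="average")
        labels = np.ceil(ranks * n_bins / n).astype(int) - 1
    elif method == "equal-width":
        width = np.ptp(x) / n_bins
        labels = np.minimum(((x - x.min()) // width).astype(int), n_bins - 1)
    else:
        raise ValueError(f"unknown discretization method {method!r}")
    return DiscretizedVector(np.clip(labels, 0, n_bins - 1), n_bins, method)


def _joint_counts(*vectors: DiscretizedVector) -> np.ndarray:
    shape = tuple(int(v.labels.max()) + 1 for v in vectors)
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, tuple(v.labels for v in vectors), 1.0)
    return counts


def mi(dx: DiscretizedVector, dy: DiscretizedVector) -> float:
    """Plug-in mutual information in nats (0 log 0 = 0)."""
    if len(dx) != len(dy):
        raise ValueError("vectors must have equal length")
    pxy = _joint_counts(dx, dy) / len(dx)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    val = float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))
    return max(val, 0.0)


def cmi(dx: DiscretizedVector, dy: DiscretizedVector, dz: DiscretizedVector) -> float:
    """Plug-in conditional mutual information I(X;Y|Z) in nats."""
    if not (len(dx) == len(dy) == len(dz)):
        raise ValueError("vectors must have equal length")
    n = len(dx)
    pxyz = _joint_counts(dx, dy, dz) / n
    pxz = pxyz.sum(axis=1, keepdims=True)
    pyz = pxyz.sum(axis=0, keepdims=True)
    pz = pxyz.sum(axis=(0, 1), keepdims=True)
    mask = pxyz > 0
    num = np.broadcast_to(pz * pxyz, pxyz.shape)[mask]
    den = np.broadcast_to(pxz * pyz, pxyz.shape)[mask]
    val = float(np.sum(pxyz[mask] * np.log(num / den)))
    return max(val, 0.0)


def vdw_scores(v: np.ndarray) -> np.ndarray:
    """Van der Waerden normal scores Phi^-1(rank / (N+1)), average ranks."""
    v = np.asarray(v, dtype=float)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf(ranks / (len(v) + 1))


def la(x: np.ndarray, y: np.ndarray, m: np.ndarray) -> float | None:
    """Liquid association of (x, y) modulated by m.

    z-scores of x and y use the sample standard deviation (N-1); m is
    converted to Van der Waerden normal scores; the outer average divides
    by N.  Constant x or y makes the statistic undefined (``None``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if not (len(x) == len(y) == len(m)):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("liquid association needs at least 3 samples")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        logger.warning("la: constant input vector, statistic undefined")
        return None
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    return float(np.sum(zx * zy * vdw_scores(m)) / n)


@dataclass(frozen=True)
class SharedMirnaContext:
    """Shared-miRNA bookkeeping for one candidate pair."""

    gene1: str
    gene2: str
    shared_mirnas: frozenset[str]
    t: int
    T1: int
    T2: int
    Q: int
    summed_mirna_expression: np.ndarray | None  # None when t == 0


def pair_context(
    gene1: str,
    gene2: str,
    interactions: InteractionTable,
    mirna_expr: ExpressionMatrix,
    universe: frozenset[str] | set[str],
) -> SharedMirnaContext:
    """Count targeting miRNAs within the universe and sum shared expression.

    Q = |universe|; T1/T2/t are counted within the universe only.  The
    summed shared-miRNA expression vector (samples in matrix order) is only
    defined when t >= 1.
    """
    universe = set(universe)
    m1 = interactions.mirnas_of(gene1) & universe
    m2 = interactions.mirnas_of(gene2) & universe
    shared = m1 & m2
    summed = None
    if shared:
        rows = [m for m in mirna_expr.gene_symbols if m in shared]
        summed = mirna_expr.data.loc[rows].to_numpy(dtype=float).sum(axis=0)
    return SharedMirnaContext(
        gene1=gene1,
        gene2=gene2,
        shared_mirnas=frozenset(shared),
        t=len(shared),
        T1=len(m1),
        T2=len(m2),
        Q=len(universe),
        summed_mirna_expression=summed,
    )


@dataclass(frozen=True)
class PairMeasureRecord:
    """Measure values for one canonical (gene1 < gene2) candidate pair."""

    gene1: str
    gene2: str
    group_pair: str
    t: int
    shared_mirnas: frozenset[str]
    values: dict[str, float | None]  # measure name -> value (None = undefined)

    def __post_init__(self) -> None:
        if self.gene1 >= self.gene2:
            raise ValueError("pair must be canonical: gene1 < gene2")


def compute_pair_record(
    gene1: str,
    gene2: str,
    group_pair: str,
    cerna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    interactions: InteractionTable,
    universe,
    measures=MEASURES,
    n_bins: int | None = None,
    discretize_method: DiscretizeMethod = "equal-frequency",
    custom=None,
) -> PairMeasureRecord:
    """Compute the selected measures for one pair.

    Pairs with no shared miRNA get MS = 1 exactly and absent CMI/LA.
    ``custom`` maps extra measure names to callables ``f(x, y, ctx)``.
    """
    if gene1 > gene2:
        gene1, gene2 = gene2, gene1
    ctx = pair_context(gene1, gene2, interactions, mirna_expr, universe)
    x = cerna_expr.row(gene1)
    y = cerna_expr.row(gene2)
    if n_bins is None:
        n_bins = default_n_bins(len(x))
    values: dict[str, float | None] = {}
    dx = dy = None
    for name in measures:
        if name == "MS":
            values["MS"] = ms(ctx.t, ctx.T1, ctx.T2, ctx.Q)
        elif name == "PCC":
            values["PCC"] = pcc(x, y)
        elif name == "MI":
            dx = dx or discretize(x, n_bins, discretize_method)
            dy = dy or discretize(y, n_bins, discretize_method)
            values["MI"] = mi(dx, dy)
        elif name == "CMI":
            if ctx.t == 0:
                logger.debug("cmi skipped for (%s, %s): no shared miRNA", gene1, gene2)
                values["CMI"] = None
            else:
                dx = dx or discretize(x, n_bins, discretize_method)
                dy = dy or discretize(y, n_bins, discretize_method)
                dz = discretize(
                    ctx.summed_mirna_expression, n_bins, discretize_method
                )
                values["CMI"] = cmi(dx, dy, dz)
        elif name == "LA":
            if ctx.t == 0:
                logger.debug("la skipped for (%s, %s): no shared miRNA", gene1, gene2)
                values["LA"] = None
            else:
                values["LA"] = la(x, y, ctx.summed_mirna_expression)
        elif custom and name in custom:
            values[name] = custom[name](x, y, ctx)
        else:
            raise ValueError(f"unknown measure {name!r}")
    return PairMeasureRecord(
        gene1=gene1,
        gene2=gene2,
        group_pair=group_pair,
        t=ctx.t,
        shared_mirnas=ctx.shared_mirnas,
        values=values,
    )
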