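"""Local over-representation analysis and module-biomarker survival analysis.

ORA reuses the same hypergeometric upper tail as the shared-miRNA enrichment
measure (one implementation, two call sites), with Benjamini-Hochberg
adjustment across the collection.  Survival analysis provides the
Kaplan-Meier product-limit estimator, a k-sample log-rank test, expression
based patient stratification and a thin Cox proportional-hazards adapter
around lifelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cernanet.pair_measures import ms

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] | None = None

    @classmethod
    def from_sets(cls, sets, universe, descriptions=None) -> "GeneSetCollection":
        universe = frozenset(universe)
        if not universe:
            raise ValueError("empty universe")
        restricted = {}
        dropped = 0
        for name, genes in sets.items():
            genes = frozenset(genes)
            dropped += len(genes - universe)
            restricted[name] = genes & universe
        if dropped:
            logger.info(
                "gene sets: %d out-of-universe symbols dropped on restriction",
                dropped,
            )
        return cls(restricted, universe, descriptions or {})


def read_gmt(path: str | Path, universe) -> GeneSetCollection:
    """Read a GMT-style file: set name, description, genes (tab-delimited)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
            descriptions[fields[0]] = fields[1]
    return GeneSetCollection.from_sets(sets, universe, descriptions)


def ora(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    p(set) = upper-tail probability of observing at least the overlap,
    evaluated via the same ``ms`` routine used for shared-miRNA enrichment
    with (t=overlap, T1=|set|, T2=|query|, Q=|universe|).  q-values are
    Benjamini-Hochberg across the collection.
    """
    query = frozenset(query) & collection.universe
    if not collection.universe:
        raise ValueError("empty universe")
    rows = []
    for name in sorted(collection.sets):
        genes = collection.sets[name]
        overlap = query & genes
        p = ms(len(overlap), len(genes), len(query), len(collection.universe))
        rows.append(
            {
                "set": name,
                "set_size": len(genes),
                "query_size": len(query),
                "overlap": len(overlap),
                "overlap_genes": ";".join(sorted(overlap)),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set", "set_size", "query_size", "overlap", "overlap_genes", "p_value"],
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = []
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SurvivalTable:
    """Per-patient time-to-event data (time > 0, event in {0, 1})."""

    data: pd.DataFrame  # index = sample ids; columns time, event (+ covariates)

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


def read_survival(path: str | Path, delimiter: str = "\t") -> SurvivalTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.columns = [c.lower() for c in df.columns]
    return SurvivalTable(df)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit step function with its median survival time."""

    event_times: np.ndarray
    survival: np.ndarray
    median: float  # inf if the curve never drops to <= 0.5

    def at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.event_times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i).

    ``event_times`` are the distinct times with at least one event; an
    all-censored input yields a flat curve at 1.0 with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if events.sum() == 0:
        logger.warning("km_curve: no events, survival curve is flat at 1.0")
        return KMCurve(np.array([]), np.array([]), float("inf"))
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    ts, surv = [], []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n_at_risk
        ts.append(t)
        surv.append(s)
    surv_arr = np.asarray(surv)
    below = np.nonzero(surv_arr <= 0.5)[0]
    median = float(ts[below[0]]) if below.size else float("inf")
    return KMCurve(np.asarray(ts), surv_arr, median)


def logrank(group_labels, times, events) -> tuple[float, float]:
    """k-sample log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed minus expected event counts per
    group are accumulated with the hypergeometric (multivariate) variance;
    the statistic is (O-E)' V^+ (O-E) on the first k-1 groups with k-1 df.
    """
    labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = sorted(set(labels.tolist()))
    k = len(groups)
    if k < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for g in groups:
        if np.sum(labels == g) == 0:
            raise ValueError(f"group {g!r} is empty")
    gidx = np.array([groups.index(l) for l in labels])
    oe = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        d = int(np.sum((times == t) & (events == 1)))
        if n == 0 or d == 0:
            continue
        n_g = np.array([np.sum(at_risk & (gidx == j)) for j in range(k)], dtype=float)
        d_g = np.array(
            [np.sum((times == t) & (events == 1) & (gidx == j)) for j in range(k)],
            dtype=float,
        )
        e_g = d * n_g / n
        oe += d_g - e_g
        if n > 1:
            c = d * (n - d) / (n - 1) / n**2
            V += c * (np.diag(n_g * n) - np.outer(n_g, n_g))
    v_sub = V[: k - 1, : k - 1]
    oe_sub = oe[: k - 1]
    stat = float(oe_sub @ np.linalg.pinv(v_sub) @ oe_sub)
    p = float(stats.chi2.sf(stat, df=k - 1))
    return stat, p


def stratify_by_module(
    patient_expr: pd.DataFrame,
    module_genes,
    rule: str = "median",
    seed: int = 0,
) -> pd.Series:
    """Label patients low/high from module-gene expression.

    ``patient_expr`` is genes x patients.  Default rule: per-patient score =
    mean of per-gene z-scores; low if score < median, high otherwise.
    Alternatives: ``kmeans`` (k=2 on the score, low = lower-center cluster)
    and ``single:<gene>`` (median split on one gene).
    """
    genes = [g for g in module_genes if g in patient_expr.index]
    if not genes:
        raise ValueError("none of the module genes are in the patient expression")
    if rule.startswith("single:"):
        gene = rule.split(":", 1)[1]
        if gene not in patient_expr.index:
            raise ValueError(f"gene {gene!r} not in patient expression")
        score = patient_expr.loc[gene].astype(float)
    else:
        sub = patient_expr.loc[genes].astype(float)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
        score = sub.sub(mean, axis=0).div(sd, axis=0).mean(axis=0)
    if rule == "kmeans":
        from scipy.cluster.vq import kmeans2

        rng = np.random.default_rng(seed)
        vals = score.to_numpy(dtype=float).reshape(-1, 1)
        centers, assign = kmeans2(vals, 2, seed=rng, minit="++")
        low_cluster = int(np.argmin(centers.ravel()))
        labels = np.where(assign == low_cluster, "low", "high")
    else:
        med = float(score.median())
        if np.ptp(score.to_numpy(dtype=float)) == 0:
            logger.warning("stratify_by_module: degenerate scores, all 'high'")
        labels = np.where(score < med, "low", "high")
    return pd.Series(labels, index=patient_expr.columns, name="group")


def cox_fit(survival: SurvivalTable, covariates: list[str]):
    """Thin adapter around lifelines' Cox proportional-hazards fitter.

    Returns the per-covariate summary (hazard ratios + CIs); convergence or
    separation failures are surfaced verbatim.
    """
    from lifelines import CoxPHFitter

    for c in covariates:
        if c not in survival.data.columns:
            raise ValueError(f"covariate {c!r} not in survival table")
        if survival.data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    df = survival.data[["time", "event", *covariates]].astype(float)
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    summary = fitter.summary
    return summary[["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
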