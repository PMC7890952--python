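"""Synthetic miRNA/ceRNA datasets with planted competing-endogenous structure.

Each planted triad couples two target genes to a shared high-variance miRNA
through negative (repressive) regulation, which induces a positive
target-target correlation — exactly the signal the pair measures are built
to detect.  The interaction table lists the shared driver plus shared decoy
miRNAs so that the hypergeometric enrichment of planted pairs is strong,
while background genes receive sparse random targets.  All randomness flows
from one seed through a single generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from cernanet.io_harmonize import (
    AnnotationTable,
    ExpressionMatrix,
    InteractionTable,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed fully determines it."""

    n_samples: int = 60
    n_mirnas: int = 60
    n_coding: int = 60
    n_noncoding: int = 20
    n_planted_triads: int = 20
    noise_sd: float = 0.3
    repression_strength: float = 0.8
    seed: int = 0
    n_shared_decoys: int = 3    # extra miRNAs shared by a planted pair
    n_private_mirnas: int = 2   # random private miRNAs per planted gene
    background_targets: int = 3  # random miRNAs per background gene

    def validate(self) -> None:
        n_genes = self.n_coding + self.n_noncoding
        if self.n_planted_triads * 2 > n_genes:
            raise ValueError("not enough genes for the requested planted triads")
        if self.n_planted_triads > self.n_mirnas:
            raise ValueError("not enough miRNAs for the requested planted triads")
        if self.n_shared_decoys + 1 + self.n_private_mirnas > self.n_mirnas:
            raise ValueError("miRNA universe too small for shared+private sets")
        for name in ("n_samples", "n_mirnas", "n_coding"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class FixtureData:
    cerna_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    interactions: InteractionTable
    annotation: AnnotationTable
    planted_pairs: list[tuple[str, str]]  # canonical gene1 < gene2

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cerna_expr": outdir / "cerna_expr.tsv",
            "mirna_expr": outdir / "mirna_expr.tsv",
            "interactions": outdir / "interactions.tsv",
            "annotation": outdir / "annotation.tsv",
            "planted_pairs": outdir / "planted_pairs.tsv",
        }
        self.cerna_expr.write(paths["cerna_expr"])
        self.mirna_expr.write(paths["mirna_expr"])
        self.interactions.write(paths["interactions"])
        self.annotation.write(paths["annotation"])
        with open(paths["planted_pairs"], "w", encoding="utf-8") as fh:
            fh.write("gene1\tgene2\n")
            for g1, g2 in self.planted_pairs:
                fh.write(f"{g1}\t{g2}\n")
        return paths


def generate(spec: FixtureSpec) -> FixtureData:
    """Generate the four pipeline inputs plus the planted ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_coding + spec.n_noncoding
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    mirnas = [f"mir{i:03d}" for i in range(spec.n_mirnas)]
    genes = [f"G{i:04d}" for i in range(spec.n_coding)] + [
        f"NC{i:04d}" for i in range(spec.n_noncoding)
    ]
    biotype = ["protein_coding"] * spec.n_coding + ["lincRNA"] * spec.n_noncoding

    # miRNA expression: log2-like values around 6, unit variance
    mirna_mat = rng.normal(6.0, 1.0, size=(spec.n_mirnas, spec.n_samples))

    # background ceRNA expression: FPKM-like positive baseline ~N(8, 1)
    cerna_mat = rng.normal(8.0, 1.0, size=(n_genes, spec.n_samples))

    gene_index = {g: i for i, g in enumerate(genes)}
    mirna_index = {m: i for i, m in enumerate(mirnas)}
    pairs: set[tuple[str, str]] = set()
    planted: list[tuple[str, str]] = []

    # planted triads take genes pairwise off a shuffled deck
    deck = list(genes)
    rng.shuffle(deck)
    for i in range(spec.n_planted_triads):
        g1, g2 = deck[2 * i], deck[2 * i + 1]
        driver = mirnas[i]
        e_m = mirna_mat[mirna_index[driver]]
        b = spec.repression_strength
        for g in (g1, g2):
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
            baseline = rng.normal(13.0, 0.1)
            cerna_mat[gene_index[g]] = baseline - b * e_m + noise
        others = [m for m in mirnas if m != driver]
        decoys = rng.choice(others, size=spec.n_shared_decoys, replace=False)
        shared = [driver, *decoys]
        for g in (g1, g2):
            for m in shared:
                pairs.add((m, g))
            remaining = [m for m in mirnas if m not in set(shared)]
            private = rng.choice(remaining, size=spec.n_private_mirnas, replace=False)
            for m in private:
                pairs.add((m, g))
        planted.append(tuple(sorted((g1, g2))))

    planted_genes = {g for p in planted for g in p}
    for g in genes:
        if g in planted_genes:
            continue
        chosen = rng.choice(mirnas, size=spec.background_targets, replace=False)
        for m in chosen:
            pairs.add((m, g))

    cerna_expr = ExpressionMatrix(
        pd.DataFrame(cerna_mat, index=pd.Index(genes, name="gene"), columns=samples)
    )
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(mirna_mat, index=pd.Index(mirnas, name="mirna"), columns=samples)
    )
    annotation = AnnotationTable(
        pd.DataFrame(
            {"biotype": biotype}, index=pd.Index(genes, name="gene")
        )
    )
    return FixtureData(
        cerna_expr=cerna_expr,
        mirna_expr=mirna_expr,
        interactions=InteractionTable.from_pairs(pairs),
        annotation=annotation,
        planted_pairs=sorted(planted),
    )


def generate_survival(
    n_patients: int,
    module_genes: list[str],
    effect_size: float,
    seed: int = 0,
    horizon: float = 10.0,
    base_hazard: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exponential event times with hazard scaled by the module score.

    Per-patient module score = mean expression of ``module_genes`` (each
    gene ~ N(0,1) across patients); hazard = base * exp(effect_size *
    score); administrative censoring at ``horizon``.  Returns (survival
    table with columns time/event indexed by patient, genes x patients
    expression frame).
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    patients = [f"P{i:03d}" for i in range(n_patients)]
    expr = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(len(module_genes), n_patients)),
        index=pd.Index(list(module_genes), name="gene"),
        columns=patients,
    )
    score = expr.mean(axis=0).to_numpy()
    hazard = base_hazard * np.exp(effect_size * score)
    raw_times = rng.exponential(1.0 / hazard)
    event = (raw_times <= horizon).astype(int)
    time = np.minimum(raw_times, horizon)
    surv = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(patients, name="sample")
    )
    return surv, expr
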