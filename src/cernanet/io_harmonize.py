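"""Delimited-text readers and symbol-set harmonization.

All four pipeline inputs are plain delimited text (tab, comma, semicolon or
space).  Reading validates shape and symbol uniqueness up front so that every
downstream stage can assume clean, finite, uniquely-named data.  Harmonization
computes the three symbol sets that gate all further work: valid ceRNAs,
valid miRNAs and valid samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: delimiter sniffing priority (first match on the header line wins)
_DELIMITERS = [("\t", "tab"), (",", "comma"), (";", "semicolon"), (" ", "space")]

_DELIM_BY_NAME = {
    "auto": None,
    "tab": "\t",
    "comma": ",",
    "semicolon": ";",
    "space": " ",
    "\t": "\t",
    ",": ",",
    ";": ";",
    " ": " ",
}


class InputValidationError(ValueError):
    """Raised when an input file violates the format contract."""


def _resolve_delimiter(path: Path, delimiter: str) -> str:
    """Resolve ``delimiter`` ('auto' sniffs the header line only)."""
    if delimiter not in _DELIM_BY_NAME:
        raise InputValidationError(f"unknown delimiter {delimiter!r}")
    sep = _DELIM_BY_NAME[delimiter]
    if sep is not None:
        return sep
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    for cand, _name in _DELIMITERS:
        if cand in header:
            return cand
    raise InputValidationError(
        f"{path}: could not sniff a delimiter from the header line"
    )


@dataclass(frozen=True)
class ExpressionMatrix:
    """Named genes x named samples grid of finite real expression values."""

    data: pd.DataFrame  # index = gene symbols, columns = sample names

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise InputValidationError(f"duplicate gene symbols: {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise InputValidationError(f"duplicate sample names: {dup_samples}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise InputValidationError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise InputValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)

    def subset(
        self, genes: list[str] | None = None, samples: list[str] | None = None
    ) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            df = df.loc[[g for g in df.index if g in set(genes)]]
        if samples is not None:
            df = df[[s for s in df.columns if s in set(samples)]]
        return ExpressionMatrix(df.copy())

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter)


def read_expression(path: str | Path, delimiter: str = "auto") -> ExpressionMatrix:
    """Read an expression matrix (first row sample names, first column symbols).

    Parameters
    ----------
    path:
        Delimited text file.
    delimiter:
        One of ``auto``, ``tab``, ``comma``, ``semicolon``, ``space`` or the
        literal character.  Auto mode sniffs the header line with priority
        tab > comma > semicolon > space.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise InputValidationError(f"{path}: duplicate gene symbols: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise InputValidationError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise InputValidationError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


@dataclass(frozen=True)
class InteractionTable:
    """Bipartite miRNA -> target mapping (deduplicated pair set)."""

    pairs: frozenset[tuple[str, str]]
    _targets_of: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)
    _mirnas_of: dict[str, frozenset[str]] = field(repr=False, default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs) -> "InteractionTable":
        pairs = frozenset((str(m), str(t)) for m, t in pairs)
        targets: dict[str, set[str]] = {}
        mirnas: dict[str, set[str]] = {}
        for m, t in pairs:
            targets.setdefault(m, set()).add(t)
            mirnas.setdefault(t, set()).add(m)
        return cls(
            pairs,
            {m: frozenset(v) for m, v in targets.items()},
            {t: frozenset(v) for t, v in mirnas.items()},
        )

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self._targets_of)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self._mirnas_of)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self._targets_of.get(mirna, frozenset())

    def mirnas_of(self, target: str) -> frozenset[str]:
        return self._mirnas_of.get(target, frozenset())

    def restrict(self, mirnas: set[str], targets: set[str]) -> "InteractionTable":
        """Keep only pairs whose both endpoints fall in the given sets."""
        kept = [(m, t) for m, t in self.pairs if m in mirnas and t in targets]
        return InteractionTable.from_pairs(kept)

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"mirna{delimiter}target\n")
            for m, t in sorted(self.pairs):
                fh.write(f"{m}{delimiter}{t}\n")


def _read_rows(path: Path, sep: str, n_fields: int):
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < n_fields or any(
                not f.strip() for f in fields[:n_fields]
            ):
                raise InputValidationError(
                    f"{path}: line {lineno}: expected {n_fields} non-empty "
                    f"fields, got {fields!r}"
                )
            rows.append([f.strip() for f in fields])
    return rows


def _drop_header(rows, header):
    """Apply the header flag: True/False or 'auto' (non-overlap heuristic)."""
    if not rows:
        return rows
    if header is True:
        return rows[1:]
    if header is False:
        return rows
    first = set(rows[0])
    body = {f for row in rows[1:] for f in row}
    if rows[1:] and not (first & body):
        return rows[1:]
    return rows


def read_interactions(
    path: str | Path, delimiter: str = "auto", header: bool | str = "auto"
) -> InteractionTable:
    """Read a two-column (miRNA, target) interaction table.

    Duplicate rows are collapsed with a logged count; rows with missing
    fields raise with their line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        sep = _resolve_delimiter(path, delimiter)
    except InputValidationError:
        if path.stat().st_size == 0 or not path.read_text().strip():
            logger.warning("%s: empty interaction file", path)
            return InteractionTable.from_pairs([])
        raise
    rows = _drop_header(_read_rows(path, sep, 2), header)
    if not rows:
        logger.warning("%s: empty interaction table", path)
        return InteractionTable.from_pairs([])
    raw = [(r[0], r[1]) for r in rows]
    table = InteractionTable.from_pairs(raw)
    n_dup = len(raw) - len(table)
    if n_dup:
        logger.info("%s: collapsed %d duplicate interaction rows", path, n_dup)
    return table


@dataclass(frozen=True)
class AnnotationTable:
    """One record per gene symbol with named string attributes (e.g. biotype)."""

    data: pd.DataFrame  # index = gene symbols, columns = attribute names

    def __post_init__(self) -> None:
        dup = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup:
            raise InputValidationError(f"duplicate annotation symbols: {dup}")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    def attribute(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"annotation attribute {name!r} not found")
        return self.data[name]

    def subset(self, genes) -> "AnnotationTable":
        keep = [g for g in self.data.index if g in set(genes)]
        return AnnotationTable(self.data.loc[keep].copy())

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.data.to_csv(path, sep=delimiter, index_label="gene")


def read_annotation(
    path: str | Path, delimiter: str = "auto", header: bool | str = "auto"
) -> AnnotationTable:
    """Read a gene-annotation table (symbol + attribute columns).

    Records missing attribute values are kept with the attribute empty (a
    warning is logged); duplicate symbol rows are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _resolve_delimiter(path, delimiter)
    with open(path, "r", encoding="utf-8") as fh:
        raw = [
            line.rstrip("\n").rstrip("\r").split(sep)
            for line in fh
            if line.strip()
        ]
    if not raw:
        logger.warning("%s: empty annotation table", path)
        return AnnotationTable(pd.DataFrame(index=pd.Index([], name="gene")))
    width = max(len(r) for r in raw)
    rows = []
    for lineno, r in enumerate(raw, start=1):
        if not r[0].strip():
            raise InputValidationError(f"{path}: line {lineno}: missing gene symbol")
        if len(r) < width or any(not f.strip() for f in r[1:]):
            logger.warning(
                "%s: line %d: missing attribute value(s), kept empty", path, lineno
            )
        rows.append([f.strip() for f in r] + [""] * (width - len(r)))
    rows = _drop_header(rows, header)
    if rows and rows is not raw and len(raw) == len(rows) + 1:
        columns = [c if c else f"attr{i}" for i, c in enumerate(raw[0][1:], 1)]
    else:
        columns = [f"attr{i}" for i in range(1, width)]
    df = pd.DataFrame(
        [r[1:] for r in rows],
        index=pd.Index([r[0] for r in rows], name="gene"),
        columns=columns,
    )
    return AnnotationTable(df)


@dataclass(frozen=True)
class HarmonizedSets:
    """The three symbol intersections that gate all downstream work."""

    valid_cernas: frozenset[str]
    valid_mirnas: frozenset[str]
    valid_samples: frozenset[str]


def harmonize(
    cerna_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    interactions: InteractionTable,
    annotation: AnnotationTable,
) -> HarmonizedSets:
    """Intersect symbols across the four inputs.

    valid ceRNAs = ceRNA expression symbols ∩ interaction targets ∩
    annotation symbols; valid miRNAs = miRNA expression symbols ∩
    interaction miRNAs; valid samples = shared sample names.  Any empty
    intersection is a hard error naming the empty set.
    """
    cernas = (
        set(cerna_expr.gene_symbols) & interactions.targets & set(annotation.gene_symbols)
    )
    mirnas = set(mirna_expr.gene_symbols) & interactions.mirnas
    samples = set(cerna_expr.sample_names) & set(mirna_expr.sample_names)
    for name, s in (
        ("valid_cernas", cernas),
        ("valid_mirnas", mirnas),
        ("valid_samples", samples),
    ):
        if not s:
            raise InputValidationError(f"harmonization produced an empty {name} set")
    dropped = len(interactions.targets - cernas)
    if dropped:
        logger.info(
            "harmonize: %d interaction targets absent from expression/annotation "
            "are dropped",
            dropped,
        )
    logger.info(
        "harmonize: %d valid ceRNAs, %d valid miRNAs, %d valid samples",
        len(cernas),
        len(mirnas),
        len(samples),
    )
    return HarmonizedSets(frozenset(cernas), frozenset(mirnas), frozenset(samples))
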