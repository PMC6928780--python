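"""Expression-matrix and gene-set data model, file formats, and count normalization.

Expression matrices are plain TSV (genes in rows, first column gene ids,
header row of sample ids). Gene-set collections use the MSigDB GMT dialect:
one set per line, ``name TAB description TAB gene TAB gene ...``.

Count normalization implements the median-of-ratios size-factor estimator:
for sample *j*,

    s_j = median over genes g of  c_gj / geomean_j'(c_gj')

where only genes with strictly positive counts in every sample contribute
to the median (their geometric mean is well defined and positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MatrixKind",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "estimate_size_factors",
    "normalize",
    "log_transform",
]


class MatrixKind(str, Enum):
    RAW_COUNTS = "raw_counts"
    NORMALIZED = "normalized"
    LOG_NORMALIZED = "log_normalized"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Data violate an invariant of the type being constructed."""


class NormalizationError(ValueError):
    """Size factors cannot be estimated for this matrix."""


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Array of shape ``(len(gene_ids), len(sample_ids))``; finite and
        non-negative.
    kind
        Whether values are raw counts, size-factor normalized counts, or
        log2 of normalized counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: MatrixKind = MatrixKind.RAW_COUNTS

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.kind = MatrixKind(self.kind)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if self.kind in (MatrixKind.RAW_COUNTS, MatrixKind.NORMALIZED) and np.any(
            self.values < 0
        ):
            raise ValidationError(f"{self.kind.value} values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, kind: MatrixKind = MatrixKind.RAW_COUNTS
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            kind=kind,
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (a GMT file in memory).

    ``sets`` maps set name to an ordered list of unique gene ids;
    ``descriptions`` carries the GMT description field per set.
    """

    name: str
    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {set_name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(
                    f"gene set {set_name!r} contains duplicate genes"
                )
        self.descriptions = {
            k: self.descriptions.get(k, "") for k in self.sets
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filter_sizes(
        self, min_size: int, max_size: int, universe: set[str] | None = None
    ) -> "GeneSetCollection":
        """Restrict sets to ``universe`` (if given) and drop sets whose
        restricted size falls outside ``[min_size, max_size]``."""
        kept: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        for name, genes in self.sets.items():
            g = [x for x in genes if universe is None or x in universe]
            if min_size <= len(g) <= max_size:
                kept[name] = g
                desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(name=self.name, sets=kept, descriptions=desc)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples expression TSV.

    The first row is ``<anything> TAB sample ids...``; each subsequent row is
    ``gene_id TAB value...``. Rows whose field count differs from the header
    raise :class:`ParseError` naming the line; duplicate gene or sample ids
    raise :class:`ValidationError`.
    """
    path = Path(path)
    with open(path, "rt") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        n_fields = len(sample_ids) + 1
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    values = np.array(rows, dtype=float).reshape(len(gene_ids), len(sample_ids))
    return ExpressionMatrix(gene_ids, sample_ids, values, MatrixKind.RAW_COUNTS)


def _format_value(x: float) -> str:
    # canonical form: integers print without a decimal point
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the canonical TSV form read_expression_tsv accepts."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for g, row in zip(m.gene_ids, m.values):
            fh.write(g + "\t" + "\t".join(_format_value(x) for x in row) + "\n")


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Parse a GMT gene-set file.

    Each non-empty line is ``set-name TAB description TAB gene [TAB gene...]``.
    Duplicate genes within a line are dropped (first occurrence kept); a line
    with fewer than three fields raises :class:`ParseError`.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields, "
                    f"got {len(fields)}"
                )
            set_name = fields[0]
            if set_name in sets:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set name {set_name!r}"
                )
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[set_name] = genes
            desc[set_name] = fields[1]
    return GeneSetCollection(
        name=name or path.stem, sets=sets, descriptions=desc
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for set_name, genes in collection.sets.items():
            desc = collection.descriptions.get(set_name, "")
            fh.write("\t".join([set_name, desc, *genes]) + "\n")


def estimate_size_factors(m: ExpressionMatrix) -> dict[str, float]:
    """Median-of-ratios size factors (the DESeq2 estimator).

    Genes with a zero count in any sample are excluded from the reference,
    so the per-gene geometric mean is taken over log counts of all-positive
    genes only. The resulting factors are rescaled to unit geometric mean,
    which fixes the overall scale so that re-estimating factors on the
    normalized matrix returns exactly 1 for every sample. Raises
    :class:`NormalizationError` when no gene is positive in every sample.
    """
    if m.kind is not MatrixKind.RAW_COUNTS:
        raise ValidationError("size factors are estimated from raw counts")
    counts = m.values
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        raise NormalizationError(
            "no gene has positive counts in every sample; "
            "size factors are undefined"
        )
    logc = np.log(counts[positive])
    log_geomean = logc.mean(axis=1)  # per-gene reference
    # s_j = median_g of the ratio c_gj / geomean_g, taken in linear space
    ratios = np.exp(logc - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return dict(zip(m.sample_ids, factors.tolist()))


def normalize(m: ExpressionMatrix, size_factors: Mapping[str, float]) -> ExpressionMatrix:
    """Divide each sample's counts by its size factor."""
    missing = [s for s in m.sample_ids if s not in size_factors]
    if missing:
        raise ValidationError(f"missing size factors for samples: {missing}")
    s = np.array([size_factors[j] for j in m.sample_ids], dtype=float)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValidationError("size factors must be positive and finite")
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=m.values / s[None, :],
        kind=MatrixKind.NORMALIZED,
    )


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); pseudocount must be positive."""
    if not (pseudocount > 0 and math.isfinite(pseudocount)):
        raise ValidationError("pseudocount must be a positive finite number")
    return ExpressionMatrix(
        gene_ids=list(m.gene_ids),
        sample_ids=list(m.sample_ids),
        values=np.log2(m.values + pseudocount),
        kind=MatrixKind.LOG_NORMALIZED,
    )
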