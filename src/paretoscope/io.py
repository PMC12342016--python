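"""Readers and validators for expression matrices, gene sets, and sample attributes.

The expression input is a tab-separated table of non-negative TPM values with
one header row and one leading identifier column.  Internally everything is
oriented samples x genes.  No log transform or other preprocessing is applied
anywhere in the pipeline: raw TPM values flow straight into PCA and simplex
fitting.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "AttributeTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_informative_genes",
    "read_gmt",
    "read_attributes",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """A samples x genes matrix of non-negative TPM values.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Non-negative, finite expression values.
    sample_ids, gene_ids : list of str
        Unique identifiers for rows and columns respectively.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(x for x in ids if x in seen or seen.add(x))
                raise ValidationError(f"duplicate {name} identifier: {dup!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set name -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class AttributeTable:
    """Per-sample discrete and continuous attributes; missing values allowed."""

    sample_ids: list[str]
    discrete: dict[str, dict[str, str]] = field(default_factory=dict)
    continuous: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.sample_ids)
        for col, mapping in list(self.discrete.items()) + list(self.continuous.items()):
            extra = set(mapping) - known
            if extra:
                raise ValidationError(
                    f"attribute column {col!r} references unknown samples: {sorted(extra)[:3]}"
                )
        for col, mapping in self.continuous.items():
            for s, v in mapping.items():
                if not np.isfinite(v):
                    raise ValidationError(f"non-finite value in {col!r} for sample {s!r}")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_expression_matrix(
    path: str | Path, orientation: str = "samples_by_genes"
) -> ExpressionMatrix:
    """Read a TSV expression table and orient it samples x genes.

    Parameters
    ----------
    path : str or Path
        TSV (optionally gzipped) with a header row of identifiers and a
        leading label column.
    orientation : {"samples_by_genes", "genes_by_samples"}
        How rows/columns are laid out in the file; the result is always
        samples x genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any() or df.isna().any().any():
        mask = bad | df.isna()
        i = int(np.argmax(mask.values.any(axis=1)))
        j = int(np.argmax(mask.values[i]))
        raise ValidationError(
            f"non-numeric cell at row {mask.index[i]!r}, column {mask.columns[j]!r} "
            f"(value {df.iloc[i, j]!r})"
        )
    # numpy's string parsing is correctly rounded; pandas' fast parser is not
    exact = df.astype(float)
    if orientation == "genes_by_samples":
        exact = exact.T
    return ExpressionMatrix(
        values=exact.to_numpy(dtype=float),
        sample_ids=list(exact.index.astype(str)),
        gene_ids=list(exact.columns.astype(str)),
    )


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    """Write samples x genes TSV (full float precision round-trips)."""
    df = x.to_frame()
    path = Path(path)
    opener = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "wt")
    with opener as fh:
        df.to_csv(fh, sep="\t")  # shortest round-trip float representation


def filter_informative_genes(
    x: ExpressionMatrix, sd_min: float = 1.0, var_min: float = 1.0
) -> ExpressionMatrix:
    """Keep genes whose across-sample standard deviation and variance pass thresholds.

    A gene is informative when its sample standard deviation >= ``sd_min``
    AND its sample variance >= ``var_min`` (n-1 denominator).  At the default
    thresholds of 1 TPM the two conditions coincide, but both are evaluated.
    Gene order is preserved; samples are untouched.
    """
    sd = np.std(x.values, axis=0, ddof=1)
    var = np.var(x.values, axis=0, ddof=1)
    keep = (sd >= sd_min) & (var >= var_min)
    if not keep.any():
        raise ValidationError(
            f"no genes pass sd >= {sd_min} and var >= {var_min}; nothing to analyze"
        )
    return ExpressionMatrix(
        values=x.values[:, keep],
        sample_ids=list(x.sample_ids),
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB gene...)."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(fields)} fields, expected >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            sets[name] = (desc, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_attributes(
    path: str | Path,
    declared_types: dict[str, str] | None = None,
    known_samples: list[str] | None = None,
) -> AttributeTable:
    """Read a sample-attribute TSV with a ``sample_id`` first column.

    Columns are typed by ``declared_types`` ({"col": "discrete"|"continuous"});
    undeclared columns default to continuous when every non-missing value
    parses as a number, discrete otherwise.  Rows for samples absent from
    ``known_samples`` (when given) are dropped with a warning.
    """
    declared_types = declared_types or {}
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    sample_col = df.columns[0]
    samples = list(df[sample_col].astype(str))
    if known_samples is not None:
        known = set(known_samples)
        missing = [s for s in samples if s not in known]
        if missing:
            warnings.warn(
                f"dropping {len(missing)} attribute rows for samples absent from "
                f"the expression matrix (e.g. {missing[:3]})"
            )
            df = df[df[sample_col].astype(str).isin(known)]
            samples = list(df[sample_col].astype(str))
    discrete: dict[str, dict[str, str]] = {}
    continuous: dict[str, dict[str, float]] = {}
    for col in df.columns[1:]:
        raw = df[col]
        present = raw.notna() & (raw.astype(str).str.strip() != "")
        kind = declared_types.get(col)
        if kind is None:
            numeric = pd.to_numeric(raw[present], errors="coerce")
            kind = "continuous" if present.any() and numeric.notna().all() else "discrete"
        if kind == "continuous":
            numeric = pd.to_numeric(raw[present], errors="raise")
            continuous[col] = {
                str(s): float(v) for s, v in zip(df[sample_col][present], numeric)
            }
        elif kind == "discrete":
            discrete[col] = {
                str(s): str(v) for s, v in zip(df[sample_col][present], raw[present])
            }
        else:
            raise ValueError(f"unknown declared type {kind!r} for column {col!r}")
    return AttributeTable(sample_ids=samples, discrete=discrete, continuous=continuous)
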