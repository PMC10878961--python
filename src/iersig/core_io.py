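"""Domain containers and file I/O for expression matrices, gene sets and annotations.

The central container is :class:`ExpressionMatrix`, a dense genes x samples
matrix with a declared layer kind (``counts``, ``normalized`` or
``log_normalized``) and per-sample metadata.  Gene identity is matched
case-sensitively on symbols throughout the package; internal coordinates are
0-based, with MatrixMarket's 1-based indices converted at the boundary.

Also implemented here are the two bulk-preparation steps applied before any
signature analysis: low-expression gene filtering (a gene is kept when its
mean count across samples is at least the number of samples) and
median-of-ratios size-factor normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

LAYER_KINDS = ("counts", "normalized", "log_normalized")


class MatrixError(ValueError):
    """Contract violation on an :class:`ExpressionMatrix` operation."""


class GmtParseError(ValueError):
    """Malformed line in a GMT gene-set file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with layer kind and per-sample metadata.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    values
        ``(n_genes, n_samples)`` float array; finite, and non-negative for
        ``counts`` and ``normalized`` layers.
    layer_kind
        One of ``counts``, ``normalized``, ``log_normalized``.
    sample_meta
        Optional DataFrame of per-sample annotations (batch, age_group,
        condition, ...), indexed by sample id and covering every sample.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    layer_kind: str = "counts"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise MatrixError("duplicate sample ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise MatrixError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise MatrixError("non-finite entries in expression values")
        if self.layer_kind not in LAYER_KINDS:
            raise MatrixError(f"unknown layer_kind {self.layer_kind!r}")
        if self.layer_kind in ("counts", "normalized") and (self.values < 0).any():
            raise MatrixError(f"negative entries in a {self.layer_kind} layer")
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=pd.Index(self.sample_ids))
        else:
            missing = set(self.sample_ids) - set(map(str, self.sample_meta.index))
            if missing:
                raise MatrixError(f"sample_meta missing samples: {sorted(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.sample_ids].copy()

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(
            list(genes), self.sample_ids, self.values[rows], self.layer_kind,
            self.sample_meta,
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in samples]
        return ExpressionMatrix(
            self.gene_ids, list(samples), self.values[:, cols], self.layer_kind,
            self.sample_meta.loc[list(samples)],
        )

    def require_layer(self, *kinds: str) -> None:
        if self.layer_kind not in kinds:
            raise MatrixError(
                f"operation requires layer in {kinds}, got {self.layer_kind!r}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols."""

    name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(map(str, self.genes)))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with a declared universe.

    Genes falling outside the universe are tolerated but recorded per set in
    ``out_of_universe`` so the remainder is always declared.
    """

    sets: list
    universe: frozenset

    def __post_init__(self) -> None:
        self.universe = frozenset(map(str, self.universe))
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names in collection")
        self.out_of_universe = {
            s.name: frozenset(s.genes - self.universe) for s in self.sets
        }

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class GeneAnnotationTable:
    """Mapping gene id -> gene length in base pairs (all positive)."""

    lengths: dict

    def __post_init__(self) -> None:
        self.lengths = {str(g): int(v) for g, v in self.lengths.items()}
        bad = [g for g, v in self.lengths.items() if v <= 0]
        if bad:
            raise ValueError(f"non-positive gene lengths for {bad[:5]}")

    def __getitem__(self, gene: str) -> int:
        return self.lengths[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.lengths


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated genes per line).

    Duplicate genes within a line are deduplicated with a warning; lines with
    fewer than three fields raise :class:`GmtParseError` naming the line.
    The collection universe is the union of all genes in the file.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate genes in set {name!r} "
                    "deduplicated"
                )
            sets.append(GeneSet(name, frozenset(genes)))
    universe = frozenset().union(*(s.genes for s in sets)) if sets else frozenset()
    return GeneSetCollection(sets, universe)


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    """Write gene sets in GMT format (description field written as ``na``)."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# dense / sparse matrices, RNK, annotations
# ---------------------------------------------------------------------------


def read_matrix_tsv(path, layer_kind: str = "counts",
                    sample_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a dense TSV (gene rows, header of sample ids) into a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)),
        df.to_numpy(dtype=float), layer_kind, sample_meta,
    )


def write_matrix_tsv(m: ExpressionMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a per-sample metadata TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mtx(directory, matrix_name: str = "matrix.mtx",
             features_name: str = "features.tsv",
             barcodes_name: str = "barcodes.tsv") -> ExpressionMatrix:
    """Read a MatrixMarket triplet + features/barcodes directory as counts.

    The MTX header's 1-based indices are converted to the internal 0-based
    convention by the reader.  Dimension mismatches between the triplet header
    and the feature/barcode files, and duplicate feature ids, raise
    :class:`MatrixError`.
    """
    directory = Path(directory)
    mat = spio.mmread(directory / matrix_name)
    features = pd.read_csv(directory / features_name, sep="\t", header=None)
    barcodes = pd.read_csv(directory / barcodes_name, sep="\t", header=None)
    gene_ids = [str(g) for g in features.iloc[:, 0]]
    cell_ids = [str(b) for b in barcodes.iloc[:, 0]]
    if mat.shape != (len(gene_ids), len(cell_ids)):
        raise MatrixError(
            f"MTX shape {mat.shape} does not match features x barcodes "
            f"({len(gene_ids)}, {len(cell_ids)})"
        )
    if len(set(gene_ids)) != len(gene_ids):
        raise MatrixError("duplicate gene id in features file")
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
    return ExpressionMatrix(gene_ids, cell_ids, dense, "counts")


def write_mtx(m: ExpressionMatrix, directory, matrix_name: str = "matrix.mtx",
              features_name: str = "features.tsv",
              barcodes_name: str = "barcodes.tsv") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(m.values)
    field = "integer" if np.allclose(m.values, np.round(m.values)) else "real"
    if field == "integer":
        coo = coo.astype(np.int64)
    spio.mmwrite(str(directory / matrix_name), coo, field=field)
    pd.Series(m.gene_ids).to_csv(directory / features_name, sep="\t",
                                 header=False, index=False)
    pd.Series(m.sample_ids).to_csv(directory / barcodes_name, sep="\t",
                                   header=False, index=False)


def read_rnk(path) -> list:
    """Read a two-column gene / score RNK file into (gene, score) pairs."""
    pairs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            pairs.append((fields[0], float(fields[1])))
    return pairs


def write_rnk(pairs: Iterable, path) -> None:
    with open(path, "w") as fh:
        for gene, score in pairs:
            fh.write(f"{gene}\t{score:.10g}\n")


def read_gene_lengths(path) -> GeneAnnotationTable:
    """Read a TSV of gene id and length_bp (header optional)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("gene length table needs >=2 columns")
    first = df.columns[1]
    try:  # headerless file: first row was data
        int(first)
        df = pd.read_csv(path, sep="\t", header=None)
    except (TypeError, ValueError):
        pass
    return GeneAnnotationTable(dict(zip(df.iloc[:, 0].astype(str),
                                        df.iloc[:, 1].astype(int))))


def write_gene_lengths(ann: GeneAnnotationTable, path) -> None:
    pd.DataFrame(
        {"gene_id": list(ann.lengths), "length_bp": list(ann.lengths.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bulk data preparation
# ---------------------------------------------------------------------------


def filter_low_expression(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose mean count across samples is below the sample count.

    A gene is retained exactly when ``mean(counts) >= n_samples`` (i.e. its
    total count is at least ``n_samples ** 2``).  The sample set is unchanged.
    """
    m.require_layer("counts")
    means = m.values.mean(axis=1)
    keep = means >= m.n_samples
    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(kept_genes, m.sample_ids, m.values[keep],
                            "counts", m.sample_meta)


def estimate_size_factors(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, geometric-mean centred.

    Reference genes are those with all-positive counts across samples; each
    sample's factor is the median over reference genes of the count divided by
    the gene's geometric mean, then the factors are divided by their own
    geometric mean so that their logs sum to zero.
    """
    values = np.asarray(values, dtype=float)
    ref = (values > 0).all(axis=1)
    if not ref.any():
        raise MatrixError(
            "no gene has positive counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    logs = np.log(values[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_sf = np.median(logs - log_geomean, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric-mean centring
    return np.exp(log_sf)


def size_factor_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor.

    Size factors are recorded in the returned matrix's ``sample_meta`` under
    ``size_factor``; the returned layer kind is ``normalized``.
    """
    m.require_layer("counts")
    sf = estimate_size_factors(m.values)
    meta = m.sample_meta.copy()
    meta["size_factor"] = sf
    return ExpressionMatrix(m.gene_ids, m.sample_ids, m.values / sf,
                            "normalized", meta)


def log_normalize_cp10k(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p."""
    m.require_layer("counts")
    totals = m.values.sum(axis=0)
    zero = [s for s, t in zip(m.sample_ids, totals) if t == 0]
    if zero:
        raise MatrixError(f"cells with zero total counts: {zero[:10]}")
    scaled = m.values / totals * target_sum
    return ExpressionMatrix(m.gene_ids, m.sample_ids, np.log1p(scaled),
                            "log_normalized", m.sample_meta)
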