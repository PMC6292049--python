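"""Count-matrix container, I/O, normalization and transformations.

The canonical in-memory layout is samples in rows, genes in columns.
Readers accept either orientation and transpose to canonical form.

Normalization follows the upper-quartile scheme used for RNA-seq library
sizes: each sample's scaling factor is the 75th percentile of its
library-size-normalized nonzero counts, factors are rescaled to have
geometric mean one, and counts-per-million are computed against the
resulting effective library sizes. The log and rank-based inverse-normal
(Blom) transforms prepare data for Gaussian-mixture comparators; the NB
mixture itself runs on untransformed normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse
from scipy.stats import norm, rankdata

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "upper_quartile_cpm",
    "mad_top_genes",
    "log_transform",
    "blom_transform",
]


@dataclass
class CountMatrix:
    """N x G matrix of non-negative expression values with identifiers.

    ``allow_negative`` relaxes the non-negativity invariant for matrices
    produced by transforms whose codomain is the real line (log of values
    below one, Blom scores); raw and normalized counts keep it False.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    allow_negative: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, g = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        if not self.gene_ids:
            self.gene_ids = [f"g{j + 1}" for j in range(g)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(s) for s in self.gene_ids]
        if len(self.sample_ids) != n or len(self.gene_ids) != g:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if np.any(~np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"missing or non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if not self.allow_negative and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, allow_negative: bool = False) -> "CountMatrix":
        return cls(
            df.to_numpy(dtype=float),
            list(df.index),
            list(df.columns),
            allow_negative=allow_negative,
        )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _read_delimited(path: Path, sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.argmax(bad.to_numpy())]
            raise ValueError(f"non-numeric entry at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = df.index[np.argmax(converted.isna().to_numpy())]
            raise ValueError(f"missing entry at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def read_counts(
    path,
    format: str | None = None,
    orientation: str = "samples",
    allow_negative: bool = False,
) -> CountMatrix:
    """Load a count matrix from TSV/CSV/MTX into canonical samples x genes form.

    ``orientation`` declares what the file's *rows* are: ``"samples"``
    (canonical) or ``"genes"`` (the matrix is transposed after loading).
    MTX files need sidecar id files ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    with one identifier per line. ``allow_negative`` loads already
    transformed (real-valued) matrices without the count validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in {"samples", "genes"}:
        raise ValueError("orientation must be 'samples' or 'genes'")
    fmt = format or _infer_format(path)
    if fmt in {"tsv", "csv"}:
        df = _read_delimited(path, "\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        mat = spio.mmread(path)
        values = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        rows = path.with_suffix(".rows.txt").read_text().split()
        cols = path.with_suffix(".cols.txt").read_text().split()
        df = pd.DataFrame(np.asarray(values, dtype=float), index=rows, columns=cols)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if orientation == "genes":
        df = df.T
    return CountMatrix.from_frame(df, allow_negative=allow_negative)


def write_counts(X: CountMatrix, path, format: str | None = None) -> None:
    """Write a count matrix (samples in rows); mirrors :func:`read_counts`."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in {"tsv", "csv"}:
        X.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(X.values))
        path.with_suffix(".rows.txt").write_text("\n".join(X.sample_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(X.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def upper_quartile_cpm(X: CountMatrix) -> CountMatrix:
    """Upper-quartile-normalized counts per million.

    Per sample the factor is the 75th percentile of the nonzero counts
    divided by the library size; factors are rescaled to geometric mean
    one; effective library size = total count x factor; the output is
    ``1e6 * x / effective_library_size``. Output rows are invariant to
    rescaling a sample's raw counts by a positive constant.
    """
    values = X.values
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        i = int(np.argmax(totals == 0))
        raise ValueError(f"sample {X.sample_ids[i]!r} has all-zero counts")
    factors = np.empty(X.n_samples)
    for i in range(X.n_samples):
        nonzero = values[i][values[i] > 0]
        factors[i] = np.quantile(nonzero, 0.75) / totals[i]
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff_lib = totals * factors
    out = 1e6 * values / eff_lib[:, None]
    return CountMatrix(out, list(X.sample_ids), list(X.gene_ids))


def mad_top_genes(X: CountMatrix, top_n: int) -> CountMatrix:
    """Keep the ``top_n`` most variable genes by median absolute deviation.

    MAD is computed across samples per gene without the 1.4826 consistency
    constant (the ranking is scale-invariant either way). Genes are
    returned in descending-MAD order with ties broken by original gene
    order; sample order is preserved.
    """
    if top_n > X.n_genes:
        raise ValueError(f"top_n={top_n} exceeds number of genes ({X.n_genes})")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    med = np.median(X.values, axis=0)
    mad = np.median(np.abs(X.values - med), axis=0)
    order = np.argsort(-mad, kind="stable")[:top_n]
    return CountMatrix(
        X.values[:, order],
        list(X.sample_ids),
        [X.gene_ids[j] for j in order],
        allow_negative=X.allow_negative,
    )


def log_transform(X: CountMatrix, pseudocount: float = 1.0) -> CountMatrix:
    """Elementwise natural log of ``x + pseudocount``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(X.values == 0):
        raise ValueError("zero entries require a positive pseudocount")
    return CountMatrix(
        np.log(X.values + pseudocount),
        list(X.sample_ids),
        list(X.gene_ids),
        allow_negative=True,
    )


def blom_transform(X: CountMatrix) -> CountMatrix:
    """Rank-based inverse-normal (Blom) scores, per gene across samples.

    Each gene's values are replaced by ``Phi^{-1}((r - 3/8) / (N + 1/4))``
    where ``r`` is the within-gene rank of the sample (average ranks for
    ties) and ``Phi^{-1}`` the standard normal quantile function.
    """
    if X.n_samples < 2:
        raise ValueError("Blom transform needs >= 2 samples")
    n = X.n_samples
    ranks = np.apply_along_axis(rankdata, 0, X.values)
    scores = norm.ppf((ranks - 0.375) / (n + 0.25))
    return CountMatrix(scores, list(X.sample_ids), list(X.gene_ids), allow_negative=True)
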