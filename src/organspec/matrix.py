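"""Gene x organ count matrix with consistent margins.

``CountMatrix`` is a thin wrapper around a pandas DataFrame of
nonnegative integer counts (genes as rows, organs as columns).  Margins
are always derived from the counts, so they cannot drift out of sync:
``gene_totals[i]`` is the total number of tags (ESTs) observed for gene
i across organs (K_i), ``organ_totals[j]`` the total for organ j (M_j),
and ``grand_total`` the overall total N.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, FormatError

__all__ = ["CountMatrix"]


class CountMatrix:
    """Immutable-by-convention gene x organ integer count matrix.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with organ names as
        columns; values must be nonnegative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[0] == 0 or counts.shape[1] == 0:
            raise EmptyMatrixError("count matrix has no genes or no organs")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int.to_numpy(), values):
                raise FormatError("counts must be integers")
            counts = as_int
        if (counts.to_numpy() < 0).any():
            raise FormatError("counts must be nonnegative")
        if counts.index.has_duplicates:
            raise FormatError("duplicate gene identifiers in count matrix")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate organ names in count matrix")
        self._counts = counts.copy()
        self._counts.index.name = "gene"
        self._counts.columns.name = "organ"

    # -- views -----------------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        return self._counts

    @property
    def genes(self) -> list[str]:
        return list(self._counts.index)

    @property
    def organs(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def gene_totals(self) -> pd.Series:
        """K_i: total tags per gene."""
        return self._counts.sum(axis=1)

    @property
    def organ_totals(self) -> pd.Series:
        """M_j: total tags per organ."""
        return self._counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        """N: total tags in the matrix."""
        return int(self._counts.to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self._counts.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self._counts.equals(other._counts)

    def __repr__(self) -> str:
        g, o = self.shape
        return f"CountMatrix({g} genes x {o} organs, N={self.grand_total})"

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path_or_buf) -> None:
        """Write as TSV: genes as rows, organs as columns, header row.

        Integer cells are written verbatim so a round trip is bit-exact.
        """
        self._counts.to_csv(path_or_buf, sep="\t")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "CountMatrix":
        """Read a matrix written by :meth:`to_tsv`.

        Lines starting with '#' are treated as comments and skipped.
        """
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df)

    def to_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()
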