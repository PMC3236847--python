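"""Per-(gene, organ) organ-specificity statistics.

The model: condition on the margins of the gene x organ count matrix and
treat each of the K_i tags of gene i as an independent Bernoulli trial
that lands in organ j with probability p = M_j / N, where M_j is organ
j's total tag count and N the grand total.  The observed count x_ij is
then Binomial(K_i, p) under the null hypothesis that gene and organ are
independent, and the statistics are:

==========  =========================================================
AE          absolute expression, the observed count x_ij
EE          expected expression K_i * M_j / N under independence
RE          relative expression AE / EE ("adjusted" tag count)
AZ          absolute z-score, binomial standardization of x_ij
RZ          relative z-score, standardization of gene i's RE profile
            across organs (population sd)
p-value     exact binomial upper tail P(X >= x_ij)
==========  =========================================================

RZ is bounded: the largest population z-score within a profile of n
organs is sqrt(n - 1), so an RZ cutoff of 4 is only attainable with at
least 17 organs.  See docs/methods.md for the consequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMatrixError, OrganSpecError
from .matrix import CountMatrix

__all__ = [
    "NullModel",
    "SpecificityScore",
    "binomial_pvalue",
    "expected_expression",
    "relative_expression",
    "absolute_zscore",
    "relative_zscore",
    "normal_tail_pvalue",
    "score_matrix",
    "write_scores",
    "read_scores",
]

SCORE_COLUMNS = ["gene", "organ", "AE", "EE", "RE", "AZ", "RZ", "pvalue"]


@dataclass(frozen=True)
class NullModel:
    """Binomial null for one (gene, organ) cell.

    K: total tags in the gene; M: total tags in the organ; N: total tags
    overall.  The success probability is p = M / N.
    """

    K: int
    M: int
    N: int

    def __post_init__(self):
        if self.N <= 0:
            raise OrganSpecError("null model requires N > 0")
        if not (0 <= self.M <= self.N):
            raise OrganSpecError("null model requires 0 <= M <= N")
        if not (0 <= self.K <= self.N):
            raise OrganSpecError("null model requires 0 <= K <= N")

    @property
    def p(self) -> float:
        return self.M / self.N


@dataclass(frozen=True)
class SpecificityScore:
    """All statistics for one (gene, organ) cell."""

    gene: str
    organ: str
    AE: int
    EE: float
    RE: float
    AZ: float
    RZ: float
    pvalue: float


def binomial_pvalue(x: int, model: NullModel) -> float:
    """Exact upper-tail binomial p-value P(X >= x), X ~ Binomial(K, p).

    This is the probability of observing a count at least as extreme as
    x under the independence null, with enrichment as the alternative.
    """
    if x < 0 or x > model.K:
        raise OrganSpecError(f"x={x} outside [0, K={model.K}]")
    # sf(x-1) = P(X > x-1) = P(X >= x); scipy evaluates the regularized
    # incomplete beta, accurate in the far tail.
    return float(stats.binom.sf(x - 1, model.K, model.p))


def expected_expression(model: NullModel) -> float:
    """EE = K * M / N, the expected count under independence."""
    return model.K * model.M / model.N


def relative_expression(AE: int, EE: float) -> float:
    """RE = AE / EE.

    Convention: an all-zero cell (AE = 0 with EE = 0) has RE = 0; a
    positive count with zero expectation is undefined and raises.
    """
    if EE == 0:
        if AE == 0:
            return 0.0
        raise OrganSpecError("RE undefined: AE > 0 with EE = 0")
    return AE / EE


def absolute_zscore(x: int, model: NullModel) -> float:
    """AZ: standard deviations of the observed count above the binomial
    mean, (x - Kp) / sqrt(Kp(1-p))."""
    p = model.p
    if model.K == 0 or p <= 0.0 or p >= 1.0:
        raise OrganSpecError("AZ requires K > 0 and 0 < p < 1")
    return (x - model.K * p) / np.sqrt(model.K * p * (1.0 - p))


def relative_zscore(re_row) -> np.ndarray:
    """Standardize one gene's RE profile across organs.

    Uses the population standard deviation over the gene's organs.  A
    flat profile (sd = 0) maps to all-zero RZ, so genes expressed evenly
    never look specific.  Requires at least two organs.

    Note the hard bound: max |RZ| <= sqrt(n_organs - 1).
    """
    row = np.asarray(re_row, dtype=float)
    if row.ndim != 1 or row.size < 2:
        raise OrganSpecError("relative z-score requires >= 2 organs")
    sd = row.std()  # population sd (ddof=0)
    if sd == 0.0:
        return np.zeros_like(row)
    return (row - row.mean()) / sd


def normal_tail_pvalue(z: float) -> float:
    """Upper tail 1 - Phi(z) of the standard normal.

    Used to translate z-score cutoffs into p-value cutoffs when pairing
    thresholds (z = 2..6 give 2.28e-2, 1.35e-3, 3.17e-5, 2.87e-7,
    9.87e-10).
    """
    return float(stats.norm.sf(z))


def score_matrix(matrix: CountMatrix) -> pd.DataFrame:
    """Compute all statistics for every (gene, organ) cell.

    Returns a long-format DataFrame with columns
    gene, organ, AE, EE, RE, AZ, RZ, pvalue, one row per cell, in
    matrix order.  Genes with zero total count are skipped with a
    warning (their statistics are undefined).

    Degenerate organs (M = 0, possible only before organ filtering) get
    EE = 0, RE = 0, AZ = 0 and p-value 1 for their necessarily-zero
    cells.
    """
    if matrix.shape[1] < 2:
        raise EmptyMatrixError("scoring requires at least 2 organs")
    X = matrix.counts.to_numpy(dtype=np.int64)
    K = X.sum(axis=1)
    M = X.sum(axis=0)
    N = X.sum()
    if N == 0:
        raise EmptyMatrixError("cannot score an all-zero matrix")

    zero_k = K == 0
    if zero_k.any():
        warnings.warn(
            f"skipping {int(zero_k.sum())} gene(s) with zero total count",
            stacklevel=2,
        )
        X = X[~zero_k]
        K = K[~zero_k]
    genes = np.asarray(matrix.genes, dtype=object)[~zero_k]
    organs = np.asarray(matrix.organs, dtype=object)

    P = M / N  # per-organ success probabilities
    EE = np.outer(K, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        RE = np.where(EE > 0, X / np.where(EE > 0, EE, 1.0), 0.0)
        var = K[:, None] * P * (1.0 - P)
        AZ = np.where(var > 0, (X - EE) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    # exact binomial upper tail, vectorized over cells
    pval = stats.binom.sf(X - 1, K[:, None], P[None, :])
    pval = np.clip(pval, 0.0, 1.0)

    # RZ: row-standardized RE
    mu = RE.mean(axis=1, keepdims=True)
    sd = RE.std(axis=1, keepdims=True)
    RZ = np.where(sd > 0, (RE - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    n_g, n_o = X.shape
    return pd.DataFrame(
        {
            "gene": np.repeat(genes, n_o),
            "organ": np.tile(organs, n_g),
            "AE": X.ravel(),
            "EE": EE.ravel(),
            "RE": RE.ravel(),
            "AZ": AZ.ravel(),
            "RZ": RZ.ravel(),
            "pvalue": pval.ravel(),
        }
    )


def write_scores(scores: pd.DataFrame, path_or_buf) -> None:
    """Write a score table as TSV, fixed column order, >= 6 significant
    digits (scientific notation for the float columns)."""
    out = scores[SCORE_COLUMNS]
    out.to_csv(path_or_buf, sep="\t", index=False, float_format="%.6e")


def read_scores(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    df["gene"] = df["gene"].astype(str)
    df["organ"] = df["organ"].astype(str)
    return df
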