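"""Organ-specific gene (OSG) classification and threshold calibration.

A (gene, organ) cell qualifies when all four criteria hold:

    p-value <= max_pvalue, RZ >= min_RZ, RE >= min_RE, AE >= min_AE

(defaults 1e-5, 4, 4, 10).  A gene qualifying in exactly one organ is an
absolute (single-organ) OSG; in two or more organs, a relative
(multiple-organ) OSG.

Threshold pairing ties each candidate RZ cutoff z to the p-value cutoff
10**floor(log10(1 - Phi(z))): z = 2..6 yield (1e-2, 2), (1e-3, 3),
(1e-5, 4), (1e-7, 5), (1e-10, 6).  Calibration then fixes min_AE and
min_RE from data means and picks the loosest pair on that ladder whose
absolute-OSG purity reaches the target (default 95%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, OrganSpecError
from .specificity import normal_tail_pvalue

__all__ = [
    "ThresholdSet",
    "OSGCall",
    "call_osg",
    "qualifying_cells",
    "pair_thresholds",
    "threshold_table",
    "calibrate_thresholds",
    "overlap_matrix",
    "top_genes_per_organ",
    "write_calls",
    "read_calls",
]


@dataclass(frozen=True)
class ThresholdSet:
    """The four OSG cutoffs."""

    max_pvalue: float = 1e-5
    min_RZ: float = 4.0
    min_RE: float = 4.0
    min_AE: int = 10

    def __post_init__(self):
        if not (0.0 < self.max_pvalue <= 1.0):
            raise OrganSpecError("max_pvalue must be in (0, 1]")
        if self.min_RZ < 0 or self.min_RE < 0 or self.min_AE < 0:
            raise OrganSpecError("min_RZ, min_RE and min_AE must be >= 0")

    def with_pair(self, max_pvalue: float, min_RZ: float) -> "ThresholdSet":
        return replace(self, max_pvalue=max_pvalue, min_RZ=min_RZ)


@dataclass(frozen=True)
class OSGCall:
    """One gene's qualifying organs."""

    gene: str
    organs: frozenset = field(default_factory=frozenset)

    @property
    def cls(self) -> str:
        """'absolute' (one organ), 'relative' (several), or 'none'."""
        n = len(self.organs)
        if n == 0:
            return "none"
        return "absolute" if n == 1 else "relative"


def qualifying_cells(scores: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Rows of the score table satisfying all four criteria."""
    mask = (
        (scores["pvalue"] <= thresholds.max_pvalue)
        & (scores["RZ"] >= thresholds.min_RZ)
        & (scores["RE"] >= thresholds.min_RE)
        & (scores["AE"] >= thresholds.min_AE)
    )
    return scores.loc[mask]


def call_osg(scores: pd.DataFrame, thresholds: ThresholdSet | None = None) -> list[OSGCall]:
    """Classify genes as absolute/relative OSGs.

    Returns one :class:`OSGCall` per gene with at least one qualifying
    organ, in gene order of first appearance.
    """
    thresholds = thresholds or ThresholdSet()
    cells = qualifying_cells(scores, thresholds)
    calls = []
    for gene, grp in cells.groupby("gene", sort=False):
        calls.append(OSGCall(gene=str(gene), organs=frozenset(grp["organ"])))
    return calls


def pair_thresholds(z_values) -> list[tuple[float, float]]:
    """Pair each RZ cutoff z with the p-value cutoff obtained by
    rounding its normal upper-tail probability down to a power of ten."""
    pairs = []
    for z in z_values:
        if not math.isfinite(z):
            raise OrganSpecError(f"non-finite z value: {z}")
        tail = normal_tail_pvalue(z)
        exponent = math.floor(math.log10(tail))
        pairs.append((10.0 ** exponent, float(z)))
    return pairs


def _table_row(scores, max_pvalue, min_RZ, min_RE, min_AE):
    calls = call_osg(
        scores,
        ThresholdSet(max_pvalue=max_pvalue, min_RZ=min_RZ, min_RE=min_RE, min_AE=min_AE),
    )
    n_osg = len(calls)
    n_a = sum(1 for c in calls if c.cls == "absolute")
    n_r = n_osg - n_a
    return {
        "max_pvalue": max_pvalue,
        "min_RZ": min_RZ,
        "n_OSG": n_osg,
        "n_R_OSG": n_r,
        "n_A_OSG": n_a,
        "pct_A_OSG": (n_a / n_osg) if n_osg else 0.0,
    }


def threshold_table(
    scores: pd.DataFrame,
    pairs: list[tuple[float, float]],
    min_RE: float = 4.0,
    min_AE: int = 10,
) -> pd.DataFrame:
    """Per-pair comparison of OSG counts, holding min_RE and min_AE
    fixed: columns n_OSG, n_R_OSG, n_A_OSG, pct_A_OSG (fraction,
    full precision)."""
    rows = [_table_row(scores, p, z, min_RE, min_AE) for p, z in pairs]
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def calibrate_thresholds(
    scores: pd.DataFrame,
    target_pct_absolute: float = 0.95,
    z_values=(2, 3, 4, 5, 6),
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Derive all four cutoffs from the score table.

    1. min_AE: the mean AE over all cells, rounded half-up.
    2. min_RE: the mean RE over cells passing the AE cutoff, rounded
       half-up.
    3. Among the (p-value, RZ) ladder from :func:`pair_thresholds`,
       pick the loosest pair whose resulting absolute-OSG share is at
       least ``target_pct_absolute`` (more OSGs is better, subject to
       purity).

    Returns the calibrated :class:`ThresholdSet` and the per-pair
    comparison table.  Raises :class:`CalibrationError` (carrying the
    table) if no pair reaches the purity target.
    """
    min_AE = _round_half_up(float(scores["AE"].mean()))
    passed = scores.loc[scores["AE"] >= min_AE]
    if passed.empty:
        raise CalibrationError("no cells pass the calibrated AE cutoff")
    min_RE = _round_half_up(float(passed["RE"].mean()))

    pairs = pair_thresholds(z_values)  # ascending z = loosest first
    table = threshold_table(scores, pairs, min_RE=min_RE, min_AE=min_AE)
    ok = table.loc[(table["pct_A_OSG"] >= target_pct_absolute) & (table["n_OSG"] > 0)]
    if ok.empty:
        raise CalibrationError(
            f"no (p-value, RZ) pair reaches {target_pct_absolute:.0%} absolute-OSG purity",
            table=table,
        )
    best = ok.iloc[0]  # loosest qualifying pair identifies the most OSGs
    thresholds = ThresholdSet(
        max_pvalue=float(best["max_pvalue"]),
        min_RZ=float(best["min_RZ"]),
        min_RE=float(min_RE),
        min_AE=int(min_AE),
    )
    return thresholds, table


def overlap_matrix(calls: list[OSGCall], organs: list[str] | None = None) -> pd.DataFrame:
    """Symmetric organ x organ OSG-overlap counts.

    Off-diagonal cell (a, b) counts genes specific to both a and b; the
    diagonal holds each organ's total OSG count.
    """
    if organs is None:
        organs = sorted({o for c in calls for o in c.organs})
    idx = {o: i for i, o in enumerate(organs)}
    mat = np.zeros((len(organs), len(organs)), dtype=np.int64)
    for call in calls:
        members = sorted(o for o in call.organs if o in idx)
        for i, a in enumerate(members):
            mat[idx[a], idx[a]] += 1
            for b in members[i + 1:]:
                mat[idx[a], idx[b]] += 1
                mat[idx[b], idx[a]] += 1
    return pd.DataFrame(mat, index=organs, columns=organs)


def top_genes_per_organ(
    scores: pd.DataFrame,
    calls: list[OSGCall],
    n: int,
) -> list[tuple[str, list[str]]]:
    """The top n qualifying genes of each organ, ranked by RZ
    (descending), ties broken by smaller p-value then gene identifier.

    Organs are returned in sorted order; an organ with fewer than n OSGs
    contributes all of them, one with none contributes an empty list.
    """
    if n < 1:
        raise OrganSpecError("n must be >= 1")
    pairs = {(c.gene, o) for c in calls for o in c.organs}
    organs = sorted({o for c in calls for o in c.organs})
    key = list(zip(scores["gene"].astype(str), scores["organ"].astype(str)))
    member = pd.Series([k in pairs for k in key], index=scores.index)
    qual = scores.loc[member]
    out = []
    for organ in organs:
        sub = qual.loc[qual["organ"] == organ]
        sub = sub.sort_values(
            ["RZ", "pvalue", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        out.append((organ, [str(g) for g in sub["gene"].head(n)]))
    return out


def write_calls(calls: list[OSGCall], scores: pd.DataFrame, path_or_buf) -> None:
    """Write qualifying (gene, organ) cells with class labels and their
    statistics as TSV."""
    pairs = {(c.gene, o): c.cls for c in calls for o in c.organs}
    rows = []
    for _, r in scores.iterrows():
        k = (str(r["gene"]), str(r["organ"]))
        if k in pairs:
            rows.append(
                {
                    "gene": k[0],
                    "organ": k[1],
                    "class": pairs[k],
                    "AE": int(r["AE"]),
                    "EE": r["EE"],
                    "RE": r["RE"],
                    "AZ": r["AZ"],
                    "RZ": r["RZ"],
                    "pvalue": r["pvalue"],
                }
            )
    pd.DataFrame(
        rows,
        columns=["gene", "organ", "class", "AE", "EE", "RE", "AZ", "RZ", "pvalue"],
    ).to_csv(path_or_buf, sep="\t", index=False, float_format="%.6e")


def read_calls(path_or_buf) -> list[OSGCall]:
    """Rebuild OSG calls from a table written by :func:`write_calls`."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    calls = []
    for gene, grp in df.groupby("gene", sort=False):
        calls.append(OSGCall(gene=str(gene), organs=frozenset(grp["organ"].astype(str))))
    return calls
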