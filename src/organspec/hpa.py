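"""Digitize ordinal protein-atlas expression annotations and score them.

Immunohistochemistry resources annotate expression with ordinal labels
rather than numbers.  The fixed digitization maps the eight labels onto
a 0-9 scale:

    None 0, Negative 1, Low 2, Weak 3, Medium 5, Moderate 6, High 7,
    Strong 9

(the gaps encode that e.g. "Strong" is further above "High" than "High"
is above "Moderate").  Digitized scores are treated as pseudo-counts and
fed through the same binomial machinery used for tag counts: the
resulting z-scores are meaningful rankings, while the exact binomial
p-values on pseudo-counts are heuristic and should be read as scores,
not calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import AmbiguityError, VocabularyError
from .matrix import CountMatrix
from .organs import canonical_organ
from .specificity import score_matrix
from .classify import OSGCall

__all__ = [
    "LEVEL_SCORES",
    "OrdinalAnnotation",
    "digitize",
    "read_annotations",
    "score_ordinal_matrix",
    "same_organ_concordance",
    "write_concordance_report",
]

#: label -> 0-9 score, strictly increasing along the ordinal ladder
LEVEL_SCORES: dict[str, int] = {
    "none": 0,
    "negative": 1,
    "low": 2,
    "weak": 3,
    "medium": 5,
    "moderate": 6,
    "high": 7,
    "strong": 9,
}


@dataclass(frozen=True)
class OrdinalAnnotation:
    """One (gene, organ) ordinal expression annotation."""

    gene: str
    organ: str
    level_label: str

    @property
    def score(self) -> int:
        return digitize(self.level_label)


def digitize(label: str) -> int:
    """Map an ordinal expression label (case-insensitive) to its 0-9
    score."""
    try:
        return LEVEL_SCORES[label.strip().lower()]
    except KeyError:
        valid = ", ".join(sorted(LEVEL_SCORES))
        raise VocabularyError(f"unknown expression label {label!r}; valid labels: {valid}")


def read_annotations(path_or_buf) -> list[OrdinalAnnotation]:
    """TSV reader: gene <tab> organ <tab> level_label."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    for need in ("gene", "organ"):
        if need not in cols:
            raise VocabularyError(f"annotation table missing column {need!r}")
    label_col = next((c for c in cols if c not in ("gene", "organ")), None)
    if label_col is None:
        raise VocabularyError("annotation table missing a level-label column")
    return [
        OrdinalAnnotation(str(r["gene"]), canonical_organ(str(r["organ"])), str(r[label_col]))
        for r in df.to_dict("records")
    ]


def score_ordinal_matrix(annotations: list[OrdinalAnnotation]) -> pd.DataFrame:
    """Assemble digitized scores into a gene x organ pseudo-count matrix
    and score it with the binomial specificity statistics.

    Missing (gene, organ) cells default to 0 ("None"); a duplicated
    cell raises :class:`AmbiguityError`.
    """
    seen = set()
    for a in annotations:
        key = (a.gene, a.organ)
        if key in seen:
            raise AmbiguityError(f"duplicate annotation for gene {a.gene!r}, organ {a.organ!r}")
        seen.add(key)
    df = pd.DataFrame(
        [(a.gene, a.organ, a.score) for a in annotations],
        columns=["gene", "organ", "score"],
    )
    wide = df.pivot(index="gene", columns="organ", values="score").fillna(0).astype("int64")
    return score_matrix(CountMatrix(wide))


def same_organ_concordance(
    calls_a: list[OSGCall], calls_b: list[OSGCall]
) -> tuple[int, int, float]:
    """Agreement between two OSG call sets.

    Returns (overlap, concordant, fraction): genes called in both sets,
    those whose organ sets intersect, and concordant / overlap (0 when
    the overlap is empty).
    """
    by_gene_a = {c.gene: c.organs for c in calls_a if c.organs}
    by_gene_b = {c.gene: c.organs for c in calls_b if c.organs}
    shared = sorted(set(by_gene_a) & set(by_gene_b))
    concordant = sum(1 for g in shared if by_gene_a[g] & by_gene_b[g])
    overlap = len(shared)
    return overlap, concordant, (concordant / overlap) if overlap else 0.0


def write_concordance_report(
    calls_a: list[OSGCall], calls_b: list[OSGCall], path_or_buf
) -> None:
    """Per-gene concordance table plus a summary row."""
    by_gene_a = {c.gene: c.organs for c in calls_a if c.organs}
    by_gene_b = {c.gene: c.organs for c in calls_b if c.organs}
    rows = []
    for g in sorted(set(by_gene_a) & set(by_gene_b)):
        rows.append(
            {
                "gene": g,
                "organs_a": ";".join(sorted(by_gene_a[g])),
                "organs_b": ";".join(sorted(by_gene_b[g])),
                "concordant": int(bool(by_gene_a[g] & by_gene_b[g])),
            }
        )
    pd.DataFrame(rows, columns=["gene", "organs_a", "organs_b", "concordant"]).to_csv(
        path_or_buf, sep="\t", index=False
    )
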