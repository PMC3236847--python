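"""Organ-specific gene sets and GSEA-ready exports.

Builds one gene set per organ from OSG calls, plus seeded random
non-specific control sets for enrichment comparisons, and reads/writes
the two standard GSEA input dialects: GMT (one gene set per line:
name, description, then tab-separated genes) and CLS (phenotype labels:
"<n_samples> <n_classes> 1", "# class names", labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OrganSpecError, SanitizationError
from .classify import OSGCall

__all__ = [
    "GeneSet",
    "build_organ_gene_sets",
    "build_random_control_sets",
    "write_gene_sets",
    "read_gene_sets",
    "write_phenotype_labels",
    "read_phenotype_labels",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]
    kind: str = "organ_specific"  # or "random_control"

    def __post_init__(self):
        if not self.genes:
            raise OrganSpecError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise OrganSpecError(f"gene set {self.name!r} has duplicate genes")


def build_organ_gene_sets(calls: list[OSGCall]) -> list[GeneSet]:
    """One set per organ with at least one OSG; a multi-organ (relative)
    OSG appears in every organ it qualifies in."""
    members: dict[str, list[str]] = {}
    for call in calls:
        for organ in call.organs:
            members.setdefault(organ, []).append(call.gene)
    sets = []
    for organ in sorted(members):
        genes = tuple(sorted(set(members[organ])))
        sets.append(
            GeneSet(
                name=organ.replace(" ", "_").upper(),
                description=f"{organ} organ-specific genes",
                genes=genes,
                kind="organ_specific",
            )
        )
    return sets


def build_random_control_sets(
    scores: pd.DataFrame,
    calls: list[OSGCall],
    organ: str,
    k: int = 10,
    size: int | None = None,
    seed: int = 0,
    lower_rank_fraction: float = 0.5,
) -> list[GeneSet]:
    """k random non-specific control sets for one target organ.

    The candidate pool contains genes that are either ranked in the
    bottom ``lower_rank_fraction`` of the organ's RZ ranking, or are
    OSGs of some other organ but not of the target.  Each set draws
    ``size`` genes (default: the target organ's own OSG-set size)
    without replacement; sampling is reproducible under ``seed``.
    """
    target_genes = {c.gene for c in calls if organ in c.organs}
    other_osgs = {c.gene for c in calls if c.organs and organ not in c.organs}

    organ_scores = scores.loc[scores["organ"] == organ]
    if organ_scores.empty:
        raise OrganSpecError(f"organ {organ!r} absent from the score table")
    ranked = organ_scores.sort_values("RZ", ascending=False)["gene"].astype(str).tolist()
    n_lower = int(len(ranked) * lower_rank_fraction)
    lower_ranked = set(ranked[len(ranked) - n_lower:])

    pool = sorted((lower_ranked | other_osgs) - target_genes)
    if size is None:
        if not target_genes:
            raise OrganSpecError(f"no OSGs for organ {organ!r} and no explicit size")
        size = len(target_genes)
    if len(pool) < size:
        raise OrganSpecError(
            f"candidate pool ({len(pool)} genes) smaller than requested set size {size}"
        )
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(k):
        genes = tuple(sorted(rng.choice(pool, size=size, replace=False)))
        sets.append(
            GeneSet(
                name=f"RANDOM_NONSPECIFIC_{i + 1:02d}",
                description=f"random non-specific control set for {organ}",
                genes=genes,
                kind="random_control",
            )
        )
    return sets


def _sanitize(identifier: str) -> str:
    if "\t" in identifier or "\n" in identifier or "\r" in identifier:
        raise SanitizationError(f"identifier contains tab/newline: {identifier!r}")
    return identifier


def write_gene_sets(sets: list[GeneSet], stream) -> None:
    """GMT dialect: name, description, genes — tab-separated, one set
    per line."""
    if not sets:
        raise OrganSpecError("no gene sets to write")
    for s in sets:
        fields = [_sanitize(s.name), _sanitize(s.description)]
        fields.extend(_sanitize(g) for g in s.genes)
        stream.write("\t".join(fields) + "\n")


def read_gene_sets(stream) -> list[GeneSet]:
    sets = []
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise OrganSpecError("GMT line needs name, description and >= 1 gene")
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=tuple(fields[2:])))
    return sets


def write_phenotype_labels(samples: list[tuple[str, str]], stream) -> None:
    """CLS dialect: '<n> <k> 1' header, '# class...' line, label line.

    ``samples`` is a list of (sample id, class label); class order is
    order of first appearance.
    """
    if not samples:
        raise OrganSpecError("no samples to write")
    classes: list[str] = []
    for _sid, label in samples:
        _sanitize(label)
        if label in ("",):
            raise OrganSpecError("empty class label")
        if " " in label:
            raise SanitizationError(f"class label contains a space: {label!r}")
        if label not in classes:
            classes.append(label)
    stream.write(f"{len(samples)} {len(classes)} 1\n")
    stream.write("# " + " ".join(classes) + "\n")
    stream.write(" ".join(label for _sid, label in samples) + "\n")


def read_phenotype_labels(stream) -> tuple[list[str], list[str]]:
    """Returns (class names, per-sample labels)."""
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if len(lines) < 3:
        raise OrganSpecError("CLS file needs three lines")
    n, k, _one = lines[0].split()
    classes = lines[1].lstrip("#").split()
    labels = lines[2].split()
    if len(labels) != int(n) or len(classes) != int(k):
        raise OrganSpecError("CLS header inconsistent with data lines")
    return classes, labels
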