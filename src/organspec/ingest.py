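"""Ingest EST library dumps into a gene x organ count matrix.

The expected input is a tab-delimited dump with one row per EST carrying
the library metadata columns "dbEST ID", "EST name", "GenBank Acc",
"Lib Name", "Tissue type" and "Organ" (header names configurable via
synonyms; '#' lines are comments).  Parsing groups ESTs under their
library; organ assignment resolves each library to a canonical organ
(direct organ field first, then a tissue->organ mapping applied to the
tissue type and library-name tokens), dropping mixed/pooled libraries
and libraries of the wrong organism; aggregation maps GenBank accessions
to gene clusters and counts ESTs per (gene, organ).

Organ-level filtering removes sparsely sampled organs: by default an
organ is excluded when it has fewer than 100 detected genes or fewer
than 300 ESTs, and the margins (including N) are recomputed on the
surviving submatrix so that p = M/N remains a proper probability over
retained organs.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyMatrixError, FormatError
from .matrix import CountMatrix
from .organs import canonical_organ

__all__ = [
    "ESTLibraryRecord",
    "OrganAssignment",
    "AssignMethod",
    "DropReason",
    "ExternalSpecificityRecord",
    "DEFAULT_COLUMNS",
    "parse_library_table",
    "assign_organs",
    "build_count_matrix",
    "filter_organs",
    "filter_external",
    "read_tissue_map",
    "read_gene_map",
    "read_external_records",
    "write_library_dump",
]


@dataclass
class ESTLibraryRecord:
    """One EST library and its EST -> accession assignments."""

    library_id: str
    library_name: str
    tissue_type: str
    organ_label: str
    organism: str
    est_entries: list[tuple[str, str]] = field(default_factory=list)


class AssignMethod(enum.Enum):
    DIRECT_ORGAN_FIELD = "direct_organ_field"
    TISSUE_MAPPING = "tissue_mapping"
    DROPPED = "dropped"


class DropReason(enum.Enum):
    MIXED_POOL = "mixed_pool"
    NO_ORGAN_RESOLVABLE = "no_organ_resolvable"
    WRONG_ORGANISM = "wrong_organism"


@dataclass(frozen=True)
class OrganAssignment:
    library_id: str
    organ: str  # "" iff dropped
    method: AssignMethod
    drop_reason: DropReason | None = None

    def __post_init__(self):
        dropped = self.method is AssignMethod.DROPPED
        if dropped != (self.organ == "") or dropped != (self.drop_reason is not None):
            raise FormatError("inconsistent organ assignment")


@dataclass(frozen=True)
class ExternalSpecificityRecord:
    """A gene/tissue specificity score from an external resource (an SPM
    value in [0, 1]; 1 = perfectly tissue-specific)."""

    gene: str
    tissue_or_organ: str
    score: float
    source: str = ""

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise FormatError(f"SPM score {self.score} outside [0, 1]")


#: logical field -> accepted header spellings (matched case-insensitively)
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "est_id": ("dbEST ID", "dbEST_ID", "est id"),
    "est_name": ("EST name", "EST_name"),
    "accession": ("GenBank Acc", "GenBank_Acc", "accession"),
    "library_name": ("Lib Name", "Lib_Name", "library name"),
    "tissue_type": ("Tissue type", "Tissue_type", "tissue"),
    "organ": ("Organ",),
}
_OPTIONAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "organism": ("Organism",),
    "library_id": ("Lib ID", "Lib_ID", "library id"),
}


def _resolve_columns(header, synonyms, required=True):
    lower = {h.strip().lower(): h for h in header}
    resolved = {}
    for logical, names in synonyms.items():
        for name in names:
            if name.lower() in lower:
                resolved[logical] = lower[name.lower()]
                break
        else:
            if required:
                raise FormatError(
                    f"missing mandatory column {names[0]!r} in library table header"
                )
    return resolved


def parse_library_table(
    path_or_buf,
    columns: dict[str, tuple[str, ...]] | None = None,
    default_organism: str = "Homo sapiens",
) -> list[ESTLibraryRecord]:
    """Parse a per-EST dump into one record per library.

    Rows are grouped by library id (a "Lib ID" column when present,
    otherwise the library name).  Rows for non-target organisms are
    retained verbatim — filtering happens at organ assignment.
    Duplicate (library, EST id) rows trigger a warning and keep the
    first occurrence.
    """
    synonyms = columns or DEFAULT_COLUMNS
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    col = _resolve_columns(df.columns, synonyms)
    opt = _resolve_columns(df.columns, _OPTIONAL_COLUMNS, required=False)

    lib_key = opt.get("library_id", col["library_name"])
    records: dict[str, ESTLibraryRecord] = {}
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for r in df.to_dict("records"):
        lib_id = str(r[lib_key]).strip()
        if not lib_id:
            raise FormatError("empty library identifier in a data row")
        if lib_id not in records:
            records[lib_id] = ESTLibraryRecord(
                library_id=lib_id,
                library_name=str(r[col["library_name"]]),
                tissue_type=str(r[col["tissue_type"]]),
                organ_label=str(r[col["organ"]]),
                organism=str(r[opt["organism"]]) if "organism" in opt else default_organism,
            )
        est_id = str(r[col["est_id"]])
        if (lib_id, est_id) in seen:
            n_dup += 1
            continue
        seen.add((lib_id, est_id))
        records[lib_id].est_entries.append((est_id, str(r[col["accession"]])))
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate (library, EST) row(s) ignored; first occurrences kept",
            stacklevel=2,
        )
    return list(records.values())


def _tokens(text: str):
    """Unigrams and adjacent bigrams of a label, canonicalized, bigrams
    first (so 'bone marrow' wins over 'bone' when both are mapped)."""
    words = re.findall(r"[a-z]+", canonical_organ(text))
    bigrams = [f"{a} {b}" for a, b in zip(words, words[1:])]
    return bigrams + words


def assign_organs(
    records: list[ESTLibraryRecord],
    tissue_map: dict[str, str] | None = None,
    mixed_markers: list[str] | None = None,
    drop_list: set[str] | None = None,
    target_organism: str = "Homo sapiens",
) -> list[OrganAssignment]:
    """Resolve each library to a canonical organ or drop it.

    Order of precedence: wrong organism -> explicit drop list -> mixed
    markers (regex, matched against library name and tissue type) ->
    direct organ field -> tissue_map lookup on the tissue type, then on
    library-name tokens -> dropped (no organ resolvable).
    """
    tissue_map = {canonical_organ(k): canonical_organ(v) for k, v in (tissue_map or {}).items()}
    patterns = [re.compile(p, re.IGNORECASE) for p in (mixed_markers or [])]
    drop_list = drop_list or set()

    def dropped(lib, reason):
        return OrganAssignment(lib, "", AssignMethod.DROPPED, reason)

    out = []
    for rec in records:
        if rec.organism and canonical_organ(rec.organism) != canonical_organ(target_organism):
            out.append(dropped(rec.library_id, DropReason.WRONG_ORGANISM))
            continue
        if rec.library_id in drop_list:
            out.append(dropped(rec.library_id, DropReason.NO_ORGAN_RESOLVABLE))
            continue
        haystack = f"{rec.library_name} {rec.tissue_type}"
        if any(p.search(haystack) for p in patterns):
            out.append(dropped(rec.library_id, DropReason.MIXED_POOL))
            continue
        if rec.organ_label.strip():
            out.append(
                OrganAssignment(
                    rec.library_id,
                    canonical_organ(rec.organ_label),
                    AssignMethod.DIRECT_ORGAN_FIELD,
                )
            )
            continue
        tissue = canonical_organ(rec.tissue_type)
        organ = tissue_map.get(tissue)
        if organ is None:
            for token in _tokens(rec.library_name) + _tokens(rec.tissue_type):
                if token in tissue_map:
                    organ = tissue_map[token]
                    break
        if organ:
            out.append(OrganAssignment(rec.library_id, organ, AssignMethod.TISSUE_MAPPING))
        else:
            out.append(dropped(rec.library_id, DropReason.NO_ORGAN_RESOLVABLE))
    return out


def build_count_matrix(
    records: list[ESTLibraryRecord],
    assignments: list[OrganAssignment],
    gene_map: dict[str, str],
) -> tuple[CountMatrix, int]:
    """Aggregate ESTs into a gene x organ count matrix.

    ESTs in dropped libraries contribute nothing; ESTs whose accession
    is absent from ``gene_map`` are excluded and counted in the returned
    unmapped tally.
    """
    organ_of = {a.library_id: a.organ for a in assignments if a.method is not AssignMethod.DROPPED}
    counts: dict[tuple[str, str], int] = {}
    genes_order: dict[str, None] = {}
    organs_order: dict[str, None] = {}
    n_unmapped = 0
    for rec in records:
        organ = organ_of.get(rec.library_id)
        if organ is None:
            continue
        for _est_id, acc in rec.est_entries:
            gene = gene_map.get(acc)
            if gene is None:
                n_unmapped += 1
                continue
            genes_order.setdefault(gene, None)
            organs_order.setdefault(organ, None)
            counts[(gene, organ)] = counts.get((gene, organ), 0) + 1
    if not counts:
        raise EmptyMatrixError("no EST mapped to any (gene, organ)")
    df = pd.DataFrame(0, index=list(genes_order), columns=list(organs_order), dtype="int64")
    for (gene, organ), n in counts.items():
        df.at[gene, organ] = n
    if n_unmapped:
        warnings.warn(f"{n_unmapped} EST(s) with unmapped accessions excluded", stacklevel=2)
    return CountMatrix(df), n_unmapped


def filter_organs(matrix: CountMatrix, min_genes: int = 100, min_ests: int = 300) -> CountMatrix:
    """Drop sparsely sampled organs and recompute margins.

    An organ is removed when its number of detected genes (nonzero
    cells) is below ``min_genes`` or its EST total is below
    ``min_ests``; both boundaries are inclusive for retention.  N
    shrinks to the surviving submatrix.
    """
    df = matrix.counts
    n_genes = (df > 0).sum(axis=0)
    totals = df.sum(axis=0)
    keep = (n_genes >= min_genes) & (totals >= min_ests)
    if not keep.any():
        raise EmptyMatrixError("all organs removed by filtering")
    return CountMatrix(df.loc[:, keep])


def filter_external(
    records: list[ExternalSpecificityRecord], min_score: float = 0.9
) -> list[ExternalSpecificityRecord]:
    """Keep records with specificity score strictly above ``min_score``
    (the conventional SPM cut for tissue-specific genes)."""
    return [r for r in records if r.score > min_score]


# -- table readers/writers ----------------------------------------------


def read_tissue_map(path_or_buf) -> dict[str, str]:
    """Two-column TSV: tissue <tab> organ."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError("tissue map needs two columns: tissue, organ")
    return {
        canonical_organ(t): canonical_organ(o)
        for t, o in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def read_gene_map(path_or_buf) -> dict[str, str]:
    """Two-column TSV: accession <tab> gene cluster id."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    if df.shape[1] < 2:
        raise FormatError("gene map needs two columns: accession, gene")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_external_records(path_or_buf) -> list[ExternalSpecificityRecord]:
    """TSV: gene <tab> tissue <tab> score [<tab> source]."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    if df.shape[1] < 3:
        raise FormatError("external records need columns: gene, tissue, score[, source]")
    out = []
    for _, r in df.iterrows():
        out.append(
            ExternalSpecificityRecord(
                gene=str(r.iloc[0]),
                tissue_or_organ=str(r.iloc[1]),
                score=float(r.iloc[2]),
                source=str(r.iloc[3]) if df.shape[1] > 3 else "",
            )
        )
    return out


def write_library_dump(records: list[ESTLibraryRecord], path_or_buf) -> None:
    """Write records back to the per-EST dump dialect (inverse of
    :func:`parse_library_table`)."""
    rows = []
    for rec in records:
        for est_id, acc in rec.est_entries:
            rows.append(
                {
                    "dbEST ID": est_id,
                    "EST name": est_id,
                    "GenBank Acc": acc,
                    "Lib ID": rec.library_id,
                    "Lib Name": rec.library_name,
                    "Tissue type": rec.tissue_type,
                    "Organ": rec.organ_label,
                    "Organism": rec.organism,
                }
            )
    pd.DataFrame(rows).to_csv(path_or_buf, sep="\t", index=False)
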