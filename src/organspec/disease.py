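"""Link organ-specific genes to diseases of the same organ.

An organ-specific marker is an organ-specific gene that is additionally
implicated in a disease of that organ.  The linkage is a two-table join:
a gene-disease association table (e.g. a CTD-style export) and a
disease-organ table (e.g. derived from the anatomical branch of a
disease ontology).  Diseases are matched on their identifier (MeSH-style
accession) only; names are informational.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import FormatError
from .organs import canonical_organ
from .classify import OSGCall

__all__ = [
    "GeneDiseaseAssociation",
    "DiseaseOrganAssociation",
    "MarkerRecord",
    "load_association_tables",
    "read_disease_organ_hierarchy",
    "flag_markers",
    "organ_disease_fraction",
    "write_markers",
]


@dataclass(frozen=True)
class GeneDiseaseAssociation:
    gene: str
    disease_id: str
    disease_name: str = ""

    def __post_init__(self):
        if not self.gene or not self.disease_id:
            raise FormatError("gene and disease_id must be nonempty")


@dataclass(frozen=True)
class DiseaseOrganAssociation:
    disease_id: str
    organ: str
    disease_name: str = ""


@dataclass(frozen=True)
class MarkerRecord:
    """An OSG supported by at least one same-organ disease."""

    gene: str
    organ: str
    supporting_diseases: tuple[str, ...]

    def __post_init__(self):
        if not self.supporting_diseases:
            raise FormatError("a marker record needs at least one supporting disease")


def _pick(df, candidates, what):
    lower = {c.lower(): c for c in df.columns}
    for cand in candidates:
        if cand.lower() in lower:
            return lower[cand.lower()]
    raise FormatError(f"missing required column for {what}: tried {candidates}")


def load_association_tables(
    gene_disease,
    disease_organ,
    gd_columns: tuple[str, str, str] = ("gene", "disease_id", "disease_name"),
    do_columns: tuple[str, str, str] = ("disease_id", "organ", "disease_name"),
    organ_vocabulary: set[str] | None = None,
) -> tuple[list[GeneDiseaseAssociation], list[DiseaseOrganAssociation]]:
    """Read and deduplicate the two association tables.

    Both inputs are headered TSV/CSV (tab preferred; comma accepted);
    column names are configurable.  Disease-organ rows whose organ is
    outside ``organ_vocabulary`` (when given) are retained with a
    warning — anatomical vocabularies are richer than the working organ
    list and dropping them would silently lose evidence.
    """
    import warnings

    def _read(buf):
        df = pd.read_csv(buf, sep=None, engine="python", comment="#", dtype=str)
        return df.fillna("")

    gd_df = _read(gene_disease)
    g_col = _pick(gd_df, (gd_columns[0], "GeneSymbol", "GeneID"), "gene")
    d_col = _pick(gd_df, (gd_columns[1], "DiseaseID", "MeSH"), "disease id")
    try:
        n_col = _pick(gd_df, (gd_columns[2], "DiseaseName"), "disease name")
    except FormatError:
        n_col = None
    gd = []
    seen = set()
    for r in gd_df.to_dict("records"):
        key = (str(r[g_col]).strip(), str(r[d_col]).strip())
        if not key[0] or not key[1] or key in seen:
            continue
        seen.add(key)
        gd.append(GeneDiseaseAssociation(key[0], key[1], str(r[n_col]) if n_col else ""))

    do_df = _read(disease_organ)
    di_col = _pick(do_df, (do_columns[0], "DiseaseID", "MSHID"), "disease id")
    o_col = _pick(do_df, (do_columns[1], "Organ"), "organ")
    try:
        dn_col = _pick(do_df, (do_columns[2], "DiseaseName"), "disease name")
    except FormatError:
        dn_col = None
    do, seen = [], set()
    n_outside = 0
    for r in do_df.to_dict("records"):
        disease_id = str(r[di_col]).strip()
        organ = canonical_organ(str(r[o_col]))
        if not disease_id or not organ or (disease_id, organ) in seen:
            continue
        seen.add((disease_id, organ))
        if organ_vocabulary is not None and organ not in organ_vocabulary:
            n_outside += 1
        do.append(DiseaseOrganAssociation(disease_id, organ, str(r[dn_col]) if dn_col else ""))
    if n_outside:
        warnings.warn(
            f"{n_outside} disease-organ association(s) reference organs outside the "
            "working vocabulary; retained",
            stacklevel=2,
        )
    return gd, do


def read_disease_organ_hierarchy(path_or_buf) -> list[DiseaseOrganAssociation]:
    """Read a parent/child disease-hierarchy export with columns
    ChildID, ChildName, ChildMSHID, ParentID, ParentName, ParentMSHID,
    Organ and flatten it to disease-organ associations on the MeSH ids
    (rows without a MeSH id on either side contribute nothing for that
    side)."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str).fillna("")
    for need in ("ChildMSHID", "ParentMSHID", "Organ"):
        _pick(df, (need,), need)
    out, seen = [], set()
    for r in df.to_dict("records"):
        organ = canonical_organ(str(r[_pick(df, ("Organ",), "organ")]))
        for id_col, name_col in (("ChildMSHID", "ChildName"), ("ParentMSHID", "ParentName")):
            disease_id = str(r.get(id_col, "")).strip()
            if not disease_id or (disease_id, organ) in seen:
                continue
            seen.add((disease_id, organ))
            out.append(DiseaseOrganAssociation(disease_id, organ, str(r.get(name_col, ""))))
    return out


def flag_markers(
    calls: list[OSGCall],
    gd: list[GeneDiseaseAssociation],
    do_: list[DiseaseOrganAssociation],
) -> list[MarkerRecord]:
    """Flag every OSG (gene, organ) supported by >= 1 disease that is
    associated both with the gene and with the same organ.

    Markers are a subset of the OSG calls by construction; supporting
    diseases are listed sorted by identifier.
    """
    diseases_of_gene: dict[str, set[str]] = {}
    for a in gd:
        diseases_of_gene.setdefault(a.gene, set()).add(a.disease_id)
    diseases_of_organ: dict[str, set[str]] = {}
    for a in do_:
        diseases_of_organ.setdefault(a.organ, set()).add(a.disease_id)

    markers = []
    for call in sorted(calls, key=lambda c: c.gene):
        gene_dis = diseases_of_gene.get(call.gene)
        if not gene_dis:
            continue
        for organ in sorted(call.organs):
            support = gene_dis & diseases_of_organ.get(organ, set())
            if support:
                markers.append(MarkerRecord(call.gene, organ, tuple(sorted(support))))
    return markers


def organ_disease_fraction(
    calls: list[OSGCall],
    organ: str,
    gd: list[GeneDiseaseAssociation],
    do_: list[DiseaseOrganAssociation],
) -> tuple[int, int, float]:
    """For one organ: (number of OSGs, number with >= 1 same-organ
    disease, their ratio at full precision)."""
    import warnings

    organ = canonical_organ(organ)
    organ_genes = [c.gene for c in calls if organ in c.organs]
    if not organ_genes:
        warnings.warn(f"no OSGs called in organ {organ!r}", stacklevel=2)
        return 0, 0, 0.0
    markers = flag_markers([c for c in calls if organ in c.organs], gd, do_)
    linked = {m.gene for m in markers if m.organ == organ}
    n_osg = len(set(organ_genes))
    n_linked = len(linked)
    return n_osg, n_linked, n_linked / n_osg


def write_markers(markers: list[MarkerRecord], path_or_buf) -> None:
    """Marker table TSV: gene, organ, n_diseases, disease ids
    semicolon-joined."""
    rows = [
        {
            "gene": m.gene,
            "organ": m.organ,
            "n_diseases": len(m.supporting_diseases),
            "disease_ids": ";".join(m.supporting_diseases),
        }
        for m in markers
    ]
    pd.DataFrame(rows, columns=["gene", "organ", "n_diseases", "disease_ids"]).to_csv(
        path_or_buf, sep="\t", index=False
    )
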