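"""Compound/herb/target data model and TSV readers-writers.

A multi-herb formula is represented as a :class:`FormulaLibrary`: a set of
compound records, each carrying the herbs it occurs in, its predicted oral
bioavailability (OB, percent of an oral dose reaching systemic circulation),
and the provenance flags that drive the screening exception rules
(abundance, designated force-inclusion, metabolite parentage).

Compound identity is the explicit ``compound_id`` token; compounds listed
under several herbs are merged by id into one record with the union of herb
memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CompoundRecord",
    "HerbRecord",
    "TargetRecord",
    "FormulaLibrary",
    "LibraryError",
    "load_library",
    "write_library",
    "load_targets",
    "write_targets",
    "overlap_report",
]

COMPOUND_COLUMNS = [
    "compound_id",
    "name",
    "herbs",
    "ob_percent",
    "abundant",
    "parent_id",
    "designated",
    "known_active",
]

TARGET_COLUMNS = [
    "target_id",
    "short_name",
    "gene_name",
    "pdb_id",
    "cvd_related",
    "diseases",
    "pathways",
]

HERB_ROLES = {"emperor", "minister", "adjuvant", "courier", "unassigned"}


class LibraryError(ValueError):
    """Schema or validation failure in a library table."""


@dataclass
class CompoundRecord:
    """One formula ingredient.

    ``ob_percent`` is stored on the 0-100 percent scale ("OB = 78.2%" style),
    never as a fraction.  ``abundant`` marks compounds whose mass fraction in
    an herb is high enough (>= 0.2%) to force inclusion regardless of OB;
    ``designated`` force-includes a compound (a pharmacologically important
    parent, or a known in-vivo metabolite when ``parent_id`` is set).
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob_percent: float
    abundant: bool = False
    parent_id: str | None = None
    designated: bool = False
    known_active: bool = False

    def __post_init__(self) -> None:
        if not self.herbs:
            raise LibraryError(f"compound {self.compound_id!r}: empty herb set")
        if not (0.0 <= self.ob_percent <= 100.0):
            raise LibraryError(
                f"compound {self.compound_id!r}: ob_percent {self.ob_percent} "
                "outside [0, 100]"
            )
        if self.parent_id == self.compound_id:
            raise LibraryError(
                f"compound {self.compound_id!r}: parent_id refers to itself"
            )


@dataclass
class HerbRecord:
    herb_id: str
    name: str
    role_label: str = "unassigned"

    def __post_init__(self) -> None:
        if self.role_label not in HERB_ROLES:
            raise LibraryError(
                f"herb {self.herb_id!r}: unknown role {self.role_label!r}"
            )


@dataclass
class TargetRecord:
    """A protein target with disease and pathway annotations."""

    target_id: str
    short_name: str = ""
    gene_name: str = ""
    pdb_id: str | None = None
    cvd_related: bool = False
    diseases: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()


@dataclass
class FormulaLibrary:
    """Validated compound library with per-herb bookkeeping."""

    compounds: dict[str, CompoundRecord]
    herbs: dict[str, HerbRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.compounds.values():
            if rec.parent_id is not None and rec.parent_id not in self.compounds:
                raise LibraryError(
                    f"compound {rec.compound_id!r}: parent {rec.parent_id!r} "
                    "not in library"
                )

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def per_herb_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.compounds.values():
            for h in rec.herbs:
                counts[h] = counts.get(h, 0) + 1
        return counts

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        return self.compounds[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.compounds


def _split_set(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(tok.strip() for tok in str(cell).split(";") if tok.strip())


def _parse_bool(cell, where: str) -> bool:
    s = str(cell).strip()
    if s in {"0", "0.0", "", "nan", "False", "false"}:
        return False
    if s in {"1", "1.0", "True", "true"}:
        return True
    raise LibraryError(f"{where}: cannot parse boolean {cell!r}")


def _compounds_from_frame(df: pd.DataFrame) -> dict[str, CompoundRecord]:
    missing = [c for c in COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"compounds table missing columns: {missing}")

    records: dict[str, CompoundRecord] = {}
    for i, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        try:
            ob = float(row["ob_percent"])
        except (TypeError, ValueError) as exc:
            raise LibraryError(f"row {i} ({cid!r}): unparseable ob_percent") from exc
        if not (0.0 <= ob <= 100.0):
            raise LibraryError(
                f"row {i} ({cid!r}): ob_percent {ob} outside [0, 100]"
            )
        parent = row["parent_id"]
        parent = None if pd.isna(parent) or str(parent).strip() == "" else str(parent).strip()
        rec = CompoundRecord(
            compound_id=cid,
            name=str(row["name"]),
            herbs=_split_set(row["herbs"]),
            ob_percent=ob,
            abundant=_parse_bool(row["abundant"], f"row {i}"),
            parent_id=parent,
            designated=_parse_bool(row["designated"], f"row {i}"),
            known_active=_parse_bool(row["known_active"], f"row {i}"),
        )
        if cid in records:
            prev = records[cid]
            # same compound listed under several herbs: merge memberships,
            # but any other field disagreement is a duplicate-id error
            same = (
                prev.name == rec.name
                and prev.ob_percent == rec.ob_percent
                and prev.abundant == rec.abundant
                and prev.parent_id == rec.parent_id
                and prev.designated == rec.designated
                and prev.known_active == rec.known_active
            )
            if not same:
                raise LibraryError(f"row {i}: duplicate compound_id {cid!r} "
                                   "with conflicting fields")
            records[cid] = CompoundRecord(
                compound_id=cid,
                name=prev.name,
                herbs=prev.herbs | rec.herbs,
                ob_percent=prev.ob_percent,
                abundant=prev.abundant,
                parent_id=prev.parent_id,
                designated=prev.designated,
                known_active=prev.known_active,
            )
        else:
            records[cid] = rec
    return records


def load_library(path) -> FormulaLibrary:
    """Read a compounds TSV (see COMPOUND_COLUMNS) into a validated library."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[])
    return FormulaLibrary(compounds=_compounds_from_frame(df))


def library_to_frame(library: FormulaLibrary) -> pd.DataFrame:
    rows = []
    for rec in library.compounds.values():
        rows.append(
            {
                "compound_id": rec.compound_id,
                "name": rec.name,
                "herbs": ";".join(sorted(rec.herbs)),
                "ob_percent": repr(rec.ob_percent),
                "abundant": int(rec.abundant),
                "parent_id": rec.parent_id or "",
                "designated": int(rec.designated),
                "known_active": int(rec.known_active),
            }
        )
    return pd.DataFrame(rows, columns=COMPOUND_COLUMNS)


def write_library(library: FormulaLibrary, path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False)


def load_targets(path) -> dict[str, TargetRecord]:
    """Read a targets TSV into a mapping target_id -> TargetRecord."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=[])
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"targets table missing columns: {missing}")
    out: dict[str, TargetRecord] = {}
    for i, row in df.iterrows():
        tid = str(row["target_id"]).strip()
        if tid in out:
            raise LibraryError(f"row {i}: duplicate target_id {tid!r}")
        pdb = str(row["pdb_id"]).strip() or None
        out[tid] = TargetRecord(
            target_id=tid,
            short_name=str(row["short_name"]),
            gene_name=str(row["gene_name"]),
            pdb_id=pdb,
            cvd_related=_parse_bool(row["cvd_related"], f"row {i}"),
            diseases=_split_set(row["diseases"]),
            pathways=_split_set(row["pathways"]),
        )
    return out


def write_targets(targets: dict[str, TargetRecord], path) -> None:
    rows = []
    for rec in targets.values():
        rows.append(
            {
                "target_id": rec.target_id,
                "short_name": rec.short_name,
                "gene_name": rec.gene_name,
                "pdb_id": rec.pdb_id or "",
                "cvd_related": int(rec.cvd_related),
                "diseases": ";".join(sorted(rec.diseases)),
                "pathways": ";".join(sorted(rec.pathways)),
            }
        )
    pd.DataFrame(rows, columns=TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def overlap_report(library: FormulaLibrary) -> dict[frozenset, int]:
    """Count compounds per herb-membership subset.

    The subset counts partition the library: their sum equals the number of
    unique compounds.
    """
    counts: dict[frozenset, int] = {}
    for rec in library.compounds.values():
        counts[rec.herbs] = counts.get(rec.herbs, 0) + 1
    return counts
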