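"""Building-block catalog data model, I/O and physicochemical properties.

A catalog is an ordered collection of building blocks (BBs) of one class,
as exported by a vendor in SDF or CSV form.  On ingest every structure is
canonicalised; records that fail to parse, are multi-fragment (salts), or
lack the class's defining functional group are excluded and recorded in the
catalog's rejection log rather than silently dropped.

Physicochemical properties (PCPs) follow the conventions common in
DEL/fragment work:

* ``mw``    — average-atomic-weight molecular weight, Da;
* ``clogp`` — Crippen atom-contribution logP estimate (one open estimator
  is used uniformly for BB filtering and product properties);
* ``tpsa``  — topological polar surface area, Å²;
* ``hbd``   — number of N/O heavy atoms bearing at least one hydrogen
  (atom-based donor count: an -NH2 is one donor);
* ``hba``   — Lipinski acceptor count, i.e. the number of N plus O atoms.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .errors import CatalogFormatError, CatalogIOError, SchemaError
from .patterns import BBClass, has_defining_group

__all__ = [
    "BBClass",
    "PCPSet",
    "BuildingBlock",
    "Catalog",
    "Rejection",
    "compute_pcp",
    "canonical_smiles",
    "read_catalog_sdf",
    "read_catalog_csv",
    "write_catalog_csv",
]

PCP_COLUMNS = ("mw", "clogp", "tpsa", "hbd", "hba")


@dataclass(frozen=True)
class PCPSet:
    """Physicochemical property vector for one structure."""

    mw: float
    clogp: float
    tpsa: float
    hbd: int
    hba: int

    def passes_ro5(self) -> bool:
        """Lipinski rule-of-5: MW < 500, clogP < 5, HBD <= 5, HBA <= 10."""
        return self.mw < 500 and self.clogp < 5 and self.hbd <= 5 and self.hba <= 10

    def passes_ro3(self) -> bool:
        """Rule-of-3: MW < 300, clogP <= 3, HBD <= 3, HBA <= 3."""
        return self.mw < 300 and self.clogp <= 3 and self.hbd <= 3 and self.hba <= 3


@dataclass(frozen=True)
class BuildingBlock:
    """One catalog entry: structure, class, cost and properties.

    ``cost`` is USD per 250 mg pack; ``None`` means the vendor quoted no
    price.  ``smiles`` is always the RDKit canonical form.
    """

    id: str
    smiles: str
    bb_class: BBClass
    cost: float | None = None
    pcp: PCPSet | None = None

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    def with_pcp(self) -> "BuildingBlock":
        if self.pcp is not None:
            return self
        return replace(self, pcp=compute_pcp(self.smiles))


@dataclass(frozen=True)
class Rejection:
    """One excluded ingest record: identifier (or record index) and reason."""

    id: str
    reason: str


@dataclass
class Catalog:
    """An ordered, uniquely-identified collection of BBs of one class."""

    bb_class: BBClass
    members: list[BuildingBlock] = field(default_factory=list)
    provenance: str = ""
    rejected: list[Rejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [bb.id for bb in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate ids in catalog: {dupes}")
        for bb in self.members:
            if bb.bb_class is not self.bb_class:
                raise SchemaError(
                    f"member {bb.id} has class {bb.bb_class}, catalog is {self.bb_class}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def ids(self) -> list[str]:
        return [bb.id for bb in self.members]

    def smiles(self) -> list[str]:
        return [bb.smiles for bb in self.members]

    def get(self, bb_id: str) -> BuildingBlock:
        for bb in self.members:
            if bb.id == bb_id:
                return bb
        raise KeyError(bb_id)

    def with_pcp(self) -> "Catalog":
        """Return a copy whose members all carry computed PCPs."""
        return Catalog(
            self.bb_class,
            [bb.with_pcp() for bb in self.members],
            self.provenance,
            list(self.rejected),
        )

    def subset(self, keep: Iterable[str], provenance: str | None = None) -> "Catalog":
        keep_set = set(keep)
        return Catalog(
            self.bb_class,
            [bb for bb in self.members if bb.id in keep_set],
            provenance if provenance is not None else self.provenance,
        )


def compute_pcp(smiles: str) -> PCPSet:
    """Compute the PCP vector for a SMILES string.

    Raises ``ValueError`` naming the input when the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return compute_pcp_mol(mol)


def compute_pcp_mol(mol: Chem.Mol) -> PCPSet:
    hbd = 0
    hba = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() in (7, 8):
            hba += 1
            if atom.GetTotalNumHs() > 0:
                hbd += 1
    return PCPSet(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        tpsa=Descriptors.TPSA(mol),
        hbd=hbd,
        hba=hba,
    )


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _ingest_mol(
    mol: Chem.Mol | None,
    record_id: str,
    bb_class: BBClass,
    cost: float | None,
    pcp: PCPSet | None,
    rejected: list[Rejection],
) -> BuildingBlock | None:
    """Shared validation for SDF/CSV ingest; returns None on rejection."""
    if mol is None:
        rejected.append(Rejection(record_id, "unparsable_structure"))
        return None
    if len(Chem.GetMolFrags(mol)) != 1:
        rejected.append(Rejection(record_id, "multi_fragment"))
        return None
    if not has_defining_group(mol, bb_class):
        rejected.append(Rejection(record_id, "missing_defining_group"))
        return None
    bb = BuildingBlock(
        id=record_id,
        smiles=Chem.MolToSmiles(mol),
        bb_class=bb_class,
        cost=cost,
        pcp=pcp,
    )
    return bb.with_pcp() if pcp is None else bb


def _parse_cost(raw: str | None) -> float | None:
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    return value if value >= 0 and math.isfinite(value) else None


def read_catalog_sdf(
    path: str | Path,
    bb_class: BBClass,
    field_map: Mapping[str, str],
) -> Catalog:
    """Read an SDF catalog.

    ``field_map`` maps the logical fields ``id`` and ``cost`` to SDF data
    field names (vendor exports differ; no default is assumed).  Records
    failing structure parsing or lacking the class's defining group are
    excluded and listed in the returned catalog's ``rejected`` log.
    """
    path = Path(path)
    if not path.is_file():
        raise CatalogIOError(f"no such file: {path}")
    id_field = field_map.get("id")
    cost_field = field_map.get("cost")
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    except OSError as exc:
        raise CatalogFormatError(f"unreadable SDF {path}: {exc}") from exc
    members: list[BuildingBlock] = []
    rejected: list[Rejection] = []
    n_records = 0
    for idx, mol in enumerate(supplier):
        n_records += 1
        record_id = f"record_{idx}"
        cost = None
        if mol is not None:
            if id_field and mol.HasProp(id_field):
                record_id = mol.GetProp(id_field)
            if cost_field and mol.HasProp(cost_field):
                cost = _parse_cost(mol.GetProp(cost_field))
        bb = _ingest_mol(mol, record_id, bb_class, cost, None, rejected)
        if bb is not None:
            members.append(bb)
    if n_records == 0 or not members:
        raise CatalogFormatError(f"no parsable records in {path}")
    return Catalog(bb_class, members, provenance=str(path), rejected=rejected)


def read_catalog_csv(
    path: str | Path,
    bb_class: BBClass,
    column_map: Mapping[str, str] | None = None,
) -> Catalog:
    """Read a CSV catalog with header columns.

    Default column names are ``smiles``, ``id``, ``cost`` and the PCP
    columns ``mw, clogp, tpsa, hbd, hba``; ``column_map`` renames the
    logical fields to whatever the file uses.  PCP columns, when present,
    are trusted as given; otherwise PCPs are computed from the structure.
    """
    path = Path(path)
    if not path.is_file():
        raise CatalogIOError(f"no such file: {path}")
    colmap = {"smiles": "smiles", "id": "id", "cost": "cost"}
    colmap.update({k: v for k, v in (column_map or {}).items()})

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for mandatory in ("smiles", "id"):
            if colmap[mandatory] not in header:
                raise SchemaError(
                    f"missing mandatory column {colmap[mandatory]!r} in {path}"
                )
        has_cost = colmap["cost"] in header
        has_pcp = all(c in header for c in PCP_COLUMNS)
        members: list[BuildingBlock] = []
        rejected: list[Rejection] = []
        seen: set[str] = set()
        for row in reader:
            record_id = row[colmap["id"]]
            if record_id in seen:
                raise SchemaError(f"duplicate id {record_id!r} in {path}")
            seen.add(record_id)
            cost = _parse_cost(row.get(colmap["cost"])) if has_cost else None
            pcp = None
            if has_pcp:
                try:
                    pcp = PCPSet(
                        mw=float(row["mw"]),
                        clogp=float(row["clogp"]),
                        tpsa=float(row["tpsa"]),
                        hbd=int(row["hbd"]),
                        hba=int(row["hba"]),
                    )
                except (TypeError, ValueError):
                    pcp = None
            mol = Chem.MolFromSmiles(row[colmap["smiles"]])
            bb = _ingest_mol(mol, record_id, bb_class, cost, pcp, rejected)
            if bb is not None:
                members.append(bb)
    if not members:
        raise CatalogFormatError(f"no parsable records in {path}")
    return Catalog(bb_class, members, provenance=str(path), rejected=rejected)


def write_catalog_csv(
    catalog: Catalog,
    path: str | Path,
    include_truncate: Mapping[str, str] | None = None,
) -> Path:
    """Write a catalog as CSV, round-trip safe for id/smiles/cost.

    ``include_truncate`` optionally maps BB id -> truncate SMILES, adding a
    ``truncate_smiles`` column.
    """
    if len(catalog) == 0:
        raise ValueError("refusing to write an empty catalog")
    path = Path(path)
    fields = ["id", "smiles", "cost", *PCP_COLUMNS]
    if include_truncate is not None:
        fields.append("truncate_smiles")
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            for bb in catalog.with_pcp():
                row = {
                    "id": bb.id,
                    "smiles": bb.smiles,
                    "cost": "" if bb.cost is None else repr(bb.cost),
                    "mw": repr(bb.pcp.mw),
                    "clogp": repr(bb.pcp.clogp),
                    "tpsa": repr(bb.pcp.tpsa),
                    "hbd": bb.pcp.hbd,
                    "hba": bb.pcp.hba,
                }
                if include_truncate is not None:
                    row["truncate_smiles"] = include_truncate.get(bb.id, "")
                writer.writerow(row)
    except OSError as exc:
        raise CatalogIOError(f"cannot write {path}: {exc}") from exc
    return path
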