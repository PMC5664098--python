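"""NCBI taxdump parsing, lineage reconstruction and group-membership queries.

The NCBI taxonomy is distributed as flat "dump" files (``nodes.dmp``,
``names.dmp``, ``merged.dmp``) whose fields are separated by the literal
delimiter ``\\t|\\t`` and whose records end with ``\\t|``.  Protein
identifiers are tied to taxa through either the legacy two-column
``gi_taxid_prot.dmp`` mapping (GI number -> TaxID) or the newer
``prot.accession2taxid`` four-column TSV (accession, accession.version,
taxid, gi).  This module loads those files into plain in-memory maps and
answers the two questions the Alien Index pipeline needs:

* what is the root-to-leaf lineage of a TaxID, and
* does a TaxID fall inside a given taxonomic group?

All loaders transparently accept gzip-compressed files.  Taxa that cannot
be resolved (deleted GIs, accessions absent from the mapping, TaxIDs
missing from ``nodes.dmp``) are reported as *unassigned* rather than
raised, because downstream reporting renders them as a distinct category.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping

logger = logging.getLogger(__name__)

ROOT_TAXID = 1

#: Canonical TaxIDs of the NCBI root-level branches used for hit categorization.
BASAL_TAXIDS: Mapping[int, str] = {
    2157: "Archaea",
    2: "Bacteria",
    2759: "Eukaryota",
    12884: "Viroids",
    10239: "Viruses",
}

#: Root-level branches whose hits carry no usable taxonomic signal.
IGNORED_BASAL_PREFIXES = ("other", "unclassified")

BASAL_NAMES = frozenset(BASAL_TAXIDS.values())


class TaxdumpParseError(ValueError):
    """A taxdump-style or mapping file did not follow its dialect."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class Lineage:
    """Root-to-leaf path through the taxonomy for one TaxID."""

    taxids: list[int]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.taxids) != len(self.names):
            raise ValueError("taxids and names must be parallel lists")

    @property
    def leaf(self) -> int:
        return self.taxids[-1]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.taxids

    def __str__(self) -> str:
        return "; ".join(self.names)


@dataclass
class TaxonomyDB:
    """Parent/name/rank maps plus the protein-identifier -> TaxID mapping.

    ``parent_of`` must be acyclic apart from the self-parented root
    (``parent_of[1] == 1``, as in the NCBI dumps).  ``merged_into`` is
    consulted before any parent traversal, so queries through a retired
    TaxID behave exactly like queries through its replacement.
    """

    parent_of: dict[int, int] = field(default_factory=dict)
    name_of: dict[int, str] = field(default_factory=dict)
    rank_of: dict[int, str] = field(default_factory=dict)
    merged_into: dict[int, int] = field(default_factory=dict)
    protein_to_taxid: dict[str, int] = field(default_factory=dict)
    root_taxid: int = ROOT_TAXID

    def resolve_merged(self, taxid: int) -> int:
        """Follow merge records (old -> current) before any other lookup."""
        seen = set()
        while taxid in self.merged_into and taxid not in seen:
            seen.add(taxid)
            taxid = self.merged_into[taxid]
        return taxid

    def name(self, taxid: int) -> str:
        return self.name_of.get(taxid, f"unknown taxon {taxid}")

    def lineage(self, taxid: int) -> Lineage | None:
        """Root-to-leaf lineage, or None when the TaxID is unassignable.

        Traversal is bounded by the node count so that a corrupt
        parent map cannot loop forever.
        """
        taxid = self.resolve_merged(taxid)
        if taxid not in self.parent_of:
            return None
        path = [taxid]
        steps = 0
        limit = len(self.parent_of)
        while path[-1] != self.root_taxid:
            parent = self.parent_of.get(path[-1])
            if parent is None:
                return None
            steps += 1
            if steps > limit:
                raise TaxdumpParseError(
                    "<nodes>", 0, f"cycle detected while tracing lineage of {taxid}"
                )
            if parent == path[-1]:  # self-parented non-root node: treat as local root
                break
            path.append(parent)
        path.reverse()
        return Lineage(taxids=path, names=[self.name(t) for t in path])

    def is_within(self, taxid: int, group: int) -> bool:
        """True iff ``group`` lies on the lineage of ``taxid``.

        A taxon is inside its own group.  Unknown TaxIDs are never inside
        any group (callers detect unassignability via ``lineage`` is None).
        """
        group = self.resolve_merged(group)
        lin = self.lineage(taxid)
        return lin is not None and group in lin

    def resolve_subject_taxid(self, subject_id: str) -> int | None:
        """Map a raw BLAST subject field to a TaxID, or None if unassigned.

        Composite identifiers like ``gi|12345|ref|XP_9.1|`` are split on
        ``|``: a GI number, when present, is tried first, then each
        accession-like token (versioned, then unversioned).  A bare token
        is looked up as an accession directly.
        """
        candidates: list[str] = []
        if "|" in subject_id:
            parts = [p for p in subject_id.split("|") if p]
            for i, part in enumerate(parts):
                if part == "gi" and i + 1 < len(parts) and parts[i + 1].isdigit():
                    candidates.append(parts[i + 1])
            tags = {"gi", "gb", "ref", "emb", "dbj", "sp", "tr", "pdb", "prf", "pir"}
            for part in parts:
                if part not in tags and not part.isdigit():
                    candidates.append(part)
        else:
            candidates.append(subject_id)
        for key in candidates:
            taxid = self.protein_to_taxid.get(key)
            if taxid is None and "." in key:
                taxid = self.protein_to_taxid.get(key.rsplit(".", 1)[0])
            if taxid is not None:
                return taxid
        return None

    def basal_category(self, taxid: int) -> str | None:
        """Root-level branch of a TaxID: one of Archaea/Bacteria/Eukaryota/
        Viroids/Viruses, ``"other"``/``"unclassified"``, or None."""
        lin = self.lineage(taxid)
        if lin is None:
            return None
        for t, name in zip(lin.taxids, lin.names):
            if t in BASAL_TAXIDS:
                return BASAL_TAXIDS[t]
            if name in BASAL_NAMES:
                return name
            low = name.lower()
            for prefix in IGNORED_BASAL_PREFIXES:
                if low.startswith(prefix):
                    return prefix
        return None


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _iter_dmp_records(path: str | Path, n_fields: int) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, fields) from a taxdump-dialect file.

    Records end with ``\\t|``; fields are separated by ``\\t|\\t``.  A record
    with the wrong field count is a parse error naming file and line.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            if len(fields) < n_fields:
                raise TaxdumpParseError(
                    path, lineno, f"expected >= {n_fields} fields, got {len(fields)}"
                )
            yield lineno, fields


def load_taxdump(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyDB:
    """Load ``nodes.dmp``/``names.dmp`` (and optionally ``merged.dmp``).

    Only names of class ``scientific name`` populate the name map; other
    classes (synonyms, common names, ...) are skipped.  A node without a
    scientific name falls back to ``"unknown taxon <taxid>"`` at query
    time rather than failing.
    """
    db = TaxonomyDB()
    for lineno, fields in _iter_dmp_records(nodes_path, 2):
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxdumpParseError(nodes_path, lineno, f"non-integer TaxID: {exc}") from None
        db.parent_of[taxid] = parent
        if len(fields) >= 3:
            db.rank_of[taxid] = fields[2]
    for lineno, fields in _iter_dmp_records(names_path, 4):
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise TaxdumpParseError(names_path, lineno, f"non-integer TaxID: {exc}") from None
        name_txt, name_class = fields[1], fields[3]
        if name_class == "scientific name":
            db.name_of[taxid] = name_txt
    if merged_path is not None:
        for lineno, fields in _iter_dmp_records(merged_path, 2):
            try:
                old, new = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise TaxdumpParseError(merged_path, lineno, f"non-integer TaxID: {exc}") from None
            db.merged_into[old] = new
    return db


def load_protein_mapping(path: str | Path, dialect: str) -> dict[str, int]:
    """Load a protein-identifier -> TaxID mapping.

    dialect ``"gi"``: two whitespace-separated columns (GI, TaxID), no
    header.  dialect ``"accession"``: four tab-separated columns with a
    header row (accession, accession.version, taxid, gi); both the
    versioned and unversioned accession are keyed.  On duplicate keys the
    first occurrence wins and a warning is logged.
    """
    if dialect not in ("gi", "accession"):
        raise ValueError(f"unknown mapping dialect: {dialect!r}")
    mapping: dict[str, int] = {}

    def put(key: str, taxid: int, lineno: int) -> None:
        if key in mapping:
            if mapping[key] != taxid:
                logger.warning(
                    "%s:%d: duplicate mapping for %s (keeping first: %d)",
                    path, lineno, key, mapping[key],
                )
            return
        mapping[key] = taxid

    with _open_text(path) as fh:
        if dialect == "gi":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                cols = line.split()
                if len(cols) < 2:
                    raise TaxdumpParseError(path, lineno, "expected 2 columns")
                try:
                    taxid = int(cols[1])
                except ValueError:
                    raise TaxdumpParseError(
                        path, lineno, f"non-integer TaxID: {cols[1]!r}"
                    ) from None
                put(cols[0], taxid, lineno)
        else:
            header_seen = False
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                if not header_seen:
                    header_seen = True  # header row is mandatory in this dialect
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 3:
                    raise TaxdumpParseError(path, lineno, "expected >= 3 tab-separated columns")
                try:
                    taxid = int(cols[2])
                except ValueError:
                    raise TaxdumpParseError(
                        path, lineno, f"non-integer TaxID: {cols[2]!r}"
                    ) from None
                accession, version = cols[0], cols[1]
                if version:
                    put(version, taxid, lineno)
                if accession:
                    put(accession, taxid, lineno)
    return mapping


# Thin functional wrappers mirroring the method surface, for callers that
# prefer free functions.

def lineage(db: TaxonomyDB, taxid: int) -> Lineage | None:
    return db.lineage(taxid)


def is_within(db: TaxonomyDB, taxid: int, group: int) -> bool:
    return db.is_within(taxid, group)


def resolve_subject_taxid(db: TaxonomyDB, subject_id: str) -> int | None:
    return db.resolve_subject_taxid(subject_id)
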