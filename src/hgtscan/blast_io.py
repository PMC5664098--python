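"""Streaming parser for BLAST+ tabular output with comment lines (-outfmt 7).

Only the standard 12-column layout is accepted (qseqid, sseqid, pident,
length, mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore);
a ``# Fields:`` comment announcing a different layout is an error, because
the Alien Index computation depends on bit-exact column semantics.

The parser yields one :class:`QueryBlock` per query, including queries
whose block declares ``# 0 hits found`` — those are the only way a query
with no significant hit can be detected and reported.  Peak memory is
proportional to the largest single query block, never to the file size.
Plain, gzip-compressed and single-member zip inputs are all accepted.
"""

from __future__ import annotations

import gzip
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

GZIP_MAGIC = b"\x1f\x8b"
ZIP_MAGIC = b"PK\x03\x04"

#: Canonical -outfmt 7 field descriptors, with the spellings BLAST+ emits.
_STANDARD_FIELDS = [
    ("query id", "query acc.", "query acc.ver"),
    ("subject id", "subject acc.", "subject acc.ver"),
    ("% identity",),
    ("alignment length",),
    ("mismatches",),
    ("gap opens",),
    ("q. start",),
    ("q. end",),
    ("s. start",),
    ("s. end",),
    ("evalue",),
    ("bit score",),
]


class BlastParseError(ValueError):
    """The input did not follow the -outfmt 7 dialect."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass
class BlastHit:
    """One data line of a tabular BLAST result."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bit_score: float
    raw_line: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity outside [0,100]: {self.percent_identity}")


@dataclass
class QueryBlock:
    """All hits of one query, in file order."""

    query_id: str
    hits: list[BlastHit] = field(default_factory=list)
    declared_hit_count: int | None = None


def open_maybe_compressed(path: str | Path) -> IO[str]:
    """Open plain, .gz or single-member .zip files as a text stream."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(4)
    if magic[:2] == GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="utf-8")
    if magic == ZIP_MAGIC:
        zf = zipfile.ZipFile(path)
        members = zf.namelist()
        if len(members) != 1:
            raise ValueError(
                f"{path}: zip archive must contain exactly one member, "
                f"found {len(members)}: {members}"
            )
        return io.TextIOWrapper(zf.open(members[0]), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _check_fields_comment(comment: str, lineno: int) -> None:
    declared = [f.strip() for f in comment.split(",")]
    if len(declared) < 12:
        raise BlastParseError(lineno, f"expected 12 standard fields, got {len(declared)}")
    for i, (got, allowed) in enumerate(zip(declared, _STANDARD_FIELDS)):
        if got not in allowed:
            raise BlastParseError(
                lineno,
                f"nonstandard field order: column {i + 1} is {got!r}, expected {allowed[0]!r}",
            )


def _parse_hit(line: str, lineno: int) -> BlastHit:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise BlastParseError(lineno, f"expected >= 12 tab-separated columns, got {len(cols)}")
    try:
        pident = float(cols[2])
    except ValueError:
        raise BlastParseError(lineno, f"non-numeric percent identity: {cols[2]!r}") from None
    try:
        evalue = float(cols[10])
    except ValueError:
        raise BlastParseError(lineno, f"non-numeric evalue: {cols[10]!r}") from None
    try:
        bit_score = float(cols[11])
    except ValueError:
        raise BlastParseError(lineno, f"non-numeric bit score: {cols[11]!r}") from None
    try:
        return BlastHit(
            query_id=cols[0],
            subject_id=cols[1],
            percent_identity=pident,
            evalue=evalue,
            bit_score=bit_score,
            raw_line=line.rstrip("\n"),
        )
    except ValueError as exc:
        raise BlastParseError(lineno, str(exc)) from None


def parse_blast7(stream: Iterable[str]) -> Iterator[QueryBlock]:
    """Yield one QueryBlock per query from an -outfmt 7 text stream."""
    block: QueryBlock | None = None
    lineno = 0

    def finish(b: QueryBlock) -> QueryBlock:
        if b.declared_hit_count is not None and b.declared_hit_count != len(b.hits):
            raise BlastParseError(
                lineno,
                f"query {b.query_id!r} declared {b.declared_hit_count} hits "
                f"but {len(b.hits)} data lines found",
            )
        return b

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            comment = line[1:].strip()
            if comment.startswith("Query:"):
                if block is not None:
                    yield finish(block)
                query_id = comment[len("Query:"):].strip().split()[0]
                block = QueryBlock(query_id=query_id)
            elif comment.startswith("Fields:"):
                _check_fields_comment(comment[len("Fields:"):].strip(), lineno)
            elif comment.endswith("hits found"):
                count_txt = comment[: -len("hits found")].strip()
                if block is None:
                    raise BlastParseError(lineno, "hit count before any '# Query:' comment")
                try:
                    block.declared_hit_count = int(count_txt)
                except ValueError:
                    raise BlastParseError(
                        lineno, f"unparseable hit count: {count_txt!r}"
                    ) from None
            continue
        hit = _parse_hit(line, lineno)
        if block is None:
            # outfmt 7 always announces the query; tolerate headerless data
            # by opening an implicit block keyed on column 1.
            block = QueryBlock(query_id=hit.query_id)
        elif hit.query_id != block.query_id:
            yield finish(block)
            block = QueryBlock(query_id=hit.query_id)
        block.hits.append(hit)
    if block is not None:
        yield finish(block)


def sort_hits(block: QueryBlock) -> QueryBlock:
    """Return a block with hits ordered by (evalue asc, bit score desc),
    ties broken by original file order (stable)."""
    order = sorted(
        range(len(block.hits)),
        key=lambda i: (block.hits[i].evalue, -block.hits[i].bit_score, i),
    )
    return QueryBlock(
        query_id=block.query_id,
        hits=[block.hits[i] for i in order],
        declared_hit_count=block.declared_hit_count,
    )
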