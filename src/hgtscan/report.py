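"""Output inventory: category CSVs, donor statistics, HTML pages, summary.

Every run produces the same fixed file set under the output directory
(``<P>`` is the project name):

* ``<P>_HGT_ai_full.csv`` — every query with an AI, sorted AI-descending
* ``<P>_HGT_ai_junk.csv`` — AI <= 0
* ``<P>_HGT_ai_possible.csv`` — AI > 0 and donor identity < 70%
* ``<P>_HGT_ai_very_likely.csv`` — the AI > 30 subset of possible
* ``<P>_HGT_ai_likely_contamination.csv`` — AI > 0 and identity >= 70%
* ``<P>_HGT_blastp_no_hits.csv`` — queries with no usable hit
* ``<P>_HGT_ai_{possible,very_likely,likely_contamination}_stat.csv`` —
  kingdom and species tallies of the candidate donors
* ``<P>_index.html`` + one page per reported query — color-coded hits
* ``<P>_summary.txt`` — parameter echo, per-category counts, timing

The category CSVs share one column template: AI, hit count, query name,
best E-value per basal NCBI branch (Archaea, Bacteria, Eukaryota,
Viroids, Viruses), best E-value per optional user category, best
recipient E-value, then best-hit metadata.  Absent values are rendered
as ``-``; AI is printed with two decimals (full precision is retained
in memory).
"""

from __future__ import annotations

import csv
import html
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .ai_core import (
    BASAL_ORDER,
    CATEGORY_CONTAMINATION,
    CATEGORY_JUNK,
    CATEGORY_NO_HITS,
    CATEGORY_POSSIBLE,
    CATEGORY_VERY_LIKELY,
    ROLE_DONOR,
    ROLE_EXCLUDED,
    ROLE_IGNORED,
    ROLE_RECIPIENT,
    ROLE_UNASSIGNED,
    AIConfig,
    HitRole,
    QueryVerdict,
)
from .blast_io import QueryBlock
from .taxonomy import TaxonomyDB

SENTINEL = "-"

STAT_CATEGORIES = (CATEGORY_POSSIBLE, CATEGORY_VERY_LIKELY, CATEGORY_CONTAMINATION)

#: background colors for the per-query HTML pages
ROLE_COLORS = {
    ROLE_EXCLUDED: "#99ccff",     # blue: hit inside an excluded group
    ROLE_UNASSIGNED: "#e6ccff",   # light violet: no taxonomic assignment
    ROLE_IGNORED: "#d9d9d9",      # light grey: 'other'/'unclassified'
}
BEST_DONOR_COLOR = "#99e699"      # green: best 'alien' hit
BEST_RECIPIENT_COLOR = "#ff9999"  # red: best recipient hit


@dataclass
class CategoryStats:
    """Species and kingdom tallies of candidate donors for one category."""

    by_species: Counter = field(default_factory=Counter)
    by_kingdom: Counter = field(default_factory=Counter)

    @classmethod
    def from_verdicts(cls, verdicts: Sequence[QueryVerdict]) -> "CategoryStats":
        stats = cls()
        for v in verdicts:
            stats.by_species[v.best_donor_species or "unknown"] += 1
            stats.by_kingdom[v.best_donor_kingdom or "unknown"] += 1
        return stats


def _fmt_evalue(value: float | None) -> str:
    if value is None:
        return SENTINEL
    if value == 0:
        return "0.0"
    return f"{value:.2g}"


def _fmt_ai(ai: float | None) -> str:
    return SENTINEL if ai is None else f"{ai:.2f}"


def _abbreviate_species(full_name: str) -> str:
    """'Cellulophaga algicola' -> 'C. algicola'; single tokens pass through."""
    parts = full_name.split()
    if len(parts) >= 2 and parts[0][0].isalpha():
        return f"{parts[0][0]}. {' '.join(parts[1:])}"
    return full_name


def csv_header(config: AIConfig, db: TaxonomyDB) -> list[str]:
    extra_names = [db.name(t) for t in config.extra_category_taxids]
    return (
        ["AI", "query hits number", "query name"]
        + [f"best {name} evalue" for name in BASAL_ORDER]
        + [f"best {name} evalue" for name in extra_names]
        + [
            "best recipient evalue",
            "best hit id",
            "best hit prct ident",
            "best hit org nickname",
            "best hit org full name",
            "best hit taxo group",
            "best hit taxid",
            "best hit lineage",
        ]
    )


def verdict_row(v: QueryVerdict, config: AIConfig) -> list[str]:
    row = [_fmt_ai(v.ai), str(v.hit_count), v.query_id]
    row += [_fmt_evalue(v.best_evalue_per_basal.get(name)) for name in BASAL_ORDER]
    row += [_fmt_evalue(v.best_evalue_per_extra.get(t)) for t in config.extra_category_taxids]
    row.append(_fmt_evalue(v.best_recipient_evalue))
    if v.best_hit is None:
        row += [SENTINEL] * 7
    else:
        b = v.best_hit
        row += [
            b.subject_id,
            f"{b.percent_identity:.2f}",
            _abbreviate_species(b.species) if b.species else SENTINEL,
            b.species or SENTINEL,
            b.group_label or SENTINEL,
            str(b.taxid) if b.taxid >= 0 else SENTINEL,
            b.lineage or SENTINEL,
        ]
    return row


def _sorted_by_ai(verdicts: Sequence[QueryVerdict]) -> list[QueryVerdict]:
    return sorted(
        verdicts,
        key=lambda v: (-(v.ai if v.ai is not None else float("-inf")), v.query_id),
    )


def split_by_category(verdicts: Sequence[QueryVerdict]) -> dict[str, list[QueryVerdict]]:
    """Partition plus the very_likely-within-possible overlap.

    ``possible`` deliberately includes the very_likely queries: the
    very-likely file is the AI > 30 refinement of the AI > 0 pool.
    """
    out: dict[str, list[QueryVerdict]] = {
        CATEGORY_NO_HITS: [],
        CATEGORY_JUNK: [],
        CATEGORY_POSSIBLE: [],
        CATEGORY_VERY_LIKELY: [],
        CATEGORY_CONTAMINATION: [],
    }
    for v in verdicts:
        out[v.category].append(v)
    out[CATEGORY_POSSIBLE] = out[CATEGORY_POSSIBLE] + out[CATEGORY_VERY_LIKELY]
    return out


def write_category_csvs(
    verdicts: Sequence[QueryVerdict],
    config: AIConfig,
    db: TaxonomyDB,
    project_name: str,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the six category CSVs; returns name -> path."""
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")
    header = csv_header(config, db)
    groups = split_by_category(verdicts)
    with_ai = [v for v in verdicts if v.ai is not None]

    files: dict[str, Path] = {}

    def write(name: str, rows: Sequence[QueryVerdict]) -> None:
        path = outdir / f"{project_name}_{name}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for v in _sorted_by_ai(rows):
                writer.writerow(verdict_row(v, config))
        files[name] = path

    write("HGT_ai_full", with_ai)
    write("HGT_ai_junk", groups[CATEGORY_JUNK])
    write("HGT_ai_possible", groups[CATEGORY_POSSIBLE])
    write("HGT_ai_very_likely", groups[CATEGORY_VERY_LIKELY])
    write("HGT_ai_likely_contamination", groups[CATEGORY_CONTAMINATION])

    no_hits_path = outdir / f"{project_name}_HGT_blastp_no_hits.csv"
    with open(no_hits_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query name", "query hits number", "note"])
        for v in sorted(groups[CATEGORY_NO_HITS], key=lambda v: v.query_id):
            writer.writerow([v.query_id, str(v.hit_count), v.note])
    files["HGT_blastp_no_hits"] = no_hits_path
    return files


def write_stats(
    verdicts: Sequence[QueryVerdict],
    category: str,
    project_name: str,
    outdir: str | Path,
) -> Path:
    """Two-column (taxon, occurrence) stats: kingdoms block then species
    block, each sorted by descending count then name."""
    if category not in STAT_CATEGORIES:
        raise ValueError(f"no stats file defined for category {category!r}")
    selected = split_by_category(verdicts)[category]
    stats = CategoryStats.from_verdicts(selected)
    path = Path(outdir) / f"{project_name}_HGT_ai_{category}_stat.csv"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "occurrence"])
        for counter in (stats.by_kingdom, stats.by_species):
            for name, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])):
                writer.writerow([name, str(count)])
    return path


_PAGE_STYLE = (
    "body{font-family:monospace;white-space:pre}"
    "span{display:block}"
    "table{border-collapse:collapse;font-family:sans-serif}"
    "td,th{border:1px solid #ccc;padding:2px 8px}"
)


def _render_query_page(
    verdict: QueryVerdict,
    block: QueryBlock,
    roles: Sequence[HitRole],
    truncate_colors: bool = False,
) -> str:
    """One query's raw hit lines with the taxonomic color code.

    blue = excluded group, green = best 'alien' (donor) hit, red = best
    recipient hit, light violet = unassigned, light grey =
    'other'/'unclassified'.  With ``truncate_colors`` no further line is
    colored once both the best donor and best recipient have appeared.
    """
    seen_donor = False
    seen_recipient = False
    lines = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html.escape(verdict.query_id)}</title>",
        f"<style>{_PAGE_STYLE}</style></head><body>",
        f"<h2>{html.escape(verdict.query_id)} &mdash; AI {_fmt_ai(verdict.ai)} "
        f"({html.escape(verdict.category)})</h2>",
    ]
    for hit, role in zip(block.hits, roles):
        color = None
        if truncate_colors and seen_donor and seen_recipient:
            color = None
        elif role.role == ROLE_DONOR and not seen_donor and hit.evalue == verdict.best_donor_evalue:
            color = BEST_DONOR_COLOR
            seen_donor = True
        elif role.role == ROLE_RECIPIENT and not seen_recipient and hit.evalue == verdict.best_recipient_evalue:
            color = BEST_RECIPIENT_COLOR
            seen_recipient = True
        else:
            color = ROLE_COLORS.get(role.role)
        text = html.escape(hit.raw_line)
        if color:
            lines.append(f"<span style='background-color:{color}'>{text}</span>")
        else:
            lines.append(f"<span>{text}</span>")
    lines.append("</body></html>")
    return "\n".join(lines)


def render_html(
    verdicts: Sequence[QueryVerdict],
    blocks: Mapping[str, QueryBlock],
    roles: Mapping[str, Sequence[HitRole]],
    project_name: str,
    outdir: str | Path,
    truncate_colors: bool = False,
) -> Path:
    """Write the index page plus one color-coded page per reported query.

    The index lists only the three HGT-relevant categories (very likely /
    possible / likely contamination); junk and no-hit queries appear in
    the CSVs only.  Per-query pages live in ``<P>_queries/``.
    """
    outdir = Path(outdir)
    pages_dir = outdir / f"{project_name}_queries"
    pages_dir.mkdir(parents=True, exist_ok=True)
    groups = split_by_category(verdicts)

    index_sections = []
    listed: set[str] = set()
    for category, title in (
        (CATEGORY_VERY_LIKELY, "Very likely HGT (AI &gt; 30 and &lt; 70% identity)"),
        (CATEGORY_POSSIBLE, "Possible HGT (AI &gt; 0 and &lt; 70% identity)"),
        (CATEGORY_CONTAMINATION, "Likely contamination (AI &gt; 0 and &ge; 70% identity)"),
    ):
        rows = []
        for v in _sorted_by_ai(groups[category]):
            page_name = f"{project_name}_queries/{_safe_name(v.query_id)}.html"
            donor_cat = html.escape(v.best_donor_kingdom or SENTINEL)
            rows.append(
                f"<tr><td><a href='{page_name}'>{html.escape(v.query_id)}</a></td>"
                f"<td>{_fmt_ai(v.ai)}</td><td>{donor_cat}</td></tr>"
            )
            listed.add(v.query_id)
        body = (
            "<table><tr><th>query</th><th>AI</th><th>candidate donor category</th></tr>"
            + "".join(rows)
            + "</table>"
            if rows
            else "<p>none</p>"
        )
        index_sections.append(f"<h2>{title}</h2>\n{body}")

    index_path = outdir / f"{project_name}_index.html"
    index_path.write_text(
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(project_name)}</title>"
        f"<style>{_PAGE_STYLE}</style></head><body>"
        f"<h1>{html.escape(project_name)} &mdash; candidate HGT report</h1>\n"
        + "\n".join(index_sections)
        + "</body></html>",
        encoding="utf-8",
    )

    for v in verdicts:
        if v.query_id not in listed:
            continue
        page = _render_query_page(
            v, blocks[v.query_id], roles[v.query_id], truncate_colors=truncate_colors
        )
        (pages_dir / f"{_safe_name(v.query_id)}.html").write_text(page, encoding="utf-8")
    return index_path


def _safe_name(query_id: str) -> str:
    return "".join(c if (c.isalnum() or c in "._-") else "_" for c in query_id)


def write_summary(
    config: AIConfig,
    counts: Mapping[str, int],
    elapsed_seconds: float,
    project_name: str,
    outdir: str | Path,
) -> Path:
    """Plain-text run log: parameter echo, per-category counts, elapsed time."""
    path = Path(outdir) / f"{project_name}_summary.txt"
    lines = [
        f"project: {project_name}",
        f"recipient taxid: {config.recipient_taxid}",
        "excluded taxids: " + ",".join(str(t) for t in config.excluded_taxids),
        "extra category taxids: "
        + (",".join(str(t) for t in config.extra_category_taxids) or "(none)"),
        f"AI possible threshold: > {config.ai_possible_threshold:g}",
        f"AI very likely threshold: > {config.ai_very_likely_threshold:g}",
        f"contamination identity threshold: >= {config.contamination_identity_threshold:g}%",
        f"E-value floor: {config.evalue_floor:g}",
        f"penalty E-value: {config.penalty_evalue:g}",
        "",
        "queries per category:",
    ]
    for key in (
        CATEGORY_VERY_LIKELY,
        CATEGORY_POSSIBLE,
        CATEGORY_CONTAMINATION,
        CATEGORY_JUNK,
        CATEGORY_NO_HITS,
    ):
        lines.append(f"  {key}: {counts.get(key, 0)}")
    lines.append(f"  total queries: {sum(counts.values())}")
    lines.append("")
    lines.append(f"elapsed time: {elapsed_seconds:.2f} s")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
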