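"""Alien Index computation and per-query HGT classification.

The Alien Index (AI) of a query protein compares its best BLAST hit
inside the recipient clade (the clade containing the query species,
e.g. Metazoa) with its best hit among candidate donor taxa (everything
else, after discarding user-excluded groups and the uninformative
'other'/'unclassified' root branches):

    AI = ln(best recipient E-value + 1e-200) - ln(best donor E-value + 1e-200)

A missing best hit on either side is replaced by a penalty E-value of 1,
so both E-values lie in [0, 1] and AI is bounded by +/- ln((1+1e-200)/1e-200)
~= +/-460.517.  AI > 0 means the query matches candidate donors better than
its own clade — a possible horizontal acquisition.  Queries are then
binned: AI <= 0 -> junk; AI > 0 with donor identity >= 70% -> likely
contamination; AI > 30 with identity < 70% -> very likely HGT; remaining
AI > 0 -> possible HGT.  All AI thresholds are strict; the identity
threshold is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .blast_io import BlastHit, QueryBlock, sort_hits
from .taxonomy import BASAL_TAXIDS, IGNORED_BASAL_PREFIXES, TaxonomyDB

BASAL_ORDER = tuple(BASAL_TAXIDS.values())  # Archaea, Bacteria, Eukaryota, Viroids, Viruses

CATEGORY_NO_HITS = "no_hits"
CATEGORY_JUNK = "junk"
CATEGORY_POSSIBLE = "possible"
CATEGORY_VERY_LIKELY = "very_likely"
CATEGORY_CONTAMINATION = "likely_contamination"

ROLE_EXCLUDED = "excluded"
ROLE_RECIPIENT = "recipient"
ROLE_DONOR = "donor"
ROLE_IGNORED = "ignored_other_unclassified"
ROLE_UNASSIGNED = "unassigned"


@dataclass
class AIConfig:
    """Run parameters: who the recipient is, whom to discard, thresholds.

    ``excluded_taxids`` must at least contain the query species itself,
    otherwise self-hits dominate both sides of the index.  The numeric
    constants (floor 1e-200, penalty 1) define the AI scale and should
    not normally be changed.
    """

    recipient_taxid: int
    excluded_taxids: Sequence[int]
    extra_category_taxids: Sequence[int] = ()
    evalue_floor: float = 1e-200
    penalty_evalue: float = 1.0
    ai_possible_threshold: float = 0.0
    ai_very_likely_threshold: float = 30.0
    contamination_identity_threshold: float = 70.0

    def __post_init__(self) -> None:
        if not self.excluded_taxids:
            raise ValueError(
                "excluded_taxids must be non-empty (at minimum the query species TaxID)"
            )
        if not 0 < self.evalue_floor < self.penalty_evalue <= 1:
            raise ValueError("require 0 < evalue_floor < penalty_evalue <= 1")
        if self.ai_possible_threshold > self.ai_very_likely_threshold:
            raise ValueError("ai_possible_threshold must be <= ai_very_likely_threshold")


@dataclass
class HitRole:
    """Taxonomic role of a single hit within one run's configuration."""

    role: str
    basal_category: str | None = None  # Archaea/Bacteria/Eukaryota/Viroids/Viruses or None
    extra_category: int | None = None  # deepest matching user category TaxID (report only)
    taxid: int | None = None


@dataclass
class BestHitInfo:
    """Metadata of the best usable hit, for the report columns."""

    subject_id: str
    percent_identity: float
    evalue: float
    species: str
    taxid: int
    group_label: str
    lineage: str


@dataclass
class QueryVerdict:
    """Everything the reports need to know about one query."""

    query_id: str
    hit_count: int
    ai: float | None
    best_evalue_per_basal: dict[str, float | None]
    best_evalue_per_extra: dict[int, float | None]
    best_recipient_evalue: float
    best_donor_evalue: float
    best_donor_identity: float | None
    best_donor_species: str | None
    best_donor_kingdom: str | None
    best_hit: BestHitInfo | None
    category: str
    note: str = ""


def classify_hit(taxid: int | None, config: AIConfig, db: TaxonomyDB) -> HitRole:
    """Assign one hit its taxonomic role.

    Precedence: unassigned > excluded > ignored (other/unclassified) >
    recipient > donor.  The optional user categories are resolved to the
    deepest matching TaxID for reporting only and never change the role.
    """
    if taxid is None:
        return HitRole(role=ROLE_UNASSIGNED)
    taxid = db.resolve_merged(taxid)
    lin = db.lineage(taxid)
    if lin is None:
        return HitRole(role=ROLE_UNASSIGNED)

    basal = db.basal_category(taxid)
    ignored = basal in IGNORED_BASAL_PREFIXES
    basal_label = basal if (basal in BASAL_ORDER) else None

    extra = None
    for cat in config.extra_category_taxids:
        cat_resolved = db.resolve_merged(cat)
        if cat_resolved in lin:
            if extra is None or lin.taxids.index(cat_resolved) > lin.taxids.index(extra):
                extra = cat_resolved

    for group in config.excluded_taxids:
        if db.resolve_merged(group) in lin:
            return HitRole(ROLE_EXCLUDED, basal_label, extra, taxid)
    if ignored:
        return HitRole(ROLE_IGNORED, basal_label, extra, taxid)
    if db.resolve_merged(config.recipient_taxid) in lin:
        return HitRole(ROLE_RECIPIENT, basal_label, extra, taxid)
    return HitRole(ROLE_DONOR, basal_label, extra, taxid)


def _usable(role: HitRole) -> bool:
    return role.role in (ROLE_RECIPIENT, ROLE_DONOR)


def extract_best_evalues(
    block: QueryBlock,
    roles: Sequence[HitRole],
    config: AIConfig,
    db: TaxonomyDB,
) -> tuple[float, float, float | None, dict[str, float | None], dict[int, float | None], BestHitInfo | None, HitRole | None]:
    """Scan a sorted block and pull out every per-category best E-value.

    Returns (best_recipient_evalue, best_donor_evalue, best_donor_identity,
    per-basal bests, per-extra bests, best_hit, best_donor_role).  Missing
    recipient/donor sides receive the penalty E-value; missing categories
    stay None (rendered as "-").  Because hits arrive sorted by
    (evalue asc, bit score desc, file order), the first hit of a kind is
    its best with the documented tie-breaks.
    """
    best_recipient: float | None = None
    best_donor: float | None = None
    best_donor_hit: BlastHit | None = None
    best_donor_role: HitRole | None = None
    per_basal: dict[str, float | None] = {name: None for name in BASAL_ORDER}
    per_extra: dict[int, float | None] = {t: None for t in config.extra_category_taxids}
    best_hit: BestHitInfo | None = None

    for hit, role in zip(block.hits, roles):
        if not _usable(role):
            continue
        if role.role == ROLE_RECIPIENT and best_recipient is None:
            best_recipient = hit.evalue
        if role.role == ROLE_DONOR and best_donor is None:
            best_donor = hit.evalue
            best_donor_hit = hit
            best_donor_role = role
        if role.basal_category is not None and per_basal[role.basal_category] is None:
            per_basal[role.basal_category] = hit.evalue
        if role.extra_category is not None and per_extra.get(role.extra_category) is None:
            per_extra[role.extra_category] = hit.evalue
        if best_hit is None:
            lin = db.lineage(role.taxid) if role.taxid is not None else None
            label = role.basal_category or ""
            if role.extra_category is not None:
                label = db.name(role.extra_category)
            best_hit = BestHitInfo(
                subject_id=hit.subject_id,
                percent_identity=hit.percent_identity,
                evalue=hit.evalue,
                species=db.name(role.taxid) if role.taxid is not None else "",
                taxid=role.taxid if role.taxid is not None else -1,
                group_label=label,
                lineage=str(lin) if lin is not None else "",
            )

    identity = best_donor_hit.percent_identity if best_donor_hit is not None else None
    return (
        best_recipient if best_recipient is not None else config.penalty_evalue,
        best_donor if best_donor is not None else config.penalty_evalue,
        identity,
        per_basal,
        per_extra,
        best_hit,
        best_donor_role,
    )


def alien_index(
    best_recipient_evalue: float,
    best_donor_evalue: float,
    floor: float = 1e-200,
) -> float:
    """AI = ln(best recipient E + floor) - ln(best donor E + floor).

    Both E-values must already be in [0, 1] (penalty applied upstream).
    The additive floor keeps ln finite at E = 0 and bounds the result to
    +/- ln((1 + floor) / floor), ~= +/-460.517 at the default floor.
    """
    for name, val in (("recipient", best_recipient_evalue), ("donor", best_donor_evalue)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"best {name} E-value outside [0, 1]: {val}")
    return math.log(best_recipient_evalue + floor) - math.log(best_donor_evalue + floor)


def categorize(
    ai: float | None,
    best_donor_identity: float | None,
    config: AIConfig,
    has_usable_hits: bool,
) -> str:
    """Bin one query: no_hits / junk / possible / very_likely / likely_contamination.

    very_likely is a refinement of the AI > 0, < 70%-identity pool; report
    writers emit it both in the possible file and its own file.
    """
    if not has_usable_hits:
        return CATEGORY_NO_HITS
    assert ai is not None
    if ai <= config.ai_possible_threshold:
        return CATEGORY_JUNK
    if (
        best_donor_identity is not None
        and best_donor_identity >= config.contamination_identity_threshold
    ):
        return CATEGORY_CONTAMINATION
    if ai > config.ai_very_likely_threshold:
        return CATEGORY_VERY_LIKELY
    return CATEGORY_POSSIBLE


def process_query(block: QueryBlock, config: AIConfig, db: TaxonomyDB) -> QueryVerdict:
    """Full per-query computation: roles -> best E-values -> AI -> category."""
    sorted_block = sort_hits(block)
    roles = [
        classify_hit(db.resolve_subject_taxid(h.subject_id), config, db)
        for h in sorted_block.hits
    ]
    has_usable = any(_usable(r) for r in roles)
    (
        best_recipient,
        best_donor,
        donor_identity,
        per_basal,
        per_extra,
        best_hit,
        best_donor_role,
    ) = extract_best_evalues(sorted_block, roles, config, db)

    if has_usable:
        ai = alien_index(best_recipient, best_donor, config.evalue_floor)
        note = ""
    else:
        # Both sides would carry the penalty and AI would be a meaningless 0.
        ai = None
        note = (
            "all hits excluded/ignored/unassigned"
            if block.hits
            else "no significant BLAST hits"
        )

    donor_species = None
    donor_kingdom = None
    if best_donor_role is not None and best_donor_role.taxid is not None:
        donor_species = db.name(best_donor_role.taxid)
        donor_kingdom = best_donor_role.basal_category or "unknown"

    return QueryVerdict(
        query_id=block.query_id,
        hit_count=len(block.hits),
        ai=ai,
        best_evalue_per_basal=per_basal,
        best_evalue_per_extra=per_extra,
        best_recipient_evalue=best_recipient,
        best_donor_evalue=best_donor,
        best_donor_identity=donor_identity,
        best_donor_species=donor_species,
        best_donor_kingdom=donor_kingdom,
        best_hit=best_hit,
        category=categorize(ai, donor_identity, config, has_usable),
        note=note,
    )


def assign_roles(block: QueryBlock, config: AIConfig, db: TaxonomyDB) -> list[HitRole]:
    """Roles for the hits of ``block`` in the block's own order (for HTML)."""
    return [
        classify_hit(db.resolve_subject_taxid(h.subject_id), config, db)
        for h in block.hits
    ]


def threshold_sweep(
    verdicts: Iterable[QueryVerdict],
    grid: Sequence[float],
    labels: dict[str, bool] | None = None,
) -> list[dict]:
    """Count queries above each AI threshold; with truth labels, also
    report recall and false-positive rate.

    ``labels`` maps query_id -> True (genuine transfer) / False.  Queries
    without an AI (no_hits) never count as called positive.  Recall over
    an all-negative label set is undefined and reported as None.
    """
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    scored = [(v.query_id, v.ai) for v in verdicts if v.ai is not None]
    rows = []
    for t in grid:
        called = {qid for qid, ai in scored if ai > t}
        row: dict = {"threshold": t, "count": len(called)}
        if labels is not None:
            positives = {q for q, lab in labels.items() if lab}
            negatives = {q for q, lab in labels.items() if not lab}
            row["recall"] = (
                len(called & positives) / len(positives) if positives else None
            )
            row["false_positive_rate"] = (
                len(called & negatives) / len(negatives) if negatives else None
            )
        rows.append(row)
    return rows
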