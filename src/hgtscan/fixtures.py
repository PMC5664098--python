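"""Synthetic inputs: toy taxonomies, protein mappings and BLAST results.

The whole pipeline can be exercised offline from three miniature file
families that follow the real dialects exactly:

* a taxdump (``nodes.dmp``/``names.dmp``/``merged.dmp``) for a ~30-node
  tree spanning the five NCBI basal branches plus 'other'/'unclassified',
  with a Metazoa -> Nematoda -> Tylenchida recipient-side path and
  bacterial/fungal donor-side leaves;
* both protein-mapping dialects (``gi_taxid_prot.dmp`` and
  ``prot.accession2taxid``) tying synthetic GIs/accessions to the leaves;
* -outfmt 7 BLAST files whose per-query Alien Index is planned in
  advance by inverting the AI formula: given a donor E-value d and a
  target AI, the recipient E-value is r = d * e^AI (clamped to [floor, 1]).

E-values are emitted in BLAST-style scientific notation with two
significant digits, so a plan's *realized* AI is recomputed from the
formatted strings (``PlannedQuery.expected_ai``); the pipeline recovers
that value to within 1e-9 and the intended category exactly.  Decoy hits
(excluded clade, unassignable subjects, 'other'/'unclassified') are
interleaved at seeded-random positions and must never change any
recovered value.
"""

from __future__ import annotations

import gzip
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ai_core import (
    CATEGORY_CONTAMINATION,
    CATEGORY_JUNK,
    CATEGORY_POSSIBLE,
    CATEGORY_VERY_LIKELY,
    AIConfig,
)

EVALUE_FLOOR = 1e-200


@dataclass
class TaxonNode:
    taxid: int
    parent: int
    name: str
    rank: str = "no rank"


@dataclass
class ToyTaxonomySpec:
    """A named clade tree plus merge pairs and per-leaf protein identifiers."""

    nodes: list[TaxonNode]
    merges: list[tuple[int, int]] = field(default_factory=list)
    #: leaf taxid -> list of (gi, accession.version)
    proteins: dict[int, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for node in self.nodes:
            if node.taxid in seen:
                raise ValueError(f"duplicate TaxID in toy taxonomy: {node.taxid}")
            seen.add(node.taxid)


# TaxIDs below mirror the real NCBI identifiers for the well-known taxa
# (Metazoa 33208, Tylenchida 6300, Fungi 4751, ...); purely synthetic
# leaves use the 90xxxx range.
RECIPIENT_TAXID = 33208       # Metazoa
QUERY_SPECIES_TAXID = 6306    # Meloidogyne incognita (the query species to exclude)
EXCLUDED_TAXID = 6300         # Tylenchida
DONOR_BACTERIUM_TAXID = 901001
DONOR_FUNGUS_TAXID = 901002
RECIPIENT_INSECT_TAXID = 901003
MERGED_OLD_TAXID = 999001     # retired alias of the donor bacterium


def default_toy_taxonomy() -> ToyTaxonomySpec:
    """~30-node tree covering every role the classifier distinguishes."""
    n = TaxonNode
    nodes = [
        n(1, 1, "root"),
        n(131567, 1, "cellular organisms"),
        # basal branches
        n(2157, 131567, "Archaea", "superkingdom"),
        n(2, 131567, "Bacteria", "superkingdom"),
        n(2759, 131567, "Eukaryota", "superkingdom"),
        n(12884, 1, "Viroids", "superkingdom"),
        n(10239, 1, "Viruses", "superkingdom"),
        n(28384, 1, "other sequences"),
        n(12908, 1, "unclassified sequences"),
        # recipient side: Metazoa -> Nematoda -> Tylenchida -> Meloidogyne
        n(33208, 2759, "Metazoa", "kingdom"),
        n(6231, 33208, "Nematoda", "phylum"),
        n(6300, 6231, "Tylenchida", "order"),
        n(6305, 6300, "Meloidogyne", "genus"),
        n(6306, 6305, "Meloidogyne incognita", "species"),
        n(45932, 6300, "Globodera", "genus"),
        n(31243, 45932, "Globodera rostochiensis", "species"),
        # a non-nematode metazoan (legitimate recipient hits)
        n(6656, 33208, "Arthropoda", "phylum"),
        n(901003, 6656, "Apriona japonica", "species"),
        # donor side in Eukaryota: fungi and plants
        n(4751, 2759, "Fungi", "kingdom"),
        n(901002, 4751, "Aspergillus toyensis", "species"),
        n(33090, 2759, "Viridiplantae", "kingdom"),
        n(901004, 33090, "Arabidopsis toyensis", "species"),
        # donor side in Bacteria
        n(117743, 2, "Flavobacteriia", "class"),
        n(901001, 117743, "Cellulophaga algicola", "species"),
        n(1224, 2, "Proteobacteria", "phylum"),
        n(901005, 1224, "Escherichia toyensis", "species"),
        # archaeal, viral, viroid leaves
        n(901006, 2157, "Methanococcus toyensis", "species"),
        n(901007, 10239, "Toyvirus primus", "species"),
        n(901008, 12884, "Toy viroid", "species"),
        # uninformative leaves
        n(901009, 28384, "synthetic construct", "species"),
        n(901010, 12908, "unclassified organism", "species"),
    ]
    proteins = {
        6306: [(100001, "MIN_001.1")],
        31243: [(100002, "GRO_001.1")],
        901003: [(100003, "API_001.1")],
        901002: [(100004, "FUN_001.1")],
        901004: [(100005, "PLA_001.1")],
        901001: [(100006, "CAL_001.1"), (100011, "CAL_002.1")],
        901005: [(100007, "ECO_001.1")],
        901006: [(100008, "ARC_001.1")],
        901007: [(100009, "VIR_001.1")],
        901008: [(100010, "VRD_001.1")],
        901009: [(100012, "OTH_001.1")],
        901010: [(100013, "UNC_001.1")],
    }
    return ToyTaxonomySpec(
        nodes=nodes,
        merges=[(MERGED_OLD_TAXID, DONOR_BACTERIUM_TAXID)],
        proteins=proteins,
    )


def make_toy_taxdump(spec: ToyTaxonomySpec, outdir: str | Path) -> dict[str, Path]:
    """Write dialect-correct taxdump + both mapping dialects; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    nodes_lines = [
        f"{n.taxid}\t|\t{n.parent}\t|\t{n.rank}\t|" for n in spec.nodes
    ]
    names_lines = []
    for n in spec.nodes:
        names_lines.append(f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|")
        # a decoy synonym record per node exercises the name-class filter
        names_lines.append(f"{n.taxid}\t|\tsyn {n.name}\t|\t\t|\tsynonym\t|")
    merged_lines = [f"{old}\t|\t{new}\t|" for old, new in spec.merges]

    paths["nodes"] = outdir / "nodes.dmp"
    paths["nodes"].write_text("\n".join(nodes_lines) + "\n", encoding="utf-8")
    paths["names"] = outdir / "names.dmp"
    paths["names"].write_text("\n".join(names_lines) + "\n", encoding="utf-8")
    paths["merged"] = outdir / "merged.dmp"
    paths["merged"].write_text(
        "".join(line + "\n" for line in merged_lines), encoding="utf-8"
    )

    gi_lines = []
    acc_lines = ["accession\taccession.version\ttaxid\tgi"]
    for taxid, entries in sorted(spec.proteins.items()):
        for gi, acc_ver in entries:
            gi_lines.append(f"{gi}\t{taxid}")
            bare = acc_ver.rsplit(".", 1)[0]
            acc_lines.append(f"{bare}\t{acc_ver}\t{taxid}\t{gi}")
    paths["gi_mapping"] = outdir / "gi_taxid_prot.dmp"
    paths["gi_mapping"].write_text("\n".join(gi_lines) + "\n", encoding="utf-8")
    paths["accession_mapping"] = outdir / "prot.accession2taxid"
    paths["accession_mapping"].write_text("\n".join(acc_lines) + "\n", encoding="utf-8")
    return paths


def format_evalue(value: float) -> str:
    """BLAST-style E-value text: '0.0' for zero, else 2 significant digits."""
    if value == 0:
        return "0.0"
    if value >= 1e-3:
        return f"{value:.2g}"
    mantissa, exponent = f"{value:.1e}".split("e")
    return f"{mantissa}e{int(exponent)}"


def _clamp(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


@dataclass
class PlannedQuery:
    """One synthetic query with a pre-planned Alien Index.

    ``target_ai`` fixes the recipient E-value via r = d * e^AI; after the
    two-significant-digit formatting both sides round-trip through the
    parser, so the realized index is ``expected_ai`` (within the
    formatting quantization of the target) and ``expected_category``
    follows from it.
    """

    query_id: str
    target_ai: float
    donor_evalue: float = 1e-50
    donor_identity: float = 45.0
    recipient_identity: float = 60.0
    n_excluded_decoys: int = 0
    n_unassigned_decoys: int = 0
    n_ignored_decoys: int = 0
    no_donor: bool = False
    no_recipient: bool = False

    def __post_init__(self) -> None:
        if not self.no_donor and not EVALUE_FLOOR <= self.donor_evalue <= 1:
            raise ValueError(
                f"{self.query_id}: donor E-value {self.donor_evalue} outside [floor, 1]"
            )

    @property
    def donor_evalue_text(self) -> str | None:
        return None if self.no_donor else format_evalue(self.donor_evalue)

    @property
    def recipient_evalue_text(self) -> str | None:
        if self.no_recipient:
            return None
        if self.no_donor:
            # AI = ln(r + floor) - ln(1 + floor) => r = e^AI - floor, AI <= 0
            r = _clamp(math.exp(self.target_ai), EVALUE_FLOOR, 1.0)
            return format_evalue(r)
        r = _clamp(self.donor_evalue * math.exp(self.target_ai), EVALUE_FLOOR, 1.0)
        if self.target_ai > 0 and not r > self.donor_evalue:
            raise ValueError(
                f"{self.query_id}: AI {self.target_ai} infeasible from donor "
                f"E-value {self.donor_evalue} after clamping to [floor, 1]"
            )
        return format_evalue(r)

    @property
    def expected_ai(self) -> float:
        """Realized AI after E-value formatting, as the pipeline will see it."""
        d = float(self.donor_evalue_text) if self.donor_evalue_text is not None else 1.0
        r = (
            float(self.recipient_evalue_text)
            if self.recipient_evalue_text is not None
            else 1.0
        )
        return math.log(r + EVALUE_FLOOR) - math.log(d + EVALUE_FLOOR)

    def expected_category(self, config: AIConfig | None = None) -> str:
        ai = self.expected_ai
        possible_t = config.ai_possible_threshold if config else 0.0
        very_t = config.ai_very_likely_threshold if config else 30.0
        ident_t = config.contamination_identity_threshold if config else 70.0
        if ai <= possible_t:
            return CATEGORY_JUNK
        if not self.no_donor and self.donor_identity >= ident_t:
            return CATEGORY_CONTAMINATION
        if ai > very_t:
            return CATEGORY_VERY_LIKELY
        return CATEGORY_POSSIBLE


def random_planned_queries(
    n: int,
    seed: int,
    id_prefix: str = "synth",
) -> list[PlannedQuery]:
    """n random plans spanning all four AI categories, seeded."""
    rng = random.Random(seed)
    plans = []
    for i in range(n):
        kind = rng.choice(["junk", "possible", "very_likely", "contamination", "no_donor"])
        # positive-AI plans need headroom: r = d * e^AI must stay <= 1
        donor_exp = rng.randint(75, 180) if kind in ("possible", "very_likely", "contamination") else rng.randint(5, 180)
        donor = round(rng.uniform(1.0, 9.9), 1) * 10.0 ** (-donor_exp)
        if kind == "junk":
            ai = -rng.uniform(0.5, 100.0)
        elif kind == "possible":
            ai = rng.uniform(0.5, 29.0)
        else:
            ai = rng.uniform(31.0, min(150.0, donor_exp * math.log(10) - 1))
        identity = rng.uniform(75.0, 99.0) if kind == "contamination" else rng.uniform(25.0, 65.0)
        plans.append(
            PlannedQuery(
                query_id=f"{id_prefix}{i:04d}",
                target_ai=(-rng.uniform(1.0, 50.0)) if kind == "no_donor" else ai,
                donor_evalue=donor,
                donor_identity=identity,
                no_donor=(kind == "no_donor"),
                n_excluded_decoys=rng.randint(0, 3),
                n_unassigned_decoys=rng.randint(0, 2),
                n_ignored_decoys=rng.randint(0, 2),
            )
        )
    return plans


DONOR_SUBJECT = "gi|100006|ref|CAL_001.1|"
RECIPIENT_SUBJECT = "gi|100003|ref|API_001.1|"
EXCLUDED_SUBJECT = "gi|100001|ref|MIN_001.1|"
IGNORED_SUBJECT = "gi|100012|ref|OTH_001.1|"
UNASSIGNED_SUBJECT = "gi|999999999|ref|GONE_001.1|"


def _hit_line(query_id: str, subject: str, identity: float, evalue_text: str,
              rng: random.Random) -> str:
    length = rng.randint(80, 400)
    mism = int(length * (100 - identity) / 100)
    bits = max(20.0, round(-1.4 * math.log10(float(evalue_text) + 1e-300) + 20, 1))
    return (
        f"{query_id}\t{subject}\t{identity:.2f}\t{length}\t{mism}\t0\t"
        f"1\t{length}\t1\t{length}\t{evalue_text}\t{bits:.1f}"
    )


def make_synthetic_blast(
    queries: Sequence[PlannedQuery],
    seed: int,
    outpath: str | Path,
    n_no_hit_queries: int = 0,
    compress: bool = False,
) -> Path:
    """Emit a valid -outfmt 7 file realizing the planned queries.

    Donor/recipient hits carry the planned E-values; decoys are given
    random E-values anywhere in [1e-180, 1] and interleaved at
    seeded-random positions, which must not perturb any recovered value.
    """
    rng = random.Random(seed)
    outpath = Path(outpath)
    lines: list[str] = []
    fields = (
        "query id, subject id, % identity, alignment length, mismatches, "
        "gap opens, q. start, q. end, s. start, s. end, evalue, bit score"
    )
    all_ids = [p.query_id for p in queries] + [
        f"nohit{i:03d}" for i in range(n_no_hit_queries)
    ]
    plan_by_id = {p.query_id: p for p in queries}
    for qid in all_ids:
        plan = plan_by_id.get(qid)
        hit_lines: list[str] = []
        if plan is not None:
            if plan.donor_evalue_text is not None:
                hit_lines.append(
                    _hit_line(qid, DONOR_SUBJECT, plan.donor_identity,
                              plan.donor_evalue_text, rng)
                )
            if plan.recipient_evalue_text is not None:
                hit_lines.append(
                    _hit_line(qid, RECIPIENT_SUBJECT, plan.recipient_identity,
                              plan.recipient_evalue_text, rng)
                )
            decoys = (
                [(EXCLUDED_SUBJECT, plan.n_excluded_decoys),
                 (UNASSIGNED_SUBJECT, plan.n_unassigned_decoys),
                 (IGNORED_SUBJECT, plan.n_ignored_decoys)]
            )
            for subject, count in decoys:
                for _ in range(count):
                    ev = format_evalue(10.0 ** (-rng.uniform(0, 180)))
                    decoy = _hit_line(qid, subject, rng.uniform(20, 99), ev, rng)
                    hit_lines.insert(rng.randint(0, len(hit_lines)), decoy)
        lines.append("# BLASTP 2.12.0+")
        lines.append(f"# Query: {qid}")
        lines.append("# Database: toy_nr")
        if hit_lines:
            lines.append(f"# Fields: {fields}")
        lines.append(f"# {len(hit_lines)} hits found")
        lines.extend(hit_lines)
    lines.append("# BLAST processed {} queries".format(len(all_ids)))
    text = "\n".join(lines) + "\n"
    if compress or outpath.suffix == ".gz":
        with gzip.open(outpath, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        outpath.write_text(text, encoding="utf-8")
    return outpath


def default_config() -> AIConfig:
    """The configuration matching the default toy taxonomy: Metazoa as
    recipient, Tylenchida excluded (covers the query species)."""
    return AIConfig(recipient_taxid=RECIPIENT_TAXID, excluded_taxids=[EXCLUDED_TAXID])
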