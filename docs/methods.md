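# Methods

## Model and procedure

`hgtscan` implements E-value-comparison screening for horizontal gene
transfer. The underlying model is deliberately simple: if a query
protein's closest database relatives, measured by BLAST E-value, sit in
a distant clade rather than in the query's own clade, horizontal
acquisition (or contamination) is a candidate explanation. The method
makes no phylogenetic inference — it is a triage statistic meant to
shrink the set of genes worth a real tree.

Per query, the pipeline is: (1) parse one `-outfmt 7` block; (2) map
each hit's subject identifier to a TaxID (GI number preferred when a
composite `gi|...|` identifier carries one, then versioned accession,
then unversioned); (3) reconstruct the subject lineage from the
parent map and assign a role with precedence *unassigned → excluded →
other/unclassified → recipient → donor*; (4) take the minimum E-value
on the recipient and donor sides, substituting the penalty value 1 for
a missing side; (5) compute
`AI = ln(E_rec + floor) − ln(E_don + floor)`; (6) categorize.

Hits are re-sorted by (E-value ascending, bit score descending, file
order) before scanning, so the "best" hit of each kind is well defined
even if the input ordering is unusual; all per-category best E-values
(five NCBI basal branches plus any user categories) are taken over the
full hit list, not truncated at the first recipient/donor pair, so the
report columns are complete.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `recipient_taxid` | — | single TaxID of the clade containing the query species |
| `excluded_taxids` | — | ≥1 TaxIDs whose hits are discarded entirely; must cover the query species so self-hits cannot mask transfers |
| `extra_category_taxids` | empty | report-only columns; never affect AI |
| `evalue_floor` | 1e-200 | additive constant; fixes the AI range to ±ln((1+floor)/floor) ≈ ±460.517 |
| `penalty_evalue` | 1 | stand-in for a missing recipient or donor best hit |
| `ai_possible_threshold` | 0 (strict >) | junk vs possible boundary |
| `ai_very_likely_threshold` | 30 (strict >) | possible vs very-likely boundary |
| `contamination_identity_threshold` | 70% (inclusive ≥) | donor identity above which a positive-AI query is flagged as likely contamination |

Boundary semantics are exact: AI thresholds are strict inequalities and
the identity threshold is inclusive. The identity used for the 70% rule
is that of the hit achieving the best *donor* E-value (ties broken by
higher bit score, then file order) — the identity of a recipient best
hit is irrelevant to the contamination question. The very-likely pool is
written as a subset of the possible pool (possible = all AI > 0 with
identity < 70%), so file row counts satisfy
`full = junk + possible\very_likely + very_likely + contamination`.

## Design choices where the design was open

* **Queries whose every hit is excluded/ignored/unassigned** would get
  the penalty on both sides and a meaningless AI of 0; they are instead
  reported in the no-hits file with a distinguishing note.
* **Merged/deleted taxa**: `merged.dmp` is honored before any traversal
  (a retired TaxID behaves exactly like its replacement); TaxIDs absent
  from `nodes.dmp` are unassignable, which matches how deleted protein
  records are rendered (violet) in the HTML report. Mapping rows that
  point at a merged TaxID resolve through the merge, then fall back to
  unassigned.
* **Duplicate mapping rows** keep the first occurrence and log a warning.
* **Per-category best E-values** are reported for every category with at
  least one hit ("-" otherwise), rather than only flagging the category
  of the overall best hit — strictly more informative and unambiguous.
* **HTML coloring** marks every line by role by default; the
  `--html-truncate-colors` flag stops coloring after the best donor and
  best recipient lines for the terser traditional rendering.
* **Abbreviated species name** is first initial of the genus plus the
  epithet ("C. algicola"); the abbreviated taxonomic group is the basal
  branch, or the user category name when one matches.
* **Significance filtering** is the responsibility of the BLAST run
  (e.g. `-evalue 1e-3`); the parser never re-filters hits.

## Numerical notes

AI is evaluated in double precision with the natural logarithm; at the
default floor the extreme values 460.5/−460.5 are exact to well below
the reporting precision (CSVs print AI with 2 decimals; full precision
is kept internally). Double precision reproduces an
arbitrary-precision evaluation of the worked donor-8e-81 /
recipient-9e-68 scenario to ~2e-14, far inside the 1e-9 tolerance the
tests assert. Inputs outside [0, 1] are contract violations and raise.

## Synthetic data

The fixture generator emulates the three input file families at toy
scale. The taxonomy is a ~30-node tree spanning the five NCBI basal
branches plus `other`/`unclassified`, with the real TaxIDs for the
well-known taxa (Metazoa 33208, Nematoda 6231, Tylenchida 6300, Fungi
4751, Viridiplantae 33090, ...) and synthetic leaves in the 90xxxx
range, one merged-TaxID pair, and both protein-mapping dialects.

BLAST files are built backwards from intent: a `PlannedQuery` fixes a
donor E-value and a target AI, from which the recipient E-value is
`E_rec = E_don · e^AI`, clamped to [floor, 1]. E-values are printed in
BLAST-style 2-significant-digit scientific notation, so the *realized*
AI is recomputed from the formatted strings (`expected_ai`); the
pipeline recovers that value to 1e-9 and the intended category exactly.
Randomized plans (seeded; byte-identical files on re-run) cover all
four AI categories, donor-free queries, zero-hit queries and decoy hits
from excluded/unassignable/uninformative subjects at random positions.

What the toy data does **not** emulate: realistic E-value/bit-score/
identity correlations, multiple HSPs per subject pair at scale,
database-size effects on E-values, and real taxonomies with tens of
thousands of nodes or rank anomalies. Passing tests therefore
demonstrate the bookkeeping — role assignment, best-value extraction,
the AI arithmetic, categorization and report consistency — not the
biological error rate of any AI threshold on real proteomes, which
depends entirely on the reference library and clades involved.

Default synthetic problem sizes (100–150 random queries or blocks per
property suite, 10,000 random pairs for the AI function's invariants)
keep the whole suite under a few seconds while exercising every code
path; the generators scale to arbitrary sizes via their `n` and `seed`
arguments.

## Limitations

* E-value-based indices under-call transfers in short proteins (less
  magnitude available on either side) and in proteins whose clade is
  poorly represented in the database.
* A high AI cannot distinguish HGT from contamination or database
  mislabeling by itself; the 70% identity rule is a heuristic quarantine,
  not a verdict.
* Queries missing from the BLAST file entirely (not even a zero-hit
  block) cannot be detected; only `# 0 hits found` blocks reach the
  no-hits report.
* Custom `-outfmt "7 ..."` column layouts and comment-free `-outfmt 6`
  are rejected rather than guessed at.
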