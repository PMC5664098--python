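# hgtscan

Taxonomy-aware screening of whole-proteome BLAST results for candidate
**horizontal gene transfers (HGT)** — genes that entered a genome by a
route other than parent-to-offspring inheritance.

`hgtscan` is for genomicists who have BLASTed a predicted proteome
against a large protein library (e.g. NCBI NR) and want a fast, fully
offline triage of which proteins look horizontally acquired, before
committing to per-gene phylogenetics. It takes the BLAST tabular result,
the NCBI taxonomy dump files and a protein→TaxID mapping, and produces
ranked CSV tables, donor statistics and a color-coded HTML report.

## The Alien Index

For each query protein, every BLAST hit is assigned a taxonomic role by
reconstructing its subject's lineage from the taxonomy:

* **recipient** — the hit lies inside the clade containing the query
  species (e.g. Metazoa, TaxID 33208);
* **donor** ("alien") — the hit lies outside the recipient clade and
  outside all excluded groups;
* **excluded** — inside a user-supplied group to discard (at minimum the
  query species itself, to remove self-hits);
* hits to the uninformative `other`/`unclassified` root branches, and
  hits whose identifier no longer maps to any taxon, are set aside.

With `E_rec` the best (smallest) recipient E-value and `E_don` the best
donor E-value — a missing side receiving a penalty value of 1 — the
Alien Index is

```
AI = ln(E_rec + 1e-200) − ln(E_don + 1e-200)
```

The additive floor keeps the logarithm finite at `E = 0` and bounds AI
to ±ln((1+1e-200)/1e-200) ≈ ±460.5. **AI > 0** means the protein matches
candidate donors better than its own clade. Queries are binned as:

| category | rule |
|---|---|
| junk | AI ≤ 0 |
| possible HGT | AI > 0 and donor identity < 70% |
| very likely HGT | AI > 30 and donor identity < 70% (subset of possible) |
| likely contamination | AI > 0 and donor identity ≥ 70% |
| no hits | no usable hit at all |

The 70% rule flags candidates so similar to a donor protein that
contamination of the assembly is the more likely explanation. An AI of
14 corresponds to a ≈1.2×10⁶-fold E-value gap; thresholds in that region
trade recall against false positives, and the `threshold_sweep` utility
tabulates counts/recall/false-positive rate over any AI grid.

## Worked example

Generate a complete toy input set (miniature taxdump, protein mappings,
and a synthetic BLAST file with planned AI values), then scan it:

```
hgtscan simulate --outdir toy --queries 30 --seed 7
hgtscan run --blast toy/blast.tsv --taxdump toy \
    --mapping toy/gi_taxid_prot.dmp --mapping-dialect gi \
    --project demo --recipient-taxid 33208 --exclude-taxids 6300 \
    --category-taxids 4751,33090 --outdir toy/out
```

which logs:

```
INFO hgtscan: processed 32 queries
INFO hgtscan:   no_hits: 2
INFO hgtscan:   junk: 13
INFO hgtscan:   possible: 3
INFO hgtscan:   very_likely: 8
INFO hgtscan:   likely_contamination: 6
```

Here 11 of 32 toy queries have AI > 0 with donor identity < 70% (8 of
them above AI 30, the high-confidence pool) and 6 match a donor at ≥70%
identity, so they are quarantined as possible contamination rather than
HGT. `toy/out/` then contains the full inventory: `demo_HGT_ai_full.csv`
(all scored queries, AI-descending, with per-kingdom best E-values and
best-hit taxonomy), the per-category CSVs and `_stat` donor tallies,
`demo_index.html` linking to one color-coded page per reported query
(blue = excluded hit, green = best donor, red = best recipient, violet =
unassignable, grey = other/unclassified), and `demo_summary.txt`. The
first data row of `demo_HGT_ai_full.csv` reads

```
144.83,5,synth0027,-,7.2e-99,5.7e-36,-,-,-,-,5.7e-36,gi|100006|ref|CAL_001.1|,...
```

an AI of 144.83 driven by a bacterial best hit at 7.2e-99 against a
best metazoan hit at 5.7e-36.

With real data, point `--taxdump` at an unpacked NCBI `taxdump` and
`--mapping` at `prot.accession2taxid` (`--mapping-dialect accession`);
plain, gzip- and single-member zip inputs are all accepted.

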