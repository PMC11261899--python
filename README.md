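# qctags

Standardized quality-control contextual-data tags for pathogen sequence
submissions — a library and CLI implementing the PHA4GE QC tag standard.

## The problem

Public health laboratories routinely produce sequence datasets that miss a
surveillance program's QC thresholds but remain valuable: for validating
pipelines, benchmarking tools, training staff, and understanding real-world
assay performance. Sharing such data safely requires that the known issues
travel with the submission in a form that is searchable and unambiguous.
The PHA4GE standard defines five contextual-data fields for this, each
backed by the Genomic Epidemiology Ontology (GenEpiO):

| Field | Ontology ID | Content |
|---|---|---|
| quality control method name | GENEPIO:0100557 | free text (tool, pipeline, or link) |
| quality control method version | GENEPIO:0100558 | free text (semver or ISO 8601 date preferred) |
| quality control determination | GENEPIO:0100559 | picklist, 6 terms (GENEPIO:0100562–0100567) |
| quality control issues | GENEPIO:0100560 | picklist, 10 terms (0100568–0100575, 0100751, 0101038) |
| quality control details | GENEPIO:0100561 | free text |

Picklist values are written `label [CURIE]`, e.g.
`sequence failed quality control [GENEPIO:0100564]`; identifiers are the
ground truth and labels may vary by synonym. Multiple values are
semicolon-separated, with method versions listed in the same order as
method names. Synthetic data (lab constructs, spiked mixtures) is marked
with `synthetic lab construct [GENEPIO:0101039]` in the
*experimental specimen role type* field and must not inherit metadata from
a biological source.

`qctags` provides:

- a **term registry** holding the standard's 23 CURIE-bearing core terms
  with synonym-aware, case-insensitive label↔CURIE resolution and
  deployment extensions (the in-library analogue of a New Term Request);
- a **record model** and wire **dialects** (display names, SRA snake_case
  attribute names, canonical JSON) with lossless round-tripping;
- a **validation rule engine** (R1–R9) for the standard's best practices —
  method name required, version alignment, picklist membership,
  synthetic-data isolation, and more;
- **adapters** that translate the outputs of common QC tools (ncov-tools,
  FastQC, Kraken2, samtools depth, Nextclade, Quast+Samtools, VADR,
  PHoeNIx, multi-classifier taxonomy consensus) into standardized tags via
  explicit, threshold-configurable rule tables;
- **submission emitters** for SRA user-defined attribute TSVs and ENA
  `EXPERIMENT_ATTRIBUTE` XML fragments, plus determination-breakdown
  reporting for submission campaigns.

## Worked example

A SARS-CoV-2 consensus sequence is checked with ncov-tools 1.9.1, which
reports 7 ambiguous sites — above its excess-ambiguity cutoff of 5, a
pattern consistent with contamination or a real mixed infection:

```sh
$ printf 'ambiguous_sites\t7\n' > ncov.tsv
$ qctags annotate --tool ncov-tools --report ncov.tsv --version 1.9.1
quality_control_method_name	ncov-tools
quality_control_method_version	1.9.1
quality_control_determination	sequence flagged for potential quality control issues [GENEPIO:0100566]
quality_control_issues	sequence contaminated [GENEPIO:0100569]
quality_control_details	>5 ambiguous sites in consensus, sequence indicative of contamination or real mixed infection
```

The determination says the sequence is *flagged*, not failed: ncov-tools
emits warnings rather than a pass/fail verdict, and the tags preserve that
distinction. The same record can be written as an SRA attribute row, an ENA
XML fragment, or canonical JSON (`qctags convert`). Vocabulary lookups are
synonym-aware in both directions:

```sh
$ qctags terms resolve "sequenced contaminated"
label:    sequence contaminated
curie:    GENEPIO:0100569
category: issue
synonyms: sequenced contaminated
```

The equivalent library calls:

```python
from qctags import adapt_ncov_tools, parse_tool_report, render_record

report = parse_tool_report("ncov-tools", "ambiguous_sites\t7\n", version="1.9.1")
record = adapt_ncov_tools(report)
print(render_record(record))
```

## Layout

- `src/qctags/terms.py` — ontology term registry (bundled vocabulary in
  `src/qctags/data/terms.tsv`)
- `src/qctags/records.py`, `dialect.py` — record model and wire formats
- `src/qctags/validation.py` — rule engine
- `src/qctags/adapters.py` — QC-tool adapters and minimal report parsers
- `src/qctags/submission.py` — SRA/ENA emitters
- `src/qctags/fixtures.py`, `reporting.py` — reference scenarios, synthetic
  collection generation, determination breakdowns
- `docs/methods.md` — models, rules, thresholds, and design notes
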