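# Methods

This note documents the models, rules, and numerical choices behind
`qctags`, and what its tests do and do not establish.

## Vocabulary model

The registry stores each controlled term as a canonical label, an optional
CURIE (`PREFIX:7-digit-local`, e.g. `GENEPIO:0100564`), a category, and a
synonym set. Twenty-three CURIE-bearing core terms make up the standard's
fixed vocabulary: 5 field terms, 6 determinations, 10 issues, and 2
miscellaneous terms (`Not Applicable`, `synthetic lab construct`). Two
further field terms — *experimental specimen role type* and *experimental
specimen details* — have no published ontology identifier; the registry
deliberately leaves their CURIEs empty rather than guessing, and they render
as bare labels. The method-name vocabulary is open: the bundled names
(FastANI, FastQC, Kraken2, Mash, Nextclade, ncov-tools, PHoeNIx, Quast,
samtools depth, Samtools, VADR) are suggestions for autocomplete, not a
constraint.

Decisions taken where the design was genuinely open:

- **Case.** Canonical labels are lowercase except `Not Applicable`, which is
  conventionally capitalized; all lookups are case-insensitive.
- **Synonyms, not duplicates.** "sequenced contaminated" is a synonym of
  "sequence contaminated" — both usages share CURIE `GENEPIO:0100569`, so
  they are one term. Term references in records keep the as-given spelling;
  rendering defaults to that spelling (so reference fixtures reproduce
  their sources byte-for-byte) with a `style="canonical"` option that
  normalizes to registry labels.
- **Extensions.** Deployment-specific vocabulary (e.g. a network's
  "significant quality control issues" determination) registers as an
  extension term, participating in lookups and validation exactly like core
  vocabulary. Whether such terms have official CURIEs is unknown to us;
  they are CURIE-less unless the caller supplies one.

## Record model and dialects

A record pairs each method with its version internally, although the wire
formats carry two parallel, positionally aligned lists; pairing happens at
parse time. Empty lists — not sentinel strings — represent absent values;
`Not Applicable` is always an explicit term reference. A methods-only
record is legal: method metadata is valuable even when no issues are
reported.

The multi-value separator is `"; "` on output. Input splitting accepts
semicolons always and falls back to commas when no semicolon is present,
because real submissions contain comma-joined method lists; one reference
scenario preserves exactly that (its method and version cells join with
`", "` while its term lists keep semicolons), which is why `render_record`
takes a separate `method_joiner`. The version cell keeps empty segments
during splitting — an empty slot means "this method has no version" and
must hold its position.

Details cells are atomic free text (never split on separators, since prose
legitimately contains them), with one exception: a cell that is exactly the
`Not Applicable` term parses to the term reference.

The canonical JSON document (`spec_version`, `dialect`, `records[]`) is
this package's own interchange schema, defined here because the standard's
repository schema is not reproduced; terms are encoded CURIE-first and
CURIE-only terms have labels restored from the registry on read
(identifiers are ground truth; labels are presentation).

## Validation rules

Rules R1–R9 (see `validation.py` for the table) encode the standard's best
practices. Severity choices that were judgement calls:

- **R3 (version format) is a warning, not an error**: the version field is
  declared free text; ISO 8601 / semantic versioning is guidance. Real
  tool versions like `1.19` are two-component and would otherwise fail.
- **R9 (Not Applicable exclusivity) is introduced here**: observed usage
  always has `Not Applicable` as a sole value, but exclusivity is nowhere
  stated, so violating it warns rather than errors.
- **"quality control not performed" alongside populated issues** warns via
  R8: the combination is never exhibited in practice and an error would
  over-interpret.
- A determination is *not* required when issues are present; the engine
  stays silent on that combination (documented here rather than emitted,
  since it is a question of style, not a stated rule).
- R7's inherited-field list (`host`, `isolation_source`,
  `collection_date`, …) is a pragmatic default drawn from common
  BioSample attributes and is overridable per call.

Severities are overridable per deployment (`severity_overrides`), matching
how surveillance networks profile the rules. The strict profile differs
from lenient only in R5 (unregistered term: error vs warning), which keeps
strict ≥ lenient in finding counts by construction.

## Adapters and thresholds

Each adapter is an explicit rule table from tool outcomes to tags. The
determination tier (*flagged* vs *failed* vs *minor*) follows the observed
convention per tool family: tools that warn without verdicts (ncov-tools,
Kraken2 purity checks, VADR alerts, classification conflicts) *flag*;
hard criterion misses (depth at resistance loci, FastQC module failures,
Nextclade coverage, PHoeNIx metric failures) *fail*; borderline assembly
contiguity/coverage yields *minor*.

Threshold defaults, with provenance:

| Parameter | Default | Basis |
|---|---|---|
| `max_ambiguous_sites` | 5 | ncov-tools' own excess-ambiguity rule (strictly `>5`) |
| `min_locus_depth` | 10 reads | this package's choice; typical variant-calling floor |
| `max_offtarget_fraction` | 0.2 | this package's choice |
| `max_contigs` | 200 | this package's choice; bacterial-assembly rule of thumb |
| `min_mean_depth` | 30× | this package's choice; common SNP-analysis floor |

Only the first is anchored in a tool's published behaviour; QC thresholds
legitimately differ across laboratories, so all are keyword parameters and
CLI-configurable (`--config thresholds.yaml`). All comparisons are strict
inequalities; values exactly at a threshold pass.

Details cells frequently carry wet-lab context no tool can know (Ct
values, DNA concentrations, multiplexing decisions). Adapters therefore
accept an operator `details=` override and otherwise emit a mechanical
description; two mechanical defaults (the excess-ambiguity description and
the `Not Applicable` term for cause-less frameshift flags) coincide with
the reference scenarios' cells, the rest of the scenario details are
operator-supplied fixture data.

Report parsers accept minimal canonical text forms, not full native
formats: FastQC `summary.txt` status lines; the Kraken2 6-column report
(fractions read from `U`/`S` rows); 3-column samtools-depth TSV (per-locus
depth = mean over rows, with the first column read as the locus name);
Quast key/value TSV; a `seqName`/`qc.flags` Nextclade TSV; a VADR
alert-code list; a PHoeNIx metric/status table with an `overall_status`
row; ncov-tools key/value summary. MultiQC-grade coverage of native
schemas is out of scope.

## Reference scenarios and the synthetic generator

Eleven reference scenarios (in `fixtures.py`) span the vocabulary and the
adapter set; scenarios 1–10 are tool-report pipelines, scenario 11 a
synthetic-mixture record entered directly. Scenario 11 deliberately places
a determination-category term in the issues list; it is constructed in
relaxed mode and the validator reports the placement (R8 warnings, no
errors) — the record is preserved as entered rather than corrected.
Scenario 9's alert list is ordered (low similarity, early stop,
frameshift) to match its reference issue order, since adapter output
follows alert order. Scenario 8's organisms are synthetic stand-ins; the
three-way classifier conflict plus wet-lab disagreement is the tested
pattern.

`generate_fixture_collection` draws determinations i.i.d. from configured
category weights (defaults 0.61 / 0.10 / 0.28 / 0.01 across no issues /
minor / flagged / significant — the mix of a production wastewater
surveillance deployment, with "significant quality control issues"
auto-registered as an extension), one method from a tool mix, and one
plausible issue for issue-bearing determinations. All randomness flows
through a single `random.Random(seed)`; no global state. What the
generator does *not* emulate: correlated issues within a record,
multi-method records, free-text details variation, or dirty input
(misspellings, stray separators) — so passing recovery tests shows the
aggregation and generation machinery is correct, not that the package is
robust to arbitrary real-world submissions (the lenient parser and R5
handle those, and are tested separately).

`summarize_determinations` counts a record once per *distinct*
determination by default (a mixture record with passed+failed counts in
both), switchable to first-determination-only; the per-category convention
means counts can exceed the record total. Percentages are half-up-rounded
integers of `100·count/total` with no renormalization, so they sum to 100
only up to ±(number of categories).

## Problem sizes and determinism

The test suite's randomized checks use fixed seeds throughout: 500 records
for the four-format roundtrip check, 10 000 records for frequency recovery
(binomial ±2 pp tolerance), 100-case hypothesis properties (derandomized).
The acceptance script sweeps ambiguous-site counts 0–10 in seeded-shuffled
order. These sizes keep the whole suite under a few seconds while leaving
the statistical tolerances comfortably non-trivial.

## Known limitations

- Validation is metadata-level only; no QC claims are re-derived from
  reads or assemblies.
- The ENA emitter produces the `EXPERIMENT_ATTRIBUTES` fragment only, not
  the full EXPERIMENT document, and no live submission is attempted.
- The registry is self-contained; it does not query ontology lookup
  services, so vocabulary updates ship as data-file updates.
- Cross-record checks (e.g. consistency of a sample across runs) are out
  of scope; tags describe one sample at one point in time.
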