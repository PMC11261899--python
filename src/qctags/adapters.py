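"""Adapters from QC-tool outputs to standardized tag records.

Each adapter consumes a normalized :class:`ToolReport` and applies an
explicit rule table to emit a :class:`~qctags.records.QCRecord`. Adapters do
not run the tools or recompute metrics; they translate already-computed QC
outcomes into the controlled vocabulary. Because QC thresholds differ across
laboratories, every numeric threshold is a keyword parameter; only the
ncov-tools excess-ambiguity cutoff (">5 ambiguous sites") is fixed by the
tool's own behaviour — the remaining defaults are this package's documented
choices (see docs/methods.md).

Details cells often carry wet-lab context no tool can know (Ct values, DNA
concentrations); each adapter therefore accepts a ``details=`` override and
otherwise emits a mechanical description of what fired.

Report parsers accept minimal canonical text forms of each tool's output
(documented per parser), not the full native formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

from .errors import (
    AdapterMismatchError,
    MissingLocusError,
    MissingTaxonError,
    ReportFormatError,
)
from .records import QCMethod, QCRecord, TermRef, VersionString
from .terms import TermRegistry, default_registry

_FRACTION_TOL = 1e-6

# Canonical vocabulary used by the rule tables.
DET_NO_ISSUES = "GENEPIO:0100562"
DET_PASSED = "GENEPIO:0100563"
DET_FAILED = "GENEPIO:0100564"
DET_MINOR = "GENEPIO:0100565"
DET_FLAGGED = "GENEPIO:0100566"
ISSUE_LOW_QUALITY = "GENEPIO:0100568"
ISSUE_CONTAMINATED = "GENEPIO:0100569"
ISSUE_LOW_AVG_COVERAGE = "GENEPIO:0100570"
ISSUE_LOW_PERCENT_GENOME = "GENEPIO:0100571"
ISSUE_LOW_SIGNAL_NOISE = "GENEPIO:0100574"
ISSUE_LOW_CHARACTERISTIC = "GENEPIO:0100575"
ISSUE_FRAMESHIFT = "GENEPIO:0100751"
ISSUE_TAXONOMY_INCONSISTENT = "GENEPIO:0101038"
NOT_APPLICABLE = "GENEPIO:0001619"

#: Default VADR alert-code → issue-term mapping. Keys cover both VADR's own
#: short codes and readable aliases.
DEFAULT_VADR_ALERT_MAP = {
    "cdsstopn": ISSUE_LOW_CHARACTERISTIC,
    "early_stop": ISSUE_LOW_CHARACTERISTIC,
    "fsthicnf": ISSUE_FRAMESHIFT,
    "fstlocnf": ISSUE_FRAMESHIFT,
    "frameshift": ISSUE_FRAMESHIFT,
    "lowsimis": ISSUE_LOW_PERCENT_GENOME,
    "lowsim5s": ISSUE_LOW_PERCENT_GENOME,
    "low_feature_similarity": ISSUE_LOW_PERCENT_GENOME,
}

#: Documented threshold defaults (overridable per call / via CLI config).
DEFAULT_THRESHOLDS = {
    "max_ambiguous_sites": 5,      # ncov-tools' own ">5 ambiguous sites" rule
    "min_locus_depth": 10,         # reads; per-locus depth floor
    "max_offtarget_fraction": 0.2, # Kraken2 off-target read fraction
    "max_contigs": 200,            # assembly fragmentation ceiling
    "min_mean_depth": 30.0,        # fold-coverage floor
}


@dataclass(frozen=True)
class ToolReport:
    """Normalized parse of one QC tool's output.

    ``metrics`` holds scalar values, ``flags`` tool-emitted alert/flag
    codes, ``per_locus`` per-locus read depths, ``taxa`` per-taxon read
    fractions in [0, 1].
    """

    tool: str
    version: str = ""
    metrics: Mapping[str, "float | str"] = dc_field(default_factory=dict)
    flags: tuple[str, ...] = ()
    per_locus: "tuple[tuple[str, float], ...] | None" = None
    taxa: "tuple[tuple[str, float], ...] | None" = None

    def __post_init__(self):
        if self.per_locus is not None:
            for name, depth in self.per_locus:
                if depth < 0:
                    raise ValueError(f"negative depth for locus {name!r}")
        if self.taxa is not None:
            total = sum(f for _, f in self.taxa)
            if total > 1 + _FRACTION_TOL:
                raise ValueError(f"taxon read fractions sum to {total} > 1")
            for name, f in self.taxa:
                if f < 0:
                    raise ValueError(f"negative fraction for taxon {name!r}")


def _check_tool(report: ToolReport, expected: str) -> None:
    if report.tool.strip().lower() != expected.lower():
        raise AdapterMismatchError(
            f"report is from {report.tool!r}, not {expected!r}"
        )


def _ref(registry: TermRegistry, curie: str, spelling: str | None = None) -> TermRef:
    return TermRef(registry.resolve_curie(curie), spelling=spelling)


def _assemble(
    registry: TermRegistry,
    methods: Sequence[tuple[str, str]],
    determination: str | None,
    issues: Sequence[TermRef],
    details: "str | None",
    na_details_when_empty: bool = False,
) -> QCRecord:
    dets = (_ref(registry, determination),) if determination else ()
    det_field: "str | TermRef | None" = details
    if details is None and determination and na_details_when_empty:
        det_field = _ref(registry, NOT_APPLICABLE)
    return QCRecord(
        methods=tuple(
            QCMethod(n, VersionString(v) if v else None) for n, v in methods
        ),
        determinations=dets,
        issues=tuple(issues),
        details=det_field,
    )


# -- ncov-tools -----------------------------------------------------------


def adapt_ncov_tools(
    report: ToolReport,
    *,
    max_ambiguous_sites: int = 5,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """ncov-tools consensus QC: excess ambiguity and frameshift flags.

    Strictly more than ``max_ambiguous_sites`` ambiguous sites in the
    consensus raises the excess-ambiguity flag (possible contamination or a
    real mixed infection) — determination *flagged*, issue *sequence
    contaminated*. A ``frameshift`` flag yields the same determination with
    issue *excess frameshift mutations detected*; with no operator details
    the details cell is the explicit Not Applicable term, since the tool
    reports no cause. No flags → a methods-only record (the tool calls
    neither pass nor fail).
    """
    _check_tool(report, "ncov-tools")
    registry = registry or default_registry()
    issues: list[TermRef] = []
    determination = None
    mech_details = None
    amb = report.metrics.get("ambiguous_sites")
    if amb is not None and float(amb) > max_ambiguous_sites:
        determination = DET_FLAGGED
        issues.append(_ref(registry, ISSUE_CONTAMINATED))
        mech_details = (
            f">{max_ambiguous_sites} ambiguous sites in consensus, sequence "
            "indicative of contamination or real mixed infection"
        )
    if "frameshift" in report.flags:
        determination = DET_FLAGGED
        issues.append(_ref(registry, ISSUE_FRAMESHIFT))
    return _assemble(
        registry,
        [("ncov-tools", report.version)],
        determination,
        issues,
        details if details is not None else mech_details,
        na_details_when_empty=True,
    )


# -- samtools depth -------------------------------------------------------


def adapt_samtools_depth(
    report: ToolReport,
    target_loci: Sequence[str],
    min_depth: float = 10,
    *,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Per-locus depth check at characteristic loci (e.g. AMR positions).

    Any target locus with mean depth strictly below ``min_depth`` fails the
    sequence with issue *low coverage of characteristic mutations*; a locus
    at exactly ``min_depth`` passes. Targets absent from the report raise
    :class:`MissingLocusError`.
    """
    _check_tool(report, "samtools depth")
    registry = registry or default_registry()
    if report.per_locus is None:
        raise ReportFormatError("samtools depth report has no per-locus depths")
    depths = {name: d for name, d in report.per_locus}
    low = []
    for locus in target_loci:
        if locus not in depths:
            raise MissingLocusError(f"target locus {locus!r} absent from depth report")
        if depths[locus] < min_depth:
            low.append(locus)
    determination = DET_FAILED if low else None
    issues = [_ref(registry, ISSUE_LOW_CHARACTERISTIC)] if low else []
    mech = (
        f"read depth below {min_depth:g} at characteristic loci: {', '.join(low)}"
        if low
        else None
    )
    return _assemble(
        registry,
        [("samtools depth", report.version)],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- FastQC ---------------------------------------------------------------

_FASTQC_STATUSES = {"pass", "warn", "fail"}
#: module-level rule table: (module name, status) → issue term
FASTQC_ISSUE_RULES = (
    ("Per base sequence quality", "fail", ISSUE_LOW_QUALITY),
    ("Per sequence GC content", "fail", ISSUE_CONTAMINATED),
)


def adapt_fastqc(
    report: ToolReport,
    *,
    details: "str | None" = None,
    contaminated_spelling: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """FastQC module statuses → tags, via an explicit rule table.

    A failed *Per base sequence quality* module maps to *low quality
    sequence*; a failed *Per sequence GC content* module (bimodal or shifted
    GC suggests contamination) maps to *sequence contaminated*. Any failed
    module fails the sequence; warnings only → *minor quality control issues
    identified*; all passes → *no quality control issues identified*.

    ``contaminated_spelling`` selects the emitted spelling of the
    contamination tag (the registry treats "sequenced contaminated" as a
    synonym of "sequence contaminated"; some submitters print the former).
    """
    _check_tool(report, "FastQC")
    registry = registry or default_registry()
    statuses: dict[str, str] = {}
    for flag in report.flags:
        module, _, status = flag.rpartition("=")
        status = status.strip().lower()
        if not module or status not in _FASTQC_STATUSES:
            raise ReportFormatError(f"bad FastQC module status {flag!r}")
        statuses[module.strip()] = status
    issues = []
    for module, status, issue_curie in FASTQC_ISSUE_RULES:
        if statuses.get(module) == status:
            spelling = (
                contaminated_spelling if issue_curie == ISSUE_CONTAMINATED else None
            )
            issues.append(_ref(registry, issue_curie, spelling))
    if "fail" in statuses.values():
        determination = DET_FAILED
    elif "warn" in statuses.values():
        determination = DET_MINOR
    else:
        determination = DET_NO_ISSUES
    failed = sorted(m for m, s in statuses.items() if s == "fail")
    mech = f"FastQC modules failed: {', '.join(failed)}" if failed else None
    return _assemble(
        registry,
        [("FastQC", report.version)],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- Kraken2 --------------------------------------------------------------


def adapt_kraken2(
    report: ToolReport,
    target_taxon: str,
    *,
    max_offtarget_fraction: float = 0.2,
    exclude_unclassified: bool = True,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Read-classification purity check against a target taxon.

    The off-target fraction is ``1 - target - unclassified`` (unclassified
    reads are excluded by default; set ``exclude_unclassified=False`` to
    count them as off-target). Strictly above ``max_offtarget_fraction`` the
    sequence is flagged with issue *low signal to noise ratio*.
    """
    _check_tool(report, "Kraken2")
    registry = registry or default_registry()
    if report.taxa is None:
        raise ReportFormatError("Kraken2 report has no taxon fractions")
    taxa = {name.strip().lower(): f for name, f in report.taxa}
    key = target_taxon.strip().lower()
    if key not in taxa:
        raise MissingTaxonError(f"target taxon {target_taxon!r} absent from report")
    off = 1.0 - taxa[key]
    if exclude_unclassified:
        off -= taxa.get("unclassified", 0.0)
    determination = None
    issues = []
    mech = None
    if off > max_offtarget_fraction:
        determination = DET_FLAGGED
        issues.append(_ref(registry, ISSUE_LOW_SIGNAL_NOISE))
        mech = (
            f"{off:.0%} of classified reads assigned to taxa other than "
            f"{target_taxon}"
        )
    return _assemble(
        registry,
        [("Kraken2", report.version)],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- Nextclade ------------------------------------------------------------


def adapt_nextclade(
    report: ToolReport,
    *,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Nextclade QC flags: low genome coverage and/or high N count.

    Either flag fails the sequence with issue *low percent genome captured*
    (emitted once even when both flags are present).
    """
    _check_tool(report, "Nextclade")
    registry = registry or default_registry()
    hit = [f for f in ("low_coverage", "high_N") if f in report.flags]
    determination = DET_FAILED if hit else None
    issues = [_ref(registry, ISSUE_LOW_PERCENT_GENOME)] if hit else []
    mech = f"Nextclade QC flags: {', '.join(hit)}" if hit else None
    return _assemble(
        registry,
        [("Nextclade", report.version)],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- Quast + Samtools assembly pair ---------------------------------------


def adapt_assembly_pair(
    quast: ToolReport,
    samtools: ToolReport,
    *,
    max_contigs: int = 200,
    min_mean_depth: float = 30.0,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Joint assembly QC from Quast (contiguity) and Samtools (depth).

    Contig count strictly above ``max_contigs`` → *low quality sequence*;
    mean depth strictly below ``min_mean_depth`` → *low average genome
    coverage*; any issue → *minor quality control issues identified*. The
    record lists both tools with positionally aligned versions.
    """
    _check_tool(quast, "Quast")
    _check_tool(samtools, "Samtools")
    registry = registry or default_registry()
    issues = []
    notes = []
    contigs = quast.metrics.get("n_contigs")
    depth = samtools.metrics.get("mean_depth")
    if contigs is not None and float(contigs) > max_contigs:
        issues.append(_ref(registry, ISSUE_LOW_QUALITY))
        notes.append(f"{int(float(contigs))} contigs (limit {max_contigs})")
    if depth is not None and float(depth) < min_mean_depth:
        issues.append(_ref(registry, ISSUE_LOW_AVG_COVERAGE))
        notes.append(f"{float(depth):g}x mean depth (minimum {min_mean_depth:g}x)")
    determination = DET_MINOR if issues else None
    return _assemble(
        registry,
        [("Quast", quast.version), ("Samtools", samtools.version)],
        determination,
        issues,
        details if details is not None else ("; ".join(notes) or None),
    )


# -- multi-tool taxonomic consensus ---------------------------------------


def adapt_taxonomic_consensus(
    calls: Sequence[tuple[str, str, str]],
    wetlab_id: "str | None" = None,
    *,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Cross-method species-identification consistency.

    ``calls`` is an ordered list of ``(tool, version, taxon)``. If the set
    of distinct taxa across the in-silico calls — plus the wet-lab
    identification when given — has more than one member, the sequence is
    flagged with issue *taxonomic designation inconsistent across methods*.
    """
    if not calls:
        raise ValueError("at least one classifier call is required")
    registry = registry or default_registry()
    taxa = {taxon.strip().lower() for _, _, taxon in calls}
    if wetlab_id is not None:
        taxa.add(wetlab_id.strip().lower())
    inconsistent = len(taxa) > 1
    determination = DET_FLAGGED if inconsistent else None
    issues = [_ref(registry, ISSUE_TAXONOMY_INCONSISTENT)] if inconsistent else []
    mech = (
        "species identification inconsistent across classification methods"
        if inconsistent
        else None
    )
    return _assemble(
        registry,
        [(tool, version) for tool, version, _ in calls],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- VADR -----------------------------------------------------------------


def adapt_vadr(
    report: ToolReport,
    alert_map: "Mapping[str, str] | None" = None,
    *,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """VADR annotation alerts → issue tags through an alert-code map.

    Defaults: early stop codon → *low coverage of characteristic
    mutations*; frameshift → *excess frameshift mutations detected*; low
    feature similarity → *low percent genome captured*. Issue order follows
    alert order with duplicates removed (first occurrence wins); any alert
    flags the sequence. Unmapped alert codes are not dropped: they are
    recorded in the details cell.
    """
    _check_tool(report, "VADR")
    registry = registry or default_registry()
    amap = dict(DEFAULT_VADR_ALERT_MAP if alert_map is None else alert_map)
    issues: list[TermRef] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for code in report.flags:
        curie = amap.get(code.strip().lower())
        if curie is None:
            unmapped.append(code)
            continue
        if curie not in seen:
            seen.add(curie)
            issues.append(_ref(registry, curie))
    determination = DET_FLAGGED if report.flags else None
    mech = None
    if unmapped:
        mech = f"unmapped VADR alert codes: {', '.join(unmapped)}"
    return _assemble(
        registry,
        [("VADR", report.version)],
        determination,
        issues,
        details if details is not None else mech,
    )


# -- PHoeNIx --------------------------------------------------------------


def adapt_phoenix(
    report: ToolReport,
    *,
    details: "str | None" = None,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """PHoeNIx pipeline summary: overall status plus per-metric statuses.

    Overall SUCCESS with every metric SUCCESS → *sequence passed quality
    control*, with issues and details both the explicit Not Applicable
    term. Any non-SUCCESS metric fails the sequence, naming the failing
    metrics in details. A SUCCESS report with no per-metric statuses passes
    vacuously, with a note to that effect.
    """
    _check_tool(report, "PHoeNIx")
    registry = registry or default_registry()
    overall = report.metrics.get("overall_status")
    if overall is None:
        raise ReportFormatError("PHoeNIx report lacks an overall status")
    metric_statuses = {
        k: str(v) for k, v in report.metrics.items() if k != "overall_status"
    }
    failing = sorted(k for k, v in metric_statuses.items() if v != "SUCCESS")
    if str(overall) == "SUCCESS" and not failing:
        record = _assemble(
            registry,
            [("PHoeNIx", report.version)],
            DET_PASSED,
            [_ref(registry, NOT_APPLICABLE)],
            details,
        )
        if details is None:
            na = _ref(registry, NOT_APPLICABLE)
            note = (
                na
                if metric_statuses
                else "overall SUCCESS; no individual metric statuses reported"
            )
            record = record.with_details(note)
        return record
    mech = f"failing metrics: {', '.join(failing) or 'overall status ' + str(overall)}"
    return _assemble(
        registry,
        [("PHoeNIx", report.version)],
        DET_FAILED,
        [],
        details if details is not None else mech,
    )


# -- minimal canonical report parsers ------------------------------------


def parse_fastqc_summary(text: str, version: str = "") -> ToolReport:
    """FastQC ``summary.txt`` lines: ``STATUS<TAB>Module name[<TAB>file]``."""
    flags = []
    for line in _rows(text):
        if len(line) < 2:
            raise ReportFormatError(f"bad FastQC summary line: {line!r}")
        status, module = line[0].strip().lower(), line[1].strip()
        if status not in _FASTQC_STATUSES:
            raise ReportFormatError(f"unknown FastQC status {line[0]!r}")
        flags.append(f"{module}={status}")
    return ToolReport(tool="FastQC", version=version, flags=tuple(flags))


def parse_kraken2_report(text: str, version: str = "") -> ToolReport:
    """Kraken2 6-column report: percent, clade reads, direct reads, rank,
    taxid, name. Taxon fractions are taken from unclassified (``U``) and
    species (``S``) rows."""
    taxa = []
    for row in _rows(text):
        if len(row) != 6:
            raise ReportFormatError(f"Kraken2 report row needs 6 columns: {row!r}")
        percent, _, _, rank, _, name = row
        if rank.strip() in ("U", "S"):
            taxa.append((name.strip(), float(percent) / 100.0))
    return ToolReport(tool="Kraken2", version=version, taxa=tuple(taxa))


def parse_samtools_depth(text: str, version: str = "") -> ToolReport:
    """samtools-depth 3-column TSV (locus, position, depth); the per-locus
    depth is the mean over that locus's rows."""
    sums: dict[str, list[float]] = {}
    for row in _rows(text):
        if len(row) != 3:
            raise ReportFormatError(f"depth row needs 3 columns: {row!r}")
        locus, _, depth = row
        sums.setdefault(locus.strip(), []).append(float(depth))
    per_locus = tuple((k, sum(v) / len(v)) for k, v in sums.items())
    return ToolReport(tool="samtools depth", version=version, per_locus=per_locus)


def parse_quast_report(text: str, version: str = "") -> ToolReport:
    """Quast tab-separated key/value report; ``# contigs`` → ``n_contigs``."""
    metrics: dict[str, "float | str"] = {}
    for row in _rows(text):
        if len(row) != 2:
            raise ReportFormatError(f"Quast row needs 2 columns: {row!r}")
        key, value = row[0].strip(), row[1].strip()
        if key == "# contigs":
            key = "n_contigs"
        try:
            metrics[key] = float(value)
        except ValueError:
            metrics[key] = value
    return ToolReport(tool="Quast", version=version, metrics=metrics)


def parse_samtools_coverage(text: str, version: str = "") -> ToolReport:
    """Tab-separated key/value form with a ``mean_depth`` entry."""
    metrics: dict[str, "float | str"] = {}
    for row in _rows(text):
        if len(row) != 2:
            raise ReportFormatError(f"coverage row needs 2 columns: {row!r}")
        try:
            metrics[row[0].strip()] = float(row[1])
        except ValueError:
            metrics[row[0].strip()] = row[1].strip()
    return ToolReport(tool="Samtools", version=version, metrics=metrics)


def parse_nextclade_tsv(text: str, version: str = "") -> ToolReport:
    """Minimal Nextclade QC TSV: header ``seqName<TAB>qc.flags`` with
    semicolon-separated flag codes (``low_coverage``, ``high_N``)."""
    rows = _rows(text)
    if not rows or rows[0][:2] != ["seqName", "qc.flags"]:
        raise ReportFormatError("Nextclade TSV needs a 'seqName\\tqc.flags' header")
    flags: list[str] = []
    for row in rows[1:]:
        if len(row) >= 2 and row[1].strip():
            flags.extend(f.strip() for f in row[1].split(";") if f.strip())
    return ToolReport(tool="Nextclade", version=version, flags=tuple(flags))


def parse_vadr_alerts(text: str, version: str = "") -> ToolReport:
    """VADR alert list: one alert code per line (optional tab + description)."""
    flags = tuple(row[0].strip() for row in _rows(text) if row[0].strip())
    return ToolReport(tool="VADR", version=version, flags=flags)


def parse_phoenix_summary(text: str, version: str = "") -> ToolReport:
    """PHoeNIx summary table: ``metric<TAB>status`` rows including an
    ``overall_status`` row."""
    metrics: dict[str, "float | str"] = {}
    for row in _rows(text):
        if len(row) != 2:
            raise ReportFormatError(f"PHoeNIx row needs 2 columns: {row!r}")
        metrics[row[0].strip()] = row[1].strip()
    return ToolReport(tool="PHoeNIx", version=version, metrics=metrics)


def parse_ncov_tools_summary(text: str, version: str = "") -> ToolReport:
    """ncov-tools summary: ``key<TAB>value`` rows; ``flags`` is a
    comma-separated list, numeric values become metrics."""
    metrics: dict[str, "float | str"] = {}
    flags: tuple[str, ...] = ()
    for row in _rows(text):
        if len(row) != 2:
            raise ReportFormatError(f"ncov-tools row needs 2 columns: {row!r}")
        key, value = row[0].strip(), row[1].strip()
        if key == "flags":
            flags = tuple(f.strip() for f in value.split(",") if f.strip())
            continue
        try:
            metrics[key] = float(value)
        except ValueError:
            metrics[key] = value
    return ToolReport(tool="ncov-tools", version=version, metrics=metrics, flags=flags)


REPORT_PARSERS = {
    "ncov-tools": parse_ncov_tools_summary,
    "samtools depth": parse_samtools_depth,
    "FastQC": parse_fastqc_summary,
    "Kraken2": parse_kraken2_report,
    "Nextclade": parse_nextclade_tsv,
    "Quast": parse_quast_report,
    "Samtools": parse_samtools_coverage,
    "VADR": parse_vadr_alerts,
    "PHoeNIx": parse_phoenix_summary,
}


def parse_tool_report(tool: str, text: str, version: str = "") -> ToolReport:
    """Dispatch to the minimal-form parser for ``tool``."""
    for name, parser in REPORT_PARSERS.items():
        if name.lower() == tool.strip().lower():
            return parser(text, version)
    raise ReportFormatError(f"no report parser for tool {tool!r}")


def _rows(text: str) -> list[list[str]]:
    # No comment syntax: Quast keys legitimately start with '#'.
    return [line.split("\t") for line in text.splitlines() if line.strip()]
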