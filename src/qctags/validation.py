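"""Best-practice rule engine for QC tag records.

Findings are report entries, never exceptions. The nine rules:

========  ========  =====================================================
rule      severity  checks
========  ========  =====================================================
R1        error     QC tags present but no method name (a method name must
                    always accompany the other tags)
R2        warning   a method lacks a version
R3        warning   a version is neither semantic (X.Y.Z) nor an ISO 8601
                    date (versions are free strings; this is guidance)
R4        error     version list length differs from method list length
                    (versions must be recorded in method-name order)
R5        error*/   a term does not resolve in the registry (*error under
          warning   the strict profile, warning under lenient)
R6        info      duplicate values within a multi-value list
R7        error     a synthetic-lab-construct record carries inherited
                    biological-sample metadata in its passthrough fields
R8        warning   a term used outside its category (e.g. a determination
                    term in the issues list), or "quality control not
                    performed" alongside populated issues
R9        warning   Not Applicable mixed with other values in a list
========  ========  =====================================================

Severities are overridable per deployment via ``severity_overrides``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import QCRecord, RecordCollection, TermRef
from .terms import TermRegistry

SEVERITIES = ("error", "warning", "info")

#: BioSample-style attribute names that describe an original biological
#: source; a synthetic lab construct must not inherit them (rule R7).
INHERITED_SAMPLE_FIELDS = frozenset(
    {
        "host",
        "host_age",
        "host_sex",
        "host_disease",
        "isolation_source",
        "collection_date",
        "geo_loc_name",
        "lat_lon",
        "culture_collection",
        "specimen_voucher",
        "env_broad_scale",
        "env_local_scale",
        "env_medium",
    }
)

_NOT_PERFORMED_CURIE = "GENEPIO:0100567"


@dataclass(frozen=True)
class ValidationIssue:
    """One rule finding against one record."""

    rule_id: str
    severity: str
    field: str
    message: str

    def __post_init__(self):
        if self.severity not in SEVERITIES:
            raise ValueError(f"bad severity {self.severity!r}")
        if not (self.rule_id.startswith("R") and self.rule_id[1:].isdigit()
                and 1 <= int(self.rule_id[1:]) <= 9):
            raise ValueError(f"bad rule id {self.rule_id!r}")


@dataclass
class ValidationReport:
    """All findings for one record; ``passed`` iff no error-level findings."""

    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    def by_severity(self, severity: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == severity]

    def by_rule(self, rule_id: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.rule_id == rule_id]


@dataclass
class CollectionValidation:
    """Per-record reports plus a rule/severity summary for a collection."""

    reports: list[ValidationReport]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.reports)

    @property
    def summary(self) -> dict[str, Counter]:
        by_rule: Counter = Counter()
        by_severity: Counter = Counter()
        for rep in self.reports:
            for issue in rep.issues:
                by_rule[issue.rule_id] += 1
                by_severity[issue.severity] += 1
        return {"by_rule": by_rule, "by_severity": by_severity}


def _dup_labels(refs: tuple[TermRef, ...]) -> list[str]:
    counts = Counter(r.key() for r in refs)
    return [str(k) for k, n in counts.items() if n > 1]


def validate_record(
    record: QCRecord,
    registry: TermRegistry | None = None,
    profile: str = "strict",
    severity_overrides: dict[str, str] | None = None,
    inherited_fields: frozenset[str] = INHERITED_SAMPLE_FIELDS,
) -> ValidationReport:
    """Apply rules R1–R9 to one record.

    Pure and deterministic: repeated calls yield identical reports. The
    ``strict`` profile reports unresolved terms (R5) as errors, ``lenient``
    as warnings; strict never reports fewer findings than lenient.
    """
    if profile not in ("strict", "lenient"):
        raise ValueError(f"unknown profile {profile!r}")
    overrides = severity_overrides or {}
    findings: list[ValidationIssue] = []

    def add(rule: str, default_severity: str, fld: str, message: str):
        findings.append(
            ValidationIssue(rule, overrides.get(rule, default_severity), fld, message)
        )

    # R1 — tags without a method name
    if record.has_qc_tags() and not record.methods:
        add("R1", "error", "method_name",
            "QC tags present but no quality control method name; a method "
            "name must always be included")

    # R2/R3 — version presence and format
    for m in record.methods:
        if m.version is None:
            add("R2", "warning", "method_version",
                f"method {m.name!r} has no recorded version")
        elif m.version.scheme == "other":
            add("R3", "warning", "method_version",
                f"version {m.version.raw!r} of {m.name!r} is neither X.Y.Z "
                "semantic versioning nor an ISO 8601 date")

    # R4 — positional name/version misalignment on the wire
    if (
        record.declared_version_count is not None
        and record.methods
        and record.declared_version_count != len(record.methods)
    ):
        add("R4", "error", "method_version",
            f"{record.declared_version_count} versions recorded for "
            f"{len(record.methods)} method names; versions must align "
            "positionally with names")

    # R5 — unregistered terms
    r5_severity = "error" if profile == "strict" else "warning"
    for fld, refs in (
        ("determination", record.determinations),
        ("issues", record.issues),
        ("specimen_role", (record.specimen_role,) if record.specimen_role else ()),
    ):
        for ref in refs:
            if not ref.resolved:
                add("R5", r5_severity, fld,
                    f"value {ref.label or ref.curie!r} does not resolve in "
                    "the term registry; submit a New Term Request if it is "
                    "genuinely new vocabulary")

    # R6 — duplicates within a list
    for fld, refs in (("determination", record.determinations), ("issues", record.issues)):
        for dup in _dup_labels(refs):
            add("R6", "info", fld, f"duplicate value {dup!r}")

    # R7 — synthetic constructs must not inherit biological-sample metadata
    if record.specimen_role is not None and record.specimen_role.is_synthetic_construct():
        inherited = [k for k, _ in record.extras if k.strip().lower() in inherited_fields]
        if inherited:
            add("R7", "error", "extras",
                "synthetic lab construct record carries inherited "
                f"biological-sample fields: {', '.join(inherited)}")

    # R8 — cross-category term use, and "not performed" with issues
    for fld, category, refs in (
        ("determination", "determination", record.determinations),
        ("issues", "issue", record.issues),
    ):
        for ref in refs:
            if ref.resolved and ref.term.category not in (category, "misc"):
                add("R8", "warning", fld,
                    f"{ref.term.category} term {ref.term.label!r} used in "
                    f"the {fld} field")
    if record.issues and any(
        r.curie == _NOT_PERFORMED_CURIE for r in record.determinations
    ):
        add("R8", "warning", "determination",
            "determination 'quality control not performed' is inconsistent "
            "with populated issues")

    # R9 — Not Applicable must be a sole value
    for fld, refs in (("determination", record.determinations), ("issues", record.issues)):
        if len(refs) > 1 and any(r.is_not_applicable() for r in refs):
            add("R9", "warning", fld, "Not Applicable mixed with other values")

    return ValidationReport(findings)


def validate_collection(
    collection: RecordCollection,
    registry: TermRegistry | None = None,
    profile: str = "strict",
    **kwargs,
) -> CollectionValidation:
    """Validate every record; the result aggregates counts by rule/severity."""
    return CollectionValidation(
        [validate_record(r, registry, profile, **kwargs) for r in collection]
    )
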