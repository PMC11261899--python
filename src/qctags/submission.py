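"""Repository submission artifacts: SRA attribute tables, ENA XML fragments.

The QC tags travel to the public repositories as user-defined attributes:
tab-separated columns named in the snake_case dialect for SRA, or
``EXPERIMENT_ATTRIBUTE`` TAG/VALUE elements for ENA experiment metadata.
Writers are bit-stable (fixed column order, no timestamps) so submissions
diff cleanly; writers refuse collections that fail validation, attaching
the per-record reports to the error.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET

from .dialect import SRA_SNAKE, FieldDialect, parse_record, render_record
from .errors import DocumentFormatError, SubmissionValidationError
from .records import QCRecord, RecordCollection
from .terms import TermRegistry, default_registry
from .validation import CollectionValidation, validate_collection

#: The five QC columns in standard order, then the specimen-role columns.
QC_COLUMNS = tuple(
    SRA_SNAKE.external(f)
    for f in ("method_name", "method_version", "determination", "issues", "details")
)
SPECIMEN_COLUMNS = tuple(
    SRA_SNAKE.external(f) for f in ("specimen_role", "specimen_details")
)

#: Companion contextual-data attributes some networks submit alongside the
#: QC tags; they pass through :func:`read_sra_table` verbatim as extras.
COMPANION_ATTRIBUTES = (
    "amplicon_PCR_primer_scheme",
    "amplicon_size",
    "dehosting_method",
    "sequence_submitter_contact_email",
)


def _cell_ok(value: str) -> None:
    if "\t" in value or "\n" in value or "\r" in value:
        raise DocumentFormatError(
            f"cell value contains a tab or newline, which TSV cells cannot "
            f"carry: {value!r}"
        )


def _column_order(rows: list[dict[str, str]], extra_columns=None) -> list[str]:
    cols = list(QC_COLUMNS)
    if any(c in row for row in rows for c in SPECIMEN_COLUMNS):
        cols += [c for c in SPECIMEN_COLUMNS if any(c in r for r in rows)]
    seen = set(cols)
    for row in rows:
        for name in row:
            if name not in seen:
                seen.add(name)
                cols.append(name)
    for name in extra_columns or ():
        if name not in seen:
            seen.add(name)
            cols.append(name)
    return cols


def write_sra_table(
    collection: RecordCollection,
    registry: TermRegistry | None = None,
    extra_columns=None,
    *,
    style: str = "as-given",
) -> str:
    """Serialize a collection as an SRA user-defined-attribute TSV.

    Header order: the five QC columns, the specimen columns when used, then
    passthrough columns in first-seen order. Term cells carry
    ``label [CURIE]`` strings; absent fields are empty cells. A collection
    with validation errors (lenient profile) is refused.
    """
    registry = registry or default_registry()
    check = validate_collection(collection, registry, profile="lenient")
    if not check.passed:
        raise SubmissionValidationError(
            "collection has validation errors; not writing a submission table",
            reports=check.reports,
        )
    rows = [render_record(r, SRA_SNAKE, style=style) for r in collection]
    cols = _column_order(rows, extra_columns)
    buf = io.StringIO()
    buf.write("\t".join(cols) + "\n")
    for row in rows:
        cells = []
        for c in cols:
            value = row.get(c, "")
            _cell_ok(value)
            cells.append(value)
        buf.write("\t".join(cells) + "\n")
    return buf.getvalue()


def read_sra_table(
    text: str,
    registry: TermRegistry | None = None,
    dialect: FieldDialect = SRA_SNAKE,
    profile: str = "lenient",
) -> tuple[RecordCollection, CollectionValidation]:
    """Parse an SRA attribute TSV into records plus per-row reports.

    Parsing is lenient (unresolved vocabulary is kept and reported, not
    dropped); unknown columns — including the companion contextual-data
    attributes — are preserved verbatim in each record's extras.
    """
    registry = registry or default_registry()
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise DocumentFormatError("missing header row")
    header = lines[0].split("\t")
    records = []
    for i, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        cells = line.split("\t")
        if len(cells) > len(header):
            raise DocumentFormatError(f"row has more cells than the header", f"line {i}")
        cells += [""] * (len(header) - len(cells))
        fields = {h: c for h, c in zip(header, cells) if c.strip() != ""}
        records.append(parse_record(fields, dialect, registry, mode="lenient"))
    collection = RecordCollection(records=records, dialect=dialect.name)
    reports = validate_collection(collection, registry, profile=profile)
    return collection, reports


# -- ENA ------------------------------------------------------------------


def write_ena_experiment_attributes(
    record: QCRecord,
    registry: TermRegistry | None = None,
    *,
    style: str = "as-given",
) -> str:
    """Render one record as an ENA ``EXPERIMENT_ATTRIBUTES`` XML fragment.

    One ``EXPERIMENT_ATTRIBUTE`` element per populated field, TAG in the
    snake_case dialect, VALUE the rendered cell, in deterministic field
    order. The record must validate without errors.
    """
    registry = registry or default_registry()
    check = validate_collection(
        RecordCollection([record]), registry, profile="lenient"
    )
    if not check.passed:
        raise SubmissionValidationError(
            "record has validation errors; not writing ENA attributes",
            reports=check.reports,
        )
    fields = render_record(record, SRA_SNAKE, style=style)
    root = ET.Element("EXPERIMENT_ATTRIBUTES")
    for tag, value in fields.items():
        attr = ET.SubElement(root, "EXPERIMENT_ATTRIBUTE")
        ET.SubElement(attr, "TAG").text = tag
        ET.SubElement(attr, "VALUE").text = value
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def read_ena_experiment_attributes(
    text: str,
    registry: TermRegistry | None = None,
) -> QCRecord:
    """Parse an ``EXPERIMENT_ATTRIBUTES`` fragment back into a record."""
    registry = registry or default_registry()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise DocumentFormatError(f"not well-formed XML: {exc}") from exc
    if root.tag != "EXPERIMENT_ATTRIBUTES":
        raise DocumentFormatError(f"unexpected root element {root.tag!r}")
    fields: dict[str, str] = {}
    for attr in root.findall("EXPERIMENT_ATTRIBUTE"):
        tag = attr.findtext("TAG")
        value = attr.findtext("VALUE")
        if tag is None:
            raise DocumentFormatError("EXPERIMENT_ATTRIBUTE without a TAG")
        fields[tag] = value or ""
    return parse_record(fields, SRA_SNAKE, registry, mode="lenient")


# -- submission template --------------------------------------------------


def write_submission_template(registry: TermRegistry | None = None) -> tuple[str, dict]:
    """A blank SRA attribute template plus a machine-readable picklist map.

    Stands in for the drop-down-bearing submission spreadsheet: the TSV is
    the header row; the sidecar maps each constrained column to its allowed
    values (rendered ``label [CURIE]``).
    """
    registry = registry or default_registry()
    header = "\t".join(QC_COLUMNS + SPECIMEN_COLUMNS) + "\n"
    picklists = {
        SRA_SNAKE.external("determination"): [
            t.render() for t in registry.terms("determination")
        ],
        SRA_SNAKE.external("issues"): [t.render() for t in registry.terms("issue")],
        SRA_SNAKE.external("method_name"): [
            t.label for t in registry.terms("method")
        ],
        SRA_SNAKE.external("specimen_role"): [
            t.render() for t in registry.terms("misc")
        ],
    }
    return header, picklists
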