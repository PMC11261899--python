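"""Wire dialects: multi-value strings, field names, canonical JSON.

Tag values travel as flat strings in spreadsheet cells: multiple values are
semicolon-separated, each term is rendered ``label [CURIE]``, and method
versions are a second list positionally aligned with the method names. Two
field-name dialects are supported: ``display`` (the capitalized field labels
shown in interfaces) and ``sra_snake`` (the snake_case attribute names used
for SRA user-defined fields, e.g. ``quality_control_method_name``).

The canonical JSON document is this package's lossless interchange form:
CURIE-first term objects, explicit nulls, a ``spec_version`` marker.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping

from .errors import DocumentFormatError, MalformedTokenError, UnknownTermError
from .records import (
    QCMethod,
    QCRecord,
    RecordCollection,
    TermRef,
    VersionString,
    record_equals,
    resolve_details,
)
from .terms import TermRegistry

JSON_SPEC_VERSION = "1.0.0"

#: Internal field identifiers, in canonical column order.
FIELD_IDS = (
    "method_name",
    "method_version",
    "determination",
    "issues",
    "details",
    "specimen_role",
    "specimen_details",
)

_DIALECTS: dict[str, dict[str, str]] = {
    "display": {
        "method_name": "Quality control method name",
        "method_version": "Quality control method version",
        "determination": "Quality control determination",
        "issues": "Quality control issues",
        "details": "Quality control details",
        "specimen_role": "Experimental specimen role type",
        "specimen_details": "Experimental specimen details",
    },
    "sra_snake": {
        "method_name": "quality_control_method_name",
        "method_version": "quality_control_method_version",
        "determination": "quality_control_determination",
        "issues": "quality_control_issues",
        "details": "quality_control_details",
        "specimen_role": "experimental_specimen_role_type",
        "specimen_details": "experimental_specimen_details",
    },
}


@dataclass(frozen=True)
class FieldDialect:
    """A bijection between internal field ids and external field names."""

    name: str
    field_map: Mapping[str, str]

    def external(self, field_id: str) -> str:
        return self.field_map[field_id]

    def internal(self, external_name: str) -> str | None:
        return self._reverse.get(external_name.strip().lower())

    @property
    def _reverse(self) -> dict[str, str]:
        return {v.lower(): k for k, v in self.field_map.items()}


def get_dialect(name: str) -> FieldDialect:
    """Look up a built-in dialect: ``display`` or ``sra_snake``."""
    key = name.replace("-", "_")
    if key not in _DIALECTS:
        raise KeyError(f"unknown dialect {name!r}; expected one of {sorted(_DIALECTS)}")
    return FieldDialect(key, _DIALECTS[key])


DISPLAY = get_dialect("display")
SRA_SNAKE = get_dialect("sra_snake")


# -- token-level parsing --------------------------------------------------


@dataclass(frozen=True)
class TermToken:
    """A parsed term string: a label and/or a bracketed CURIE."""

    label: str | None
    curie: str | None


_CURIE_SHAPE = re.compile(r"^[A-Za-z][A-Za-z0-9_.]*:\d+$")
_BRACKETED = re.compile(r"^(?P<label>.*?)\s*\[(?P<curie>[A-Za-z][A-Za-z0-9_.]*:\d+)\]$")


def parse_multivalue(raw: str, lenient: bool = False) -> list[str]:
    """Split a multi-value cell on semicolons.

    Surrounding whitespace is trimmed and empty segments dropped. In lenient
    mode a cell with no semicolon additionally splits on commas (some
    real-world records use comma separators despite the semicolon rule).
    """
    if raw is None:
        return []
    parts = raw.split(";")
    if lenient and len(parts) == 1:
        parts = raw.split(",")
    return [p.strip() for p in parts if p.strip()]


def parse_term_string(raw: str) -> TermToken:
    """Parse ``label [CURIE]``, a bare label, or a bare CURIE.

    A trailing square-bracketed CURIE is split off; a bare ``PREFIX:digits``
    yields a CURIE-only token. An unbalanced trailing bracket raises
    :class:`MalformedTokenError`; brackets that do not enclose a CURIE are
    treated as ordinary label text.
    """
    s = raw.strip()
    m = _BRACKETED.match(s)
    if m:
        label = m.group("label").strip()
        return TermToken(label=label or None, curie=m.group("curie"))
    if s.count("[") != s.count("]"):
        raise MalformedTokenError(f"unbalanced bracket in term string: {raw!r}")
    if _CURIE_SHAPE.match(s):
        return TermToken(label=None, curie=s)
    return TermToken(label=s, curie=None)


# -- record <-> field map -------------------------------------------------


def _render_details(d, style: str) -> str:
    if isinstance(d, TermRef):
        return d.render(style)
    return d


def render_record(
    record: QCRecord,
    dialect: FieldDialect = SRA_SNAKE,
    *,
    style: str = "as-given",
    joiner: str = "; ",
    method_joiner: str | None = None,
) -> dict[str, str]:
    """Render a record as an ordered external-name → cell-text map.

    Term cells carry ``label [CURIE]`` values joined by ``joiner`` (the
    documented convention is ``"; "``); the version cell is positionally
    aligned with the method-name cell; absent fields are omitted; extras are
    appended verbatim after the standard fields. ``method_joiner`` lets the
    method/version cells use a different separator (some real records join
    methods with commas while keeping semicolons in the term lists).
    """
    mj = joiner if method_joiner is None else method_joiner
    out: dict[str, str] = {}
    if record.methods:
        out[dialect.external("method_name")] = mj.join(m.name for m in record.methods)
        if any(m.version is not None for m in record.methods):
            out[dialect.external("method_version")] = mj.join(
                (m.version.raw if m.version else "") for m in record.methods
            )
    if record.determinations:
        out[dialect.external("determination")] = joiner.join(
            t.render(style) for t in record.determinations
        )
    if record.issues:
        out[dialect.external("issues")] = joiner.join(t.render(style) for t in record.issues)
    if record.details is not None:
        out[dialect.external("details")] = _render_details(record.details, style)
    if record.specimen_role is not None:
        out[dialect.external("specimen_role")] = record.specimen_role.render(style)
    if record.specimen_details is not None:
        out[dialect.external("specimen_details")] = record.specimen_details
    for k, v in record.extras:
        out[k] = v
    return out


def _split_versions(raw: str) -> list[str]:
    """Split a version cell, *keeping* empty segments.

    Versions are positionally aligned with method names, so an empty segment
    is meaningful (that method has no recorded version) and must hold its
    position rather than be dropped.
    """
    if raw is None or raw.strip() == "":
        return []
    if ";" in raw:
        parts = raw.split(";")
    elif "," in raw:
        parts = raw.split(",")
    else:
        parts = [raw]
    return [p.strip() for p in parts]


def parse_record(
    fields: Mapping[str, str],
    dialect: FieldDialect = SRA_SNAKE,
    registry: TermRegistry | None = None,
    mode: str = "lenient",
) -> QCRecord:
    """Inverse of :func:`render_record`.

    Unknown field names land in ``extras`` in input order. Strict mode
    raises on any token that does not resolve in the registry; lenient mode
    retains unresolved tokens for the validator. Multi-value splitting is
    lenient (comma fallback) in both modes — strictness governs vocabulary,
    not separators.
    """
    if registry is None:
        raise ValueError("a TermRegistry is required")
    from .records import _resolve_token  # shared token resolution

    known: dict[str, str] = {}
    extras: list[tuple[str, str]] = []
    for name, value in fields.items():
        fid = dialect.internal(name)
        if fid is None:
            extras.append((name, value))
        elif value is not None and str(value).strip() != "":
            known[fid] = str(value)

    names = parse_multivalue(known.get("method_name", ""), lenient=True)
    versions = _split_versions(known.get("method_version", ""))
    methods = tuple(
        QCMethod(n, VersionString(versions[i]) if i < len(versions) and versions[i] else None)
        for i, n in enumerate(names)
    )
    declared = len(versions) if versions and len(versions) != len(names) else None

    dets = tuple(
        _resolve_token(v, "determination", registry, mode, "determination")
        for v in parse_multivalue(known.get("determination", ""))
    )
    iss = tuple(
        _resolve_token(v, "issue", registry, mode, "issue")
        for v in parse_multivalue(known.get("issues", ""))
    )
    details = known.get("details")
    det_val = resolve_details(details, registry) if details is not None else None
    role = None
    if "specimen_role" in known:
        role = _resolve_token(
            known["specimen_role"], "misc", registry, mode, "experimental specimen role type"
        )
    return QCRecord(
        methods=methods,
        determinations=dets,
        issues=iss,
        details=det_val,
        specimen_role=role,
        specimen_details=known.get("specimen_details"),
        extras=tuple(extras),
        declared_version_count=declared,
    )


# -- canonical JSON -------------------------------------------------------


def _term_obj(ref: TermRef) -> dict:
    return {"curie": ref.curie, "label": ref.label or None}


def _record_obj(record: QCRecord) -> dict:
    details: dict | str | None
    if isinstance(record.details, TermRef):
        details = {"term": _term_obj(record.details)}
    else:
        details = record.details
    return {
        "methods": [
            {"name": m.name, "version": m.version.raw if m.version else None}
            for m in record.methods
        ],
        "determinations": [_term_obj(t) for t in record.determinations],
        "issues": [_term_obj(t) for t in record.issues],
        "details": details,
        "specimen_role": _term_obj(record.specimen_role) if record.specimen_role else None,
        "specimen_details": record.specimen_details,
        "extras": [[k, v] for k, v in record.extras],
    }


def to_canonical_json(collection: RecordCollection, indent: int | None = 2) -> str:
    """Serialize a collection to the canonical JSON document (CURIE-first)."""
    doc = {
        "spec_version": JSON_SPEC_VERSION,
        "dialect": collection.dialect,
        "records": [_record_obj(r) for r in collection.records],
    }
    return json.dumps(doc, indent=indent, ensure_ascii=False) + "\n"


def _ref_from_obj(obj, registry: TermRegistry, path: str) -> TermRef:
    if not isinstance(obj, dict):
        raise DocumentFormatError("term must be an object", path)
    curie = obj.get("curie")
    label = obj.get("label")
    if curie:
        try:
            term = registry.resolve_curie(curie)
            # Restore the canonical label for CURIE-only terms.
            return TermRef(term, spelling=label)
        except UnknownTermError:
            return TermRef(None, spelling=label, raw_curie=curie)
    if not label:
        raise DocumentFormatError("term needs a curie or a label", path)
    try:
        return TermRef(registry.resolve_label(label), spelling=label)
    except UnknownTermError:
        return TermRef(None, spelling=label)


def from_canonical_json(text: str, registry: TermRegistry) -> RecordCollection:
    """Parse the canonical JSON document back into a collection.

    CURIE-only terms have their labels restored from the registry
    (identifiers are the ground truth; labels are presentation). Malformed
    documents raise :class:`DocumentFormatError` with a JSON path.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "records" not in doc:
        raise DocumentFormatError("missing 'records' array", "$")
    records = []
    for i, obj in enumerate(doc["records"]):
        path = f"records[{i}]"
        if not isinstance(obj, dict):
            raise DocumentFormatError("record must be an object", path)
        methods = tuple(
            QCMethod(m["name"], VersionString(m["version"]) if m.get("version") else None)
            for m in obj.get("methods", [])
        )
        dets = tuple(
            _ref_from_obj(t, registry, f"{path}.determinations[{j}]")
            for j, t in enumerate(obj.get("determinations", []))
        )
        iss = tuple(
            _ref_from_obj(t, registry, f"{path}.issues[{j}]")
            for j, t in enumerate(obj.get("issues", []))
        )
        raw_details = obj.get("details")
        details: str | TermRef | None
        if isinstance(raw_details, dict):
            details = _ref_from_obj(raw_details.get("term"), registry, f"{path}.details")
        else:
            details = raw_details
        role_obj = obj.get("specimen_role")
        role = _ref_from_obj(role_obj, registry, f"{path}.specimen_role") if role_obj else None
        records.append(
            QCRecord(
                methods=methods,
                determinations=dets,
                issues=iss,
                details=details,
                specimen_role=role,
                specimen_details=obj.get("specimen_details"),
                extras=tuple((k, v) for k, v in obj.get("extras", [])),
            )
        )
    return RecordCollection(records=records, dialect=doc.get("dialect", "sra_snake"))


def roundtrips(record: QCRecord, registry: TermRegistry, dialect: FieldDialect = SRA_SNAKE) -> bool:
    """True if the record survives render → parse with content equality."""
    return record_equals(record, parse_record(render_record(record, dialect), dialect, registry))
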