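"""QC contextual-data record model.

A :class:`QCRecord` captures one sample's quality-control annotation: the
methods used (with versions), the determination(s), the issue tags, free-text
details, and — for artificial data — the experimental-specimen role fields.
Internally versions are *paired* with their method (the wire formats carry
two parallel, positionally aligned lists; pairing happens at parse time),
term values are resolved registry references, and absent values are empty
lists/None — never sentinel strings. ``Not Applicable`` is an explicit term
reference.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import UnknownTermError
from .terms import OntologyTerm, TermRegistry

NOT_APPLICABLE_CURIE = "GENEPIO:0001619"
SYNTHETIC_CONSTRUCT_CURIE = "GENEPIO:0101039"

_SEMVER_RE = re.compile(r"^\d+\.\d+\.\d+$")
_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


@dataclass(frozen=True)
class VersionString:
    """A method version with its detected convention.

    ``scheme`` is ``semver`` for integer ``X.Y.Z``, ``iso_date`` for a
    calendar-valid ``YYYY-MM-DD``, otherwise ``other``. Developers may use
    any convention; the scheme only drives a best-practice warning.
    """

    raw: str
    scheme: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "scheme", classify_version(self.raw))

    def __str__(self) -> str:
        return self.raw


def classify_version(raw: str) -> str:
    raw = raw.strip()
    if _SEMVER_RE.match(raw):
        return "semver"
    if _ISO_DATE_RE.match(raw):
        try:
            datetime.date.fromisoformat(raw)
            return "iso_date"
        except ValueError:
            return "other"
    return "other"


@dataclass(frozen=True)
class QCMethod:
    """One QC method (pipeline, tool, or link) with an optional version."""

    name: str
    version: VersionString | None = None

    def __post_init__(self):
        if not self.name.strip():
            raise ValueError("method name must be non-empty")


@dataclass(frozen=True)
class TermRef:
    """A reference to a vocabulary term as used in one record.

    ``spelling`` preserves the as-given label (submitters may use synonyms
    like "sequenced contaminated"); equality and validation go through the
    resolved ``term``. An unresolved reference (lenient parse) has
    ``term=None`` and keeps whatever label/CURIE text it was given.
    """

    term: OntologyTerm | None
    spelling: str | None = None
    raw_curie: str | None = None

    @property
    def label(self) -> str:
        if self.spelling is not None:
            return self.spelling
        if self.term is not None:
            return self.term.label
        return self.raw_curie or ""

    @property
    def curie(self) -> str | None:
        if self.term is not None:
            return self.term.curie
        return self.raw_curie

    @property
    def resolved(self) -> bool:
        return self.term is not None

    def key(self):
        """Identity key: CURIE when available, lowercased label otherwise."""
        return self.curie if self.curie is not None else self.label.lower()

    def render(self, style: str = "as-given") -> str:
        """Render as ``label [CURIE]``.

        ``style='as-given'`` keeps the submitted spelling; ``'canonical'``
        substitutes the registry's canonical label.
        """
        if style == "canonical" and self.term is not None:
            return self.term.render()
        if self.curie is None:
            return self.label
        if self.spelling is None and self.term is not None:
            return self.term.render()
        return f"{self.label} [{self.curie}]"

    def is_not_applicable(self) -> bool:
        return self.curie == NOT_APPLICABLE_CURIE

    def is_synthetic_construct(self) -> bool:
        return self.curie == SYNTHETIC_CONSTRUCT_CURIE


@dataclass(frozen=True)
class QCRecord:
    """One sample's QC tag annotation.

    ``extras`` passes through unrecognized attributes verbatim (e.g. the
    companion contextual-data fields a network like GenomeTrakr submits
    alongside the QC tags). ``declared_version_count`` remembers the length
    of the wire-format version list when it disagreed with the method list,
    so the validator can report the misalignment.
    """

    methods: tuple[QCMethod, ...] = ()
    determinations: tuple[TermRef, ...] = ()
    issues: tuple[TermRef, ...] = ()
    details: "str | TermRef | None" = None
    specimen_role: TermRef | None = None
    specimen_details: str | None = None
    extras: tuple[tuple[str, str], ...] = ()
    declared_version_count: int | None = None

    @property
    def extras_map(self) -> dict[str, str]:
        return dict(self.extras)

    def with_details(self, details: "str | TermRef | None") -> "QCRecord":
        return replace(self, details=details)

    def has_qc_tags(self) -> bool:
        """True if any QC field beyond the method name/version is populated."""
        return bool(self.determinations or self.issues or self.details is not None)


@dataclass
class RecordCollection:
    """An ordered collection of records plus the field-name dialect tag."""

    records: list[QCRecord] = field(default_factory=list)
    dialect: str = "sra_snake"

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# -- construction ---------------------------------------------------------


def _resolve_token(
    value: str,
    category: str,
    registry: TermRegistry,
    mode: str,
    field_name: str,
) -> TermRef:
    """Resolve one term token (label, CURIE, or ``label [CURIE]``).

    Strict mode requires resolution within ``category``; relaxed mode falls
    back to any category (the validator later reports cross-category use)
    and retains unresolvable tokens for the validator instead of raising.
    """
    from .dialect import parse_term_string  # local import; no cycle at call time

    token = parse_term_string(value)
    if token.curie is not None:
        try:
            term = registry.resolve_curie(token.curie)
        except UnknownTermError:
            if mode == "strict":
                raise UnknownTermError(
                    f"{field_name}: {value}", category=category
                ) from None
            return TermRef(None, spelling=token.label, raw_curie=token.curie)
        if mode == "strict" and term.category not in (category, "misc"):
            raise UnknownTermError(f"{field_name}: {value}", category=category)
        return TermRef(term, spelling=token.label)
    primary: UnknownTermError | None = None
    for cat in (category, "misc"):
        try:
            return TermRef(registry.resolve_label(token.label, cat), spelling=token.label)
        except UnknownTermError as exc:
            if cat == category:
                primary = exc
    if mode == "strict":
        raise UnknownTermError(
            f"{field_name}: {token.label}",
            suggestion=primary.suggestion if primary else None,
            category=category,
        ) from None
    try:
        return TermRef(registry.resolve_label(token.label, None), spelling=token.label)
    except UnknownTermError:
        return TermRef(None, spelling=token.label)


def resolve_details(value: str, registry: TermRegistry) -> "str | TermRef":
    """Details are atomic free text, except an explicit Not Applicable term."""
    from .dialect import parse_term_string

    try:
        token = parse_term_string(value)
    except Exception:
        return value
    if token.curie is not None:
        try:
            term = registry.resolve_curie(token.curie)
            if term.curie == NOT_APPLICABLE_CURIE:
                return TermRef(term, spelling=token.label)
        except UnknownTermError:
            pass
        return value
    if value.strip().lower() == "not applicable":
        return TermRef(registry.resolve_curie(NOT_APPLICABLE_CURIE), spelling=value.strip())
    return value


def build_record(
    methods: Sequence[tuple[str, "str | None"]] = (),
    determinations: Sequence[str] = (),
    issues: Sequence[str] = (),
    details: "str | None" = None,
    specimen_role: "str | None" = None,
    specimen_details: "str | None" = None,
    registry: TermRegistry | None = None,
    mode: str = "strict",
    extras: "dict[str, str] | None" = None,
) -> QCRecord:
    """Build a record from textual field values, resolving every term.

    ``methods`` is a sequence of ``(name, version-or-None)`` pairs.
    Determination/issue entries may be labels, CURIEs, or ``label [CURIE]``
    strings; input order is preserved. ``mode='relaxed'`` permits
    cross-category and unregistered tokens (deferred to validation); strict
    mode raises :class:`UnknownTermError` naming the field and value.
    """
    if registry is None:
        raise ValueError("a TermRegistry is required")
    qmethods = tuple(
        QCMethod(name, VersionString(ver) if ver not in (None, "") else None)
        for name, ver in methods
    )
    dets = tuple(
        _resolve_token(v, "determination", registry, mode, "determination")
        for v in determinations
    )
    iss = tuple(_resolve_token(v, "issue", registry, mode, "issue") for v in issues)
    det_val: "str | TermRef | None" = None
    if details is not None:
        det_val = resolve_details(details, registry)
    role = None
    if specimen_role is not None:
        role = _resolve_token(specimen_role, "misc", registry, mode, "experimental specimen role type")
    return QCRecord(
        methods=qmethods,
        determinations=dets,
        issues=iss,
        details=det_val,
        specimen_role=role,
        specimen_details=specimen_details,
        extras=tuple((extras or {}).items()),
    )


# -- equality -------------------------------------------------------------


def _details_key(d: "str | TermRef | None"):
    if d is None:
        return None
    if isinstance(d, TermRef):
        return ("term", d.key())
    return ("text", d.strip())


def record_equals(a: QCRecord, b: QCRecord) -> bool:
    """Content equality after term resolution.

    Terms compare by CURIE when available (identifier-first), otherwise by
    case-insensitive label; methods compare by case-insensitive name plus
    raw version string; list order matters; extras compare as ordered pairs.
    """
    def meth_key(ms: Iterable[QCMethod]):
        return tuple((m.name.strip().lower(), m.version.raw if m.version else None) for m in ms)

    def term_keys(ts: Iterable[TermRef]):
        return tuple(t.key() for t in ts)

    return (
        meth_key(a.methods) == meth_key(b.methods)
        and term_keys(a.determinations) == term_keys(b.determinations)
        and term_keys(a.issues) == term_keys(b.issues)
        and _details_key(a.details) == _details_key(b.details)
        and (a.specimen_role.key() if a.specimen_role else None)
        == (b.specimen_role.key() if b.specimen_role else None)
        and (a.specimen_details or "").strip() == (b.specimen_details or "").strip()
        and a.extras == b.extras
    )
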