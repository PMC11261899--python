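"""Exception hierarchy for qctags.

Every error raised by the library derives from :class:`QCTagsError`, so CLI
and pipeline callers can catch one type. Validation findings are *not*
exceptions — see :mod:`qctags.validation` — only structural problems
(unknown vocabulary, malformed input, adapter misuse) raise.
"""

from __future__ import annotations


class QCTagsError(Exception):
    """Base class for all qctags errors."""


class UnknownTermError(QCTagsError, KeyError):
    """A label or CURIE does not resolve in the term registry.

    Carries the nearest registered label as a suggestion, plus a pointer to
    the New Term Request route by which missing vocabulary is proposed
    upstream.
    """

    def __init__(self, query: str, suggestion: str | None = None, category: str | None = None):
        self.query = query
        self.suggestion = suggestion
        self.category = category
        msg = f"unknown term: {query!r}"
        if category:
            msg += f" (category: {category})"
        if suggestion:
            msg += f"; nearest registered label is {suggestion!r}"
        msg += (
            ". If this is genuinely new vocabulary, submit a New Term Request "
            "to the PHA4GE QC-tag maintainers instead of inventing a value."
        )
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its repr otherwise
        return self.args[0]


class TermConflictError(QCTagsError):
    """An extension term collides with an already-registered label or CURIE."""


class MalformedTokenError(QCTagsError, ValueError):
    """A term string could not be parsed (e.g. unbalanced bracket)."""


class AdapterMismatchError(QCTagsError, ValueError):
    """A tool report was handed to the adapter of a different tool."""


class MissingLocusError(QCTagsError, KeyError):
    """A requested target locus is absent from a per-locus depth report."""

    def __str__(self) -> str:
        return self.args[0]


class MissingTaxonError(QCTagsError, KeyError):
    """The target taxon is absent from a taxonomic-classification report."""

    def __str__(self) -> str:
        return self.args[0]


class ReportFormatError(QCTagsError, ValueError):
    """A QC-tool report file does not match its minimal canonical form."""


class DocumentFormatError(QCTagsError, ValueError):
    """A serialized collection (JSON / TSV / XML) is malformed.

    ``path`` locates the offending element, e.g. ``records[3].issues``.
    """

    def __init__(self, message: str, path: str | None = None):
        self.path = path
        super().__init__(f"{message} (at {path})" if path else message)


class SubmissionValidationError(QCTagsError):
    """A collection failed validation and was refused by a writer.

    The per-record validation reports are attached as ``reports``.
    """

    def __init__(self, message: str, reports=None):
        self.reports = reports or []
        super().__init__(message)
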