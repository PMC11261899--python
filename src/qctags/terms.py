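"""Controlled-vocabulary term registry for QC contextual-data tags.

The registry houses the GenEpiO-backed vocabulary of the PHA4GE quality
control tag standard: the five QC fields, the determination and issue
picklists, the two miscellaneous terms (``Not Applicable``, ``synthetic lab
construct``), and the open method-name suggestion vocabulary. Labels and
CURIEs (compact identifiers such as ``GENEPIO:0100564``) resolve
bidirectionally; identifiers are the ground truth of the standard, labels
may vary by synonym, so lookups are case-insensitive and synonym-aware.

Deployments extend the vocabulary with :meth:`TermRegistry.register_extension`
(the in-library analogue of a New Term Request), e.g. GenomeTrakr's
``significant quality control issues`` determination.
"""

from __future__ import annotations

import csv
import difflib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

from .errors import TermConflictError, UnknownTermError

#: Valid term categories. ``field`` names an attribute; ``determination``
#: and ``issue`` are the two closed picklists; ``misc`` holds cross-field
#: terms; ``method`` is the open method-name suggestion vocabulary.
CATEGORIES = ("field", "determination", "issue", "misc", "method")

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_.]*):(\d+)$")
_LOCAL_WIDTH = 7


def pad_local(local: str) -> str:
    """Zero-pad a CURIE local identifier to the canonical 7 digits."""
    return local.zfill(_LOCAL_WIDTH)


def split_curie(curie: str) -> tuple[str, str]:
    """Split ``PREFIX:digits`` into (prefix, zero-padded local part)."""
    m = _CURIE_RE.match(curie.strip())
    if not m:
        raise UnknownTermError(curie)
    return m.group(1), pad_local(m.group(2))


@dataclass(frozen=True)
class OntologyTerm:
    """One controlled-vocabulary entry.

    ``curie_local`` is a 7-character zero-padded digit string; terms without
    a published identifier (the specimen-role fields, method names, some
    extensions) carry ``None`` and render as a bare label.
    """

    label: str
    curie_prefix: str | None
    curie_local: str | None
    category: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    provenance: str = "core"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.curie_prefix is None) != (self.curie_local is None):
            raise ValueError("curie_prefix and curie_local must be set together")
        if self.curie_local is not None and not re.fullmatch(r"\d{7}", self.curie_local):
            raise ValueError(f"curie_local must be 7 digits, got {self.curie_local!r}")

    @property
    def curie(self) -> str | None:
        """Rendered CURIE, e.g. ``GENEPIO:0100564``, or None if unassigned."""
        if self.curie_prefix is None:
            return None
        return f"{self.curie_prefix}:{self.curie_local}"

    def render(self) -> str:
        """Render as ``label [CURIE]``, or bare label for CURIE-less terms."""
        if self.curie is None:
            return self.label
        return f"{self.label} [{self.curie}]"


class TermRegistry:
    """Bidirectional label/CURIE resolver over a set of :class:`OntologyTerm`.

    Lookup by label is case-insensitive and covers registered synonyms;
    lookup by CURIE zero-pads the local part before comparison.
    """

    def __init__(self, terms: Iterable[OntologyTerm] = ()):
        self._terms: list[OntologyTerm] = []
        # (category, lowercased label-or-synonym) -> term
        self._by_label: dict[tuple[str, str], OntologyTerm] = {}
        self._by_curie: dict[str, OntologyTerm] = {}
        for t in terms:
            self._add(t)

    # -- construction -----------------------------------------------------

    def _add(self, term: OntologyTerm) -> None:
        keys = [(term.category, term.label.lower())]
        keys += [(term.category, s.lower()) for s in term.synonyms]
        for k in keys:
            if k in self._by_label:
                raise TermConflictError(
                    f"label {k[1]!r} already registered in category {k[0]!r}"
                )
        if term.curie is not None and term.curie in self._by_curie:
            raise TermConflictError(f"CURIE {term.curie} already registered")
        self._terms.append(term)
        for k in keys:
            self._by_label[k] = term
        if term.curie is not None:
            self._by_curie[term.curie] = term

    def register_extension(
        self, label: str, category: str, curie: str | None = None,
        synonyms: Iterable[str] = (),
    ) -> OntologyTerm:
        """Register a deployment-specific term (provenance ``extension``).

        Extension terms participate in all lookups and in validation exactly
        like core terms; a CURIE-less extension renders as its bare label.
        Raises :class:`TermConflictError` on a duplicate label or CURIE.
        """
        label = label.strip()
        if not label:
            raise ValueError("extension label must be non-empty")
        prefix = local = None
        if curie is not None:
            prefix, local = split_curie(curie)
        term = OntologyTerm(
            label=label,
            curie_prefix=prefix,
            curie_local=local,
            category=category,
            synonyms=frozenset(s.strip() for s in synonyms if s.strip()),
            provenance="extension",
        )
        self._add(term)
        return term

    # -- lookup -----------------------------------------------------------

    def __iter__(self) -> Iterator[OntologyTerm]:
        return iter(self._terms)

    def __len__(self) -> int:
        return len(self._terms)

    def terms(self, category: str | None = None) -> list[OntologyTerm]:
        if category is None:
            return list(self._terms)
        return [t for t in self._terms if t.category == category]

    def core_curie_terms(self) -> list[OntologyTerm]:
        """The CURIE-bearing core terms (the standard's fixed vocabulary)."""
        return [t for t in self._terms if t.provenance == "core" and t.curie]

    def resolve_label(self, label: str, category: str | None = None) -> OntologyTerm:
        """Resolve a canonical label or synonym, case-insensitively.

        ``category`` restricts the search space; without it the label must be
        unambiguous across categories. Unknown labels raise
        :class:`UnknownTermError` carrying a nearest-label suggestion.
        """
        query = label.strip()
        if not query:
            raise ValueError("label must be non-empty")
        key = query.lower()
        if category is not None:
            hit = self._by_label.get((category, key))
            if hit is not None:
                return hit
            raise UnknownTermError(query, self._suggest(key, category), category)
        hits = {id(t): t for c in CATEGORIES if (t := self._by_label.get((c, key)))}
        if len(hits) == 1:
            return next(iter(hits.values()))
        if len(hits) > 1:
            cats = sorted(t.category for t in hits.values())
            raise UnknownTermError(
                query, suggestion=None,
                category=f"ambiguous across categories: {', '.join(cats)}",
            )
        raise UnknownTermError(query, self._suggest(key, None))

    def resolve_curie(self, curie: str) -> OntologyTerm:
        """Resolve a ``PREFIX:digits`` identifier (local part zero-padded)."""
        prefix, local = split_curie(curie)
        hit = self._by_curie.get(f"{prefix}:{local}")
        if hit is None:
            raise UnknownTermError(curie)
        return hit

    def resolve(self, query: str, category: str | None = None) -> OntologyTerm:
        """Resolve either a CURIE or a label, whichever ``query`` looks like."""
        if _CURIE_RE.match(query.strip()):
            return self.resolve_curie(query)
        return self.resolve_label(query, category)

    def _suggest(self, key: str, category: str | None) -> str | None:
        pool = {
            lbl: self._by_label[(cat, lbl)].label
            for (cat, lbl) in self._by_label
            if category is None or cat == category
        }
        close = difflib.get_close_matches(key, pool.keys(), n=1, cutoff=0.5)
        return pool[close[0]] if close else None


def render_term(term: OntologyTerm) -> str:
    """Render a term as ``label [CURIE]`` (bare label when CURIE-less)."""
    return term.render()


def _load_core_terms() -> list[OntologyTerm]:
    text = resources.files("qctags").joinpath("data/terms.tsv").read_text("utf-8")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    out = []
    for row in csv.DictReader(lines, delimiter="\t"):
        prefix = local = None
        if row["curie"]:
            prefix, local = split_curie(row["curie"])
        syns = frozenset(s for s in row["synonyms"].split("|") if s)
        out.append(
            OntologyTerm(
                label=row["label"],
                curie_prefix=prefix,
                curie_local=local,
                category=row["category"],
                synonyms=syns,
                provenance=row["provenance"],
            )
        )
    return out


def default_registry() -> TermRegistry:
    """A fresh registry loaded from the bundled core vocabulary.

    Returns a new mutable instance each call so extension registrations in
    one pipeline never leak into another.
    """
    return TermRegistry(_load_core_terms())
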