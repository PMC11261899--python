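"""Multi-value parsing, term tokens, render/parse roundtrips, canonical JSON."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_random_record
from qctags.dialect import (
    DISPLAY,
    SRA_SNAKE,
    from_canonical_json,
    parse_multivalue,
    parse_record,
    parse_term_string,
    render_record,
    to_canonical_json,
)
from qctags.errors import DocumentFormatError, MalformedTokenError, UnknownTermError
from qctags.fixtures import EXPECTED_FIELDS, scenario_collection, scenario_record
from qctags.records import RecordCollection, record_equals


class TestParseMultivalue:
    @pytest.mark.parametrize(
        "raw,lenient,expected",
        [
            ("Mash; Kraken2; FastANI", False, ["Mash", "Kraken2", "FastANI"]),
            ("Quast, Samtools", True, ["Quast", "Samtools"]),
            ("Quast, Samtools", False, ["Quast, Samtools"]),
            (";;", False, []),
            ("", False, []),
            ("  a ;  b ", False, ["a", "b"]),
            ("a,b;c", True, ["a,b", "c"]),  # semicolon present: no comma split
        ],
    )
    def test_splitting(self, raw, lenient, expected):
        assert parse_multivalue(raw, lenient=lenient) == expected

    @given(st.lists(st.text(alphabet="abcXYZ 2.-", min_size=1).map(str.strip).filter(bool), max_size=5))
    @settings(max_examples=100, derandomize=True)
    def test_join_then_parse_is_idempotent(self, values):
        joined = "; ".join(values)
        once = parse_multivalue(joined)
        assert parse_multivalue("; ".join(once)) == once
        assert all(v for v in once)


class TestParseTermString:
    def test_label_with_bracketed_curie(self):
        token = parse_term_string("low percent genome captured [GENEPIO:0100571]")
        assert token.label == "low percent genome captured"
        assert token.curie == "GENEPIO:0100571"

    def test_bare_label(self):
        token = parse_term_string("ncov-tools")
        assert token.label == "ncov-tools" and token.curie is None

    def test_bare_curie(self):
        token = parse_term_string("GENEPIO:0100564")
        assert token.label is None and token.curie == "GENEPIO:0100564"

    def test_unbalanced_bracket_raises(self):
        with pytest.raises(MalformedTokenError):
            parse_term_string("foo [GENEPIO:123")

    def test_non_curie_brackets_stay_in_label(self):
        token = parse_term_string("CFSAN Wastewater Analysis Pipeline [C-WAP]")
        assert token.curie is None
        assert "C-WAP" in token.label


def test_render_scenario3_snake_case_field_map(registry):
    rendered = render_record(scenario_record(3, registry), SRA_SNAKE)
    assert rendered == {
        "quality_control_method_name": "samtools depth",
        "quality_control_method_version": "1.19",
        "quality_control_determination": "sequence failed quality control [GENEPIO:0100564]",
        "quality_control_issues": "low coverage of characteristic mutations [GENEPIO:0100575]",
        "quality_control_details": "low DNA concentration",
    }


def test_render_empty_record_is_empty_map(registry):
    from qctags.records import QCRecord

    assert render_record(QCRecord(), SRA_SNAKE) == {}


def test_parse_splits_multivalue_issue_cell(registry):
    record = parse_record(
        {"quality_control_issues":
         "low quality sequence [GENEPIO:0100568]; sequenced contaminated [GENEPIO:0100569]"},
        SRA_SNAKE, registry,
    )
    assert [t.curie for t in record.issues] == ["GENEPIO:0100568", "GENEPIO:0100569"]


def test_unknown_field_names_pass_through_as_extras(registry):
    record = parse_record({"unknown_column": "x"}, SRA_SNAKE, registry)
    assert record.extras == (("unknown_column", "x"),)


def test_strict_parse_raises_on_unknown_vocabulary(registry):
    with pytest.raises(UnknownTermError):
        parse_record(
            {"quality_control_method_name": "t",
             "quality_control_issues": "sequence imploded"},
            SRA_SNAKE, registry, mode="strict",
        )


def test_lenient_parse_retains_unknown_vocabulary(registry):
    record = parse_record(
        {"quality_control_method_name": "t",
         "quality_control_issues": "sequence imploded"},
        SRA_SNAKE, registry, mode="lenient",
    )
    assert record.issues[0].label == "sequence imploded"
    assert not record.issues[0].resolved


def test_version_alignment_with_a_missing_version(registry):
    record = parse_record(
        {"quality_control_method_name": "Quast; Samtools",
         "quality_control_method_version": "5.2.0; "},
        SRA_SNAKE, registry,
    )
    assert record.methods[0].version.raw == "5.2.0"
    assert record.methods[1].version is None
    assert record.declared_version_count is None  # two aligned slots
    rendered = render_record(record, SRA_SNAKE)
    reparsed = parse_record(rendered, SRA_SNAKE, registry)
    assert record_equals(record, reparsed)


def test_render_parse_roundtrip_over_all_scenarios(registry):
    for k in EXPECTED_FIELDS:
        for dialect in (DISPLAY, SRA_SNAKE):
            record = scenario_record(k, registry)
            rendered = render_record(record, dialect)
            assert record_equals(record, parse_record(rendered, dialect, registry))


def test_render_parse_roundtrip_on_randomized_records(registry):
    rng = random.Random(20240611)
    for _ in range(100):
        record = make_random_record(rng, registry)
        for dialect in (DISPLAY, SRA_SNAKE):
            rendered = render_record(record, dialect)
            assert record_equals(record, parse_record(rendered, dialect, registry))


def test_canonical_label_render_style_normalizes_synonyms(registry):
    rendered = render_record(scenario_record(4, registry), SRA_SNAKE, style="canonical")
    assert "sequence contaminated [GENEPIO:0100569]" in rendered["quality_control_issues"]


class TestCanonicalJson:
    def test_roundtrip_over_scenario_collection(self, registry):
        collection = scenario_collection(registry)
        back = from_canonical_json(to_canonical_json(collection), registry)
        assert len(back) == len(collection)
        for a, b in zip(collection, back):
            assert record_equals(a, b)

    def test_empty_collection(self, registry):
        doc = to_canonical_json(RecordCollection())
        assert '"records": []' in doc
        assert len(from_canonical_json(doc, registry)) == 0

    def test_curie_only_terms_get_labels_restored(self, registry):
        doc = (
            '{"spec_version": "1.0.0", "records": [{'
            '"methods": [{"name": "t", "version": "1.0.0"}],'
            '"determinations": [{"curie": "GENEPIO:0100564"}],'
            '"issues": [], "details": null}]}'
        )
        record = from_canonical_json(doc, registry).records[0]
        assert record.determinations[0].label == "sequence failed quality control"

    def test_malformed_document_reports_a_path(self, registry):
        with pytest.raises(DocumentFormatError):
            from_canonical_json("{\"records\": [{\"determinations\": [42]}]}", registry)
        with pytest.raises(DocumentFormatError):
            from_canonical_json("not json", registry)
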