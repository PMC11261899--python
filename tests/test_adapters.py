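"""Tool adapters: golden scenarios, rule tables, boundaries, monotonicity."""

import itertools

import pytest

from qctags import adapters
from qctags.adapters import ToolReport
from qctags.dialect import DISPLAY, render_record
from qctags.errors import (
    AdapterMismatchError,
    MissingLocusError,
    MissingTaxonError,
    ReportFormatError,
)
from qctags.fixtures import (
    EXAMPLE_JOINERS,
    EXPECTED_FIELDS,
    annotate_scenario,
    generate_tool_report,
)
from qctags.validation import validate_record


@pytest.mark.parametrize("k", range(1, 11))
def test_scenario_pipeline_reproduces_reference_fields(registry, k):
    """Report → adapter → render matches the reference cells byte-for-byte."""
    record = annotate_scenario(k, registry)
    rendered = render_record(record, DISPLAY, method_joiner=EXAMPLE_JOINERS[k])
    assert rendered == EXPECTED_FIELDS[k]


@pytest.mark.parametrize("k", range(1, 11))
def test_adapter_outputs_validate_error_free(registry, k):
    report = validate_record(annotate_scenario(k, registry), registry, "strict")
    assert report.passed


class TestNcovTools:
    @pytest.mark.parametrize("sites", range(11))
    def test_excess_ambiguity_boundary_sweep(self, registry, sites):
        """The contamination flag appears for >5 ambiguous sites, never at <=5."""
        report = ToolReport("ncov-tools", "1.9.1", metrics={"ambiguous_sites": sites})
        record = adapters.adapt_ncov_tools(report, registry=registry)
        contaminated = any(t.curie == "GENEPIO:0100569" for t in record.issues)
        assert contaminated == (sites > 5)
        if sites <= 5:
            assert not record.has_qc_tags()  # methods-only record

    def test_frameshift_flag_emits_excess_frameshift_issue(self, registry):
        report = ToolReport("ncov-tools", "1.9.1", flags=("frameshift",))
        record = adapters.adapt_ncov_tools(report, registry=registry)
        assert [t.curie for t in record.issues] == ["GENEPIO:0100751"]
        assert record.determinations[0].curie == "GENEPIO:0100566"
        assert record.details.is_not_applicable()

    def test_worsening_ambiguity_never_removes_the_issue(self, registry):
        issue_sets = []
        for sites in range(11):
            report = ToolReport("ncov-tools", "1.9.1", metrics={"ambiguous_sites": sites})
            record = adapters.adapt_ncov_tools(report, registry=registry)
            issue_sets.append({t.curie for t in record.issues})
        for lo, hi in zip(issue_sets, issue_sets[1:]):
            assert lo <= hi

    def test_wrong_tool_report_is_rejected(self, registry):
        with pytest.raises(AdapterMismatchError):
            adapters.adapt_ncov_tools(ToolReport("FastQC"), registry=registry)


class TestSamtoolsDepth:
    def test_locus_at_exactly_min_depth_passes(self, registry):
        report = ToolReport("samtools depth", "1.19",
                            per_locus=(("rpoB", 10.0), ("katG", 10.0)))
        record = adapters.adapt_samtools_depth(
            report, ["rpoB", "katG"], min_depth=10, registry=registry
        )
        assert not record.has_qc_tags()

    def test_low_locus_fails_with_characteristic_mutation_issue(self, registry):
        report = ToolReport("samtools depth", "1.19",
                            per_locus=(("rpoB", 3.0), ("katG", 40.0)))
        record = adapters.adapt_samtools_depth(
            report, ["rpoB", "katG"], min_depth=10, registry=registry
        )
        assert record.determinations[0].curie == "GENEPIO:0100564"
        assert [t.curie for t in record.issues] == ["GENEPIO:0100575"]

    def test_absent_target_locus_raises(self, registry):
        report = ToolReport("samtools depth", "1.19", per_locus=(("rpoB", 30.0),))
        with pytest.raises(MissingLocusError):
            adapters.adapt_samtools_depth(report, ["gyrA"], registry=registry)


class TestFastqc:
    @pytest.mark.parametrize(
        "quality,gc", list(itertools.product(["pass", "warn", "fail"], repeat=2))
    )
    def test_rule_table_over_all_status_combinations(self, registry, quality, gc):
        """Enumerate the two rule-bearing modules' statuses; check against
        the rule-table definition computed independently here."""
        report = ToolReport(
            "FastQC", "0.12.0",
            flags=(f"Per base sequence quality={quality}",
                   f"Per sequence GC content={gc}"),
        )
        record = adapters.adapt_fastqc(report, registry=registry)
        expected_issues = []
        if quality == "fail":
            expected_issues.append("GENEPIO:0100568")
        if gc == "fail":
            expected_issues.append("GENEPIO:0100569")
        if "fail" in (quality, gc):
            expected_det = "GENEPIO:0100564"
        elif "warn" in (quality, gc):
            expected_det = "GENEPIO:0100565"
        else:
            expected_det = "GENEPIO:0100562"
        assert [t.curie for t in record.issues] == expected_issues
        assert record.determinations[0].curie == expected_det

    def test_unknown_module_status_raises(self, registry):
        report = ToolReport("FastQC", "0.12.0", flags=("Per base sequence quality=maybe",))
        with pytest.raises(ReportFormatError):
            adapters.adapt_fastqc(report, registry=registry)


class TestKraken2:
    def test_pure_target_sample_has_no_issues(self, registry):
        report = ToolReport("Kraken2", "2.1.3", taxa=(("SARS-CoV-2", 1.0),))
        record = adapters.adapt_kraken2(report, "SARS-CoV-2", registry=registry)
        assert not record.has_qc_tags()

    def test_offtarget_exactly_at_threshold_passes(self, registry):
        report = ToolReport("Kraken2", "2.1.3",
                            taxa=(("target", 0.8), ("other", 0.2)))
        record = adapters.adapt_kraken2(
            report, "target", max_offtarget_fraction=0.2, registry=registry
        )
        assert not record.has_qc_tags()

    def test_offtarget_above_threshold_flags_signal_to_noise(self, registry):
        report = ToolReport("Kraken2", "2.1.3",
                            taxa=(("SARS-CoV-2", 0.55), ("Homo sapiens", 0.45)))
        record = adapters.adapt_kraken2(report, "SARS-CoV-2", registry=registry)
        assert record.determinations[0].curie == "GENEPIO:0100566"
        assert [t.curie for t in record.issues] == ["GENEPIO:0100574"]

    def test_unclassified_reads_are_excluded_by_default(self, registry):
        report = ToolReport("Kraken2", "2.1.3",
                            taxa=(("target", 0.7), ("unclassified", 0.3)))
        assert not adapters.adapt_kraken2(report, "target", registry=registry).has_qc_tags()
        counted = adapters.adapt_kraken2(
            report, "target", exclude_unclassified=False, registry=registry
        )
        assert counted.has_qc_tags()

    def test_missing_target_taxon_raises(self, registry):
        report = ToolReport("Kraken2", "2.1.3", taxa=(("Homo sapiens", 1.0),))
        with pytest.raises(MissingTaxonError):
            adapters.adapt_kraken2(report, "SARS-CoV-2", registry=registry)


class TestNextclade:
    @pytest.mark.parametrize(
        "flags,n_issues",
        [((), 0), (("low_coverage",), 1), (("high_N",), 1),
         (("low_coverage", "high_N"), 1)],
    )
    def test_coverage_issue_emitted_once(self, registry, flags, n_issues):
        report = ToolReport("Nextclade", "3.1.0", flags=flags)
        record = adapters.adapt_nextclade(report, registry=registry)
        assert len(record.issues) == n_issues
        if n_issues:
            assert record.issues[0].curie == "GENEPIO:0100571"
            assert record.determinations[0].curie == "GENEPIO:0100564"


class TestAssemblyPair:
    def _run(self, registry, contigs, depth):
        quast = ToolReport("Quast", "5.2.0", metrics={"n_contigs": contigs})
        samtools = ToolReport("Samtools", "1.19", metrics={"mean_depth": depth})
        return adapters.adapt_assembly_pair(quast, samtools, registry=registry)

    def test_both_within_limits(self, registry):
        assert not self._run(registry, 150, 45.0).has_qc_tags()

    def test_only_depth_violated(self, registry):
        record = self._run(registry, 150, 15.0)
        assert [t.curie for t in record.issues] == ["GENEPIO:0100570"]
        assert record.determinations[0].curie == "GENEPIO:0100565"

    def test_both_violated_lists_both_issues_with_two_methods(self, registry):
        record = self._run(registry, 400, 15.0)
        assert [t.curie for t in record.issues] == ["GENEPIO:0100568", "GENEPIO:0100570"]
        assert [m.name for m in record.methods] == ["Quast", "Samtools"]
        assert [m.version.raw for m in record.methods] == ["5.2.0", "1.19"]


class TestTaxonomicConsensus:
    CALLS = (("Mash", "2.3", "Taxon A"), ("Kraken2", "2.1.3", "Taxon A"),
             ("FastANI", "1.34", "Taxon A"))

    def test_unanimous_calls_have_no_issues(self, registry):
        record = adapters.adapt_taxonomic_consensus(self.CALLS, registry=registry)
        assert not record.has_qc_tags()
        assert [m.name for m in record.methods] == ["Mash", "Kraken2", "FastANI"]

    def test_wetlab_disagreement_flags_inconsistency(self, registry):
        record = adapters.adapt_taxonomic_consensus(
            self.CALLS, wetlab_id="Taxon B", registry=registry
        )
        assert [t.curie for t in record.issues] == ["GENEPIO:0101038"]
        assert record.determinations[0].curie == "GENEPIO:0100566"

    def test_empty_calls_raise(self, registry):
        with pytest.raises(ValueError):
            adapters.adapt_taxonomic_consensus((), registry=registry)


class TestVadr:
    def test_repeated_alerts_deduplicate_preserving_first_occurrence(self, registry):
        report = ToolReport("VADR", "1.6.3",
                            flags=("fsthicnf", "fstlocnf", "cdsstopn", "fsthicnf"))
        record = adapters.adapt_vadr(report, registry=registry)
        assert [t.curie for t in record.issues] == ["GENEPIO:0100751", "GENEPIO:0100575"]

    def test_unmapped_alert_is_kept_in_details(self, registry):
        report = ToolReport("VADR", "1.6.3", flags=("cdsstopn", "weirdalert"))
        record = adapters.adapt_vadr(report, registry=registry)
        assert "weirdalert" in record.details
        assert [t.curie for t in record.issues] == ["GENEPIO:0100575"]

    def test_no_alerts_is_methods_only(self, registry):
        record = adapters.adapt_vadr(ToolReport("VADR", "1.6.3"), registry=registry)
        assert not record.has_qc_tags()


class TestPhoenix:
    def test_all_success_passes_with_explicit_not_applicable(self, registry):
        record = adapters.adapt_phoenix(
            generate_tool_report("PHoeNIx", 10), registry=registry
        )
        assert record.determinations[0].curie == "GENEPIO:0100563"
        assert record.issues[0].is_not_applicable()
        assert record.details.is_not_applicable()

    def test_one_failing_metric_fails_and_is_named(self, registry):
        metrics = {"overall_status": "FAIL", "coverage_check": "FAILED",
                   "assembly_ratio": "SUCCESS"}
        record = adapters.adapt_phoenix(
            ToolReport("PHoeNIx", "2.1.0", metrics=metrics), registry=registry
        )
        assert record.determinations[0].curie == "GENEPIO:0100564"
        assert "coverage_check" in record.details

    def test_success_with_no_metrics_passes_vacuously_with_note(self, registry):
        record = adapters.adapt_phoenix(
            ToolReport("PHoeNIx", "2.1.0", metrics={"overall_status": "SUCCESS"}),
            registry=registry,
        )
        assert record.determinations[0].curie == "GENEPIO:0100563"
        assert "no individual metric statuses" in record.details

    def test_missing_overall_status_raises(self, registry):
        with pytest.raises(ReportFormatError):
            adapters.adapt_phoenix(ToolReport("PHoeNIx", "2.1.0"), registry=registry)


class TestReportParsers:
    def test_kraken2_report_fractions(self):
        report = adapters.parse_tool_report(
            "Kraken2",
            "45.00\t45\t45\tS\t9606\tHomo sapiens\n"
            "5.00\t5\t5\tU\t0\tunclassified\n"
            "50.00\t50\t50\tS\t2697049\tSARS-CoV-2\n",
        )
        assert dict(report.taxa)["SARS-CoV-2"] == pytest.approx(0.5)
        assert dict(report.taxa)["unclassified"] == pytest.approx(0.05)

    def test_samtools_depth_mean_per_locus(self):
        report = adapters.parse_tool_report(
            "samtools depth", "rpoB\t1\t2\nrpoB\t2\t4\nkatG\t1\t40\n"
        )
        assert dict(report.per_locus) == {"rpoB": 3.0, "katG": 40.0}

    def test_fastqc_summary_rejects_bad_status(self):
        with pytest.raises(ReportFormatError):
            adapters.parse_tool_report("FastQC", "meh\tPer base sequence quality\n")

    def test_quast_contig_key_is_normalized(self):
        report = adapters.parse_tool_report("Quast", "# contigs\t400\n")
        assert report.metrics["n_contigs"] == 400

    def test_taxon_fractions_over_one_are_rejected(self):
        with pytest.raises(ValueError):
            ToolReport("Kraken2", taxa=(("a", 0.7), ("b", 0.7)))

    def test_unsupported_tool_has_no_parser(self):
        with pytest.raises(ReportFormatError):
            adapters.parse_tool_report("mystery-tool", "")


def test_clean_scenario_reports_produce_no_issues(registry):
    for tool in ("ncov-tools", "samtools depth", "FastQC", "Kraken2",
                 "Nextclade", "VADR", "PHoeNIx"):
        report = generate_tool_report(tool, "clean", seed=3)
        if tool == "ncov-tools":
            record = adapters.adapt_ncov_tools(report, registry=registry)
        elif tool == "samtools depth":
            record = adapters.adapt_samtools_depth(
                report, [n for n, _ in report.per_locus], registry=registry
            )
        elif tool == "FastQC":
            record = adapters.adapt_fastqc(report, registry=registry)
        elif tool == "Kraken2":
            record = adapters.adapt_kraken2(report, "SARS-CoV-2", registry=registry)
        elif tool == "Nextclade":
            record = adapters.adapt_nextclade(report, registry=registry)
        elif tool == "VADR":
            record = adapters.adapt_vadr(report, registry=registry)
        else:
            record = adapters.adapt_phoenix(report, registry=registry)
        bad = [t for t in record.issues if not t.is_not_applicable()]
        assert not bad, f"{tool} clean report produced issues"
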