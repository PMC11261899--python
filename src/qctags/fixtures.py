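"""Worked-example scenario fixtures and synthetic collection generation.

Eleven reference scenarios exercise the full vocabulary: consensus-ambiguity
and frameshift flags (ncov-tools), per-locus depth failure (samtools depth),
read-quality/GC contamination (FastQC), off-target reads (Kraken2), genome
coverage (Nextclade), a two-tool assembly assessment (Quast + Samtools), a
cross-method taxonomy conflict (Mash/Kraken2/FastANI + wet lab), multi-alert
viral annotation (VADR), an all-clear pipeline run (PHoeNIx), and a
synthetic-lab-construct mixture study. Scenarios 1–10 carry a machine input
(the tool report in its minimal canonical form) plus the operator-supplied
context that goes in the details cell; scenario 11 is a direct field map.
``expected_fields`` holds the reference rendering of every scenario, used by
the golden tests.

:func:`generate_fixture_collection` makes larger synthetic collections with
controlled determination frequencies for testing aggregation; its default
category weights follow the proportions observed in a production wastewater
surveillance deployment of these tags (61/10/28/1 % across no issues /
minor / flagged / significant), with "significant quality control issues"
as a deployment extension term.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

from . import adapters
from .dialect import DISPLAY, get_dialect, parse_record, render_record
from .errors import QCTagsError, UnknownTermError
from .records import QCRecord, RecordCollection, build_record
from .terms import TermRegistry, default_registry

_D = "; "

#: Reference field values per scenario, in the display dialect. Scenario 7's
#: source record uses comma separators (a real-world deviation from the
#: semicolon rule), preserved here via its ``joiner``.
EXPECTED_FIELDS: dict[int, dict[str, str]] = {
    1: {
        "Quality control method name": "ncov-tools",
        "Quality control method version": "1.9.1",
        "Quality control determination":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]",
        "Quality control issues": "sequence contaminated [GENEPIO:0100569]",
        "Quality control details":
            ">5 ambiguous sites in consensus, sequence indicative of "
            "contamination or real mixed infection",
    },
    2: {
        "Quality control method name": "ncov-tools",
        "Quality control method version": "1.9.1",
        "Quality control determination":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]",
        "Quality control issues": "excess frameshift mutations detected [GENEPIO:0100751]",
        "Quality control details": "Not Applicable [GENEPIO:0001619]",
    },
    3: {
        "Quality control method name": "samtools depth",
        "Quality control method version": "1.19",
        "Quality control determination": "sequence failed quality control [GENEPIO:0100564]",
        "Quality control issues": "low coverage of characteristic mutations [GENEPIO:0100575]",
        "Quality control details": "low DNA concentration",
    },
    4: {
        "Quality control method name": "FastQC",
        "Quality control method version": "0.12.0",
        "Quality control determination": "sequence failed quality control [GENEPIO:0100564]",
        "Quality control issues":
            "low quality sequence [GENEPIO:0100568]; "
            "sequenced contaminated [GENEPIO:0100569]",
        "Quality control details": "contaminated cultured isolate",
    },
    5: {
        "Quality control method name": "Kraken2",
        "Quality control method version": "2.1.3",
        "Quality control determination":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]",
        "Quality control issues": "low signal to noise ratio [GENEPIO:0100574]",
        "Quality control details": "high host reads present from clinical specimen",
    },
    6: {
        "Quality control method name": "Nextclade",
        "Quality control method version": "3.1.0",
        "Quality control determination": "sequence failed quality control [GENEPIO:0100564]",
        "Quality control issues": "low percent genome captured [GENEPIO:0100571]",
        "Quality control details": "Ct value of 35",
    },
    7: {
        "Quality control method name": "Quast, Samtools",
        "Quality control method version": "5.2.0, 1.19",
        "Quality control determination":
            "minor quality control issues identified [GENEPIO:0100565]",
        "Quality control issues":
            "low quality sequence [GENEPIO:0100568]; "
            "low average genome coverage [GENEPIO:0100570]",
        "Quality control details": "high number of samples multiplexed on same sequencing run",
    },
    8: {
        "Quality control method name": "Mash; Kraken2; FastANI",
        "Quality control method version": "2.3; 2.1.3; 1.34",
        "Quality control determination":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]",
        "Quality control issues":
            "taxonomic designation inconsistent across methods [GENEPIO:0101038]",
        "Quality control details":
            "WGS species identification inconsistent across multiple taxonomic "
            "classification methods and inconsistent with identification from "
            "culture. Potential novel species/subspecies and/or underrepresented "
            "in public repository databases.",
    },
    9: {
        "Quality control method name": "VADR",
        "Quality control method version": "1.6.3",
        "Quality control determination":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]",
        "Quality control issues":
            "low percent genome captured [GENEPIO:0100571]; "
            "low coverage of characteristic mutations [GENEPIO:0100575]; "
            "excess frameshift mutations detected [GENEPIO:0100751]",
        "Quality control details": "multi-freeze thaw cycles for specimen. Amplicon drop-out.",
    },
    10: {
        "Quality control method name": "PHoeNIx",
        "Quality control method version": "2.1.0",
        "Quality control determination": "sequence passed quality control [GENEPIO:0100563]",
        "Quality control issues": "Not Applicable [GENEPIO:0001619]",
        "Quality control details": "Not Applicable [GENEPIO:0001619]",
    },
    11: {
        "Quality control method name": "ncov-tools",
        "Quality control method version": "1.9.1",
        "Quality control determination":
            "sequence passed quality control [GENEPIO:0100563]; "
            "sequence failed quality control [GENEPIO:0100564]",
        "Quality control issues":
            "sequence flagged for potential quality control issues [GENEPIO:0100566]; "
            "low coverage of characteristic mutations [GENEPIO:0100575]; "
            "sequence contaminated [GENEPIO:0100569]; "
            "low signal to noise ratio [GENEPIO:0100574]",
        "Quality control details":
            "Various quality control issues may arise depending on the mixture "
            "ratio for each sample and the particular mutations of each "
            "variant. Where one sample was added at a low level the sequence "
            "may pass quality control.",
        "Experimental specimen role type": "synthetic lab construct [GENEPIO:0101039]",
        "Experimental specimen details":
            "two different SARS-CoV-2 variants were mixed at varying ratios "
            "and whole genome sequenced to determine if our QC analysis would "
            "flag them with quality issues and at what level a mixture or "
            "potential contamination would be detected.",
    },
}

#: Method/version-cell joiner used by each scenario's source record.
#: Scenario 7 joins its method and version cells with commas (a real-world
#: deviation) while keeping semicolons in the term lists.
EXAMPLE_JOINERS: dict[int, str] = {k: _D for k in EXPECTED_FIELDS}
EXAMPLE_JOINERS[7] = ", "

SCENARIO_TOOLS: dict[int, tuple[str, ...]] = {
    1: ("ncov-tools",),
    2: ("ncov-tools",),
    3: ("samtools depth",),
    4: ("FastQC",),
    5: ("Kraken2",),
    6: ("Nextclade",),
    7: ("Quast", "Samtools"),
    8: ("Mash", "Kraken2", "FastANI"),
    9: ("VADR",),
    10: ("PHoeNIx",),
}

#: Minimal-canonical-form report text per (scenario, tool).
_REPORT_TEXTS: dict[tuple[int, str], str] = {
    (1, "ncov-tools"): "ambiguous_sites\t7\n",
    (2, "ncov-tools"): "ambiguous_sites\t2\nflags\tframeshift\n",
    (3, "samtools depth"): (
        "rpoB\t761110\t3\nrpoB\t761111\t3\nkatG\t2155168\t40\nkatG\t2155169\t40\n"
    ),
    (4, "FastQC"): (
        "pass\tBasic Statistics\n"
        "fail\tPer base sequence quality\n"
        "fail\tPer sequence GC content\n"
        "warn\tOverrepresented sequences\n"
    ),
    (5, "Kraken2"): (
        "45.00\t450000\t450000\tS\t9606\tHomo sapiens\n"
        "55.00\t550000\t550000\tS\t2697049\tSARS-CoV-2\n"
    ),
    (6, "Nextclade"): "seqName\tqc.flags\nsample1\tlow_coverage;high_N\n",
    (7, "Quast"): "# contigs\t400\nTotal length\t4641652\n",
    (7, "Samtools"): "mean_depth\t15\n",
    (9, "VADR"): "lowsimis\tlow feature similarity\ncdsstopn\tearly stop codon\nfsthicnf\tframeshift\n",
    (10, "PHoeNIx"): "overall_status\tSUCCESS\n"
    + "".join(f"metric_{i:02d}\tSUCCESS\n" for i in range(1, 28)),
}

_TOOL_VERSIONS: dict[tuple[int, str], str] = {
    (1, "ncov-tools"): "1.9.1",
    (2, "ncov-tools"): "1.9.1",
    (3, "samtools depth"): "1.19",
    (4, "FastQC"): "0.12.0",
    (5, "Kraken2"): "2.1.3",
    (6, "Nextclade"): "3.1.0",
    (7, "Quast"): "5.2.0",
    (7, "Samtools"): "1.19",
    (9, "VADR"): "1.6.3",
    (10, "PHoeNIx"): "2.1.0",
}

#: Operator-supplied details per scenario (wet-lab context the tool cannot
#: know). Scenarios 1, 2 and 10 need none: the adapters' mechanical output
#: already matches the reference rendering.
SCENARIO_DETAILS: dict[int, str] = {
    3: EXPECTED_FIELDS[3]["Quality control details"],
    4: EXPECTED_FIELDS[4]["Quality control details"],
    5: EXPECTED_FIELDS[5]["Quality control details"],
    6: EXPECTED_FIELDS[6]["Quality control details"],
    7: EXPECTED_FIELDS[7]["Quality control details"],
    8: EXPECTED_FIELDS[8]["Quality control details"],
    9: EXPECTED_FIELDS[9]["Quality control details"],
}

#: Scenario 8: classifier calls and the wet-lab identification they conflict
#: with (synthetic stand-in organisms; the conflict pattern is what matters).
SCENARIO_8_CALLS = (
    ("Mash", "2.3", "Salmonella enterica"),
    ("Kraken2", "2.1.3", "Salmonella bongori"),
    ("FastANI", "1.34", "Salmonella enterica subsp. arizonae"),
)
SCENARIO_8_WETLAB = "Salmonella enterica subsp. diarizonae"


def generate_tool_report(
    tool: str, scenario: "int | str", seed: int = 0
) -> adapters.ToolReport:
    """Produce the ToolReport for a scenario, or a clean (no-issue) report.

    Scenario reports are fixed reference inputs — identical regardless of
    seed; ``scenario='clean'`` draws unremarkable values seeded by ``seed``.
    """
    if scenario == "clean":
        return _clean_report(tool, random.Random(seed))
    k = int(scenario)
    if k not in SCENARIO_TOOLS:
        raise QCTagsError(f"no tool-report scenario {scenario!r}")
    if tool not in SCENARIO_TOOLS[k]:
        raise QCTagsError(f"scenario {k} does not involve tool {tool!r}")
    if k == 8:
        raise QCTagsError(
            "scenario 8 is a list of classifier calls, not a tool report; "
            "see SCENARIO_8_CALLS"
        )
    text = _REPORT_TEXTS[(k, tool)]
    return adapters.parse_tool_report(tool, text, version=_TOOL_VERSIONS[(k, tool)])


def _clean_report(tool: str, rng: random.Random) -> adapters.ToolReport:
    t = tool.strip().lower()
    if t == "ncov-tools":
        return adapters.ToolReport(
            "ncov-tools", "1.9.1", metrics={"ambiguous_sites": rng.randint(0, 5)}
        )
    if t == "samtools depth":
        loci = (("rpoB", float(rng.randint(10, 200))), ("katG", float(rng.randint(10, 200))))
        return adapters.ToolReport("samtools depth", "1.19", per_locus=loci)
    if t == "fastqc":
        modules = ("Basic Statistics", "Per base sequence quality", "Per sequence GC content")
        return adapters.ToolReport(
            "FastQC", "0.12.0", flags=tuple(f"{m}=pass" for m in modules)
        )
    if t == "kraken2":
        target = round(rng.uniform(0.85, 0.95), 3)
        return adapters.ToolReport(
            "Kraken2", "2.1.3",
            taxa=(("SARS-CoV-2", target), ("unclassified", round(1 - target, 3))),
        )
    if t == "nextclade":
        return adapters.ToolReport("Nextclade", "3.1.0", flags=())
    if t == "quast":
        return adapters.ToolReport(
            "Quast", "5.2.0", metrics={"n_contigs": float(rng.randint(20, 200))}
        )
    if t == "samtools":
        return adapters.ToolReport(
            "Samtools", "1.19", metrics={"mean_depth": round(rng.uniform(30, 120), 1)}
        )
    if t == "vadr":
        return adapters.ToolReport("VADR", "1.6.3", flags=())
    if t == "phoenix":
        metrics = {"overall_status": "SUCCESS"}
        metrics.update({f"metric_{i:02d}": "SUCCESS" for i in range(1, 28)})
        return adapters.ToolReport("PHoeNIx", "2.1.0", metrics=metrics)
    raise QCTagsError(f"unsupported tool {tool!r}")


def annotate_scenario(k: int, registry: TermRegistry | None = None) -> QCRecord:
    """Run scenario ``k`` end to end: report(s) → adapter → record.

    Scenario 11 has no tool run; its record is parsed from the reference
    field map in relaxed mode (it deliberately places a determination-
    category term in the issues field, which validation reports).
    """
    registry = registry or default_registry()
    details = SCENARIO_DETAILS.get(k)
    if k in (1, 2):
        return adapters.adapt_ncov_tools(
            generate_tool_report("ncov-tools", k), details=details, registry=registry
        )
    if k == 3:
        return adapters.adapt_samtools_depth(
            generate_tool_report("samtools depth", k),
            target_loci=["rpoB", "katG"],
            details=details,
            registry=registry,
        )
    if k == 4:
        return adapters.adapt_fastqc(
            generate_tool_report("FastQC", k),
            details=details,
            contaminated_spelling="sequenced contaminated",
            registry=registry,
        )
    if k == 5:
        return adapters.adapt_kraken2(
            generate_tool_report("Kraken2", k),
            target_taxon="SARS-CoV-2",
            details=details,
            registry=registry,
        )
    if k == 6:
        return adapters.adapt_nextclade(
            generate_tool_report("Nextclade", k), details=details, registry=registry
        )
    if k == 7:
        return adapters.adapt_assembly_pair(
            generate_tool_report("Quast", k),
            generate_tool_report("Samtools", k),
            details=details,
            registry=registry,
        )
    if k == 8:
        return adapters.adapt_taxonomic_consensus(
            SCENARIO_8_CALLS, SCENARIO_8_WETLAB, details=details, registry=registry
        )
    if k == 9:
        return adapters.adapt_vadr(
            generate_tool_report("VADR", k), details=details, registry=registry
        )
    if k == 10:
        return adapters.adapt_phoenix(
            generate_tool_report("PHoeNIx", k), registry=registry
        )
    if k == 11:
        return parse_record(EXPECTED_FIELDS[11], DISPLAY, registry, mode="lenient")
    raise QCTagsError(f"no scenario {k}")


def scenario_record(k: int, registry: TermRegistry | None = None) -> QCRecord:
    """The reference record for scenario ``k``, parsed from its field map."""
    registry = registry or default_registry()
    return parse_record(EXPECTED_FIELDS[k], DISPLAY, registry, mode="lenient")


def scenario_collection(registry: TermRegistry | None = None) -> RecordCollection:
    """All 11 reference records as one display-dialect collection."""
    registry = registry or default_registry()
    return RecordCollection(
        records=[scenario_record(k, registry) for k in sorted(EXPECTED_FIELDS)],
        dialect="display",
    )


# -- synthetic collection generation --------------------------------------

#: Determination mix of a production wastewater-surveillance deployment.
DEFAULT_CATEGORY_WEIGHTS = {
    "no quality control issues identified": 0.61,
    "minor quality control issues identified": 0.10,
    "sequence flagged for potential quality control issues": 0.28,
    "significant quality control issues": 0.01,
}

DEFAULT_TOOL_MIX = {
    "FastQC": 0.4,
    "Kraken2": 0.3,
    "ncov-tools": 0.3,
}

_TOOL_VERSION_SUGGESTIONS = {
    "FastQC": "0.12.0",
    "Kraken2": "2.1.3",
    "ncov-tools": "1.9.1",
    "Nextclade": "3.1.0",
    "PHoeNIx": "2.1.0",
    "Quast": "5.2.0",
    "Samtools": "1.19.0",
    "VADR": "1.6.3",
}

_ISSUE_POOL = (
    "low quality sequence",
    "sequence contaminated",
    "low average genome coverage",
    "low percent genome captured",
    "read lengths shorter than expected",
    "sequence amplification artefacts",
    "low signal to noise ratio",
    "low coverage of characteristic mutations",
)

#: Determinations that plausibly carry issue tags in generated records.
_ISSUE_BEARING = {
    "minor quality control issues identified",
    "sequence flagged for potential quality control issues",
    "sequence failed quality control",
    "significant quality control issues",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for synthetic collection generation.

    Weights need not sum to one; they are relative. Unregistered
    determination labels are auto-registered as extension terms, mirroring
    how deployments extend the picklists.
    """

    n_records: int
    category_weights: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    tool_mix: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_TOOL_MIX))
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 0:
            raise ValueError("n_records must be >= 0")
        for name, weights in (("category_weights", self.category_weights),
                              ("tool_mix", self.tool_mix)):
            if not weights or all(w <= 0 for w in weights.values()):
                raise ValueError(f"{name} needs at least one positive weight")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} weights must be nonnegative")


def generate_fixture_collection(
    spec: FixtureSpec, registry: TermRegistry | None = None
) -> RecordCollection:
    """Generate a deterministic synthetic collection.

    Every record passes strict validation; determination frequencies
    converge to ``category_weights`` as ``n_records`` grows. Randomness is
    confined to one ``random.Random(spec.seed)`` instance — no global state.
    """
    registry = registry or default_registry()
    rng = random.Random(spec.seed)
    for label in spec.category_weights:
        try:
            registry.resolve_label(label, "determination")
        except UnknownTermError:
            registry.register_extension(label, "determination")
    cat_labels = list(spec.category_weights)
    cat_weights = [spec.category_weights[c] for c in cat_labels]
    tools = list(spec.tool_mix)
    tool_weights = [spec.tool_mix[t] for t in tools]
    records = []
    for _ in range(spec.n_records):
        det = rng.choices(cat_labels, cat_weights)[0]
        tool = rng.choices(tools, tool_weights)[0]
        version = _TOOL_VERSION_SUGGESTIONS.get(tool, "1.0.0")
        issues: list[str] = []
        if det in _ISSUE_BEARING:
            issues = [rng.choice(_ISSUE_POOL)]
        records.append(
            build_record(
                methods=[(tool, version)],
                determinations=[det],
                issues=issues,
                registry=registry,
                mode="strict",
            )
        )
    return RecordCollection(records=records, dialect="sra_snake")


def render_scenario(k: int, dialect_name: str = "display",
                    registry: TermRegistry | None = None) -> dict[str, str]:
    """Reference rendering of scenario ``k`` in the requested dialect."""
    registry = registry or default_registry()
    return render_record(
        scenario_record(k, registry),
        get_dialect(dialect_name),
        method_joiner=EXAMPLE_JOINERS[k],
    )
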