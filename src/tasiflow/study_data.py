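"""Published summary statistics of the motivating stress smRNA/microarray
study (smRNA reads: DDBJ AB948670-AB967973; microarray: GEO GSE57174).

The raw deposited data are not bundled; what is recorded here are the
study's printed per-library summary counts and headline figures. They
serve two purposes: arithmetic consistency checks (the per-library counts
must reproduce the printed totals) and as the reference scale the
synthetic-data generator emulates.
"""

from __future__ import annotations

#: Mapped smRNA sequence counts per library after structural-RNA
#: elimination (tRNA/rRNA/snoRNA/snRNA removed).
REPORTED_SEQUENCES_PER_LIBRARY = {
    "drought_1-5h": 17_758,
    "drought_6-10h": 10_367,
    "cold_1-5h": 2_104,
    "cold_6-10h": 2_869,
    "salt_1-5h": 10_247,
    "salt_6-10h": 6_148,
    "control": 9_791,
}

#: smRNA locus counts per library under the <150 nt grouping rule.
REPORTED_LOCI_PER_LIBRARY = {
    "drought_1-5h": 4_574,
    "drought_6-10h": 3_138,
    "cold_1-5h": 1_595,
    "cold_6-10h": 2_018,
    "salt_1-5h": 3_645,
    "salt_6-10h": 2_417,
    "control": 4_162,
}

#: Total raw 454 reads across the seven libraries.
REPORTED_TOTAL_READS = 480_343
#: Sequences perfectly matching at least one genomic locus (all libraries).
REPORTED_TOTAL_MAPPED = 59_284
#: Unique signatures across the seven libraries combined.
REPORTED_UNIQUE_SIGNATURES = 12_028
#: Unique signatures represented by a single read ("approximately 39%").
REPORTED_SINGLETONS = 4_681

#: Headline microarray/downstream figures (FDR < 0.075 two-way ANOVA).
REPORTED_DE_GENES = 513
REPORTED_GO_R2 = {"GO:0009414": 0.09, "GO:0048437": 0.387}
REPORTED_COEXPRESSED_GENES = 155
REPORTED_MOTIF_GENES = 64


def sequences_total() -> int:
    """Sum of the per-library mapped sequence counts."""
    return sum(REPORTED_SEQUENCES_PER_LIBRARY.values())


def singleton_percentage() -> float:
    """Percent of unique signatures that are singletons."""
    return 100.0 * REPORTED_SINGLETONS / REPORTED_UNIQUE_SIGNATURES
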