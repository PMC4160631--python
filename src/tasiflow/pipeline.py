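"""End-to-end orchestration: simulate -> smRNA analysis -> expression analysis.

One YAML-serializable config drives a fully deterministic run: the same
config and seed produce byte-identical report files. The report bundle
mirrors the study's summary outputs: a per-library table of retained
sequence and locus counts, the genomic-category composition table,
stress-responsive family calls, the ANOVA/Venn summary, GO-set ratio
correlations, the coexpression gene list and the promoter-motif census.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import expression, io, smrna, synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and synthetic-data parameters of one pipeline run.

    Threshold defaults are the analysis constants used throughout the
    package: <150 nt locus gap, enrichment alpha 1e-3, ANOVA FDR 0.075,
    coexpression alpha 0.01, TGTCTC auxin-response element within 1 kb
    upstream, and the 17-30 nt read-length window.
    """

    seed: int = 0
    outdir: str = "tasiflow_run"
    # thresholds
    gap: int = smrna.LOCUS_GAP
    alpha: float = smrna.ENRICHMENT_ALPHA
    fdr: float = expression.ANOVA_FDR
    coexpr_alpha: float = expression.COEXPRESSION_ALPHA
    motif: str = expression.AUXRE_MOTIF
    window: int = expression.PROMOTER_WINDOW
    min_len: int = smrna.MIN_READ_LEN
    max_len: int = smrna.MAX_READ_LEN
    # synthetic-data knobs (None -> module defaults)
    smrna_depth: int = 10_000
    motif_rate: float = 0.5
    n_genes: int = 1000
    noise_sd: float = 0.25
    anchor_genes: tuple[str, str] = ("ARF3", "ARF4")
    # optional external inputs (paths); when set they replace simulation
    genome_fasta: str | None = None
    genome_gff3: str | None = None
    reads_tsv: str | None = None
    matrix_prefix: str | None = None

    def validate(self) -> None:
        if self.gap < 1 or not (0 < self.alpha < 1) or not (0 < self.fdr < 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.coexpr_alpha < 1):
            raise ValueError("coexpression alpha out of range")
        if self.min_len > self.max_len or self.min_len < 1:
            raise ValueError("bad read-length window")
        for p in (self.genome_fasta, self.genome_gff3, self.reads_tsv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    def config_hash(self) -> str:
        """Hash over the result-affecting fields (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = io.read_yaml(path)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "anchor_genes" in data:
            data["anchor_genes"] = tuple(data["anchor_genes"])
        return cls(**data)


#: Default GO sets planted in the synthetic factorial matrix: effect-pair
#: correlations chosen to emulate an uncorrelated stress-marker category,
#: a moderately co-responding floral-development category and a
#: co-responding auxin-response category.
DEFAULT_GO_RHO = {
    "GO:0009414": 0.30,   # response to water deprivation: R^2 ~ 0.09
    "GO:0048437": 0.622,  # floral organ development: R^2 ~ 0.387
    "GO:0009733": 0.55,   # response to auxin
}
GO_SET_SIZE = 100


def default_expression_spec(n_genes: int, noise_sd: float, seed: int
                            ) -> synth.ExpressionEffectSpec:
    """Factorial spec with three planted GO sets on disjoint gene blocks."""
    ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    go_sets = []
    at = 0
    for term, rho in DEFAULT_GO_RHO.items():
        go_sets.append(synth.GoSetSpec(term, tuple(ids[at:at + GO_SET_SIZE]), rho))
        at += GO_SET_SIZE
    if at > n_genes:
        raise ValueError(f"n_genes must be >= {at} to hold the GO sets")
    # the first two auxin-set genes become the coexpression anchors: both
    # higher in the mutant and lower under drought (co-regulated targets
    # of the same small-RNA pathway), so they co-respond positively
    donors = go_sets[-1].genes[:2]
    return synth.ExpressionEffectSpec(
        n_genes=n_genes,
        genotype_effects={donors[0]: 1.0, donors[1]: 0.9},
        treatment_effects={donors[0]: -1.0, donors[1]: -1.1},
        noise_sd=noise_sd,
        go_sets=tuple(go_sets),
        seed=seed,
    )


@dataclass
class RunReport:
    """Tables produced by one pipeline run, writable as a TSV bundle."""

    library_summary: pd.DataFrame
    composition_counts: pd.DataFrame
    composition_pct: pd.DataFrame
    enrichment: pd.DataFrame
    anova: pd.DataFrame
    venn: dict[str, int]
    go_r2: pd.DataFrame
    coexpressed_genes: list[str]
    motif_gene_count: int
    provenance: dict

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.library_summary.to_csv(out / "library_summary.tsv", sep="\t")
        self.composition_counts.to_csv(out / "composition_counts.tsv", sep="\t")
        self.composition_pct.to_csv(out / "composition_pct.tsv", sep="\t",
                                    float_format="%.4f")
        self.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        self.anova.to_csv(out / "anova.tsv", sep="\t")
        self.go_r2.to_csv(out / "go_r2.tsv", sep="\t", index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary_text())
        io.write_yaml(self.provenance, out / "provenance.yaml")
        return out

    def summary_text(self) -> str:
        lines = ["# tasiflow run summary", ""]
        lines.append("## Sequences and loci per library")
        lines.append(self.library_summary.to_string())
        lines.append("")
        lines.append("## Differential expression (Venn partition)")
        for k, v in sorted(self.venn.items()):
            lines.append(f"{k}: {v}")
        lines.append("")
        lines.append("## GO-set ratio correlations")
        lines.append(self.go_r2.to_string(index=False))
        lines.append("")
        n_sig = int(self.enrichment["significant"].sum())
        lines.append(f"stress-responsive (family, library) calls: {n_sig}")
        lines.append(f"coexpressed genes (both anchors): {len(self.coexpressed_genes)}")
        lines.append(f"genes with promoter motif: {self.motif_gene_count}")
        lines.append("")
        return "\n".join(lines)


def run_pipeline(config: RunConfig, write: bool = True) -> RunReport:
    """Execute every stage on (by default) synthetic inputs.

    Stage order: genome generation and motif planting; smRNA library
    simulation; length filter -> collapse -> exact mapping -> structural
    filter -> classification -> composition -> loci -> miRNA-total
    normalization -> hypergeometric enrichment; expression simulation ->
    75th-percentile normalization -> two-way ANOVA + BH -> Venn -> ratio
    axes -> GO R^2 -> coexpression screen; promoter motif scan. Any stage
    failure aborts with the stage name.
    """
    config.validate()
    stage = "setup"
    try:
        # ---- synthetic or external inputs -------------------------------
        stage = "genome"
        if config.genome_fasta and config.genome_gff3:
            genome = io.read_genome(config.genome_fasta, config.genome_gff3)
        else:
            genome = synth.generate_genome(synth.GenomeSpec(seed=config.seed))
            genome, _motif_truth = synth.plant_promoter_motifs(
                genome, rate=config.motif_rate, motif=config.motif,
                window=config.window, seed=config.seed + 1,
            )

        stage = "smrna-simulation"
        if config.reads_tsv:
            reads = io.read_reads_tsv(config.reads_tsv)
        else:
            reads, _smrna_truth = synth.simulate_smrna_libraries(
                genome,
                synth.SmrnaEffectSpec(depth=config.smrna_depth, seed=config.seed + 2),
            )
        libraries = list(reads)

        # ---- smRNA chain ------------------------------------------------
        stage = "length-filter"
        filtered, removed_by_length = {}, {}
        for lib, rr in reads.items():
            filtered[lib], removed_by_length[lib] = smrna.filter_by_length(
                rr, config.min_len, config.max_len
            )

        stage = "collapse"
        sigs, collapse_summary = smrna.collapse_signatures(filtered)

        stage = "map"
        mapped, unmapped = smrna.map_exact(sigs, genome)

        stage = "structural-filter"
        index = smrna.FeatureIndex(genome.features)
        kept, structural = smrna.filter_structural(mapped, index)

        stage = "classify"
        categories = smrna.classify_all(kept, index)
        composition = smrna.tabulate_composition(kept, categories, libraries)

        stage = "loci"
        n_loci = smrna.loci_per_library(kept, libraries, gap=config.gap)

        stage = "enrichment"
        fams = smrna.family_counts(kept, categories, index, libraries)
        totals = smrna.mirna_totals(composition)
        enrichment = smrna.call_stress_responsive(
            smrna.enrich_families(fams, totals, synth.CONTROL_LIBRARY),
            alpha=config.alpha,
        )

        # per-library sequence counts after all filters (reads retained)
        retained_reads = composition.counts.sum(axis=0)
        library_summary = pd.DataFrame(
            {
                "raw_reads": pd.Series({l: len(reads[l]) for l in libraries}),
                "removed_by_length": pd.Series(removed_by_length),
                "retained_reads": retained_reads,
                "n_loci": n_loci,
            }
        )
        # conservation: removed + unmapped + structural + retained == raw
        lost = {l: 0 for l in libraries}
        for s in unmapped + structural:
            for l, c in s.counts.items():
                lost[l] += c
        recon = (
            library_summary["removed_by_length"]
            + pd.Series(lost)
            + library_summary["retained_reads"]
        )
        if not (recon == library_summary["raw_reads"]).all():
            raise AssertionError("read-count conservation violated")

        # ---- expression chain -------------------------------------------
        stage = "expression-simulation"
        if config.matrix_prefix:
            matrix_df, design = io.read_matrix_tsv(config.matrix_prefix)
            go_memberships: dict[str, tuple[str, ...]] = {}
        else:
            spec = default_expression_spec(config.n_genes, config.noise_sd,
                                           config.seed + 3)
            fm, truth = synth.simulate_expression_matrix(spec)
            matrix_df, design = fm.intensities, fm.design
            go_memberships = dict(truth.go_memberships)
            # the coexpression anchors are two auxin-response-set genes, so
            # their profiles carry planted effects other set members share
            donors = go_memberships.get("GO:0009733", tuple(matrix_df.index))[:2]
            rename = dict(zip(donors, config.anchor_genes))
            matrix_df = matrix_df.rename(index=rename)
            go_memberships = {
                term: tuple(rename.get(g, g) for g in genes)
                for term, genes in go_memberships.items()
            }

        stage = "normalize"
        norm = expression.percentile75_normalize(matrix_df)

        stage = "anova"
        anova = expression.add_fdr(expression.two_way_anova(norm, design),
                                   threshold=config.fdr)
        venn = expression.venn_partition(anova, threshold=config.fdr)

        stage = "ratio-axes"
        ratios = expression.ratio_axes(norm, design)
        go_rows = []
        for term, members in go_memberships.items():
            gc = expression.go_scatter_r2(ratios, term, list(members))
            go_rows.append((term, gc.n_genes, gc.r2, gc.sign))
        go_r2 = pd.DataFrame(go_rows, columns=["term", "n_genes", "r2", "sign"])

        stage = "coexpression"
        coex = expression.coexpression_screen(norm, config.anchor_genes,
                                              alpha=config.coexpr_alpha)
        coexpressed = sorted(coex.index[coex["coexpressed"]])

        stage = "motif-scan"
        hits = expression.scan_promoter_motif(genome, config.motif, config.window)
        motif_gene_count = len(expression.genes_with_motif(hits))

    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "total_reads": int(sum(len(r) for r in reads.values())),
        "unique_signatures": collapse_summary.total_unique,
        "singletons": collapse_summary.singletons,
    }
    report = RunReport(
        library_summary=library_summary,
        composition_counts=composition.counts,
        composition_pct=composition.percentages,
        enrichment=enrichment,
        anova=anova,
        venn=venn,
        go_r2=go_r2,
        coexpressed_genes=coexpressed,
        motif_gene_count=motif_gene_count,
        provenance=provenance,
    )
    if write:
        report.write(config.outdir)
    return report
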