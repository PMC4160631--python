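# Methods

## Scope and data model

The package implements a two-armed analysis of the tasiRNA-ARF pathway
under abiotic stress: a small-RNA sequencing arm (read classification,
locus clustering, enrichment testing across seven treatment libraries) and
a factorial expression arm (2 × 2 × 3 genotype × treatment microarray
analysis with downstream screens). All coordinates are 0-based half-open
internally; GFF3 (1-based closed) and BED (0-based half-open) conversions
happen only at the I/O boundary and are round-trip tested.

## Synthetic data

Real libraries at the scale of the motivating study depend on deposited
454 and array data, so every stage is exercised on synthetic data with
ground truth. What the generator emulates — and what it does not — bounds
what passing tests show about real data.

**Genome.** Two 200 kb chromosomes of i.i.d. uniform ACGT sequence carry
ten feature classes (protein-coding genes, TE genes, pseudogenes,
intergenic TEs, MIRNA, TAS, tRNA, rRNA, snoRNA, snRNA) placed by rejection
sampling with a 60 nt margin; placement failure names the crowded
category. Each MIRNA locus stores one 21-nt mature sequence cut from the
locus; each TAS locus stores a phase-start coordinate. Random sequence of
this size makes ≥17-nt reads map essentially uniquely, so classification
is identifiable; it has none of the repeat structure, paralogy or
compositional bias of a real genome, which is why the mapper and
classifier are additionally verified against brute-force oracles rather
than only on simulations.

**smRNA libraries.** Seven libraries (drought/cold/salt × two pooled time
windows + nonstressed control), default depth 10,000 reads each. Each
library is one multinomial draw over {expressed loci, degradation
fragments, intergenic background}: class base shares at fold-change 1 are
miRNA 0.30, ta-siRNA 0.12, protein-coding 0.08, TE gene 0.04, pseudogene
0.03, intergenic TE 0.04, structural RNAs 0.08 combined, split equally
over the loci of a class. Treatment fold-changes multiply a class's (or a
single locus's) share in both libraries of that treatment — defaults plant
the studied signal, ta-siRNA reduction under drought (×0.25) and high
salinity (×0.3) — and the unassigned remainder is absorbed by background
reads, so a fold-change shows up as the intended count ratio against the
control rather than being renormalized away. The degradation fraction
(sense-strand fragments starting uniformly within protein-coding genes)
is elevated under drought (0.25) and salt (0.22) versus cold (0.12) and
control (0.10), reproducing the observed stress-dependent rise of
sense-strand percentages. MIRNA loci emit their mature 21-mer; TAS loci
emit 21-mers on the fixed register from the stored phase-start (register
choice is ours; real ta-siRNA registers are set by the miRNA cleavage
site); all other sources draw lengths from a discretized normal over
17–30 nt peaked at 22. Not modeled: sequencing error, homopolymer
artifacts, adapter chemistry, 5'-nucleotide biases — the analysis chain
under test assumes perfect-match reads, as does the exact mapper.

**Factorial matrices.** log₂ intensity of gene *g* in sample
(x_g, x_t, rep) is `baseline + gen·x_g + trt·x_t + int·x_g·x_t + ε`,
ε ~ N(0, 0.25²) by default, baseline ~ N(8, 1.5²); the matrix stores
2^(log₂), hence strictly positive intensities. GO sets plant a bivariate
normal (genotype, treatment) effect pair with correlation ρ and axis SD 1
on their member genes; explicit per-gene effects override set draws. The
planted ρ controls only the *true* effect correlation; the observed ratio
R² shrinks with noise and with sampling (SD of r ≈ (1−ρ²)/√n), which the
tolerance in the recovery tests reflects. One caveat found during
development and kept as a documented behavior: if planted effects cover
most of the array, each sample's 75th percentile itself tracks the
effects and distorts the ratio axes; recovery tests therefore embed the
300-gene set in a 2000-gene, mostly-null matrix, matching how a GO
category sits on a real platform.

**Promoter motifs and Ct tables.** Motif planting writes TGTCTC (reading
sense on the gene's strand) at a random feature-free position within 1 kb
upstream of a Bernoulli(rate) subset of genes, protecting previous
plantings; genes without a valid position are skipped and reported. Ct
tables are generated from known fold-changes (one PCR cycle = factor 2),
so ΔΔCt recovery is exact when noise is zero.

## Small-RNA chain

Reads are length-filtered to 17–30 nt before collapsing. Collapsing
conserves counts (asserted); a singleton is a signature with total count 1
across all libraries. The exact mapper reports every perfect-match
occurrence of the sequence (plus strand) and of its reverse complement
(minus strand, leftmost coordinate); candidates come from a 17-mer seed
index and are verified by full comparison, and equality with a naive
both-strand scan is asserted in the tests. Ambiguous-base reads are
flagged invalid, never silently dropped.

Structural filtering removes a signature if *any* hit overlaps a
tRNA/rRNA/snoRNA/snRNA feature on either strand — conservative by design,
preventing structural fragments from leaking into other categories.
Classification assigns exactly one category per signature by precedence
miRNA > ta-siRNA > protein-coding sense > protein-coding antisense >
TE gene > pseudogene > intergenic TE > other intergenic, evaluated over
all hits (dedicated smRNA loci first, so the categories partition reads
the way mutually exclusive composition wedges require); any ≥1 nt overlap
counts as "mapped to" a feature. Locus clustering is strand-agnostic
single-linkage over hit intervals with a strict gap rule: intervals merge
when `next.start − prev.end < 150`; a gap of exactly 150 nt separates
loci.

Normalization divides family counts by the library's total miRNA count
(raw ratio, no ×10⁶ scaling): the miRNA fraction is stable against the
degradation fragments that inflate other categories under stress. The
enrichment test is the exact hypergeometric tail (scipy's `hypergeom`,
no normal approximation): draws n = the stress library's miRNA total,
population N = stress + control totals, successes K = pooled family
count, p_up = P(X ≥ k), p_down = P(X ≤ k), flagged strictly below
α = 10⁻³. The 2×2 margin construction is isolated in one function so
alternatives are swappable. Count-level simulation puts the per-test
false-flag rate near 2 × 10⁻³ under the null — close to nominal for a
discrete test — and because one simulated run yields only ~170 tests,
rate checks aggregate several replicate simulations.

## Expression chain

75th-percentile normalization divides each sample by its own
linear-interpolation quantile (numpy's default), making the result
bit-reproducible and idempotent. The two-way ANOVA is the closed-form
balanced 2×2 decomposition on log₂ intensities, vectorized across genes —
sums of squares are orthogonal in a balanced design, so factor order is
irrelevant; the model includes the interaction term, but significance
calls use only the two main-effect q-values, matching the two reported
contrasts. Zero residual variance is flagged degenerate (NaN p) rather
than propagated. The statsmodels OLS fit of the same model serves as the
independent cross-check in the tests, never as the implementation. BH-FDR
(statsmodels `multipletests`) is applied per factor across genes at
threshold 0.075. Log₂ is our choice of analysis scale: the source
protocol is silent on the transform, and log₂ matches the ratio axes.

Ratio axes use sums of replicate cell means exactly as defined
(x = log₂((rdr6-NS + rdr6-D)/(WT-NS + WT-D)), y analogously for
treatment); with no interaction and no noise these reduce to the planted
genotype and treatment effects, which is what makes ρ² recovery a clean
oracle. Genes with a zero cell mean are excluded and logged; GO R² needs
≥3 finite member pairs and reports zero-variance axes as undefined rather
than NaN.

The coexpression screen computes Pearson r against each anchor across
≥10 conditions with the exact two-sided t-test (t = r√((m−2)/(1−r²))),
requiring r > 0 and p < 0.01 for *both* anchors; constant profiles are
excluded with a log entry and anchors are excluded from their own result.
The motif scan extracts ≤1 kb upstream of the annotated CDS start (not
the transcription start) on the gene's strand, truncated at chromosome
edges, and searches case-insensitively for the motif and its reverse
complement; a sense-only flag preserves the narrower single-orientation
reading. ΔΔCt follows the standard definition with the calibrator fixed
at relative expression 1.

## Pipeline and determinism

A single YAML-serializable `RunConfig` carries every threshold (defaults:
gap 150 nt, enrichment α 10⁻³, FDR 0.075, coexpression α 0.01, motif
TGTCTC, window 1000 nt, lengths 17–30 nt) and the synthetic-data knobs;
CLI flags override config values. Every generator and stage is a pure
function of config + seed, and report files are written with fixed float
formatting, so identical runs are byte-identical — asserted by comparing
full report bundles. Each filtering stage logs removed/retained counts
and the pipeline asserts read-count conservation
(raw = length-removed + unmapped + structural + retained) per library.
The default pipeline names two auxin-set genes as the coexpression
anchors and plants them with concordant effects (higher in the mutant,
lower under drought), mirroring two co-regulated targets of one small-RNA
pathway.

## Problem sizes and known limitations

Tests and the acceptance script run at reduced but statistically adequate
scales chosen once: depth 10,000 reads/library for enrichment recovery
and null-rate checks (4 replicate simulations ≈ 670 tests), 2000 genes
for type-I and FDR calibration (20 replicates for the mean FDP), 300-gene
GO sets in 2000-gene matrices for R² recovery (6 replicates averaged in
the acceptance script), and depth 2000/400 genes for the byte-identity
determinism check. The headline dataset-level numbers of the motivating
study (total reads, unique signatures, DE-gene counts) depend on its
deposited data and are not reproduced here; what is checked instead is
the internal arithmetic of its published summary table and the recovery
behavior of each method at these operating points. Mismatch-tolerant
alignment, phasing-score discovery of novel TAS loci, miRNA target
prediction and GO enrichment testing are out of scope.
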