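"""Synthetic data with full ground truth.

Everything downstream of this module (read classification, locus clustering,
enrichment testing, factorial ANOVA, motif scanning) is validated against
data generated here: a small annotated genome, seven stress/control smRNA
libraries with planted fold-changes and mRNA-degradation fractions, a
genotype x treatment factorial expression matrix with planted effects and
GO-set effect correlations, promoters with planted auxin-response elements,
and qPCR Ct tables.

Every generator is a pure function of its spec (including the seed): the
same spec yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Genome model
# ---------------------------------------------------------------------------

#: Annotation classes carried by the toy genome.
FEATURE_CATEGORIES = (
    "protein_coding",
    "TE_gene",
    "pseudogene",
    "intergenic_TE",
    "MIRNA",
    "TAS",
    "tRNA",
    "rRNA",
    "snoRNA",
    "snRNA",
)

#: Housekeeping/structural RNA classes eliminated before smRNA analysis.
STRUCTURAL_CATEGORIES = ("tRNA", "rRNA", "snoRNA", "snRNA")

# Typical feature spans (nt) used when placing features on the toy genome.
_FEATURE_LENGTHS = {
    "protein_coding": 1200,
    "TE_gene": 800,
    "pseudogene": 600,
    "intergenic_TE": 400,
    "MIRNA": 120,
    "TAS": 320,
    "tRNA": 80,
    "rRNA": 160,
    "snoRNA": 100,
    "snRNA": 140,
}

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

MATURE_MIRNA_LEN = 21  #: mature miRNAs and phased ta-siRNAs are 21 nt


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed genomic interval, 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    ftype: str
    #: mature 21-nt sequence for MIRNA loci (on the feature strand)
    mature_seq: str | None = None
    #: first nucleotide of the 21-nt phasing register for TAS loci
    phase_start: int | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for {self.name}: [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Chromosome sequences plus a typed feature table."""

    sequences: dict[str, str]
    features: list[Feature]

    def features_of(self, *ftypes: str) -> list[Feature]:
        want = set(ftypes)
        return [f for f in self.features if f.ftype in want]

    def feature_sequence(self, feat: Feature) -> str:
        """Spliced-out feature sequence on the feature's own strand."""
        s = self.sequences[feat.chrom][feat.start:feat.end]
        return s if feat.strand == "+" else reverse_complement(s)

    def subsequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        s = self.sequences[chrom][start:end]
        return s if strand == "+" else reverse_complement(s)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the toy annotated genome.

    Defaults give 2 x 200 kb chromosomes carrying all ten annotation
    classes with room to spare: large enough that random 17-30 nt reads
    map uniquely, small enough for exact mapping in seconds.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_features: dict[str, int] = field(
        default_factory=lambda: {
            "protein_coding": 40,
            "TE_gene": 8,
            "pseudogene": 6,
            "intergenic_TE": 10,
            "MIRNA": 20,
            "TAS": 8,
            "tRNA": 8,
            "rRNA": 4,
            "snoRNA": 4,
            "snRNA": 4,
        }
    )
    #: minimum clearance between placed features (nt)
    margin: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1000:
            raise ValueError("need >=1 chromosome of >=1000 nt")
        for cat, n in self.n_features.items():
            if cat not in FEATURE_CATEGORIES:
                raise ValueError(f"unknown feature category {cat!r}")
            if n < 0:
                raise ValueError(f"negative count for {cat}")
        footprint = sum(
            (_FEATURE_LENGTHS[c] + self.margin) * n for c, n in self.n_features.items()
        )
        if footprint > 0.7 * self.n_chromosomes * self.chrom_length:
            raise ValueError(
                f"feature footprint {footprint} nt does not fit "
                f"{self.n_chromosomes} x {self.chrom_length} nt with margins"
            )


_NAME_PREFIX = {
    "protein_coding": "GENE",
    "TE_gene": "TEG",
    "pseudogene": "PSD",
    "intergenic_TE": "ITE",
    "MIRNA": "MIR",
    "TAS": "TAS",
    "tRNA": "TRNA",
    "rRNA": "RRNA",
    "snoRNA": "SNO",
    "snRNA": "SNR",
}


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Generate random chromosome sequences and place non-overlapping features.

    Placement is rejection sampling against previously placed intervals
    (inflated by ``spec.margin``); after a bounded number of failures the
    crowded category is named in the error. MIRNA loci store the 21-nt
    mature sequence cut from the locus; TAS loci store a phase-start
    coordinate for 21-nt phased emission.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sequences = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=spec.chrom_length))
        for i in range(spec.n_chromosomes)
    }
    chroms = list(sequences)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    features: list[Feature] = []

    def overlaps(chrom: str, start: int, end: int) -> bool:
        m = spec.margin
        return any(start - m < e and s < end + m for s, e in placed[chrom])

    counter = 0
    for cat in FEATURE_CATEGORIES:  # fixed order => deterministic
        n = spec.n_features.get(cat, 0)
        length = _FEATURE_LENGTHS[cat]
        for i in range(n):
            for attempt in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, spec.chrom_length - length))
                if not overlaps(chrom, start, start + length):
                    break
            else:
                raise RuntimeError(
                    f"could not place feature {i + 1}/{n} of category {cat!r}: "
                    "genome too crowded"
                )
            counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"{_NAME_PREFIX[cat]}-{counter:04d}"
            mature = None
            phase = None
            if cat == "MIRNA":
                off = int(rng.integers(10, length - MATURE_MIRNA_LEN - 10))
                raw = sequences[chrom][start + off:start + off + MATURE_MIRNA_LEN]
                mature = raw if strand == "+" else reverse_complement(raw)
            elif cat == "TAS":
                phase = start + int(rng.integers(0, 30))
            placed[chrom].append((start, start + length))
            features.append(
                Feature(name, chrom, start, start + length, strand, cat, mature, phase)
            )
    features.sort(key=lambda f: (f.chrom, f.start))
    return AnnotatedGenome(sequences, features)


# ---------------------------------------------------------------------------
# smRNA library simulation
# ---------------------------------------------------------------------------

#: The seven sequencing libraries: three stresses x two pooled time windows
#: plus the nonstressed control.
DEFAULT_LIBRARIES = (
    "drought_1-5h",
    "drought_6-10h",
    "cold_1-5h",
    "cold_6-10h",
    "salt_1-5h",
    "salt_6-10h",
    "control",
)

CONTROL_LIBRARY = "control"


def stress_of(library: str) -> str | None:
    """Treatment name for a library label, or None for the control."""
    return None if library == CONTROL_LIBRARY else library.rsplit("_", 1)[0]


def _default_length_dist() -> dict[int, float]:
    # unimodal over 17-30 nt, peaked at 21-24 as in plant smRNA libraries
    w = {l: math.exp(-0.5 * ((l - 22.0) / 2.2) ** 2) for l in range(17, 31)}
    z = sum(w.values())
    return {l: v / z for l, v in w.items()}


@dataclass(frozen=True)
class SmrnaEffectSpec:
    """Planted structure of the seven smRNA libraries.

    ``class_shares`` are the expected fractions of each library's depth
    emitted by each annotation class at fold-change 1; fold-changes
    multiply a class's (or single locus's) share in the two libraries of
    the named treatment, with the unassigned remainder absorbed by random
    intergenic background reads. ``degradation_fraction`` is the per-library
    share of sense-strand mRNA fragments, elevated under drought and high
    salinity where mRNA turnover products accumulate.
    """

    libraries: tuple[str, ...] = DEFAULT_LIBRARIES
    depth: int = 10_000
    class_shares: dict[str, float] = field(
        default_factory=lambda: {
            "MIRNA": 0.30,
            "TAS": 0.12,
            "protein_coding": 0.08,
            "TE_gene": 0.04,
            "pseudogene": 0.03,
            "intergenic_TE": 0.04,
            "tRNA": 0.03,
            "rRNA": 0.03,
            "snoRNA": 0.01,
            "snRNA": 0.01,
        }
    )
    #: (treatment -> {class-or-locus-name -> multiplier}); applied to both
    #: pooled time-window libraries of the treatment
    fold_changes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "drought": {"TAS": 0.25},
            "salt": {"TAS": 0.3},
            "cold": {},
        }
    )
    degradation_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "drought_1-5h": 0.25,
            "drought_6-10h": 0.25,
            "cold_1-5h": 0.12,
            "cold_6-10h": 0.12,
            "salt_1-5h": 0.22,
            "salt_6-10h": 0.22,
            "control": 0.10,
        }
    )
    length_dist: dict[int, float] = field(default_factory=_default_length_dist)
    seed: int = 0

    def validate(self, genome: AnnotatedGenome) -> None:
        if self.depth <= 0:
            raise ValueError("library depth must be > 0")
        for lib, d in self.degradation_fraction.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"degradation fraction for {lib} outside [0,1]")
        if any(v < 0 for v in self.class_shares.values()):
            raise ValueError("class shares must be nonnegative")
        locus_names = {f.name for f in genome.features}
        for trt, fmap in self.fold_changes.items():
            for key, mult in fmap.items():
                if key not in FEATURE_CATEGORIES and key not in locus_names:
                    raise ValueError(
                        f"fold-change key {key!r} ({trt}) is neither a feature "
                        "category nor a locus in the genome"
                    )
                if mult < 0:
                    raise ValueError(f"negative fold-change for {key}")
        if not all(17 <= l <= 30 for l in self.length_dist):
            raise ValueError("read lengths must lie in 17-30 nt")


@dataclass
class SmrnaTruth:
    """Ground truth of a simulated smRNA library set.

    ``locus_counts``: sampled reads per locus per library (index also holds
    the ``degradation`` and ``background`` pseudo-sources); columns sum to
    the requested depth. ``expected_share``: the multinomial probabilities
    used. ``locus_category``: locus name -> annotation class.
    """

    locus_counts: pd.DataFrame
    expected_share: pd.DataFrame
    locus_category: pd.Series


def _sample_lengths(rng, dist: dict[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(dist))
    p = np.array([dist[l] for l in lengths], dtype=float)
    return rng.choice(lengths, size=n, p=p / p.sum())


def simulate_smrna_libraries(
    genome: AnnotatedGenome, eff: SmrnaEffectSpec
) -> tuple[dict[str, list[str]], SmrnaTruth]:
    """Sample the seven read multisets plus ground truth.

    Each library draws ``depth`` reads multinomially over {expressed loci,
    degradation fragments, intergenic background} with locus probabilities
    scaled by the treatment's fold-changes. MIRNA loci emit their stored
    21-nt mature sequence; TAS loci emit 21-nt reads cut in phase from the
    stored phase-start; all other sources draw lengths from the library-wide
    length distribution. Degradation fragments start uniformly on the sense
    strand of protein-coding genes.
    """
    eff.validate(genome)
    rng = np.random.default_rng(eff.seed)

    loci = [f for f in genome.features if f.ftype in eff.class_shares]
    by_class: dict[str, list[Feature]] = {}
    for f in loci:
        by_class.setdefault(f.ftype, []).append(f)
    # equal split of a class's share over its loci
    base_share = {}
    for cat, share in eff.class_shares.items():
        members = by_class.get(cat, [])
        for f in members:
            base_share[f.name] = share / len(members)
    cat_of = {f.name: f.ftype for f in loci}
    feat_of = {f.name: f for f in loci}
    names = [f.name for f in loci]

    genes = genome.features_of("protein_coding")
    gene_w = np.array([g.length for g in genes], dtype=float)
    gene_p = gene_w / gene_w.sum() if len(genes) else None

    # precompute intergenic sampling: positions not covered by any feature
    cover = {c: np.zeros(len(s), dtype=bool) for c, s in genome.sequences.items()}
    for f in genome.features:
        cover[f.chrom][f.start:f.end] = True
    free = {c: np.flatnonzero(~m) for c, m in cover.items()}

    sources = names + ["degradation", "background"]
    prob = pd.DataFrame(0.0, index=sources, columns=list(eff.libraries))
    for lib in eff.libraries:
        trt = stress_of(lib)
        fmap = eff.fold_changes.get(trt, {}) if trt else {}
        for name in names:
            mult = fmap.get(name, fmap.get(cat_of[name], 1.0))
            prob.loc[name, lib] = base_share[name] * mult
        d = eff.degradation_fraction.get(lib, 0.0)
        prob.loc["degradation", lib] = d
        bg = 1.0 - prob[lib].sum()
        if bg < -1e-9:
            raise ValueError(
                f"library {lib}: shares exceed 1 (fold-changes too large "
                "for the configured class shares)"
            )
        prob.loc["background", lib] = max(bg, 0.0)

    counts = pd.DataFrame(0, index=sources, columns=list(eff.libraries), dtype=int)
    reads: dict[str, list[str]] = {}
    max_len = max(eff.length_dist)
    for lib in eff.libraries:
        p = prob[lib].to_numpy()
        c = rng.multinomial(eff.depth, p / p.sum())
        counts[lib] = c
        lib_reads: list[str] = []
        for src, n in zip(sources, c):
            if n == 0:
                continue
            if src == "degradation":
                idx = rng.choice(len(genes), size=n, p=gene_p)
                lens = _sample_lengths(rng, eff.length_dist, n)
                for gi, L in zip(idx, lens):
                    g = genes[gi]
                    L = int(min(L, g.length))
                    s = int(rng.integers(g.start, g.end - L + 1))
                    lib_reads.append(genome.subsequence(g.chrom, s, s + L, g.strand))
            elif src == "background":
                lens = _sample_lengths(rng, eff.length_dist, n)
                for L in lens:
                    for _ in range(50):
                        chrom = list(genome.sequences)[int(rng.integers(len(genome.sequences)))]
                        pos = int(free[chrom][rng.integers(len(free[chrom]))])
                        if pos + L <= len(genome.sequences[chrom]) and not cover[chrom][
                            pos:pos + int(L)
                        ].any():
                            break
                    strand = "+" if rng.random() < 0.5 else "-"
                    lib_reads.append(genome.subsequence(chrom, pos, pos + int(L), strand))
            else:
                f = feat_of[src]
                if f.ftype == "MIRNA":
                    lib_reads.extend([f.mature_seq] * n)
                elif f.ftype == "TAS":
                    k_max = (f.end - MATURE_MIRNA_LEN - f.phase_start) // MATURE_MIRNA_LEN
                    ks = rng.integers(0, k_max + 1, size=n)
                    for k in ks:
                        s = f.phase_start + int(k) * MATURE_MIRNA_LEN
                        lib_reads.append(
                            genome.subsequence(f.chrom, s, s + MATURE_MIRNA_LEN, f.strand)
                        )
                else:
                    lens = _sample_lengths(rng, eff.length_dist, n)
                    for L in lens:
                        L = int(min(L, f.length))
                        s = int(rng.integers(f.start, f.end - L + 1))
                        lib_reads.append(genome.subsequence(f.chrom, s, s + L, f.strand))
        assert len(lib_reads) == int(c.sum())
        reads[lib] = lib_reads

    truth = SmrnaTruth(
        locus_counts=counts,
        expected_share=prob,
        locus_category=pd.Series(cat_of, name="category"),
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Factorial expression simulation
# ---------------------------------------------------------------------------

GENOTYPES = ("WT", "rdr6")
TREATMENTS = ("nonstressed", "drought")


@dataclass(frozen=True)
class GoSetSpec:
    """A GO gene set whose member genes get correlated effect pairs.

    (genotype, treatment) log2 effects of member genes are drawn from a
    bivariate normal with standard deviation ``effect_sd`` on each axis and
    correlation ``rho`` between axes — the planted analogue of a gene
    category responding jointly to the mutation and to the stress.
    """

    term: str
    genes: tuple[str, ...]
    rho: float
    effect_sd: float = 1.0

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"|rho| must be <= 1 for {self.term}")


@dataclass(frozen=True)
class ExpressionEffectSpec:
    """Planted structure of the genotype x treatment factorial matrix.

    log2 intensity of gene g in sample (x_g, x_t, rep) is
    ``baseline_g + gen_g*x_g + trt_g*x_t + int_g*x_g*x_t + N(0, noise_sd)``
    with x_g = 1 for the rdr6 genotype and x_t = 1 for drought; the matrix
    holds 2**(log2 intensity), so all intensities are positive.
    """

    n_genes: int = 1000
    n_replicates: int = 3
    #: per-gene planted log2 effects; genes absent from a map get 0
    genotype_effects: dict[str, float] = field(default_factory=dict)
    treatment_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    go_sets: tuple[GoSetSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per cell")
        gene_ids = set(self.gene_ids())
        for gs in self.go_sets:
            missing = set(gs.genes) - gene_ids
            if missing:
                raise ValueError(f"GO set {gs.term} references unknown genes {sorted(missing)[:3]}")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


@dataclass
class FactorialMatrix:
    """Genes x samples intensity matrix with its factorial sample sheet."""

    intensities: pd.DataFrame  # genes x samples, > 0
    design: pd.DataFrame  # sample -> genotype, treatment, replicate

    def __post_init__(self):
        if not self.intensities.columns.equals(self.design.index):
            raise ValueError("sample sheet does not match matrix columns")


@dataclass
class ExpressionTruth:
    effects: pd.DataFrame  # gene -> genotype, treatment, interaction (log2)
    go_memberships: dict[str, tuple[str, ...]]
    go_rho: dict[str, float]


def simulate_expression_matrix(
    eff: ExpressionEffectSpec,
) -> tuple[FactorialMatrix, ExpressionTruth]:
    """Draw the 2 x 2 x r factorial matrix plus per-gene true effects."""
    eff.validate()
    rng = np.random.default_rng(eff.seed)
    genes = eff.gene_ids()
    n = len(genes)

    effects = pd.DataFrame(
        0.0, index=genes, columns=["genotype", "treatment", "interaction"]
    )
    for gs in eff.go_sets:
        cov = gs.effect_sd ** 2 * np.array([[1.0, gs.rho], [gs.rho, 1.0]])
        # svd method tolerates the singular cov at |rho| = 1
        pairs = rng.multivariate_normal([0.0, 0.0], cov, size=len(gs.genes), method="svd")
        effects.loc[list(gs.genes), "genotype"] = pairs[:, 0]
        effects.loc[list(gs.genes), "treatment"] = pairs[:, 1]
    # explicit per-gene effects take precedence over GO-set draws
    for col, m in (
        ("genotype", eff.genotype_effects),
        ("treatment", eff.treatment_effects),
        ("interaction", eff.interaction_effects),
    ):
        for g, v in m.items():
            if g not in effects.index:
                raise ValueError(f"effect for unknown gene {g!r}")
            effects.loc[g, col] = v

    baseline = rng.normal(eff.baseline_log2_mean, eff.baseline_log2_sd, size=n)
    samples, cols = [], {}
    for gt in GENOTYPES:
        for trt in TREATMENTS:
            for rep in range(1, eff.n_replicates + 1):
                sid = f"{gt}_{'NS' if trt == 'nonstressed' else 'D'}_r{rep}"
                samples.append((sid, gt, trt, rep))
                xg = 1.0 if gt == "rdr6" else 0.0
                xt = 1.0 if trt == "drought" else 0.0
                log2 = (
                    baseline
                    + effects["genotype"].to_numpy() * xg
                    + effects["treatment"].to_numpy() * xt
                    + effects["interaction"].to_numpy() * xg * xt
                    + rng.normal(0.0, eff.noise_sd, size=n)
                )
                cols[sid] = np.exp2(log2)
    design = pd.DataFrame(
        [(gt, trt, rep) for _, gt, trt, rep in samples],
        index=pd.Index([s for s, *_ in samples], name="sample"),
        columns=["genotype", "treatment", "replicate"],
    )
    mat = FactorialMatrix(pd.DataFrame(cols, index=pd.Index(genes, name="gene")), design)
    truth = ExpressionTruth(
        effects=effects,
        go_memberships={gs.term: gs.genes for gs in eff.go_sets},
        go_rho={gs.term: gs.rho for gs in eff.go_sets},
    )
    return mat, truth


def planted_factorial(
    n_genes: int,
    n_genotype: int,
    n_treatment: int,
    n_both: int,
    effect_log2: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ExpressionEffectSpec:
    """Spec with blocks of genotype-only / treatment-only / both-effect genes.

    The first ``n_genotype`` genes respond to the mutation only, the next
    ``n_treatment`` to the stress only, the next ``n_both`` to both; the
    remainder are null.
    """
    if n_genotype + n_treatment + n_both > n_genes:
        raise ValueError("planted blocks exceed n_genes")
    ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    g_eff = {g: effect_log2 for g in ids[:n_genotype]}
    t_eff = {g: effect_log2 for g in ids[n_genotype:n_genotype + n_treatment]}
    both = ids[n_genotype + n_treatment:n_genotype + n_treatment + n_both]
    g_eff.update({g: effect_log2 for g in both})
    t_eff.update({g: effect_log2 for g in both})
    return ExpressionEffectSpec(
        n_genes=n_genes,
        genotype_effects=g_eff,
        treatment_effects=t_eff,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Promoter motif planting
# ---------------------------------------------------------------------------

@dataclass
class MotifTruth:
    """Planted motif copies: (gene, chrom, genomic start, upstream offset)."""

    plantings: pd.DataFrame  # gene, chrom, start, offset_upstream
    skipped: list[str]  # genes whose upstream window could not take the motif


def plant_promoter_motifs(
    genome: AnnotatedGenome,
    rate: float,
    motif: str = "tgtctc",
    window: int = 1000,
    seed: int = 0,
) -> tuple[AnnotatedGenome, MotifTruth]:
    """Write ``motif`` upstream of a Bernoulli(rate) subset of genes.

    The motif is written so it reads in the given orientation on the gene's
    coding strand, at a random position within ``window`` nt upstream of the
    gene start that does not fall inside another annotated feature or a
    previously planted copy. Genes without such a position are skipped and
    reported in the truth.
    """
    motif = motif.upper()
    if not set(motif) <= set("ACGT"):
        raise ValueError("motif must be over ACGT")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs = {c: list(s) for c, s in genome.sequences.items()}

    cover = {c: np.zeros(len(s), dtype=bool) for c, s in genome.sequences.items()}
    for f in genome.features:
        cover[f.chrom][f.start:f.end] = True

    rows, skipped = [], []
    m = len(motif)
    for gene in genome.features_of("protein_coding"):
        if rng.random() >= rate:
            continue
        if gene.strand == "+":
            lo, hi = max(0, gene.start - window), gene.start
        else:
            lo, hi = gene.end, min(len(seqs[gene.chrom]), gene.end + window)
        # candidate placements fully inside the window and outside features
        cands = [
            p
            for p in range(lo, hi - m + 1)
            if not cover[gene.chrom][p:p + m].any()
        ]
        if not cands:
            skipped.append(gene.name)
            continue
        pos = int(cands[int(rng.integers(len(cands)))])
        text = motif if gene.strand == "+" else reverse_complement(motif)
        seqs[gene.chrom][pos:pos + m] = list(text)
        cover[gene.chrom][pos:pos + m] = True  # protect from later plantings
        offset = gene.start - (pos + m) if gene.strand == "+" else pos - gene.end
        rows.append((gene.name, gene.chrom, pos, offset))

    out = AnnotatedGenome({c: "".join(s) for c, s in seqs.items()}, list(genome.features))
    truth = MotifTruth(
        plantings=pd.DataFrame(rows, columns=["gene", "chrom", "start", "offset_upstream"]),
        skipped=skipped,
    )
    return out, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    fold_changes: dict[str, float],
    calibrator: str,
    base_target_ct: float = 24.0,
    base_reference_ct: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table in which each sample's true expression is a known fold of
    the calibrator's (fold 1.0 for the calibrator itself): one PCR cycle
    equals a factor of two, so Ct_target drops by log2(fold)."""
    if calibrator not in fold_changes:
        raise ValueError("calibrator must appear in fold_changes")
    rng = np.random.default_rng(seed)
    rows = []
    for sample, fold in fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold for {sample} must be > 0")
        tgt = base_target_ct - math.log2(fold) + rng.normal(0, noise_sd)
        ref = base_reference_ct + rng.normal(0, noise_sd)
        rows.append((sample, tgt, ref))
    return pd.DataFrame(rows, columns=["sample", "target_ct", "reference_ct"]).set_index(
        "sample"
    )
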