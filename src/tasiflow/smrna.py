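"""Small-RNA sequencing analysis.

The read-processing chain: length-filter raw reads to 17-30 nt, collapse to
unique signatures with per-library counts, map each signature exactly to
both strands of the genome, eliminate signatures touching structural RNAs
(tRNA/rRNA/snoRNA/snRNA), classify the rest by genomic category, cluster
mapped positions into loci (<150 nt gap rule), normalize family counts
against each library's total miRNA count, and call stress-responsive
families with an exact hypergeometric tail test at alpha = 1e-3.

Coordinates are 0-based half-open throughout; GFF3 conversion happens at
the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .synth import (
    AnnotatedGenome,
    Feature,
    STRUCTURAL_CATEGORIES,
    reverse_complement,
)

logger = logging.getLogger(__name__)

MIN_READ_LEN = 17
MAX_READ_LEN = 30
LOCUS_GAP = 150  #: hits closer than this many nt belong to the same locus
ENRICHMENT_ALPHA = 1e-3

#: Classification categories in precedence order: dedicated smRNA loci
#: first, then genic, then repeat/intergenic fallbacks. A multi-mapping
#: signature takes the highest-precedence category among all its hits.
CATEGORY_PRECEDENCE = (
    "miRNA",
    "ta-siRNA",
    "protein_coding_sense",
    "protein_coding_antisense",
    "TE_gene",
    "pseudogene",
    "intergenic_TE",
    "other_intergenic",
)


@dataclass
class MappedSignature:
    """A unique smRNA sequence with its exact genomic hits and counts."""

    sequence: str
    hits: list[tuple[str, int, str]]  # (chrom, 0-based start, strand)
    counts: dict[str, int] = field(default_factory=dict)  # library -> reads
    invalid: bool = False  # non-ACGT sequence

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mapped(self) -> bool:
        return bool(self.hits)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SmrnaLocus:
    chrom: str
    start: int
    end: int  # half-open
    members: tuple[int, ...]  # indices into the hit list that built the locus


# ---------------------------------------------------------------------------
# Collapsing and length filtering
# ---------------------------------------------------------------------------

def filter_by_length(
    reads: list[str], min_len: int = MIN_READ_LEN, max_len: int = MAX_READ_LEN
) -> tuple[list[str], int]:
    """Keep reads within [min_len, max_len]; return (kept, n_removed)."""
    kept = [r for r in reads if min_len <= len(r) <= max_len]
    removed = len(reads) - len(kept)
    if removed:
        logger.info("length filter removed %d of %d reads", removed, len(reads))
    return kept, removed


@dataclass
class CollapseSummary:
    total_reads: int
    total_unique: int
    singletons: int

    @property
    def singleton_fraction(self) -> float | None:
        """Share of unique signatures seen exactly once overall; None when
        there are no signatures."""
        if self.total_unique == 0:
            return None
        return self.singletons / self.total_unique


def collapse_signatures(
    reads_per_library: dict[str, list[str]]
) -> tuple[list[MappedSignature], CollapseSummary]:
    """Collapse identical reads into unique signatures with per-library counts.

    Count conservation holds: the summed counts equal the number of input
    reads. A singleton is a signature with total count 1 across all
    libraries.
    """
    table: dict[str, MappedSignature] = {}
    total = 0
    for lib, reads in reads_per_library.items():
        for r in reads:
            total += 1
            sig = table.get(r)
            if sig is None:
                sig = table[r] = MappedSignature(r, hits=[], counts={})
            sig.counts[lib] = sig.counts.get(lib, 0) + 1
    sigs = [table[s] for s in sorted(table)]
    singletons = sum(1 for s in sigs if s.total_count == 1)
    return sigs, CollapseSummary(total, len(sigs), singletons)


# ---------------------------------------------------------------------------
# Exact mapping
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _prefix_index(chroms: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    """Positions of every k-mer on the plus strand of every chromosome."""
    idx: dict[str, list[tuple[str, int]]] = {}
    for chrom, s in chroms.items():
        for i in range(len(s) - k + 1):
            idx.setdefault(s[i:i + k], []).append((chrom, i))
    return idx


def map_exact(
    signatures: list[MappedSignature], genome: AnnotatedGenome
) -> tuple[list[MappedSignature], list[MappedSignature]]:
    """Report every perfect-match occurrence of each signature.

    Plus-strand hits are occurrences of the sequence itself; minus-strand
    hits are occurrences of its reverse complement, reported at the
    occurrence's leftmost genomic coordinate. Returns (mapped, unmapped);
    sequences with ambiguous bases are flagged invalid and returned with
    the unmapped.

    Candidate positions come from a seed index of MIN_READ_LEN-mers and
    are verified by full-sequence comparison, so the result is identical
    to a naive scan of both strands (asserted by the test suite).
    """
    chroms = {c: s.upper() for c, s in genome.sequences.items()}
    k = min([MIN_READ_LEN] + [len(s.sequence) for s in signatures if s.sequence])
    index = _prefix_index(chroms, k)

    def occurrences(seq: str) -> list[tuple[str, int]]:
        return [
            (chrom, i)
            for chrom, i in index.get(seq[:k], ())
            if chroms[chrom].startswith(seq, i)
        ]

    mapped, unmapped = [], []
    for sig in signatures:
        seq = sig.sequence.upper()
        if not seq or not set(seq) <= set("ACGT"):
            sig.invalid = True
            sig.hits = []
            unmapped.append(sig)
            continue
        rc = reverse_complement(seq)
        hits = [(c, i, "+") for c, i in occurrences(seq)]
        hits += [(c, i, "-") for c, i in occurrences(rc)]
        sig.hits = sorted(hits)
        (mapped if hits else unmapped).append(sig)
    logger.info("mapped %d signatures, %d unmapped", len(mapped), len(unmapped))
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Feature overlap index
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Interval lookup of annotated features, strand kept on the feature."""

    def __init__(self, features: list[Feature]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        """Features overlapping [start, end) by >= 1 nt, any strand."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda f: (f.start, f.name))


def filter_structural(
    signatures: list[MappedSignature], index: FeatureIndex
) -> tuple[list[MappedSignature], list[MappedSignature]]:
    """Eliminate signatures with any hit overlapping a structural-RNA feature.

    One structural hit disqualifies the whole signature regardless of its
    other hits (either strand): conservative, keeps rRNA fragments from
    leaking into downstream categories. Raises if a signature was never
    mapped.
    """
    kept, removed = [], []
    structural = set(STRUCTURAL_CATEGORIES)
    for sig in signatures:
        if not sig.hits:
            raise ValueError(
                f"signature {sig.sequence[:12]}... has no hits: map before filtering"
            )
        bad = any(
            f.ftype in structural
            for chrom, start, _ in sig.hits
            for f in index.overlapping(chrom, start, start + sig.length)
        )
        (removed if bad else kept).append(sig)
    logger.info("structural filter removed %d of %d signatures",
                len(removed), len(signatures))
    return kept, removed


# ---------------------------------------------------------------------------
# Locus clustering
# ---------------------------------------------------------------------------

def cluster_loci(
    intervals: list[tuple[str, int, int]], gap: int = LOCUS_GAP
) -> list[SmrnaLocus]:
    """Single-linkage merge of hit intervals separated by < ``gap`` nt.

    Strand-agnostic; intervals are (chrom, start, end) half-open. Two
    intervals on the same chromosome join the same locus when
    ``next.start - prev.end < gap`` (a gap of exactly ``gap`` keeps them
    apart). Overlapping intervals always merge.
    """
    for chrom, s, e in intervals:
        if s < 0 or e < s:
            raise ValueError(f"bad interval ({chrom}, {s}, {e})")
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i][0], intervals[i][1]))
    loci: list[SmrnaLocus] = []
    cur: list[int] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for i in order:
        chrom, s, e = intervals[i]
        if cur and chrom == cur_chrom and s - cur_end < gap:
            cur.append(i)
            cur_end = max(cur_end, e)
        else:
            if cur:
                loci.append(SmrnaLocus(cur_chrom, cur_start, cur_end, tuple(cur)))
            cur, cur_chrom, cur_start, cur_end = [i], chrom, s, e
    if cur:
        loci.append(SmrnaLocus(cur_chrom, cur_start, cur_end, tuple(cur)))
    return loci


def loci_per_library(
    signatures: list[MappedSignature], libraries: list[str], gap: int = LOCUS_GAP
) -> pd.Series:
    """Number of smRNA loci per library: cluster the hit intervals of the
    signatures present (count > 0) in each library."""
    out = {}
    for lib in libraries:
        ivals = [
            (chrom, start, start + sig.length)
            for sig in signatures
            if sig.counts.get(lib, 0) > 0
            for chrom, start, _ in sig.hits
        ]
        out[lib] = len(cluster_loci(ivals, gap))
    return pd.Series(out, name="n_loci")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _hit_category(chrom: str, start: int, end: int, strand: str,
                  index: FeatureIndex) -> str:
    best = "other_intergenic"
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    for f in index.overlapping(chrom, start, end):
        if f.ftype == "MIRNA":
            cat = "miRNA"
        elif f.ftype == "TAS":
            cat = "ta-siRNA"
        elif f.ftype == "protein_coding":
            cat = ("protein_coding_sense" if strand == f.strand
                   else "protein_coding_antisense")
        elif f.ftype in ("TE_gene", "pseudogene", "intergenic_TE"):
            cat = f.ftype
        else:
            continue  # structural features are handled by filter_structural
        if rank[cat] < rank[best]:
            best = cat
    return best


def classify_signature(sig: MappedSignature, index: FeatureIndex) -> str:
    """Assign the single highest-precedence category over all hits."""
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    best = "other_intergenic"
    for chrom, start, strand in sig.hits:
        cat = _hit_category(chrom, start, start + sig.length, strand, index)
        if rank[cat] < rank[best]:
            best = cat
    return best


def classify_all(
    signatures: list[MappedSignature], index: FeatureIndex
) -> pd.Series:
    return pd.Series(
        {s.sequence: classify_signature(s, index) for s in signatures},
        name="category",
    )


@dataclass
class CompositionTable:
    """Per-library read counts and percentages by genomic category."""

    counts: pd.DataFrame  # categories x libraries
    percentages: pd.DataFrame
    empty_libraries: list[str]


def tabulate_composition(
    signatures: list[MappedSignature],
    categories: pd.Series,
    libraries: list[str],
) -> CompositionTable:
    """Read-count composition per library; percentages sum to 100 except in
    flagged empty libraries (all-zero rows are kept, percentages NaN)."""
    acc = {cat: {lib: 0 for lib in libraries} for cat in CATEGORY_PRECEDENCE}
    for sig in signatures:
        row = acc[categories[sig.sequence]]
        for lib, c in sig.counts.items():
            if lib in row:
                row[lib] += c
    counts = pd.DataFrame(acc).T.reindex(index=list(CATEGORY_PRECEDENCE),
                                         columns=libraries).astype(int)
    totals = counts.sum(axis=0)
    empty = [lib for lib in libraries if totals[lib] == 0]
    if empty:
        logger.warning("libraries with no classified reads: %s", empty)
    pct = counts / totals.replace(0, np.nan) * 100.0
    return CompositionTable(counts, pct, empty)


def family_counts(
    signatures: list[MappedSignature],
    categories: pd.Series,
    index: FeatureIndex,
    libraries: list[str],
) -> pd.DataFrame:
    """Per-family read counts for miRNA and ta-siRNA signatures.

    The family of a signature is the MIRNA/TAS locus it maps into (the
    first such locus in coordinate order if several).
    """
    rows: dict[str, dict[str, int]] = {}
    for sig in signatures:
        if categories[sig.sequence] not in ("miRNA", "ta-siRNA"):
            continue
        fam = None
        for chrom, start, _ in sig.hits:
            for f in index.overlapping(chrom, start, start + sig.length):
                if f.ftype in ("MIRNA", "TAS"):
                    fam = f.name
                    break
            if fam:
                break
        if fam is None:
            continue
        row = rows.setdefault(fam, {})
        for lib, c in sig.counts.items():
            row[lib] = row.get(lib, 0) + c
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=libraries)
    return df.fillna(0).astype(int).sort_index()


# ---------------------------------------------------------------------------
# Normalization against total miRNA counts
# ---------------------------------------------------------------------------

def mirna_totals(composition: CompositionTable) -> pd.Series:
    """Total miRNA-classified read count per library, the normalization
    denominator that corrects for library-specific degradation content."""
    return composition.counts.loc["miRNA"]


def normalize_by_mirna(
    counts: pd.DataFrame, totals: pd.Series, control_library: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize family counts by each library's total miRNA count.

    Returns (normalized, relative) where normalized = count / miRNA-total
    and relative = normalized / normalized[control]. A family absent from
    the control has an undefined (NaN) relative value, never infinity.
    """
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"miRNA total is zero in libraries: {list(zero.index)}")
    norm = counts / totals
    ctrl = norm[control_library].replace(0, np.nan)
    relative = norm.div(ctrl, axis=0)
    return norm, relative


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """Exact hypergeometric tail probabilities for a family count.

    Population of N miRNA-fraction reads (stress + control pooled), K of
    them from the family; n reads drawn (the stress library); k of the
    draws from the family. Returns (p_up, p_down) = (P(X >= k), P(X <= k)).
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    p_up = float(hypergeom.sf(k - 1, N, K, n))
    p_down = float(hypergeom.cdf(k, N, K, n))
    return min(p_up, 1.0), min(p_down, 1.0)


def enrich_families(
    counts: pd.DataFrame,
    totals: pd.Series,
    control_library: str,
) -> pd.DataFrame:
    """Per-(family, stress library) enrichment against the control.

    2x2 margins: draws n = the stress library's miRNA total with k family
    reads among them; population N = stress + control miRNA totals with
    K = pooled family reads.
    """
    if control_library not in counts.columns:
        raise ValueError(f"control library {control_library!r} missing")
    rows = []
    n_ctrl = int(totals[control_library])
    for lib in counts.columns:
        if lib == control_library:
            continue
        n = int(totals[lib])
        N = n + n_ctrl
        for fam, row in counts.iterrows():
            k = int(row[lib])
            K = k + int(row[control_library])
            p_up, p_down = hypergeom_enrichment(k, n, K, N)
            rows.append((fam, lib, k, n, K, N, p_up, p_down))
    return pd.DataFrame(
        rows, columns=["family", "library", "k", "n", "K", "N", "p_up", "p_down"]
    )


def call_stress_responsive(
    results: pd.DataFrame, alpha: float = ENRICHMENT_ALPHA
) -> pd.DataFrame:
    """Flag families per stress library at the strict threshold p < alpha.

    direction is 'up' when p_up < alpha, 'down' when p_down < alpha, ''
    otherwise; a p equal to alpha is not significant.
    """
    out = results.copy()
    up = out["p_up"] < alpha
    down = out["p_down"] < alpha
    out["significant"] = up | down
    out["direction"] = np.where(up, "up", np.where(down, "down", ""))
    return out
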