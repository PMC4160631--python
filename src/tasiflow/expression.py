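"""Factorial microarray analysis and downstream screens.

Covers the expression half of the pipeline: 75th-percentile array
normalization, gene-wise two-way ANOVA (genotype x treatment with
interaction) on log2 intensities with Benjamini-Hochberg FDR per factor,
the Venn partition of differentially expressed genes, the two-axis log2
ratio scatter (mutant-vs-wild-type against drought-vs-nonstressed) with
GO-set restricted R-squared, a Pearson coexpression screen anchored on
two genes, promoter scanning for a cis-element, and delta-delta-Ct
relative quantification for qPCR tables.

The ANOVA is computed in closed form for the balanced 2x2 layout (sums of
squares are orthogonal, so factor order is irrelevant), vectorized across
genes; the statsmodels OLS fit of the same model is used as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import (
    AnnotatedGenome,
    FactorialMatrix,
    GENOTYPES,
    TREATMENTS,
    reverse_complement,
)

logger = logging.getLogger(__name__)

ANOVA_FDR = 0.075
COEXPRESSION_ALPHA = 0.01
AUXRE_MOTIF = "tgtctc"
PROMOTER_WINDOW = 1000


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def percentile75_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) by its own 75th percentile.

    The quantile uses linear interpolation between order statistics, so the
    result is bit-reproducible; afterwards every sample's 75th percentile
    equals 1. Raises on nonpositive intensities, listing offending cells.
    """
    bad = matrix.le(0)
    if bad.to_numpy().any():
        cells = [(g, s) for g, s in zip(*np.nonzero(bad.to_numpy()))]
        named = [(matrix.index[g], matrix.columns[s]) for g, s in cells[:5]]
        raise ValueError(f"nonpositive intensities at {named}"
                         + (" ..." if len(cells) > 5 else ""))
    q75 = matrix.quantile(0.75, axis=0, interpolation="linear")
    return matrix / q75


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

def _cell_masks(design: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    masks = {}
    for gt in GENOTYPES:
        for trt in TREATMENTS:
            m = ((design["genotype"] == gt) & (design["treatment"] == trt)).to_numpy()
            masks[(gt, trt)] = m
    return masks


def two_way_anova(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise balanced two-way ANOVA on log2 intensities.

    Model: log2(y) ~ genotype + treatment + genotype:treatment, each term
    F-tested on 1 df against the pooled within-cell residual. Requires a
    balanced design with >= 2 replicates per cell (orthogonal sums of
    squares, so the decomposition is order-independent). Genes with zero
    residual variance are flagged ``degenerate`` with NaN p-values rather
    than propagating division by zero.
    """
    if not matrix.columns.equals(design.index):
        raise ValueError("design index must match matrix columns")
    masks = _cell_masks(design)
    reps = {k: int(m.sum()) for k, m in masks.items()}
    r = next(iter(reps.values()))
    if r < 2 or any(v != r for v in reps.values()):
        raise ValueError(f"need a balanced design with >=2 replicates/cell, got {reps}")

    y = np.log2(matrix.to_numpy(dtype=float))
    n_genes, n_samples = y.shape
    cell_means = {k: y[:, m].mean(axis=1) for k, m in masks.items()}
    grand = y.mean(axis=1)

    gt_mean = {
        gt: (cell_means[(gt, TREATMENTS[0])] + cell_means[(gt, TREATMENTS[1])]) / 2
        for gt in GENOTYPES
    }
    trt_mean = {
        trt: (cell_means[(GENOTYPES[0], trt)] + cell_means[(GENOTYPES[1], trt)]) / 2
        for trt in TREATMENTS
    }
    # balanced orthogonal decomposition: each factor mean covers 2r samples
    ss_g = 2 * r * sum((gt_mean[gt] - grand) ** 2 for gt in GENOTYPES)
    ss_t = 2 * r * sum((trt_mean[t] - grand) ** 2 for t in TREATMENTS)
    ss_int = r * sum(
        (cell_means[(gt, t)] - gt_mean[gt] - trt_mean[t] + grand) ** 2
        for gt in GENOTYPES
        for t in TREATMENTS
    )
    ss_resid = sum(
        ((y[:, m] - cell_means[k][:, None]) ** 2).sum(axis=1)
        for k, m in masks.items()
    )
    df_resid = n_samples - 4
    ms_resid = ss_resid / df_resid
    degenerate = ms_resid <= 0

    out = pd.DataFrame(index=matrix.index.copy())
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, ss in (("genotype", ss_g), ("treatment", ss_t),
                         ("interaction", ss_int)):
            F = np.where(degenerate, np.nan, ss / ms_resid)
            out[f"F_{name}"] = F
            out[f"p_{name}"] = np.where(
                degenerate, np.nan, stats.f.sf(F, 1, df_resid)
            )
    out["degenerate"] = degenerate
    if degenerate.any():
        logger.warning("%d genes with zero residual variance flagged degenerate",
                       int(degenerate.sum()))
    return out


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_fdr(anova: pd.DataFrame, threshold: float = ANOVA_FDR) -> pd.DataFrame:
    """Attach per-factor BH q-values and FDR flags for the two main effects.

    Significance calls use the main-effect q-values only; the interaction p
    is reported but not thresholded.
    """
    out = anova.copy()
    for factor in ("genotype", "treatment"):
        p = out[f"p_{factor}"].to_numpy()
        ok = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        if ok.any():
            q[ok] = bh_fdr(p[ok])
        out[f"q_{factor}"] = q
        out[f"sig_{factor}"] = q < threshold
    return out


def venn_partition(anova: pd.DataFrame, threshold: float = ANOVA_FDR) -> dict[str, int]:
    """Partition flagged genes into genotype-only / treatment-only / both."""
    g = anova[f"q_genotype"] < threshold
    t = anova[f"q_treatment"] < threshold
    return {
        "rdr6_only": int((g & ~t).sum()),
        "drought_only": int((~g & t).sum()),
        "both": int((g & t).sum()),
    }


# ---------------------------------------------------------------------------
# Ratio scatter and GO-set correlation
# ---------------------------------------------------------------------------

def ratio_axes(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Two orthogonal log2 contrast axes from the four cell means.

    x = log2((rdr6 nonstressed + rdr6 drought) / (WT nonstressed + WT drought))
    y = log2((WT drought + rdr6 drought) / (WT nonstressed + rdr6 nonstressed))

    Replicate means are computed per cell first, then summed. Genes with a
    zero cell mean are excluded and logged.
    """
    masks = _cell_masks(design)
    m = {k: matrix.loc[:, mask].mean(axis=1) for k, mask in masks.items()}
    wns, wd = m[("WT", "nonstressed")], m[("WT", "drought")]
    rns, rd = m[("rdr6", "nonstressed")], m[("rdr6", "drought")]
    ok = (wns > 0) & (wd > 0) & (rns > 0) & (rd > 0)
    if (~ok).any():
        logger.warning("excluding %d genes with a zero cell mean", int((~ok).sum()))
    x = np.log2((rns + rd)[ok] / (wns + wd)[ok])
    y = np.log2((wd + rd)[ok] / (wns + rns)[ok])
    return pd.DataFrame({"x": x, "y": y})


@dataclass
class GoCorrelation:
    term: str
    n_genes: int
    r2: float | None  # None when an axis has zero variance
    sign: int  # sign of the Pearson correlation (0 when undefined)


def go_scatter_r2(ratios: pd.DataFrame, term: str, members: list[str]) -> GoCorrelation:
    """Squared Pearson correlation of the two ratio axes within a GO set."""
    sub = ratios.loc[ratios.index.intersection(members)].dropna()
    if len(sub) < 3:
        raise ValueError(f"GO set {term}: need >= 3 member genes with finite "
                         f"ratios, have {len(sub)}")
    x, y = sub["x"].to_numpy(), sub["y"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("GO set %s: zero variance on an axis, R^2 undefined", term)
        return GoCorrelation(term, len(sub), None, 0)
    r = stats.pearsonr(x, y).statistic
    return GoCorrelation(term, len(sub), float(r * r), int(np.sign(r)))


# ---------------------------------------------------------------------------
# Coexpression screen
# ---------------------------------------------------------------------------

def coexpression_screen(
    compendium: pd.DataFrame,
    anchors: tuple[str, str] = ("ARF3", "ARF4"),
    alpha: float = COEXPRESSION_ALPHA,
) -> pd.DataFrame:
    """Genes positively coexpressed with BOTH anchor genes.

    For every gene, the Pearson correlation with each anchor across the
    compendium's conditions plus the two-sided t-test p-value; a gene
    passes when r > 0 and p < alpha for both anchors. Constant-profile
    genes are excluded (correlation undefined) and logged; anchors are
    excluded from their own result.
    """
    m = compendium.shape[1]
    if m < 10:
        raise ValueError(f"compendium needs >= 10 conditions, has {m}")
    for a in anchors:
        if a not in compendium.index:
            raise ValueError(f"anchor gene {a!r} not in compendium")
    x = compendium.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("excluding %d constant-profile genes", int(constant.sum()))

    z = x - x.mean(axis=1, keepdims=True)
    out = pd.DataFrame(index=compendium.index)
    passing = ~constant
    for a in anchors:
        av = z[compendium.index.get_loc(a)]
        a_sd = av.std()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (z @ av) / (m * sd * a_sd)
            r = np.clip(r, -1.0, 1.0)
            t = r * np.sqrt((m - 2) / np.maximum(1.0 - r ** 2, 1e-300))
            p = 2.0 * stats.t.sf(np.abs(t), m - 2)
        out[f"r_{a}"] = np.where(constant, np.nan, r)
        out[f"p_{a}"] = np.where(constant, np.nan, p)
        passing &= (out[f"r_{a}"] > 0) & (out[f"p_{a}"] < alpha)
    out["coexpressed"] = passing
    out.loc[list(anchors), "coexpressed"] = False
    return out


# ---------------------------------------------------------------------------
# Promoter motif scan
# ---------------------------------------------------------------------------

def extract_promoters(
    genome: AnnotatedGenome, window: int = PROMOTER_WINDOW
) -> dict[str, str]:
    """Up to ``window`` nt immediately upstream of each protein-coding
    gene's start, oriented 5'->3' on the gene's strand (so the string ends
    at the start codon), truncated at the chromosome edge."""
    out = {}
    for g in genome.features_of("protein_coding"):
        chrom_len = len(genome.sequences[g.chrom])
        if g.strand == "+":
            lo, hi = max(0, g.start - window), g.start
            out[g.name] = genome.subsequence(g.chrom, lo, hi, "+")
        else:
            lo, hi = g.end, min(chrom_len, g.end + window)
            out[g.name] = genome.subsequence(g.chrom, lo, hi, "-")
    return out


def scan_sequence(seq: str, motif: str, both_orientations: bool = True
                  ) -> list[tuple[int, str]]:
    """Case-insensitive occurrences of motif (and optionally its reverse
    complement) in seq, as (offset, orientation) with orientation in
    {'sense', 'antisense'}."""
    s, mo = seq.upper(), motif.upper()
    targets = [("sense", mo)]
    if both_orientations:
        targets.append(("antisense", reverse_complement(mo)))
    hits = []
    for orient, pat in targets:
        i = s.find(pat)
        while i != -1:
            hits.append((i, orient))
            i = s.find(pat, i + 1)
    return sorted(hits)


def scan_promoter_motif(
    genome: AnnotatedGenome,
    motif: str = AUXRE_MOTIF,
    window: int = PROMOTER_WINDOW,
    both_orientations: bool = True,
) -> pd.DataFrame:
    """Scan every gene's upstream window for the motif.

    Returns one row per hit: gene, offset within the oriented promoter
    string (0 = most upstream position of the window), upstream distance
    from the motif's 3' end to the gene start, and orientation.
    """
    promoters = extract_promoters(genome, window)
    rows = []
    for gene, prom in promoters.items():
        for off, orient in scan_sequence(prom, motif, both_orientations):
            dist = len(prom) - off - len(motif)
            rows.append((gene, off, dist, orient))
    return pd.DataFrame(rows, columns=["gene", "offset", "upstream_distance",
                                       "orientation"])


def genes_with_motif(hits: pd.DataFrame) -> list[str]:
    return sorted(hits["gene"].unique())


# ---------------------------------------------------------------------------
# Delta-delta-Ct
# ---------------------------------------------------------------------------

def delta_delta_ct(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ct must have one row per sample with finite ``target_ct`` and
    ``reference_ct`` columns. dCt = target - reference; ddCt = dCt -
    dCt(calibrator); relative expression = 2**(-ddCt), 1 for the
    calibrator by construction.
    """
    for col in ("target_ct", "reference_ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
        if not np.isfinite(ct[col]).all():
            raise ValueError(f"non-finite values in {col}")
    if calibrator not in ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    out = ct.copy()
    out["dct"] = out["target_ct"] - out["reference_ct"]
    out["ddct"] = out["dct"] - out.loc[calibrator, "dct"]
    out["relative_expression"] = np.exp2(-out["ddct"])
    return out
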