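"""smRNA chain: mapping, filtering, clustering, classification, enrichment.

The nontrivial operations are checked against independent brute-force
oracles: a naive both-strand substring scan for the mapper, transitive
closure of the pairwise gap relation for locus clustering, and exhaustive
enumeration of draws for the hypergeometric tails.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tasiflow import smrna, synth
from tasiflow.smrna import MappedSignature
from tasiflow.synth import AnnotatedGenome, Feature, reverse_complement


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def naive_scan(sequences: dict[str, str], read: str) -> list[tuple[str, int, str]]:
    """Reference mapper: scan every offset of both strands."""
    hits = []
    rc = reverse_complement(read)
    for chrom, s in sequences.items():
        for i in range(len(s) - len(read) + 1):
            if s[i:i + len(read)] == read:
                hits.append((chrom, i, "+"))
            if s[i:i + len(read)] == rc:
                hits.append((chrom, i, "-"))
    return sorted(hits)


def brute_force_clusters(intervals, gap=150):
    """Transitive closure of the symmetric 'gap < threshold' relation."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        ci, si, ei = intervals[i]
        cj, sj, ej = intervals[j]
        if ci != cj:
            continue
        d = max(sj - ei, si - ej)  # negative when overlapping
        if d < gap:
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def enumerate_hypergeom_tails(k, n, K, N):
    """Tail probabilities by enumerating all C(N, n) draws."""
    pop = [1] * K + [0] * (N - K)
    total = up = down = 0
    for draw in itertools.combinations(range(N), n):
        x = sum(pop[i] for i in draw)
        total += 1
        up += x >= k
        down += x <= k
    return up / total, down / total


def _sig(seq, counts=None, hits=()):
    return MappedSignature(seq, hits=list(hits), counts=counts or {})


# ---------------------------------------------------------------------------
# map_exact
# ---------------------------------------------------------------------------

class TestMapExact:
    def test_both_strand_hits_on_toy_genome(self):
        g = AnnotatedGenome({"chr": "AAAACCCGGGTTTT"}, [])
        sig = _sig("CCCGG")
        mapped, unmapped = smrna.map_exact([sig], g)
        assert mapped and not unmapped
        assert sig.hits == [("chr", 4, "+"), ("chr", 5, "-")]

    def test_absent_read_flagged_unmapped(self):
        g = AnnotatedGenome({"chr": "AAAAAAAAAA"}, [])
        sig = _sig("CGCGC")
        mapped, unmapped = smrna.map_exact([sig], g)
        assert not mapped and unmapped == [sig] and sig.hits == []

    def test_palindromic_read_reports_both_strands_at_same_start(self):
        read = "ACGCGT"  # equals its reverse complement
        assert reverse_complement(read) == read
        g = AnnotatedGenome({"chr": "TTACGCGTTT"}, [])
        sig = _sig(read)
        smrna.map_exact([sig], g)
        assert sig.hits == [("chr", 2, "+"), ("chr", 2, "-")]

    def test_ambiguous_bases_flagged_invalid(self):
        g = AnnotatedGenome({"chr": "ACGTACGTACGT"}, [])
        sig = _sig("ACNGT")
        mapped, unmapped = smrna.map_exact([sig], g)
        assert sig.invalid and sig in unmapped

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_scan_on_random_genomes(self, seed):
        rng = np.random.default_rng(seed)
        sequences = {
            f"chr{i}": "".join(rng.choice(list("ACGT"), size=int(rng.integers(200, 5000))))
            for i in range(1, 3)
        }
        g = AnnotatedGenome(sequences, [])
        reads = []
        for _ in range(20):
            chrom = f"chr{int(rng.integers(1, 3))}"
            L = int(rng.integers(17, 31))
            s = int(rng.integers(0, len(sequences[chrom]) - L))
            read = sequences[chrom][s:s + L]
            if rng.random() < 0.5:
                read = reverse_complement(read)
            reads.append(read)
        reads.append("".join(rng.choice(list("ACGT"), size=25)))  # likely absent
        sigs = [_sig(r) for r in reads]
        smrna.map_exact(sigs, g)
        for sig in sigs:
            assert sig.hits == naive_scan(sequences, sig.sequence)


# ---------------------------------------------------------------------------
# collapse / length filter
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_counts_conserved_and_singletons(self):
        a, c = "A" * 17, "C" * 17
        sigs, summary = smrna.collapse_signatures({"lib": [a, a, c]})
        assert summary.total_reads == 3
        assert summary.total_unique == 2
        assert summary.singleton_fraction == pytest.approx(0.5)
        counts = {s.sequence: s.total_count for s in sigs}
        assert counts == {a: 2, c: 1}

    def test_empty_input_fraction_undefined(self):
        sigs, summary = smrna.collapse_signatures({"lib": []})
        assert sigs == [] and summary.singleton_fraction is None

    def test_all_distinct_reads_are_singletons(self):
        reads = [("ACGT" * 8)[:17 + i] for i in range(10)]
        _, summary = smrna.collapse_signatures({"lib": reads})
        assert summary.singleton_fraction == 1.0

    def test_length_filter_bounds(self):
        reads = ["A" * 16, "A" * 17, "A" * 30, "A" * 31]
        kept, removed = smrna.filter_by_length(reads)
        assert kept == ["A" * 17, "A" * 30] and removed == 2


# ---------------------------------------------------------------------------
# structural filter
# ---------------------------------------------------------------------------

def _feature(name, ftype, start, end, chrom="chr", strand="+"):
    return Feature(name, chrom, start, end, strand, ftype)


class TestFilterStructural:
    def test_rrna_only_hit_removed(self):
        idx = smrna.FeatureIndex([_feature("r1", "rRNA", 100, 200)])
        sig = _sig("A" * 20, hits=[("chr", 150, "+")])
        kept, removed = smrna.filter_structural([sig], idx)
        assert removed == [sig] and kept == []

    def test_any_structural_hit_disqualifies(self):
        idx = smrna.FeatureIndex(
            [_feature("r1", "rRNA", 100, 200), _feature("g1", "protein_coding", 500, 900)]
        )
        sig = _sig("A" * 20, hits=[("chr", 150, "+"), ("chr", 600, "+")])
        kept, removed = smrna.filter_structural([sig], idx)
        assert removed == [sig]

    def test_no_structural_features_identity(self):
        idx = smrna.FeatureIndex([_feature("g1", "protein_coding", 0, 100)])
        sigs = [_sig("A" * 20, hits=[("chr", 10, "+")])]
        kept, removed = smrna.filter_structural(sigs, idx)
        assert kept == sigs and removed == []

    def test_unmapped_signature_rejected(self):
        idx = smrna.FeatureIndex([])
        with pytest.raises(ValueError, match="map"):
            smrna.filter_structural([_sig("A" * 20)], idx)


# ---------------------------------------------------------------------------
# cluster_loci
# ---------------------------------------------------------------------------

class TestClusterLoci:
    def test_gap_rule_example(self):
        ivals = [("chr", 100, 120), ("chr", 200, 220), ("chr", 380, 400)]
        loci = smrna.cluster_loci(ivals)
        assert len(loci) == 2
        assert {frozenset(l.members) for l in loci} == {
            frozenset({0, 1}),
            frozenset({2}),
        }

    def test_single_hit_single_locus(self):
        loci = smrna.cluster_loci([("chr", 5, 25)])
        assert len(loci) == 1 and (loci[0].start, loci[0].end) == (5, 25)

    def test_gap_of_exactly_threshold_not_merged(self):
        loci = smrna.cluster_loci([("chr", 0, 100), ("chr", 250, 300)], gap=150)
        assert len(loci) == 2

    def test_gap_just_below_threshold_merged(self):
        loci = smrna.cluster_loci([("chr", 0, 100), ("chr", 249, 300)], gap=150)
        assert len(loci) == 1

    def test_negative_coordinates_rejected(self):
        with pytest.raises(ValueError):
            smrna.cluster_loci([("chr", -1, 10)])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chrA", "chrB"]),
                st.integers(min_value=0, max_value=2000),
                st.integers(min_value=1, max_value=60),
            ),
            max_size=50,
        )
    )
    def test_matches_transitive_closure(self, raw):
        ivals = [(c, s, s + l) for c, s, l in raw]
        loci = smrna.cluster_loci(ivals)
        got = {frozenset(l.members) for l in loci}
        assert got == brute_force_clusters(ivals)


# ---------------------------------------------------------------------------
# classification and composition
# ---------------------------------------------------------------------------

class TestClassify:
    def setup_method(self):
        self.idx = smrna.FeatureIndex(
            [
                _feature("m1", "MIRNA", 100, 220),
                _feature("g1", "protein_coding", 150, 1400, strand="+"),
                _feature("t1", "TAS", 2000, 2300),
                _feature("te1", "TE_gene", 3000, 3800),
            ]
        )

    def test_mirna_takes_precedence_over_gene(self):
        sig = _sig("A" * 21, hits=[("chr", 180, "+")])
        assert smrna.classify_signature(sig, self.idx) == "miRNA"

    def test_antisense_hit_on_plus_strand_gene(self):
        sig = _sig("A" * 21, hits=[("chr", 600, "-")])
        assert smrna.classify_signature(sig, self.idx) == "protein_coding_antisense"

    def test_no_overlap_falls_back_to_intergenic(self):
        sig = _sig("A" * 21, hits=[("chr", 50_000, "+")])
        assert smrna.classify_signature(sig, self.idx) == "other_intergenic"

    def test_multimapper_takes_best_category_across_hits(self):
        sig = _sig("A" * 21, hits=[("chr", 3100, "+"), ("chr", 2100, "+")])
        assert smrna.classify_signature(sig, self.idx) == "ta-siRNA"

    def test_composition_percentages(self):
        sigs = [
            _sig("A" * 21, counts={"L": 50}, hits=[("chr", 180, "+")]),
            _sig("C" * 21, counts={"L": 50}, hits=[("chr", 800, "+")]),
        ]
        cats = smrna.classify_all(sigs, self.idx)
        table = smrna.tabulate_composition(sigs, cats, ["L"])
        assert table.percentages.loc["miRNA", "L"] == 50.0
        assert table.percentages.loc["protein_coding_sense", "L"] == 50.0
        assert table.percentages["L"].sum() == pytest.approx(100.0, abs=0.01)

    def test_empty_library_flagged(self):
        sigs = [_sig("A" * 21, counts={"L1": 5}, hits=[("chr", 180, "+")])]
        cats = smrna.classify_all(sigs, self.idx)
        table = smrna.tabulate_composition(sigs, cats, ["L1", "L2"])
        assert table.empty_libraries == ["L2"]

    def test_degradation_fraction_raises_sense_percentage(
        self, small_genome
    ):
        eff = synth.SmrnaEffectSpec(
            depth=4000,
            degradation_fraction={
                **{lib: 0.1 for lib in synth.DEFAULT_LIBRARIES},
                "drought_1-5h": 0.3,
            },
            fold_changes={},
            seed=8,
        )
        reads, _ = synth.simulate_smrna_libraries(small_genome, eff)
        sigs, _ = smrna.collapse_signatures(reads)
        mapped, _ = smrna.map_exact(sigs, small_genome)
        idx = smrna.FeatureIndex(small_genome.features)
        kept, _ = smrna.filter_structural(mapped, idx)
        cats = smrna.classify_all(kept, idx)
        table = smrna.tabulate_composition(kept, cats, list(reads))
        sense = table.percentages.loc["protein_coding_sense"]
        assert sense["drought_1-5h"] > sense["control"]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalizeByMirna:
    def test_arithmetic_example(self):
        counts = pd.DataFrame({"stress": [30], "control": [50]}, index=["fam"])
        totals = pd.Series({"stress": 600, "control": 500})
        norm, rel = smrna.normalize_by_mirna(counts, totals, "control")
        assert norm.loc["fam", "stress"] == pytest.approx(0.05)
        assert norm.loc["fam", "control"] == pytest.approx(0.10)
        assert rel.loc["fam", "stress"] == pytest.approx(0.5)

    def test_identical_libraries_relative_one(self):
        counts = pd.DataFrame({"a": [7, 3], "control": [7, 3]}, index=["f1", "f2"])
        totals = pd.Series({"a": 100, "control": 100})
        _, rel = smrna.normalize_by_mirna(counts, totals, "control")
        assert (rel == 1.0).all().all()

    def test_scale_invariance(self):
        counts = pd.DataFrame({"a": [10], "control": [20]}, index=["f"])
        totals = pd.Series({"a": 200, "control": 400})
        norm1, _ = smrna.normalize_by_mirna(counts, totals, "control")
        norm2, _ = smrna.normalize_by_mirna(counts * 2, totals * 2, "control")
        pd.testing.assert_frame_equal(norm1, norm2)

    def test_zero_mirna_total_names_library(self):
        counts = pd.DataFrame({"bad": [1], "control": [1]}, index=["f"])
        totals = pd.Series({"bad": 0, "control": 10})
        with pytest.raises(ValueError, match="bad"):
            smrna.normalize_by_mirna(counts, totals, "control")

    def test_zero_control_count_undefined_not_inf(self):
        counts = pd.DataFrame({"a": [5], "control": [0]}, index=["f"])
        totals = pd.Series({"a": 100, "control": 100})
        _, rel = smrna.normalize_by_mirna(counts, totals, "control")
        assert np.isnan(rel.loc["f", "a"])


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

class TestHypergeomEnrichment:
    def test_enumeration_example(self):
        p_up, _ = smrna.hypergeom_enrichment(4, 4, 5, 10)
        assert p_up == pytest.approx(5 / 210, abs=1e-12)

    def test_k_zero_boundary(self):
        p_up, p_down = smrna.hypergeom_enrichment(0, 4, 5, 10)
        assert p_up == pytest.approx(1.0, abs=1e-12)
        assert p_down == pytest.approx(
            math.comb(5, 4) / math.comb(10, 4), abs=1e-12
        )

    def test_tails_cover_point_mass_at_expectation(self):
        N, K, n = 12, 6, 6
        k = round(n * K / N)
        from scipy.stats import hypergeom

        pm = hypergeom.pmf(k, N, K, n)
        p_up, p_down = smrna.hypergeom_enrichment(k, n, K, N)
        assert p_up >= pm and p_down >= pm

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            smrna.hypergeom_enrichment(6, 4, 5, 10)

    @pytest.mark.parametrize("N", [8, 10, 12])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(0, N + 1, 2):
            for n in range(1, N + 1, 3):
                for k in range(0, min(n, K) + 1):
                    p_up, p_down = smrna.hypergeom_enrichment(k, n, K, N)
                    e_up, e_down = enumerate_hypergeom_tails(k, n, K, N)
                    assert abs(p_up - e_up) < 1e-12
                    assert abs(p_down - e_down) < 1e-12


class TestCallStressResponsive:
    def _frame(self, p_up, p_down):
        return pd.DataFrame(
            {"family": ["f"], "library": ["l"], "k": [1], "n": [10],
             "K": [2], "N": [20], "p_up": [p_up], "p_down": [p_down]}
        )

    def test_below_threshold_flagged_up(self):
        out = smrna.call_stress_responsive(self._frame(5e-4, 1.0))
        assert out.significant.iloc[0] and out.direction.iloc[0] == "up"

    def test_exact_threshold_not_flagged(self):
        out = smrna.call_stress_responsive(self._frame(1e-3, 1.0))
        assert not out.significant.iloc[0]

    def test_planted_tas_families_flagged_down(self, small_genome):
        eff = synth.SmrnaEffectSpec(
            depth=10_000,
            fold_changes={"drought": {"TAS": 0.25}, "salt": {}, "cold": {}},
            seed=12,
        )
        reads, _ = synth.simulate_smrna_libraries(small_genome, eff)
        sigs, _ = smrna.collapse_signatures(reads)
        mapped, _ = smrna.map_exact(sigs, small_genome)
        idx = smrna.FeatureIndex(small_genome.features)
        kept, _ = smrna.filter_structural(mapped, idx)
        cats = smrna.classify_all(kept, idx)
        comp = smrna.tabulate_composition(kept, cats, list(reads))
        fams = smrna.family_counts(kept, cats, idx, list(reads))
        calls = smrna.call_stress_responsive(
            smrna.enrich_families(fams, smrna.mirna_totals(comp), "control")
        )
        tas = calls[calls.family.str.startswith("TAS-")
                    & calls.library.str.startswith("drought")]
        assert len(tas) > 0
        assert (tas.direction == "down").all() and tas.significant.all()


# ---------------------------------------------------------------------------
# loci-per-library statistic
# ---------------------------------------------------------------------------

def test_loci_per_library_counts_only_present_signatures():
    sigs = [
        _sig("A" * 20, counts={"L1": 3}, hits=[("chr", 100, "+")]),
        _sig("C" * 20, counts={"L1": 1, "L2": 2}, hits=[("chr", 1000, "+")]),
    ]
    out = smrna.loci_per_library(sigs, ["L1", "L2"])
    assert out["L1"] == 2 and out["L2"] == 1
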