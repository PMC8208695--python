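"""Codon-position mapping, coverage filtering, counting, effects, spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbiorate import (
    AnalysisConfig,
    CdsFeature,
    DepthTrack,
    GenomeSequence,
    VariantRecord,
    build_codon_position_map,
    build_coverage_mask,
    classify_variant_effect,
    count_third_position_changes,
    count_third_position_sites,
    estimate_rate,
    filter_variants_by_mask,
    intersect_masks,
    run_rate_comparison,
    select_fully_covered_cds,
    substitution_spectrum,
)

# Independent translation oracle: the Mollicutes/Spiroplasma code written
# out as a literal (standard assignments except TGA = Trp).
TABLE4 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

ALL_CODONS = sorted(TABLE4)


class TestCodonPositionMap:
    def test_plus_strand_frame(self):
        genome = [GenomeSequence("c1", "ATGAAA", "linear")]
        cds = [CdsFeature("c1", 0, 6, "+", 0, "g1")]
        m = build_codon_position_map(genome, cds)
        assert m.codon_pos["c1"].tolist() == [1, 2, 3, 1, 2, 3]

    def test_minus_strand_frame_counted_from_end(self):
        genome = [GenomeSequence("c1", "ATGAAA", "linear")]
        cds = [CdsFeature("c1", 0, 6, "-", 0, "g1")]
        m = build_codon_position_map(genome, cds)
        # frame cycles 1,2,3 from the end coordinate downward
        assert m.codon_pos["c1"].tolist() == [3, 2, 1, 3, 2, 1]

    def test_overlapping_cds_positions_are_none(self):
        genome = [GenomeSequence("c1", "A" * 12, "linear")]
        cds = [
            CdsFeature("c1", 0, 6, "+", 0, "g1"),
            CdsFeature("c1", 3, 9, "+", 0, "g2"),
        ]
        m = build_codon_position_map(genome, cds)
        assert m.codon_pos["c1"][3:6].tolist() == [0, 0, 0]
        assert m.owner["c1"][3:6].tolist() == [-1, -1, -1]
        assert m.codon_pos["c1"][0:3].tolist() == [1, 2, 3]

    def test_out_of_frame_cds_excluded(self, caplog):
        genome = [GenomeSequence("c1", "A" * 10, "linear")]
        cds = [CdsFeature("c1", 0, 7, "+", 0, "g1")]
        m = build_codon_position_map(genome, cds)
        assert m.cds_list == [] and m.excluded == cds
        assert (m.codon_pos["c1"] == 0).all()

    def test_unknown_contig_names_locus(self):
        genome = [GenomeSequence("c1", "A" * 10, "linear")]
        with pytest.raises(ValueError, match="gX"):
            build_codon_position_map(genome, [CdsFeature("c2", 0, 6, "+", 0, "gX")])

    def test_equal_thirds_per_in_frame_cds(self, small_fixture_set):
        """Exactly one third of in-frame non-overlapping CDS positions get
        each codon-position label."""
        m = small_fixture_set.cpmap
        cp = m.codon_pos["chr1"]
        for cds in m.cds_list[:20]:
            sub = cp[cds.start : cds.end]
            n1, n2, n3 = (sub == 1).sum(), (sub == 2).sum(), (sub == 3).sum()
            assert n1 == n2 == n3 == cds.length // 3


class TestCoverageMask:
    def test_threshold(self):
        t = DepthTrack("l", "c1", np.array([5, 4, 5]))
        m = build_coverage_mask(t, 5)
        assert m.intervals == [(0, 1), (2, 3)]

    def test_all_zero_empty(self):
        m = build_coverage_mask(DepthTrack("l", "c1", np.zeros(5, int)), 5)
        assert m.intervals == [] and m.n_positions == 0

    def test_min_depth_one_spans_contig(self):
        m = build_coverage_mask(DepthTrack("l", "c1", np.ones(5, int)), 1)
        assert m.intervals == [(0, 5)]

    def test_intersection(self):
        a = build_coverage_mask(DepthTrack("l", "c1", np.array([1, 1, 1, 0])), 1)
        b = build_coverage_mask(DepthTrack("l", "c1", np.array([0, 1, 1, 1])), 1)
        m = intersect_masks([a, b])
        assert m.intervals == [(1, 3)]

    def test_empty_mask_absorbs(self):
        a = build_coverage_mask(DepthTrack("l", "c1", np.ones(4, int)), 1)
        e = build_coverage_mask(DepthTrack("l", "c1", np.zeros(4, int)), 1)
        assert intersect_masks([a, e]).intervals == []

    def test_idempotent(self):
        a = build_coverage_mask(DepthTrack("l", "c1", np.array([3, 0, 3, 3])), 2)
        assert intersect_masks([a, a]).intervals == a.intervals

    def test_contig_mismatch_errors(self):
        a = build_coverage_mask(DepthTrack("l", "c1", np.ones(4, int)), 1)
        b = build_coverage_mask(DepthTrack("l", "c2", np.ones(4, int)), 1)
        with pytest.raises(ValueError):
            intersect_masks([a, b])

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=60), st.integers(1, 6))
    @settings(max_examples=100, deadline=None)
    def test_intervals_merged_and_match_threshold(self, depths, min_depth):
        m = build_coverage_mask(DepthTrack("l", "c1", np.array(depths)), min_depth)
        # sorted, disjoint, non-adjacent
        for (s1, e1), (s2, e2) in zip(m.intervals, m.intervals[1:]):
            assert s1 < e1 <= s2 < e2 and e1 < s2
        assert np.array_equal(m.to_bool(), np.array(depths) >= min_depth)


class TestCdsAndVariantFiltering:
    def _mask(self, flags):
        from symbiorate.rate_pipeline import CoverageMask

        return CoverageMask.from_bool("c1", np.array(flags, bool), 5)

    def test_one_uncovered_base_disqualifies(self):
        cds = [CdsFeature("c1", 0, 6, "+", 0, "g1")]
        assert select_fully_covered_cds(cds, self._mask([1, 1, 1, 1, 1, 0])) == []
        assert select_fully_covered_cds(cds, self._mask([1, 1, 1, 1, 1, 1])) == cds

    def test_empty_cds_list(self):
        assert select_fully_covered_cds([], self._mask([1, 1])) == []

    def test_snp_at_masked_position_retained(self):
        v = VariantRecord("c1", 2, "A", "G", "snp")
        assert filter_variants_by_mask([v], self._mask([0, 0, 1, 0])) == [v]

    def test_mnp_spanning_unmasked_base_dropped(self):
        v = VariantRecord("c1", 1, "AT", "GC", "mnp")
        assert filter_variants_by_mask([v], self._mask([1, 1, 0, 1])) == []
        assert filter_variants_by_mask([v], self._mask([0, 1, 1, 1])) == [v]

    def test_empty_variant_list(self):
        assert filter_variants_by_mask([], self._mask([1])) == []


class TestCounting:
    @pytest.fixture
    def setup(self):
        genome = [GenomeSequence("c1", "ATGAAATTTGGG", "linear")]
        cds = [CdsFeature("c1", 0, 12, "+", 0, "g1")]
        cpmap = build_codon_position_map(genome, cds)
        return genome, cds, cpmap

    def test_snp_at_third_position_counts(self, setup):
        _, cds, cpmap = setup
        v = VariantRecord("c1", 2, "G", "A", "snp")
        assert count_third_position_changes([v], cpmap, cds) == 1

    def test_snp_at_second_position_does_not(self, setup):
        _, cds, cpmap = setup
        v = VariantRecord("c1", 1, "T", "C", "snp")
        assert count_third_position_changes([v], cpmap, cds) == 0

    def test_mnp_decomposed_base_by_base(self, setup):
        # ref ATG -> alt ATA over a full codon: only the third base differs
        _, cds, cpmap = setup
        v = VariantRecord("c1", 0, "ATG", "ATA", "mnp")
        assert count_third_position_changes([v], cpmap, cds) == 1

    def test_indels_count_zero(self, setup):
        _, cds, cpmap = setup
        ins = VariantRecord("c1", 2, "G", "GT", "ins")
        dele = VariantRecord("c1", 2, "GA", "G", "del")
        assert count_third_position_changes([ins, dele], cpmap, cds) == 0

    def test_changes_in_unretained_cds_ignored(self, setup):
        _, _cds, cpmap = setup
        v = VariantRecord("c1", 2, "G", "A", "snp")
        assert count_third_position_changes([v], cpmap, []) == 0

    def test_site_denominator(self, setup):
        _, cds, cpmap = setup
        assert count_third_position_sites(cpmap, cds) == 4
        from symbiorate.rate_pipeline import CoverageMask

        half = CoverageMask.from_bool("c1", np.arange(12) < 6, 5)
        assert count_third_position_sites(cpmap, cds, half) == 2


class TestRateEstimate:
    def test_arithmetic(self):
        est = estimate_rate(3, 100_000, 6.0, "x")
        assert est.rate == pytest.approx(5.0e-6)

    def test_zero_changes(self):
        assert estimate_rate(0, 1000, 2.0).rate == 0.0

    @pytest.mark.parametrize("k,L,t", [(1, 0, 1.0), (1, 10, 0.0), (1, 10, -2.0)])
    def test_invalid_denominators_error(self, k, L, t):
        with pytest.raises(ValueError):
            estimate_rate(k, L, t)

    def test_poisson_sampling_oracle(self):
        """Counts drawn from the true Poisson process recover the rate
        within 3 standard errors in nearly all replicates."""
        rate, years, L = 1.0e-5, 10.0, 200_000
        rng = np.random.default_rng(42)
        lam = rate * years * L
        ok = 0
        for _ in range(200):
            k = rng.poisson(lam)
            est = estimate_rate(int(k), L, years)
            ok += abs(est.rate - rate) <= 3 * np.sqrt(lam) / (L * years)
        assert ok >= 196


class TestEffectClassification:
    def _classify(self, codon, pos_in_codon, alt, strand="+", code=4):
        genome = [GenomeSequence("c1", codon, "linear")]
        cds = [CdsFeature("c1", 0, 3, strand, 0, "g1")]
        cpmap = build_codon_position_map(genome, cds)
        if strand == "-":
            # variant coordinates are genomic; flip within the codon
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            genome = [GenomeSequence("c1", _revcomp(codon), "linear")]
            cpmap = build_codon_position_map(genome, cds)
            gpos = 2 - pos_in_codon
            ref = comp[codon[pos_in_codon]]
            v = VariantRecord("c1", gpos, ref, comp[alt], "snp")
        else:
            v = VariantRecord("c1", pos_in_codon, codon[pos_in_codon], alt, "snp")
        return classify_variant_effect(v, cpmap, genome, code)

    def test_all_576_codon_changes_match_brute_force_oracle(self):
        mismatches = []
        for codon in ALL_CODONS:
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mut = codon[:i] + alt + codon[i + 1 :]
                    expected = (
                        "synonymous" if TABLE4[codon] == TABLE4[mut] else "nonsynonymous"
                    )
                    got = self._classify(codon, i, alt)
                    if got.effect != expected:
                        mismatches.append((codon, i, alt, got.effect, expected))
        assert not mismatches

    def test_minus_strand_agrees_with_oracle(self):
        for codon in ["TGA", "AAA", "GGC", "TAT"]:
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mut = codon[:i] + alt + codon[i + 1 :]
                    expected = (
                        "synonymous" if TABLE4[codon] == TABLE4[mut] else "nonsynonymous"
                    )
                    assert self._classify(codon, i, alt, strand="-").effect == expected

    def test_tga_trp_under_table4_but_not_table11(self):
        # TGA->TGG: silent in the Spiroplasma code, stop-loss in the
        # standard bacterial code
        assert self._classify("TGA", 2, "G").effect == "synonymous"
        assert self._classify("TGA", 2, "G", code=11).effect == "nonsynonymous"

    def test_indel_effects(self, toy_genome, toy_cds, toy_cpmap):
        genome = [toy_genome]
        ins1 = VariantRecord("c1", 2, "G", "GT", "ins")
        assert classify_variant_effect(ins1, toy_cpmap, genome).effect == "frameshift"
        ins3 = VariantRecord("c1", 2, "G", "GTTT", "ins")
        assert classify_variant_effect(ins3, toy_cpmap, genome).effect == "inframe_indel"

    def test_intergenic_and_multicodon(self, toy_genome, toy_cpmap):
        genome = [toy_genome]
        inter = VariantRecord("c1", 20, "A", "C", "snp")
        assert classify_variant_effect(inter, toy_cpmap, genome).effect == "intergenic"
        # MNP spanning two codons of g1
        multi = VariantRecord("c1", 2, "GA", "TG", "mnp")
        assert classify_variant_effect(multi, toy_cpmap, genome).effect == "complex"

    def test_unsupported_code_errors(self, toy_genome, toy_cpmap):
        v = VariantRecord("c1", 2, "G", "A", "snp")
        with pytest.raises(ValueError):
            classify_variant_effect(v, toy_cpmap, [toy_genome], genetic_code=99)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestSpectrum:
    def test_gc_to_at_classes_collapse(self):
        vs = [
            VariantRecord("c1", 0, "G", "A", "snp"),
            VariantRecord("c1", 1, "C", "T", "snp"),
        ]
        spec = substitution_spectrum(vs)
        assert spec.counts["GC>AT"] == 2 and spec.gc_to_at_fraction == 1.0

    def test_empty_input_undefined_fraction(self):
        spec = substitution_spectrum([])
        assert spec.total == 0 and spec.gc_to_at_fraction is None

    def test_mnp_decomposition_conserves_counts(self):
        vs = [
            VariantRecord("c1", 0, "GAT", "AAC", "mnp"),  # G>A and T>C
            VariantRecord("c1", 10, "A", "AT", "ins"),  # ignored
        ]
        spec = substitution_spectrum(vs)
        assert spec.total == 2
        assert spec.counts["GC>AT"] == 1 and spec.counts["AT>GC"] == 1

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")).filter(
                lambda p: p[0] != p[1]
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_class_counts_sum_to_substitutions(self, pairs):
        vs = [
            VariantRecord("c1", i, r, a, "snp") for i, (r, a) in enumerate(pairs)
        ]
        assert substitution_spectrum(vs).total == len(pairs)


class TestCoverageRobustness:
    def test_dropout_does_not_bias_the_rate(self):
        """Deleting ~30% of coverage shrinks the considered site set but
        leaves the estimator unbiased: the mean estimate over 100 replicate
        evolutions stays within one single-replicate Poisson SE of the true
        rate (the mean's own SE is ten times tighter, so this detects bias
        well above the noise floor without flagging the noise itself)."""
        from symbiorate import SimulationConfig, evolve_sequence, generate_fixture_set

        cfg = SimulationConfig(
            genome_length=200_000, n_cds=160, seed=211,
            mean_depth=20.0, dropout_fraction=0.30, n_libraries=1,
        )
        fx = generate_fixture_set(cfg)
        mask = intersect_masks([build_coverage_mask(t, 5) for t in fx.depth_tracks])
        retained = select_fully_covered_cds(fx.cpmap.cds_list, mask)
        L = count_third_position_sites(fx.cpmap, retained, mask)
        assert 0 < L < count_third_position_sites(fx.cpmap, fx.cpmap.cds_list)

        r_true, t = cfg.rate_per_site_per_year, cfg.years
        rates = []
        for s in range(100):
            _, truth = evolve_sequence(
                fx.genome, fx.cpmap, cfg, np.random.default_rng(40_000 + s)
            )
            kept = filter_variants_by_mask(truth.true_variants, mask)
            k = count_third_position_changes(kept, fx.cpmap, retained)
            rates.append(estimate_rate(k, L, t).rate)
        one_se = np.sqrt(r_true * t * L) / (L * t)
        assert abs(np.mean(rates) - r_true) <= one_se


class TestPipelineMonotonicity:
    def test_raising_min_depth_never_enlarges_anything(self, small_fixture_set):
        """Stricter coverage thresholds can only shrink the mask, the
        retained-CDS set, and both rate-count terms."""
        fx = small_fixture_set
        prev = None
        for min_depth in (1, 5, 10, 20):
            mask = intersect_masks(
                [build_coverage_mask(t, min_depth) for t in fx.depth_tracks]
            )
            retained = select_fully_covered_cds(fx.cpmap.cds_list, mask)
            kept = filter_variants_by_mask(fx.truth.true_variants, mask)
            cur = (
                mask.n_positions,
                len(retained),
                count_third_position_changes(kept, fx.cpmap, retained),
                count_third_position_sites(fx.cpmap, retained, mask),
            )
            if prev is not None:
                assert all(c <= p for c, p in zip(cur, prev))
            prev = cur
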