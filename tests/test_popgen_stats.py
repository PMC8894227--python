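"""Diversity statistics, nucleotide diversity, codon effects and NJ trees."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import tetrahap.popgen_stats as pg
import tetrahap.synthetic_data as syn
from tetrahap.model import Amplicon, HaplotypePanel, TetraGenotype

from .oracles import best_quartet_topology


def _cohort_from_class_counts(counts: dict[str, int]) -> list[TetraGenotype]:
    """Cohort whose Gallais-class composition matches ``counts`` exactly.

    Distinct allele labels per pattern slot keep Ai/Ho determined purely by
    the multiplicity patterns.
    """
    patterns = {
        "monogenic": ("a", "a", "a", "a"),
        "digenic-simplex": ("a", "a", "a", "b"),
        "digenic-duplex": ("a", "a", "b", "b"),
        "trigenic": ("a", "a", "b", "c"),
        "tetragenic": ("a", "b", "c", "d"),
    }
    out, i = [], 0
    for cls, n in counts.items():
        for _ in range(n):
            out.append(
                TetraGenotype(f"i{i}", tuple(patterns[cls]))
            )
            i += 1
    return out


PRINTED_CLASS_COUNTS = {
    "tetragenic": 77,
    "trigenic": 185,
    "digenic-simplex": 76,
    "digenic-duplex": 37,
    "monogenic": 9,
}


class TestDiversity:
    def test_ho_and_ai_from_printed_class_counts(self):
        cohort = _cohort_from_class_counts(PRINTED_CLASS_COUNTS)
        stats = pg.diversity(cohort, n_permutations=0)
        assert round(stats.ho, 3) == 0.765
        assert round(stats.ai, 2) == 2.86

    def test_single_tetragenic_genotype_fully_heterozygous(self):
        cohort = [
            TetraGenotype("i0", ("A", "B", "C", "D")),
            TetraGenotype("i1", ("A", "B", "C", "D")),
        ]
        stats = pg.diversity(cohort, n_permutations=0)
        assert stats.ho == 1.0
        assert stats.ai == 4.0

    def test_unresolved_excluded(self):
        cohort = _cohort_from_class_counts({"tetragenic": 5}) + [
            TetraGenotype("bad", (), status="failed")
        ]
        stats = pg.diversity(cohort, n_permutations=0)
        assert stats.n_individuals == 5
        assert stats.n_excluded == 1

    def test_f_near_zero_under_hwe(self, preset_panel):
        fs = []
        for s in range(30):
            cohort = syn.sample_cohort(preset_panel, 400, seed=300 + s)
            stats = pg.diversity(cohort, n_permutations=0)
            fs.append(stats.f)
        assert abs(np.mean(fs)) < 0.02

    def test_hwe_permutation_p_uniform_under_null(self, preset_panel):
        pvals = []
        for s in range(200):
            cohort = syn.sample_cohort(preset_panel, 100, seed=1000 + s)
            stats = pg.diversity(cohort, n_permutations=199, seed=s)
            pvals.append(stats.hwe_p)
        _, p = sps.kstest(pvals, "uniform")
        assert p > 0.01

    def test_hwe_type_one_error_calibrated(self, preset_panel):
        rejections = 0
        n_sim = 400
        for s in range(n_sim):
            cohort = syn.sample_cohort(preset_panel, 80, seed=5000 + s)
            stats = pg.diversity(cohort, n_permutations=199, seed=s)
            rejections += stats.hwe_p <= 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_grouping_collapses_subtypes(self):
        cohort = [TetraGenotype("i0", ("A1", "A2", "A3", "B"))]
        grouped = pg.diversity(
            cohort + cohort, grouping={"A1": "A", "A2": "A", "A3": "A"},
            n_permutations=0,
        )
        assert grouped.ai == 2.0


class TestClassSummary:
    def test_mean_per_class_matches_published_ratio(self):
        # 384 genotypes spread over 111 distinct multisets -> 3.5 per class
        labels = [f"h{k}" for k in range(40)]
        classes = list(itertools.combinations(labels, 4))[:111]
        genotypes = []
        i = 0
        for ci, cls in enumerate(classes):
            copies = 4 if ci < 384 - 111 * 3 else 3  # 21 classes of 4, 90 of 3
            for _ in range(copies):
                genotypes.append(TetraGenotype(f"i{i}", cls))
                i += 1
        assert len(genotypes) == 384
        summary = pg.genotypic_class_summary(genotypes)
        assert summary.n_classes == 111
        assert round(summary.mean_per_class, 1) == 3.5

    def test_identical_cohort_single_class(self):
        genotypes = [TetraGenotype(f"i{k}", ("A", "A", "B", "C")) for k in range(7)]
        summary = pg.genotypic_class_summary(genotypes)
        assert summary.n_classes == 1
        assert summary.mean_per_class == 7

    def test_class_counts_match_multinomial_expectation(self):
        cfg = syn.SimConfig(
            seed=5, n_haplotypes=3, amplicon_lengths=(200,), target_pi=0.01,
            frequencies={"X": 0.5, "Y": 0.3, "Z": 0.2},
        )
        panel = syn.generate_haplotypes(cfg)
        cohort = syn.sample_cohort(panel, 100_000, seed=6)
        summary = pg.genotypic_class_summary(cohort)
        probs = {"X": 0.5, "Y": 0.3, "Z": 0.2}
        expected, observed = [], []
        from collections import Counter
        from math import factorial

        for key, obs in summary.class_counts.items():
            alleles = key.split(",")
            mult = Counter(alleles)
            coef = factorial(4)
            p = 1.0
            for a, m in mult.items():
                coef //= factorial(m)
                p *= probs[a] ** m
            expected.append(coef * p * 100_000)
            observed.append(obs)
        _, p = sps.chisquare(observed, np.array(expected) * sum(observed) / sum(expected))
        assert p > 0.01


class TestNucleotideDiversity:
    def test_two_haplotypes_weighted_and_unweighted(self):
        seqs = {"X": "A" * 99 + "T", "Y": "A" * 100}
        panel = HaplotypePanel(
            amplicons=[Amplicon("a", 100)],
            sequences={h: {"a": s} for h, s in seqs.items()},
            frequencies={"X": 0.9, "Y": 0.1},
        )
        est = pg.nucleotide_diversity(panel)
        assert est.pi_unweighted == pytest.approx(0.01)
        assert est.pi_weighted == pytest.approx(2 * 0.9 * 0.1 * 0.01)

    @pytest.mark.parametrize("pi,spacing", [(0.0185, 54), (0.0162, 62)])
    def test_published_snp_spacing_conversion(self, pi, spacing):
        assert pg.snp_spacing(pi) == spacing

    def test_indel_columns_excluded_pairwise(self):
        seqs = {"X": "AAT-A", "Y": "AATCA", "Z": "CATCA"}
        panel = HaplotypePanel(
            amplicons=[Amplicon("a", 5)],
            sequences={h: {"a": s} for h, s in seqs.items()},
            frequencies={h: 1 / 3 for h in seqs},
        )
        est = pg.nucleotide_diversity(panel)
        # X-Y: 0/4; X-Z: 1/4; Y-Z: 1/5
        assert est.pi_unweighted == pytest.approx((0 + 0.25 + 0.2) / 3)

    def test_unaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            HaplotypePanel(
                amplicons=[Amplicon("a", 5)],
                sequences={"X": {"a": "AAAAA"}, "Y": {"a": "AAA"}},
                frequencies={"X": 0.5, "Y": 0.5},
            )


class TestCodonEffects:
    def _panel(self, ref, alt, freq_alt=0.3):
        length = len(ref)
        return HaplotypePanel(
            amplicons=[Amplicon("a", length)],
            sequences={"R": {"a": ref}, "M": {"a": alt}},
            frequencies={"R": 1 - freq_alt, "M": freq_alt},
        )

    def test_third_position_change_synonymous(self):
        panel = self._panel("GATGAT", "GATGAC")
        tally = pg.codon_effects(panel, [pg.ExonInterval("a", 1, 6, 0)])
        assert (tally.n_synonymous, tally.n_nonsynonymous) == (1, 0)

    def test_nonsynonymous_change_detected(self):
        panel = self._panel("GATGAT", "GATGAA")  # Asp -> Glu
        tally = pg.codon_effects(panel, [pg.ExonInterval("a", 1, 6, 0)])
        assert (tally.n_synonymous, tally.n_nonsynonymous) == (0, 1)
        change = tally.changes[0]
        assert (change.ref_aa, change.alt_aa) == ("D", "E")

    def test_planted_tally_recovered_exactly(self):
        # 3 synonymous (3rd-position silent) + 2 non-synonymous planted
        ref = "GATGCTAAAGGGTTT"  # D A K G F
        alt = "GACGCGAAGGCGTTA"  # D A K A L : syn@1, syn@2, syn@3, nonsyn@4, nonsyn@5
        panel = self._panel(ref, alt)
        tally = pg.codon_effects(panel, [pg.ExonInterval("a", 1, 15, 0)])
        assert tally.n_synonymous == 3
        assert tally.n_nonsynonymous == 2
        assert tally.n_codons == 5

    def test_intronic_variants_counted_separately(self):
        ref = "TTGATGATTT"
        alt = "ATGATGATTA"  # changes at positions 1 and 10 (outside exon 3..8)
        panel = self._panel(ref, alt)
        tally = pg.codon_effects(panel, [pg.ExonInterval("a", 3, 8, 0)])
        assert tally.n_intronic == 2
        assert tally.n_polymorphic_codons == 0

    def test_premature_stop_flagged_dysfunctional(self):
        panel = self._panel("TATGAT", "TAAGAT")  # Tyr -> stop
        tally = pg.codon_effects(panel, [pg.ExonInterval("a", 1, 6, 0)])
        assert len(tally.dysfunctional) == 1


class TestNjTree:
    def test_jc_distance_closed_form(self):
        assert pg.jc_distance(0.05) == pytest.approx(0.0517, abs=5e-5)

    def test_jc_saturated_pair_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            pg.jc_distance(0.76)

    def test_four_taxon_additive_topology_recovered(self):
        # additive tree ((A,B),(C,D)) with internal branch 0.05
        rng = np.random.default_rng(2)
        base = rng.choice(list("ACGT"), size=400)

        def mutate(seq, k, rng):
            s = seq.copy()
            pos = rng.choice(len(s), size=k, replace=False)
            for p in pos:
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return s

        inner1 = mutate(base, 20, rng)  # internal edge
        seqs = {
            "A": "".join(mutate(base, 8, rng)),
            "B": "".join(mutate(base, 8, rng)),
            "C": "".join(mutate(inner1, 8, rng)),
            "D": "".join(mutate(inner1, 8, rng)),
        }
        res = pg.nj_tree(seqs, jc=False)
        dm = {
            x: {y: pg._p_distance(seqs[x], seqs[y]) for y in seqs} for x in seqs
        }
        pair, other, internal = best_quartet_topology(dm, ["A", "B", "C", "D"])
        tips_under = [
            frozenset(t.name for t in node.tips())
            for node in res.tree.non_tips(include_self=False)
        ]
        assert any(s in (pair, other) for s in tips_under)
        assert internal > 0

    def test_identical_sequences_star_tree(self):
        seqs = {h: "ACGT" * 50 for h in "WXYZ"}
        res = pg.nj_tree(seqs)
        assert res.tree.descending_branch_length() == pytest.approx(0.0)

    def test_tree_length_invariant_under_relabeling(self, preset_panel):
        seqs = {h: preset_panel.concatenated(h) for h in preset_panel.names}
        res1 = pg.nj_tree(seqs)
        renamed = {f"t_{h}": s for h, s in seqs.items()}
        res2 = pg.nj_tree(renamed)
        assert res1.tree.descending_branch_length() == pytest.approx(
            res2.tree.descending_branch_length()
        )

    def test_bootstrap_support_high_for_clear_split(self):
        rng = np.random.default_rng(5)
        base = rng.choice(list("ACGT"), size=300)
        group1 = base.copy()
        group1[:30] = "A"
        seqs = {
            "A": "".join(group1),
            "B": "".join(group1),
            "C": "".join(base),
            "D": "".join(base),
            "E": "".join(base),
        }
        seqs["A"] = seqs["A"][:1] + "C" + seqs["A"][2:]
        seqs["C"] = seqs["C"][:2] + "G" + seqs["C"][3:]
        res = pg.nj_tree(seqs, bootstrap_n=100, seed=7)
        key = frozenset({"A", "B"})
        assert res.support.get(key, 0) > 90

    def test_outgroup_roots_tree(self, preset_panel):
        seqs = {h: preset_panel.concatenated(h) for h in preset_panel.names[:6]}
        res = pg.nj_tree(seqs, outgroup=preset_panel.names[0])
        root_children_tipsets = [
            {t.name for t in child.tips(include_self=True)}
            for child in res.tree.children
        ]
        assert any(s == {preset_panel.names[0]} for s in root_children_tipsets)
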