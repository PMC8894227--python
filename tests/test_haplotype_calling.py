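"""Co-segregation clustering, tag-rule derivation and genotype resolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tetrahap.haplotype_calling as hc
import tetrahap.synthetic_data as syn
from tetrahap.model import DosageMatrix

from .oracles import exhaustive_resolve


def _matrix(data: dict[str, list[float]], amp="a") -> DosageMatrix:
    df = pd.DataFrame(data).T
    df.columns = [f"i{j}" for j in range(df.shape[1])]
    return DosageMatrix(amp, df)


class TestDosageR2:
    def test_identical_vectors_give_r2_one(self):
        m = _matrix({"a:1:T": [0, 1, 2, 3, 4], "a:2:G": [0, 1, 2, 3, 4]})
        rep = hc.compute_dosage_r2(m)
        assert rep.r2.loc["a:1:T", "a:2:G"] == pytest.approx(1.0)

    def test_complementary_allele_gives_r2_one(self):
        v = [0.0, 1, 2, 3, 4]
        m = _matrix({"a:1:T": v, "a:2:G": [4 - x for x in v]})
        rep = hc.compute_dosage_r2(m)
        assert rep.r2.loc["a:1:T", "a:2:G"] == pytest.approx(1.0)

    def test_monomorphic_variant_flagged_and_masked(self):
        m = _matrix({"a:1:T": [2, 2, 2, 2], "a:2:G": [0, 1, 2, 3]})
        rep = hc.compute_dosage_r2(m)
        assert rep.monomorphic == ["a:1:T"]
        assert np.isnan(rep.r2.loc["a:1:T", "a:2:G"])

    def test_unlinked_variants_have_low_mean_r2(self, preset_panel):
        cohort = syn.sample_cohort(preset_panel, 400, seed=31)
        x = syn.genotype_dosages(cohort, "B").to_numpy(dtype=float)
        y = syn.genotype_dosages(cohort, "C").to_numpy(dtype=float)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 < 0.05

    def test_requires_two_variants(self):
        m = _matrix({"a:1:T": [0, 1, 2]})
        with pytest.raises(ValueError):
            hc.compute_dosage_r2(m)


class TestClustering:
    def test_pairwise_perfect_correlation_one_cluster(self):
        m = _matrix({f"a:{i}:T": [0, 1, 2, 3, 4] for i in (1, 2, 3)})
        clusters = hc.cluster_cosegregating(hc.compute_dosage_r2(m), 0.9)
        assert clusters == [["a:1:T", "a:2:T", "a:3:T"]]

    def test_block_diagonal_gives_two_clusters(self):
        m = _matrix(
            {
                "a:1:T": [0, 1, 2, 3, 4, 0],
                "a:2:G": [0, 1, 2, 3, 4, 0],
                "a:3:C": [4, 0, 1, 0, 2, 2],
                "a:4:A": [4, 0, 1, 0, 2, 2],
            }
        )
        clusters = hc.cluster_cosegregating(hc.compute_dosage_r2(m), 0.9)
        assert len(clusters) == 2

    def test_noise_free_preset_has_one_unique_cluster_per_haplotype(
        self, preset_panel
    ):
        cohort = syn.sample_cohort(preset_panel, 400, seed=37)
        dos = syn.observe_dosages(cohort, preset_panel, noise_sd=0.0, seed=0)
        for amp in preset_panel.amplicons:
            inc = preset_panel.incidence(amp.id)
            rep = hc.compute_dosage_r2(dos[amp.id])
            clusters = hc.cluster_cosegregating(rep, 0.9999)
            unique_cols = inc.columns[(inc.sum(axis=0) == 1)]
            hap_of = {v: inc.index[inc[v] == 1][0] for v in unique_cols}
            tagged_haps = {hap_of[v] for c in clusters for v in c if v in hap_of}
            assert tagged_haps == set(preset_panel.names)


class TestRulesFromIncidence:
    def test_unique_tag_preferred_and_best_chosen(self):
        inc = pd.DataFrame(
            [[1, 1, 1]], index=["X"], columns=["a:5:T", "a:2:G", "a:9:C"]
        )
        # a:2:G has a missing value; a:5:T and a:9:C complete -> max variance, min pos
        m = _matrix(
            {
                "a:5:T": [0, 1, 2, 4],
                "a:2:G": [0, 1, np.nan, 4],
                "a:9:C": [0, 1, 2, 4],
            }
        )
        rs = hc.rules_from_incidence(inc, m, amplicon_id="a")
        assert rs.rules[0].variant == "a:5:T"

    def test_shared_tag_subtraction_rule(self):
        # D's only variant is shared with K; K has a unique tag
        inc = pd.DataFrame(
            [[1, 0], [1, 1]], index=["D", "K"], columns=["a:418:C", "a:419:C"]
        )
        rs = hc.rules_from_incidence(inc, amplicon_id="a")
        by_target = {r.target: r for r in rs.rules}
        assert by_target["D"].subtract == ("K",)
        col = pd.Series({"a:418:C": 2.0, "a:419:C": 1.0})
        out = hc._evaluate_rules(rs, col, 4, True)
        assert out["D"] == 1.0

    def test_identical_rows_merge_or_raise(self):
        inc = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]],
            index=["A1", "A2", "B"],
            columns=["a:1:T", "a:2:G"],
        )
        rs = hc.rules_from_incidence(inc, amplicon_id="a")
        assert rs.members["A1/A2"] == ("A1", "A2")
        with pytest.raises(ValueError, match="indistinguishable"):
            hc.rules_from_incidence(inc, amplicon_id="a", merge_identical=False)

    def test_cyclic_dependency_raises_with_offenders(self):
        # three haplotypes, only pairwise-shared variants: no evaluation order
        inc = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1], [0, 1, 1]],
            index=["X", "Y", "Z"],
            columns=["a:1:T", "a:2:G", "a:3:C"],
        )
        with pytest.raises(ValueError, match="cyclic"):
            hc.rules_from_incidence(inc, amplicon_id="a")


class TestLargestRemainder:
    @given(
        st.lists(st.floats(0, 4), min_size=2, max_size=16),
        st.integers(0, 8),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sums_to_total_and_stays_close(self, raw, total):
        out = hc.largest_remainder_round(np.array(raw), total)
        assert out.sum() == total
        assert (out >= 0).all()

    def test_integer_input_unchanged(self):
        out = hc.largest_remainder_round(np.array([2.0, 1.0, 1.0, 0.0]), 4)
        assert out.tolist() == [2, 1, 1, 0]


class TestResolveGenotypes:
    def test_noise_free_exact_recovery(self, small_panel):
        cohort = syn.sample_cohort(small_panel, 60, seed=41)
        dos = syn.observe_dosages(cohort, small_panel, noise_sd=0.0, seed=0)
        called = hc.resolve_with_panel(dos, small_panel)
        truth = {g.individual: g.alleles for g in cohort}
        assert all(g.alleles == truth[g.individual] for g in called)
        assert all(g.status == "resolved" for g in called)

    def test_matches_exhaustive_oracle_small_panel(self, small_panel):
        cohort = syn.sample_cohort(small_panel, 40, seed=43)
        dos = syn.observe_dosages(cohort, small_panel, noise_sd=0.0, seed=0)
        called = hc.resolve_with_panel(dos, small_panel)
        incs = {a.id: small_panel.incidence(a.id) for a in small_panel.amplicons}
        names = list(incs["amp1"].index)
        for i, g in enumerate(called):
            cols = {
                amp: dos[amp].values.iloc[:, i].to_numpy() for amp in dos
            }
            oracle, score = exhaustive_resolve(cols, incs, names)
            assert score == pytest.approx(0.0)
            assert g.alleles == oracle

    def test_matches_exhaustive_oracle_preset_sampled(self, preset_panel):
        cohort = syn.sample_cohort(preset_panel, 12, seed=47)
        dos = syn.observe_dosages(cohort, preset_panel, noise_sd=0.0, seed=0)
        called = hc.resolve_with_panel(dos, preset_panel)
        incs = {a.id: preset_panel.incidence(a.id) for a in preset_panel.amplicons}
        names = list(incs["amp1"].index)
        for i, g in enumerate(called):
            cols = {amp: dos[amp].values.iloc[:, i].to_numpy() for amp in dos}
            oracle, _ = exhaustive_resolve(cols, incs, names)
            assert g.alleles == oracle

    def test_reconstruction_conserves_dosages(self, small_panel):
        from collections import Counter

        cohort = syn.sample_cohort(small_panel, 30, seed=53)
        dos = syn.observe_dosages(cohort, small_panel, noise_sd=0.0, seed=0)
        called = hc.resolve_with_panel(dos, small_panel)
        for i, g in enumerate(called):
            assert len(g.alleles) == 4
            counts = Counter(g.alleles)
            for amp in dos:
                inc = small_panel.incidence(amp)
                copies = np.array([counts.get(h, 0) for h in inc.index])
                assert np.array_equal(
                    copies @ inc.to_numpy(), dos[amp].values.iloc[:, i].to_numpy()
                )

    def test_sum_violation_flagged_failed_not_repaired(self):
        inc = pd.DataFrame(
            [[1, 0], [0, 1]], index=["X", "Y"], columns=["a:1:T", "a:2:G"]
        )
        rs = hc.rules_from_incidence(inc, amplicon_id="a")
        m = _matrix({"a:1:T": [3.0], "a:2:G": [3.0]})  # sums to 6, not 4
        out = hc.resolve_genotypes({"a": m}, {"a": rs})
        assert out[0].status == "failed"
        assert out[0].alleles == ()

    def test_grouped_only_with_single_amplicon_iis(self):
        inc = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]],
            index=["A1", "A2", "B"],
            columns=["a:1:T", "a:2:G"],
        )
        rs = hc.rules_from_incidence(inc, amplicon_id="a")
        m = _matrix({"a:1:T": [2.0], "a:2:G": [2.0]})
        out = hc.resolve_genotypes(
            {"a": m}, {"a": rs}, grouping={"A1": "A", "A2": "A"}
        )
        assert out[0].status == "grouped-only"
        assert out[0].alleles == ("A", "A", "B", "B")

    def test_cross_amplicon_rescue_of_iis_group(self):
        # amplicon a cannot split A1/A2; amplicon b can -> full resolution
        inc_a = pd.DataFrame(
            [[1, 0], [1, 0], [0, 1]],
            index=["A1", "A2", "B"], columns=["a:1:T", "a:2:G"],
        )
        inc_b = pd.DataFrame(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
            index=["A1", "A2", "B"], columns=["b:1:T", "b:2:G", "b:3:C"],
        )
        rs = {
            "a": hc.rules_from_incidence(inc_a, amplicon_id="a"),
            "b": hc.rules_from_incidence(inc_b, amplicon_id="b"),
        }
        mats = {
            "a": _matrix({"a:1:T": [2.0], "a:2:G": [2.0]}, amp="a"),
            "b": _matrix({"b:1:T": [2.0], "b:2:G": [0.0], "b:3:C": [2.0]}, amp="b"),
        }
        out = hc.resolve_genotypes(mats, rs, grouping={"A1": "A", "A2": "A"})
        assert out[0].status == "resolved"
        assert out[0].alleles == ("A1", "A1", "B", "B")

    def test_amplicon_disagreement_fails_individual(self):
        inc = pd.DataFrame([[1, 0], [0, 1]], index=["X", "Y"],
                           columns=["a:1:T", "a:2:G"])
        inc_b = pd.DataFrame([[1, 0], [0, 1]], index=["X", "Y"],
                             columns=["b:1:T", "b:2:G"])
        rs = {
            "a": hc.rules_from_incidence(inc, amplicon_id="a"),
            "b": hc.rules_from_incidence(inc_b, amplicon_id="b"),
        }
        mats = {
            "a": _matrix({"a:1:T": [3.0], "a:2:G": [1.0]}, amp="a"),
            "b": _matrix({"b:1:T": [2.0], "b:2:G": [2.0]}, amp="b"),
        }
        out = hc.resolve_genotypes(mats, rs)
        assert out[0].status == "failed"


class TestEndToEnd:
    def test_de_novo_recovers_full_panel_under_noise(self, preset_panel):
        cohort = syn.sample_cohort(preset_panel, 400, seed=61)
        dos = syn.observe_dosages(cohort, preset_panel, noise_sd=0.15, seed=62)
        geno, _ = hc.call_de_novo(dos)
        resolved = [g for g in geno if g.status == "resolved"]
        assert len(resolved) / len(geno) >= 0.96
        haps = {a for g in resolved for a in g.alleles}
        assert len(haps) == 16

    def test_recovery_monotone_in_noise_and_missingness(self, small_panel):
        cohort = syn.sample_cohort(small_panel, 150, seed=67)

        def rate(noise, miss):
            dos = syn.observe_dosages(
                cohort, small_panel, noise_sd=noise, missing_rate=miss, seed=68
            )
            called = hc.resolve_with_panel(dos, small_panel)
            return np.mean([g.status == "resolved" for g in called])

        assert rate(0.0, 0.0) >= rate(0.25, 0.0) >= rate(0.6, 0.0)
        assert rate(0.0, 0.0) >= rate(0.0, 0.3) >= rate(0.0, 0.6)

    def test_two_noise_free_amplicons_always_concordant(self, small_panel):
        cohort = syn.sample_cohort(small_panel, 80, seed=71)
        dos = syn.observe_dosages(cohort, small_panel, noise_sd=0.0, seed=0)
        called = hc.resolve_with_panel(dos, small_panel)
        assert all(g.status == "resolved" for g in called)
        assert all(set(g.support) == {"amp1", "amp2"} for g in called)


class TestClassify:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("A", "A", "A", "A"), "monogenic"),
            (("A", "A", "A", "B"), "digenic-simplex"),
            (("A", "A", "B", "B"), "digenic-duplex"),
            (("B", "B", "C", "H"), "trigenic"),
            (("A", "B", "C", "D"), "tetragenic"),
        ],
    )
    def test_gallais_patterns(self, alleles, expected):
        assert hc.classify_genotype(alleles) == expected

    def test_wrong_ploidy_rejected(self):
        with pytest.raises(ValueError):
            hc.classify_genotype(("A", "B", "C"))
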