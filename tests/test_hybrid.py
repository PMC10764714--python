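import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iqsmerge import hybrid
from iqsmerge.hybrid import (
    HybridConfig,
    accord_split_iqs,
    classify_concordance,
    merge_runs,
    select_trio,
)
from iqsmerge.vcf_io import GenotypePosterior, ImputedDataset, VariantKey

from conftest import make_keys, point_mass_gp


trio = GenotypePosterior


class TestSelectTrio:
    def test_confident_run_wins_beyond_margin(self):
        a, b = trio(0.95, 0.05, 0.0), trio(0.85, 0.15, 0.0)
        kept, label = select_trio(a, b, HybridConfig(delta=0.05))
        assert kept == a and label == "A_selected"  # 0.95 > 0.85 + 0.05

    def test_margin_boundary_is_strict_priority_to_b(self):
        a, b = trio(0.90, 0.10, 0.0), trio(0.85, 0.15, 0.0)
        kept, label = select_trio(a, b, HybridConfig(delta=0.05))
        assert kept == b and label == "B_selected"  # 0.90 > 0.90 is false

    def test_missing_side_passes_through(self):
        b = trio(0.4, 0.6, 0.0)
        assert select_trio(None, b) == (b, "B_only")
        a = trio(0.7, 0.3, 0.0)
        assert select_trio(a, None) == (a, "A_only")
        assert select_trio(None, None) == (None, "missing")

    def test_retained_trio_is_never_blended(self):
        a, b = trio(0.6, 0.4, 0.0), trio(0.55, 0.45, 0.0)
        kept, _ = select_trio(a, b, HybridConfig(delta=0.0))
        assert kept in (a, b)

    def test_priority_a_mirrors_the_rule(self):
        a, b = trio(0.85, 0.15, 0.0), trio(0.90, 0.10, 0.0)
        kept, label = select_trio(a, b, HybridConfig(delta=0.05, priority_source="a"))
        assert kept == a and label == "A_selected"  # 0.90 not > 0.85 + 0.05

    @given(
        st.floats(1 / 3, 1.0),
        st.floats(1 / 3, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_at_zero_delta_except_exact_ties(self, pa, pb):
        a = trio(pa, 1 - pa, 0.0)
        b = trio(pb, 1 - pb, 0.0)
        cfg = HybridConfig(delta=0.0)
        kept_ab, _ = select_trio(a, b, cfg)
        kept_ba, _ = select_trio(b, a, cfg)
        if a.p_max == b.p_max:
            # exact ties go to the priority source in both orders
            assert kept_ab == b and kept_ba == a
        else:
            winner = a if a.p_max > b.p_max else b
            assert kept_ab == winner and kept_ba == winner

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HybridConfig(delta=1.0)
        with pytest.raises(ValueError):
            HybridConfig(priority_source="c")


class TestClassifyConcordance:
    def test_agreement_and_disagreement(self):
        assert classify_concordance(trio(0.95, 0.05, 0), trio(0.85, 0.15, 0)) == "Accord"
        assert classify_concordance(trio(0.2, 0.7, 0.1), trio(0.6, 0.3, 0.1)) == "Discord"
        assert classify_concordance(None, trio(0.9, 0.1, 0)) == "n/a"

    def test_argmax_tie_breaks_to_smaller_code(self):
        assert classify_concordance(trio(0.5, 0.5, 0), trio(0.9, 0.1, 0)) == "Accord"


class TestMergeRuns:
    def _runs(self):
        keys_a = make_keys(3)  # 100, 200, 300
        keys_b = make_keys(3, start=200)  # 200, 300, 400
        gp_a = np.tile([0.98, 0.02, 0.0], (3, 2, 1))
        gp_b = np.tile([0.80, 0.20, 0.0], (3, 2, 1))
        a = ImputedDataset(keys_a, ["s1", "s2"], gp_a, source="A")
        b = ImputedDataset(keys_b, ["s1", "s2"], gp_b, source="B")
        return a, b

    def test_union_complete_and_unique(self):
        a, b = self._runs()
        merged, prov = merge_runs(a, b)
        assert merged.n_variants == 4
        assert len(set(merged.variants)) == 4
        assert prov.n_intersection == 2
        assert prov.n_only_a == 1 and prov.n_only_b == 1

    def test_single_source_variants_pass_through(self):
        a, b = self._runs()
        merged, prov = merge_runs(a, b)
        by_key = {k: i for i, k in enumerate(merged.variants)}
        only_b = by_key[VariantKey("1", 400, "A", "G")]
        assert (prov.source[only_b] == hybrid.B_ONLY).all()
        assert np.allclose(merged.gp[only_b], [0.80, 0.20, 0.0])
        only_a = by_key[VariantKey("1", 100, "A", "G")]
        assert (prov.source[only_a] == hybrid.A_ONLY).all()

    def test_selection_copies_trios_unchanged(self):
        a, b = self._runs()
        merged, prov = merge_runs(a, b)
        by_key = {k: i for i, k in enumerate(merged.variants)}
        shared = by_key[VariantKey("1", 200, "A", "G")]
        # a is confident beyond delta, so a is selected everywhere
        assert (prov.source[shared] == hybrid.A_SELECTED).all()
        assert np.allclose(merged.gp[shared], [0.98, 0.02, 0.0])

    def test_vectorised_merge_matches_scalar_rule(self):
        rng = np.random.default_rng(5)
        keys = make_keys(30)
        gp_a = rng.dirichlet(np.ones(3), size=(30, 4))
        gp_b = rng.dirichlet(np.ones(3), size=(30, 4))
        a = ImputedDataset(keys, list("wxyz"), gp_a)
        b = ImputedDataset(keys, list("wxyz"), gp_b)
        cfg = HybridConfig(delta=0.05)
        merged, prov = merge_runs(a, b, cfg)
        for v in range(30):
            for s in range(4):
                kept, label = select_trio(a.trio(v, s), b.trio(v, s), cfg)
                assert np.allclose(merged.gp[v, s], kept.as_array())
                assert hybrid.SOURCE_LABELS[int(prov.source[v, s])] == label

    def test_concordance_fractions_partition(self):
        rng = np.random.default_rng(6)
        keys = make_keys(50)
        gp_a = rng.dirichlet(np.ones(3), size=(50, 3))
        gp_b = rng.dirichlet(np.ones(3), size=(50, 3))
        gp_a[::7] = np.nan  # some missing genotypes
        a = ImputedDataset(keys, list("pqr"), gp_a)
        b = ImputedDataset(keys, list("pqr"), gp_b)
        _, prov = merge_runs(a, b)
        for s in range(3):
            col = prov.concordance[:, s]
            total = (col == hybrid.ACCORD).sum() + (col == hybrid.DISCORD).sum() + (col == hybrid.NA).sum()
            assert total == 50


class TestAccordSplit:
    def test_identical_runs_are_all_accord(self, tiny_truth):
        gp = point_mass_gp(tiny_truth.calls)
        a = ImputedDataset(list(tiny_truth.variants), list(tiny_truth.samples), gp, source="A")
        b = ImputedDataset(list(tiny_truth.variants), list(tiny_truth.samples), gp.copy(), source="B")
        merged, _ = merge_runs(a, b)
        report = accord_split_iqs(a, b, merged, tiny_truth)
        assert (report["accord_fraction"] == 1.0).all()
        assert not report["discord_defined"].any()
        assert report["discord_correct_hyb"].isna().all()

    def test_total_disagreement_with_a_always_right(self):
        keys = make_keys(6)
        truth_calls = np.array([[0], [1], [2], [0], [1], [2]], dtype=np.int8)
        from iqsmerge.vcf_io import TruthGenotypes

        truth = TruthGenotypes(keys, ["s1"], truth_calls)
        gp_a = point_mass_gp(truth_calls) * 0.96 + 0.02  # confident, correct
        wrong = (truth_calls + 1) % 3
        gp_b = point_mass_gp(wrong) * 0.7 + 0.1  # less confident, wrong
        a = ImputedDataset(keys, ["s1"], gp_a, source="A")
        b = ImputedDataset(keys, ["s1"], gp_b, source="B")
        merged, prov = merge_runs(a, b, HybridConfig(delta=0.05))
        report = accord_split_iqs(a, b, merged, truth)
        assert report.loc[0, "accord_fraction"] == 0.0
        assert report.loc[0, "discord_correct_a"] == 1.0
        assert report.loc[0, "discord_correct_b"] == 0.0
        # a is selected everywhere (0.98 > 0.80 + 0.05) and always correct
        assert (prov.source == hybrid.A_SELECTED).all()
        assert report.loc[0, "discord_correct_hyb"] == 1.0

    def test_accord_more_reliable_than_discord_in_simulation(self, scenario):
        merged, _ = merge_runs(scenario.run_a, scenario.run_b)
        report = accord_split_iqs(scenario.run_a, scenario.run_b, merged, scenario.truth)
        assert report["accord_correct"].mean() > report["discord_correct_hyb"].mean()
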