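import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iqsmerge import metrics
from iqsmerge.metrics import (
    ContingencyTable3x3,
    StratumSpec,
    build_contingency,
    hard_call_gp,
    het_dosage_distribution,
    iqs,
    iqs_from_table,
    iqs_stratified,
    read_bed,
)
from iqsmerge.vcf_io import MISSING, ImputedDataset, TruthGenotypes

from conftest import make_keys, point_mass_gp


def kappa_reference(table: np.ndarray) -> float:
    """Independent Cohen's-kappa oracle: sklearn on weighted pseudo-observations."""
    from sklearn.metrics import cohen_kappa_score

    y_true, y_pred, w = [], [], []
    for j in range(3):
        for k in range(3):
            y_true.append(j)
            y_pred.append(k)
            w.append(table[j, k])
    return cohen_kappa_score(y_true, y_pred, labels=[0, 1, 2], sample_weight=w)


class TestBuildContingency:
    def test_point_masses_fill_hard_cells(self):
        truth = np.array([0, 0, 1, 2])
        gp = point_mass_gp(np.array([0, 0, 1, 1]))
        t = build_contingency(gp, truth)
        assert t.N == 4
        assert t.n[0, 0] == 2 and t.n[1, 1] == 1 and t.n[2, 1] == 1
        assert t.n.sum() == pytest.approx(4)

    def test_fractional_trio_is_placed_as_a_row(self):
        t = build_contingency(np.array([[0.2, 0.5, 0.3]]), np.array([1]))
        assert t.n[1].tolist() == [0.2, 0.5, 0.3]
        assert t.N == 1

    def test_missing_truth_and_missing_trios_excluded(self):
        gp = np.array([[0.9, 0.1, 0.0], [np.nan] * 3, [0.5, 0.5, 0.0]])
        truth = np.array([0, 1, MISSING])
        t = build_contingency(gp, truth)
        assert t.N == 1
        assert build_contingency(gp, np.full(3, MISSING)).empty

    def test_row_sums_equal_truth_counts(self):
        rng = np.random.default_rng(7)
        gp = rng.dirichlet(np.ones(3), size=50)
        truth = rng.integers(0, 3, size=50)
        t = build_contingency(gp, truth)
        for j in range(3):
            assert t.n[j].sum() == pytest.approx((truth == j).sum(), abs=1e-9)


class TestIqsFromTable:
    def test_hand_computed_example(self):
        # truth [0,0,1,2], point masses on [0,0,1,1]
        t = build_contingency(point_mass_gp(np.array([0, 0, 1, 1])), np.array([0, 0, 1, 2]))
        r = iqs_from_table(t)
        assert r.p_o == pytest.approx(0.75)
        assert r.p_c == pytest.approx(0.375)  # (2*2 + 1*2 + 1*0)/16
        assert r.iqs == pytest.approx(0.6)

    def test_perfect_imputation_scores_exactly_one(self):
        truth = np.array([0, 1, 2, 1, 0])
        r = iqs(point_mass_gp(truth), truth)
        assert r.p_o == 1.0 and r.iqs == 1.0

    def test_constant_prediction_scores_exactly_zero(self):
        truth = np.array([0, 1, 2, 1])
        gp = np.tile([1.0, 0.0, 0.0], (4, 1))
        r = iqs(gp, truth)
        assert r.p_o == pytest.approx(r.p_c)
        assert r.iqs == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_table_is_flagged_undefined(self):
        # monomorphic stratum perfectly predicted: P_c = 1
        truth = np.zeros(5, dtype=int)
        r = iqs(point_mass_gp(truth), truth)
        assert not r.defined and np.isnan(r.iqs)
        assert not iqs_from_table(ContingencyTable3x3(np.zeros((3, 3)), 0)).defined

    def test_matches_independent_kappa_on_random_fractional_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            table = rng.random((3, 3)) * 10
            t = ContingencyTable3x3(table, table.sum())
            r = iqs_from_table(t)
            assert r.iqs == pytest.approx(kappa_reference(table), abs=1e-10)

    def test_pooling_is_cellwise_table_addition(self):
        rng = np.random.default_rng(3)
        gp = rng.dirichlet(np.ones(3), size=40)
        truth = rng.integers(0, 3, size=40)
        pooled = build_contingency(gp, truth)
        left = build_contingency(gp[:25], truth[:25])
        right = build_contingency(gp[25:], truth[25:])
        combined = left + right
        assert np.allclose(combined.n, pooled.n)
        assert combined.N == pooled.N

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_genotype_ordering(self, seed):
        rng = np.random.default_rng(seed)
        gp = rng.dirichlet(np.ones(3), size=30)
        truth = rng.integers(0, 3, size=30)
        perm = rng.permutation(30)
        assert iqs(gp, truth).iqs == pytest.approx(iqs(gp[perm], truth[perm]).iqs, abs=1e-12)


class TestStratified:
    def _datasets(self):
        keys = make_keys(4)
        truth_calls = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        truth = TruthGenotypes(keys, ["good", "flat"], truth_calls)
        gp = np.empty((4, 2, 3))
        gp[:, 0] = point_mass_gp(truth_calls[:, 0])  # perfect for sample "good"
        gp[:, 1] = [1.0, 0.0, 0.0]  # constant prediction for sample "flat"
        imp = ImputedDataset(keys, ["good", "flat"], gp)
        return imp, truth

    def test_per_individual_perfect_vs_constant(self):
        imp, truth = self._datasets()
        out = iqs_stratified(imp, truth, StratumSpec("individual")).set_index("stratum")
        assert out.loc["good", "iqs"] == pytest.approx(1.0)
        assert out.loc["flat", "iqs"] == pytest.approx(0.0, abs=1e-12)

    def test_per_variant_matches_direct_computation(self):
        imp, truth = self._datasets()
        out = iqs_stratified(imp, truth, StratumSpec("variant"))
        direct = iqs(imp.gp[0], truth.calls[0])
        assert out.iloc[0]["iqs"] == pytest.approx(direct.iqs, nan_ok=True)
        assert len(out) == 4

    def test_region_axis_pools_contained_variants(self):
        imp, truth = self._datasets()
        regions = [metrics.Region("left", "1", 50, 250), metrics.Region("all", "1", 1, 1000)]
        out = iqs_stratified(imp, truth, StratumSpec("region", regions=regions))
        assert out.set_index("stratum").loc["left", "n_genotypes"] == 4  # 2 variants x 2 samples
        assert out.set_index("stratum").loc["all", "n_genotypes"] == 8

    def test_maf_bin_axis_uses_truth_maf(self):
        keys = make_keys(2)
        # variant 0 monomorphic-ish rare (1 het / 6 alleles), variant 1 common
        truth = TruthGenotypes(keys, ["a", "b", "c"], np.array([[0, 0, 1], [1, 2, 0]], dtype=np.int8))
        gp = point_mass_gp(truth.calls)
        imp = ImputedDataset(keys, ["a", "b", "c"], gp)
        out = iqs_stratified(imp, truth, StratumSpec("maf_bin", maf_threshold=0.2))
        assert out.set_index("stratum").loc["rare", "n_genotypes"] == 3
        assert out.set_index("stratum").loc["common", "n_genotypes"] == 3

    def test_hard_call_mode_collapses_trios(self):
        gp = np.array([[[0.4, 0.35, 0.25]]])
        assert hard_call_gp(gp)[0, 0].tolist() == [1.0, 0.0, 0.0]
        nan_trio = np.array([[[np.nan] * 3]])
        assert np.isnan(hard_call_gp(nan_trio)).all()

    def test_group_accuracy_gradient_shows_in_per_individual_iqs(self, scenario):
        """Samples imputed with higher accuracy score higher, per group."""
        out = iqs_stratified(scenario.run_a, scenario.truth, StratumSpec("individual"))
        out["group"] = out["stratum"].map(scenario.groups)
        means = out.groupby("group")["iqs"].mean()
        assert means["west"] > means["east"]


class TestHetDosage:
    def test_perfect_hets_land_at_one(self):
        keys = make_keys(2)
        truth = TruthGenotypes(keys, ["s1"], np.array([[1], [1]], dtype=np.int8))
        imp = ImputedDataset(keys, ["s1"], np.array([[[0, 1, 0]], [[0, 1, 0]]], float))
        mask = np.array([[True], [False]])
        out = het_dosage_distribution(imp, truth, mask)
        one_bin = (out["bin_left"] <= 1.0) & (out["bin_right"] > 1.0)
        assert out.loc[one_bin, "count_inside"].sum() == 1
        assert out.loc[one_bin, "count_outside"].sum() == 1
        assert out["count_inside"].sum() == 1 and out["count_outside"].sum() == 1

    def test_half_dosage_counted_in_its_bin(self):
        keys = make_keys(1)
        truth = TruthGenotypes(keys, ["s1"], np.array([[1]], dtype=np.int8))
        imp = ImputedDataset(keys, ["s1"], np.array([[[0.5, 0.5, 0.0]]]))
        out = het_dosage_distribution(imp, truth, np.array([[True]]))
        hit = out[(out["count_inside"] > 0)]
        assert len(hit) == 1
        assert hit["bin_left"].iloc[0] <= 0.5 < hit["bin_right"].iloc[0] + 1e-12

    def test_no_heterozygotes_yields_empty_histograms(self):
        keys = make_keys(1)
        truth = TruthGenotypes(keys, ["s1"], np.array([[0]], dtype=np.int8))
        imp = ImputedDataset(keys, ["s1"], np.array([[[1.0, 0, 0]]]))
        out = het_dosage_distribution(imp, truth, np.array([[True]]))
        assert out["count_inside"].sum() == 0 and out["count_outside"].sum() == 0

    def test_masked_region_with_higher_accuracy_peaks_at_one(self):
        """Dosage mass near 1 is larger inside a mask where imputation is better."""
        rng = np.random.default_rng(11)
        n = 400
        keys = make_keys(n)
        truth = TruthGenotypes(keys, ["s1"], np.ones((n, 1), dtype=np.int8))
        gp = np.empty((n, 1, 3))
        inside = np.zeros((n, 1), dtype=bool)
        inside[: n // 2] = True
        for v in range(n):
            a = 0.95 if inside[v, 0] else 0.55
            good = rng.random() < a
            gp[v, 0] = [0.0, 1.0, 0.0] if good else [1.0, 0.0, 0.0]
        imp = ImputedDataset(keys, ["s1"], gp)
        out = het_dosage_distribution(imp, truth, inside)
        near_one = (out["bin_left"] >= 0.9) & (out["bin_left"] < 1.05)
        assert out.loc[near_one, "count_inside"].sum() > out.loc[near_one, "count_outside"].sum()


def test_read_bed_converts_to_one_based_inclusive(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("1\t99\t200\tgeneA\n2\t0\t50\n")
    regions = read_bed(bed)
    assert regions[0] == metrics.Region("geneA", "1", 100, 200)
    assert regions[1].start == 1 and regions[1].end == 50
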