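import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fmapy.compare import (
    DegenerateFitWarning,
    DesignTable,
    bh_fdr,
    kruskal_wallis,
    log2_fold_change,
    quasi_poisson_test,
    run_comparison,
)
from fmapy.quantify import AbundanceTable


def qp_oracle(a, b):
    """Closed-form two-group quasi-Poisson Wald test.

    Fitted means of a saturated group factor equal the sample means; the
    Wald variance of the log mean ratio is phi*(1/(n_a m_a) + 1/(n_b m_b))
    with phi = Pearson X^2/(n-2), referenced to Student-t with n-2 df.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    ma, mb = a.mean(), b.mean()
    n = a.size + b.size
    x2 = ((a - ma) ** 2).sum() / ma + ((b - mb) ** 2).sum() / mb
    phi = x2 / (n - 2)
    se = np.sqrt(phi * (1 / (a.size * ma) + 1 / (b.size * mb)))
    t = np.log(mb / ma) / se
    return float(2 * stats.t.sf(abs(t), n - 2))


def make_table(data: dict[str, list[float]], samples: list[str]) -> AbundanceTable:
    rpkm = pd.DataFrame(data, index=samples).T
    return AbundanceTable(
        kos=list(rpkm.index), samples=samples,
        raw=(rpkm * 0).astype(np.int64), rpkm=rpkm, totals={},
    )


TWO_GROUPS = ["a"] * 5 + ["b"] * 5


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        assert kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3) == pytest.approx(1.0, abs=1e-12)

    def test_separated_groups_worked_value(self):
        # tie-free closed form: H = 6.8182 -> p = chi2.sf(H, 1)
        p = kruskal_wallis(list(range(1, 11)), TWO_GROUPS)
        assert p == pytest.approx(stats.chi2.sf(6.818181818, df=1), rel=1e-6)
        assert p == pytest.approx(0.00902, abs=5e-5)

    def test_all_tied_returns_one(self):
        assert kruskal_wallis([4.0] * 10, TWO_GROUPS) == 1.0

    def test_three_groups_supported(self):
        p = kruskal_wallis([1, 2, 3, 10, 11, 12, 20, 21, 22],
                           ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert 0 < p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], ["a", "a"])


class TestQuasiPoisson:
    def test_identical_groups_p_one(self):
        p = quasi_poisson_test([5, 6, 7, 5, 6, 7], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_worked_case_matches_oracle(self):
        vals = [10, 12, 11, 9, 30, 28, 31, 33]
        p = quasi_poisson_test(vals, ["a"] * 4 + ["b"] * 4)
        assert p == pytest.approx(qp_oracle(vals[:4], vals[4:]), abs=1e-6)

    def test_all_zero_group_degenerate(self):
        with pytest.warns(DegenerateFitWarning):
            p = quasi_poisson_test([0, 0, 0, 5, 6, 7], ["a"] * 3 + ["b"] * 3)
        assert p == 1.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            quasi_poisson_test([-1, 2, 3, 4], ["a", "a", "b", "b"])

    def test_oracle_agreement_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            na, nb = rng.integers(3, 10, 2)
            a = rng.gamma(5, 2, na) + 0.5
            b = rng.gamma(5, 4, nb) + 0.5
            p = quasi_poisson_test(np.concatenate([a, b]), ["a"] * na + ["b"] * nb)
            assert p == pytest.approx(qp_oracle(a, b), abs=1e-6)

    def test_three_group_f_test(self):
        vals = [10, 11, 9, 10, 30, 31, 29, 30, 50, 49, 51, 50]
        p = quasi_poisson_test(vals, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        assert 0 < p < 0.01


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change(5, 5, 1.0) == 0.0

    def test_power_of_two(self):
        assert log2_fold_change(4, 1, 1e-9) == pytest.approx(2.0, abs=1e-6)

    def test_pseudocount_handles_zero(self):
        assert log2_fold_change(0, 3, 1.0) == pytest.approx(-2.0, abs=1e-12)

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError):
            log2_fold_change(1, 1, 0.0)


class TestBhFdr:
    def test_hand_computed_case(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == [0.2]

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_q_at_least_p_and_order_preserved(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50).tolist()
        q = bh_fdr(p)
        assert all(qi >= pi - 1e-15 and qi <= 1 for pi, qi in zip(p, q))
        # step-up: sorted q follows sorted p ordering monotonically
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-15).all()


class TestRunComparison:
    samples = [f"s{i}" for i in range(10)]
    design = DesignTable(
        assignments={f"s{i}": ("ctrl" if i < 5 else "case") for i in range(10)}
    )

    def test_separated_ko_called_da(self):
        table = make_table(
            {"K1": [10, 11, 9, 10, 11, 80, 82, 79, 81, 80],
             "K2": [50, 51, 49, 50, 51, 50, 49, 51, 50, 49]},
            self.samples,
        )
        res = run_comparison(table, self.design)
        assert res.da_kos == {"K1"}
        assert res.table.loc["K1", "log2_fc"] == pytest.approx(3.0, abs=0.1)

    def test_identical_values_no_da(self):
        table = make_table({"K1": [5.0] * 10, "K2": [7.0] * 10}, self.samples)
        res = run_comparison(table, self.design)
        assert res.da_kos == frozenset()

    def test_all_zero_ko_excluded_before_testing(self):
        table = make_table({"K1": [0.0] * 10, "K2": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]},
                           self.samples)
        res = run_comparison(table, self.design)
        assert "K1" not in res.table.index

    def test_label_swap_negates_lfc_keeps_p(self):
        table = make_table(
            {"K1": [10, 11, 9, 10, 11, 80, 82, 79, 81, 80]}, self.samples
        )
        fwd = run_comparison(table, self.design)
        swapped = DesignTable(
            assignments=self.design.assignments, groups=["case", "ctrl"]
        )
        rev = run_comparison(table, swapped)
        assert rev.table.loc["K1", "log2_fc"] == pytest.approx(
            -fwd.table.loc["K1", "log2_fc"], rel=1e-9
        )
        assert rev.table.loc["K1", "p_value"] == pytest.approx(
            fwd.table.loc["K1", "p_value"], rel=1e-9
        )

    def test_metagenomeseq_is_external_extension_point(self):
        table = make_table({"K1": [1.0] * 10}, self.samples)
        with pytest.raises(NotImplementedError, match="extension point"):
            run_comparison(table, self.design, method="metagenomeseq")

    def test_fdr_filter_stricter_than_raw(self):
        rng = np.random.default_rng(4)
        data = {f"K{i}": rng.uniform(1, 100, 10).tolist() for i in range(40)}
        table = make_table(data, self.samples)
        raw = run_comparison(table, self.design, filter_on="raw")
        fdr = run_comparison(table, self.design, filter_on="fdr")
        assert fdr.da_kos <= raw.da_kos


class TestDesignTable:
    def test_first_group_is_reference(self):
        d = DesignTable(assignments={"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
        assert d.reference == "g1"

    def test_from_tsv_with_reference_override(self, tmp_path):
        path = tmp_path / "design.tsv"
        path.write_text("sample_id\tgroup\ns1\tx\ns2\tx\ns3\ty\ns4\ty\n")
        d = DesignTable.from_tsv(path, reference="y")
        assert d.reference == "y"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            DesignTable(assignments={"s1": "g", "s2": "g"})

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            DesignTable(assignments={"s1": "g1", "s2": "g1", "s3": "g2"})
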