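from math import comb

import numpy as np
import pandas as pd
import pytest

from fmapy.compare import ComparisonResult
from fmapy.enrich import da_operons, enrich_features, fisher_enrichment
from tests.conftest import make_db


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher p: enumerate every fixed-margin table and
    sum hypergeometric probabilities not exceeding the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def pmf(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / denom

    p_obs = pmf(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))


def comparison_of(lfc_by_ko: dict[str, float], da: set[str]) -> ComparisonResult:
    df = pd.DataFrame(
        {
            "p_value": [0.01 if k in da else 0.5 for k in lfc_by_ko],
            "q_value": [0.05 if k in da else 0.8 for k in lfc_by_ko],
            "log2_fc": list(lfc_by_ko.values()),
            "is_da": [k in da for k in lfc_by_ko],
        },
        index=list(lfc_by_ko),
    )
    return ComparisonResult(
        table=df, method="kruskal", reference_group="ctrl", case_group="case",
        alpha=0.05, min_abs_log2fc=1.0, filter_on="raw",
    )


class TestDaOperons:
    db = make_db(
        proteins=[(f"P{i}", f"K{i}", 100) for i in range(1, 10)],
        operons=[
            ("OP1", ["K1", "K2"], ""),
            ("OP2", ["K1", "K2", "K3"], ""),
            ("OP3", ["K4", "K4", "K5"], "dupes collapse"),
        ],
    )

    def test_full_membership_required(self):
        ops = da_operons({"K1", "K2", "K9"}, self.db)
        assert [o.operon_id for o in ops] == ["OP1"]

    def test_partial_membership_excluded(self):
        assert da_operons({"K1", "K2"}, self.db) == da_operons({"K1", "K2", "K9"}, self.db)
        assert "OP2" not in [o.operon_id for o in da_operons({"K1", "K2"}, self.db)]

    def test_empty_da_set(self):
        assert da_operons(set(), self.db) == []

    def test_duplicate_members_collapse(self):
        ops = da_operons({"K4", "K5"}, self.db)
        assert [o.operon_id for o in ops] == ["OP3"]

    def test_monotone_under_da_growth(self):
        rng = np.random.default_rng(9)
        kos = [f"K{i}" for i in range(1, 10)]
        for _ in range(50):
            small = set(rng.choice(kos, size=rng.integers(0, 6), replace=False))
            extra = set(rng.choice(kos, size=rng.integers(0, 4), replace=False))
            before = {o.operon_id for o in da_operons(small, self.db)}
            after = {o.operon_id for o in da_operons(small | extra, self.db)}
            assert before <= after


class TestFisherEnrichment:
    def test_worked_case_one_over_126(self):
        universe = {f"K{i}" for i in range(10)}
        feature = {f"K{i}" for i in range(5)}
        da = feature  # a=5, b=0, c=0, d=5
        p, count, coverage = fisher_enrichment(da, feature, universe)
        assert p == pytest.approx(2 / comb(10, 5), rel=1e-10)
        assert count == 5 and coverage == 1.0

    def test_degenerate_margins_p_one(self):
        universe = {f"K{i}" for i in range(8)}
        p, _, _ = fisher_enrichment(universe, set(list(universe)[:3]), universe)
        assert p == 1.0

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment({"K1"}, {"K1"}, set())

    def test_feature_outside_universe_errors(self):
        with pytest.raises(ValueError, match="feature"):
            fisher_enrichment({"K1"}, {"K9"}, {"K1", "K2"})

    def test_row_swap_symmetry(self):
        universe = {f"K{i}" for i in range(20)}
        feature = {f"K{i}" for i in range(6)}
        da = {f"K{i}" for i in range(3, 12)}
        p1, _, _ = fisher_enrichment(da, feature, universe)
        p2, _, _ = fisher_enrichment(universe - da, feature, universe)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            n = int(rng.integers(4, 41))
            kos = [f"K{i}" for i in range(n)]
            feature = set(rng.choice(kos, size=rng.integers(1, n), replace=False))
            da = set(rng.choice(kos, size=rng.integers(0, n + 1), replace=False))
            p, a, _ = fisher_enrichment(da, feature, set(kos))
            b = len(feature) - a
            c = len(da & set(kos)) - a
            d = n - len(feature) - c
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)


class TestEnrichFeatures:
    db = make_db(
        proteins=[(f"P{i}", f"K{i}", 100) for i in range(1, 21)],
        pathways=[
            ("mapA", "enriched", [f"K{i}" for i in range(1, 6)]),
            ("mapB", "untouched", [f"K{i}" for i in range(10, 15)]),
        ],
        operons=[("OP1", ["K1", "K2"], "both DA")],
    )

    def test_pathway_with_all_da_members_small_p(self):
        lfc = {f"K{i}": (2.0 if i <= 5 else 0.0) for i in range(1, 21)}
        comp = comparison_of(lfc, {f"K{i}" for i in range(1, 6)})
        results = enrich_features(comp, self.db, kind="pathway")
        assert [r.feature_id for r in results] == ["mapA"]
        r = results[0]
        assert r.coverage == 1.0
        assert r.p_value == pytest.approx(fisher_oracle(5, 0, 0, 15), abs=1e-10)

    def test_zero_da_pathway_not_reported(self):
        comp = comparison_of({f"K{i}": 0.0 for i in range(1, 21)}, set())
        assert enrich_features(comp, self.db, kind="pathway") == []

    def test_operon_avg_log2fc_is_mean_over_da_members(self):
        lfc = {f"K{i}": 0.0 for i in range(1, 21)}
        lfc["K1"], lfc["K2"] = 2.0, 3.0
        comp = comparison_of(lfc, {"K1", "K2"})
        (r,) = enrich_features(comp, self.db, kind="operon")
        assert r.feature_id == "OP1"
        assert r.avg_log2_fc == pytest.approx(2.5)

    def test_coverage_consistency_three_decimals(self):
        lfc = {f"K{i}": 1.5 for i in range(1, 21)}
        comp = comparison_of(lfc, {"K1", "K2", "K3", "K11"})
        for r in enrich_features(comp, self.db, kind="pathway"):
            assert round(r.coverage, 3) == round(r.ko_count / r.feature_size, 3)

    def test_unknown_kind_rejected(self):
        comp = comparison_of({"K1": 1.0}, {"K1"})
        with pytest.raises(ValueError, match="kind"):
            enrich_features(comp, self.db, kind="module")

    def test_detected_universe_changes_background(self):
        lfc = {f"K{i}": 2.0 for i in range(1, 21)}
        comp = comparison_of(lfc, {f"K{i}" for i in range(1, 6)})
        ref = enrich_features(comp, self.db, kind="pathway", universe_mode="reference")
        det = enrich_features(
            comp, self.db, kind="pathway", universe_mode="detected",
            detected_kos={f"K{i}" for i in range(1, 11)},
        )
        assert ref[0].p_value != det[0].p_value
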