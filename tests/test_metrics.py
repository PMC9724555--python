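import math

import pytest

from ibdbench import (
    GeneticMap,
    HaplotypeId,
    HapPair,
    MetricConfig,
    best_match,
    bin_segments,
    evaluate_binned,
    evaluate_reported,
    evaluate_truth,
)
from ibdbench.synthdata import ScenarioSpec, gen_scenario, oracle_report

from .conftest import cm_segment, make_pair

APPROX = dict(abs=1e-9)


class TestBestMatch:
    def test_single_candidate_covering(self, umap, pair):
        subject = cm_segment(umap, 12, 18, pair=pair)
        cand = cm_segment(umap, 10, 20, pair=pair)
        m = best_match(subject, [cand])
        assert m.best is cand
        assert m.best_overlap_cm == pytest.approx(6.0, **APPROX)
        assert m.covered  # 6/6 >= 0.5

    def test_tie_broken_toward_closer_length_then_earlier_start(self, umap, pair):
        subject = cm_segment(umap, 0, 10, pair=pair)
        short = cm_segment(umap, 0, 4, pair=pair)
        long = cm_segment(umap, 5, 9, pair=pair)
        m = best_match(subject, [short, long])
        assert m.best_overlap_cm == pytest.approx(4.0, **APPROX)
        assert not m.covered  # 4/10 < 0.5
        # equal overlap, equal |length diff| -> earlier start wins
        assert m.best is short

    def test_no_same_pair_candidate(self, umap):
        subject = cm_segment(umap, 0, 10, pair=make_pair("p"))
        other = cm_segment(umap, 0, 10, pair=make_pair("q"))
        m = best_match(subject, [other])
        assert m.best is None and not m.covered


class TestEvaluateReported:
    def test_nested_report(self, umap, pair):
        T = [cm_segment(umap, 10, 20, pair=pair)]
        R = [cm_segment(umap, 12, 18, pair=pair)]
        acc, lacc, disc = evaluate_reported(R, T)
        assert acc == pytest.approx(1.0, **APPROX)
        assert lacc == pytest.approx(1.0, **APPROX)
        assert disc == pytest.approx(4.0, **APPROX)  # |6 - 10|

    def test_fragmented_report(self, umap, pair):
        T = [cm_segment(umap, 0, 10, pair=pair)]
        R = [cm_segment(umap, 0, 4, pair=pair), cm_segment(umap, 5, 9, pair=pair)]
        acc, lacc, disc = evaluate_reported(R, T)
        assert acc == pytest.approx(1.0, **APPROX)
        assert lacc == pytest.approx(1.0, **APPROX)
        assert disc == pytest.approx(6.0, **APPROX)  # sqrt((36+36)/2)

    def test_disjoint_report(self, umap, pair):
        T = [cm_segment(umap, 50, 60, pair=pair)]
        R = [cm_segment(umap, 0, 4, pair=pair)]
        acc, lacc, disc = evaluate_reported(R, T)
        assert acc == 0.0 and lacc == 0.0 and math.isnan(disc)

    def test_empty_reported_all_missing(self, umap, pair):
        T = [cm_segment(umap, 0, 10, pair=pair)]
        assert all(math.isnan(v) for v in evaluate_reported([], T))


class TestEvaluateTruth:
    def test_fragmented_coverage(self, umap, pair):
        T = [cm_segment(umap, 0, 10, pair=pair)]
        R = [cm_segment(umap, 0, 4, pair=pair), cm_segment(umap, 5, 9, pair=pair)]
        rec, pw, apw = evaluate_truth(T, R)
        assert rec == pytest.approx(0.0, **APPROX)  # best 4/10 < 0.5
        assert pw == pytest.approx(0.4, **APPROX)
        assert apw == pytest.approx(0.8, **APPROX)  # union 4 + 4

    def test_exact_match(self, umap, pair):
        T = [cm_segment(umap, 3, 8, pair=pair)]
        assert evaluate_truth(T, list(T)) == pytest.approx((1.0, 1.0, 1.0), **APPROX)

    def test_half_coverage_boundary_inclusive(self, umap, pair):
        T = [cm_segment(umap, 0, 10, pair=pair)]
        R = [cm_segment(umap, 0, 5, pair=pair)]
        rec, pw, apw = evaluate_truth(T, R)
        assert rec == pytest.approx(1.0, **APPROX)  # "at least 50%"

    def test_union_does_not_double_count_overlapping_reports(self, umap, pair):
        T = [cm_segment(umap, 0, 10, pair=pair)]
        R = [cm_segment(umap, 0, 6, pair=pair), cm_segment(umap, 4, 8, pair=pair)]
        _, _, apw = evaluate_truth(T, R)
        assert apw == pytest.approx(0.8, **APPROX)  # union [0,8), not 10/10


class TestBinning:
    def test_assignments(self, umap):
        edges = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
        segs = {
            2.9: "[2,3)",
            7.5: "[7,inf)",
            3.0: "[3,4)",
        }
        for length, label in segs.items():
            s = cm_segment(umap, 10, 10 + length)
            bins = bin_segments([s], edges)
            assert s in bins[label]
        short = cm_segment(umap, 10, 11.5)
        bins = bin_segments([short], edges)
        assert all(short not in v for v in bins.values())

    def test_full_set_reference_rescues_cross_bin_match(self, umap, pair):
        truth = [cm_segment(umap, 10, 13, pair=pair)]  # 3.0 cM -> [3,4)
        reported = [cm_segment(umap, 10.05, 12.95, pair=pair)]  # 2.9 cM -> [2,3)
        full = evaluate_binned(truth, reported, reference="full")
        assert full["[2,3)"].accuracy == pytest.approx(1.0, **APPROX)
        per_bin = evaluate_binned(truth, reported, reference="binned")
        assert per_bin["[2,3)"].accuracy == pytest.approx(0.0, **APPROX)

    def test_identity_sets_score_perfectly(self, umap):
        segs = [
            cm_segment(umap, 10 * i, 10 * i + 2.5 + i, pair=make_pair(f"p{i}"))
            for i in range(5)
        ]
        report = evaluate_binned(segs, list(segs))
        for label, row in report.rows.items():
            if row.n_truth == 0:
                continue
            assert row.accuracy == 1.0 and row.recall == 1.0
            assert row.power == 1.0 and row.accumulative_power == 1.0
            assert row.length_discrepancy_cm == pytest.approx(0.0, **APPROX)

    def test_report_counts_and_frame(self, umap, pair):
        truth = [cm_segment(umap, 0, 4, pair=pair)]
        report = evaluate_binned(truth, list(truth))
        df = report.to_frame()
        assert df.loc["all", "n_truth"] == 1
        assert df.loc["[4,5)", "n_truth"] == 1
        assert "accuracy" in df.columns
        assert '"bins"' in report.to_json()


def scenario(seed, **kw):
    defaults = dict(
        n_pairs=6,
        boundary_jitter_cm=0.4,
        fragmentation_prob=0.3,
        false_positive_rate=0.15,
        drop_rate=0.1,
    )
    defaults.update(kw)
    return gen_scenario(ScenarioSpec(seed=seed, **defaults), GeneticMap.uniform(60_000_000))


class TestProperties:
    def test_duality_under_role_swap(self):
        cfg = MetricConfig()
        for seed in range(40):
            truth, reported, _ = scenario(seed)
            acc, lacc, _ = evaluate_reported(reported, truth, cfg)
            rec, pw, _ = evaluate_truth(reported, truth, cfg)
            assert acc == pytest.approx(rec, **APPROX)
            assert lacc == pytest.approx(pw, **APPROX)

    def test_accumulative_power_dominates_power(self):
        for seed in range(40):
            truth, reported, _ = scenario(seed)
            report = evaluate_binned(truth, reported)
            for row in report.rows.values():
                if not math.isnan(row.power):
                    assert row.accumulative_power >= row.power - 1e-12

    def test_one_minus_accuracy_is_false_positive_fraction(self, umap):
        cfg = MetricConfig()
        for seed in range(20):
            truth, reported, _ = scenario(seed)
            if not reported:
                continue
            acc, _, _ = evaluate_reported(reported, truth, cfg)
            n_fp = sum(
                1 for r in reported if not best_match(r, truth, cfg).covered
            )
            assert acc + n_fp / len(reported) == pytest.approx(1.0, **APPROX)

    def test_order_permutation_invariance(self):
        truth, reported, _ = scenario(123)
        fwd = evaluate_binned(truth, reported)
        rev = evaluate_binned(truth[::-1], reported[::-1])
        for label in fwd.rows:
            a, b = fwd[label].as_dict(), rev[label].as_dict()
            for k in a:
                # permutation only reorders float accumulation
                assert (
                    a[k] == pytest.approx(b[k], abs=1e-12)
                    or (isinstance(a[k], float) and math.isnan(a[k]) and math.isnan(b[k]))
                )

    def test_fractions_in_unit_interval(self):
        for seed in range(20):
            truth, reported, _ = scenario(seed)
            for row in evaluate_binned(truth, reported).rows.values():
                for f in ("accuracy", "length_accuracy", "recall", "power",
                          "accumulative_power"):
                    v = getattr(row, f)
                    assert math.isnan(v) or 0.0 <= v <= 1.0
                assert math.isnan(row.length_discrepancy_cm) or row.length_discrepancy_cm >= 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("reference", ["full", "binned"])
    def test_engine_equals_naive_oracle(self, reference):
        cfg = MetricConfig()
        for seed in range(60):
            truth, reported, _ = scenario(seed)
            got = evaluate_binned(truth, reported, cfg, reference=reference)
            exp = oracle_report(truth, reported, cfg, reference=reference)
            for label in exp.rows:
                g, e = got[label].as_dict(), exp[label].as_dict()
                for k in g:
                    same = g[k] == e[k] or (
                        isinstance(g[k], float) and math.isnan(g[k]) and math.isnan(e[k])
                    )
                    assert same, (seed, label, k, g[k], e[k])


class TestIndividualPairMode:
    def test_hapless_detector_output_matches_across_hap_combos(self, umap):
        cfg = MetricConfig(pair_mode="individual")
        t_pair = HapPair(HaplotypeId("A", 0), HaplotypeId("B", 1))
        r_pair = HapPair(HaplotypeId("A", 1), HaplotypeId("B", 0))
        truth = [cm_segment(umap, 10, 16, pair=t_pair)]
        reported = [cm_segment(umap, 10, 16, pair=r_pair)]
        acc, lacc, disc = evaluate_reported(reported, truth, cfg)
        assert (acc, lacc, disc) == pytest.approx((1.0, 1.0, 0.0), **APPROX)
        assert evaluate_reported(reported, truth)[0] == 0.0  # haplotype mode: no match
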