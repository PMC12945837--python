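"""PT screens, concordance, label-listedness, SOC rollup and rules."""

from itertools import combinations

import numpy as np
import pytest

from pvscreen import (
    LabelList,
    MappingError,
    RuleError,
    ThresholdConfig,
    concordance,
    deduplicate,
    exposed_report_ids,
    flag_unlisted,
    parse_rule,
    screen_pt,
    soc_rollup,
)
from pvscreen.screening import ScreenResult
from pvscreen.stats import METHODS
from pvscreen.synthetic import InjectedSignal, SyntheticConfig, generate

import pandas as pd


def small_db(seed=5, signals=(), n_pts=40, bg=20_000, target=400):
    catalog = [(f"pt_{i:03d}", f"soc_{i % 6}", 1.0 / n_pts) for i in range(n_pts)]
    cfg = SyntheticConfig(
        seed=seed,
        n_background_records=bg,
        n_target_reports=target,
        pt_catalog=catalog,
        injected_signals=list(signals),
        duplicate_fraction=0.0,
    )
    store, manifest = generate(cfg)
    store = deduplicate(store)
    exposed = exposed_report_ids(store, [cfg.target_drug])
    return cfg, store, exposed, manifest


class TestScreenPt:
    def test_single_injected_signal_is_the_only_positive(self):
        cfg, store, exposed, _ = small_db(
            seed=5, signals=[InjectedSignal("pt_007", 10.0)]
        )
        res = screen_pt(store, exposed, cfg.hierarchy())
        assert list(res.positive["pt"]) == ["pt_007"]

    def test_unreachable_min_a_gives_zero_rows(self):
        cfg, store, exposed, _ = small_db(seed=6)
        res = screen_pt(
            store, exposed, cfg.hierarchy(),
            thresholds=ThresholdConfig(min_a=10**9),
        )
        assert len(res.table) == 0
        assert res.metadata["n_positive"] == 0

    def test_five_method_concordant_subset_of_each_method(self):
        cfg, store, exposed, _ = small_db(
            seed=7, signals=[InjectedSignal("pt_001", 8.0), InjectedSignal("pt_020", 3.0)]
        )
        res = screen_pt(store, exposed, cfg.hierarchy())
        t = res.table
        all_five = t[[f"flag_{m}" for m in METHODS]].all(axis=1)
        for m in METHODS:
            assert (all_five <= t[f"flag_{m}"]).all()

    def test_unmapped_pt_error_lists_offenders(self):
        from pvscreen import MedDRAHierarchy

        cfg, store, exposed, _ = small_db(seed=8)
        partial = MedDRAHierarchy({"pt_000": "soc_0"})
        with pytest.raises(MappingError) as err:
            screen_pt(store, exposed, partial, thresholds=ThresholdConfig(min_a=1))
        assert "pt_001" in str(err.value)

    def test_rows_ranked_by_ror_then_a_then_pt(self):
        cfg, store, exposed, _ = small_db(seed=9)
        t = screen_pt(store, exposed, cfg.hierarchy(), thresholds=ThresholdConfig(min_a=1)).table
        rors = t["ror"].to_numpy()
        finite = rors[np.isfinite(rors)]
        assert (np.diff(finite) <= 1e-12).all()

    def test_deterministic_tsv_bytes(self, tmp_path):
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        for out in (out1, out2):
            cfg, store, exposed, _ = small_db(seed=10)
            screen_pt(store, exposed, cfg.hierarchy()).to_tsv(out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_ranking_stable_under_input_row_permutation(self):
        cfg, store, exposed, _ = small_db(seed=12)
        res1 = screen_pt(store, exposed, cfg.hierarchy())
        reversed_store = store.replace_reports(list(reversed(store.reports)))
        res2 = screen_pt(reversed_store, exposed, cfg.hierarchy())
        pd.testing.assert_frame_equal(res1.table, res2.table)


class TestRuleLanguage:
    @pytest.mark.parametrize(
        "expr,flags,expected",
        [
            ("ror & prr", {"ror": True, "prr": False}, False),
            ("ror | prr", {"ror": True, "prr": False}, True),
            ("!mhra", {"mhra": False}, True),
            ("(ror & prr) | (bcpnn & ebgm)", {"ror": False, "prr": True, "bcpnn": True, "ebgm": True}, True),
        ],
    )
    def test_evaluation(self, expr, flags, expected):
        full = {m: np.array([flags.get(m, False)]) for m in METHODS}
        assert parse_rule(expr)(full)[0] == expected

    @pytest.mark.parametrize("expr", ["", "ror &", "unknown_method", "(ror", "ror ^ prr"])
    def test_malformed_rules_rejected(self, expr):
        with pytest.raises(RuleError):
            parse_rule(expr)


class TestConcordance:
    def _result_from_flag_matrix(self, matrix):
        rows = {
            "soc": ["s"] * len(matrix), "pt": [f"p{i}" for i in range(len(matrix))],
            "a": [5] * len(matrix), "ror": [2.0] * len(matrix), "positive": [True] * len(matrix),
        }
        for j, m in enumerate(METHODS):
            rows[f"flag_{m}"] = [bool(r[j]) for r in matrix]
        return ScreenResult(pd.DataFrame(rows))

    def test_all_rows_all_methods(self):
        res = self._result_from_flag_matrix([[1] * 5] * 4)
        c = concordance(res)
        assert c["at_least"]["+".join(sorted(METHODS))] == 4
        assert c["exactly"]["+".join(sorted(METHODS))] == 4

    def test_matches_power_set_enumeration(self):
        rng = np.random.default_rng(42)
        matrix = rng.integers(0, 2, size=(18, 5))
        res = self._result_from_flag_matrix(matrix)
        c = concordance(res)
        profiles = [frozenset(m for j, m in enumerate(METHODS) if row[j]) for row in matrix]
        for k in range(6):
            for subset in combinations(METHODS, k):
                key = "+".join(sorted(subset))
                assert c["at_least"][key] == sum(1 for p in profiles if set(subset) <= p)
                assert c["exactly"][key] == sum(1 for p in profiles if p == set(subset))

    def test_exactly_counts_partition_flagged_rows(self):
        rng = np.random.default_rng(1)
        matrix = rng.integers(0, 2, size=(12, 5))
        res = self._result_from_flag_matrix(matrix)
        c = concordance(res)
        assert sum(c["exactly"].values()) == len(matrix)


class TestLabelListedness:
    def test_full_label_gives_zero_unlisted(self):
        cfg, store, exposed, _ = small_db(seed=13, signals=[InjectedSignal("pt_003", 10.0)])
        res = screen_pt(store, exposed, cfg.hierarchy())
        label = LabelList(pt for pt, _, _ in cfg.pt_catalog)
        out = flag_unlisted(res, label)
        assert out.metadata["n_unlisted"] == 0

    def test_disjoint_label_marks_all_positive_unlisted(self):
        cfg, store, exposed, _ = small_db(seed=13, signals=[InjectedSignal("pt_003", 10.0)])
        res = screen_pt(store, exposed, cfg.hierarchy())
        out = flag_unlisted(res, LabelList(["something else"]))
        assert out.metadata["n_unlisted"] == res.metadata["n_positive"] > 0

    def test_counts_injected_unlisted_signals(self):
        signals = [InjectedSignal(f"pt_{i:03d}", 12.0) for i in range(8)]
        cfg, store, exposed, _ = small_db(seed=14, signals=signals, target=1200)
        res = screen_pt(store, exposed, cfg.hierarchy())
        listed = LabelList([pt for pt, _, _ in cfg.pt_catalog[20:]])
        out = flag_unlisted(res, listed)
        flagged_injected = set(res.positive["pt"]) & {s.pt for s in signals}
        assert out.metadata["n_unlisted"] == len(flagged_injected)


class TestSocRollup:
    def test_single_soc_store_has_proportion_one(self, four_report_store, tiny_hierarchy):
        exposed = exposed_report_ids(four_report_store, ["targetol"])
        roll = soc_rollup(four_report_store, exposed, tiny_hierarchy)
        assert len(roll) == 1
        assert roll["proportion"].iloc[0] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self):
        cfg, store, exposed, _ = small_db(seed=15)
        roll = soc_rollup(store, exposed, cfg.hierarchy())
        assert roll["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_recovers_generator_soc_mix(self):
        catalog = [("pt_a", "soc_A", 0.34), ("pt_b", "soc_B", 0.66)]
        # one reaction per report: within-report PT dedup would otherwise
        # pull the two-PT record mix toward 0.5
        cfg = SyntheticConfig(
            seed=16, n_background_records=5000, n_target_reports=1500,
            pt_catalog=catalog, duplicate_fraction=0.0, extra_reactions_mean=0.0,
        )
        store, _ = generate(cfg)
        store = deduplicate(store)
        exposed = exposed_report_ids(store, [cfg.target_drug])
        roll = soc_rollup(store, exposed, cfg.hierarchy()).set_index("soc")
        assert roll.loc["soc_A", "proportion"] == pytest.approx(0.34, abs=0.03)
        assert roll.loc["soc_B", "proportion"] == pytest.approx(0.66, abs=0.03)
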