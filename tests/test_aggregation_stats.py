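import numpy as np
import pandas as pd
import pytest

from epoclib.aggregation_stats import (
    CoreSetConfig,
    StemLengthAnalysis,
    StemRecord,
    aelw,
    core_filter,
    stem_distribution_analysis,
    stem_lengths,
)
from epoclib.clade_detection import CladeCall, Epoc, detect_clades
from epoclib.synthetic_data import simulate_stem_cohort
from epoclib.taxonomy import DOMAIN_EUK, DOMAIN_PROK
from epoclib.tree_ops import find_mrca, tree_from_string

from conftest import make_taxonomy


def _elw_df(rows):
    return pd.DataFrame(
        rows, columns=["epoc_id", "clade_id", "candidate_label", "elw"]
    )


def _epoc(epoc_id, annotations=("k1",)):
    tree = tree_from_string("((E1:1,E2:1):1,(P1:1,P2:1):1);")
    return Epoc(epoc_id=epoc_id, alignment=None, tree=tree,
                annotations=list(annotations))


class TestCoreFilter:
    def test_window_is_strict(self):
        epocs = [_epoc("e1")]
        elw = _elw_df([
            ("e1", "c0", "Asgard", 0.5),     # inside
            ("e1", "c0", "Bacilli", 0.4),    # at lower bound: dropped
            ("e1", "c0", "Chlorobi", 0.99),  # at upper bound: dropped
            ("e1", "c0", "Aquificae", 0.995),
        ])
        out = core_filter(elw, epocs, CoreSetConfig())
        assert list(out["candidate_label"]) == ["Asgard"]

    def test_elw_one_admitted_only_under_exception(self):
        epocs = [_epoc("e1", annotations=("oxphos",))]
        elw = _elw_df([("e1", "c0", "Alphaproteobacteria", 1.0)])
        assert core_filter(elw, epocs, CoreSetConfig()).empty
        cfg = CoreSetConfig(oxphos_exception=True,
                            exception_annotations=frozenset({"oxphos"}))
        out = core_filter(elw, epocs, cfg)
        assert len(out) == 1
        # exception only applies to matching annotation categories
        other = [_epoc("e1", annotations=("glycolysis",))]
        assert core_filter(elw, other, cfg).empty

    def test_unannotated_epocs_dropped(self):
        epocs = [_epoc("e1", annotations=())]
        elw = _elw_df([("e1", "c0", "Asgard", 0.5)])
        assert core_filter(elw, epocs, CoreSetConfig()).empty

    def test_leca_scope_enforced_with_taxonomy(self):
        # eukaryotic clade with only two class labels fails the scope rule
        tree = tree_from_string(
            "(((E1:1,E2:1):1,(E3:1,E4:1):1):1,(P1:1,(P2:1,P3:1):1):1);"
        )
        tax = make_taxonomy({
            "E1": (DOMAIN_EUK, "Metazoa", "Amorphea"),
            "E2": (DOMAIN_EUK, "Metazoa", "Amorphea"),
            "E3": (DOMAIN_EUK, "Streptophyta", "Diaphoretickes"),
            "E4": (DOMAIN_EUK, "Streptophyta", "Diaphoretickes"),
            **{f"P{i}": (DOMAIN_PROK, "Asgard") for i in (1, 2, 3)},
        })
        calls = detect_clades(tree, tax, min_euk_size=4)
        euk = next(c for c in calls if c.domain == "eukaryotic")
        euk.clade_id = "c0"
        epoc = Epoc(epoc_id="e1", alignment=None, tree=tree,
                    euk_clades=[euk], annotations=["k1"])
        elw = _elw_df([("e1", "c0", "Asgard", 0.5)])
        assert core_filter(elw, [epoc], CoreSetConfig(),
                           taxonomy=tax).empty

    def test_subset_and_idempotent(self):
        epocs = [_epoc("e1")]
        elw = _elw_df([
            ("e1", "c0", "Asgard", 0.5),
            ("e1", "c0", "Bacilli", 0.45),
            ("e1", "c0", "Chlorobi", 0.05),
        ])
        out = core_filter(elw, epocs, CoreSetConfig())
        assert len(out) == 2
        again = core_filter(out, epocs, CoreSetConfig())
        pd.testing.assert_frame_equal(again.reset_index(drop=True),
                                      out.reset_index(drop=True))


class TestAelw:
    def test_single_epoc_category_equals_its_rows(self):
        core = _elw_df([("e1", "c0", "Asgard", 0.73)])
        out = aelw(core, {"e1": ["k1"]}, min_epocs=1)
        assert out.loc[0, "aelw"] == pytest.approx(0.73)

    def test_mean_of_two_rows(self):
        core = _elw_df([
            ("e1", "c0", "Asgard", 0.4),
            ("e2", "c0", "Asgard", 0.6),
        ])
        out = aelw(core, {"e1": ["k1"], "e2": ["k1"]}, min_epocs=1)
        assert out.loc[0, "aelw"] == pytest.approx(0.5)
        assert out.loc[0, "n_epocs"] == 2

    def test_small_categories_flagged(self):
        rows = [(f"e{i}", "c0", "Asgard", 0.5) for i in range(19)]
        core = _elw_df(rows)
        grouping = {f"e{i}": ["k1"] for i in range(19)}
        out = aelw(core, grouping, min_epocs=20)
        assert bool(out.loc[0, "below_min"]) is True

    def test_bounds_within_member_range(self, rng):
        rows = []
        grouping = {}
        for i in range(30):
            rows.append((f"e{i}", "c0", "Asgard", float(rng.uniform(0.4, 0.99))))
            grouping[f"e{i}"] = ["k1"]
        core = _elw_df(rows)
        out = aelw(core, grouping)
        assert core["elw"].min() <= out.loc[0, "aelw"] <= core["elw"].max()

    def test_empty_core_gives_empty_table(self):
        assert aelw(_elw_df([]), {}).empty


STEM_TREE = (
    "(((E1:1.0,E2:1.0):0.5,(P1:0.1,P2:0.1):0.2):0.3,"
    "(Q1:0.1,(Q2:0.1,Q3:0.1):0.1):0.3);"
)


def _call(tree, names, label, domain):
    node = find_mrca(tree, names)
    return CladeCall(
        node=node, label=label, member_leaves=frozenset(names),
        clade_size=len(names), n_label=len(names), score=1.0,
        domain=domain, clade_id="c0",
    )


class TestStemLengths:
    def test_hand_built_tree(self):
        tree = tree_from_string(STEM_TREE)
        euk = _call(tree, ["E1", "E2"], "Eukaryota", "eukaryotic")
        sister = _call(tree, ["P1", "P2"], "Asgard", "prokaryotic")
        rec = stem_lengths(tree, euk, sister, epoc_id="t")
        assert rec.sl == pytest.approx(0.5)
        assert rec.median_bl == pytest.approx(1.0)
        assert rec.nsl == pytest.approx(0.5)

    def test_median_of_leaf_depths(self):
        tree = tree_from_string(
            "(((E1:0.5,(E2:0.5,E3:1.5):0.5):0.4,(P1:0.1,P2:0.1):0.1):0.2,"
            "(Q1:0.1,Q2:0.1):0.2);"
        )
        euk = _call(tree, ["E1", "E2", "E3"], "Eukaryota", "eukaryotic")
        sister = _call(tree, ["P1", "P2"], "Asgard", "prokaryotic")
        rec = stem_lengths(tree, euk, sister)
        # depths from the clade root: 0.5, 1.0, 2.0 -> median 1.0
        assert rec.median_bl == pytest.approx(1.0)
        assert rec.sl == pytest.approx(0.4)

    def test_distant_sister_accumulates_path(self):
        tree = tree_from_string(STEM_TREE)
        euk = _call(tree, ["E1", "E2"], "Eukaryota", "eukaryotic")
        far = _call(tree, ["Q1", "Q2", "Q3"], "Bacilli", "prokaryotic")
        rec = stem_lengths(tree, euk, far)
        assert rec.sl == pytest.approx(0.5 + 0.3)

    def test_zero_median_rejected_with_warning(self):
        tree = tree_from_string(
            "(((E1:0.0,E2:0.0):0.5,(P1:0.1,P2:0.1):0.2):0.1,Q1:0.4);"
        )
        euk = _call(tree, ["E1", "E2"], "Eukaryota", "eukaryotic")
        sister = _call(tree, ["P1", "P2"], "Asgard", "prokaryotic")
        with pytest.warns(UserWarning):
            assert stem_lengths(tree, euk, sister) is None

    def test_record_invariants(self):
        rec = StemRecord("e", "c0", "Asgard", sl=0.2, median_bl=0.4)
        assert rec.nsl == pytest.approx(0.5)
        with pytest.raises(ValueError):
            StemRecord("e", "c0", "Asgard", sl=-0.1, median_bl=1.0)
        with pytest.raises(ValueError):
            StemRecord("e", "c0", "Asgard", sl=0.1, median_bl=0.0)


class TestStemDistributionAnalysis:
    def test_bootstrap_replicates_deterministic_and_monotone(self):
        records = simulate_stem_cohort(
            60, {"a": ("lognormal", (-1.5, 0.6)),
                 "b": ("lognormal", (-1.2, 0.6))}, seed=2,
        )
        r1 = stem_distribution_analysis(records, n_boot=50, seed=5)
        r2 = stem_distribution_analysis(records, n_boot=50, seed=5)
        for g in r1["groups"]:
            assert np.array_equal(r1["groups"][g]["boot_cdfs"],
                                  r2["groups"][g]["boot_cdfs"])
            cdf = r1["groups"][g]["cdf"]
            assert np.all(np.diff(cdf) >= 0)
            for boot in r1["groups"][g]["boot_cdfs"]:
                assert np.all(np.diff(boot) >= 0)

    def test_small_groups_excluded(self):
        records = simulate_stem_cohort(
            30, {"a": ("lognormal", (-1.5, 0.6)),
                 "b": ("lognormal", (-1.5, 0.6))}, seed=1,
        )
        records += simulate_stem_cohort(
            2, {"tiny": ("lognormal", (-1.5, 0.6))}, seed=2
        )
        with pytest.warns(UserWarning):
            report = stem_distribution_analysis(records, n_boot=20, seed=0)
        assert report["excluded_groups"] == ["tiny"]
        assert set(report["groups"]) == {"a", "b"}

    def test_single_group_left_raises(self):
        records = simulate_stem_cohort(
            30, {"a": ("lognormal", (-1.5, 0.6))}, seed=1
        )
        records += simulate_stem_cohort(
            1, {"b": ("lognormal", (-1.5, 0.6))}, seed=2
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                stem_distribution_analysis(records, n_boot=20, seed=0)

    def test_shift_detected_in_split_comparisons(self):
        records = simulate_stem_cohort(
            300, {"a": ("normal", (0.3, 0.5)), "b": ("normal", (1.3, 0.5))},
            seed=3,
        )
        model = StemLengthAnalysis(records)
        res = model.fit(n_boot=50, seed=0, split_points=(0.3, 0.35))
        comp = res.comparison("a", "b")
        for s in (0.3, 0.35):
            assert comp["split_tests"][s]["above_p"] < 0.01

    def test_results_summary_mentions_groups(self):
        records = simulate_stem_cohort(
            40, {"Asgard": ("lognormal", (-1.5, 0.6)),
                 "Alphaproteobacteria": ("lognormal", (-1.0, 0.6))}, seed=4,
        )
        res = StemLengthAnalysis(records).fit(n_boot=20, seed=0)
        text = res.summary()
        assert "Asgard" in text
        assert "Alphaproteobacteria" in text
        tbl = res.split_table()
        assert {"below_p", "above_p"} <= set(tbl.columns)
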