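"""pegRNA frequencies, scores, filters and variant function scores, checked
against hand arithmetic and an independent step-by-step oracle."""

import numpy as np
import pandas as pd
import pytest

from pescreen import scoring
from pescreen.model import ScreenConfig, SchemaError, Variant
from conftest import make_design


def series(values, ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


class TestFrequencies:
    def test_pseudocount_formula(self):
        freqs = scoring.pegrna_frequencies(series([0, 1, 3]))
        assert np.allclose(freqs.values, [1 / 7, 2 / 7, 4 / 7])

    def test_all_zero_counts_uniform(self):
        freqs = scoring.pegrna_frequencies(series([0] * 5))
        assert np.allclose(freqs.values, 0.2)

    def test_pseudocount_breaks_scale_invariance(self):
        # doubling counts changes pseudocounted frequencies; verify against
        # direct arithmetic
        c = series([2, 6])
        doubled = scoring.pegrna_frequencies(2 * c)
        assert np.allclose(doubled.values, [5 / 18, 13 / 18])
        assert not np.allclose(doubled.values,
                               scoring.pegrna_frequencies(c).values)

    def test_sums_to_one(self):
        assert scoring.pegrna_frequencies(series([5, 0, 17, 2])).sum() == \
            pytest.approx(1.0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=10 ** 6), min_size=1,
                max_size=50))
def test_frequency_property(counts):
    """Pseudocounted frequencies are strictly positive, sum to one and
    preserve the count ordering."""
    c = pd.Series(counts, dtype=float)
    f = scoring.pegrna_frequencies(c)
    assert (f > 0).all()
    assert f.sum() == pytest.approx(1.0)
    order = np.argsort(c.values, kind="stable")
    assert (np.diff(f.values[order]) >= -1e-15).all()


class TestPegRNAScores:
    def test_no_change_scores_zero(self):
        f = series([0.5, 0.5])
        assert np.allclose(scoring.pegrna_scores(f, f).values, 0.0)

    def test_doubling_scores_one(self):
        assert scoring.pegrna_scores(series([0.25]), series([0.5])).iloc[0] \
            == pytest.approx(1.0)

    def test_extinction_with_pseudocount(self):
        # pre count 99, post count 0, both samples total 1e4 over 2 pegRNAs:
        # freq_pre = 100/10002, freq_post = 1/10002
        counts_pre = series([99, 9901])
        counts_post = series([0, 10000])
        f_pre = scoring.pegrna_frequencies(counts_pre)
        f_post = scoring.pegrna_frequencies(counts_post)
        score = scoring.pegrna_scores(f_pre, f_post).iloc[0]
        assert score == pytest.approx(np.log2((1 / 10002) / (100 / 10002)))
        assert score == pytest.approx(-np.log2(100))


class TestFilters:
    def make_table(self, freq_pre, pct):
        return pd.DataFrame({
            "pegrna_id": [f"p{i}" for i in range(len(freq_pre))],
            "freq_pre": freq_pre,
            "freq_post": freq_pre,
            "pegrna_score": 0.0,
            "st_editing_pre_pct": pct,
        })

    def test_frequency_threshold_inclusive(self):
        cfg = ScreenConfig(freq_min=6e-5)
        t = scoring.apply_filters(
            self.make_table([5.9e-5, 6e-5, 6.1e-5], [80, 80, 80]), cfg)
        assert list(t["passed_freq_filter"]) == [False, True, True]

    def test_activity_threshold_inclusive(self):
        cfg = ScreenConfig(st_activity_min_pct=75)
        t = scoring.apply_filters(
            self.make_table([1e-3] * 3, [74.9, 75.0, 80.0]), cfg)
        assert list(t["passed_activity_filter"]) == [False, True, True]

    def test_undefined_editing_dropped(self):
        cfg = ScreenConfig(st_activity_min_pct=5)
        t = scoring.apply_filters(self.make_table([1e-3], [np.nan]), cfg)
        assert not t["passed_activity_filter"].iloc[0]
        assert not t["retained"].iloc[0]


class TestNormalizeToNeutral:
    def test_median_subtraction(self):
        s = series([2.4, 0.3, 0.4, 0.5, 0.1, 0.6],
                   ["x", "n1", "n2", "n3", "n4", "n5"])
        out = scoring.normalize_to_neutral(s, ["n1", "n2", "n3", "n4", "n5"])
        assert out["x"] == pytest.approx(2.4 - 0.4)

    def test_all_neutral_median_zero(self):
        s = series([1.0, 2.0, 3.0, 4.0, 5.0])
        out = scoring.normalize_to_neutral(s, list(s.index))
        assert out.median() == 0.0

    def test_even_count_median_matches_sort_oracle(self):
        vals = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        s = series(vals)
        out = scoring.normalize_to_neutral(s, list(s.index), min_neutral=5)
        srt = sorted(vals)
        oracle_median = (srt[2] + srt[3]) / 2
        assert np.allclose(out.values, np.array(vals) - oracle_median)

    def test_too_few_neutral_errors(self):
        s = series([1.0, 2.0, 3.0])
        with pytest.raises(SchemaError, match="neutral"):
            scoring.normalize_to_neutral(s, list(s.index), min_neutral=5)


def build_screen(rng, pegrna_scores_by_cond, variant_of, consequences):
    """Construct score tables + library objects from a dict
    {cond: {pegrna_id: score}}; every pegRNA is retained."""
    designs = []
    variants = []
    seen = set()
    for pid, vid in variant_of.items():
        designs.append(make_design(pid, vid, rng))
        if vid not in seen:
            seen.add(vid)
            variants.append(Variant(vid, consequence=consequences[vid]))
    tables = {}
    for cond, scores in pegrna_scores_by_cond.items():
        pids = list(scores)
        tables[cond] = pd.DataFrame({
            "pegrna_id": pids,
            "freq_pre": 1e-3,
            "freq_post": 1e-3,
            "pegrna_score": [scores[p] for p in pids],
            "st_editing_pre_pct": 90.0,
            "passed_negctrl_filter": True,
            "passed_freq_filter": True,
            "passed_activity_filter": True,
            "retained": True,
        })
    return designs, variants, tables


def multi_condition_oracle(pegrna_scores_by_cond, variant_of, neutral_ids,
                           min_conditions=2):
    """Independent spreadsheet-style re-implementation of the aggregation:
    per-condition variant means -> per-condition neutral-median subtraction
    -> cross-condition mean -> drop (< min_conditions) -> final neutral-
    median subtraction."""
    per_cond = {}
    for cond, scores in pegrna_scores_by_cond.items():
        sums, ns = {}, {}
        for pid, sc in scores.items():
            vid = variant_of[pid]
            sums[vid] = sums.get(vid, 0.0) + sc
            ns[vid] = ns.get(vid, 0) + 1
        means = {v: sums[v] / ns[v] for v in sums}
        med = float(np.median([means[v] for v in means if v in neutral_ids]))
        per_cond[cond] = {v: m - med for v, m in means.items()}
    all_vids = sorted({v for d in per_cond.values() for v in d})
    averaged, nconds = {}, {}
    for v in all_vids:
        vals = [d[v] for d in per_cond.values() if v in d]
        if len(vals) >= min_conditions:
            averaged[v] = float(np.mean(vals))
            nconds[v] = len(vals)
    med = float(np.median([averaged[v] for v in averaged
                           if v in neutral_ids]))
    return {v: averaged[v] - med for v in averaged}, nconds


class TestFunctionScores:
    def test_two_condition_mean(self, rng):
        variant_of = {"p1": "vx", "p2": "vx", "p3": "vx"}
        for i in range(5):
            variant_of[f"n{i}"] = f"vn{i}"
        consequences = {"vx": "missense",
                        **{f"vn{i}": "synonymous" for i in range(5)}}
        by_cond = {
            "c1": {"p1": 1.0, "p2": 3.0, **{f"n{i}": 0.0 for i in range(5)}},
            "c2": {"p3": 2.0, **{f"n{i}": 0.0 for i in range(5)}},
        }
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        fs = scoring.function_scores(tables, designs, variants, cfg)
        got = fs.set_index("variant_id").loc["vx"]
        # neutral medians are 0 in both conditions: mean(mean(1,3), 2) = 2
        assert got["function_score"] == pytest.approx(2.0)
        assert got["n_conditions"] == 2
        assert got["n_pegrnas"] == 3

    def test_single_condition_variant_excluded(self, rng):
        variant_of = {"p1": "vx"}
        for i in range(5):
            variant_of[f"n{i}"] = f"vn{i}"
        consequences = {"vx": "missense",
                        **{f"vn{i}": "synonymous" for i in range(5)}}
        by_cond = {
            "c1": {"p1": 5.0, **{f"n{i}": 0.0 for i in range(5)}},
            "c2": {f"n{i}": 0.0 for i in range(5)},
            "c3": {f"n{i}": 0.0 for i in range(5)},
            "c4": {f"n{i}": 0.0 for i in range(5)},
        }
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        fs = scoring.function_scores(tables, designs, variants, cfg)
        assert "vx" not in set(fs["variant_id"])

    def test_toy_screen_matches_independent_oracle(self, rng):
        # 6 variants x 3 pegRNAs x 2 conditions with scattered dropouts
        toy_rng = np.random.default_rng(7)
        variant_of = {}
        consequences = {}
        for vi in range(6):
            vid = f"v{vi}"
            consequences[vid] = "synonymous" if vi < 5 else "nonsense"
            for j in range(3):
                variant_of[f"p{vi}_{j}"] = vid
        by_cond = {}
        for cond in ("c1", "c2"):
            scores = {}
            for pid in variant_of:
                if toy_rng.random() < 0.8:
                    scores[pid] = float(np.round(toy_rng.normal(
                        -3 if variant_of[pid] == "v5" else 0, 1), 3))
            by_cond[cond] = scores
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        fs = scoring.function_scores(tables, designs, variants, cfg)
        neutral = {f"v{i}" for i in range(5)}
        expected, nconds = multi_condition_oracle(by_cond, variant_of,
                                                  neutral)
        got = fs.set_index("variant_id")
        assert set(got.index) == set(expected)
        for v, e in expected.items():
            assert got.loc[v, "function_score"] == pytest.approx(e)
            assert got.loc[v, "n_conditions"] == nconds[v]

    def test_single_mode_normalizes_pegrna_scores_first(self, rng):
        variant_of = {"p1": "vx", "p2": "vx"}
        for i in range(5):
            variant_of[f"n{i}"] = f"vn{i}"
        consequences = {"vx": "missense",
                        **{f"vn{i}": "synonymous" for i in range(5)}}
        by_cond = {"c1": {"p1": -4.0, "p2": -2.0,
                          "n0": 0.5, "n1": 1.0, "n2": 1.5, "n3": 0.0,
                          "n4": 2.0}}
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="single")
        fs = scoring.function_scores(tables, designs, variants, cfg)
        got = fs.set_index("variant_id")
        # neutral pegRNA median is 1.0; mean((-4-1), (-2-1)) = -4
        assert got.loc["vx", "function_score"] == pytest.approx(-4.0)
        assert got.loc["vn4", "function_score"] == pytest.approx(1.0)

    def test_neutral_median_exactly_zero_after_final_normalization(self, rng):
        toy_rng = np.random.default_rng(3)
        variant_of = {f"p{i}": f"v{i}" for i in range(12)}
        consequences = {f"v{i}": ("synonymous" if i < 8 else "missense")
                        for i in range(12)}
        by_cond = {c: {p: float(toy_rng.normal()) for p in variant_of}
                   for c in ("c1", "c2", "c3")}
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        fs = scoring.function_scores(tables, designs, variants, cfg)
        neutral_scores = fs.loc[fs["variant_id"].str.slice(1).astype(int) < 8,
                                "function_score"]
        assert neutral_scores.median() == pytest.approx(0.0, abs=1e-12)

    def test_raising_activity_threshold_never_adds_variants(self, rng):
        """Monotone coverage loss as the ST-activity filter rises."""
        toy_rng = np.random.default_rng(11)
        variant_of = {f"p{i}": f"v{i // 2}" for i in range(40)}
        consequences = {f"v{i}": ("synonymous" if i < 10 else "missense")
                        for i in range(20)}
        by_cond = {"c1": {p: float(toy_rng.normal()) for p in variant_of}}
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        tables["c1"]["st_editing_pre_pct"] = toy_rng.uniform(0, 100, 40)
        prev = None
        for threshold in (0, 10, 30, 75, 95):
            cfg = ScreenConfig(scoring_mode="single",
                               st_activity_min_pct=threshold)
            refiltered = scoring.apply_filters(tables["c1"], cfg)
            try:
                fs = scoring.function_scores({"c1": refiltered}, designs,
                                             variants, cfg)
                n = len(fs)
            except SchemaError:
                n = 0
            if prev is not None:
                assert n <= prev
            prev = n


class TestCellLineScores:
    def test_symmetric_conditions_identity(self, rng):
        variant_of = {f"p{i}": f"v{i}" for i in range(8)}
        consequences = {f"v{i}": ("synonymous" if i < 6 else "missense")
                        for i in range(8)}
        scores = {f"p{i}": float(i - 3) for i in range(8)}
        by_cond = {"a": dict(scores), "b": dict(scores)}
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        cl = scoring.cellline_scores(tables, {"a": "L1", "b": "L1"},
                                     designs, variants, cfg)
        fs = scoring.function_scores(tables, designs, variants, cfg)
        merged = cl.merge(fs, on="variant_id", suffixes=("_cl", "_fs"))
        assert np.allclose(merged["function_score_cl"],
                           merged["function_score_fs"])

    def test_two_cell_lines_separate(self, rng):
        variant_of = {f"p{i}": f"v{i}" for i in range(8)}
        consequences = {f"v{i}": ("synonymous" if i < 6 else "missense")
                        for i in range(8)}
        by_cond = {"a": {f"p{i}": float(i) for i in range(8)},
                   "b": {f"p{i}": float(-i) for i in range(8)}}
        designs, variants, tables = build_screen(rng, by_cond, variant_of,
                                                 consequences)
        cfg = ScreenConfig(scoring_mode="multi")
        cl = scoring.cellline_scores(tables, {"a": "L1", "b": "L2"},
                                     designs, variants, cfg)
        assert set(cl["cell_line"]) == {"L1", "L2"}
        l1 = cl[cl.cell_line == "L1"].set_index("variant_id")
        # single-condition cell line: that condition's normalized score,
        # renormalized (idempotent here)
        assert l1.loc["v7", "function_score"] == pytest.approx(
            7.0 - 2.5 - np.median([0 - 2.5, 1 - 2.5, 2 - 2.5, 3 - 2.5,
                                   4 - 2.5, 5 - 2.5]))


class TestMeanVariantSTEditing:
    def test_single_pegrna_identity(self, tiny_library):
        designs, _ = tiny_library
        obs = pd.DataFrame({"pegrna_id": [d.pegrna_id for d in designs],
                            "st_editing_pct": [40.0, np.nan, 10.0]})
        got = scoring.mean_variant_st_editing([obs], designs)
        assert got["v1"] == 40.0
        assert "v2" not in got.index

    def test_mean_across_conditions(self, tiny_library):
        designs, _ = tiny_library
        obs1 = pd.DataFrame({"pegrna_id": ["pg1"], "st_editing_pct": [10.0]})
        obs2 = pd.DataFrame({"pegrna_id": ["pg1"], "st_editing_pct": [30.0]})
        got = scoring.mean_variant_st_editing([obs1, obs2], designs)
        assert got["v1"] == pytest.approx(20.0)


def brute_spearman(x, y):
    """Rank correlation via the Pearson formula on midranks."""
    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestFeatureCorrelations:
    def make_library(self, rng, values):
        designs = []
        for i, v in enumerate(values):
            d = make_design(f"p{i}", f"v{i}", rng)
            object.__setattr__(d, "features", dict(v))
            designs.append(d)
        return designs

    def test_monotone_feature_gives_rho_one(self, rng):
        designs = self.make_library(
            rng, [{"pbs_length": float(i)} for i in range(6)])
        editing = pd.Series([5.0, 8, 12, 30, 55, 80],
                            index=[f"p{i}" for i in range(6)])
        rho = scoring.compute_feature_correlations(editing, designs)
        assert rho["pbs_length"] == pytest.approx(1.0)

    def test_constant_feature_undefined(self, rng):
        designs = self.make_library(rng, [{"pbs_length": 13.0}] * 5)
        editing = pd.Series([5.0, 8, 12, 30, 55],
                            index=[f"p{i}" for i in range(5)])
        rho = scoring.compute_feature_correlations(editing, designs)
        assert np.isnan(rho["pbs_length"])

    def test_ten_point_fixture_matches_rank_oracle(self, rng):
        feat = [3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3]
        edit = [12.0, 3, 45, 7, 50, 90, 4, 60, 44, 15]
        designs = self.make_library(rng, [{"rtt_length": f} for f in feat])
        editing = pd.Series(edit, index=[f"p{i}" for i in range(10)])
        rho = scoring.compute_feature_correlations(editing, designs)
        assert rho["rtt_length"] == pytest.approx(brute_spearman(feat, edit))
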