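import collections

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpgdeconv import (
    BetaMatrix,
    ParabolaGate,
    aupr,
    cpg_stats,
    f1_best,
    parabola_select,
    rank_markers,
    stratified_folds,
)
from cpgdeconv.simulate import SimulationConfig, simulate_selection_benchmark

from oracles import (
    brute_force_average_precision,
    brute_force_best_f1,
    parabola_passing_set,
)


class TestStratifiedFolds:
    def test_perfect_stratification(self):
        labels = {f"a{i}": "A" for i in range(10)} | {f"b{i}": "B" for i in range(10)}
        plan = stratified_folds(labels, k=10, seed=0)
        for f in range(10):
            fold = plan.fold_samples(f)
            assert len(fold) == 2
            assert {labels[s] for s in fold} == {"A", "B"}

    def test_deterministic_given_seed(self):
        labels = {f"s{i}": "AB"[i % 2] for i in range(17)}
        assert (
            stratified_folds(labels, 5, 3).assignment
            == stratified_folds(labels, 5, 3).assignment
        )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            stratified_folds({"a": "A", "b": "A"}, k=1, seed=0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_per_class_fold_counts_balanced(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        k = int(rng.integers(2, 8))
        labels = {f"s{i}": f"c{rng.integers(3)}" for i in range(n)}
        plan = stratified_folds(labels, k=k, seed=seed)
        per_class = collections.defaultdict(collections.Counter)
        for s, f in plan.assignment.items():
            per_class[labels[s]][f] += 1
        for cls, counts in per_class.items():
            full = [counts.get(f, 0) for f in range(k)]
            assert max(full) - min(full) <= 1, (cls, full)


class TestCpgStats:
    def _matrix(self, rows):
        return BetaMatrix(
            pd.DataFrame(rows, index=pd.Index([f"cg{i}" for i in range(len(rows))], name="cpg_id"),
                         columns=["s1", "s2", "s3", "s4"])
        )

    def _ann(self):
        return pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3", "s4"],
             "cell_type": ["T", "T", "O", "O"]}
        )

    def test_degenerate_groups(self):
        m = self._matrix([[0.0, 0.0, 1.0, 1.0]])
        stats = cpg_stats(m, self._ann(), "T")
        assert stats.loc["cg0", "dMean"] == -1.0
        assert stats.loc["cg0", "sVar"] == 0.0
        assert stats.loc["cg0", "direction"] == "hypo"

    def test_identical_constant_groups(self):
        m = self._matrix([[0.5, 0.5, 0.5, 0.5]])
        stats = cpg_stats(m, self._ann(), "T")
        assert stats.loc["cg0", "dMean"] == 0.0
        assert stats.loc["cg0", "sVar"] == 0.0

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, size=(8, 6))
        m = BetaMatrix(pd.DataFrame(
            vals, index=pd.Index([f"cg{i}" for i in range(8)], name="cpg_id"),
            columns=[f"s{i}" for i in range(6)]))
        ann = pd.DataFrame({"sample_id": [f"s{i}" for i in range(6)],
                            "cell_type": ["T", "T", "T", "O", "O", "O"]})
        stats = cpg_stats(m, ann, "T")
        for i in range(8):
            t, o = vals[i, :3], vals[i, 3:]
            assert stats["dMean"].iloc[i] == pytest.approx(t.mean() - o.mean(), abs=1e-12)
            assert stats["sVar"].iloc[i] == pytest.approx(
                t.var(ddof=1) + o.var(ddof=1), abs=1e-12)

    def test_small_group_rejected(self):
        m = self._matrix([[0.1, 0.2, 0.3, 0.4]])
        ann = pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"],
                            "cell_type": ["T", "O", "O", "O"]})
        with pytest.raises(ValueError, match="2 samples"):
            cpg_stats(m, ann, "T")

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, size=(5, 8))
        ids = [f"s{i}" for i in range(8)]
        types = ["T"] * 4 + ["O"] * 4
        m = BetaMatrix(pd.DataFrame(vals, index=[f"cg{i}" for i in range(5)], columns=ids))
        ann = pd.DataFrame({"sample_id": ids, "cell_type": types})
        perm = rng.permutation(8)
        m2 = BetaMatrix(m.data.iloc[:, perm])
        stats1 = cpg_stats(m, ann, "T")
        stats2 = cpg_stats(m2, ann, "T")
        pd.testing.assert_frame_equal(stats1, stats2)


def stats_table(dmean, svar):
    return pd.DataFrame(
        {"dMean": dmean, "sVar": svar,
         "direction": np.where(np.asarray(dmean) > 0, "hyper", "hypo")},
        index=pd.Index([f"cg{i:03d}" for i in range(len(dmean))], name="cpg_id"),
    )


class TestParabolaSelect:
    def test_zero_variance_selected_at_a_init(self):
        table = stats_table([-0.5], [0.0])
        hyper, hypo, a = parabola_select(table, ParabolaGate(min_hyper=0, min_hypo=1))
        assert hypo == ["cg000"] and hyper == [] and a == pytest.approx(0.1)

    def test_no_escalation_when_minima_met(self):
        dmean = [0.8] * 10 + [-0.8] * 10
        table = stats_table(dmean, [0.0] * 20)
        *_, a = parabola_select(table, ParabolaGate())
        assert a == pytest.approx(0.1)

    def test_escalation_to_a_03(self):
        """Hyper side reaches 10 only at a=0.3; gate set verified by brute force."""
        dmean = [-0.5] * 12 + [0.5] * 3 + [0.5] * 7
        svar = [0.001] * 12 + [0.002] * 3 + [0.015] * 7
        table = stats_table(dmean, svar)
        hyper, hypo, a_final = parabola_select(table, ParabolaGate())
        assert a_final == pytest.approx(0.3)
        for a in (0.1, 0.2):
            h, _ = parabola_passing_set(dmean, svar, a)
            assert len(h) < 10
        exp_hyper, exp_hypo = parabola_passing_set(dmean, svar, 0.3)
        assert {table.index[i] for i in exp_hyper} == set(hyper)
        assert {table.index[i] for i in exp_hypo} == set(hypo)

    def test_cap_returns_all_with_warning(self):
        table = stats_table([0.1, -0.1], [0.9, 0.9])
        with pytest.warns(UserWarning, match="a_max"):
            hyper, hypo, a = parabola_select(table, ParabolaGate())
        assert a == pytest.approx(10.0)

    def test_zero_dmean_on_neither_side(self):
        table = stats_table([0.0], [0.0])
        hyper, hypo, _ = parabola_select(table, ParabolaGate(min_hyper=0, min_hypo=0))
        assert hyper == [] and hypo == []


class TestRankingMetrics:
    def test_perfect_separation(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.2, 0.8, 0.9]
        assert aupr(s, y) == pytest.approx(1.0)
        assert f1_best(s, y) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = [1, 0, 0, 0]
        s = [0.5] * 4
        assert aupr(s, y) == pytest.approx(0.25)

    def test_all_positive_classifier_f1_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            s = rng.normal(size=n)
            p = y.mean()
            assert f1_best(s, y) >= 2 * p / (p + 1) - 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            aupr([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError, match="class"):
            f1_best([0.1, 0.2], [0, 0])

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(2, 13))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            # coarse scores force plenty of ties
            s = rng.integers(0, 4, size=n) / 3.0
            assert aupr(s, y) == pytest.approx(
                brute_force_average_precision(s, y), abs=1e-12)
            assert f1_best(s, y) == pytest.approx(
                brute_force_best_f1(s, y), abs=1e-12)

    def test_matches_sklearn_average_precision(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = np.zeros(n, dtype=int)
            y[: int(rng.integers(1, n))] = 1
            rng.shuffle(y)
            s = rng.normal(size=n).round(1)
            assert aupr(s, y) == pytest.approx(
                sklearn_metrics.average_precision_score(y, s), abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 15))
        y = np.zeros(n, dtype=int)
        y[: int(rng.integers(1, n))] = 1
        rng.shuffle(y)
        s = rng.integers(0, 5, size=n).astype(float)
        t = np.exp(s) + 3.0  # strictly increasing transform
        assert aupr(s, y) == pytest.approx(aupr(t, y), abs=1e-12)
        assert f1_best(s, y) == pytest.approx(f1_best(t, y), abs=1e-12)


def _two_fold_fixture():
    """8 samples, 2 types, one perfect hypo marker for T plus flat CpGs."""
    ids = [f"s{i}" for i in range(8)]
    types = ["T"] * 4 + ["O"] * 4
    marker = [0.05, 0.06, 0.04, 0.05, 0.95, 0.94, 0.96, 0.95]
    flat = [0.5, 0.51, 0.49, 0.5, 0.5, 0.51, 0.49, 0.5]
    m = BetaMatrix(pd.DataFrame(
        [marker, flat],
        index=pd.Index(["cg_marker", "cg_flat"], name="cpg_id"), columns=ids))
    ann = pd.DataFrame({"sample_id": ids, "cell_type": types})
    return m, ann


class TestRankMarkers:
    def test_planted_perfect_marker_scores_near_dmean(self):
        m, ann = _two_fold_fixture()
        labels = ann.set_index("sample_id")["cell_type"]
        plan = stratified_folds(labels, k=2, seed=0)
        gate = ParabolaGate(min_hyper=0, min_hypo=1)
        ranking = rank_markers(m, ann, "T", plan, gate=gate)
        row = ranking.table.loc["cg_marker"]
        assert row["direction"] == "hypo"
        assert row["selection_frequency"] == pytest.approx(1.0)
        assert row["mean_metric"] == pytest.approx(1.0)
        # final score = mean(AUPR * |dMean|) * frequency ~ |dMean| ~ 0.9
        assert row["final_score"] == pytest.approx(0.9, abs=0.02)
        assert row["rank"] == 1

    def test_never_selected_cpg_scores_zero_and_ranks_last(self):
        m, ann = _two_fold_fixture()
        labels = ann.set_index("sample_id")["cell_type"]
        plan = stratified_folds(labels, k=2, seed=0)
        gate = ParabolaGate(min_hyper=0, min_hypo=1)
        ranking = rank_markers(m, ann, "T", plan, gate=gate)
        flat = ranking.table.loc["cg_flat"]
        assert flat["final_score"] == 0.0
        same_dir = ranking.table[ranking.table["direction"] == flat["direction"]]
        selected = same_dir[same_dir["final_score"] > 0]
        assert (flat["rank"] > selected["rank"]).all() if len(selected) else True

    def test_final_scores_within_unit_interval(self):
        cfg = SimulationConfig(n_background_cpgs=50, n_marker_cpgs_per_type=2, seed=9)
        m, ann, _ = simulate_selection_benchmark(cfg)
        labels = ann.set_index("sample_id")["cell_type"]
        plan = stratified_folds(labels, k=5, seed=9)
        ranking = rank_markers(m, ann, "type01", plan,
                               gate=ParabolaGate(min_hyper=0, min_hypo=2))
        assert (ranking.table["final_score"] >= 0).all()
        assert (ranking.table["final_score"] <= 1).all()

    def test_too_small_folds_rejected(self):
        m, ann = _two_fold_fixture()
        labels = ann.set_index("sample_id")["cell_type"]
        plan = stratified_folds(labels, k=4, seed=0)  # 1 sample/type/fold
        with pytest.raises(ValueError, match="fold"):
            rank_markers(m, ann, "T", plan)

    def test_sample_permutation_leaves_ranking_unchanged(self):
        cfg = SimulationConfig(n_background_cpgs=40, n_marker_cpgs_per_type=2,
                               n_cell_types=3, seed=21)
        m, ann, _ = simulate_selection_benchmark(cfg)
        labels = ann.set_index("sample_id")["cell_type"]
        plan = stratified_folds(labels, k=5, seed=2)
        gate = ParabolaGate(min_hyper=0, min_hypo=2)
        r1 = rank_markers(m, ann, "type02", plan, gate=gate)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(m.sample_ids))
        m2 = BetaMatrix(m.data.iloc[:, perm])
        ann2 = ann.iloc[rng.permutation(len(ann))].reset_index(drop=True)
        r2 = rank_markers(m2, ann2, "type02", plan, gate=gate)
        pd.testing.assert_frame_equal(r1.table, r2.table)
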