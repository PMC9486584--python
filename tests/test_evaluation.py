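import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dimona import (
    DrugTargetMap,
    SensitivityTable,
    diagonal_roc,
    differential_network,
    evaluate_ranking,
    ground_truth_mwu,
    pagerank_baseline,
    partial_auc,
    rank_correlation,
    roc_metrics,
)
from dimona.evaluation import GroundTruth
from oracles import exact_mwu_p_two_sided, power_iteration_pagerank
from test_differential import integrated


def sens_table(per_drug):
    """Build a SensitivityTable from {drug: {condition: [values]}}."""
    rows = []
    for drug, conds in per_drug.items():
        for cond, vals in conds.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "cell_line_id": f"{cond}{i}",
                        "condition": cond,
                        "drug_id": drug,
                        "sensitivity": v,
                    }
                )
    return SensitivityTable(pd.DataFrame(rows))


def truth_from(pvals):
    table = pd.DataFrame(
        [{"drug_id": d, "p_value": p, "n_a": 5, "n_b": 5} for d, p in pvals.items()]
    )
    return GroundTruth("A", "B", table)


class TestGroundTruthMWU:
    def test_fully_separated_exact_p(self):
        s = sens_table({"d": {"A": [1, 2, 3], "B": [4, 5, 6]}})
        gt = ground_truth_mwu(s, "A", "B")
        assert gt.table.iloc[0]["p_value"] == pytest.approx(0.1)

    def test_matches_enumeration_oracle_small_samples(self):
        rng = np.random.default_rng(8)
        for n_a, n_b in [(3, 3), (3, 4), (4, 4), (5, 5), (4, 6)]:
            a = rng.normal(size=n_a)
            b = rng.normal(loc=0.5, size=n_b)
            s = sens_table({"d": {"A": list(a), "B": list(b)}})
            gt = ground_truth_mwu(s, "A", "B")
            expected = exact_mwu_p_two_sided(a, b)
            assert gt.table.iloc[0]["p_value"] == pytest.approx(expected, abs=1e-12)

    def test_identical_pooled_values_no_evidence(self):
        s = sens_table({"d": {"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]}})
        gt = ground_truth_mwu(s, "A", "B")
        assert gt.table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_underreplicated_drug_excluded(self):
        s = sens_table(
            {
                "ok": {"A": [1, 2, 3], "B": [4, 5, 6]},
                "thin": {"A": [1, 2], "B": [4, 5, 6]},
            }
        )
        gt = ground_truth_mwu(s, "A", "B", min_reps=3)
        assert list(gt.table["drug_id"]) == ["ok"]

    def test_absent_condition_rejected(self):
        s = sens_table({"d": {"A": [1, 2, 3]}})
        with pytest.raises(ValueError, match="absent"):
            ground_truth_mwu(s, "A", "B")


class TestRocMetrics:
    def test_perfect_ranking(self):
        truth = truth_from(
            {"p1": 0.001, "p2": 0.002, "n1": 0.5, "n2": 0.6, "n3": 0.7}
        )
        pred = {"p1": 5.0, "p2": 4.0, "n1": 3.0, "n2": 2.0, "n3": 1.0}
        auc, pauc, n = roc_metrics(pred, truth, gt_threshold=0.01)
        assert auc == pytest.approx(1.0)
        assert pauc == pytest.approx(0.1)
        assert n == 5

    def test_diagonal_baselines(self):
        fpr, tpr = diagonal_roc()
        from sklearn.metrics import auc as sk_auc

        assert sk_auc(fpr, tpr) == pytest.approx(0.5)
        assert partial_auc(fpr, tpr) == pytest.approx(0.005)

    def test_reversed_ranking_complements_auc(self):
        rng = np.random.default_rng(3)
        pvals = {f"d{i}": float(p) for i, p in enumerate(rng.uniform(0, 0.2, 30))}
        truth = truth_from(pvals)
        scores = {d: float(s) for d, s in zip(pvals, rng.normal(size=30))}
        auc_fwd, _, _ = roc_metrics(scores, truth, gt_threshold=0.05)
        auc_rev, _, _ = roc_metrics(
            {d: -s for d, s in scores.items()}, truth, gt_threshold=0.05
        )
        assert auc_fwd + auc_rev == pytest.approx(1.0)

    def test_pauc_range(self):
        rng = np.random.default_rng(4)
        pvals = {f"d{i}": float(p) for i, p in enumerate(rng.uniform(0, 0.2, 40))}
        truth = truth_from(pvals)
        for trial in range(5):
            scores = {d: float(s) for d, s in zip(pvals, rng.normal(size=40))}
            _, pauc, _ = roc_metrics(scores, truth, gt_threshold=0.05)
            assert 0.0 <= pauc <= 0.1 + 1e-12

    def test_single_class_rejected(self):
        truth = truth_from({"a": 0.5, "b": 0.6, "c": 0.7})
        with pytest.raises(ValueError, match="single class"):
            roc_metrics({"a": 1.0, "b": 2.0, "c": 3.0}, truth, gt_threshold=0.01)


class TestRankCorrelation:
    def test_perfect_anti_rank(self):
        truth = truth_from({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04})
        rho, _ = rank_correlation({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0}, truth)
        assert rho == pytest.approx(-1.0)

    def test_identical_order(self):
        truth = truth_from({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04})
        rho, _ = rank_correlation({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}, truth)
        assert rho == pytest.approx(1.0)

    def test_random_permutations_center_on_zero(self):
        rng = np.random.default_rng(11)
        n, trials = 100, 1000
        pvals = {f"d{i}": (i + 1) / (n + 1) for i in range(n)}
        truth = truth_from(pvals)
        rhos = []
        scores = np.arange(n, dtype=float)
        for _ in range(trials):
            rng.shuffle(scores)
            rho, _ = rank_correlation(dict(zip(pvals, scores)), truth)
            rhos.append(rho)
        se = 1 / np.sqrt(n - 1) / np.sqrt(trials)
        assert abs(np.mean(rhos)) < 3 * se

    def test_insufficient_overlap_rejected(self):
        truth = truth_from({"a": 0.01, "b": 0.02})
        with pytest.raises(ValueError):
            rank_correlation({"a": 1.0, "b": 2.0}, truth)


class TestPagerankBaseline:
    def test_two_node_symmetry(self):
        a = integrated([("t", "x", 0.8)], "A")
        b = integrated([("t", "x", 0.2)], "B")
        diff = differential_network(a, b)
        scores = pagerank_baseline(diff, DrugTargetMap({"d": {("p", "t")}}))
        assert scores["d"] == pytest.approx(0.5)

    def test_pagerank_vector_sums_to_one(self):
        rng = np.random.default_rng(1)
        edges_a = [(f"n{i}", f"n{j}", rng.uniform(-1, 1)) for i, j in
                   itertools.combinations(range(6), 2) if rng.random() < 0.7]
        edges_b = [(u, v, rng.uniform(-1, 1)) for u, v, _ in edges_a]
        diff = differential_network(
            integrated(edges_a, "A"), integrated(edges_b, "B")
        )
        targets = DrugTargetMap({f"d{i}": {("p", f"n{i}")} for i in range(6)})
        scores = pagerank_baseline(diff, targets)
        assert sum(scores.values()) == pytest.approx(1.0)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(6)
        edges_a = [("a", "b", 0.9), ("b", "c", -0.4), ("c", "d", 0.7),
                   ("d", "e", 0.2), ("e", "f", -0.8), ("a", "f", 0.5),
                   ("b", "e", 0.1)]
        edges_b = [(u, v, rng.uniform(-1, 1)) for u, v, _ in edges_a]
        diff = differential_network(
            integrated(edges_a, "A"), integrated(edges_b, "B")
        )
        g = nx.Graph()
        for u, v, d in diff.graph.edges(data="raw_diff"):
            g.add_edge(u, v, weight=abs(d))
        oracle = power_iteration_pagerank(g)
        targets = DrugTargetMap(
            {f"d_{n}": {("p", n)} for n in "abcdef"}
        )
        scores = pagerank_baseline(diff, targets)
        for n in "abcdef":
            assert scores[f"d_{n}"] == pytest.approx(oracle[("p", n)], abs=1e-10)

    def test_unmapped_drug_unscored(self):
        a = integrated([("t", "x", 0.8)], "A")
        b = integrated([("t", "x", 0.2)], "B")
        diff = differential_network(a, b)
        scores = pagerank_baseline(diff, DrugTargetMap({"d": {("p", "zz")}}))
        assert scores["d"] is None


def test_evaluate_ranking_joint_summary():
    truth = truth_from({"a": 0.001, "b": 0.002, "c": 0.5, "d": 0.6, "e": 0.7})
    pred = {"a": 5.0, "b": 4.0, "c": 3.0, "d": 2.0, "e": 1.0}
    res = evaluate_ranking(pred, truth, gt_threshold=0.01)
    assert res.auc == pytest.approx(1.0)
    assert res.pauc == pytest.approx(0.1)
    assert res.spearman_rho == pytest.approx(-1.0)
    assert res.n_drugs == 5
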