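"""Ground truth construction, ROC/pAUC evaluation, and a PageRank baseline.

Ground truth for differential drug response comes from cell-line sensitivity
panels: for each drug with at least ``min_reps`` measurements per condition,
a two-sided Mann-Whitney U test compares its sensitivities between the two
conditions, and the resulting p-value ranks the drugs (small p = strong
evidence of a differential response). Predictions are evaluated two ways:

* **ROC** — drugs with ground-truth p below a fixed threshold are positives;
  the predicted score ranks drugs and the ROC curve, its AUC, and the
  unnormalized partial AUC over false positive rates in [0, 0.1] are
  reported. The pAUC of an uninformative ranking is 0.1^2 / 2 = 0.005 and of
  a perfect one 0.1, so pAUC measures enrichment of true positives among the
  top-ranked drugs.
* **Rank correlation** — Spearman's rho between predicted scores and
  ground-truth p-values over the commonly ranked drugs; a good predictor
  gives high scores to low p-values, hence a negative rho.

The baseline ranks drugs by the mean weighted PageRank of their targets in
the differential network, using absolute raw differential edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

from .differential import DifferentialNetwork
from .io import DrugTargetMap, SensitivityTable

__all__ = [
    "GroundTruth",
    "EvalResult",
    "ground_truth_mwu",
    "roc_metrics",
    "rank_correlation",
    "evaluate_ranking",
    "pagerank_baseline",
    "diagonal_roc",
    "partial_auc",
]

#: FPR upper bound of the partial AUC.
PAUC_FPR_LIMIT = 0.1


@dataclass
class GroundTruth:
    """Per-drug Mann-Whitney p-values between the two conditions.

    ``table`` columns: drug_id, p_value, n_a, n_b (replicate counts).
    """

    condition_a: str
    condition_b: str
    table: pd.DataFrame

    def p_values(self) -> pd.Series:
        return self.table.set_index("drug_id")["p_value"]


@dataclass
class EvalResult:
    """Joint ROC and rank-correlation summary of one prediction."""

    auc: float
    pauc: float
    spearman_rho: float
    spearman_p: float
    n_drugs: int
    ground_truth_threshold: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "pauc": self.pauc,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n_drugs": self.n_drugs,
            "ground_truth_threshold": self.ground_truth_threshold,
        }


def ground_truth_mwu(
    sens: SensitivityTable,
    condA: str,
    condB: str,
    min_reps: int = 3,
) -> GroundTruth:
    """Two-sided Mann-Whitney U ground truth per qualifying drug.

    Drugs with fewer than ``min_reps`` measurements in either condition are
    excluded. Exact p-values are used for small tie-free samples (scipy's
    default policy: exact below 8 per group without ties, normal
    approximation with tie correction otherwise). The table is sorted by
    ascending p.
    """
    present = set(sens.data["condition"].unique())
    for c in (condA, condB):
        if c not in present:
            raise ValueError(f"condition {c!r} absent from sensitivity table")
    rows = []
    for drug in sorted(sens.data["drug_id"].unique()):
        a = sens.values_for(drug, condA)
        b = sens.values_for(drug, condB)
        if len(a) < min_reps or len(b) < min_reps:
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"drug_id": drug, "p_value": float(res.pvalue), "n_a": len(a), "n_b": len(b)}
        )
    table = pd.DataFrame(rows, columns=["drug_id", "p_value", "n_a", "n_b"])
    table = table.sort_values(["p_value", "drug_id"], kind="mergesort").reset_index(
        drop=True
    )
    return GroundTruth(condition_a=condA, condition_b=condB, table=table)


def partial_auc(fpr: np.ndarray, tpr: np.ndarray, limit: float = PAUC_FPR_LIMIT) -> float:
    """Unnormalized trapezoidal area under (fpr, tpr) for fpr in [0, limit]."""
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    grid = np.unique(np.concatenate([fpr[fpr <= limit], [limit]]))
    tpr_i = np.interp(grid, fpr, tpr)
    return float(np.trapezoid(tpr_i, grid))


def diagonal_roc(n_points: int = 101) -> tuple[np.ndarray, np.ndarray]:
    """The theoretical uninformative (random-ranking) ROC curve."""
    x = np.linspace(0.0, 1.0, n_points)
    return x, x.copy()


def roc_metrics(
    pred_ranking: dict[str, float] | pd.Series,
    truth: GroundTruth,
    gt_threshold: float = 0.01,
) -> tuple[float, float, int]:
    """AUC and unnormalized pAUC of a predicted drug ranking.

    Ground-truth positives are drugs with p below ``gt_threshold``; only
    drugs present in both the prediction and the ground truth enter. Returns
    ``(auc, pauc, n_drugs)``. Ties in the predicted score are handled by the
    ROC convention of a single diagonal segment across the tied block.
    """
    pred = pd.Series(pred_ranking, dtype=float).dropna()
    p = truth.p_values()
    common = pred.index.intersection(p.index)
    if len(common) == 0:
        raise ValueError("no drugs shared between prediction and ground truth")
    y_true = (p.loc[common] < gt_threshold).to_numpy()
    y_score = pred.loc[common].to_numpy()
    if y_true.all() or not y_true.any():
        raise ValueError(
            "binarization yields a single class; choose another threshold"
        )
    fpr, tpr, _ = metrics.roc_curve(y_true, y_score)
    auc = float(metrics.auc(fpr, tpr))
    return auc, partial_auc(fpr, tpr), int(len(common))


def rank_correlation(
    pred_ranking: dict[str, float] | pd.Series,
    truth: GroundTruth,
) -> tuple[float, float]:
    """Spearman rho (and p) between predicted scores and ground-truth p-values."""
    pred = pd.Series(pred_ranking, dtype=float).dropna()
    p = truth.p_values()
    common = pred.index.intersection(p.index)
    if len(common) < 3:
        raise ValueError("rank correlation needs >= 3 commonly ranked drugs")
    rho, pval = stats.spearmanr(pred.loc[common], p.loc[common])
    return float(rho), float(pval)


def evaluate_ranking(
    pred_ranking: dict[str, float] | pd.Series,
    truth: GroundTruth,
    gt_threshold: float = 0.01,
) -> EvalResult:
    """Full evaluation: ROC AUC, pAUC and Spearman correlation."""
    auc, pauc, n = roc_metrics(pred_ranking, truth, gt_threshold)
    rho, pval = rank_correlation(pred_ranking, truth)
    return EvalResult(
        auc=auc,
        pauc=pauc,
        spearman_rho=rho,
        spearman_p=pval,
        n_drugs=n,
        ground_truth_threshold=gt_threshold,
    )


def pagerank_baseline(
    diff: DifferentialNetwork,
    targets: DrugTargetMap,
    damping: float = 0.85,
) -> dict[str, float | None]:
    """Mean weighted PageRank of each drug's targets in the differential graph.

    Edge weights are the absolute raw differential edge weights (not the
    integrated scores). Drugs with no target in the graph map to ``None``.
    """
    g = nx.Graph()
    g.add_nodes_from(diff.graph.nodes)
    g.add_weighted_edges_from(
        (u, v, abs(d)) for u, v, d in diff.graph.edges(data="raw_diff")
    )
    pr = nx.pagerank(g, alpha=damping, weight="weight", tol=1e-13, max_iter=1000)
    scores: dict[str, float | None] = {}
    for drug in targets.drugs:
        tnodes = [t for t in targets.targets_of(drug) if t in pr]
        scores[drug] = float(np.mean([pr[t] for t in tnodes])) if tnodes else None
    return scores
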