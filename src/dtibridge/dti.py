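"""Target-specific likelihood-of-interaction (LOI) scoring and its
leave-one-out cross-validated evaluation.

For a target T with N known (benchmark) ligands in the compound library, the
LOI of a candidate compound C is the mean BAES between C and T's benchmarks,
leaving C itself out when it is a benchmark. LOOCV labels every compound in
the universe positive (benchmark) or negative (everything else — unknown
true ligands contaminate the negatives by design) and evaluates the ranking
with ROC AUC, a stratified 2000-replicate bootstrap confidence interval, and
the enrichment above the LOI threshold at 90% specificity: odds ratio
OR = (TP/FN) / (FP/TN) and a one-sided (greater) Fisher exact test. A target
is called well characterised when the AUC interval's lower bound exceeds 0.5
and the Fisher p is below 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TargetModel",
    "LOIScore",
    "ContingencyTable",
    "TargetEvalReport",
    "loi",
    "loocv_scores",
    "roc_auc",
    "bootstrap_auc_ci",
    "specificity_threshold",
    "contingency_at_threshold",
    "odds_ratio",
    "fisher_exact_p",
    "evaluate_target",
]


@dataclass
class TargetModel:
    target_id: str
    benchmark_ligands: frozenset[str]

    def __post_init__(self) -> None:
        self.benchmark_ligands = frozenset(self.benchmark_ligands)
        if not self.benchmark_ligands:
            raise ValueError(f"target {self.target_id!r} has no benchmark ligands")

    @property
    def n(self) -> int:
        return len(self.benchmark_ligands)


@dataclass
class LOIScore:
    compound_id: str
    target_id: str
    loi: float
    n_benchmarks_used: int


@dataclass
class ContingencyTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fn + self.fp + self.tn == 0:
            raise ValueError("contingency table is all zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class TargetEvalReport:
    target_id: str
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    threshold: float
    table: ContingencyTable
    odds_ratio: float
    fisher_p: float
    n_pos: int
    n_neg: int
    well_characterized: bool

    def to_dict(self) -> dict:
        return {
            "target_id": self.target_id,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci_low,
            "auc_ci_high": self.auc_ci_high,
            "threshold": self.threshold,
            "tp": self.table.tp,
            "fn": self.table.fn,
            "fp": self.table.fp,
            "tn": self.table.tn,
            "odds_ratio": self.odds_ratio,
            "fisher_p": self.fisher_p,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "well_characterized": self.well_characterized,
        }


def loi(compound: str, model: TargetModel, sim: SimilarityMatrix) -> LOIScore:
    """Mean BAES between a compound and the target's benchmarks, leaving the
    compound itself out of the benchmark set."""
    benchmarks = sorted(model.benchmark_ligands - {compound})
    if not benchmarks:
        raise ValueError(
            f"target {model.target_id!r} has no benchmark other than {compound!r}"
        )
    values = [sim.score(compound, b) for b in benchmarks]
    return LOIScore(
        compound_id=compound,
        target_id=model.target_id,
        loi=float(np.mean(values)),
        n_benchmarks_used=len(benchmarks),
    )


def loocv_scores(
    model: TargetModel, sim: SimilarityMatrix, universe: list[str] | None = None
) -> pd.DataFrame:
    """Leave-one-out LOI of every compound, labelled positive (benchmark) or
    negative. Benchmarks score against the other N-1 benchmarks; negatives
    against all N."""
    if model.n < 2:
        raise ValueError("LOOCV needs at least 2 benchmark ligands")
    if universe is None:
        universe = list(sim.compound_ids)
    missing = model.benchmark_ligands - set(universe)
    if missing:
        raise ValueError(f"benchmarks absent from universe: {sorted(missing)}")
    rows = []
    for c in universe:
        score = loi(c, model, sim)
        rows.append(
            {
                "compound_id": c,
                "loi": score.loi,
                "label": int(c in model.benchmark_ligands),
            }
        )
    return pd.DataFrame(rows)


def roc_auc(scores: pd.DataFrame) -> float:
    """AUC via the Mann-Whitney rank statistic: P(LOI_pos > LOI_neg) plus
    half the tie probability."""
    labels = scores["label"].to_numpy()
    values = scores["loi"].to_numpy(dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(values)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def bootstrap_auc_ci(
    scores: pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the AUC.

    Positives and negatives are resampled with replacement within their own
    stratum, so every replicate retains both classes; reproducible given the
    seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = scores["label"].to_numpy()
    values = scores["loi"].to_numpy(dtype=float)
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap needs both classes")
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=len(pos), replace=True)
        n = rng.choice(neg, size=len(neg), replace=True)
        merged = np.concatenate([p, n])
        ranks = stats.rankdata(merged)
        u = ranks[: len(p)].sum() - len(p) * (len(p) + 1) / 2
        aucs[b] = u / (len(p) * len(n))
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(low), float(high)


def specificity_threshold(neg_scores: np.ndarray | list, specificity: float = 0.90) -> float:
    """The LOI threshold at the requested specificity: the ceil(q * n)-th
    smallest negative score. A compound is called positive iff its LOI is
    strictly above the threshold, guaranteeing at least ``specificity`` of
    negatives at or below it."""
    neg = np.sort(np.asarray(neg_scores, dtype=float))
    if neg.size == 0:
        raise ValueError("need at least one negative score")
    k = math.ceil(specificity * neg.size)
    k = min(max(k, 1), neg.size)
    return float(neg[k - 1])


def contingency_at_threshold(scores: pd.DataFrame, threshold: float) -> ContingencyTable:
    labels = scores["label"].to_numpy()
    values = scores["loi"].to_numpy(dtype=float)
    above = values > threshold
    return ContingencyTable(
        tp=int(np.sum(above & (labels == 1))),
        fn=int(np.sum(~above & (labels == 1))),
        fp=int(np.sum(above & (labels == 0))),
        tn=int(np.sum(~above & (labels == 0))),
    )


def odds_ratio(t: ContingencyTable) -> float:
    """Enrichment odds ratio OR = (TP/FN) / (FP/TN).

    Returns 0 when TP = 0 and +inf when a zero FN or FP cell makes the
    ratio unbounded."""
    if t.tp == 0:
        return 0.0
    if t.fn == 0 or t.fp == 0:
        return math.inf
    return (t.tp / t.fn) / (t.fp / t.tn)


def fisher_exact_p(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p: the hypergeometric tail
    P(X >= TP) for the observed margins."""
    _, p = stats.fisher_exact(t.as_array(), alternative="greater")
    return float(p)


def evaluate_target(
    model: TargetModel,
    sim: SimilarityMatrix,
    universe: list[str] | None = None,
    min_ligands: int = 5,
    n_boot: int = 2000,
    specificity: float = 0.90,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> TargetEvalReport | None:
    """Full LOOCV evaluation of one target.

    Returns ``None`` (with a log line) when the target has fewer than
    ``min_ligands`` benchmarks — too few for a stable bootstrap and Fisher
    test."""
    if model.n < min_ligands:
        logger.info(
            "skipping target %s: %d ligands < min_ligands=%d",
            model.target_id, model.n, min_ligands,
        )
        return None
    scores = loocv_scores(model, sim, universe)
    auc = roc_auc(scores)
    ci_low, ci_high = bootstrap_auc_ci(scores, n_boot=n_boot, level=level, seed=seed)
    neg = scores.loc[scores["label"] == 0, "loi"].to_numpy()
    threshold = specificity_threshold(neg, specificity)
    table = contingency_at_threshold(scores, threshold)
    o_r = odds_ratio(table)
    p = fisher_exact_p(table)
    return TargetEvalReport(
        target_id=model.target_id,
        auc=auc,
        auc_ci_low=ci_low,
        auc_ci_high=ci_high,
        threshold=threshold,
        table=table,
        odds_ratio=o_r,
        fisher_p=p,
        n_pos=int(scores["label"].sum()),
        n_neg=int((1 - scores["label"]).sum()),
        well_characterized=bool(ci_low > 0.5 and p < 0.05),
    )
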