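"""Target-target interaction (TTI) screen.

A target-target interaction is the collective enrichment of one target's
ligand family above another target's 90%-specificity LOI threshold: if the
designated ligands of target T1 systematically look like ligands of a
ligand-disjoint ("distant") target T2 in expression space, the two targets
may share off-target pharmacology. The screen scores every compound against
T2's benchmark model, sets the threshold from T2's negatives, and Fisher-tests
whether T1's family falls above it more often than the background does.

Only raw one-sided p-values are the screen's contract; a Benjamini-Hochberg
adjusted column is appended to matrix output purely as a reading convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dti import (
    ContingencyTable,
    TargetModel,
    contingency_at_threshold,
    fisher_exact_p,
    loi,
    specificity_threshold,
)
from .similarity import SimilarityMatrix

__all__ = ["TTIRecord", "tti_test", "tti_matrix"]

MASKED = "masked"


@dataclass
class TTIRecord:
    ligand_family_target: str  # T1: the family being tested
    model_target: str  # T2: the target whose LOI model scores the family
    table: ContingencyTable
    fisher_p: float
    n_family: int
    threshold: float


def tti_test(
    t1: TargetModel,
    t2: TargetModel,
    sim: SimilarityMatrix,
    universe: list[str] | None = None,
    specificity: float = 0.90,
) -> TTIRecord:
    """Test whether T1's ligand family is enriched above T2's LOI threshold.

    Preconditions: T1 and T2 are distant targets (no shared ligands).
    Positives are T1's ligands; negatives are the rest of the universe minus
    T2's own ligands (known, not discoveries). T2's benchmarks score
    leave-self-out exactly as in LOOCV."""
    shared = t1.benchmark_ligands & t2.benchmark_ligands
    if shared:
        raise ValueError(
            f"targets {t1.target_id!r} and {t2.target_id!r} share ligands "
            f"{sorted(shared)}; not distant — mask this pair instead"
        )
    if universe is None:
        universe = list(sim.compound_ids)
    family = sorted(t1.benchmark_ligands & set(universe))
    if not family:
        raise ValueError(f"no ligand of {t1.target_id!r} present in the universe")

    loi_values = {c: loi(c, t2, sim).loi for c in universe}
    t2_negatives = [c for c in universe if c not in t2.benchmark_ligands]
    threshold = specificity_threshold(
        np.array([loi_values[c] for c in t2_negatives]), specificity
    )

    kept = [c for c in universe if c not in t2.benchmark_ligands]
    scores = pd.DataFrame(
        {
            "compound_id": kept,
            "loi": [loi_values[c] for c in kept],
            "label": [int(c in t1.benchmark_ligands) for c in kept],
        }
    )
    table = contingency_at_threshold(scores, threshold)
    return TTIRecord(
        ligand_family_target=t1.target_id,
        model_target=t2.target_id,
        table=table,
        fisher_p=fisher_exact_p(table),
        n_family=len(family),
        threshold=threshold,
    )


def tti_matrix(
    targets: list[TargetModel],
    sim: SimilarityMatrix,
    universe: list[str] | None = None,
    specificity: float = 0.90,
) -> pd.DataFrame:
    """All ordered distant target pairs, long format.

    Rows are (family_target T1, model_target T2) with the 2x2 table and
    Fisher p; pairs sharing an annotated ligand carry an explicit mask marker
    and no p-value. The matrix is asymmetric: the family and model roles
    differ. A BH-adjusted p column over the unmasked cells is appended."""
    if len(targets) < 2:
        raise ValueError("need at least two targets")
    rows = []
    for t1 in targets:
        for t2 in targets:
            if t1.target_id == t2.target_id:
                continue
            if t1.benchmark_ligands & t2.benchmark_ligands:
                rows.append(
                    {
                        "family_target": t1.target_id,
                        "model_target": t2.target_id,
                        "tp": None, "fn": None, "fp": None, "tn": None,
                        "fisher_p": None,
                        "masked": True,
                    }
                )
                continue
            rec = tti_test(t1, t2, sim, universe, specificity)
            rows.append(
                {
                    "family_target": rec.ligand_family_target,
                    "model_target": rec.model_target,
                    "tp": rec.table.tp, "fn": rec.table.fn,
                    "fp": rec.table.fp, "tn": rec.table.tn,
                    "fisher_p": rec.fisher_p,
                    "masked": False,
                }
            )
    df = pd.DataFrame(rows)
    df["fisher_p_bh"] = _benjamini_hochberg(df["fisher_p"])
    return df.sort_values(
        ["masked", "fisher_p"], na_position="last", kind="stable"
    ).reset_index(drop=True)


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    """BH step-up adjusted p-values; NaN (masked) cells stay NaN."""
    out = pd.Series(np.nan, index=p.index, dtype=float)
    valid = p.dropna()
    if valid.empty:
        return out
    m = len(valid)
    order = np.argsort(valid.to_numpy())
    adj = valid.to_numpy()[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out.loc[valid.index[order]] = np.minimum(adj, 1.0)
    return out
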