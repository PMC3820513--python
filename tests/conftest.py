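import numpy as np
import pandas as pd
import pytest

import dtibridge as dtb


@pytest.fixture(scope="session")
def default_screen():
    """One default synthetic screen, adjusted and scored, shared read-only."""
    cfg = dtb.SimConfig(seed=11)
    expr, meta, dtm, truth = dtb.simulate(cfg)
    adjusted, report = dtb.adjust(expr, meta)
    profiles = dtb.build_profiles(adjusted, meta)
    sim = dtb.baes_matrix(profiles)
    return {
        "config": cfg,
        "expr": expr,
        "meta": meta,
        "dtm": dtm,
        "truth": truth,
        "adjusted": adjusted,
        "adjust_report": report,
        "sim": sim,
    }


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 instances, two batches, one bridge drug (D1)."""
    data = pd.DataFrame(
        {
            "i1": [2.0, 1.0, 0.5],
            "i2": [4.0, 1.0, 1.0],
            "i3": [1.0, 0.5, 0.25],
            "i4": [8.0, 2.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return dtb.ExpressionMatrix(data)


@pytest.fixture()
def tiny_meta():
    return dtb.InstanceTable(
        pd.DataFrame(
            {
                "instance_id": ["i1", "i2", "i3", "i4"],
                "batch_id": ["X", "X", "Y", "Y"],
                "compound_id": ["D1", "D2", "D1", "D3"],
            }
        )
    )


def ranked_from_positions(tag_positions: set[int], n: int) -> tuple[set[str], dtb.RankedGeneList]:
    """Build a ranked list of n genes with tags at the given 1-based positions."""
    genes = [f"g{i:03d}" for i in range(1, n + 1)]
    ranked = dtb.RankedGeneList(compound_id="q", ordering=genes)
    tags = {genes[p - 1] for p in tag_positions}
    return tags, ranked


def ks_oracle(tag_positions, n: int) -> float:
    """Loop-based two-sided KS statistic from 1-based tag positions."""
    from fractions import Fraction

    v = sorted(tag_positions)
    t = len(v)
    a = max(Fraction(j, t) - Fraction(v[j - 1], n) for j in range(1, t + 1))
    b = max(Fraction(v[j - 1], n) - Fraction(j - 1, t) for j in range(1, t + 1))
    return float(a) if a >= b else float(-b)


def auc_oracle(pos, neg) -> float:
    """Pairwise counting AUC: wins + half-ties over all pos x neg pairs."""
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def fisher_greater_oracle(tp: int, fn: int, fp: int, tn: int) -> float:
    """Hypergeometric tail P(X >= tp) by direct enumeration."""
    from math import comb

    pos = tp + fn
    total = tp + fn + fp + tn
    drawn = tp + fp
    denom = comb(total, drawn)
    return sum(
        comb(pos, k) * comb(total - pos, drawn - k) for k in range(tp, min(pos, drawn) + 1)
    ) / denom


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
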