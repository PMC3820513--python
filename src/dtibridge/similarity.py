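"""Per-compound profiles, rank signatures and the bidirectional KS
connectivity score (BAES, bridge-adjusted expression similarity).

Each compound's instances are averaged (on log2 scale) into one synthetic
expression profile; genes are ranked most-up-regulated first, and the top
and bottom ``s`` genes (default 250) form the up/down tag sets of the
compound's signature. Querying compound B's ranked list with compound A's
signature uses the two-sided Kolmogorov-Smirnov statistic of the original
connectivity-map enrichment score: with tag positions V(1) < ... < V(t) in a
list of n genes,

    a = max_j ( j/t - V(j)/n ),   b = max_j ( V(j)/n - (j-1)/t )

and the statistic is ``a`` if a >= b else ``-b``. The directed connectivity
score is ks_up - ks_down, zeroed when the two share a sign (discordant
signatures carry no evidence); BAES is the mean of the two directed scores
of a pair, hence symmetric and bounded by 2 in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, InstanceTable

__all__ = [
    "CompoundProfile",
    "RankedGeneList",
    "Signature",
    "SimilarityMatrix",
    "build_profiles",
    "rank_and_sign",
    "ks_statistic",
    "connectivity_score",
    "baes",
    "baes_matrix",
]

DEFAULT_SIGNATURE_SIZE = 250


@dataclass
class CompoundProfile:
    compound_id: str
    profile: pd.Series  # per-gene mean log2 fold change, full gene universe
    n_instances: int


@dataclass
class RankedGeneList:
    """A bijection over the gene universe: position 1 = most up-regulated."""

    compound_id: str
    ordering: list[str]

    def positions(self) -> dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.ordering)}


@dataclass
class Signature:
    compound_id: str
    up_tags: frozenset[str]
    down_tags: frozenset[str]
    s: int


class SimilarityMatrix:
    """Symmetric compound x compound BAES scores with optional directed scores.

    Stored as a dense float matrix with NaN on the diagonal (self-similarity
    is undefined in the pair set).
    """

    def __init__(
        self,
        compound_ids: list[str],
        scores: np.ndarray,
        directed: np.ndarray | None = None,
    ):
        self.compound_ids = list(compound_ids)
        self._index = {c: i for i, c in enumerate(self.compound_ids)}
        self.scores = scores
        self.directed = directed  # directed[i, j] = score of sig_i queried on ranked_j

    def score(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError(f"self-similarity of {a!r} is undefined")
        return float(self.scores[self._index[a], self._index[b]])

    def row(self, a: str) -> pd.Series:
        return pd.Series(self.scores[self._index[a]], index=self.compound_ids)

    @property
    def n_pairs(self) -> int:
        m = len(self.compound_ids)
        return m * (m - 1) // 2

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered pair, lexicographically ordered."""
        rows = []
        ids = self.compound_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rec = {
                    "compound_a": ids[i],
                    "compound_b": ids[j],
                    "baes": self.scores[i, j],
                }
                if self.directed is not None:
                    rec["score_ab"] = self.directed[i, j]
                    rec["score_ba"] = self.directed[j, i]
                rows.append(rec)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimilarityMatrix":
        ids = sorted(set(df["compound_a"]) | set(df["compound_b"]))
        index = {c: i for i, c in enumerate(ids)}
        m = len(ids)
        scores = np.full((m, m), np.nan)
        directed = None
        has_directed = {"score_ab", "score_ba"} <= set(df.columns)
        if has_directed:
            directed = np.full((m, m), np.nan)
        for row in df.itertuples(index=False):
            i, j = index[row.compound_a], index[row.compound_b]
            scores[i, j] = scores[j, i] = row.baes
            if has_directed:
                directed[i, j] = row.score_ab
                directed[j, i] = row.score_ba
        return cls(ids, scores, directed)


# ---------------------------------------------------------------------------
# Profiles and signatures
# ---------------------------------------------------------------------------


def build_profiles(
    expr: ExpressionMatrix, meta: InstanceTable, linear_mean: bool = False
) -> list[CompoundProfile]:
    """One synthetic expression profile per compound: the mean over its
    instances, pooled across batches, cell lines and doses.

    By default the mean is taken on log2 scale (geometric mean of ratios);
    ``linear_mean`` averages the raw ratios before taking logs instead.
    """
    present = [i for i in meta.instance_ids if i in set(expr.instance_ids)]
    sub = meta.data[meta.data["instance_id"].isin(present)]
    profiles = []
    for compound, grp in sub.groupby("compound_id", sort=True):
        cols = list(grp["instance_id"])
        block = expr.data[cols]
        if linear_mean:
            prof = np.log2(block.mean(axis=1))
        else:
            prof = np.log2(block).mean(axis=1)
        profiles.append(
            CompoundProfile(compound_id=compound, profile=prof, n_instances=len(cols))
        )
    return profiles


def rank_and_sign(
    profile: CompoundProfile, s: int = DEFAULT_SIGNATURE_SIZE
) -> tuple[RankedGeneList, Signature]:
    """Rank genes by descending log2 fold change and cut the signature.

    Ties resolve lexicographically by gene id so the ordering is
    deterministic; the tag-set size is clamped to floor(n/2) so up and down
    tags never overlap.
    """
    prof = profile.profile
    order = sorted(prof.index, key=lambda g: (-prof[g], g))
    eff = min(s, len(order) // 2)
    ranked = RankedGeneList(compound_id=profile.compound_id, ordering=order)
    sig = Signature(
        compound_id=profile.compound_id,
        up_tags=frozenset(order[:eff]),
        down_tags=frozenset(order[-eff:]) if eff else frozenset(),
        s=eff,
    )
    return ranked, sig


# ---------------------------------------------------------------------------
# KS / connectivity scoring
# ---------------------------------------------------------------------------


def _ks_from_positions(positions: np.ndarray, n: int) -> float:
    """KS statistic from sorted 1-based tag positions in a list of n genes."""
    v = np.sort(np.asarray(positions, dtype=float))
    t = len(v)
    j = np.arange(1, t + 1, dtype=float)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    # the tie a == b resolves toward +a; tolerate float rounding of the
    # exact-rational tie
    return float(a) if a >= b - 1e-12 else float(-b)


def ks_statistic(tags: set[str], ranked: RankedGeneList) -> float:
    """Two-sided KS enrichment statistic of ``tags`` within ``ranked``.

    Positive when the tags crowd the top of the list, negative toward the
    bottom; the tie a == b resolves toward +a.
    """
    if not tags:
        raise ValueError("empty tag set")
    pos = ranked.positions()
    missing = set(tags) - pos.keys()
    if missing:
        raise KeyError(f"tags absent from gene universe: {sorted(missing)[:5]}")
    v = np.array([pos[g] for g in tags])
    return _ks_from_positions(v, len(ranked.ordering))


def connectivity_score(sig: Signature, ranked: RankedGeneList) -> float:
    """Directed score of one signature against one ranked list, in [-2, 2].

    Zero whenever up- and down-tag statistics agree in sign (the signature's
    two halves disagree about the query's direction)."""
    ks_up = ks_statistic(set(sig.up_tags), ranked)
    ks_down = ks_statistic(set(sig.down_tags), ranked)
    return _combine(ks_up, ks_down)


def _combine(ks_up: float, ks_down: float) -> float:
    if (ks_up > 0 and ks_down > 0) or (ks_up < 0 and ks_down < 0):
        return 0.0
    return ks_up - ks_down


def baes(
    a: str,
    b: str,
    profiles: list[CompoundProfile] | dict[str, CompoundProfile],
    s: int = DEFAULT_SIGNATURE_SIZE,
) -> float:
    """BAES of one unordered compound pair: mean of the two directed scores."""
    if a == b:
        raise ValueError("BAES of a compound with itself is undefined")
    if not isinstance(profiles, dict):
        profiles = {p.compound_id: p for p in profiles}
    ranked_a, sig_a = rank_and_sign(profiles[a], s)
    ranked_b, sig_b = rank_and_sign(profiles[b], s)
    return 0.5 * (connectivity_score(sig_a, ranked_b) + connectivity_score(sig_b, ranked_a))


def baes_matrix(
    profiles: list[CompoundProfile], s: int = DEFAULT_SIGNATURE_SIZE
) -> SimilarityMatrix:
    """All-pairs BAES over the compound library (C(m, 2) unordered pairs).

    Vectorised: per query compound, the KS statistics of every signature's
    tag positions within that compound's ranked list are computed in one
    sweep over an (m, s) position array.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two compound profiles")
    profiles = sorted(profiles, key=lambda p: p.compound_id)
    ids = [p.compound_id for p in profiles]
    m = len(ids)
    genes = list(profiles[0].profile.index)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    eff = min(s, n // 2)

    # rank position (1-based) of each gene in each compound's ordering,
    # and each compound's up/down tag gene indices
    rank_pos = np.empty((m, n), dtype=np.int32)
    up_idx = np.empty((m, eff), dtype=np.int32)
    down_idx = np.empty((m, eff), dtype=np.int32)
    for ci, p in enumerate(profiles):
        ranked, sig = rank_and_sign(p, s)
        order_idx = np.fromiter((gene_index[g] for g in ranked.ordering), dtype=np.int32, count=n)
        rank_pos[ci, order_idx] = np.arange(1, n + 1, dtype=np.int32)
        up_idx[ci] = order_idx[:eff]
        down_idx[ci] = order_idx[n - eff:]

    j = np.arange(1, eff + 1, dtype=float)
    directed = np.full((m, m), np.nan)

    def ks_all(tag_idx: np.ndarray, query: int) -> np.ndarray:
        # KS of every compound's tag set within compound `query`'s ranking
        v = np.sort(rank_pos[query][tag_idx].astype(float), axis=1)
        a = np.max(j / eff - v / n, axis=1)
        b = np.max(v / n - (j - 1) / eff, axis=1)
        return np.where(a >= b - 1e-12, a, -b)

    for q in range(m):
        ks_up = ks_all(up_idx, q)
        ks_down = ks_all(down_idx, q)
        same_sign = ((ks_up > 0) & (ks_down > 0)) | ((ks_up < 0) & (ks_down < 0))
        directed[:, q] = np.where(same_sign, 0.0, ks_up - ks_down)
    np.fill_diagonal(directed, np.nan)

    scores = 0.5 * (directed + directed.T)
    return SimilarityMatrix(ids, scores, directed)
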