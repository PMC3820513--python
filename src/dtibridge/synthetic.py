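"""Synthetic connectivity-map-shaped data with known ground truth.

The generator emulates the structure of a multi-batch drug-perturbation
expression screen: many batches of varying size (a few large ones), compounds
occasionally re-assayed in a second batch (the bridges that make adjustment
possible), and ligand families that share a target-specific module of
downstream genes — the premise that drugs binding the same target perturb
the same transcriptional program.

Generative model, per gene g and instance i (all on log2 scale):

    log2 value(g, i) = drug_effect(compound(i), g)
                       + batch_offset(batch(i), g)
                       + eps,   eps ~ Normal(0, noise_sd)

where drug_effect is the sum of the compound's target-module effects (signed:
half of each module up, half down, magnitude ``effect_size``), any planted
off-target module (scaled by ``tti_scale``), and a sparse idiosyncratic
component distinguishing individual compounds. Batch offsets are additive in
log space — the model family under which bridge adjustment is exactly
correct; a multiplicative-in-log misspecification mode exists for robustness
testing and is off by default.

Emitted matrices are linear ratios 2**log2value > 0 and pass all core_data
validators; everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import DrugTargetMap, ExpressionMatrix, InstanceTable

__all__ = ["SimConfig", "SimTruth", "simulate", "scramble_labels"]


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults give a desk-scale screen: 2000 genes, 10 batches with three
    large ones, 120 compounds of which 48 are ligands of 6 targets (8 each),
    40-gene modules with unit mean |log2 FC|, batch effects comparable in
    magnitude to drug effects, and moderate residual noise.
    """

    n_genes: int = 2000
    n_batches: int = 10
    # relative expected batch sizes; None -> three large batches, rest small
    batch_size_distribution: tuple[float, ...] | None = None
    n_compounds: int = 120
    bridge_density: float = 0.5  # P(compound re-assayed in a second batch)
    n_targets: int = 6
    ligands_per_target: int = 8
    module_size: int = 40
    effect_size: float = 1.0  # mean |log2 FC| of module genes
    batch_sd: float = 1.0  # sd of per-(batch, gene) log2 offsets
    noise_sd: float = 0.3  # residual log2-scale noise
    idiosyncratic_frac: float = 0.2  # fraction of genes with compound-specific effect
    tti_pairs: tuple[tuple[str, str], ...] = ()  # (family_target, model_target)
    tti_scale: float = 1.0  # planted off-target module strength relative to its own
    batch_model: str = "additive"  # or "multiplicative" (misspecification mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_batches, self.n_compounds, self.n_targets,
               self.ligands_per_target, self.module_size) < 1:
            raise ValueError("all counts must be >= 1")
        if self.batch_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_targets * self.ligands_per_target > self.n_compounds:
            raise ValueError("more ligands requested than compounds available")
        if self.batch_model not in ("additive", "multiplicative"):
            raise ValueError("batch_model must be 'additive' or 'multiplicative'")

    def batch_weights(self) -> np.ndarray:
        if self.batch_size_distribution is not None:
            w = np.asarray(self.batch_size_distribution, dtype=float)
            if len(w) != self.n_batches:
                raise ValueError("batch_size_distribution length != n_batches")
        else:
            n_big = min(3, self.n_batches)
            w = np.array([45.0] * n_big + [10.0] * (self.n_batches - n_big))
        return w / w.sum()


@dataclass
class SimTruth:
    """Everything the generator knows that the pipeline must recover."""

    batch_offsets: pd.DataFrame  # genes x batches, log2 scale
    module_effects: dict[str, pd.Series]  # target -> signed per-gene module effect
    compound_targets: dict[str, set[str]]
    drug_effects: pd.DataFrame  # genes x compounds, log2 scale
    tti_pairs: tuple[tuple[str, str], ...]
    warnings: list[str] = field(default_factory=list)


def simulate(config: SimConfig) -> tuple[ExpressionMatrix, InstanceTable, DrugTargetMap, SimTruth]:
    """Draw one screen: expression matrix, instance metadata, annotation and
    the ground truth behind them."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    batches = [f"B{i:02d}" for i in range(config.n_batches)]
    compounds = [f"C{i:04d}" for i in range(config.n_compounds)]
    targets = [f"T{i + 1}" for i in range(config.n_targets)]

    # target modules: disjoint gene sets, half up / half down at effect_size
    module_effects: dict[str, pd.Series] = {}
    if config.n_targets * config.module_size > config.n_genes:
        raise ValueError("modules do not fit disjointly into the gene universe")
    module_pool = rng.choice(config.n_genes, size=config.n_targets * config.module_size,
                             replace=False)
    for k, t in enumerate(targets):
        idx = module_pool[k * config.module_size:(k + 1) * config.module_size]
        eff = pd.Series(0.0, index=genes)
        half = config.module_size // 2
        eff.iloc[idx[:half]] = config.effect_size
        eff.iloc[idx[half:]] = -config.effect_size
        module_effects[t] = eff

    # ligand assignment: the first n_targets * ligands_per_target compounds
    compound_targets: dict[str, set[str]] = {c: set() for c in compounds}
    pos = 0
    for t in targets:
        for _ in range(config.ligands_per_target):
            compound_targets[compounds[pos]].add(t)
            pos += 1

    # drug effects: module sums + planted off-target modules + sparse idiosyncrasy
    known_targets = set(targets)
    for fam, mod in config.tti_pairs:
        if fam not in known_targets or mod not in known_targets:
            raise ValueError(f"tti pair ({fam}, {mod}) names an unknown target")
    drug_effects = pd.DataFrame(0.0, index=genes, columns=compounds)
    n_idio = max(1, round(config.idiosyncratic_frac * config.n_genes))
    for c in compounds:
        eff = np.zeros(config.n_genes)
        for t in compound_targets[c]:
            eff += module_effects[t].to_numpy()
            for fam, mod in config.tti_pairs:
                if fam == t:
                    eff += config.tti_scale * module_effects[mod].to_numpy()
        idio_idx = rng.choice(config.n_genes, size=n_idio, replace=False)
        eff[idio_idx] += rng.normal(0.0, config.effect_size, size=n_idio)
        drug_effects[c] = eff

    # instance layout: home batch per compound; bridge re-assays in another batch
    weights = config.batch_weights()
    rows = []
    counter = 0
    for c in compounds:
        home = batches[rng.choice(config.n_batches, p=weights)]
        rows.append((f"I{counter:05d}", home, c))
        counter += 1
        if config.n_batches > 1 and rng.random() < config.bridge_density:
            others = [b for b in batches if b != home]
            w = np.array([weights[batches.index(b)] for b in others])
            other = others[rng.choice(len(others), p=w / w.sum())]
            rows.append((f"I{counter:05d}", other, c))
            counter += 1
    meta_df = pd.DataFrame(rows, columns=["instance_id", "batch_id", "compound_id"])
    meta = InstanceTable(meta_df)

    warnings: list[str] = []
    if config.n_batches > 1:
        multi = meta_df.groupby("compound_id")["batch_id"].nunique()
        if (multi < 2).all():
            warnings.append(
                "no compound spans two batches: adjustment will report "
                "unadjustable batches"
            )

    batch_offsets = pd.DataFrame(
        rng.normal(0.0, config.batch_sd, size=(config.n_genes, config.n_batches)),
        index=genes, columns=batches,
    )

    log2v = np.empty((config.n_genes, len(meta_df)))
    for col, (_, b, c) in enumerate(meta_df.itertuples(index=False)):
        base = drug_effects[c].to_numpy()
        off = batch_offsets[b].to_numpy()
        if config.batch_model == "additive":
            signal = base + off
        else:  # multiplicative in log space: violates the bridging assumption
            signal = base * (1.0 + off)
        log2v[:, col] = signal + rng.normal(0.0, config.noise_sd, size=config.n_genes)

    expr = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2v), index=pd.Index(genes, name="gene_id"),
                     columns=list(meta_df["instance_id"]))
    )
    pairs = pd.DataFrame(
        [(c, t) for c, ts in compound_targets.items() for t in sorted(ts)],
        columns=["compound_id", "target_id"], dtype=str,
    )
    dtm = DrugTargetMap(pairs)
    truth = SimTruth(
        batch_offsets=batch_offsets,
        module_effects=module_effects,
        compound_targets=compound_targets,
        drug_effects=drug_effects,
        tti_pairs=config.tti_pairs,
        warnings=warnings,
    )
    return expr, meta, dtm, truth


def scramble_labels(
    dtm: DrugTargetMap, seed: int, universe: list[str] | None = None
) -> DrugTargetMap:
    """Null-model control: permute ligand identities while preserving every
    target's ligand-set size.

    A random bijection is applied to the compound ids appearing in the map;
    when ``universe`` is given, the images are drawn from the whole compound
    universe instead, severing any residual link between annotation and
    expression."""
    rng = np.random.default_rng(seed)
    sources = sorted(set(dtm.pairs["compound_id"]))
    if universe is None:
        images = list(sources)
        rng.shuffle(images)
    else:
        universe = sorted(set(universe))
        if len(universe) < len(sources):
            raise ValueError("universe smaller than the set of annotated compounds")
        images = list(rng.choice(universe, size=len(sources), replace=False))
    mapping = dict(zip(sources, images))
    out = dtm.pairs.copy()
    out["compound_id"] = out["compound_id"].map(mapping)
    return DrugTargetMap(out)
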