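"""Synthetic class-imbalanced, zero-inflated compositional microbiome data.

The generator emulates the statistical shape of a two-cohort saliva 16S
species table: ~124 taxa dominated by a handful of species, zero-inflated
multinomial counts at log-normal sequencing depth, a 1:6 minority:majority
class split (current smokers vs. non-current smokers), a multiplicative
class effect planted on a subset of taxa (by default localized to one clade
so a phylogeny-aware augmenter has structure to exploit), and a random
rooted bifurcating tree over the taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo import PhyloTree
from .tables import SampleMetadata, TaxaTable

__all__ = ["SyntheticConfig", "generate_tree", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating distribution for a synthetic smoking-microbiome cohort.

    Defaults mirror the study conditions: 175 minority (current smoker) vs
    1,070 majority samples over 124 taxa. ``dominance`` power-skews the base
    composition so the top ~20 taxa carry >= 75% of the mass; ``effect_size``
    multiplies the minority-class mean abundance of ``effect_taxa`` taxa
    (1.0 = null data); ``within_class_concentration`` sets sample-to-sample
    Dirichlet variation; read depth is log-normal; ``dropout`` zeroes
    low-abundance taxa per (sample, taxon) to emulate sparsity.
    """

    n_minority: int = 175
    n_majority: int = 1070
    n_taxa: int = 124
    dominance: float = 3.0
    effect_taxa: int = 12
    effect_size: float = 3.0
    within_class_concentration: float = 50.0
    depth_lognormal: tuple[float, float] = (np.log(20_000.0), 0.5)
    dropout: float = 0.3
    clade_effect: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_minority, self.n_majority, self.n_taxa) < 1:
            raise ValueError("sample and taxon counts must be positive")
        if self.effect_taxa > self.n_taxa:
            raise ValueError("effect_taxa cannot exceed n_taxa")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be a probability")
        if self.effect_size <= 0 or self.dominance <= 0:
            raise ValueError("effect_size and dominance must be positive")
        if self.within_class_concentration <= 0:
            raise ValueError("within_class_concentration must be positive")


def _taxon_ids(n: int) -> list[str]:
    return [f"taxon_{i + 1:04d}" for i in range(n)]


def generate_tree(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    """Random rooted bifurcating tree by sequential random leaf attachment.

    Starts from a two-leaf cherry; each further leaf splits a uniformly
    chosen existing edge. Branch lengths are exponential with mean 0.1.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    labels = _taxon_ids(n_taxa)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    leaves = []
    for lbl in labels[:2]:
        nd = dendropy.Node(taxon=taxa.get_taxon(lbl))
        root.add_child(nd)
        leaves.append(nd)
    # nodes whose incoming edge can be split (everything below the root)
    attachable = list(leaves)
    for lbl in labels[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent_node
        mid = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(mid)
        mid.add_child(target)
        new_leaf = dendropy.Node(taxon=taxa.get_taxon(lbl))
        mid.add_child(new_leaf)
        attachable.extend([mid, new_leaf])
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(0.1))
    return PhyloTree(tree)


def _pick_effect_taxa(
    config: SyntheticConfig, tree: PhyloTree, taxon_ids: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """Column indices of the taxa carrying the class effect."""
    if config.effect_taxa == 0:
        return np.empty(0, dtype=int)
    if not config.clade_effect:
        return rng.choice(config.n_taxa, size=config.effect_taxa, replace=False)
    nodes = tree.indexed_nodes(list(taxon_ids))
    # clade whose leaf count is closest to effect_taxa (prefer >=)
    best, best_key = None, None
    for node in nodes:
        if not node.children:
            continue
        size = len(node.leaf_set)
        if size == config.n_taxa:
            continue  # skip the root clade
        key = (abs(size - config.effect_taxa), size < config.effect_taxa)
        if best_key is None or key < best_key:
            best, best_key = node, key
    leaf_set = np.sort(best.leaf_set)
    if len(leaf_set) > config.effect_taxa:
        leaf_set = rng.choice(leaf_set, size=config.effect_taxa, replace=False)
    return np.sort(leaf_set)


def class_mean_compositions(
    config: SyntheticConfig, tree: PhyloTree, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(majority_mean, minority_mean, effect_columns) of the generator.

    The base composition is a symmetric Dirichlet draw raised to the
    ``dominance`` power and renormalized; the minority mean additionally
    multiplies the effect taxa by ``effect_size`` and renormalizes.
    """
    base = rng.dirichlet(np.ones(config.n_taxa))
    base = base**config.dominance
    total = base.sum()
    if total <= 0 or (base / total).max() >= 1.0 - 1e-12:
        raise ValueError("degenerate base composition (all mass on one taxon)")
    base /= total
    effect_cols = _pick_effect_taxa(config, tree, _taxon_ids(config.n_taxa), rng)
    minority_mean = base.copy()
    minority_mean[effect_cols] *= config.effect_size
    minority_mean /= minority_mean.sum()
    return base, minority_mean, effect_cols


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[TaxaTable, SampleMetadata, PhyloTree]:
    """Draw a full synthetic cohort: count table, metadata, and tree.

    Per sample: composition ~ Dirichlet(concentration * class mean), depth ~
    LogNormal, counts ~ Multinomial(depth, composition); dropout then zeroes
    taxa below the median base abundance with the configured probability.
    Minority samples are labeled current smokers; the majority is split
    50/50 into never and former smokers.
    """
    rng = np.random.default_rng(config.seed)
    tree = generate_tree(config.n_taxa, rng)
    base, minority_mean, _ = class_mean_compositions(config, tree, rng)

    n_total = config.n_minority + config.n_majority
    is_minority = np.zeros(n_total, dtype=bool)
    is_minority[: config.n_minority] = True

    mu, sd = config.depth_lognormal
    depths = np.maximum(rng.lognormal(mu, sd, size=n_total).astype(int), config.n_taxa)
    counts = np.zeros((n_total, config.n_taxa), dtype=np.int64)
    conc = config.within_class_concentration
    for i in range(n_total):
        mean = minority_mean if is_minority[i] else base
        alpha = conc * mean
        comp = rng.dirichlet(alpha)
        if not np.isfinite(comp).all() or comp.sum() <= 0:
            comp = mean
        counts[i] = rng.multinomial(depths[i], comp)

    low = base < np.median(base)
    if config.dropout > 0 and low.any():
        drop = rng.uniform(size=(n_total, config.n_taxa)) < config.dropout
        counts[:, low] = np.where(drop[:, low], 0, counts[:, low])

    sample_ids = [f"sample_{i + 1:04d}" for i in range(n_total)]
    table = TaxaTable(
        pd.DataFrame(counts, index=sample_ids, columns=_taxon_ids(config.n_taxa)),
        normalized=False,
    )

    status = np.empty(n_total, dtype=object)
    status[is_minority] = "current"
    maj_ids = np.flatnonzero(~is_minority)
    n_never = len(maj_ids) // 2
    shuffled = rng.permutation(maj_ids)
    status[shuffled[:n_never]] = "never"
    status[shuffled[n_never:]] = "former"

    meta = pd.DataFrame(
        {
            "smoking_status": status,
            "sex": rng.choice(["female", "male"], size=n_total),
            "age_group": rng.choice(
                ["50-59", "60-69", "70-79"], size=n_total, p=[0.2, 0.5, 0.3]
            ),
            "ethnicity": rng.choice(
                ["European", "Non-European"], size=n_total, p=[0.87, 0.13]
            ),
            "study": rng.choice(["S1", "S2"], size=n_total, p=[0.87, 0.13]),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table, SampleMetadata(meta), tree
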