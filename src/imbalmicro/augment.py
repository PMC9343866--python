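"""Training-set augmentation schemes for class-imbalanced abundance data.

Five schemes are provided, all operating on the minority class only:

* ``smote_over`` / ``adasyn_over`` — interpolation-based over-sampling until
  the minority class equals the majority class.
* ``smote_combined`` / ``adasyn_combined`` — over-sampling to an intermediate
  target given by the ratio equation in :func:`combined_ratio`, then random
  under-sampling of the majority class to the same size.
* ``tada`` — a phylogeny-aware generative augmenter: each synthetic sample is
  drawn by pushing a pseudo-count mass down the rooted taxon tree, splitting
  at every internal node with a Dirichlet-multinomial whose mean is the
  source sample's observed clade proportions and whose concentration ``nu``
  controls how far synthetic samples stray from their source.

Augmentation must only ever see training data; fold handling lives in
:mod:`imbalmicro.evaluate` and enforces that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .phylo import PhyloTree

__all__ = [
    "SCHEMES",
    "GenerativeParams",
    "AugmentationPlan",
    "AugmentedSet",
    "combined_ratio",
    "smote_oversample",
    "adasyn_oversample",
    "random_undersample",
    "tada_augment",
    "apply_plan",
]

SCHEMES = (
    "none",
    "smote_combined",
    "smote_over",
    "adasyn_combined",
    "adasyn_over",
    "tada",
)

_COMBINED = {"smote_combined", "adasyn_combined"}
_OVER_ONLY = {"smote_over", "adasyn_over", "tada"}
_INTERPOLATING = {"smote_combined", "smote_over", "adasyn_combined", "adasyn_over"}


@dataclass(frozen=True)
class GenerativeParams:
    """Knobs of the tree-based generative augmenter.

    nu:
        Dirichlet concentration at each internal split. Large nu keeps
        synthetic samples close to their source composition; nu -> inf
        reproduces the source exactly (up to sampling depth).
    depth:
        Pseudo-depth D: relative abundances are converted to D working
        counts before the tree walk, and re-normalized afterwards.
    depth_source:
        "fixed" uses ``depth`` for every synthetic sample.
    branch_scaled_variance:
        If True, the concentration at a node is divided by the mean child
        branch length, so long-branch splits get noisier draws.
    """

    nu: float = 100.0
    depth: int = 10_000
    depth_source: str = "fixed"
    branch_scaled_variance: bool = False

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.depth < 1:
            raise ValueError("depth must be a positive integer")
        if self.depth_source not in ("fixed", "per_sample"):
            raise ValueError("depth_source must be 'fixed' or 'per_sample'")


@dataclass(frozen=True)
class AugmentationPlan:
    """Which scheme to run on a training split, and with what parameters."""

    scheme: str = "none"
    k_neighbors: int = 5
    over_ratio: float | str = "auto"
    under_ratio: float | str = "auto"
    tada_params: GenerativeParams = field(default_factory=GenerativeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        for name in ("over_ratio", "under_ratio"):
            v = getattr(self, name)
            if v != "auto" and not (0 < float(v) <= 1):
                raise ValueError(f"{name} must be 'auto' or in (0, 1]")

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "scheme": self.scheme,
            "k_neighbors": self.k_neighbors,
            "over_ratio": self.over_ratio,
            "under_ratio": self.under_ratio,
            "tada": {"nu": self.tada_params.nu, "depth": self.tada_params.depth},
            "seed": self.seed,
        }

    @classmethod
    def from_json_dict(cls, d: dict[str, Any]) -> "AugmentationPlan":
        tada = d.get("tada", {})
        return cls(
            scheme=d.get("scheme", "none"),
            k_neighbors=int(d.get("k_neighbors", 5)),
            over_ratio=d.get("over_ratio", "auto"),
            under_ratio=d.get("under_ratio", "auto"),
            tada_params=GenerativeParams(
                nu=float(tada.get("nu", 100.0)), depth=int(tada.get("depth", 10_000))
            ),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class AugmentedSet:
    """A training split after augmentation.

    ``origin`` flags each row as "original" or "synthetic"; synthetic rows sit
    after all originals and record the row indices (into the input matrix) of
    their parent sample(s).
    """

    features: np.ndarray
    labels: np.ndarray
    origin: np.ndarray  # array of "original"/"synthetic"
    parent_ids: list[tuple[int, ...] | None]
    plan: AugmentationPlan

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def combined_ratio(c_min: int, c_max: int) -> tuple[float, float]:
    """Over/under-sampling ratio equation for the combined schemes.

    With t = |c_min - c_max|, returns (|t - c_min| / c_max, (c_max - t) / c_min),
    interpreted as minority:majority target fractions. Algebraically the
    under-sampling ratio is always exactly 1 (c_max - t = c_min when
    c_min <= c_max); it is computed as written regardless.
    """
    if c_min <= 0:
        raise ValueError("no minority samples (c_min must be positive)")
    if c_max < c_min:
        raise ValueError("c_min must not exceed c_max")
    t = abs(c_min - c_max)
    over = abs(t - c_min) / c_max
    under = (c_max - t) / c_min
    return over, under


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _k_nearest(
    query: np.ndarray, pool: np.ndarray, k: int, exclude_self: bool
) -> np.ndarray:
    """Indices of the k nearest pool rows per query row.

    Ties broken by lower row index (stable argsort on squared distances).
    ``exclude_self`` assumes query is a prefix-aligned subset of pool, i.e.
    query row i equals pool row i.
    """
    d2 = _pairwise_sq_dists(query, pool)
    if exclude_self:
        for i in range(min(query.shape[0], pool.shape[0])):
            d2[i, i] = np.inf
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def _effective_k(k: int, n_minority: int) -> int:
    if n_minority < 2:
        raise ValueError("need at least 2 minority samples for interpolation")
    if n_minority <= k:
        warnings.warn(
            f"k_neighbors={k} >= minority size {n_minority}; reducing to "
            f"{n_minority - 1}",
            stacklevel=3,
        )
        return n_minority - 1
    return k


def _spread_allocation(n_new: int, n_sources: int, rng: np.random.Generator) -> np.ndarray:
    """Even per-source synthetic counts; remainder sources chosen by rng."""
    base, rem = divmod(n_new, n_sources)
    alloc = np.full(n_sources, base, dtype=int)
    if rem:
        extra = rng.choice(n_sources, size=rem, replace=False)
        alloc[extra] += 1
    return alloc


def _interpolate(
    minority: np.ndarray,
    alloc: np.ndarray,
    neighbors: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """SMOTE-style line interpolation given per-source allocations."""
    rows: list[np.ndarray] = []
    parents: list[tuple[int, int]] = []
    k = neighbors.shape[1]
    for i in range(minority.shape[0]):
        for _ in range(alloc[i]):
            j = int(neighbors[i, rng.integers(k)])
            u = rng.uniform()
            rows.append(minority[i] + u * (minority[j] - minority[i]))
            parents.append((i, j))
    if not rows:
        return np.empty((0, minority.shape[1])), []
    return np.vstack(rows), parents


def smote_oversample(
    minority: np.ndarray,
    n_new: int,
    k: int,
    rng: np.random.Generator,
    return_parents: bool = False,
):
    """Generate ``n_new`` synthetic minority rows by line interpolation.

    Each synthetic row is x + u (x_nn - x) for a source row x, one of its k
    nearest minority neighbors x_nn (Euclidean, ties to the lower index),
    and u uniform on [0, 1]. Generation is spread as evenly as possible
    across source rows, the remainder going to rng-chosen sources.
    """
    minority = np.asarray(minority, dtype=float)
    if n_new == 0:
        out = np.empty((0, minority.shape[1]))
        return (out, []) if return_parents else out
    k = _effective_k(k, minority.shape[0])
    neighbors = _k_nearest(minority, minority, k, exclude_self=True)
    alloc = _spread_allocation(n_new, minority.shape[0], rng)
    synth, parents = _interpolate(minority, alloc, neighbors, rng)
    return (synth, parents) if return_parents else synth


def adasyn_weights(
    minority: np.ndarray, majority: np.ndarray, k: int
) -> np.ndarray:
    """Per-minority-row hardness weights r_i.

    r_i is the fraction of majority members among the k nearest neighbors of
    minority row i in the pooled (minority + majority) set, self excluded.
    """
    pooled = np.vstack([minority, majority])
    neighbors = _k_nearest(minority, pooled, k, exclude_self=True)
    return (neighbors >= minority.shape[0]).sum(axis=1) / neighbors.shape[1]


def _largest_remainder(n_total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of n_total proportional to normalized weights."""
    shares = n_total * weights / weights.sum()
    alloc = np.floor(shares).astype(int)
    remainder = n_total - alloc.sum()
    if remainder:
        frac = shares - alloc
        # ties broken by lower index: stable sort on -frac
        order = np.argsort(-frac, kind="stable")
        alloc[order[:remainder]] += 1
    return alloc


def adasyn_oversample(
    minority: np.ndarray,
    majority: np.ndarray,
    n_new: int,
    k: int,
    rng: np.random.Generator,
    return_parents: bool = False,
):
    """ADASYN over-sampling: allocate more synthetics to harder minority rows.

    Falls back to plain SMOTE (with a warning) when no minority row has a
    majority neighbor, i.e. all density weights are zero.
    """
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    if majority.shape[0] == 0 or minority.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if n_new == 0:
        out = np.empty((0, minority.shape[1]))
        return (out, []) if return_parents else out
    k_eff = _effective_k(k, minority.shape[0])
    r = adasyn_weights(minority, majority, k)
    if r.sum() == 0:
        warnings.warn(
            "no majority samples near any minority sample; falling back to SMOTE",
            stacklevel=2,
        )
        return smote_oversample(minority, n_new, k, rng, return_parents=return_parents)
    alloc = _largest_remainder(n_new, r)
    neighbors = _k_nearest(minority, minority, k_eff, exclude_self=True)
    synth, parents = _interpolate(minority, alloc, neighbors, rng)
    return (synth, parents) if return_parents else synth


def random_undersample(
    majority: np.ndarray, n_keep: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of majority rows without replacement, order preserved."""
    majority = np.asarray(majority)
    n = majority.shape[0]
    if not 1 <= n_keep <= n:
        raise ValueError(f"n_keep must be in [1, {n}], got {n_keep}")
    kept = np.sort(rng.choice(n, size=n_keep, replace=False))
    return majority[kept], kept


def tada_augment(
    minority: np.ndarray,
    tree: PhyloTree,
    n_new: int,
    params: GenerativeParams,
    rng: np.random.Generator,
    taxon_ids: Sequence[str] | None = None,
    return_parents: bool = False,
    return_trace: bool = False,
):
    """Phylogeny-aware generative over-sampling of compositional rows.

    For each synthetic sample a source row is chosen (even spread across
    sources); its composition is pushed down the rooted tree as ``depth``
    pseudo-counts. At each internal node the node's count is divided among
    the children by a Dirichlet draw with mean equal to the source row's
    observed clade proportions and concentration ``nu`` (for a binary node
    this is a Beta(nu*p, nu*(1-p)) split), then integer counts are assigned
    multinomially given the draw — so child counts always sum exactly to the
    parent count, and clades the source row lacks stay at zero. Leaf counts
    are finally re-normalized to a composition.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.shape[0] == 0:
        raise ValueError("minority class is empty")
    if taxon_ids is None:
        taxon_ids = tree.leaf_labels
    if len(taxon_ids) != minority.shape[1]:
        raise ValueError(
            f"matrix has {minority.shape[1]} columns but {len(taxon_ids)} taxon ids"
        )
    if params.depth < len(taxon_ids):
        raise ValueError("pseudo-depth must be at least the number of taxa")
    nodes = tree.indexed_nodes(list(taxon_ids))
    n_taxa = minority.shape[1]
    if n_new == 0:
        out = np.empty((0, n_taxa))
        if return_trace:
            return (out, [], []) if return_parents else (out, [])
        return (out, []) if return_parents else out

    alloc = _spread_allocation(n_new, minority.shape[0], rng)
    counts = np.zeros((n_new, n_taxa), dtype=np.int64)
    parents: list[tuple[int]] = []
    trace: list[dict] = []
    row_of: list[int] = []
    for i in np.flatnonzero(alloc):
        row_of.extend([i] * alloc[i])
        parents.extend([(int(i),)] * alloc[i])
    row_of_arr = np.asarray(row_of, dtype=int)

    # group synthetic samples by source row so Dirichlet draws vectorize
    for src in np.unique(row_of_arr):
        mask = row_of_arr == src
        n_s = int(mask.sum())
        total = minority[src].sum()
        if total <= 0:
            raise ValueError(f"minority row {src} has zero total abundance")
        p = minority[src] / total
        node_counts: dict[int, np.ndarray] = {0: np.full(n_s, params.depth, dtype=np.int64)}
        for idx, node in enumerate(nodes):
            cnt = node_counts.pop(idx, None)
            if cnt is None:
                continue
            if not node.children:
                counts[mask, node.leaf_index] = cnt
                continue
            clade_mass = np.array([p[nodes[c].leaf_set].sum() for c in node.children])
            m = clade_mass.sum()
            if m <= 0 or cnt.max() == 0:
                # no source mass in this clade: all descendants stay zero
                for c in node.children:
                    node_counts[c] = np.zeros(n_s, dtype=np.int64)
                continue
            probs = clade_mass / m
            pos = probs > 0
            nu = params.nu
            if params.branch_scaled_variance:
                mean_bl = float(
                    np.mean([max(nodes[c].branch_length, 0.0) for c in node.children])
                )
                nu = nu / max(mean_bl, 1e-9)
            if pos.sum() == 1:
                w = np.tile(pos.astype(float), (n_s, 1))
            else:
                w = np.zeros((n_s, len(node.children)))
                draws = rng.dirichlet(nu * probs[pos], size=n_s)
                # tiny alphas can underflow every gamma variate to zero
                bad = ~np.isfinite(draws).all(axis=1)
                if bad.any():
                    draws[bad] = probs[pos]
                w[:, pos] = draws
            child_counts = rng.multinomial(cnt, w)
            if return_trace:
                trace.append(
                    {"node": idx, "parent": cnt.copy(), "children": child_counts.copy()}
                )
            for j, c in enumerate(node.children):
                node_counts[c] = child_counts[:, j]

    synth = counts / counts.sum(axis=1, keepdims=True)
    if return_trace:
        return (synth, parents, trace) if return_parents else (synth, trace)
    return (synth, parents) if return_parents else synth


def _resolve_targets(
    scheme: str,
    c_min: int,
    c_max: int,
    over_ratio: float | str,
    under_ratio: float | str,
) -> tuple[int, int]:
    """Final (minority, majority) class sizes for a scheme."""
    if scheme == "none":
        return c_min, c_max
    if scheme in _OVER_ONLY:
        return c_max, c_max
    over, under = combined_ratio(c_min, c_max)
    if over_ratio != "auto":
        over = float(over_ratio)
    if under_ratio != "auto":
        under = float(under_ratio)
    target_min = max(c_min, int(np.floor(over * c_max + 0.5)))
    # under_ratio is the final minority:majority fraction; the printed
    # equation gives exactly 1, i.e. equalized classes
    target_maj = min(c_max, int(np.floor(target_min / under + 0.5)))
    return target_min, target_maj


def apply_plan(
    features: np.ndarray,
    labels: np.ndarray,
    plan: AugmentationPlan,
    tree: PhyloTree | None = None,
    taxon_ids: Sequence[str] | None = None,
) -> AugmentedSet:
    """Run an augmentation plan on a (training) feature matrix.

    Returns the original rows (majority possibly under-sampled, in input
    order) followed by the synthetic minority rows. Scheme "none" is a
    passthrough.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if plan.scheme == "tada" and tree is None:
        raise ValueError("scheme 'tada' requires a phylogenetic tree")

    rng = np.random.default_rng(plan.seed)
    order = np.argsort(class_counts, kind="stable")
    minority_label, majority_label = classes[order[0]], classes[order[1]]
    c_min, c_max = int(class_counts[order[0]]), int(class_counts[order[1]])
    min_idx = np.flatnonzero(labels == minority_label)
    maj_idx = np.flatnonzero(labels == majority_label)
    minority = features[min_idx]
    majority = features[maj_idx]

    target_min, target_maj = _resolve_targets(
        plan.scheme, c_min, c_max, plan.over_ratio, plan.under_ratio
    )
    n_new = target_min - c_min

    if plan.scheme == "none":
        synth = np.empty((0, features.shape[1]))
        parents: list[tuple[int, ...]] = []
        kept_maj = np.arange(len(maj_idx))
    else:
        if plan.scheme in _INTERPOLATING and c_min < 2:
            raise ValueError("interpolation schemes need >= 2 minority samples")
        if plan.scheme.startswith("smote"):
            synth, parents = smote_oversample(
                minority, n_new, plan.k_neighbors, rng, return_parents=True
            )
        elif plan.scheme.startswith("adasyn"):
            synth, parents = adasyn_oversample(
                minority, majority, n_new, plan.k_neighbors, rng, return_parents=True
            )
        else:  # tada
            synth, parents = tada_augment(
                minority,
                tree,
                n_new,
                plan.tada_params,
                rng,
                taxon_ids=taxon_ids,
                return_parents=True,
            )
        if target_maj < c_max:
            _, kept_maj = random_undersample(majority, target_maj, rng)
        else:
            kept_maj = np.arange(len(maj_idx))

    # originals in input order (minority rows all kept, majority filtered)
    keep_mask = np.zeros(len(labels), dtype=bool)
    keep_mask[min_idx] = True
    keep_mask[maj_idx[kept_maj]] = True
    orig_rows = np.flatnonzero(keep_mask)

    out_features = np.vstack([features[orig_rows], synth]) if len(synth) else features[orig_rows].copy()
    out_labels = np.concatenate(
        [labels[orig_rows], np.full(len(synth), minority_label, dtype=labels.dtype)]
    )
    origin = np.array(["original"] * len(orig_rows) + ["synthetic"] * len(synth))
    parent_ids: list[tuple[int, ...] | None] = [None] * len(orig_rows)
    # map parents from minority-local indices to input row indices
    for par in parents:
        parent_ids.append(tuple(int(min_idx[j]) for j in par))

    out = AugmentedSet(out_features, out_labels, origin, parent_ids, plan)
    got = out.class_counts()
    if got[int(minority_label)] != target_min or got[int(majority_label)] != target_maj:
        raise AssertionError(
            f"class-balance contract violated: got {got}, "
            f"wanted {{min: {target_min}, maj: {target_maj}}}"
        )
    return out
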