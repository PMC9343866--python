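"""Metrics, leakage-safe nested cross-validation, and final-model training.

The evaluation layout is a 5x2 nested cross-validation repeated 10 times:
per repeat, a stratified 80/20 split reserves a holdout; the 80% training
set is split into 5 stratified outer folds; each outer-training fold is
split 50/50 into two inner folds on which hyperparameters are chosen by
randomized search maximizing mean validation MCC. Augmentation is applied
independently to every *training* portion (each inner-training half and the
outer-training fold) and never to validation, outer-test, or holdout data.

The confusion-matrix positive class is the smoker (label 0, the minority
class); AUC scores are oriented to smoker probability.
"""

from __future__ import annotations

import json
import logging
import pickle
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationPlan, AugmentedSet, apply_plan
from .classifiers import POSITIVE_LABEL, ClassifierSpec, FittedBackend
from .phylo import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "FoldScheme",
    "CVResult",
    "mcc",
    "auc",
    "confusion_from_predictions",
    "stratified_split",
    "stratified_kfold",
    "random_search",
    "nested_cv",
    "train_final_and_holdout",
    "ModelArtifact",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the smoker (label 0) as positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, positive: int = POSITIVE_LABEL
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); if any factor of
    the denominator is zero the coefficient is defined as 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = (float(cm.tp), float(cm.tn), float(cm.fp), float(cm.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def auc(labels: np.ndarray, scores: np.ndarray, positive: int = POSITIVE_LABEL) -> float:
    """Rank-based ROC AUC: U / (n_pos * n_neg), ties credited 0.5.

    ``scores`` must be oriented so larger means more positive-like.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties at 0.5 credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _derive_rng(master_seed: int, *tokens: Any) -> np.random.Generator:
    """Counter-based child stream: stable under adding plans or specs."""
    entropy = [master_seed & 0x7FFFFFFF] + [
        zlib.crc32(str(t).encode()) for t in tokens
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _derive_int(master_seed: int, *tokens: Any) -> int:
    return int(_derive_rng(master_seed, *tokens).integers(2**31 - 1))


def stratified_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two-way stratified split; part A receives floor(fraction * class size)
    per class plus any leftover sample, assignment uniform within class."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("stratified split needs two classes")
    part_a, part_b = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        n = len(idx)
        # epsilon guards float noise (e.g. 0.2 * 175 = 34.999...)
        n_a = int(np.floor(fraction * n + 1e-9))
        n_b = int(np.floor((1 - fraction) * n + 1e-9))
        n_a += n - n_a - n_b  # leftover sample goes to part A
        if n_a == 0 or n_b == 0:
            raise ValueError(
                f"class {c!r} would have an empty partition (n={n}, fraction={fraction})"
            )
        perm = rng.permutation(idx)
        part_a.append(perm[:n_a])
        part_b.append(perm[n_a:])
    return np.sort(np.concatenate(part_a)), np.sort(np.concatenate(part_b))


def stratified_kfold(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index partition into k stratified folds (returned as test sets)."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    for f, members in enumerate(folds):
        if not members:
            raise ValueError(f"fold {f} is empty; too few samples for k={k}")
    return [np.sort(np.array(members, dtype=int)) for members in folds]


@dataclass(frozen=True)
class FoldScheme:
    """5x2 nested-CV layout with 10 repeats over an 80/20 stratified split."""

    outer_k: int = 5
    inner_n: int = 2
    repeats: int = 10
    train_fraction: float = 0.8
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_n != 2 or self.repeats < 1:
            raise ValueError("need outer_k >= 2, inner_n == 2, repeats >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class CVResult:
    """Tidy per-fold records plus fold-membership manifests.

    ``records`` columns: data_type, classifier, repeat, fold, mcc, auc,
    hyperparameters_json, failed. ``manifests`` maps
    ("test", repeat, fold) -> original sample ids of the outer test fold and
    ("train", repeat, fold, data_type) -> ids of the augmented training fold
    (synthetic rows carry "syn_<i>" ids). ``class_counts`` records pre/post
    augmentation counts per training fold.
    """

    records: pd.DataFrame
    manifests: dict[tuple, list[str]] = field(default_factory=dict)
    class_counts: dict[tuple, dict[str, dict[int, int]]] = field(default_factory=dict)

    def mean_metric(self, metric: str = "mcc") -> pd.DataFrame:
        ok = self.records[~self.records["failed"]]
        return ok.groupby(["data_type", "classifier"])[metric].agg(["mean", "std", "count"])

    def metric_values(self, data_type: str, classifier: str, metric: str = "mcc") -> np.ndarray:
        r = self.records
        sel = r[(r.data_type == data_type) & (r.classifier == classifier) & (~r.failed)]
        return sel[metric].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        df = self.records.copy()
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def manifests_to_json(self, path: str | Path) -> None:
        ser = {"|".join(str(p) for p in key): ids for key, ids in self.manifests.items()}
        Path(path).write_text(json.dumps(ser, indent=1, sort_keys=True), encoding="utf-8")


def _augmented_ids(aset: AugmentedSet, base_ids: Sequence[str]) -> list[str]:
    syn = 0
    out = []
    for i, o in enumerate(aset.origin):
        if o == "original":
            out.append(str(base_ids[i]))
        else:
            out.append(f"syn_{syn:05d}")
            syn += 1
    return out


def random_search(
    spec: ClassifierSpec,
    inner_sets: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    rng: np.random.Generator,
) -> dict[str, Any]:
    """Randomized hyperparameter search maximizing mean inner-validation MCC.

    ``inner_sets`` holds (X_train_augmented, y_train_augmented, X_val, y_val)
    tuples; ties are broken in favor of the first-sampled configuration. A
    backend failure scores that configuration at -inf.
    """
    best_params: dict[str, Any] | None = None
    best_score = -np.inf
    for it in range(spec.n_search_iterations):
        params = spec.sample_params(rng)
        fit_seed = int(rng.integers(2**31 - 1))
        scores = []
        try:
            for X_tr, y_tr, X_val, y_val in inner_sets:
                model = spec.fit(X_tr, y_tr, params, fit_seed)
                cm = confusion_from_predictions(y_val, model.predict(X_val))
                scores.append(mcc(cm))
            score = float(np.mean(scores))
        except Exception as exc:  # noqa: BLE001 - backend failures are scored, not fatal
            logger.error("search iteration %d for %s failed: %s", it, spec.name, exc)
            score = -np.inf
        if score > best_score:
            best_score, best_params = score, params
    if best_params is None:
        raise RuntimeError(f"every search configuration failed for {spec.name}")
    return best_params


def _augment_fold(
    X: np.ndarray,
    y: np.ndarray,
    plan: AugmentationPlan,
    seed: int,
    tree: PhyloTree | None,
    taxon_ids: Sequence[str] | None,
) -> AugmentedSet:
    seeded = AugmentationPlan(
        scheme=plan.scheme,
        k_neighbors=plan.k_neighbors,
        over_ratio=plan.over_ratio,
        under_ratio=plan.under_ratio,
        tada_params=plan.tada_params,
        seed=seed,
    )
    return apply_plan(X, y, seeded, tree=tree, taxon_ids=taxon_ids)


def nested_cv(
    features: np.ndarray,
    labels: np.ndarray,
    plans: Sequence[AugmentationPlan],
    specs: Sequence[ClassifierSpec],
    scheme: FoldScheme,
    tree: PhyloTree | None = None,
    taxon_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CVResult:
    """Run the full nested cross-validation over plans x classifier specs.

    Produces repeats x outer_k (mcc, auc) records per (plan, spec). Each
    repeat re-randomizes the entire chain, including the 80/20 split whose
    20% holdout is untouched here (it belongs to the final-model stage).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    ids = [str(s) for s in sample_ids] if sample_ids is not None else [f"s{i:05d}" for i in range(n)]
    names = [p.scheme for p in plans]
    if len(set(names)) != len(names):
        raise ValueError("plans must have distinct schemes")

    rows: list[dict[str, Any]] = []
    manifests: dict[tuple, list[str]] = {}
    class_counts: dict[tuple, dict[str, dict[int, int]]] = {}
    ms = scheme.master_seed

    for rep in range(scheme.repeats):
        train_idx, _holdout = stratified_split(
            y, scheme.train_fraction, _derive_rng(ms, "holdout", rep)
        )
        fold_tests = stratified_kfold(
            y[train_idx], scheme.outer_k, _derive_rng(ms, "outer", rep)
        )
        for f, test_local in enumerate(fold_tests):
            test_idx = train_idx[test_local]
            mask = np.ones(len(train_idx), dtype=bool)
            mask[test_local] = False
            outer_train = train_idx[mask]
            half_a_loc, half_b_loc = stratified_split(
                y[outer_train], 0.5, _derive_rng(ms, "inner", rep, f)
            )
            halves = (outer_train[half_a_loc], outer_train[half_b_loc])
            manifests[("test", rep, f)] = [ids[i] for i in test_idx]

            for plan in plans:
                aug_seed = _derive_int(ms, "augment", rep, f, plan.scheme)
                try:
                    aug_outer = _augment_fold(
                        X[outer_train], y[outer_train], plan, aug_seed, tree, taxon_ids
                    )
                    inner_sets = []
                    for h, (tr_h, val_h) in enumerate(
                        ((halves[0], halves[1]), (halves[1], halves[0]))
                    ):
                        aug_h = _augment_fold(
                            X[tr_h], y[tr_h], plan, aug_seed + h + 1, tree, taxon_ids
                        )
                        inner_sets.append(
                            (aug_h.features, aug_h.labels, X[val_h], y[val_h])
                        )
                except Exception as exc:  # noqa: BLE001 - fold failure is recorded
                    logger.error(
                        "augmentation %s failed in repeat %d fold %d: %s",
                        plan.scheme, rep, f, exc,
                    )
                    for spec in specs:
                        rows.append(
                            {
                                "data_type": plan.scheme,
                                "classifier": spec.name,
                                "repeat": rep,
                                "fold": f,
                                "mcc": np.nan,
                                "auc": np.nan,
                                "hyperparameters_json": "",
                                "failed": True,
                            }
                        )
                    continue

                outer_ids = [ids[i] for i in outer_train]
                manifests[("train", rep, f, plan.scheme)] = _augmented_ids(
                    aug_outer, outer_ids
                )
                vals, cnts = np.unique(y[outer_train], return_counts=True)
                class_counts[(rep, f, plan.scheme)] = {
                    "pre": {int(v): int(c) for v, c in zip(vals, cnts)},
                    "post": aug_outer.class_counts(),
                }
                logger.info(
                    "repeat %d fold %d plan %s: class counts %s -> %s",
                    rep, f, plan.scheme,
                    class_counts[(rep, f, plan.scheme)]["pre"],
                    class_counts[(rep, f, plan.scheme)]["post"],
                )

                for spec in specs:
                    rng_search = _derive_rng(ms, "search", rep, f, plan.scheme, spec.name)
                    row = {
                        "data_type": plan.scheme,
                        "classifier": spec.name,
                        "repeat": rep,
                        "fold": f,
                        "mcc": np.nan,
                        "auc": np.nan,
                        "hyperparameters_json": "",
                        "failed": True,
                    }
                    try:
                        params = random_search(spec, inner_sets, rng_search)
                        fit_seed = _derive_int(ms, "fit", rep, f, plan.scheme, spec.name)
                        model = spec.fit(
                            aug_outer.features, aug_outer.labels, params, fit_seed
                        )
                        y_pred = model.predict(X[test_idx])
                        scores = model.score_positive(X[test_idx])
                        cm = confusion_from_predictions(y[test_idx], y_pred)
                        row.update(
                            mcc=mcc(cm),
                            auc=auc(y[test_idx], scores),
                            hyperparameters_json=json.dumps(params, sort_keys=True, default=str),
                            failed=False,
                        )
                    except Exception as exc:  # noqa: BLE001
                        logger.error(
                            "backend %s failed in repeat %d fold %d plan %s: %s",
                            spec.name, rep, f, plan.scheme, exc,
                        )
                    rows.append(row)

    records = pd.DataFrame(rows)
    return CVResult(records=records, manifests=manifests, class_counts=class_counts)


@dataclass
class ModelArtifact:
    """Final fitted model plus the metadata needed to reproduce it."""

    backend: FittedBackend
    plan_json: dict[str, Any]
    classifier: str
    hyperparameters: dict[str, Any]
    master_seed: int
    holdout_mcc: float
    holdout_auc: float

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "plan": self.plan_json,
            "classifier": self.classifier,
            "hyperparameters": {k: str(v) for k, v in self.hyperparameters.items()},
            "master_seed": self.master_seed,
            "holdout_mcc": self.holdout_mcc,
            "holdout_auc": self.holdout_auc,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True), encoding="utf-8"
        )

    @staticmethod
    def load(path: str | Path) -> "ModelArtifact":
        with Path(path).open("rb") as fh:
            return pickle.load(fh)


def train_final_and_holdout(
    features: np.ndarray,
    labels: np.ndarray,
    plan: AugmentationPlan,
    spec: ClassifierSpec,
    scheme: FoldScheme,
    tree: PhyloTree | None = None,
    taxon_ids: Sequence[str] | None = None,
) -> ModelArtifact:
    """Train the selected (plan, classifier) on the 80% split, score the 20%.

    Hyperparameters are re-tuned by randomized search over a stratified
    50/50 inner split of the 80% (training halves augmented, validation
    halves untouched); the winning configuration is refit on the augmented
    80% and evaluated once on the pristine 20% holdout.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    ms = scheme.master_seed
    train_idx, hold_idx = stratified_split(
        y, scheme.train_fraction, _derive_rng(ms, "final-holdout")
    )
    if len(np.unique(y[hold_idx])) < 2:
        raise ValueError("holdout fold is missing a class")
    half_a, half_b = stratified_split(y[train_idx], 0.5, _derive_rng(ms, "final-inner"))
    halves = (train_idx[half_a], train_idx[half_b])
    aug_seed = _derive_int(ms, "final-augment", plan.scheme)
    inner_sets = []
    for h, (tr_h, val_h) in enumerate(((halves[0], halves[1]), (halves[1], halves[0]))):
        aug_h = _augment_fold(X[tr_h], y[tr_h], plan, aug_seed + h + 1, tree, taxon_ids)
        inner_sets.append((aug_h.features, aug_h.labels, X[val_h], y[val_h]))
    params = random_search(spec, inner_sets, _derive_rng(ms, "final-search", spec.name))
    aug_train = _augment_fold(X[train_idx], y[train_idx], plan, aug_seed, tree, taxon_ids)
    model = spec.fit(
        aug_train.features, aug_train.labels, params,
        _derive_int(ms, "final-fit", plan.scheme, spec.name),
    )
    y_pred = model.predict(X[hold_idx])
    scores = model.score_positive(X[hold_idx])
    cm = confusion_from_predictions(y[hold_idx], y_pred)
    return ModelArtifact(
        backend=model,
        plan_json=plan.to_json_dict(),
        classifier=spec.name,
        hyperparameters=params,
        master_seed=ms,
        holdout_mcc=mcc(cm),
        holdout_auc=auc(y[hold_idx], scores),
    )
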