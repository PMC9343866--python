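"""End-to-end workflow orchestration: simulate/ingest -> preprocess ->
nested CV over data types x classifiers -> comparison -> final model.

A run is driven by a validated configuration (YAML-friendly nested dict);
every stage writes its artifacts under the output directory together with a
run manifest (config hash, master seed, package versions, per-stage wall
time) sufficient to regenerate the outputs. All randomness flows from the
single ``master_seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .augment import SCHEMES, AugmentationPlan, GenerativeParams
from .classifiers import CLASSIFIER_NAMES, default_specs
from .compare import compare_data_types
from .evaluate import FoldScheme, nested_cv, train_final_and_holdout
from .phylo import PhyloTree
from .synthetic import SyntheticConfig, generate_dataset
from .tables import (
    BinaryLabels,
    SampleMetadata,
    TaxaTable,
    binarize_smoking,
    filter_low_abundance,
    filter_low_coverage,
    intersect_taxa,
    read_metadata_tsv,
    read_taxa_tsv,
    tss_normalize,
    write_metadata_tsv,
    write_taxa_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "preprocess"]

_TOP_KEYS = {
    "inputs", "simulate", "preprocess", "plans", "classifiers", "folds",
    "n_search_iterations", "master_seed", "final", "out_dir",
}
_INPUT_KEYS = {"table", "table_b", "metadata", "tree"}
_PRE_KEYS = {"min_reads", "abundance_threshold", "renormalize_after_intersect"}
_FOLD_KEYS = {"outer_k", "inner_n", "repeats", "train_fraction"}
_FINAL_KEYS = {"plan", "classifier"}
_SIM_KEYS = {f.name for f in __import__("dataclasses").fields(SyntheticConfig)}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``inputs`` (taxa TSV, metadata TSV, Newick tree paths) or
    ``simulate`` (synthetic-generator settings) supplies the data. Defaults
    run the full study grid: six data types, seven classifiers, 5x2 nested
    CV with 10 repeats.
    """

    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    preprocess: dict[str, Any] = field(
        default_factory=lambda: {
            "min_reads": 1000,
            "abundance_threshold": 1e-4,
            "renormalize_after_intersect": True,
        }
    )
    plans: list[str] = field(default_factory=lambda: list(SCHEMES))
    classifiers: list[str] = field(default_factory=lambda: list(CLASSIFIER_NAMES))
    folds: dict[str, Any] = field(
        default_factory=lambda: {
            "outer_k": 5, "inner_n": 2, "repeats": 10, "train_fraction": 0.8,
        }
    )
    n_search_iterations: int = 30
    master_seed: int = 0
    final: dict[str, str] = field(
        default_factory=lambda: {"plan": "auto", "classifier": "auto"}
    )
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        cfg = cls(**{k: v for k, v in raw.items() if k in _TOP_KEYS})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.inputs is not None:
            _check_keys(self.inputs, _INPUT_KEYS, "inputs")
            for req in ("table", "metadata"):
                if req not in self.inputs:
                    raise ValueError(f"inputs requires '{req}'")
        if self.simulate is not None:
            _check_keys(self.simulate, _SIM_KEYS, "simulate")
        if self.inputs is None and self.simulate is None:
            self.simulate = {}
        _check_keys(self.preprocess, _PRE_KEYS, "preprocess")
        _check_keys(self.folds, _FOLD_KEYS, "folds")
        _check_keys(self.final, _FINAL_KEYS, "final")
        bad = [p for p in self.plans if p not in SCHEMES]
        if bad:
            raise ValueError(f"unknown plan scheme(s): {bad}; choose from {SCHEMES}")
        bad = [c for c in self.classifiers if c not in CLASSIFIER_NAMES]
        if bad:
            raise ValueError(
                f"unknown classifier name(s): {bad}; choose from {CLASSIFIER_NAMES}"
            )
        if self.n_search_iterations < 1:
            raise ValueError("n_search_iterations must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def fold_scheme(self) -> FoldScheme:
        return FoldScheme(master_seed=self.master_seed, **self.folds)

    def plan_objects(self) -> list[AugmentationPlan]:
        return [
            AugmentationPlan(scheme=s, seed=self.master_seed, tada_params=GenerativeParams())
            for s in self.plans
        ]


def preprocess(
    table: TaxaTable,
    meta: SampleMetadata,
    table_b: TaxaTable | None = None,
    min_reads: int = 1000,
    abundance_threshold: float = 1e-4,
    renormalize_after_intersect: bool = True,
) -> tuple[TaxaTable, BinaryLabels]:
    """Coverage filter -> TSS -> abundance filter (-> intersect) -> renormalize.

    With a second table the two are restricted to their shared taxa after
    per-table filtering, mirroring a cross-cohort taxon intersection; rows
    are re-normalized at the end so classifiers see proper compositions
    (switchable via ``renormalize_after_intersect``).
    """

    def _filtered(t: TaxaTable) -> TaxaTable:
        t = filter_low_coverage(t, min_reads=min_reads)
        t = tss_normalize(t)
        return filter_low_abundance(t, threshold=abundance_threshold)

    a = _filtered(table)
    if table_b is not None:
        b = _filtered(table_b)
        a, b = intersect_taxa(a, b)
        merged = pd.concat([a.data, b.data], axis=0)
        if merged.index.has_duplicates:
            raise ValueError("sample ids overlap between the two tables")
        a = TaxaTable(merged, normalized=False)
    if renormalize_after_intersect:
        a = tss_normalize(a)
    labels = binarize_smoking(meta)
    labels = BinaryLabels(labels.labels.loc[a.sample_ids])
    return a, labels


def _write_failed_marker(out: Path, stage: str, exc: Exception) -> None:
    (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns a summary dict (also written as JSON).

    On stage failure a FAILED marker naming the stage is left next to any
    partial artifacts and the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "versions": {"imbalmicro": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    stage = "simulate/ingest"
    try:
        t0 = time.perf_counter()
        if config.inputs is not None:
            table = read_taxa_tsv(config.inputs["table"])
            meta = read_metadata_tsv(config.inputs["metadata"])
            table_b = (
                read_taxa_tsv(config.inputs["table_b"])
                if "table_b" in config.inputs else None
            )
            tree = (
                PhyloTree.from_newick(config.inputs["tree"])
                if "tree" in config.inputs else None
            )
        else:
            sim = SyntheticConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.master_seed)})
            table, meta, tree = generate_dataset(sim)
            table_b = None
            write_taxa_tsv(table, out / "simulated_taxa.tsv")
            write_metadata_tsv(meta, out / "simulated_metadata.tsv")
            tree.write_newick(out / "simulated_tree.nwk")
            (out / "simulated_config.json").write_text(
                json.dumps(asdict(sim), sort_keys=True, indent=1), encoding="utf-8"
            )
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "preprocess"
        t0 = time.perf_counter()
        prepped, labels = preprocess(table, meta, table_b=table_b, **config.preprocess)
        if tree is not None:
            tree = tree.prune_to(prepped.taxon_ids)
        counts = labels.class_counts()
        if len(counts) < 2:
            raise ValueError(f"single-class labels after preprocessing: {counts}")
        write_taxa_tsv(prepped, out / "preprocessed_taxa.tsv")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
        manifest["class_counts"] = counts

        stage = "nested_cv"
        t0 = time.perf_counter()
        specs = default_specs(config.classifiers, config.n_search_iterations)
        needs_tree = "tada" in config.plans
        if needs_tree and tree is None:
            raise ValueError("plan 'tada' requires a tree input")
        result = nested_cv(
            prepped.values,
            labels.to_array(),
            config.plan_objects(),
            specs,
            config.fold_scheme(),
            tree=tree,
            taxon_ids=prepped.taxon_ids,
            sample_ids=prepped.sample_ids,
        )
        result.to_tsv(out / "cv_records.tsv")
        result.manifests_to_json(out / "cv_fold_manifests.json")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "compare"
        t0 = time.perf_counter()
        for metric in ("mcc", "auc"):
            report = compare_data_types(result, metric=metric)
            report.write(out)
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "final"
        t0 = time.perf_counter()
        means = result.mean_metric("mcc")["mean"]
        plan_name, clf_name = config.final["plan"], config.final["classifier"]
        if plan_name == "auto" or clf_name == "auto":
            best_dt, best_clf = means.idxmax()
            plan_name = best_dt if plan_name == "auto" else plan_name
            clf_name = best_clf if clf_name == "auto" else clf_name
        plan = next(p for p in config.plan_objects() if p.scheme == plan_name)
        spec = default_specs([clf_name], config.n_search_iterations)[0]
        artifact = train_final_and_holdout(
            prepped.values, labels.to_array(), plan, spec, config.fold_scheme(),
            tree=tree, taxon_ids=prepped.taxon_ids,
        )
        artifact.save(out / "final_model.pkl")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)
        manifest["final"] = {
            "plan": plan_name,
            "classifier": clf_name,
            "holdout_mcc": artifact.holdout_mcc,
            "holdout_auc": artifact.holdout_auc,
            "ncv_mean_mcc": float(means.loc[(plan_name, clf_name)]),
        }
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        _write_failed_marker(out, stage, exc)
        raise

    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str), encoding="utf-8"
    )
    return manifest
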