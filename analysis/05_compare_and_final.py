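"""Statistical comparison of data types and final-model holdout validation.

From the nested-CV records of 03: per-classifier Kruskal-Wallis omnibus,
BH-corrected pairwise Wilcoxon matrix, per-data-type summaries and percent
change vs the non-augmented baseline. Then trains the final model (TADA +
SVML, mirroring the study's choice) on the 80% split and validates once on
the untouched 20% holdout.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from imbalmicro.augment import AugmentationPlan
from imbalmicro.classifiers import default_specs
from imbalmicro.compare import compare_data_types
from imbalmicro.evaluate import CVResult, FoldScheme, train_final_and_holdout
from imbalmicro.phylo import PhyloTree
from imbalmicro.tables import read_taxa_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results"))
    ap.add_argument("--tree", type=Path, default=Path("results/data/tree.nwk"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--plan", default="tada")
    ap.add_argument("--classifier", default="SVML")
    args = ap.parse_args()
    logging.basicConfig(level=logging.WARNING)

    records = pd.read_csv(args.data / "cv_records.tsv", sep="\t")
    result = CVResult(records=records)
    for metric in ("mcc", "auc"):
        report = compare_data_types(result, metric=metric)
        report.write(args.out)
        if metric == "mcc":
            print(report.summary.round(3).to_string(index=False))
            print("\npercent change vs baseline (pooled augmented):")
            print(report.percent_increase.round(1).to_string(index=False))
    report.boxplot(args.out / "comparison_boxplot.png", records[~records.failed])

    prepped = read_taxa_tsv(args.data / "preprocessed_taxa.tsv", normalized=True)
    labels = pd.read_csv(args.data / "labels.tsv", sep="\t", index_col=0)["label"]
    tree = PhyloTree.from_newick(args.tree).prune_to(prepped.taxon_ids)
    artifact = train_final_and_holdout(
        prepped.values, labels.loc[prepped.sample_ids].to_numpy(),
        AugmentationPlan(scheme=args.plan),
        default_specs([args.classifier], 10)[0],
        FoldScheme(repeats=2, master_seed=args.seed),
        tree=tree, taxon_ids=prepped.taxon_ids,
    )
    artifact.save(args.out / "final_model.pkl")
    print(
        f"\nfinal model ({args.plan} + {args.classifier}): holdout MCC "
        f"{artifact.holdout_mcc:.3f}, holdout AUC {artifact.holdout_auc:.3f}"
    )


if __name__ == "__main__":
    main()
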