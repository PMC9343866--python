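"""Preprocess the cohort: coverage filter (>1,000 reads), total-sum
scaling, mean-relative-abundance < 1e-4 taxon filter, re-normalization,
and binary label construction (current smoker = 0, non-current = 1).
"""

import argparse
from pathlib import Path

from imbalmicro.pipeline import preprocess
from imbalmicro.tables import read_metadata_tsv, read_taxa_tsv, write_taxa_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_taxa_tsv(args.data / "taxa.tsv")
    meta = read_metadata_tsv(args.data / "metadata.tsv")
    prepped, labels = preprocess(table, meta)
    args.out.mkdir(parents=True, exist_ok=True)
    write_taxa_tsv(prepped, args.out / "preprocessed_taxa.tsv")
    labels.labels.to_csv(args.out / "labels.tsv", sep="\t", lineterminator="\n")
    print(
        f"kept {prepped.n_samples}/{table.n_samples} samples and "
        f"{prepped.n_taxa}/{table.n_taxa} taxa; class counts {labels.class_counts()} "
        f"(0 = current smoker)"
    )


if __name__ == "__main__":
    main()
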