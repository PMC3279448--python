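"""Aggregate per-subject class methylation under both classing schemes.

Builds the bioinformatic attribute classes (census of observed CGI / PcG /
TFBS / repeat tuples) and the per-subject aggregate methylation matrices
for both the model-based and attribute-based schemes.
"""

import argparse
from pathlib import Path

from repmeth import io
from repmeth.classing import aggregate_class_methylation, assign_bioinformatic_classes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--clustering", type=Path, default=Path("results/clustering"))
    ap.add_argument("--outdir", type=Path, default=Path("results/classes"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix = io.read_beta_matrix(args.data / "beta_matrix.tsv")
    annotation = io.read_annotation(args.data / "annotation.tsv")
    rpmm_classes = io.read_class_assignment(args.clustering / "rpmm_classes.tsv")
    matrix = matrix.loc[rpmm_classes.index]   # clustering already autosomal

    bio_labels, census = assign_bioinformatic_classes(annotation.loc[matrix.index])
    census.to_csv(args.outdir / "bio_class_census.csv", index=False)
    print(f"{len(census)} nonempty bioinformatic classes "
          f"(largest: {census.iloc[0]['bio_class']}, "
          f"{census.iloc[0]['n_loci']} loci)")

    for name, labels in (("rpmm", rpmm_classes), ("bioinformatic", bio_labels)):
        agg = aggregate_class_methylation(matrix, labels)
        io.write_aggregates(agg, args.outdir / f"aggregates_{name}.tsv")
        print(f"{name}: {agg.shape[1]} classes x {agg.shape[0]} subjects "
              f"(aggregate range {agg.to_numpy().min():.3f}-"
              f"{agg.to_numpy().max():.3f})")


if __name__ == "__main__":
    main()
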