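"""Cluster CpG loci into methylation classes.

Filters the beta matrix to autosomes, runs the depth-4 recursively
partitioned beta-mixture clustering, and reports how the terminal classes
line up with the generator's latent classes.
"""

import argparse
from pathlib import Path

import pandas as pd

from repmeth import io
from repmeth.preprocess import filter_autosomal, screen_outliers
from repmeth.rpmm import rpmm_fit


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/clustering"))
    ap.add_argument("--max-depth", type=int, default=4)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix = io.read_beta_matrix(args.data / "beta_matrix.tsv")
    annotation = io.read_annotation(args.data / "annotation.tsv")
    matrix = filter_autosomal(matrix, annotation)
    qc = screen_outliers(matrix)
    print(f"{matrix.shape[0]} autosomal loci, {matrix.shape[1]} subjects; "
          f"{int(qc.flags.sum())} Mahalanobis outlier(s) at alpha={qc.alpha}")

    tree, assignment = rpmm_fit(matrix, max_depth=args.max_depth)
    io.write_tree(tree, args.outdir / "rpmm_tree.json")
    io.write_class_assignment(assignment, args.outdir / "rpmm_classes.tsv")
    summary = pd.DataFrame({
        "class": range(1, assignment.n_classes + 1),
        "node": assignment.node_labels,
        "size": assignment.class_sizes,
        "mean_beta": assignment.class_means.round(4),
    })
    summary.to_csv(args.outdir / "rpmm_class_summary.csv", index=False)
    print(f"{assignment.n_classes} terminal classes "
          f"(class 1 mean {assignment.class_means[0]:.3f} ... "
          f"class {assignment.n_classes} mean {assignment.class_means[-1]:.3f})")

    truth = io.read_truth(args.data / "truth.json")
    truth_series = pd.Series(truth.latent_class[:len(matrix)],
                             index=matrix.index) \
        if len(truth.latent_class) == len(matrix) else None
    if truth_series is not None:
        fitted = assignment.as_series()
        agree = fitted.groupby(truth_series).agg(
            lambda s: s.value_counts().iloc[0]).sum() / len(fitted)
        print(f"majority-mapping agreement with latent classes: {agree:.3f}")


if __name__ == "__main__":
    main()
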