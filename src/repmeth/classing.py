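"""Attribute-driven CpG classing and per-subject aggregate methylation.

A bioinformatic class is the tuple of seven binary genomic attributes of a
locus — CGI status, polycomb-target status, TFBS proximity (<= 1 kb), and
overlap with Alu, LINE-1, LINE-2 or MIR repeats — in that canonical order.
Only classes observed in the data are reported. Aggregate class
methylation is the unweighted per-subject mean beta over a class's loci,
used for both this scheme and the model-based (RPMM) classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "BIO_ATTRIBUTES",
    "bio_class_key",
    "assign_bioinformatic_classes",
    "aggregate_class_methylation",
]

# canonical attribute order for the class key
BIO_ATTRIBUTES = ("cgi", "pcg", "tfbs", "repeat_alu", "repeat_line1",
                  "repeat_line2", "repeat_mir")
_ATTR_LABELS = {"cgi": "CGI", "pcg": "PcG", "tfbs": "TFBS", "repeat_alu": "Alu",
                "repeat_line1": "LINE-1", "repeat_line2": "LINE-2",
                "repeat_mir": "MIR"}


def bio_class_key(row) -> str:
    """Readable class label, e.g. 'CGI/PcG/TFBS'; 'baseline' if all flags off."""
    parts = [_ATTR_LABELS[a] for a in BIO_ATTRIBUTES if bool(row[a])]
    return "/".join(parts) if parts else "baseline"


def assign_bioinformatic_classes(annotation: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Map each locus to its attribute tuple and census the nonempty classes.

    Returns ``(class_of_locus, census)`` where the census lists each
    observed class with its locus count, sorted by descending size then
    label.
    """
    missing = [a for a in BIO_ATTRIBUTES if a not in annotation.columns]
    if missing:
        raise ValueError(f"annotation lacks attribute columns: {missing}")
    labels = annotation[list(BIO_ATTRIBUTES)].astype(bool).apply(bio_class_key, axis=1)
    labels.name = "bio_class"
    census = (
        labels.value_counts()
        .rename_axis("bio_class")
        .reset_index(name="n_loci")
        .sort_values(["n_loci", "bio_class"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return labels, census


def aggregate_class_methylation(matrix: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-subject mean beta within each class (subjects x classes).

    ``classes`` maps locus id -> class label (RPMM index or bioinformatic
    key) and must cover every matrix locus. Classes present in the map but
    absent from the matrix are skipped with a warning.
    """
    classes = pd.Series(classes)
    uncovered = matrix.index.difference(classes.index)
    if len(uncovered) > 0:
        raise ValueError(f"{len(uncovered)} matrix loci missing a class label "
                         f"(first: {uncovered[0]})")
    empty = set(classes.unique()) - set(classes.loc[matrix.index].unique())
    if empty:
        warnings.warn(f"classes with no loci in the matrix excluded: {sorted(map(str, empty))}")
    grouped = matrix.groupby(classes.loc[matrix.index].to_numpy()).mean()
    out = grouped.T  # subjects x classes
    out.index.name = "subject_id"
    out.columns.name = "class"
    return out
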