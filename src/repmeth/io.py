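"""Readers, writers and pipeline configuration.

Matrices travel as TSV (loci as rows, subject-id header), tables as CSV,
trees and summaries as JSON, configuration as YAML; everything is UTF-8.
Readers validate rather than repair: an out-of-range beta or a duplicate
locus id is an error naming the offending cell.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rpmm import ClassAssignment, RpmmTree
from .synthetic_data import SimConfig, TrueLabels

__all__ = [
    "read_beta_matrix", "write_beta_matrix",
    "read_cohort", "write_cohort",
    "read_annotation", "write_annotation",
    "write_truth", "read_truth",
    "write_class_assignment", "read_class_assignment",
    "write_tree", "write_aggregates", "read_aggregates",
    "write_omnibus", "PipelineConfig",
]


def read_beta_matrix(path) -> pd.DataFrame:
    """Load a loci x subjects beta matrix, validating ids and the [0,1] range."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "locus_id"
    dup = df.index[df.index.duplicated()]
    if len(dup) > 0:
        raise ValueError(f"duplicate locus id(s): {', '.join(map(str, dup[:5]))}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric beta value in {path}: {exc}") from exc
    if np.isnan(values).any():
        locus, subj = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric or missing beta at locus {df.index[locus]}, "
            f"subject {df.columns[subj]}"
        )
    bad = np.argwhere((values < 0) | (values > 1))
    if len(bad) > 0:
        locus, subj = bad[0]
        raise ValueError(
            f"beta value {values[locus, subj]} outside [0, 1] at locus "
            f"{df.index[locus]}, subject {df.columns[subj]}"
        )
    return df.astype(float)


def write_beta_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6g")


_BOOL_COLS = ["cgi", "pcg", "tfbs", "repeat_alu", "repeat_line1",
              "repeat_line2", "repeat_mir"]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False,
                     na_values=[])
    for col in _BOOL_COLS:
        if col in df.columns and df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(["true", "1", "yes"])
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t")


def write_truth(truth: TrueLabels, path) -> None:
    payload = {
        "latent_class": [int(k) for k in truth.latent_class],
        "class_means": [float(m) for m in truth.class_means],
        "effects": truth.effects,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> TrueLabels:
    payload = json.loads(Path(path).read_text())
    return TrueLabels(
        latent_class=np.asarray(payload["latent_class"], dtype=int),
        class_means=np.asarray(payload["class_means"], dtype=float),
        effects=payload.get("effects", {}),
    )


def write_class_assignment(assignment: ClassAssignment, path) -> None:
    assignment.as_series().rename("class").rename_axis("locus_id").to_csv(
        path, sep="\t")


def read_class_assignment(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["class"]


def write_tree(tree: RpmmTree, path) -> None:
    Path(path).write_text(json.dumps({
        "max_depth": tree.max_depth,
        "n_subjects": len(tree.subjects),
        "root": tree.root.to_dict(),
    }, indent=1))


def write_aggregates(aggregates: pd.DataFrame, path) -> None:
    aggregates.to_csv(path, sep="\t", float_format="%.6g")


def read_aggregates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_omnibus(result, path_csv, path_json) -> None:
    result.per_class.to_csv(path_csv)
    Path(path_json).write_text(json.dumps({
        "p_value": result.p_value,
        "observed_max_t": result.observed_max_t,
        "null_limit_95": result.null_limit,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
    }, indent=1))


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; seeds are recorded in every output."""

    outdir: str = "results/pipeline"
    seed: int = 0
    markers: tuple = ("line1", "aluyb8")
    schemes: tuple = ("rpmm", "bioinformatic")
    omnibus_B: int = 10000
    gsea_B: int = 200
    max_depth: int = 4
    outlier_alpha: float = 0.001
    drop_outliers: bool = False
    sim: dict = field(default_factory=dict)   # SimConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("markers", "schemes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.sim)
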