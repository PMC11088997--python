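"""Clone-level descriptive statistics.

Cluster annotations are first merged into broad cell classes (mitotic /
PN / IN, with an optional MGE/CGE split of the INs); each clone is then
characterized by the exact set of classes its cells occupy — the
categories of an UpSet plot — and by its size, summarized per
perturbation arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ClassMap:
    """Cluster-annotation → class mapping, with optional IN sub-classes.

    ``classes`` sends every cluster annotation observed in the data to one
    of the broad classes (typically mitotic | PN | IN); ``in_subclasses``
    optionally refines IN annotations into IN-MGE / IN-CGE.  The map must
    be total over the observed annotations: an unmapped annotation is an
    error, never silently dropped.
    """

    classes: dict
    in_subclasses: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ClassMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(classes=raw["classes"], in_subclasses=raw.get("in_subclasses", {}))


def assign_classes(cell_metadata: pd.DataFrame, class_map: ClassMap) -> pd.DataFrame:
    """Add a ``cell_class`` column from the annotation column.

    The annotation column is ``annotation`` (or ``cluster`` as a
    fallback).  IN cells with an entry in the sub-map get the sub-class
    label instead of plain IN.  Raises on any annotation absent from the
    map, listing the offenders.
    """
    col = "annotation" if "annotation" in cell_metadata.columns else "cluster"
    if col not in cell_metadata.columns:
        raise ValueError("cell_metadata needs an 'annotation' (or 'cluster') column")
    ann = cell_metadata[col]
    unmapped = sorted(set(ann) - set(class_map.classes))
    if unmapped:
        raise ValueError(f"annotations missing from the class map: {unmapped}")
    out = cell_metadata.copy()
    labels = ann.map(class_map.classes)
    if class_map.in_subclasses:
        sub = ann.map(class_map.in_subclasses)
        labels = labels.where(~((labels == "IN") & sub.notna()), sub)
    out["cell_class"] = labels
    return out


def intersect_clone_classes(
    clone_table: pd.DataFrame, multicell_only: bool = False
) -> pd.DataFrame:
    """UpSet-style clone–class intersection counts per perturbation arm.

    Each clone maps to the exact set of classes its cells occupy (a clone
    spanning IN and PN counts under {IN, PN}, not under {IN}).  For each
    arm, the proportion of a combination is its clone count divided by the
    total number of clones in that arm, so proportions sum to 1 per arm.

    Returns a tidy frame (combination, arm, count, proportion, plus the
    per-class cell counts as ``set_size_<class>`` attributes in
    ``DataFrame.attrs["set_sizes"]``).
    """
    if clone_table.empty:
        return pd.DataFrame(columns=["combination", "arm", "count", "proportion"])
    table = clone_table
    if multicell_only:
        sizes = table.groupby("clone_id")["cell_id"].transform("size")
        table = table[sizes >= 2]
    if table.empty:
        return pd.DataFrame(columns=["combination", "arm", "count", "proportion"])

    per_clone = (
        table.groupby(["arm", "clone_id"])["cell_class"]
        .agg(lambda s: "+".join(sorted(set(s))))
        .rename("combination")
        .reset_index()
    )
    counts = per_clone.groupby(["arm", "combination"], sort=True).size().rename("count").reset_index()
    totals = counts.groupby("arm")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    counts = counts[["combination", "arm", "count", "proportion"]]
    counts.attrs["set_sizes"] = (
        table.groupby(["arm", "cell_class"])["cell_id"].nunique().to_dict()
    )
    return counts


def clone_size_summary(clone_table: pd.DataFrame, multicell_only: bool = False) -> dict:
    """Per-arm clone sizes with mean ± s.d. and per-batch means.

    With ``multicell_only``, singleton clones (size 1) are excluded before
    summarizing.  The s.d. is the sample value (ddof=1); with a single
    clone it is reported as 0 and with no clones as NaN.
    """
    out: dict = {}
    for arm, sub in clone_table.groupby("arm", sort=True):
        sizes = sub.groupby("clone_id")["cell_id"].size()
        if multicell_only:
            sizes = sizes[sizes >= 2]
        per_batch = (
            sub.groupby(["batch", "clone_id"])["cell_id"].size().rename("size").reset_index()
        )
        if multicell_only:
            per_batch = per_batch[per_batch["size"] >= 2]
        out[arm] = {
            "sizes": sizes.sort_index().tolist(),
            "n_clones": int(len(sizes)),
            "mean": float(sizes.mean()) if len(sizes) else np.nan,
            "sd": float(sizes.std(ddof=1)) if len(sizes) > 1 else (0.0 if len(sizes) == 1 else np.nan),
            "batch_means": {
                b: float(g["size"].mean()) for b, g in per_batch.groupby("batch", sort=True)
            },
        }
    return out
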