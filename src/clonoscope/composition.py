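"""Differential cell-type abundance and module-score effects between
perturbation arms.

Abundance: for each cell type, a Poisson regression of its per-(batch,
arm) cell count on arm and batch with an exposure offset log(total cells
in that batch × arm).  The arm coefficient is then a log rate ratio of
the cell type's *proportion* between arms, robust to arm-level capture
differences; Wald p-values are BH-corrected across cell types.

Module scores: per gene module, an ordinary linear regression of the
per-cell score on arm, batch and the number of detected genes; the arm
coefficient is the perturbation effect and p-values are Bonferroni
corrected across module × arm tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


def composition_table(cell_metadata: pd.DataFrame, min_count: int = 1) -> pd.DataFrame:
    """Tally cells per (batch, arm, cell_type) and attach per-(batch, arm)
    totals.

    ``min_count`` drops (batch, arm, cell_type) rows below the threshold
    after totals are computed (low-count filtering; default keeps
    everything with at least one cell).
    """
    counts = (
        cell_metadata.groupby(["batch", "arm", "cell_class"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"cell_class": "cell_type"})
    )
    totals = counts.groupby(["batch", "arm"])["count"].transform("sum")
    counts["total"] = totals
    return counts[counts["count"] >= min_count].reset_index(drop=True)


def _validate_composition(table: pd.DataFrame) -> None:
    need = {"batch", "arm", "cell_type", "count", "total"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    if (table["count"] < 0).any() or (table["count"] % 1 != 0).any():
        raise ValueError("counts must be nonnegative integers")
    if (table["total"] <= 0).any():
        raise ValueError("every (batch, arm) must have a positive total")


def composition_poisson(table: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Per-cell-type Poisson regression of counts on arm (+ batch, offset).

    Fits log E[count] = β0 + β_arm + β_batch + log(total) for each cell
    type and reports the perturbation coefficient β_arm (log rate ratio,
    perturbed vs control), its standard error, Wald p, and BH-adjusted q
    across cell types.  A cell type entirely absent from one arm cannot
    yield a finite MLE (separation); it is reported with ``unstable=True``
    and NaN effect rather than being silently fit on pseudo-data.
    """
    _validate_composition(table)
    arms = sorted(table["arm"].unique())
    if control_label not in arms:
        raise ValueError(f"control label {control_label!r} not among arms {arms}")
    if len(arms) != 2:
        raise ValueError(f"exactly two arms required, got {arms}")
    perturbed = next(a for a in arms if a != control_label)

    # complete the grid with explicit zero counts so absence is informative
    grid = (
        table[["batch", "arm", "total"]]
        .drop_duplicates()
        .merge(pd.DataFrame({"cell_type": sorted(table["cell_type"].unique())}), how="cross")
    )
    full = grid.merge(table, on=["batch", "arm", "total", "cell_type"], how="left")
    full["count"] = full["count"].fillna(0).astype(int)

    multi_batch = full["batch"].nunique() > 1
    rows = []
    for ct, sub in full.groupby("cell_type", sort=True):
        arm_totals = sub.groupby("arm")["count"].sum()
        if (arm_totals == 0).any():
            rows.append((ct, np.nan, np.nan, np.nan, True))
            continue
        X = pd.DataFrame({"perturbed": (sub["arm"] == perturbed).astype(float)})
        if multi_batch:
            X = pd.concat([X, pd.get_dummies(sub["batch"], drop_first=True, dtype=float)], axis=1)
        X = sm.add_constant(X, has_constant="add")
        model = sm.GLM(
            sub["count"].to_numpy(),
            X.to_numpy(),
            family=sm.families.Poisson(),
            offset=np.log(sub["total"].to_numpy(dtype=float)),
        )
        fit = model.fit()
        ix = list(X.columns).index("perturbed")
        rows.append((ct, fit.params[ix], fit.bse[ix], fit.pvalues[ix], False))

    out = pd.DataFrame(rows, columns=["cell_type", "effect", "se", "p", "unstable"])
    ok = ~out["p"].isna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def log_ratio_composition(
    table: pd.DataFrame, control_label: str, pseudo: float = 0.0
) -> pd.Series:
    """log10 proportion ratio (perturbed / control) per cell type.

    Proportions are pooled over batches; ``pseudo`` is added to both
    proportions to keep zero counts finite.
    """
    _validate_composition(table)
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    arms = sorted(table["arm"].unique())
    perturbed = next(a for a in arms if a != control_label)
    pooled = table.groupby(["arm", "cell_type"])["count"].sum().unstack(fill_value=0)
    totals = pooled.sum(axis=1)
    props = pooled.div(totals, axis=0)
    with np.errstate(divide="ignore"):
        ratio = np.log10((props.loc[perturbed] + pseudo) / (props.loc[control_label] + pseudo))
    ratio.name = "log10_proportion_ratio"
    return ratio


def module_score_effects(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    control_label: str,
) -> pd.DataFrame:
    """Linear-model perturbation effects on per-cell module scores.

    ``scores`` is cells × modules; ``metadata`` (same index) must carry
    ``arm``, ``batch`` and ``n_genes`` columns.  For every module and
    every non-control arm, fits score ~ arm + batch + n_genes on the
    control + that arm's cells and reports the arm coefficient, its p, and
    a Bonferroni-adjusted p across all module × arm tests.  A module with
    constant scores is flagged degenerate with effect 0 and p = 1.
    """
    if not scores.index.equals(metadata.index):
        metadata = metadata.loc[scores.index]
    arms = [a for a in pd.unique(metadata["arm"]) if a != control_label]
    if not arms:
        raise ValueError("no non-control arm present")
    rows = []
    for arm in arms:
        mask = metadata["arm"].isin([control_label, arm]).to_numpy()
        meta = metadata.loc[mask]
        for module in scores.columns:
            y = scores.loc[mask, module].to_numpy(dtype=float)
            if not np.all(np.isfinite(y)):
                raise ValueError(f"module {module!r} has non-finite scores")
            if np.ptp(y) == 0:
                rows.append((module, arm, 0.0, np.nan, 1.0, True))
                continue
            df = pd.DataFrame(
                {
                    "score": y,
                    "perturbed": (meta["arm"] == arm).astype(float).to_numpy(),
                    "batch": meta["batch"].to_numpy(),
                    "n_genes": meta["n_genes"].to_numpy(dtype=float),
                }
            )
            formula = "score ~ perturbed + n_genes"
            if df["batch"].nunique() > 1:
                formula += " + C(batch)"
            fit = smf.ols(formula, data=df).fit()
            rows.append(
                (module, arm, fit.params["perturbed"], fit.bse["perturbed"], fit.pvalues["perturbed"], False)
            )
    out = pd.DataFrame(rows, columns=["module", "arm", "effect", "se", "p", "degenerate"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
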