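"""Lineage coupling between cell states from shared clonal barcodes.

For every pair of cell states (i, j) the observed matrix O counts clones
with at least one cell in *both* states; an expected matrix E is derived
from O's marginals under the independence assumption of no lineage
coupling, E_ij = (row_i × col_j) / grand total, so that O/E = 1 means
coupling at the level of random expectation, >1 positive coupling, <1
depletion.  Stability comes from resampling: the ratio is recomputed over
many random subsamples of clones (1,000 trials of 25% of clones by
default), the reported score is the median ratio, and an empirical
p-value counts the trials that land on the wrong side of 1 for the pair's
direction of coupling.  Off-diagonal p-values are Benjamini–Hochberg
corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class SharedBarcodeMatrix:
    """Symmetric clone-sharing counts between cell states.

    ``O[i, j]`` is the number of clones with >= 1 cell in state i and >= 1
    cell in state j; the diagonal ``O[i, i]`` counts clones present in
    state i at all.
    """

    states: list
    O: np.ndarray

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O)
        if self.O.shape != (len(self.states), len(self.states)):
            raise ValueError("matrix shape does not match the state list")
        if not np.array_equal(self.O, self.O.T):
            raise ValueError("shared-barcode matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.O, index=self.states, columns=self.states)


@dataclass
class CouplingResult:
    """Resampled coupling scores with empirical significance."""

    states: list
    score: np.ndarray  # median O/E per pair; NaN where undefined
    p: np.ndarray  # empirical p per pair (NaN on diagonal-less undefined pairs)
    q: np.ndarray  # BH-adjusted over off-diagonal pairs
    n_valid_trials: np.ndarray
    n_trials: int
    frac: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.states)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (
                        self.states[i],
                        self.states[j],
                        self.score[i, j],
                        self.p[i, j],
                        self.q[i, j],
                        int(self.n_valid_trials[i, j]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["state_i", "state_j", "score", "p", "q", "n_valid_trials"]
        )


def _incidence(clone_table: pd.DataFrame, states: list) -> np.ndarray:
    """Boolean clones × states presence matrix."""
    state_ix = {s: i for i, s in enumerate(states)}
    unknown = sorted(set(clone_table["cell_class"]) - set(states))
    if unknown:
        raise ValueError(f"cell states not in the state list: {unknown}")
    clones = sorted(clone_table["clone_id"].unique())
    clone_ix = {c: i for i, c in enumerate(clones)}
    inc = np.zeros((len(clones), len(states)), dtype=bool)
    for clone, cls in zip(clone_table["clone_id"], clone_table["cell_class"]):
        inc[clone_ix[clone], state_ix[cls]] = True
    return inc


def observed_shared_matrix(clone_table: pd.DataFrame, states: list) -> SharedBarcodeMatrix:
    """Count clones shared between every pair of states.

    A clone is shared between states i and j when it has at least one cell
    in each.  The diagonal counts clones with any cell in the state.
    """
    if not list(states):
        raise ValueError("states must be non-empty")
    if clone_table.empty:
        return SharedBarcodeMatrix(states=list(states), O=np.zeros((len(states),) * 2, dtype=int))
    inc = _incidence(clone_table, list(states))
    O = (inc.T.astype(np.int64) @ inc.astype(np.int64))
    return SharedBarcodeMatrix(states=list(states), O=O)


def expected_matrix(O: np.ndarray | SharedBarcodeMatrix, include_diagonal: bool = True) -> np.ndarray:
    """Independence expectation from the marginals of O.

    E_ij = (Σ_k O_ik × Σ_k O_kj) / Σ_kl O_kl — the outer product of O's
    row and column sums over its grand total, the unique expectation that
    makes O/E = 1 when states assort independently.  With
    ``include_diagonal=False`` the diagonal is zeroed before taking the
    marginals (strict mode).  A grand total of zero yields an all-NaN
    matrix rather than a division error.
    """
    mat = O.O if isinstance(O, SharedBarcodeMatrix) else np.asarray(O)
    mat = mat.astype(float)
    if not include_diagonal:
        mat = mat.copy()
        np.fill_diagonal(mat, 0.0)
    total = mat.sum()
    if total == 0:
        return np.full_like(mat, np.nan)
    rows = mat.sum(axis=1)
    cols = mat.sum(axis=0)
    return np.outer(rows, cols) / total


def coupling_analysis(
    clone_table: pd.DataFrame,
    states: list,
    n_trials: int = 1000,
    frac: float = 0.25,
    seed: int = 0,
    include_diagonal: bool = True,
) -> CouplingResult:
    """Subsampled observed/expected coupling with empirical p-values.

    Per trial, ``ceil(frac * n_clones)`` clones are drawn without
    replacement, O and E recomputed, and the ratio O/E recorded for each
    pair where E > 0.  The score is the median ratio over a pair's valid
    trials.  The empirical p counts trials contradicting the pair's
    coupling direction — ratio > 1 for negatively coupled pairs
    (score < 1), ratio < 1 for positively coupled ones — with a
    pseudo-count: p = (k + 1)/(n_valid + 1), so p is never exactly 0.
    BH correction runs over the off-diagonal pairs.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    states = list(states)
    k = len(states)
    inc = _incidence(clone_table, states)
    n_clones = inc.shape[0]
    if n_clones == 0:
        raise ValueError("clone table is empty")
    m = int(np.ceil(frac * n_clones))
    rng = np.random.default_rng(seed)

    ratios = np.full((n_trials, k, k), np.nan)
    for t in range(n_trials):
        sub = inc[rng.choice(n_clones, size=m, replace=False)]
        O_t = (sub.T.astype(np.int64) @ sub.astype(np.int64)).astype(float)
        E_t = expected_matrix(O_t, include_diagonal=include_diagonal)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = O_t / E_t
        r[~(E_t > 0)] = np.nan
        ratios[t] = r

    n_valid = np.sum(~np.isnan(ratios), axis=0)
    with np.errstate(all="ignore"):
        score = np.nanmedian(ratios, axis=0)
    score[n_valid == 0] = np.nan

    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            nv = n_valid[i, j]
            if nv == 0 or np.isnan(score[i, j]):
                continue
            r = ratios[:, i, j]
            # trials at exactly 1 are "in line with random expectations":
            # they never count as evidence for coupling in either direction
            if score[i, j] >= 1.0:
                contra = np.nansum(r <= 1.0)
            else:
                contra = np.nansum(r >= 1.0)
            p[i, j] = (contra + 1.0) / (nv + 1.0)

    q = np.full((k, k), np.nan)
    iu, ju = np.triu_indices(k, k=1)
    pvals = p[iu, ju]
    ok = ~np.isnan(pvals)
    if ok.any():
        adj = multipletests(pvals[ok], method="fdr_bh")[1]
        qv = np.full(pvals.shape, np.nan)
        qv[ok] = adj
        q[iu, ju] = qv
        q[ju, iu] = qv

    return CouplingResult(
        states=states,
        score=score,
        p=p,
        q=q,
        n_valid_trials=n_valid,
        n_trials=n_trials,
        frac=frac,
        seed=seed,
    )
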