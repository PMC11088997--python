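"""Balanced, cross-validated regularized logistic classification of
interneuron (IN) versus projection-neuron (PN) fate.

The classifier is trained on the most variable genes of a normalized,
per-gene standardized expression matrix, with classes balanced by
downsampling the majority class, an L1 penalty chosen by cross-validation
on a two-thirds training split, and accuracy reported on the held-out
third.  The signed gene coefficients double as fate-predictive scores
after a sigmoid transform: 0.5 means uninformative, above 0.5 PN-
predictive, below 0.5 IN-predictive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import accuracy_score

IN_LABEL, PN_LABEL = "IN", "PN"


@dataclass
class FateModel:
    """Fitted IN/PN fate classifier."""

    genes: list
    coefficients: np.ndarray  # signed, on standardized expression; + favors PN
    intercept: float
    C: float  # inverse regularization strength selected by CV
    validation_accuracy: float
    class_encoding: dict = field(default_factory=lambda: {IN_LABEL: 0, PN_LABEL: 1})
    seed: int = 0

    def ranked_genes(self) -> pd.DataFrame:
        """Genes by |coefficient|, with the sigmoid fate score."""
        df = pd.DataFrame(
            {
                "gene": self.genes,
                "coefficient": self.coefficients,
                "score": gene_fate_scores(self),
            }
        )
        return df.reindex(df["coefficient"].abs().sort_values(ascending=False).index).reset_index(
            drop=True
        )

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "C": float(self.C),
            "validation_accuracy": float(self.validation_accuracy),
            "class_encoding": dict(self.class_encoding),
            "seed": int(self.seed),
        }


def _as_dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)


def normalize_log1p(X) -> np.ndarray:
    """Depth-normalize each cell to the median total count, then log1p."""
    X = _as_dense(X).astype(float)
    totals = X.sum(axis=1)
    totals[totals == 0] = 1.0
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    return np.log1p(X / totals[:, None] * target)


def select_variable_genes(matrix, genes: list, n: int = 3000) -> list:
    """Top-``n`` genes by variance of log1p-normalized expression.

    Ties break deterministically by gene id (lexicographically smaller
    wins).  Returns the selected ids in that deterministic order.
    """
    if n > len(genes):
        raise ValueError(f"asked for {n} genes but matrix has {len(genes)}")
    logX = normalize_log1p(matrix)
    var = logX.var(axis=0, ddof=0)
    order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
    return [genes[i] for i in order[:n]]


def balance_classes(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subsample (majority class downsampled).

    One global shuffled order decides which cells survive, so the result
    depends on class *membership* but not on how the classes are named.
    """
    labels = np.asarray(labels)
    n_min = min(int((labels == c).sum()) for c in np.unique(labels))
    order = rng.permutation(len(labels))
    picked = []
    for c in np.unique(labels):
        in_class = order[labels[order] == c]
        picked.append(in_class[:n_min])
    return np.sort(np.concatenate(picked))


def fit_fate_classifier(
    matrix,
    genes: list,
    labels,
    n_variable_genes: int | None = 3000,
    train_frac: float = 2.0 / 3.0,
    penalty: str = "l1",
    Cs: int = 8,
    cv: int = 3,
    seed: int = 0,
) -> FateModel:
    """Fit the balanced IN-vs-PN logistic classifier.

    ``matrix`` is cells × genes raw counts (dense or sparse); ``labels``
    holds "IN"/"PN" per cell.  Steps, all seeded: balance classes by
    downsampling; normalize (median-depth + log1p) and select the
    ``n_variable_genes`` most variable genes; split two-thirds train /
    one-third validation (stratified); standardize each gene on the
    training cells; fit an L1-penalized logistic model with the penalty
    chosen by ``cv``-fold cross-validation on the training split; report
    accuracy on the held-out cells.
    """
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {IN_LABEL, PN_LABEL}
    if bad:
        raise ValueError(f"labels must be IN/PN only, found {sorted(bad)}")
    for cls in (IN_LABEL, PN_LABEL):
        n_cls = int((labels == cls).sum())
        if n_cls < 10:
            raise ValueError(f"class {cls} has only {n_cls} cells (< 10); cannot fit")

    rng = np.random.default_rng(seed)
    X = _as_dense(matrix)

    keep = balance_classes(labels, rng)
    X, labels = X[keep], labels[keep]

    if n_variable_genes is not None and n_variable_genes < len(genes):
        sel = select_variable_genes(X, list(genes), n=n_variable_genes)
        col = {g: i for i, g in enumerate(genes)}
        X = X[:, [col[g] for g in sel]]
        genes = sel
    else:
        genes = list(genes)

    logX = normalize_log1p(X)
    y = (labels == PN_LABEL).astype(int)

    # stratified 2/3 train / 1/3 validation split; one global shuffled
    # order so the split is invariant to relabeling the two classes
    n_train_per_class = int(round(train_frac * min((y == 0).sum(), (y == 1).sum())))
    order = rng.permutation(len(y))
    train_parts, val_parts = [], []
    for cls in (0, 1):
        in_class = order[y[order] == cls]
        train_parts.append(in_class[:n_train_per_class])
        val_parts.append(in_class[n_train_per_class:])
    train = np.sort(np.concatenate(train_parts))
    val = np.sort(np.concatenate(val_parts))

    mu = logX[train].mean(axis=0)
    sd = logX[train].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (logX - mu) / sd

    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty=penalty,
        solver="liblinear",
        scoring="accuracy",
        max_iter=2000,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    with warnings.catch_warnings():
        # scikit-learn is mid-transition from penalty= to l1_ratios=;
        # penalty= keeps the call compatible across the versions we support
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Z[train], y[train])
    acc = accuracy_score(y[val], clf.predict(Z[val])) if len(val) else float("nan")

    return FateModel(
        genes=list(genes),
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        C=float(clf.C_[0]),
        validation_accuracy=float(acc),
        seed=seed,
    )


def gene_fate_scores(model: FateModel) -> np.ndarray:
    """Sigmoid-transformed coefficients on the (0, 1) fate scale.

    score = 1 / (1 + exp(-β)): a zero coefficient maps to 0.5, PN-
    predictive genes land above 0.5 and IN-predictive genes below.
    Raw coefficients stay available on the model.
    """
    return 1.0 / (1.0 + np.exp(-np.asarray(model.coefficients, dtype=float)))
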