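"""Virtual-trial analysis: classification of DKD vs HKD from biomarkers.

Univariate and multivariate logistic-regression analyses over a feature
table of waveform biomarkers: repeated stratified 70/30 holdout (50
iterations), validation AUC/accuracy, Pearson correlation structure, and a
combination search over biomarker subsets of increasing dimensionality with
top-combination frequency ranking.

The AUC is computed by the rank (Mann-Whitney) formula with ties counted
one half; the linear log-odds model is an unpenalised maximum-likelihood
fit on features standardised to the training split (a small ridge fallback
is applied only if the unpenalised fit fails to converge, e.g. under
complete separation).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "TrialDataset",
    "EvaluationResult",
    "CombinationSearchResult",
    "auc_roc",
    "fit_linear_logodds",
    "repeated_holdout",
    "correlation_matrix",
    "combination_search",
    "univariate_screen",
]


@dataclass
class TrialDataset:
    """Feature matrix (subjects x biomarkers) with binary labels
    (DKD = 1, HKD = 0) and optional group metadata."""

    X: pd.DataFrame
    y: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and labels differ in length")
        if self.X.isna().any().any():
            bad = self.X.columns[self.X.isna().any()].tolist()
            raise ValueError(f"missing values in features: {bad}")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class EvaluationResult:
    biomarkers: tuple[str, ...]
    aucs: np.ndarray  # per holdout iteration
    accuracies: np.ndarray
    coefficients: np.ndarray  # mean over iterations, standardised scale
    intercept: float

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class CombinationSearchResult:
    dimension: int
    n_evaluated: int
    table: pd.DataFrame  # columns: biomarkers, auc, accuracy; auc-descending
    top: pd.DataFrame  # the top-100 rows with AUC above the threshold
    frequencies: pd.Series  # biomarker -> count among top combinations
    top10: list[str] = field(default_factory=list)


def auc_roc(scores, labels) -> float:
    """Area under the ROC curve via the normalised Mann-Whitney U statistic
    (ties counted one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute an AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def fit_linear_logodds(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood linear log-odds fit; returns (coefficients,
    intercept).  Features are expected standardised by the caller."""
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("single class in labels")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
            clf.fit(X, y)
        except ConvergenceWarning:
            # separation: fall back to a weak ridge penalty
            clf = LogisticRegression(C=1.0e3, solver="lbfgs", max_iter=2000)
            clf.fit(X, y)
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def _predict_logodds(X: np.ndarray, coef: np.ndarray, intercept: float) -> np.ndarray:
    return X @ coef + intercept


def repeated_holdout(
    dataset: TrialDataset,
    biomarkers: tuple[str, ...] | list[str],
    n_iter: int = 50,
    train_frac: float = 0.70,
    seed: int = 0,
) -> EvaluationResult:
    """Repeated stratified random 70/30 holdout evaluation of one biomarker
    set; deterministic given the seed."""
    cols = list(biomarkers)
    X = dataset.X[cols].to_numpy(dtype=float)
    y = dataset.y
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    n1_tr = max(1, int(round(train_frac * idx1.size)))
    n0_tr = max(1, int(round(train_frac * idx0.size)))
    aucs = np.empty(n_iter)
    accs = np.empty(n_iter)
    coefs = np.zeros(len(cols))
    inter = 0.0
    for it in range(n_iter):
        p1 = rng.permutation(idx1)
        p0 = rng.permutation(idx0)
        tr = np.concatenate([p1[:n1_tr], p0[:n0_tr]])
        va = np.concatenate([p1[n1_tr:], p0[n0_tr:]])
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xva = (X[va] - mu) / sd
        coef, b0 = fit_linear_logodds(Xtr, y[tr])
        scores = _predict_logodds(Xva, coef, b0)
        aucs[it] = auc_roc(scores, y[va])
        accs[it] = float(np.mean((scores > 0).astype(int) == y[va]))
        coefs += coef
        inter += b0
    return EvaluationResult(
        biomarkers=tuple(cols),
        aucs=aucs,
        accuracies=accs,
        coefficients=coefs / n_iter,
        intercept=inter / n_iter,
    )


def correlation_matrix(dataset: TrialDataset) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix of the features plus a
    hierarchical-clustering column ordering for plotting.  Zero-variance
    columns yield NaN rows/columns (flagged, not dropped)."""
    if dataset.n < 3:
        raise ValueError("need at least 3 subjects")
    corr = dataset.X.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    valid = corr.columns[~corr.isna().all()]
    sub = corr.loc[valid, valid].fillna(0.0)
    if len(valid) > 2:
        dist = squareform(1.0 - np.abs(sub.to_numpy()), checks=False)
        link = hierarchy.linkage(dist, method="average")
        order = [valid[i] for i in hierarchy.leaves_list(link)]
    else:
        order = list(valid)
    order += [c for c in corr.columns if c not in valid]
    return corr, order


def _sample_combinations(names, d, cap, rng):
    total = math.comb(len(names), d)
    if total <= cap:
        return list(itertools.combinations(names, d))
    seen = set()
    out = []
    names = list(names)
    while len(out) < cap:
        pick = tuple(sorted(rng.choice(len(names), size=d, replace=False)))
        if pick not in seen:
            seen.add(pick)
            out.append(tuple(names[i] for i in pick))
    return out


def combination_search(
    dataset: TrialDataset,
    group: str = "full",
    dims=range(2, 26),
    cap_per_dim: int = 5000,
    seed: int = 0,
    n_iter: int = 50,
    auc_threshold: float = 0.8,
    top_n: int = 100,
    vocabulary: list[str] | None = None,
) -> list[CombinationSearchResult]:
    """Evaluate biomarker combinations of increasing dimensionality.

    All combinations are enumerated when their count does not exceed
    ``cap_per_dim``; otherwise a uniform random sample without replacement
    of ``cap_per_dim`` combinations is drawn (seeded).  ``group`` selects
    the vocabulary: ``"full"`` (all features) or ``"common"`` (pressure- and
    PWV-derived biomarkers excluded).
    """
    if vocabulary is None:
        if group == "full":
            vocabulary = list(dataset.X.columns)
        elif group == "common":
            vocabulary = [
                c for c in dataset.X.columns if "Pressure" not in c and "PWV" not in c
            ]
        else:
            raise ValueError(f"unknown biomarker group {group!r}")
    if not vocabulary:
        raise ValueError("empty biomarker vocabulary")
    rng = np.random.default_rng(seed)
    results = []
    for d in dims:
        if d > len(vocabulary):
            raise ValueError(
                f"dimension {d} exceeds vocabulary size {len(vocabulary)}"
            )
        combos = _sample_combinations(vocabulary, d, cap_per_dim, rng)
        rows = []
        for combo in combos:
            ev = repeated_holdout(dataset, combo, n_iter=n_iter, seed=seed)
            rows.append(
                {"biomarkers": combo, "auc": ev.mean_auc, "accuracy": ev.mean_accuracy}
            )
        table = (
            pd.DataFrame(rows)
            .sort_values("auc", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
        top = table[table["auc"] > auc_threshold].head(top_n)
        counts: dict[str, int] = {}
        for combo in top["biomarkers"]:
            for name in combo:
                counts[name] = counts.get(name, 0) + 1
        freq = pd.Series(counts, dtype=int).sort_values(ascending=False)
        results.append(
            CombinationSearchResult(
                dimension=d,
                n_evaluated=len(combos),
                table=table,
                top=top,
                frequencies=freq,
                top10=list(freq.index[:10]),
            )
        )
    return results


def univariate_screen(
    dataset: TrialDataset,
    locations=("main", "segmental", "interlobar", "arcuate"),
    n_iter: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-biomarker AUC per location (columns named
    ``<location>.<name>``); returns a location x biomarker-name table."""
    out: dict[str, dict[str, float]] = {loc: {} for loc in locations}
    for col in dataset.X.columns:
        if "." not in col:
            continue
        loc, name = col.split(".", 1)
        if loc not in out:
            continue
        ev = repeated_holdout(dataset, [col], n_iter=n_iter, seed=seed)
        out[loc][name] = ev.mean_auc
    return pd.DataFrame(out).T.loc[list(locations)]
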