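"""Radiosensitivity gene-signature classification.

Pipeline: rank genes by a one-way ANOVA F test across the radiosensitivity
cohorts, grow candidate panels from the top of the ranking (4 up to 500
genes), train a linear support-vector machine on each panel, and score it by
repeated stratified 10-fold cross-validation.

Feature selection placement matters: ranking genes on the full data before
cross-validating leaks the test folds into selection and inflates accuracy.
The default (``selection_mode='inside_cv'``) re-ranks within every training
fold, which keeps null data at chance; ``'outside_cv'`` ranks once on all
data, mirroring the simpler (optimistic) procedure common in the microarray
literature.

An optional empirical-Bayes moderation of the F statistic shrinks gene-wise
variances toward their grand mean with a fixed prior df, stabilising the
ranking when within-group df is small.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import KFold, RepeatedStratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "GeneRanking",
    "PanelEvaluation",
    "anova_f",
    "rank_genes",
    "evaluate_panels",
    "select_signature",
    "binary_mode",
    "to_binary_labels",
]


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by ascending p (ties: descending F, then gene id)."""

    genes: list[str]
    f_statistic: pd.Series
    p_value: pd.Series

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


@dataclass(frozen=True)
class PanelEvaluation:
    panel_size: int
    genes: list[str]
    mean_cv_accuracy: float
    per_repeat_accuracies: list[float]
    mean_balanced_accuracy: float


def anova_f(x: np.ndarray, group_idx: np.ndarray, n_groups: int, moderated: bool = False,
            prior_df: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA over the rows of ``x`` (genes x samples).

    Returns (F, p).  Zero within-variance rows give F = nan.  With
    ``moderated=True`` the pooled within-group variance of each gene is
    shrunk toward the across-gene mean variance with ``prior_df`` prior
    degrees of freedom before forming F (p then uses df2 + prior_df).
    """
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_tot = ((x - grand) ** 2).sum(axis=1)
    ss_within = np.zeros(x.shape[0])
    for g in range(n_groups):
        cols = x[:, group_idx == g]
        ss_within += ((cols - cols.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss_between = ss_tot - ss_within
    df1, df2 = n_groups - 1, n - n_groups
    if df2 <= 0:
        raise ValueError("need at least one residual degree of freedom")
    s2 = ss_within / df2
    if moderated:
        s2_prior = np.nanmean(s2)
        s2 = (prior_df * s2_prior + df2 * s2) / (prior_df + df2)
        df2_eff = df2 + prior_df
    else:
        df2_eff = df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / s2
    p = stats.f.sf(f, df1, df2_eff)
    return f, p


def _group_codes(groups: pd.Series | Sequence[str]) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def rank_genes(
    expr: pd.DataFrame,
    groups: pd.Series | Sequence[str],
    moderated: bool = False,
    *,
    min_group_size: int = 2,
) -> GeneRanking:
    """Rank genes by one-way ANOVA F across the cohort labels.

    ``expr`` is genes x samples; ``groups`` one label per sample (>= 2
    groups, each with >= 2 samples, no missing values).  Genes whose F is
    undefined (zero variance) are ranked last.  ``min_group_size`` is
    relaxed to 1 internally when ranking within unstratified CV folds,
    where a rare class may be nearly absent from a training fold.
    """
    codes, n_groups = _group_codes(groups)
    if len(codes) != expr.shape[1]:
        raise ValueError("one group label per sample is required")
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < min_group_size:
        raise ValueError("every group needs at least 2 samples")
    x = expr.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression matrix contains missing values")
    f, p = anova_f(x, codes, n_groups, moderated=moderated)
    tbl = pd.DataFrame({"gene": expr.index.astype(str), "f": f, "p": p})
    # undefined F -> rank last; ties by descending F then gene id
    tbl["p_key"] = tbl["p"].fillna(np.inf)
    tbl["f_key"] = -tbl["f"].fillna(-np.inf)
    tbl = tbl.sort_values(["p_key", "f_key", "gene"], kind="mergesort")
    return GeneRanking(
        genes=tbl["gene"].tolist(),
        f_statistic=pd.Series(f, index=expr.index, name="F"),
        p_value=pd.Series(p, index=expr.index, name="p"),
    )


def _make_splitter(y: np.ndarray, folds: int, repeats: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        warnings.warn(
            "smallest class has fewer samples than folds; "
            "falling back to plain (unstratified) k-fold",
            stacklevel=3,
        )
        return [
            split
            for rep in range(repeats)
            for split in KFold(n_splits=folds, shuffle=True, random_state=seed + rep).split(y)
        ], repeats
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    return list(cv.split(np.zeros_like(y), y)), repeats


def evaluate_panels(
    expr: pd.DataFrame,
    groups: pd.Series | Sequence[str],
    sizes: Sequence[int] = tuple(range(4, 501)),
    folds: int = 10,
    repeats: int = 10,
    selection_mode: str = "inside_cv",
    seed: int = 0,
    moderated: bool = False,
    C: float = 1.0,
) -> list[PanelEvaluation]:
    """Cross-validated SVM accuracy for incrementally growing gene panels.

    For each panel size k, a linear SVM (C=1 by default) is trained on the
    top-k genes and scored by repeated stratified ``folds``-fold CV.
    Accuracy is the pooled fraction correct per repeat, averaged over
    repeats; balanced accuracy is reported alongside for imbalanced
    designs.  Fold assignment is controlled by ``seed``.
    """
    if selection_mode not in ("inside_cv", "outside_cv"):
        raise ValueError("selection_mode must be 'inside_cv' or 'outside_cv'")
    y = np.asarray(groups)
    if expr.shape[1] != len(y):
        raise ValueError("one group label per sample is required")
    if expr.shape[1] < folds:
        raise ValueError("need at least as many samples as folds")
    sizes = [int(k) for k in sizes]
    if max(sizes) > expr.shape[0]:
        raise ValueError("panel size exceeds the number of genes")

    splits, n_repeats = _make_splitter(y, folds, repeats, seed)
    folds_per_repeat = len(splits) // n_repeats
    x_all = expr.to_numpy(dtype=float)
    gene_index = expr.index

    global_rank = None
    if selection_mode == "outside_cv":
        global_rank = rank_genes(expr, y, moderated=moderated)

    # predictions pooled per repeat: correct counts per (repeat, size)
    correct = np.zeros((n_repeats, len(sizes)))
    total = np.zeros(n_repeats)
    preds_for_bal: dict[int, list] = {i: [] for i in range(len(sizes))}

    for fold_i, (train, test) in enumerate(splits):
        rep = fold_i // folds_per_repeat
        if selection_mode == "inside_cv":
            ranking = rank_genes(
                expr.iloc[:, train], y[train], moderated=moderated, min_group_size=1
            )
        else:
            ranking = global_rank
        order = gene_index.get_indexer(ranking.genes)
        total[rep] += len(test)
        single_class = len(np.unique(y[train])) < 2
        for si, k in enumerate(sizes):
            idx = order[:k]
            if single_class:  # degenerate unstratified fold: predict the only class
                pred = np.full(len(test), y[train][0])
            else:
                clf = SVC(kernel="linear", C=C)
                clf.fit(x_all[np.ix_(idx, train)].T, y[train])
                pred = clf.predict(x_all[np.ix_(idx, test)].T)
            correct[rep, si] += (pred == y[test]).sum()
            preds_for_bal[si].append((y[test], pred))

    evaluations = []
    top_genes_src = global_rank if global_rank is not None else rank_genes(expr, y, moderated=moderated)
    for si, k in enumerate(sizes):
        per_repeat = (correct[:, si] / total).tolist()
        y_true = np.concatenate([t for t, _ in preds_for_bal[si]])
        y_pred = np.concatenate([p for _, p in preds_for_bal[si]])
        evaluations.append(
            PanelEvaluation(
                panel_size=k,
                genes=top_genes_src.top(k),
                mean_cv_accuracy=float(np.mean(per_repeat)),
                per_repeat_accuracies=per_repeat,
                mean_balanced_accuracy=float(balanced_accuracy_score(y_true, y_pred)),
            )
        )
    return evaluations


def select_signature(evaluations: list[PanelEvaluation]) -> PanelEvaluation:
    """Best panel by mean CV accuracy; ties go to the smaller panel."""
    if not evaluations:
        raise ValueError("no evaluations to select from")
    return max(evaluations, key=lambda e: (e.mean_cv_accuracy, -e.panel_size))


def to_binary_labels(groups: pd.Series | Sequence[str]) -> np.ndarray:
    """Collapse S/MS/MR/R cohort labels to resistant-vs-other."""
    return np.where(np.asarray(groups) == "R", "resistant", "other")


def binary_mode(
    expr: pd.DataFrame,
    groups: pd.Series | Sequence[str],
    **kwargs,
) -> list[PanelEvaluation]:
    """The panel-evaluation pipeline with resistant-vs-rest labels.

    With a 3-vs-35 style imbalance the plain accuracy of a null classifier
    approaches the majority-class rate, so balanced accuracy is the
    informative column here.
    """
    return evaluate_panels(expr, to_binary_labels(groups), **kwargs)
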