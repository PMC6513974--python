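"""Robust feature selection and SVM evaluation.

The protocol repeats, over many independently drawn epochs, a stratified
one-quarter hold-out followed by an inner 3-fold split of the training rows
(two folds train the selection objective, one validates it).  With 20 trials
per subject per level this yields exactly 15 train / 5 test rows and, within
train, 10 selection-train / 5 validation rows per subject per level.

Two selectors are run per classification problem:

* UFS — features ranked by the mean one-way ANOVA F value over the epochs'
  selection-train rows;
* SFS — greedy forward selection with a Gaussian Naive Bayes wrapper scored on
  the validation fold, with a per-iteration majority vote over epochs.

Ordered feature lists are then evaluated by a linear one-against-one SVM
(C = 1) trained on each epoch's outer-train rows and scored on the held-out
quarter, giving an accuracy-vs-set-size curve whose first local maximum and
global maximum define the robust set sizes.

The F statistic and Gaussian NB are invariant to per-feature affine
rescaling, so no explicit z-scoring is needed ahead of them; the SVM stage
z-scores features with statistics fit on the outer-train rows only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .featurebank import FEATURE_NAMES, FeatureMatrix
from .synthgen import PainLevel


class ClassificationProblem(enum.Enum):
    """The four pain-level classification problems."""

    pain_threshold = (PainLevel.B, PainLevel.T1)
    pain_tolerance = (PainLevel.B, PainLevel.T4)
    three_class = (PainLevel.B, PainLevel.T1, PainLevel.T4)
    five_class = tuple(PainLevel)

    @property
    def levels(self) -> tuple[PainLevel, ...]:
        return self.value

    @property
    def n_classes(self) -> int:
        return len(self.value)


@dataclass
class EpochSplit:
    """One epoch's stratified outer hold-out and inner 3-fold partition."""

    epoch_id: int
    train_rows: np.ndarray
    test_rows: np.ndarray
    inner_folds: list[np.ndarray]   # 3 disjoint subsets of train_rows
    val_fold: int                   # which inner fold validates the wrapper
    rng_seed: int

    @property
    def fs_train_rows(self) -> np.ndarray:
        return np.sort(
            np.concatenate(
                [f for i, f in enumerate(self.inner_folds) if i != self.val_fold]
            )
        )

    @property
    def validation_rows(self) -> np.ndarray:
        return self.inner_folds[self.val_fold]


@dataclass
class RankingResult:
    order: list[str]                # descending mean F
    mean_f: pd.Series               # indexed by feature name
    per_epoch_f: pd.DataFrame       # epochs × features


@dataclass
class SFSVoteTable:
    votes: list[dict[str, int]]     # per iteration: feature → count over epochs
    consensus: list[str]            # top-voted feature per iteration
    per_epoch: list[list[str]]      # epoch → ordered selections
    accuracies: list[dict[str, float]]  # per iteration: feature → mean val accuracy
    frequency_order: list[str] = field(default_factory=list)
    # features by total selection count over all iterations — the "most
    # frequently selected" robust set, robust to epochs agreeing on the set
    # but not on the order in which its members enter


@dataclass
class AccuracyCurve:
    n_features: np.ndarray
    per_epoch: np.ndarray           # epochs × len(n_features)
    mean: np.ndarray
    sd: np.ndarray
    features: list[str]
    local_max_n: int = 0
    global_max_n: int = 0


def make_epoch_splits(
    matrix: FeatureMatrix,
    problem: ClassificationProblem,
    n_epochs: int,
    seed: int,
) -> list[EpochSplit]:
    """Stratified splits over the matrix rows belonging to the problem's levels.

    Per (subject, level) cell: one quarter (rounded) of the rows is held out
    for testing; the remaining train rows are dealt into 3 inner folds; one
    seed-chosen fold per epoch serves as the wrapper's validation set.
    """
    present = set(matrix.meta["level"])
    missing = [lv.name for lv in problem.levels if lv.name not in present]
    if missing:
        raise ValueError(f"levels absent from matrix: {missing}")
    level_names = [lv.name for lv in problem.levels]
    meta = matrix.meta
    cells: list[np.ndarray] = []
    for subj in meta["subject"].unique():
        for lv in level_names:
            rows = np.nonzero(((meta["subject"] == subj) & (meta["level"] == lv)).to_numpy())[0]
            if len(rows):
                cells.append(rows)
    root = np.random.default_rng(seed)
    epoch_seeds = root.integers(0, 2**31 - 1, size=n_epochs)
    splits = []
    for e in range(n_epochs):
        rng = np.random.default_rng(epoch_seeds[e])
        train, test = [], []
        folds: list[list[int]] = [[], [], []]
        for rows in cells:
            perm = rng.permutation(rows)
            n_test = int(round(len(rows) / 4))
            test.extend(perm[:n_test])
            tr = perm[n_test:]
            train.extend(tr)
            # deal train rows into 3 inner folds as evenly as possible
            for i, r in enumerate(tr):
                folds[i % 3].append(r)
        splits.append(
            EpochSplit(
                epoch_id=e,
                train_rows=np.sort(np.asarray(train)),
                test_rows=np.sort(np.asarray(test)),
                inner_folds=[np.sort(np.asarray(f)) for f in folds],
                val_fold=int(rng.integers(0, 3)),
                rng_seed=int(epoch_seeds[e]),
            )
        )
    return splits


def anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """Classical one-way ANOVA F = MS_between / MS_within.

    Zero within-class variance with unequal class means returns +inf (such a
    feature separates classes perfectly and sorts first).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 classes with >= 2 values each")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(values) - len(groups)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        return float("inf") if ms_between > 0 else 0.0
    return float(ms_between / ms_within)


def _problem_rows_labels(matrix: FeatureMatrix, problem: ClassificationProblem):
    labels = matrix.meta["level"].to_numpy()
    return labels


def ufs_rank(
    matrix: FeatureMatrix, problem: ClassificationProblem, splits: list[EpochSplit]
) -> RankingResult:
    """Rank features by mean F over the epochs' selection-train rows.

    Ties (including ties at +inf) break by registry order, which the stable
    sort over the registry-ordered columns provides.
    """
    X = matrix.values.to_numpy()
    labels = _problem_rows_labels(matrix, problem)
    names = list(matrix.values.columns)
    per_epoch = np.empty((len(splits), len(names)))
    for e, split in enumerate(splits):
        rows = split.fs_train_rows
        y = labels[rows]
        for j in range(len(names)):
            per_epoch[e, j] = anova_f(X[rows, j], y)
    mean_f = per_epoch.mean(axis=0)
    order_idx = np.argsort(-mean_f, kind="stable")
    return RankingResult(
        order=[names[i] for i in order_idx],
        mean_f=pd.Series(mean_f, index=names),
        per_epoch_f=pd.DataFrame(per_epoch, columns=names),
    )


def sfs_epoch(
    matrix: FeatureMatrix,
    problem: ClassificationProblem,
    split: EpochSplit,
    max_iters: int,
) -> tuple[list[str], list[float]]:
    """Greedy forward selection with a Gaussian NB wrapper for one epoch.

    At each iteration every remaining feature is scored by NB accuracy on the
    validation fold (trained on the two selection-train folds together with
    the already-selected features); the best joins the set.  Ties break by
    registry order.  Runs to ``max_iters`` so the full curve is available for
    post-hoc maxima.
    """
    if max_iters > len(matrix.values.columns):
        raise ValueError("max_iters exceeds feature count")
    X = matrix.values.to_numpy()
    labels = _problem_rows_labels(matrix, problem)
    tr = split.fs_train_rows
    va = split.validation_rows
    y_tr, y_va = labels[tr], labels[va]
    names = list(matrix.values.columns)
    # features constant on the selection-train rows carry no information for
    # the wrapper and would degenerate the NB variance estimate: skip them
    informative_cols = X[tr].var(axis=0) > 0
    remaining = list(range(len(names)))
    selected: list[int] = []
    accs: list[float] = []
    for _ in range(max_iters):
        best_j, best_acc = None, -np.inf
        for j in remaining:
            if not informative_cols[j] and selected:
                continue
            cols = selected + [j]
            if not informative_cols[j]:
                acc = -1.0  # degenerate candidate: only picked if nothing else exists
            else:
                clf = GaussianNB()
                clf.fit(X[np.ix_(tr, cols)], y_tr)
                acc = float(np.mean(clf.predict(X[np.ix_(va, cols)]) == y_va))
            if acc > best_acc:
                best_j, best_acc = j, acc
        selected.append(best_j)
        remaining.remove(best_j)
        accs.append(max(best_acc, 0.0))
    return [names[j] for j in selected], accs


def sfs_vote(per_epoch_selections: list[list[str]], per_epoch_accs: list[list[float]] | None = None) -> SFSVoteTable:
    """Per-iteration vote counts over epochs; consensus = top-voted feature,
    ties broken by registry order."""
    n_iters = min(len(s) for s in per_epoch_selections)
    reg_pos = {n: i for i, n in enumerate(FEATURE_NAMES)}
    votes, consensus, accs = [], [], []
    for i in range(n_iters):
        counts: dict[str, int] = {}
        acc_sums: dict[str, list[float]] = {}
        for e, sel in enumerate(per_epoch_selections):
            f = sel[i]
            counts[f] = counts.get(f, 0) + 1
            if per_epoch_accs is not None:
                acc_sums.setdefault(f, []).append(per_epoch_accs[e][i])
        top = sorted(counts, key=lambda f: (-counts[f], reg_pos.get(f, 1 << 30)))[0]
        votes.append(counts)
        consensus.append(top)
        accs.append({f: float(np.mean(a)) for f, a in acc_sums.items()})
    totals: dict[str, int] = {}
    for sel in per_epoch_selections:
        for f in sel[:n_iters]:
            totals[f] = totals.get(f, 0) + 1
    freq_order = sorted(totals, key=lambda f: (-totals[f], reg_pos.get(f, 1 << 30)))
    return SFSVoteTable(votes, consensus, per_epoch_selections, accs, freq_order)


def evaluate_curve(
    matrix: FeatureMatrix,
    problem: ClassificationProblem,
    ordered_features: list[str],
    splits: list[EpochSplit],
    C: float = 1.0,
    max_n: int | None = None,
) -> AccuracyCurve:
    """Held-out accuracy of a linear one-against-one SVM (C = 1) as features
    are added in the given order.  Features are z-scored with statistics fit
    on each epoch's outer-train rows."""
    feats = ordered_features[: max_n or len(ordered_features)]
    cols = [matrix.values.columns.get_loc(f) for f in feats]
    X = matrix.values.to_numpy()
    labels = _problem_rows_labels(matrix, problem)
    per_epoch = np.empty((len(splits), len(feats)))
    for e, split in enumerate(splits):
        tr, te = split.train_rows, split.test_rows
        mu = X[np.ix_(tr, cols)].mean(axis=0)
        sd = X[np.ix_(tr, cols)].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[np.ix_(tr, cols)] - mu) / sd
        Xte = (X[np.ix_(te, cols)] - mu) / sd
        for k in range(1, len(feats) + 1):
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
            clf.fit(Xtr[:, :k], labels[tr])
            per_epoch[e, k - 1] = float(np.mean(clf.predict(Xte[:, :k]) == labels[te]))
    curve = AccuracyCurve(
        n_features=np.arange(1, len(feats) + 1),
        per_epoch=per_epoch,
        mean=per_epoch.mean(axis=0),
        sd=per_epoch.std(axis=0, ddof=1) if len(splits) > 1 else np.zeros(len(feats)),
        features=feats,
    )
    curve.local_max_n, curve.global_max_n = curve_maxima(curve)
    return curve


def curve_maxima(curve: AccuracyCurve, alpha: float = 0.05) -> tuple[int, int]:
    """Robust set sizes from the accuracy curve.

    Local maximum: the smallest n at which adding the next feature gives no
    significant difference (epoch-paired t-test, p >= alpha) nor a substantive
    one (mean gain < 0.5 accuracy points).  Global maximum: the rounded mean
    over epochs of the smallest n attaining that epoch's peak accuracy.  A
    strictly improving curve yields local = global = N.
    """
    acc = curve.per_epoch
    n_epochs, n_steps = acc.shape
    global_n = int(round(np.mean([np.argmax(acc[e]) + 1 for e in range(n_epochs)])))
    local_n = n_steps
    for k in range(n_steps - 1):
        a, b = acc[:, k], acc[:, k + 1]
        gain = float(np.mean(b - a))
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(stats.ttest_rel(b, a).pvalue) if n_epochs > 1 else 1.0
        if (p >= alpha or not np.isfinite(p)) and gain < 0.005:
            local_n = k + 1
            break
    local_n = min(local_n, global_n)
    return max(local_n, 1), max(global_n, 1)


# ---------------------------------------------------------------------------
# Convenience driver for one classification problem
# ---------------------------------------------------------------------------

@dataclass
class ProblemResult:
    problem: ClassificationProblem
    ranking: RankingResult
    vote_table: SFSVoteTable
    ufs_curve: AccuracyCurve
    sfs_curve: AccuracyCurve


def run_problem(
    matrix: FeatureMatrix,
    problem: ClassificationProblem,
    n_epochs: int = 100,
    seed: int = 0,
    sfs_iters: int = 8,
    curve_max_n: int = 10,
    C: float = 1.0,
) -> ProblemResult:
    """Full selection + evaluation for one problem on the relevant rows."""
    rows = matrix.rows_for_levels(problem.levels)
    sub = FeatureMatrix(
        values=matrix.values.iloc[rows].reset_index(drop=True),
        meta=matrix.meta.iloc[rows].reset_index(drop=True),
        normalization=matrix.normalization,
    )
    splits = make_epoch_splits(sub, problem, n_epochs, seed)
    ranking = ufs_rank(sub, problem, splits)
    sels, accs = [], []
    for split in splits:
        s, a = sfs_epoch(sub, problem, split, sfs_iters)
        sels.append(s)
        accs.append(a)
    votes = sfs_vote(sels, accs)
    ufs_curve = evaluate_curve(sub, problem, ranking.order, splits, C, curve_max_n)
    sfs_curve = evaluate_curve(sub, problem, votes.frequency_order, splits, C, curve_max_n)
    return ProblemResult(problem, ranking, votes, ufs_curve, sfs_curve)


def _dedup_keep_order(names: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for n in names:
        if n not in seen:
            seen.add(n)
            out.append(n)
    return out
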