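"""Responder classification: LDA, greedy feature selection, repeated CV.

The classifier is a pooled-covariance linear discriminant analysis: with k
classes it yields k−1 canonical discriminant functions, and prediction is
the argmax of the class scores of the shared-covariance Gaussian model with
empirical priors.  A small ridge (default 1e-6) is added to the pooled
covariance diagonal because greedy selection may propose collinear
PC/KOOS subsets.

Feature subsets are chosen by sequential forward selection: starting from
no predictors, the candidate whose addition most reduces the k-fold
cross-validated misclassification error is added, until no candidate gives
a strict reduction (ties break to the first candidate in the deterministic
column order).  Ten iterations with re-randomized stratified folds give the
10×10-fold design whose per-iteration accuracies feed a one-way ANOVA with
Fisher's LSD pairwise tests across sensor sets.

Two evaluation modes exist.  ``"selection"`` (default) reports the
selection's own cross-validation accuracy — the procedure-faithful figure,
optimistically biased because the same folds steer the greedy search.
``"nested"`` runs the selection inside each training split of an outer CV
and scores held-out folds only, giving an approximately unbiased estimate
(used for permutation-null checks).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .preprocessing import PLACEMENTS
from .features import FeatureTable

DEFAULT_RIDGE = 1e-6


def enumerate_sensor_sets(sensors=PLACEMENTS) -> list:
    """All non-empty sensor subsets, ordered by size then lexicographically."""
    sensors = tuple(sensors)
    if not 1 <= len(sensors) <= 8:
        raise ValueError("need between 1 and 8 sensors")
    subsets = []
    for r in range(1, len(sensors) + 1):
        subsets.extend(itertools.combinations(sorted(sensors), r))
    subsets.sort(key=lambda s: (len(s), s))
    return subsets


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


@dataclass
class LdaModel:
    """Pooled-covariance linear discriminant model.

    ``scalings`` holds the canonical discriminant-function coefficients
    (features × k−1), the generalized eigenvectors of the between-class
    scatter against the pooled within-class covariance; ``weights``/
    ``intercepts`` implement the Gaussian Bayes prediction rule.
    """

    classes: np.ndarray
    means: np.ndarray  # k x d
    covariance: np.ndarray  # d x d, pooled + ridge
    priors: np.ndarray  # k
    scalings: np.ndarray  # d x (k-1)
    weights: np.ndarray = field(repr=False, default=None)  # k x d
    intercepts: np.ndarray = field(repr=False, default=None)  # k


def fit_lda(X, y, ridge: float = DEFAULT_RIDGE) -> LdaModel:
    """Fit the pooled-covariance LDA; requires ≥2 samples in ≥2 classes."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes in the training data")
    n, d = X.shape
    means = np.empty((k, d))
    S = np.zeros((d, d))
    counts = np.bincount(y_codes, minlength=k)
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"class(es) {small.tolist()} have fewer than 2 training samples")
    for c in range(k):
        Xc = X[y_codes == c]
        means[c] = Xc.mean(axis=0)
        D = Xc - means[c]
        S += D.T @ D
    cov = S / (n - k)
    cov[np.diag_indices(d)] += ridge
    priors = counts / n

    W = linalg.solve(cov, means.T, assume_a="pos").T  # k x d
    b = np.log(priors) - 0.5 * np.einsum("ij,ij->i", means, W)

    # canonical discriminant functions: eig of between-class scatter vs cov
    grand = priors @ means
    Mc = (means - grand) * np.sqrt(counts[:, None])
    Sb = Mc.T @ Mc / (n - k)
    evals, evecs = linalg.eigh(Sb, cov)
    n_funcs = min(k - 1, d)  # k-1 discriminant functions need at least k-1 features
    order = np.argsort(evals)[::-1][:n_funcs]
    scalings = evecs[:, order]
    flip = np.sign(scalings[np.abs(scalings).argmax(axis=0), np.arange(n_funcs)])
    flip[flip == 0] = 1.0
    scalings = scalings * flip

    return LdaModel(
        classes=classes,
        means=means,
        covariance=cov,
        priors=priors,
        scalings=scalings,
        weights=W,
        intercepts=b,
    )


def predict(model: LdaModel, X) -> np.ndarray:
    """Class labels by argmax of the linear discriminant scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    scores = X @ model.weights.T + model.intercepts
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def stratified_folds(labels, n_folds: int, rng: np.random.Generator) -> list:
    """Random stratified fold assignment by round-robin dealing.

    Each class's shuffled members are dealt across folds from a random
    starting fold, so per-fold class counts differ by at most one — even
    when a class has fewer members than there are folds (some folds then
    simply lack that class).  ``n_folds`` is capped at the number of
    subjects with a warning.
    """
    y = np.asarray(labels)
    n = len(y)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        warnings.warn(f"capping n_folds from {n_folds} to {n} (one subject per fold)")
        n_folds = n
    folds = [[] for _ in range(n_folds)]
    ptr = int(rng.integers(n_folds))  # continue dealing across classes so
    for c in np.unique(y):            # fold sizes stay balanced within one
        idx = rng.permutation(np.flatnonzero(y == c))
        for i in idx:
            folds[ptr % n_folds].append(int(i))
            ptr += 1
    return [np.array(sorted(f), dtype=int) for f in folds if f]


# ---------------------------------------------------------------------------
# cross-validated error kernel
# ---------------------------------------------------------------------------


class _FoldCache:
    """Precomputed per-fold train/test splits and class partitions."""

    def __init__(self, y_codes: np.ndarray, folds: list, n_classes: int):
        self.n = len(y_codes)
        self.k = n_classes
        self.y = y_codes
        self.splits = []
        all_idx = np.arange(self.n)
        for te in folds:
            tr = np.setdiff1d(all_idx, te)
            ytr = y_codes[tr]
            counts = np.bincount(ytr, minlength=n_classes)
            if (counts == 0).any():
                raise ValueError("a class is absent from a training fold")
            by_class = [tr[ytr == c] for c in range(n_classes)]
            logprior = np.log(counts / len(tr))
            self.splits.append((tr, te, by_class, counts, logprior))

    def majority_error(self) -> int:
        """Misclassifications of predicting each training fold's modal class."""
        wrong = 0
        for _, te, _, counts, _ in self.splits:
            maj = int(np.argmax(counts))
            wrong += int(np.count_nonzero(self.y[te] != maj))
        return wrong


def _cv_wrong(X: np.ndarray, cache: _FoldCache, ridge: float, stop_at: int | None = None) -> int:
    """Total CV misclassifications of LDA on feature matrix X.

    Stops early (returning a value ≥ ``stop_at``) once the running count
    can no longer beat ``stop_at`` — safe for strict-improvement searches.
    """
    d = X.shape[1]
    k = cache.k
    diag = np.diag_indices(d)
    wrong = 0
    for tr, te, by_class, counts, logprior in cache.splits:
        means = np.empty((k, d))
        S = np.zeros((d, d))
        for c in range(k):
            Xc = X[by_class[c]]
            mu = Xc.mean(axis=0)
            means[c] = mu
            D = Xc - mu
            S += D.T @ D
        S /= len(tr) - k
        S[diag] += ridge
        W = linalg.solve(S, means.T, assume_a="pos").T
        b = logprior - 0.5 * np.einsum("ij,ij->i", means, W)
        pred = np.argmax(X[te] @ W.T + b, axis=1)
        wrong += int(np.count_nonzero(pred != cache.y[te]))
        if stop_at is not None and wrong >= stop_at:
            return wrong
    return wrong


# ---------------------------------------------------------------------------
# sequential forward selection and repeated CV
# ---------------------------------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of (repeated) cross-validated forward selection."""

    sensor_set: tuple
    selected_feature_names: list  # from the best iteration, in inclusion order
    cv_error_trajectory: list  # errors after each added feature (best iteration)
    iteration_accuracies: np.ndarray  # one accuracy per iteration
    iteration_selected: list  # selected names per iteration
    mean_accuracy: float
    sd_accuracy: float
    mode: str = "selection"

    def formatted_accuracy(self) -> str:
        """Mean percent with SD as a proportion, e.g. '74.4 (0.02)%'."""
        return f"{100 * self.mean_accuracy:.1f} ({self.sd_accuracy:.2f})%"


def _run_sfs(X: np.ndarray, cache: _FoldCache, ridge: float):
    """Greedy forward selection; returns (selected idx, error trajectory)."""
    n = cache.n
    current = cache.majority_error()
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    trajectory: list[float] = []
    while remaining:
        best_j, best_wrong = None, current
        for j in remaining:
            wrong = _cv_wrong(X[:, selected + [j]], cache, ridge, stop_at=best_wrong)
            if wrong < best_wrong:
                best_j, best_wrong = j, wrong
        if best_j is None:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current = best_wrong
        trajectory.append(current / n)
    return selected, trajectory, current


def sequential_forward_selection(
    table: FeatureTable,
    folds: list,
    ridge: float = DEFAULT_RIDGE,
    sensor_set: tuple = (),
) -> SelectionResult:
    """One pass of CV-guided forward selection on fixed folds."""
    if table.n_features < 1:
        raise ValueError("no candidate features")
    X = table.features.to_numpy(dtype=float)
    classes, y_codes = np.unique(table.labels.to_numpy(), return_inverse=True)
    cache = _FoldCache(y_codes, folds, len(classes))
    selected, trajectory, wrong = _run_sfs(X, cache, ridge)
    names = [table.features.columns[j] for j in selected]
    acc = 1.0 - wrong / cache.n
    return SelectionResult(
        sensor_set=tuple(sensor_set),
        selected_feature_names=names,
        cv_error_trajectory=trajectory,
        iteration_accuracies=np.array([acc]),
        iteration_selected=[names],
        mean_accuracy=acc,
        sd_accuracy=0.0,
    )


def _nested_accuracy(
    X: np.ndarray,
    y_codes: np.ndarray,
    n_classes: int,
    outer_folds: list,
    n_folds: int,
    rng: np.random.Generator,
    ridge: float,
) -> float:
    """Held-out accuracy: SFS re-run inside each outer training split."""
    wrong = 0
    all_idx = np.arange(len(y_codes))
    for te in outer_folds:
        tr = np.setdiff1d(all_idx, te)
        ytr = y_codes[tr]
        inner = stratified_folds(ytr, min(n_folds, len(tr)), rng)
        cache = _FoldCache(ytr, inner, n_classes)
        selected, _, _ = _run_sfs(X[tr], cache, ridge)
        if selected:
            model = fit_lda(X[np.ix_(tr, selected)], ytr, ridge)
            pred = predict(model, X[np.ix_(te, selected)])
        else:
            maj = np.argmax(np.bincount(ytr, minlength=n_classes))
            pred = np.full(len(te), maj)
        wrong += int(np.count_nonzero(pred != y_codes[te]))
    return 1.0 - wrong / len(y_codes)


def repeated_cv_evaluation(
    table: FeatureTable,
    n_iterations: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    mode: str = "selection",
    sensor_set: tuple = (),
) -> SelectionResult:
    """Repeat fold randomization + forward selection ``n_iterations`` times.

    Iteration i uses the generator seeded with (seed, i), so the full
    10×10-fold design is reproducible from one master seed.
    """
    if mode not in ("selection", "nested"):
        raise ValueError(f"unknown mode {mode!r}")
    X = table.features.to_numpy(dtype=float)
    classes, y_codes = np.unique(table.labels.to_numpy(), return_inverse=True)
    k = len(classes)
    accs, all_names, trajectories = [], [], []
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])
        folds = stratified_folds(y_codes, n_folds, rng)
        if mode == "selection":
            cache = _FoldCache(y_codes, folds, k)
            selected, traj, wrong = _run_sfs(X, cache, ridge)
            accs.append(1.0 - wrong / cache.n)
            all_names.append([table.features.columns[j] for j in selected])
            trajectories.append(traj)
        else:
            accs.append(_nested_accuracy(X, y_codes, k, folds, n_folds, rng, ridge))
            all_names.append([])
            trajectories.append([])
    accs = np.asarray(accs)
    best_it = int(np.argmax(accs))
    return SelectionResult(
        sensor_set=tuple(sensor_set),
        selected_feature_names=all_names[best_it],
        cv_error_trajectory=trajectories[best_it],
        iteration_accuracies=accs,
        iteration_selected=all_names,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# sensor-set comparison: one-way ANOVA + Fisher's LSD
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """ANOVA across sensor sets with unprotected pairwise LSD t-tests."""

    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # set_a, set_b, mean_diff, t, p
    best_set: tuple
    equivalent_sets: list  # sets not significantly different from the best
    alpha: float


def _set_name(s: tuple) -> str:
    return "+".join(s)


def compare_sensor_sets(results: list, alpha: float = 0.05) -> ComparisonReport:
    """Compare per-iteration accuracies across sensor sets.

    One-way ANOVA followed by Fisher's LSD (pairwise t-tests using the
    pooled ANOVA mean-square error, unadjusted alpha).  Degenerate
    zero-variance data is handled explicitly: identical accuracy vectors
    compare with p = 1.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 sensor sets to compare")
    lengths = {len(r.iteration_accuracies) for r in results}
    if len(lengths) != 1:
        raise ValueError("all sensor sets must have equal iteration counts")
    n_iter = lengths.pop()
    if n_iter < 2:
        raise ValueError("need at least 2 iterations per set")

    groups = [np.asarray(r.iteration_accuracies, dtype=float) for r in results]
    k = len(groups)
    N = k * n_iter
    grand = np.concatenate(groups).mean()
    ss_between = n_iter * sum((g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, N - k
    mse = ss_within / df_w
    if mse == 0:
        f_stat = np.inf if ss_between > 0 else 0.0
        p_anova = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_b) / mse
        p_anova = float(stats.f.sf(f_stat, df_b, df_w))

    rows = []
    for (ia, ra), (ib, rb) in itertools.combinations(enumerate(results), 2):
        diff = groups[ia].mean() - groups[ib].mean()
        if mse == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(mse * (2.0 / n_iter))
            p = float(2 * stats.t.sf(abs(t), df_w))
        rows.append(
            {
                "set_a": _set_name(ra.sensor_set),
                "set_b": _set_name(rb.sensor_set),
                "mean_diff": diff,
                "t": t,
                "p": p,
            }
        )
    pairwise = pd.DataFrame(rows)

    best_idx = int(np.argmax([g.mean() for g in groups]))
    best = results[best_idx].sensor_set
    equivalent = []
    for i, r in enumerate(results):
        if i == best_idx:
            continue
        name_a, name_b = _set_name(best), _set_name(r.sensor_set)
        row = pairwise[
            ((pairwise.set_a == name_a) & (pairwise.set_b == name_b))
            | ((pairwise.set_a == name_b) & (pairwise.set_b == name_a))
        ].iloc[0]
        if row.p >= alpha:
            equivalent.append(r.sensor_set)
    return ComparisonReport(
        anova_f=float(f_stat),
        anova_p=p_anova,
        pairwise=pairwise,
        best_set=best,
        equivalent_sets=equivalent,
        alpha=alpha,
    )
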