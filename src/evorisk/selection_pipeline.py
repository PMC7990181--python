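"""Model-selection machinery: collinearity pruning, step-wise forward l0
selection tuned by inner CV, two-loop (nested) cross-validation with
replicates, bootstrap feature importance and the permutation control.

Randomness discipline: every stochastic component (pruning coin flips, fold
shuffles, inner folds, bootstrap draws, permutations) derives its generator
from ``(seed, stream id, replicate/fold indices)``, so identical
``(data, config, seed)`` always reproduce identical selections, predictions
and frequencies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .annotation_features import FeatureMatrix
from .survival_core import (
    DegenerateLikelihoodError,
    UndefinedMetricError,
    concordance_index,
    cox_fit,
)

log = logging.getLogger(__name__)

#: default lasso tuning grid (log-spaced between 0.03 and 30)
DEFAULT_LAMBDA_GRID = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)

_STREAM_FOLDS, _STREAM_PRUNE, _STREAM_INNER, _STREAM_BOOT, _STREAM_PERMUTE = range(5)


class EmptySelectionError(RuntimeError):
    """Step-wise selection could not accept even a single feature."""


@dataclass
class SelectionConfig:
    """Knobs for the selection pipeline; defaults follow the reference protocol."""

    corr_threshold: float = 0.8
    max_k: int = 10
    outer_folds: int = 3
    outer_repeats: int = 5
    inner_scheme: str = "kfold3"  # "kfold3" or "loocv"
    n_boot: int = 1000
    boot_feature_frac: float = 0.8
    boot_sample_frac: float = 0.8
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.boot_feature_frac <= 1 or not 0 < self.boot_sample_frac <= 1:
            raise ValueError("bootstrap fractions must be in (0, 1]")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        if self.inner_scheme not in ("kfold3", "loocv"):
            raise ValueError(f"unknown inner scheme {self.inner_scheme!r}")


@dataclass
class TwoLoopResult:
    """Held-out predictions and per-replicate concordance of a two-loop run."""

    predictions: pd.DataFrame  # columns: sample, replicate, fold, eta
    replicate_ci: np.ndarray
    mean_ci: float
    sd_ci: float
    selections: dict  # (replicate, fold) -> list of feature names

    def pooled_eta(self, replicate: int) -> pd.Series:
        """Held-out risk scores of one replicate, indexed by sample."""
        sub = self.predictions[self.predictions["replicate"] == replicate]
        return sub.set_index("sample")["eta"]


@dataclass
class ImportanceTable:
    """Per-feature selection frequency over bootstrap trials."""

    frequency: dict
    n_boot: int
    n_failed: int = 0


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in key])


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------


def prune_collinear(
    df: pd.DataFrame, threshold: float = 0.8, rng: np.random.Generator | None = None
):
    """Greedy collinearity pruning at |Pearson r| > ``threshold``.

    Zero-variance columns are dropped first (their correlation is
    undefined); then a single pass over column pairs drops one member of
    each still-alive flagged pair, chosen by a seeded coin flip.  Returns
    ``(reduced df, dropped log)`` where the log lists
    ``(dropped, kept, r)`` tuples (r is None for zero-variance drops).
    """
    rng = rng or np.random.default_rng(0)
    dropped_log = []
    variances = df.var(axis=0, ddof=0)
    alive = [c for c in df.columns if variances[c] > 0]
    for c in df.columns:
        if variances[c] == 0:
            dropped_log.append((c, None, None))
    if len(alive) < 2:
        return df[alive].copy(), dropped_log
    corr = df[alive].corr().abs()
    alive_set = set(alive)
    for i, ci in enumerate(alive):
        for cj in alive[i + 1 :]:
            if ci not in alive_set:
                break
            if cj not in alive_set:
                continue
            r = corr.loc[ci, cj]
            if r > threshold:
                victim, kept = (ci, cj) if rng.random() < 0.5 else (cj, ci)
                alive_set.discard(victim)
                dropped_log.append((victim, kept, float(r)))
    kept_cols = [c for c in alive if c in alive_set]
    return df[kept_cols].copy(), dropped_log


# ---------------------------------------------------------------------------
# Inner CV scoring
# ---------------------------------------------------------------------------


def _fold_ids(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    ids = np.empty(n, dtype=int)
    ids[rng.permutation(n)] = np.arange(n) % k
    return ids


def outer_fold_assignments(
    n: int,
    n_folds: int,
    rng: np.random.Generator,
    delta: np.ndarray | None = None,
    max_tries: int = 100,
) -> np.ndarray:
    """Shuffled outer-fold ids; folds without any event are resampled."""
    for attempt in range(max_tries):
        ids = _fold_ids(n, n_folds, rng)
        if delta is None:
            return ids
        ok = all((delta[ids == f].sum() >= 1) and (delta[ids != f].sum() >= 1) for f in range(n_folds))
        if ok:
            if attempt > 0:
                warnings.warn(f"resampled outer folds {attempt} time(s) to avoid event-free folds")
            return ids
    raise DegenerateLikelihoodError("could not draw outer folds with events in every fold")


def _inner_cv_ci(
    X: np.ndarray,
    y: np.ndarray,
    delta: np.ndarray,
    cols: list[int],
    scheme: str,
    inner_ids: np.ndarray | None,
    l1_penalty: float = 0.0,
) -> float:
    """Inner-CV concordance of a Cox fit on the given columns.

    kfold3: mean of per-fold test CIs.  loocv: all held-out risk scores are
    pooled first, then a single CI is computed (a per-fold CI is undefined
    for n=1).  Returns -inf when no fold yields a defined score.
    """
    Xc = X[:, cols]
    n = len(y)
    if scheme == "loocv":
        eta = np.full(n, np.nan)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                model = cox_fit(Xc[mask], y[mask], delta[mask], l1_penalty=l1_penalty)
            except (DegenerateLikelihoodError, np.linalg.LinAlgError):
                continue
            eta[i] = model.risk_scores(Xc[i : i + 1])[0]
        ok = ~np.isnan(eta)
        if ok.sum() < 2:
            return -np.inf
        try:
            return concordance_index(eta[ok], y[ok], delta[ok])
        except UndefinedMetricError:
            return -np.inf
    scores = []
    for f in np.unique(inner_ids):
        test = inner_ids == f
        train = ~test
        if delta[train].sum() == 0:
            continue
        try:
            model = cox_fit(Xc[train], y[train], delta[train], l1_penalty=l1_penalty)
            scores.append(concordance_index(model.risk_scores(Xc[test]), y[test], delta[test]))
        except (DegenerateLikelihoodError, UndefinedMetricError, np.linalg.LinAlgError):
            continue
    return float(np.mean(scores)) if scores else -np.inf


# ---------------------------------------------------------------------------
# Step-wise forward l0 selection
# ---------------------------------------------------------------------------


def stepwise_l0(
    df: pd.DataFrame,
    y: np.ndarray,
    delta: np.ndarray,
    inner_scheme: str = "kfold3",
    max_k: int = 10,
    rng: np.random.Generator | None = None,
    baseline_ci: float = 0.5,
):
    """Greedy forward selection scored by inner-CV concordance.

    The best-scoring single feature is always taken first; from the second
    step on, every unselected feature is joined to the current set and the
    best is accepted only on strict improvement, stopping otherwise or at
    ``max_k``.  Ties break toward the lowest column index.  Returns
    ``(selected names, trace)`` where trace holds ``(feature, inner CI)``
    per accepted step.
    """
    rng = rng or np.random.default_rng(0)
    X = df.to_numpy(dtype=float)
    if X.shape[1] == 0:
        raise EmptySelectionError("no candidate features")
    n, p = X.shape
    inner_ids = _fold_ids(n, 3, rng) if inner_scheme == "kfold3" else None
    selected: list[int] = []
    trace: list[tuple[str, float]] = []
    best = baseline_ci
    while len(selected) < min(max_k, p):
        best_j, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            score = _inner_cv_ci(X, y, delta, selected + [j], inner_scheme, inner_ids)
            if score > best_score:  # strict: ties keep the lowest index
                best_j, best_score = j, score
        if not selected:
            if not np.isfinite(best_score):
                raise EmptySelectionError("every single-feature fit failed at the first step")
        elif best_j is None or not best_score > best:
            break
        selected.append(best_j)
        best = best_score
        trace.append((df.columns[best_j], float(best_score)))
    return [df.columns[j] for j in selected], trace


def _tune_lasso(
    df: pd.DataFrame,
    y: np.ndarray,
    delta: np.ndarray,
    grid,
    inner_scheme: str,
    rng: np.random.Generator,
) -> float:
    X = df.to_numpy(dtype=float)
    inner_ids = _fold_ids(len(y), 3, rng) if inner_scheme == "kfold3" else None
    cols = list(range(X.shape[1]))
    best_lam, best_score = grid[0], -np.inf
    for lam in grid:
        score = _inner_cv_ci(X, y, delta, cols, inner_scheme, inner_ids, l1_penalty=lam)
        if score > best_score:
            best_lam, best_score = lam, score
    return best_lam


# ---------------------------------------------------------------------------
# Two-loop cross-validation
# ---------------------------------------------------------------------------


def _zscore_train_test(train: pd.DataFrame, test: pd.DataFrame):
    """Standardize continuous columns using training statistics only.

    A column is treated as continuous unless its training values are all in
    {0, 1}.  Zero-variance columns are left as-is (pruning removes them)."""
    train = train.copy()
    test = test.copy()
    for col in train.columns:
        vals = train[col].to_numpy(dtype=float)
        if np.isin(np.unique(vals), (0.0, 1.0)).all():
            continue
        sd = vals.std()
        if sd == 0:
            continue
        mu = vals.mean()
        train[col] = (train[col] - mu) / sd
        test[col] = (test[col] - mu) / sd
    return train, test


def two_loop_cv(
    features: FeatureMatrix | pd.DataFrame,
    y,
    delta,
    config: SelectionConfig,
    model: str = "l0",
) -> TwoLoopResult:
    """Nested cross-validation with replicates.

    Per replicate the samples are shuffled into ``outer_folds`` folds; on
    each training fold the pipeline standardizes continuous features, prunes
    collinear ones, tunes the model (step-wise l0 or lasso) with the inner
    CV, refits on the whole training fold and scores the held-out fold.
    The concordance index is computed per replicate on the pooled held-out
    risk scores; ``mean_ci``/``sd_ci`` aggregate over replicates.
    """
    if model not in ("l0", "lasso"):
        raise ValueError(f"unknown model {model!r}")
    df = features.values if isinstance(features, FeatureMatrix) else features
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    n = len(df)
    if n != len(y):
        raise ValueError("feature matrix and outcomes are not aligned")
    samples = np.asarray(df.index)
    rows = []
    selections = {}
    replicate_ci = []
    for rep in range(config.outer_repeats):
        fold_ids = outer_fold_assignments(
            n, config.outer_folds, _rng(config.seed, _STREAM_FOLDS, rep), delta
        )
        eta_pooled = np.full(n, np.nan)
        for f in range(config.outer_folds):
            test_mask = fold_ids == f
            train_mask = ~test_mask
            tr_df, te_df = _zscore_train_test(df.loc[train_mask], df.loc[test_mask])
            pruned, _ = prune_collinear(
                tr_df, config.corr_threshold, _rng(config.seed, _STREAM_PRUNE, rep, f)
            )
            y_tr, d_tr = y[train_mask], delta[train_mask]
            rng_inner = _rng(config.seed, _STREAM_INNER, rep, f)
            if model == "l0":
                chosen, _trace = stepwise_l0(
                    pruned, y_tr, d_tr, config.inner_scheme, config.max_k, rng_inner
                )
                if chosen:
                    fit = cox_fit(pruned[chosen].to_numpy(), y_tr, d_tr, feature_names=chosen)
                    eta_test = fit.risk_scores(te_df[chosen].to_numpy())
                else:
                    eta_test = np.zeros(int(test_mask.sum()))
                selections[(rep, f)] = list(chosen)
            else:
                lam = _tune_lasso(pruned, y_tr, d_tr, config.lambda_grid, config.inner_scheme, rng_inner)
                fit = cox_fit(
                    pruned.to_numpy(), y_tr, d_tr,
                    feature_names=list(pruned.columns), l1_penalty=lam,
                )
                eta_test = fit.risk_scores(te_df[pruned.columns].to_numpy())
                selections[(rep, f)] = [
                    name for name, b in zip(fit.feature_names, fit.beta) if b != 0.0
                ]
            eta_pooled[test_mask] = eta_test
            for s, e, in zip(samples[test_mask], eta_test):
                rows.append({"sample": s, "replicate": rep, "fold": f, "eta": float(e)})
        try:
            replicate_ci.append(concordance_index(eta_pooled, y, delta))
        except UndefinedMetricError:
            replicate_ci.append(np.nan)
    replicate_ci = np.asarray(replicate_ci, dtype=float)
    return TwoLoopResult(
        predictions=pd.DataFrame(rows),
        replicate_ci=replicate_ci,
        mean_ci=float(np.nanmean(replicate_ci)),
        sd_ci=float(np.nanstd(replicate_ci, ddof=1)) if len(replicate_ci) > 1 else 0.0,
        selections=selections,
    )


# ---------------------------------------------------------------------------
# Bootstrap importance and permutation control
# ---------------------------------------------------------------------------


def bootstrap_importance(
    features: FeatureMatrix | pd.DataFrame,
    y,
    delta,
    config: SelectionConfig,
) -> ImportanceTable:
    """Selection frequency over bootstrap trials.

    Each trial draws ``boot_feature_frac`` of the features (without
    replacement) and ``boot_sample_frac`` of the samples (with replacement),
    prunes, runs step-wise l0 selection with the inner CV and records the
    selected set.  Trial-level failures are logged and counted; more than
    10% failed trials is a hard error.
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    n, p = df.shape
    n_feat = max(1, int(np.floor(config.boot_feature_frac * p)))
    n_samp = max(2, int(np.floor(config.boot_sample_frac * n)))
    counts = {c: 0 for c in df.columns}
    n_failed = 0
    for t in range(config.n_boot):
        rng = _rng(config.seed, _STREAM_BOOT, t)
        feat_idx = np.sort(rng.choice(p, size=n_feat, replace=False))
        samp_idx = rng.choice(n, size=n_samp, replace=True)
        sub = df.iloc[samp_idx, feat_idx].reset_index(drop=True)
        y_t, d_t = y[samp_idx], delta[samp_idx]
        if d_t.sum() == 0:
            n_failed += 1
            continue
        try:
            pruned, _ = prune_collinear(sub, config.corr_threshold, rng)
            chosen, _trace = stepwise_l0(
                pruned, y_t, d_t, config.inner_scheme, config.max_k, rng
            )
        except (DegenerateLikelihoodError, UndefinedMetricError, EmptySelectionError,
                np.linalg.LinAlgError) as exc:
            log.debug("bootstrap trial %d failed: %s", t, exc)
            n_failed += 1
            continue
        for name in chosen:
            counts[name] += 1
    if n_failed > 0.1 * config.n_boot:
        raise RuntimeError(f"{n_failed}/{config.n_boot} bootstrap trials failed")
    freq = {c: counts[c] / config.n_boot for c in df.columns}
    return ImportanceTable(frequency=freq, n_boot=config.n_boot, n_failed=n_failed)


def permutation_control(
    features: FeatureMatrix | pd.DataFrame,
    y,
    delta,
    config: SelectionConfig,
    model: str = "l0",
    permutation: np.ndarray | None = None,
) -> TwoLoopResult:
    """Two-loop CV after permuting feature values across samples.

    By default every feature column is shuffled independently with a seeded
    permutation, breaking any feature-outcome association while outcomes stay
    fixed.  Passing an explicit ``permutation`` applies that single row
    permutation to all columns (the identity permutation reproduces the
    unpermuted run exactly).
    """
    df = (features.values if isinstance(features, FeatureMatrix) else features).copy()
    n = len(df)
    if permutation is not None:
        df.iloc[:, :] = df.to_numpy()[np.asarray(permutation)]
    else:
        rng = _rng(config.seed, _STREAM_PERMUTE)
        for col in df.columns:
            df[col] = df[col].to_numpy()[rng.permutation(n)]
    return two_loop_cv(df, y, delta, config, model=model)


# ---------------------------------------------------------------------------
# Correlation landscape
# ---------------------------------------------------------------------------


def correlation_landscape(features: FeatureMatrix | pd.DataFrame):
    """Pairwise Pearson matrix plus a Ward-linkage display ordering.

    Zero-variance features have undefined correlation and are reported in
    the third return value instead of appearing in the matrix.
    Returns ``(corr DataFrame, ordered feature names, missing features)``.
    """
    df = features.values if isinstance(features, FeatureMatrix) else features
    if df.shape[1] < 2:
        raise ValueError("need at least two features")
    variances = df.var(axis=0, ddof=0)
    missing = [c for c in df.columns if variances[c] == 0]
    ok = [c for c in df.columns if variances[c] > 0]
    corr = df[ok].corr()
    standardized = (df[ok] - df[ok].mean()) / df[ok].std(ddof=0)
    link = hierarchy.linkage(standardized.to_numpy().T, method="ward")
    order = [ok[i] for i in hierarchy.leaves_list(link)]
    return corr, order, missing
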