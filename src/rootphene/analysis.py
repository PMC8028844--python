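"""Statistical stage: scaling, correlations, clustering, repeated
random-forest variable importance with reduced-model refit, temporal
trajectory classification, and the aggregate-metric degeneracy search.

The random-forest importance measure is the permutation-based increase in
out-of-bag (OOB) mean squared error, averaged over trees -- the regression
analog of "mean decrease in accuracy".  The forest is refit ``n_repeats``
times (default 50) with distinct seeds; a predictor is selected when its
importance is positive at the 90% level across repeats (its 10th
percentile exceeds zero).  A pooled-percentile thresholding mode is also
available.  The reduced model (selected predictors only) is accepted when
its OOB R-squared is within 2 percentage points of the full model or
better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor


# ---------------------------------------------------------------------------
# scaling / correlation / clustering
# ---------------------------------------------------------------------------

def scale_minmax(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Columnwise (x - min) / (max - min); constant columns map to 0 and
    are returned in the flagged list."""
    out = df.copy().astype(float)
    flagged = []
    for col in out.columns:
        x = out[col]
        lo, hi = x.min(), x.max()
        if not np.isfinite(hi - lo) or hi - lo <= 0:
            out[col] = 0.0
            flagged.append(col)
        else:
            out[col] = (x - lo) / (hi - lo)
    return out, flagged


def spearman_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlation matrix of the columns."""
    if len(df) < 3:
        raise ValueError("need at least 3 rows")
    return df.corr(method="spearman")


def hcluster(df: pd.DataFrame):
    """Average-linkage hierarchical clustering of the rows.

    Distance between phenotypes is 1 - Spearman correlation of their
    (scaled) phene vectors.  Returns (linkage matrix, leaf order).
    Ties are broken deterministically by row index (scipy's stable
    ordering over the condensed distance vector).
    """
    if len(df) < 2:
        raise ValueError("need at least 2 rows")
    rho = np.atleast_2d(df.T.corr(method="spearman").to_numpy())
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    from scipy.cluster.hierarchy import leaves_list
    return Z, leaves_list(Z).tolist()


# ---------------------------------------------------------------------------
# random forest importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    response: str
    predictors: list[str]
    samples: np.ndarray            # (n_repeats, p) OOB-MSE increases
    threshold: float               # pooled 90th percentile (reported)
    selected: list[str]
    r2_full: float                 # OOB % variance explained, 0-100
    r2_reduced: float
    reduced_ok: bool
    selection_rule: str = "sig90"
    notes: list[str] = field(default_factory=list)


def _oob_importance(rf: RandomForestRegressor, X: np.ndarray,
                    y: np.ndarray, rng) -> np.ndarray:
    """Mean increase in OOB MSE per predictor when it is permuted,
    averaged over trees (R randomForest %IncMSE, unscaled)."""
    n, p = X.shape
    totals = np.zeros(p)
    used = 0
    for tree, sampled in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size < 5:
            continue
        Xo = X[oob]
        yo = y[oob]
        # one stacked predict per tree: [original, perm_1, ..., perm_p]
        blocks = [Xo]
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[rng.permutation(oob.size), j]
            blocks.append(Xp)
        preds = tree.predict(np.vstack(blocks))
        preds = preds.reshape(p + 1, oob.size)
        errs = np.mean((preds - yo[None, :]) ** 2, axis=1)
        totals += errs[1:] - errs[0]
        used += 1
    if used == 0:
        raise RuntimeError("no tree had enough OOB samples")
    return totals / used


def _fit_oob_r2(X: np.ndarray, y: np.ndarray, ntree: int, mtry: int,
                seed: int) -> RandomForestRegressor:
    rf = RandomForestRegressor(
        n_estimators=ntree, max_features=min(mtry, X.shape[1]),
        oob_score=True, bootstrap=True, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf


def rf_importance(X: pd.DataFrame, y: pd.Series, response: str = "response",
                  n_repeats: int = 50, ntree: int = 1000, mtry: int = 8,
                  threshold_pct: float = 90.0, seed: int = 0,
                  selection_rule: str = "sig90") -> ImportanceResult:
    """Repeated random-forest regression with OOB permutation importance.

    Selection rules:

    - ``"sig90"`` (default): a predictor is selected when the 10th
      percentile of its importance distribution over repeats exceeds 0,
      i.e. its OOB-MSE increase is positive at the 90% significance level.
    - ``"pooled"``: threshold at the ``threshold_pct`` percentile of the
      pooled importance samples; select predictors whose median exceeds it.
    """
    notes = []
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    names = list(X.columns)
    n, p = Xv.shape
    if np.nanstd(yv) == 0:
        raise ValueError("response is constant")
    if n < 50:
        notes.append(f"only {n} rows; >=50 recommended")
    if mtry > p:
        notes.append(f"mtry={mtry} clamped to p={p}")
    master = np.random.SeedSequence(seed)
    seeds = master.generate_state(2 * n_repeats)

    samples = np.empty((n_repeats, p))
    r2s = np.empty(n_repeats)
    for i in range(n_repeats):
        rf = _fit_oob_r2(Xv, yv, ntree, mtry, int(seeds[i] % (2**31 - 1)))
        r2s[i] = rf.oob_score_
        rng = np.random.default_rng(seeds[n_repeats + i])
        samples[i] = _oob_importance(rf, Xv, yv, rng)

    pooled_threshold = float(np.percentile(samples, threshold_pct))
    medians = np.median(samples, axis=0)
    if selection_rule == "pooled":
        sel_mask = medians > pooled_threshold
    elif selection_rule == "sig90":
        q10 = np.quantile(samples, 0.10, axis=0)
        sel_mask = q10 > 0.0
    else:
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    selected = [nm for nm, s in zip(names, sel_mask) if s]
    if not selected:
        notes.append("no predictor selected (all importances ~<= 0)")

    r2_full = float(np.mean(r2s) * 100.0)
    if selected:
        idx = [names.index(s) for s in selected]
        red = np.empty(n_repeats)
        for i in range(n_repeats):
            rf = _fit_oob_r2(Xv[:, idx], yv, ntree, mtry,
                             int(seeds[i] % (2**31 - 1)))
            red[i] = rf.oob_score_
        r2_reduced = float(np.mean(red) * 100.0)
    else:
        r2_reduced = float("nan")
    reduced_ok = bool(np.isfinite(r2_reduced) and
                      r2_reduced >= r2_full - 2.0)
    return ImportanceResult(
        response=response, predictors=names, samples=samples,
        threshold=pooled_threshold, selected=selected,
        r2_full=r2_full, r2_reduced=r2_reduced, reduced_ok=reduced_ok,
        selection_rule=selection_rule, notes=notes)


def importance_summary(results: list[ImportanceResult]) -> pd.DataFrame:
    """Table-style summary: one row per response metric with full and
    reduced OOB R-squared and the selected predictors."""
    rows = []
    for r in results:
        rows.append({
            "metric": r.response,
            "r2_full": r.r2_full,
            "r2_reduced": r.r2_reduced,
            "reduced_ok": r.reduced_ok,
            "selected": ";".join(r.selected),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal dynamics
# ---------------------------------------------------------------------------

def classify_trajectory(days, values, rho_threshold: float = 0.7) -> str:
    """'increasing' / 'decreasing' / 'static' / 'neither' by the sign and
    strength of Spearman rho between day and value."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        return "neither"
    v = values[ok]
    # near-constant series are static regardless of drift direction
    rel = (v.max() - v.min()) / max(abs(np.median(v)), 1e-12)
    if rel < 0.05:
        return "static"
    rho = spearmanr(days[ok], v).statistic
    if np.isnan(rho):
        return "static"
    if rho > rho_threshold:
        return "increasing"
    if rho < -rho_threshold:
        return "decreasing"
    return "neither"


def timecourse(table: pd.DataFrame, day_col: str = "day",
               rho_threshold: float = 0.7) -> pd.DataFrame:
    """Classify each metric column's trajectory across days.

    ``table`` holds one row per day (for one phenotype) with metric
    columns; returns metric -> class long table.
    """
    days = table[day_col].to_numpy()
    rows = []
    for col in table.columns:
        if col == day_col:
            continue
        rows.append({"metric": col,
                     "trajectory": classify_trajectory(
                         days, table[col].to_numpy(), rho_threshold)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# degeneracy of aggregate metrics
# ---------------------------------------------------------------------------

@dataclass
class DegeneracyGroup:
    reference: object
    members: list
    metric_values: np.ndarray
    phene_range: pd.Series      # per-phene max-min on the min-max scale
    max_range: float


def aggregate_degeneracy_search(metric_values: pd.Series,
                                phenes: pd.DataFrame,
                                tol: float = 0.01,
                                min_group: int = 2) -> list[DegeneracyGroup]:
    """Find groups of phenotypes nearly identical in one aggregate metric
    but (possibly) very different in their phenes.

    Phenotypes within relative tolerance ``tol`` of a reference value form
    a group; for each group the spread of every phene is reported on the
    min-max scale of the whole batch.  Groups are reported largest
    phene-spread first, so the head of the list is the strongest evidence
    that the metric is a degenerate summary of the phenotype.
    """
    scaled, _ = scale_minmax(phenes)
    vals = metric_values.astype(float)
    order = vals.sort_values().index
    groups: list[DegeneracyGroup] = []
    used: set = set()
    for ref in order:
        if ref in used:
            continue
        v0 = vals[ref]
        if not np.isfinite(v0) or v0 == 0:
            continue
        members = vals.index[(np.abs(vals - v0) <= tol * abs(v0))].tolist()
        if len(members) < min_group:
            continue
        rng_ = scaled.loc[members].max() - scaled.loc[members].min()
        groups.append(DegeneracyGroup(
            reference=ref, members=members,
            metric_values=vals[members].to_numpy(),
            phene_range=rng_, max_range=float(rng_.max())))
        used.update(members)
    groups.sort(key=lambda g: -g.max_range)
    return groups
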