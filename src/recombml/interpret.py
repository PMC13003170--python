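"""Accumulated local effects (ALE) and Friedman H interaction statistics.

Both are implemented from first principles on top of a bare prediction
callable, so they work with any fitted model. ALE measures how moving a
single predictor across its local quantile intervals shifts the prediction
while holding each observation's other features fixed — robust to the strong
feature correlations in this domain, unlike partial-dependence marginals.
The H-statistics quantify how much of a model's prediction variance is
attributable to interactions (overall: one feature against all others
combined; pairwise: one feature pair), from Monte-Carlo partial-dependence
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["ALECurve", "HReport", "ale_curve", "h_overall", "h_pairwise", "h_report"]

PredictFn = Callable[[pd.DataFrame], np.ndarray]


@dataclass(frozen=True)
class ALECurve:
    """Centered accumulated local effect curve of one feature.

    ``edges`` are the (deduplicated) quantile interval edges, ``effects`` the
    centered accumulated effects at those edges, and ``counts`` the number of
    observations in each of the ``len(edges) - 1`` intervals.
    """

    feature: str
    edges: np.ndarray
    effects: np.ndarray
    counts: np.ndarray
    binary: bool = False

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"edge": self.edges, "effect": self.effects})

    def argmax_edge(self) -> float:
        """Feature value (edge) at which the centered effect is maximal."""
        return float(self.edges[int(np.argmax(self.effects))])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.edges, self.effects, marker="o", ms=3)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_xlabel(self.feature)
        ax.set_ylabel("ALE")
        return ax


def ale_curve(predict: PredictFn, X: pd.DataFrame, feature: str, K: int = 20) -> ALECurve:
    """First-order ALE curve of ``feature`` for a fitted model.

    Interval edges are empirical quantiles of the feature (duplicates
    merged); for each interval the local effect is the mean, over its
    observations, of the prediction with the feature set to the upper edge
    minus the prediction at the lower edge. Local effects are accumulated
    and centered. Continuous features are centered with the ALEPlot
    interval-midpoint rule; a binary 0/1 feature uses the two-level
    categorical variant, centered by level counts so the two values are the
    count-weighted-zero group effects.
    """
    x = X[feature].to_numpy(dtype=float)
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError(f"feature {feature!r} is constant")
    binary = uniq.size == 2
    if binary:
        edges = uniq.astype(float)
    else:
        qs = np.quantile(x, np.linspace(0, 1, K + 1))
        edges = np.unique(qs)
    n_int = edges.size - 1
    # interval of each observation: k such that edges[k] < x <= edges[k+1], first interval closed
    idx = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_int - 1)
    counts = np.bincount(idx, minlength=n_int).astype(float)

    deltas = np.zeros(n_int)
    for k in range(n_int):
        rows = idx == k
        if not rows.any():
            continue
        lo = X.loc[rows].copy()
        hi = X.loc[rows].copy()
        lo[feature] = edges[k]
        hi[feature] = edges[k + 1]
        deltas[k] = float(np.mean(np.asarray(predict(hi)) - np.asarray(predict(lo))))
    accumulated = np.concatenate([[0.0], np.cumsum(deltas)])

    n = counts.sum()
    if binary:
        # level counts: observations at the lower/upper level
        n0 = float((x == edges[0]).sum())
        n1 = float((x == edges[1]).sum())
        center = accumulated[1] * n1 / (n0 + n1)
    else:
        center = float(np.sum(counts * (accumulated[:-1] + accumulated[1:]) / 2.0) / n)
    return ALECurve(
        feature=feature,
        edges=edges,
        effects=accumulated - center,
        counts=counts,
        binary=binary,
    )


# ---------------------------------------------------------------------------
# H statistics


def _pd_profile(predict: PredictFn, X: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Monte-Carlo partial dependence of ``cols`` evaluated at each row.

    PD_S(x_S^(i)) = mean_j f(x_S^(i), x_{-S}^(j)): for each observation i the
    columns in S are fixed at row i's values while the complement cycles over
    the whole sample. Returns a centered length-n vector. O(n^2) model
    evaluations, done in one batched call.
    """
    n = len(X)
    base = pd.DataFrame(
        np.tile(X.to_numpy(dtype=float), (n, 1)), columns=X.columns
    )  # n blocks of the full sample
    for c in cols:
        base[c] = np.repeat(X[c].to_numpy(dtype=float), n)
    preds = np.asarray(predict(base), dtype=float).reshape(n, n)
    pd_vals = preds.mean(axis=1)
    return pd_vals - pd_vals.mean()


def _subsample(X: pd.DataFrame, n_sample: int | None, seed: int) -> pd.DataFrame:
    if n_sample is None or n_sample >= len(X):
        return X.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    take = rng.choice(len(X), size=n_sample, replace=False)
    return X.iloc[np.sort(take)].reset_index(drop=True)


def h_pairwise(
    predict: PredictFn,
    X: pd.DataFrame,
    j: str,
    k: str,
    n_sample: int | None = 500,
    seed: int = 0,
) -> float:
    """Friedman H for the feature pair (j, k).

    H^2 = sum[PD_jk - PD_j - PD_k]^2 / sum[PD_jk^2] with all partial
    dependences centered; H = sqrt(H^2) in [0, 1]. 0 means the joint effect
    is additive in the two features; 1 means it is pure interaction.
    """
    S = _subsample(X, n_sample, seed)
    pd_jk = _pd_profile(predict, S, [j, k])
    pd_j = _pd_profile(predict, S, [j])
    pd_k = _pd_profile(predict, S, [k])
    denom = float(np.sum(pd_jk**2))
    if denom == 0:
        return 0.0
    h2 = float(np.sum((pd_jk - pd_j - pd_k) ** 2)) / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


def h_overall(
    predict: PredictFn,
    X: pd.DataFrame,
    feature: str,
    n_sample: int | None = 500,
    seed: int = 0,
) -> float:
    """Friedman H of one feature against all remaining features combined.

    H^2 = sum[f - PD_j - PD_-j]^2 / sum[f^2] over the (sub)sample, all terms
    centered. Values near 0 mean the feature contributes additively.
    """
    S = _subsample(X, n_sample, seed)
    others = [c for c in S.columns if c != feature]
    f_vals = np.asarray(predict(S), dtype=float)
    f_vals = f_vals - f_vals.mean()
    pd_j = _pd_profile(predict, S, [feature])
    pd_rest = _pd_profile(predict, S, others)
    denom = float(np.sum(f_vals**2))
    if denom == 0:
        return 0.0
    h2 = float(np.sum((f_vals - pd_j - pd_rest) ** 2)) / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


@dataclass(frozen=True)
class HReport:
    """Overall H per feature and H per feature pair, with the sample size used.

    Pairs of mutually correlated features carry a ``collinear`` flag: for such
    pairs the H ratio is positively biased toward 1 (both marginal partial
    dependences absorb the shared signal, so their sum double-counts it), and
    the value should not be read as interaction strength.
    """

    overall: pd.Series
    pairwise: pd.DataFrame = field(repr=False)  # feature_1, feature_2, h, collinear
    n_sample: int

    def top_pair(self) -> tuple[str, str, float]:
        """Strongest interacting pair, skipping collinearity-degenerate pairs."""
        pool = self.pairwise
        if "collinear" in pool.columns and (~pool["collinear"]).any():
            pool = pool.loc[~pool["collinear"]]
        row = pool.loc[pool["h"].idxmax()]
        return str(row["feature_1"]), str(row["feature_2"]), float(row["h"])


def h_report(
    predict: PredictFn,
    X: pd.DataFrame,
    features: list[str] | None = None,
    n_sample: int | None = 300,
    seed: int = 0,
    collinear_threshold: float | None = 0.8,
) -> HReport:
    """Overall and all-pairs H statistics for a feature set.

    ``features`` restricts the scan (typically to the model's leading
    predictors — the H ratio is numerically unreliable for near-inert
    features); single-feature partial dependences are computed once and
    shared across pairs. Pairs whose members are correlated beyond
    ``collinear_threshold`` (|Pearson r|) are flagged ``collinear`` and
    skipped by :meth:`HReport.top_pair`, since the estimator is biased
    toward 1 for near-duplicate features.
    """
    features = features or list(X.columns)
    S = _subsample(X, n_sample, seed)
    others = {f: [c for c in S.columns if c != f] for f in features}
    f_vals = np.asarray(predict(S), dtype=float)
    f_vals = f_vals - f_vals.mean()
    denom_f = float(np.sum(f_vals**2))
    singles = {f: _pd_profile(predict, S, [f]) for f in features}

    overall = {}
    for f in features:
        if denom_f == 0:
            overall[f] = 0.0
            continue
        pd_rest = _pd_profile(predict, S, others[f])
        h2 = float(np.sum((f_vals - singles[f] - pd_rest) ** 2)) / denom_f
        overall[f] = float(np.sqrt(np.clip(h2, 0.0, 1.0)))

    corr = X[features].corr().abs() if collinear_threshold is not None else None
    rows = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            pd_jk = _pd_profile(predict, S, [a, b])
            denom = float(np.sum(pd_jk**2))
            if denom == 0:
                h = 0.0
            else:
                h2 = float(np.sum((pd_jk - singles[a] - singles[b]) ** 2)) / denom
                h = float(np.sqrt(np.clip(h2, 0.0, 1.0)))
            collinear = bool(corr is not None and corr.loc[a, b] > collinear_threshold)
            rows.append((a, b, h, collinear))
    pairwise = pd.DataFrame(rows, columns=["feature_1", "feature_2", "h", "collinear"])
    return HReport(
        overall=pd.Series(overall, name="h_overall"),
        pairwise=pairwise,
        n_sample=len(S),
    )
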