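"""Feature-importance extraction, direction inference, and the
multicollinearity-robustness model-selection protocol.

Correlated multi-omic features split importance among themselves in
model-specific ways; the robustness protocol quantifies how stable each
learner's ranking is when a cluster of collinear features is collapsed to a
single representative, and selects the algorithm whose rankings survive that
collapse best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTable
from .genome import GenomeLayout
from .modeling import BinPredictionModel, CVResults, ModelSpec

__all__ = [
    "ImportanceRanking",
    "ClusterSet",
    "RobustnessReport",
    "extract_importance",
    "infer_direction",
    "build_clusters",
    "importance_sd_stats",
    "robustness_protocol",
    "select_model",
]


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-feature importance scores, average-rank positions and directions."""

    frame: pd.DataFrame = field(repr=False)  # feature, score, rank, direction

    def ranks(self, features: list[str] | None = None) -> pd.Series:
        s = self.frame.set_index("feature")["rank"]
        return s if features is None else s.loc[features]


def _tree_total_importance(est) -> np.ndarray:
    """Unnormalized total impurity reduction (Gini or RSS) per feature."""
    if hasattr(est, "estimators_"):  # forest
        trees = [t.tree_ for t in est.estimators_]
        return np.sum([t.compute_feature_importances(normalize=False) for t in trees], axis=0)
    return est.tree_.compute_feature_importances(normalize=False)


def extract_importance(results: CVResults) -> ImportanceRanking:
    """Model-specific importance of each predictor of a fitted CV run.

    Decision tree / random forest: total impurity (Gini or RSS) reduction
    summed over splits. Boosted trees: gain-type importance summed over the
    ensemble. Regularized LR: absolute standardized coefficient (inputs are
    z-scored, so coefficients are on a common scale). Predictors dropped by
    the preprocessor (zero variance) get score 0.
    """
    est = results.full_model
    if est is None:
        raise ValueError("results carry no fitted model")
    kept = results.preprocessor.columns_
    if results.algorithm in ("decision_tree", "random_forest"):
        scores = _tree_total_importance(est)
    elif results.algorithm == "boosted_trees":
        scores = est.feature_importances_
    else:  # regularized_lr
        coef = est.coef_.ravel()
        scores = np.abs(coef)
    by_feature = dict(zip(kept, scores))
    all_features = results.feature_columns
    score_vec = np.array([by_feature.get(f, 0.0) for f in all_features])
    ranks = sps.rankdata(-score_vec, method="average")
    try:
        directions = infer_direction(results)
    except ValueError:
        directions = {}
    frame = pd.DataFrame(
        {
            "feature": all_features,
            "score": score_vec,
            "rank": ranks,
            "direction": [directions.get(f, "undefined") for f in all_features],
        }
    ).sort_values("rank", ignore_index=True)
    return ImportanceRanking(frame=frame)


def infer_direction(results: CVResults, X: pd.DataFrame | None = None) -> dict[str, str]:
    """Sign of each feature's association with the model's predictions.

    LR: sign of the standardized coefficient. Tree models, classification:
    whether the mean feature value is greater in predicted-hotspot bins than
    in predicted non-hotspot bins. Tree models, regression: sign of the
    Spearman correlation between feature values and predicted rate. Features
    with constant predictions or values are flagged "undefined".
    """
    est = results.full_model
    kept = results.preprocessor.columns_
    if results.algorithm == "regularized_lr":
        coef = est.coef_.ravel()
        return {f: ("positive" if c > 0 else "negative" if c < 0 else "undefined")
                for f, c in zip(kept, coef)}
    # tree-based: post-hoc from predictions on the training table
    Xraw = X if X is not None else getattr(results, "_direction_X", None)
    if Xraw is None:
        raise ValueError("direction inference needs the feature matrix X for tree models")
    pred = results.predict(Xraw)
    out: dict[str, str] = {}
    if results.task == "classification":
        hot_mask = est.predict(results.preprocessor.transform(Xraw)) == 1
        for f in Xraw.columns:
            if hot_mask.sum() in (0, len(Xraw)) or Xraw[f].std() == 0:
                out[f] = "undefined"
                continue
            out[f] = (
                "positive"
                if Xraw[f][hot_mask].mean() > Xraw[f][~hot_mask].mean()
                else "negative"
            )
    else:
        for f in Xraw.columns:
            if pred.std() == 0 or Xraw[f].std() == 0:
                out[f] = "undefined"
                continue
            rho = sps.spearmanr(Xraw[f], pred)[0]
            out[f] = "positive" if rho > 0 else "negative" if rho < 0 else "undefined"
    return out


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint clusters of highly correlated features with a representative each."""

    clusters: list[frozenset]
    representatives: dict[frozenset, str]

    def reduced_features(self, all_features: list[str]) -> list[str]:
        """Representatives plus every unclustered feature, in table order."""
        clustered = set().union(*self.clusters) if self.clusters else set()
        reps = set(self.representatives.values())
        return [f for f in all_features if f not in clustered or f in reps]


def build_clusters(
    X: pd.DataFrame,
    threshold: float = 0.80,
    representatives: dict[str, str] | None = None,
) -> ClusterSet:
    """Connected components of the |Pearson r| > threshold feature graph.

    Only components with at least two members form clusters. Representatives
    can be fixed by the caller (e.g. CpG for the methylation/annotation
    cluster, AT for nucleotide composition); otherwise the member with the
    highest mean |r| to the rest of its cluster is chosen. Components are
    transitive closures: a-b and b-c above threshold join a, b, c even if
    |r(a,c)| is low.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if X.shape[1] < 2:
        raise ValueError("need at least two features")
    corr = X.corr().abs()
    features = list(X.columns)
    adj = {f: set() for f in features}
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            if corr.loc[a, b] > threshold:
                adj[a].add(b)
                adj[b].add(a)
    seen: set[str] = set()
    clusters = []
    for f in features:
        if f in seen or not adj[f]:
            continue
        comp = set()
        stack = [f]
        while stack:
            g = stack.pop()
            if g in comp:
                continue
            comp.add(g)
            stack.extend(adj[g] - comp)
        seen |= comp
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
    reps = {}
    for comp in clusters:
        fixed = None
        if representatives:
            fixed = next((r for r in representatives.values() if r in comp), None)
        if fixed is not None:
            reps[comp] = fixed
        else:
            members = sorted(comp)
            mean_r = {m: corr.loc[m, [x for x in members if x != m]].mean() for m in members}
            reps[comp] = max(members, key=lambda m: (mean_r[m], m))
    return ClusterSet(clusters=clusters, representatives=reps)


@dataclass(frozen=True)
class RobustnessReport:
    """Ranking stability of one learner under collinear-feature collapse."""

    algorithm: str
    task: str
    spearman: float
    within_cluster_sd: float
    overall_sd: float
    sd_ratio: float
    full_ranking: ImportanceRanking = field(repr=False, default=None)
    reduced_ranking: ImportanceRanking = field(repr=False, default=None)


def _attach_direction_matrix(results: CVResults, X: pd.DataFrame) -> CVResults:
    results._direction_X = X  # type: ignore[attr-defined]
    return results


def _reduced_table(table: FeatureTable, features: list[str]) -> FeatureTable:
    keep = ["chrom", "start", "end", table.target, "snp_count"] + features
    return replace(
        table,
        frame=table.frame[keep].copy(),
        feature_columns=list(features),
    )


def importance_sd_stats(
    scores: pd.Series, clusters: ClusterSet
) -> tuple[float, float, float]:
    """Mean within-cluster SD of importance scores, overall SD, and their ratio.

    A low ratio means a model spreads importance evenly across collinear
    features instead of singling one out arbitrarily. Scale-invariant:
    multiplying all scores by a constant leaves the ratio unchanged.
    """
    within = [scores.loc[sorted(c)].std(ddof=1) for c in clusters.clusters if len(c) >= 2]
    within_sd = float(np.mean(within)) if within else 0.0
    overall_sd = float(scores.std(ddof=1))
    return within_sd, overall_sd, (within_sd / overall_sd if overall_sd > 0 else 0.0)


def robustness_protocol(
    spec: ModelSpec,
    table: FeatureTable,
    layout: GenomeLayout,
    clusters: ClusterSet,
    subgenome: str | None = None,
    spearman_features: str = "reduced",
) -> RobustnessReport:
    """Compare importance rankings with and without collinear features.

    Fits the learner twice — once on all features, once with each cluster
    collapsed to its representative — ranks features from full-data refits,
    and reports (1) the Spearman correlation between the two rankings over
    the reduced set's features ("representatives" restricts it to cluster
    representatives only), (2) the mean within-cluster SD of the full-set
    importance scores, (3) the overall SD, and (4) their ratio. Low SD ratio
    with high Spearman marks a learner whose attribution is robust to
    multicollinearity.
    """
    full_res = BinPredictionModel(table, layout, spec, subgenome=subgenome).fit()
    _attach_direction_matrix(full_res, table.X)
    full_rank = extract_importance(full_res)

    reduced_feats = clusters.reduced_features(table.feature_columns)
    if len(reduced_feats) < 3:
        warnings.warn("fewer than 3 reduced-set features; Spearman is unstable", stacklevel=2)
    red_table = _reduced_table(table, reduced_feats)
    red_res = BinPredictionModel(red_table, layout, spec, subgenome=subgenome).fit()
    _attach_direction_matrix(red_res, red_table.X)
    red_rank = extract_importance(red_res)

    if spearman_features == "representatives":
        compare = sorted(clusters.representatives.values())
    else:
        compare = reduced_feats
    r_full = full_rank.ranks(list(compare)).to_numpy()
    r_red = red_rank.ranks(list(compare)).to_numpy()
    if np.std(r_full) == 0 or np.std(r_red) == 0:
        rho = 1.0 if np.array_equal(sps.rankdata(r_full), sps.rankdata(r_red)) else 0.0
    else:
        rho = float(sps.spearmanr(r_full, r_red)[0])

    scores = full_rank.frame.set_index("feature")["score"]
    within_sd, overall_sd, ratio = importance_sd_stats(scores, clusters)
    return RobustnessReport(
        algorithm=spec.algorithm,
        task=spec.task,
        spearman=rho,
        within_cluster_sd=within_sd,
        overall_sd=overall_sd,
        sd_ratio=ratio,
        full_ranking=full_rank,
        reduced_ranking=red_rank,
    )


def select_model(
    reports: list[RobustnessReport], cv_metrics: dict[str, float] | None = None
) -> RobustnessReport:
    """Deterministic lexicographic model choice.

    Highest robustness Spearman first; ties broken by the learner's CV
    metric (AUROC or R-squared), then by the lowest within/overall SD ratio,
    then alphabetically for full determinism.
    """
    if not reports:
        raise ValueError("no candidate models")
    cv_metrics = cv_metrics or {}
    return max(
        reports,
        key=lambda r: (
            round(r.spearman, 12),
            cv_metrics.get(r.algorithm, float("-inf")),
            -r.sd_ratio,
            r.algorithm,
        ),
    )
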