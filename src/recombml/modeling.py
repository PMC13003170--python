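"""Grouped cross-validation modelling of recombination from multi-omic features.

The protocol is the contribution here: homoeolog-grouped chromosome folds
(so that duplicated ancestral chromosomes never straddle the train/validation
boundary), per-fold preprocessing fitted on the training split only,
hyperparameter search (seeded random search or a light Gaussian-process
expected-improvement loop), and pooled out-of-fold evaluation. The learners
themselves are scikit-learn estimators.

The public surface follows the statsmodels convention: build a
:class:`BinPredictionModel` from a feature table, call ``fit()``, and read
the estimates and diagnostics off the returned :class:`CVResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingClassifier, GradientBoostingRegressor
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import ElasticNet, LogisticRegression
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .features import FeatureTable
from .genome import GenomeLayout, homoeolog_folds

__all__ = [
    "auroc",
    "r_squared",
    "per_chromosome_pearson",
    "CVPlan",
    "make_cv_plan",
    "Preprocessor",
    "ModelSpec",
    "build_estimator",
    "BinPredictionModel",
    "CVResults",
    "ALGORITHMS",
]

ALGORITHMS = ("decision_tree", "regularized_lr", "random_forest", "boosted_trees")


# ---------------------------------------------------------------------------
# metrics


def auroc(labels, scores) -> float:
    """Area under the ROC curve: the probability that a random positive is
    scored above a random negative, with ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SSE/SST."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observations have zero variance")
    return 1.0 - float(((obs - pred) ** 2).sum()) / sst


def per_chromosome_pearson(obs, pred, chroms) -> pd.Series:
    """Pearson r between observed and predicted values within each chromosome."""
    df = pd.DataFrame({"obs": obs, "pred": pred, "chrom": chroms})
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        if len(sub) >= 3 and sub["obs"].std() > 0 and sub["pred"].std() > 0:
            out[chrom] = float(sps.pearsonr(sub["obs"], sub["pred"])[0])
        else:
            out[chrom] = np.nan
    return pd.Series(out, name="pearson_r")


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class CVPlan:
    """Fold plan: per fold a label and the table row indices it validates on."""

    folds: list[tuple[str, np.ndarray]]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def all_rows(self) -> np.ndarray:
        return np.concatenate([rows for _, rows in self.folds])


def make_cv_plan(
    table: FeatureTable,
    layout: GenomeLayout,
    subgenome_filter: str | None = None,
    seed: int = 0,
) -> CVPlan:
    """Homoeolog-grouped chromosome folds over the table's rows.

    Genome-wide this yields one fold per homoeolog group; restricted to one
    subgenome, one fold per chromosome. Row order is shuffled within each
    chromosome (positional dependencies removed); fold membership itself is
    deterministic.
    """
    chrom_col = table.frame["chrom"]
    for chrom in chrom_col.unique():
        if chrom not in layout:
            raise KeyError(f"chromosome {chrom!r} absent from layout")
    rng = np.random.default_rng(seed)
    folds = []
    for group in homoeolog_folds(layout, subgenome_filter):
        rows = []
        for chrom in group:
            idx = np.flatnonzero((chrom_col == chrom).to_numpy())
            rng.shuffle(idx)
            rows.append(idx)
        rows = np.concatenate(rows) if rows else np.array([], dtype=int)
        if rows.size:
            folds.append(("+".join(group), rows))
    return CVPlan(folds=folds)


# ---------------------------------------------------------------------------
# preprocessing


class Preprocessor:
    """Train-fold-only preprocessing: dummy-encode categoricals, drop
    zero-variance predictors, z-score by training mean/SD.

    The binary subgenome flag is its own dummy; like every numeric column it
    is normalized (and dropped when the training fold spans one subgenome
    only). The transform is intentionally not idempotent — applying it twice
    double-scales, which the tests assert to guard against accidental
    re-application.
    """

    def __init__(self) -> None:
        self.columns_: list[str] | None = None
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        if len(X) == 0:
            raise ValueError("empty training data")
        sds = X.std(ddof=0)
        keep = sds[sds > 0].index.tolist()
        if not keep:
            raise ValueError("all predictors have zero variance")
        self.columns_ = keep
        self.means_ = X[keep].mean()
        self.sds_ = sds[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("preprocessor not fitted")
        return (X[self.columns_] - self.means_) / self.sds_


# ---------------------------------------------------------------------------
# model specs & estimators

_SPACES: dict[str, dict[str, tuple]] = {
    "decision_tree": {
        "ccp_alpha": ("log", 1e-5, 1e-1),
        "max_depth": ("int", 2, 20),
        "min_samples_leaf": ("int", 2, 40),
    },
    "regularized_lr": {
        "penalty": ("log", 1e-4, 1e1),
        "mixture": ("float", 0.0, 1.0),
    },
    "random_forest": {
        "max_features": ("float", 0.2, 1.0),
        "n_estimators": ("int", 100, 500),
        "min_samples_leaf": ("int", 1, 20),
    },
    "boosted_trees": {
        "max_features": ("float", 0.2, 1.0),
        "n_estimators": ("int", 50, 400),
        "learning_rate": ("log", 0.01, 0.3),
        "max_depth": ("int", 2, 8),
        "min_impurity_decrease": ("log", 1e-8, 1e-2),
        "min_samples_leaf": ("int", 2, 40),
    },
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "decision_tree": {"ccp_alpha": 1e-3, "max_depth": 8, "min_samples_leaf": 5},
    "regularized_lr": {"penalty": 1e-2, "mixture": 0.5},
    "random_forest": {"max_features": 0.5, "n_estimators": 300, "min_samples_leaf": 3},
    "boosted_trees": {
        "max_features": 0.7,
        "n_estimators": 200,
        "learning_rate": 0.05,
        "max_depth": 3,
        "min_impurity_decrease": 1e-7,
        "min_samples_leaf": 5,
    },
}


@dataclass
class ModelSpec:
    """One learner configuration to tune: algorithm, task, search space, budget."""

    algorithm: str
    task: str
    budget: int = 10
    seed: int = 0
    method: str = "random"  # "random" or "bayes"
    space: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not self.space:
            self.space = dict(_SPACES[self.algorithm])


def build_estimator(algorithm: str, task: str, params: dict[str, Any], seed: int = 0):
    """Instantiate the scikit-learn estimator behind an algorithm/task pair."""
    cls = task == "classification"
    if algorithm == "decision_tree":
        klass = DecisionTreeClassifier if cls else DecisionTreeRegressor
        return klass(
            ccp_alpha=params["ccp_alpha"],
            max_depth=int(params["max_depth"]),
            min_samples_leaf=int(params["min_samples_leaf"]),
            random_state=seed,
        )
    if algorithm == "regularized_lr":
        if cls:
            return LogisticRegression(
                penalty="elasticnet",
                solver="saga",
                C=1.0 / max(params["penalty"], 1e-12),
                l1_ratio=params["mixture"],
                max_iter=5000,
                random_state=seed,
            )
        return ElasticNet(
            alpha=params["penalty"], l1_ratio=params["mixture"], max_iter=20000, random_state=seed
        )
    if algorithm == "random_forest":
        klass = RandomForestClassifier if cls else RandomForestRegressor
        return klass(
            max_features=params["max_features"],
            n_estimators=int(params["n_estimators"]),
            min_samples_leaf=int(params["min_samples_leaf"]),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "boosted_trees":
        klass = GradientBoostingClassifier if cls else GradientBoostingRegressor
        return klass(
            max_features=params["max_features"],
            n_estimators=int(params["n_estimators"]),
            learning_rate=params["learning_rate"],
            max_depth=int(params["max_depth"]),
            min_impurity_decrease=params["min_impurity_decrease"],
            min_samples_leaf=int(params["min_samples_leaf"]),
            random_state=seed,
        )
    raise ValueError(algorithm)


def _sample_params(space: dict[str, tuple], rng: np.random.Generator) -> dict[str, Any]:
    out = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "log":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "float":
            out[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        else:
            raise ValueError(kind)
    return out


def _encode(params: dict[str, Any], space: dict[str, tuple]) -> np.ndarray:
    vec = []
    for name, (kind, lo, hi) in space.items():
        v = params[name]
        if kind == "log":
            vec.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
        else:
            vec.append((v - lo) / (hi - lo))
    return np.array(vec)


def _propose_bayes(
    history: list[tuple[dict[str, Any], float]],
    space: dict[str, tuple],
    rng: np.random.Generator,
    n_candidates: int = 128,
) -> dict[str, Any]:
    """Expected-improvement proposal from a GP surrogate over past scores."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    X = np.array([_encode(p, space) for p, _ in history])
    y = np.array([s for _, s in history])
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5) + WhiteKernel(1e-4), normalize_y=True, random_state=0
    )
    gp.fit(X, y)
    cand = [_sample_params(space, rng) for _ in range(n_candidates)]
    Xc = np.array([_encode(p, space) for p in cand])
    mu, sd = gp.predict(Xc, return_std=True)
    best = y.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mu - best) / sd
        ei = (mu - best) * sps.norm.cdf(z) + sd * sps.norm.pdf(z)
    ei[sd == 0] = 0.0
    return cand[int(np.argmax(ei))]


# ---------------------------------------------------------------------------
# model / results


@dataclass
class CVResults:
    """Cross-validated fit of one learner: metrics, predictions, diagnostics."""

    algorithm: str
    task: str
    fold_labels: list[str]
    fold_metrics: np.ndarray
    mean_fold_metric: float
    overall_metric: float
    oof: pd.DataFrame = field(repr=False)
    best_params: dict[str, Any] = field(default_factory=dict)
    history: list[tuple[dict[str, Any], float]] = field(default_factory=list, repr=False)
    full_model: Any = field(default=None, repr=False)
    preprocessor: Preprocessor = field(default=None, repr=False)
    per_chrom_pearson: pd.Series | None = None
    feature_columns: list[str] = field(default_factory=list)

    @property
    def metric_name(self) -> str:
        return "AUROC" if self.task == "classification" else "R2"

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predictions of the full-data refit on raw (untransformed) features."""
        Z = self.preprocessor.transform(X)
        if self.task == "classification":
            return self.full_model.predict_proba(Z)[:, 1]
        return self.full_model.predict(Z)

    def summary(self) -> str:
        lines = [
            f"{self.algorithm} ({self.task}), {len(self.fold_labels)}-fold grouped CV",
            f"  mean fold {self.metric_name}: {self.mean_fold_metric:.4f}",
            f"  overall (pooled) {self.metric_name}: {self.overall_metric:.4f}",
        ]
        if self.per_chrom_pearson is not None:
            lines.append(
                f"  mean per-chromosome Pearson r: {np.nanmean(self.per_chrom_pearson):.4f}"
            )
        lines.append(f"  best params: {self.best_params}")
        for lab, m in zip(self.fold_labels, self.fold_metrics):
            lines.append(f"    fold {lab}: {m:.4f}")
        return "\n".join(lines)


class BinPredictionModel:
    """Predict per-bin recombination outcomes from multi-omic features.

    Parameters
    ----------
    table : FeatureTable
        Modelling table (classification or regression) on the bin grid.
    layout : GenomeLayout
        Chromosome layout providing homoeolog groups for fold construction.
    spec : ModelSpec
        Learner, task, tuning budget and search method.
    subgenome : {"A", "C", None}
        Restrict the model to one subgenome (folds become per-chromosome).
    """

    def __init__(
        self,
        table: FeatureTable,
        layout: GenomeLayout,
        spec: ModelSpec,
        subgenome: str | None = None,
    ):
        if spec.task != table.task:
            raise ValueError("spec task does not match table task")
        if subgenome is not None:
            chroms = [c.name for c in layout.chromosomes if c.subgenome == subgenome]
            keep = table.frame["chrom"].isin(chroms)
            table = FeatureTable(
                frame=table.frame.loc[keep].reset_index(drop=True),
                target=table.target,
                task=table.task,
                feature_columns=list(table.feature_columns),
                smoothable=dict(table.smoothable),
                imputation_log=dict(table.imputation_log),
            )
        self.table = table
        self.layout = layout
        self.spec = spec
        self.subgenome = subgenome

    def _score_candidate(
        self, params: dict[str, Any], plan: CVPlan, cand_seed: int
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Mean fold metric plus fold metrics and out-of-fold predictions."""
        X = self.table.X
        y = self.table.y.to_numpy()
        oof = np.full(len(X), np.nan)
        fold_metrics = np.full(plan.n_folds, np.nan)
        for i, (_, val_rows) in enumerate(plan.folds):
            train_mask = np.ones(len(X), dtype=bool)
            train_mask[val_rows] = False
            prep = Preprocessor().fit(X.loc[train_mask])
            est = build_estimator(self.spec.algorithm, self.spec.task, params, seed=cand_seed)
            est.fit(prep.transform(X.loc[train_mask]), y[train_mask])
            Zv = prep.transform(X.iloc[val_rows])
            if self.spec.task == "classification":
                pred = est.predict_proba(Zv)[:, 1]
                yv = y[val_rows]
                if yv.min() != yv.max():
                    fold_metrics[i] = auroc(yv, pred)
            else:
                pred = est.predict(Zv)
                yv = y[val_rows]
                if yv.std() > 0:
                    fold_metrics[i] = r_squared(yv, pred)
            oof[val_rows] = pred
        return float(np.nanmean(fold_metrics)), fold_metrics, oof

    def fit(self) -> CVResults:
        """Tune, cross-validate, and refit on the full data.

        Candidate 0 is always the package default configuration (so budget=1
        evaluates a sensible fixed model); further candidates come from
        seeded random search or, with ``method='bayes'``, a GP
        expected-improvement loop after 5 random warm-up draws.
        """
        spec = self.spec
        plan = make_cv_plan(self.table, self.layout, self.subgenome, seed=spec.seed)
        rng = np.random.default_rng(spec.seed)
        history: list[tuple[dict[str, Any], float]] = []
        best: tuple[float, dict, np.ndarray, np.ndarray] | None = None
        n_warmup = min(spec.budget, 5)
        for k in range(spec.budget):
            if k == 0:
                params = dict(_DEFAULTS[spec.algorithm])
            elif spec.method == "bayes" and k >= n_warmup:
                params = _propose_bayes(history, spec.space, rng)
            else:
                params = _sample_params(spec.space, rng)
            score, fold_metrics, oof = self._score_candidate(params, plan, cand_seed=spec.seed)
            history.append((params, score))
            if best is None or score > best[0]:
                best = (score, params, fold_metrics, oof)
        assert best is not None
        _, best_params, fold_metrics, oof = best

        y = self.table.y.to_numpy()
        have = ~np.isnan(oof)
        if spec.task == "classification":
            overall = auroc(y[have], oof[have])
            pearson = None
        else:
            overall = r_squared(y[have], oof[have])
            pearson = per_chromosome_pearson(
                y[have], oof[have], self.table.frame["chrom"].to_numpy()[have]
            )

        prep = Preprocessor().fit(self.table.X)
        full = build_estimator(spec.algorithm, spec.task, best_params, seed=spec.seed)
        full.fit(prep.transform(self.table.X), y)

        oof_frame = self.table.frame[["chrom", "start", "end"]].copy()
        oof_frame["observed"] = y
        oof_frame["predicted"] = oof
        return CVResults(
            algorithm=spec.algorithm,
            task=spec.task,
            fold_labels=[lab for lab, _ in plan.folds],
            fold_metrics=fold_metrics,
            mean_fold_metric=float(np.nanmean(fold_metrics)),
            overall_metric=float(overall),
            oof=oof_frame,
            best_params=best_params,
            history=history,
            full_model=full,
            preprocessor=prep,
            per_chrom_pearson=pearson,
            feature_columns=list(self.table.feature_columns),
        )
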