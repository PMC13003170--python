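"""Univariate hotspot association tests and the hotspot ~ SNP + subgenome GLM.

Two-sample pooled-variance t-tests (on z-scored features) compare hotspot
versus sampled non-hotspot bins, with a chi-square test for the subgenome
hotspot-count contrast; p-values are FDR-adjusted (Benjamini-Hochberg) with
a strict-Bonferroni option for sensitivity checks. The logistic model of
hotspot membership on SNP count and C-subgenome identity is fitted by IRLS
(statsmodels binomial GLM) and reported with Wald z statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FeatureTable

__all__ = ["TestReport", "hotspot_tests", "HotspotLogit", "HotspotLogitResults"]


@dataclass(frozen=True)
class TestReport:
    """Per-feature association tests between hotspot and non-hotspot bins."""

    frame: pd.DataFrame = field(repr=False)
    alpha: float = 0.1
    method: str = "fdr_bh"


def hotspot_tests(
    table: FeatureTable,
    alpha: float = 0.1,
    method: str = "fdr_bh",
    categorical: tuple[str, ...] = ("C_subgenome",),
) -> TestReport:
    """Compare every feature between hotspot and sampled non-hotspot bins.

    Numeric features: two-sample Student's t-test with pooled variance on
    jointly z-scored values (the z-scoring is affine so t is unchanged; it is
    applied to meet the test's scale conventions). Categorical features
    (the subgenome flag): chi-square on the 2x2 hotspot-count table.
    Adjustment: Benjamini-Hochberg step-up FDR by default ("bonferroni" for
    the strict option); features with adjusted p < ``alpha`` are significant.
    """
    if table.task != "classification":
        raise ValueError("hotspot tests require the classification table")
    y = table.y.to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be non-empty")
    rows = []
    for col in table.feature_columns:
        x = table.frame[col].to_numpy(dtype=float)
        hot, non = x[y == 1], x[y == 0]
        if col in categorical:
            contingency = np.array(
                [
                    [(hot == 1).sum(), (hot == 0).sum()],
                    [(non == 1).sum(), (non == 0).sum()],
                ]
            )
            if (contingency.sum(axis=0) == 0).any():
                stat, p = np.nan, 1.0
            else:
                stat, p = sps.chi2_contingency(contingency)[:2]
            rows.append((col, "chi2", stat, p, "depleted" if hot.mean() < non.mean() else "enriched"))
            continue
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append((col, "t", np.nan, 1.0, "none"))
            continue
        z = (x - x.mean()) / sd
        t, p = sps.ttest_ind(z[y == 1], z[y == 0], equal_var=True)
        rows.append((col, "t", t, p, "enriched" if hot.mean() > non.mean() else "depleted"))
    frame = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p_raw", "direction"])
    frame["p_adjusted"] = multipletests(frame["p_raw"], method=method)[1]
    frame["significant"] = frame["p_adjusted"] < alpha
    return TestReport(frame=frame, alpha=alpha, method=method)


class HotspotLogit:
    """Logistic model of hotspot membership on SNP count and subgenome identity.

    hotspot ~ SNP + C_subgenome, binomial GLM with logit link fitted by
    iteratively reweighted least squares. By default fitted on all
    non-SNP-empty bins with hotspot = top-quantile membership; ``zscore_snp``
    optionally standardizes the SNP count before fitting.
    """

    def __init__(self, hotspot, snp_count, c_subgenome, zscore_snp: bool = False):
        y = np.asarray(hotspot, dtype=float)
        snp = np.asarray(snp_count, dtype=float)
        if zscore_snp:
            snp = (snp - snp.mean()) / snp.std(ddof=1)
        X = pd.DataFrame({"SNP": snp, "C_subgenome": np.asarray(c_subgenome, dtype=float)})
        if y.min() == y.max():
            raise ValueError("need both hotspot and non-hotspot rows")
        self.endog = y
        self.exog = sm.add_constant(X)

    def fit(self) -> "HotspotLogitResults":
        model = sm.GLM(self.endog, self.exog, family=sm.families.Binomial())
        res = model.fit()
        p_hat = res.fittedvalues
        separated = bool(np.any((p_hat > 1 - 1e-10) | (p_hat < 1e-10)))
        return HotspotLogitResults(
            params=res.params,
            bse=res.bse,
            zvalues=res.params / res.bse,
            pvalues=res.pvalues,
            converged=bool(res.converged),
            separated=separated,
            _sm_results=res,
        )


@dataclass
class HotspotLogitResults:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    converged: bool
    separated: bool
    _sm_results: object = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )
        out.index.name = "term"
        return out
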