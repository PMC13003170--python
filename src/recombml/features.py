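"""Per-bin multi-omic feature computation and feature-table assembly.

Covers annotation coverage fractions with cross-type trimming, single-base
and read-weighted methylation rates, TE-body CHH methylation, GC content and
dinucleotide coverage, the log-compressed chromatin-accessibility score,
log-transformed expression, and simple exponential smoothing of the
per-chromosome tracks prior to modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import distribute_to_bins, merge_intervals, subtract_intervals
from .genome import BinGrid
from .recmap import RecombMap

__all__ = [
    "FeatureTable",
    "coverage_fraction",
    "methylation_rate",
    "weighted_methylation",
    "te_body_chh",
    "gc_content",
    "dinucleotide_fraction",
    "accessibility_score",
    "expression_score",
    "ses_smooth",
    "assemble_table",
    "UNSMOOTHED_FEATURES",
]

# Features whose values are not artifacts of genome binning and are therefore
# left unsmoothed (positional/identity features).
UNSMOOTHED_FEATURES = ("telomere_distance", "C_subgenome")

CALL_COLUMNS = ["chrom", "pos", "context", "tissue", "replicate", "meth", "total"]


def _per_bin_covered(
    intervals: pd.DataFrame, grid: BinGrid, trim_against: list[pd.DataFrame] | None = None
) -> np.ndarray:
    """Covered length (bp) per bin after within-type union and optional trimming."""
    covered = np.zeros(grid.n_bins, dtype=np.float64)
    grid_chroms = {c: grid.chrom_slice(c) for c in grid.frame["chrom"].unique()}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        if chrom not in grid_chroms:
            continue
        sl = grid_chroms[str(chrom)]
        chrom_len = int(grid.frame["end"].iloc[sl.stop - 1])
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        if (starts < 0).any() or (ends > chrom_len).any():
            warnings.warn(f"{chrom}: intervals outside chromosome bounds clipped", stacklevel=3)
            starts = np.clip(starts, 0, chrom_len)
            ends = np.clip(ends, 0, chrom_len)
        keep = starts < ends
        starts, ends = merge_intervals(starts[keep], ends[keep])
        if trim_against:
            for higher in trim_against:
                hsub = higher[higher["chrom"] == chrom]
                if len(hsub):
                    starts, ends = subtract_intervals(
                        starts,
                        ends,
                        hsub["start"].to_numpy(dtype=np.int64),
                        hsub["end"].to_numpy(dtype=np.int64),
                    )
        if starts.size == 0:
            continue
        lengths = (ends - starts).astype(np.float64)
        covered[sl] += distribute_to_bins(
            starts, ends, lengths, grid.width, sl.stop - sl.start
        )
    return covered


def coverage_fraction(
    intervals: pd.DataFrame, grid: BinGrid, trim_against: list[pd.DataFrame] | None = None
) -> np.ndarray:
    """Fraction (0-1) of each bin covered by the given annotation intervals.

    Overlaps within the interval set are merged first so duplicated
    annotations are not double-counted; when ``trim_against`` is supplied,
    regions overlapping those higher-priority interval sets are removed
    before computing coverage.
    """
    covered = _per_bin_covered(intervals, grid, trim_against)
    return covered / grid.lengths_bp()


# ---------------------------------------------------------------------------
# methylation


def _validate_calls(calls: pd.DataFrame, context: str | None) -> pd.DataFrame:
    missing = set(CALL_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"cytosine call table missing columns: {sorted(missing)}")
    if context is not None:
        calls = calls[calls["context"] == context]
        if len(calls) == 0:
            raise ValueError(f"no calls in context {context!r}")
    return calls


def _cytosine_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-cytosine single-base rate: replicate rates averaged within tissue,
    then averaged across tissues; cytosines not called in every replicate of
    a tissue are excluded for that tissue."""
    n_reps = calls.groupby("tissue")["replicate"].nunique()
    rep_rates = calls.assign(rate=calls["meth"] / calls["total"])
    per_tissue = (
        rep_rates.groupby(["chrom", "pos", "tissue"])
        .agg(rate=("rate", "mean"), n=("replicate", "nunique"))
        .reset_index()
    )
    per_tissue = per_tissue[per_tissue["n"] == per_tissue["tissue"].map(n_reps)]
    per_cyt = per_tissue.groupby(["chrom", "pos"])["rate"].mean().reset_index()
    return per_cyt


def _bin_mean(per_cyt: pd.DataFrame, grid: BinGrid, value_col: str = "rate") -> np.ndarray:
    """Unweighted mean of per-cytosine values over the bin containing each
    cytosine; bins with no retained cytosine are NaN (imputed downstream).
    Positions are 1-based (methylation-report convention)."""
    out = np.full(grid.n_bins, np.nan)
    for chrom, sub in per_cyt.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(str(chrom))
        except KeyError:
            continue
        n = sl.stop - sl.start
        idx = (sub["pos"].to_numpy(dtype=np.int64) - 1) // grid.width
        ok = (idx >= 0) & (idx < n)
        sums = np.zeros(n)
        cnts = np.zeros(n)
        np.add.at(sums, idx[ok], sub[value_col].to_numpy()[ok])
        np.add.at(cnts, idx[ok], 1.0)
        vals = np.full(n, np.nan)
        nz = cnts > 0
        vals[nz] = sums[nz] / cnts[nz]
        out[sl] = vals
    return out


def methylation_rate(calls: pd.DataFrame, grid: BinGrid, context: str) -> np.ndarray:
    """Per-bin single-base methylation rate for one context (CpG/CHG/CHH).

    Averaging cascade: methylated/total per replicate -> mean across the
    replicates of each tissue (cytosines missing from any replicate of a
    tissue are excluded for that tissue) -> mean across tissues -> unweighted
    mean over the retained cytosines in each bin. Bins without retained
    cytosines are NaN.
    """
    calls = _validate_calls(calls, context)
    return _bin_mean(_cytosine_rates(calls), grid)


def weighted_methylation(calls: pd.DataFrame, grid: BinGrid, context: str) -> np.ndarray:
    """Read-weighted per-bin methylation: sum(methylated) / sum(total) pooled
    over all tissues and replicates. Bins with zero total calls are NaN."""
    calls = _validate_calls(calls, context)
    out = np.full(grid.n_bins, np.nan)
    for chrom, sub in calls.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(str(chrom))
        except KeyError:
            continue
        n = sl.stop - sl.start
        idx = (sub["pos"].to_numpy(dtype=np.int64) - 1) // grid.width
        ok = (idx >= 0) & (idx < n)
        meth = np.zeros(n)
        tot = np.zeros(n)
        np.add.at(meth, idx[ok], sub["meth"].to_numpy(dtype=float)[ok])
        np.add.at(tot, idx[ok], sub["total"].to_numpy(dtype=float)[ok])
        vals = np.full(n, np.nan)
        nz = tot > 0
        vals[nz] = meth[nz] / tot[nz]
        out[sl] = vals
    return out


def te_body_chh(calls: pd.DataFrame, te_intervals: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Per-bin single-base CHH methylation restricted to cytosines inside TEs.

    Same averaging cascade as :func:`methylation_rate`, applied only to CHH
    cytosines whose (1-based) position falls within an annotated TE interval.
    """
    calls = _validate_calls(calls, "CHH")
    keep = np.zeros(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy(dtype=np.int64) - 1
    chrom_arr = calls["chrom"].to_numpy()
    for chrom, sub in te_intervals.groupby("chrom", sort=False):
        m = chrom_arr == chrom
        if not m.any():
            continue
        s, e = merge_intervals(sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
        if s.size == 0:
            continue
        j = np.searchsorted(s, pos0[m], side="right") - 1
        inside = (j >= 0) & (pos0[m] < e[np.clip(j, 0, e.size - 1)])
        keep[np.flatnonzero(m)[inside]] = True
    return _bin_mean(_cytosine_rates(calls.loc[keep]), grid)


# ---------------------------------------------------------------------------
# sequence composition


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


def gc_content(sequences: dict[str, str], grid: BinGrid) -> np.ndarray:
    """Proportion of G and C bases per bin (case-insensitive; ambiguity codes
    count as non-GC)."""
    out = np.full(grid.n_bins, np.nan)
    for chrom in grid.frame["chrom"].unique():
        if chrom not in sequences:
            continue
        sl = grid.chrom_slice(chrom)
        arr = _seq_array(sequences[chrom])
        exp_len = int(grid.frame["end"].iloc[sl.stop - 1])
        if arr.size != exp_len:
            raise ValueError(f"{chrom}: sequence length {arr.size} != layout length {exp_len}")
        is_gc = ((arr == b"G") | (arr == b"C")).astype(np.float64)
        starts = grid.frame["start"].iloc[sl].to_numpy()
        ends = grid.frame["end"].iloc[sl].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(is_gc)])
        out[sl] = (csum[ends] - csum[starts]) / (ends - starts)
    return out


def dinucleotide_fraction(sequences: dict[str, str], grid: BinGrid, dinuc: str = "AT") -> np.ndarray:
    """Fraction of bin positions covered by at least one occurrence of ``dinuc``.

    Overlapping matches are union-covered: "ATAT" is fully covered by AT,
    "AATT" half-covered (the single central match spans 2 of 4 bases).
    """
    if len(dinuc) != 2:
        raise ValueError("dinuc must be a 2-mer")
    d0, d1 = dinuc.upper().encode("ascii")
    out = np.full(grid.n_bins, np.nan)
    for chrom in grid.frame["chrom"].unique():
        if chrom not in sequences:
            continue
        sl = grid.chrom_slice(chrom)
        arr = _seq_array(sequences[chrom])
        b = arr.view(np.uint8)
        match = (b[:-1] == d0) & (b[1:] == d1)
        covered = np.zeros(arr.size, dtype=bool)
        covered[:-1] |= match
        covered[1:] |= match
        starts = grid.frame["start"].iloc[sl].to_numpy()
        ends = grid.frame["end"].iloc[sl].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(covered.astype(np.float64))])
        out[sl] = (csum[ends] - csum[starts]) / (ends - starts)
    return out


# ---------------------------------------------------------------------------
# accessibility & expression


def accessibility_score(ocr_by_tissue: dict[str, pd.DataFrame], grid: BinGrid) -> np.ndarray:
    """Chromatin accessibility per bin, averaged over tissues.

    Per tissue: open-chromatin intervals are merged, the accessible length in
    the bin computed, and transformed as log10(accessible_len + 1) /
    log10(bin_length), capped at 1. The log compression tames large
    tissue-specific peaks while keeping 0 = fully closed, 1 = fully open.
    """
    bin_len = grid.lengths_bp().astype(float)
    scores = []
    for tissue, ocrs in ocr_by_tissue.items():
        acc_len = _per_bin_covered(ocrs, grid)
        with np.errstate(divide="ignore"):
            s = np.log10(acc_len + 1.0) / np.log10(bin_len)
        scores.append(np.minimum(s, 1.0))
    return np.mean(scores, axis=0)


def expression_score(
    tpm_table: pd.DataFrame, gene_positions: pd.DataFrame, grid: BinGrid, floor_tpm: float = 0.1
) -> np.ndarray:
    """Mean transformed expression of the genes in each bin.

    Per gene: TPM averaged across replicates within each tissue, transformed
    as log10(mean TPM + ``floor_tpm``), then averaged across tissues. Genes
    are assigned to the bin containing their midpoint. Bins without genes are
    set to the transform floor log10(floor_tpm); genes missing from the
    expression table are treated as TPM 0 with a warning.

    ``tpm_table`` columns: gene, tissue, replicate, tpm.
    ``gene_positions`` columns: gene, chrom, start, end (0-based half-open).
    """
    per_tissue = tpm_table.groupby(["gene", "tissue"])["tpm"].mean()
    transformed = np.log10(per_tissue + floor_tpm)
    per_gene = transformed.groupby("gene").mean()
    floor = float(np.log10(floor_tpm))
    genes = gene_positions.copy()
    missing = ~genes["gene"].isin(per_gene.index)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} genes without expression records treated as TPM 0",
            stacklevel=2,
        )
    genes["score"] = genes["gene"].map(per_gene).fillna(floor)
    genes["mid"] = (genes["start"] + genes["end"]) // 2
    out = np.full(grid.n_bins, floor)
    for chrom, sub in genes.groupby("chrom", sort=False):
        try:
            sl = grid.chrom_slice(str(chrom))
        except KeyError:
            continue
        n = sl.stop - sl.start
        idx = sub["mid"].to_numpy(dtype=np.int64) // grid.width
        ok = (idx >= 0) & (idx < n)
        sums = np.zeros(n)
        cnts = np.zeros(n)
        np.add.at(sums, idx[ok], sub["score"].to_numpy()[ok])
        np.add.at(cnts, idx[ok], 1.0)
        vals = np.full(n, floor)
        nz = cnts > 0
        vals[nz] = sums[nz] / cnts[nz]
        out[sl] = vals
    return out


# ---------------------------------------------------------------------------
# smoothing & assembly


def ses_smooth(x, alpha: float = 0.1) -> np.ndarray:
    """Simple exponential smoothing: s_1 = x_1, s_t = alpha*x_t + (1-alpha)*s_{t-1}.

    The initial level is pinned at the first observation for reproducibility.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, x.size):
        out[t] = alpha * x[t] + (1 - alpha) * out[t - 1]
    return out


@dataclass
class FeatureTable:
    """Bins-by-features table ready for modelling.

    ``frame`` carries bin coordinates (chrom, start, end), the target column,
    the predictor columns, and ``snp_count`` (kept as metadata, never a
    predictor). ``smoothable`` flags which columns were eligible for SES
    smoothing; ``imputation_log`` records per-column imputed-bin counts.
    """

    frame: pd.DataFrame = field(repr=False)
    target: str
    task: str
    feature_columns: list[str]
    smoothable: dict[str, bool] = field(default_factory=dict)
    imputation_log: dict[str, int] = field(default_factory=dict)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def y(self) -> pd.Series:
        return self.frame[self.target]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _impute_median(frame: pd.DataFrame, columns: list[str]) -> dict[str, int]:
    log = {}
    for col in columns:
        n_missing = int(frame[col].isna().sum())
        if n_missing:
            frame[col] = frame[col].fillna(frame[col].median())
        log[col] = n_missing
    return log


def assemble_table(
    rmap: RecombMap,
    feature_tracks: pd.DataFrame,
    task: str,
    smooth_alpha: float | None = 0.1,
    unsmoothed: tuple[str, ...] = UNSMOOTHED_FEATURES,
) -> FeatureTable:
    """Build the modelling table for one task from a labelled map and tracks.

    ``feature_tracks`` must share the map's bin grid (one row per bin, same
    order) and contain only feature columns. Missing feature values (bins
    without cytosines, genes, ...) are median-imputed with a per-column count
    kept in the imputation log. SNP-empty bins are dropped before smoothing,
    then SES smoothing (if ``smooth_alpha`` is not None) is applied per
    chromosome to every smoothable feature and to the regression target —
    the binary classification target is never smoothed. Classification rows
    are the sampled hotspot/non-hotspot bins; regression rows are all
    remaining bins with the SNP-normalized rate as target.
    """
    if task not in ("classification", "regression"):
        raise ValueError("task must be 'classification' or 'regression'")
    if len(feature_tracks) != rmap.grid.n_bins:
        raise ValueError("feature tracks not on the map's bin grid")
    # columns already on the map (coordinates, snp_count, ...) are not tracks
    feature_tracks = feature_tracks.drop(
        columns=[c for c in feature_tracks.columns if c in rmap.frame.columns]
    )
    feature_cols = list(feature_tracks.columns)
    frame = pd.concat(
        [rmap.frame.reset_index(drop=True), feature_tracks.reset_index(drop=True)], axis=1
    )
    imputation_log = _impute_median(frame, feature_cols)
    frame = frame.loc[~frame["snp_empty"]].reset_index(drop=True)

    smoothable = {c: c not in unsmoothed for c in feature_cols}
    if smooth_alpha is not None:
        smooth_cols = [c for c in feature_cols if smoothable[c]] + ["normalized_rate"]
        for chrom in frame["chrom"].unique():
            m = frame["chrom"] == chrom
            idx = frame.index[m]
            ordered = frame.loc[idx].sort_values("start").index
            for col in smooth_cols:
                frame.loc[ordered, col] = ses_smooth(
                    frame.loc[ordered, col].to_numpy(), smooth_alpha
                )

    if task == "classification":
        keep = frame["hotspot_label"].isin(["hotspot", "non_hotspot_sampled"])
        frame = frame.loc[keep].reset_index(drop=True)
        frame["is_hotspot"] = (frame["hotspot_label"] == "hotspot").astype(int)
        target = "is_hotspot"
    else:
        target = "normalized_rate"

    cols = ["chrom", "start", "end", target, "snp_count"] + feature_cols
    table = FeatureTable(
        frame=frame[cols].copy(),
        target=target,
        task=task,
        feature_columns=feature_cols,
        smoothable=smoothable,
        imputation_log=imputation_log,
    )
    if table.frame[feature_cols].isna().any().any():
        raise AssertionError("feature table contains missing values after assembly")
    return table
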