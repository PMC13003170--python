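"""Crossover filtering and binned recombination-rate maps.

Implements the CO quality filters (per-individual CO-count outliers, overlong
marker intervals), proportional assignment of CO intervals to fixed-width
bins, the cM/Mbp rate formula, SNP-count normalization with SNP-empty-bin
exclusion, and balanced hotspot / non-hotspot sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._intervals import distribute_to_bins
from .genome import BinGrid

__all__ = [
    "COSet",
    "RecombMap",
    "filter_individuals",
    "filter_intervals",
    "assign_cos_to_bins",
    "recombination_rate",
    "count_snps",
    "build_recomb_map",
    "sample_hotspots",
]

CO_COLUMNS = ["chrom", "start", "end", "individual", "population", "generation"]


@dataclass(frozen=True)
class COSet:
    """A set of crossover intervals plus per-population informative-meiosis counts.

    ``frame`` columns: chrom, start, end (0-based half-open bp), individual,
    population, generation. Each informative individual contributes two
    meioses (one per parent), so meiosis counts start at 2x the individual
    count and are reduced when individuals are filtered out.
    """

    frame: pd.DataFrame = field(repr=False)
    meioses: dict[str, int]

    def __post_init__(self) -> None:
        missing = set(CO_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"CO table missing columns: {sorted(missing)}")
        if len(self.frame) and not (self.frame["start"] < self.frame["end"]).all():
            raise ValueError("all CO intervals must satisfy start < end")
        if any(m <= 0 for m in self.meioses.values()):
            raise ValueError("meiosis counts must be positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def meioses_total(self) -> int:
        return sum(self.meioses.values())

    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()


def filter_individuals(cos: COSet, max_total: int = 100) -> COSet:
    """Drop every CO of individuals with more than ``max_total`` COs in total.

    The threshold is evaluated on raw per-individual totals over both
    parental meioses and all chromosomes; an individual with exactly
    ``max_total`` COs is retained. Each removed individual subtracts two
    informative meioses from its population.
    """
    if len(cos) == 0:
        return cos
    totals = cos.frame.groupby("individual").size()
    bad = set(totals.index[totals > max_total])
    if not bad:
        return cos
    bad_mask = cos.frame["individual"].isin(bad)
    removed_pops = (
        cos.frame.loc[bad_mask, ["individual", "population"]]
        .drop_duplicates("individual")["population"]
        .value_counts()
        .to_dict()
    )
    meioses = dict(cos.meioses)
    for pop, n_removed in removed_pops.items():
        meioses[pop] = meioses.get(pop, 0) - 2 * int(n_removed)
    return COSet(frame=cos.frame.loc[~bad_mask].reset_index(drop=True), meioses=meioses)


def filter_intervals(cos: COSet, max_len: int = 2_000_000) -> COSet:
    """Discard CO intervals strictly longer than ``max_len`` bp (order preserved)."""
    if len(cos) == 0:
        return cos
    keep = (cos.frame["end"] - cos.frame["start"]) <= max_len
    return replace(cos, frame=cos.frame.loc[keep].reset_index(drop=True))


def assign_cos_to_bins(cos: COSet, grid: BinGrid) -> np.ndarray:
    """Proportionally distribute each CO interval over the bins it overlaps.

    A CO contributes ``overlap(CO, bin) / len(CO)`` to every overlapped bin,
    so its contributions sum to 1 and total CO mass is conserved.
    """
    counts = np.zeros(grid.n_bins, dtype=np.float64)
    grid_chroms = set(grid.frame["chrom"].unique())
    for chrom, sub in cos.frame.groupby("chrom", sort=False):
        if chrom not in grid_chroms:
            raise KeyError(f"CO chromosome {chrom!r} absent from bin grid")
        sl = grid.chrom_slice(str(chrom))
        counts[sl] += distribute_to_bins(
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            np.ones(len(sub)),
            grid.width,
            sl.stop - sl.start,
        )
    return counts


def recombination_rate(counts: np.ndarray, meioses_total: int, grid: BinGrid) -> np.ndarray:
    """Per-bin recombination rate in cM/Mbp.

    rate_i = 100 * (CO-equivalents in bin i / informative meioses) / bin length in Mbp.
    Truncated terminal bins use their true (shorter) length.
    """
    if meioses_total <= 0:
        raise ValueError("meioses_total must be positive")
    length_mbp = grid.lengths_bp() / 1e6
    return 100.0 * (np.asarray(counts, dtype=float) / meioses_total) / length_mbp


def count_snps(snp_positions: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    """Number of SNP markers per bin; ``snp_positions`` columns: chrom, pos (0-based)."""
    out = np.zeros(grid.n_bins, dtype=np.int64)
    grid_chroms = set(grid.frame["chrom"].unique())
    for chrom, sub in snp_positions.groupby("chrom", sort=False):
        if chrom not in grid_chroms:
            continue
        sl = grid.chrom_slice(str(chrom))
        idx = sub["pos"].to_numpy() // grid.width
        idx = idx[(idx >= 0) & (idx < sl.stop - sl.start)]
        np.add.at(out[sl], idx, 1)
    return out


@dataclass(frozen=True)
class RecombMap:
    """Binned recombination map: counts, rates, SNP normalization, hotspot labels.

    ``frame`` columns: chrom, start, end, mid, co_count, rate, snp_count,
    normalized_rate (NaN where snp_empty), snp_empty, hotspot_label
    ({hotspot, non_hotspot_sampled, unlabelled}).
    """

    frame: pd.DataFrame = field(repr=False)
    grid: BinGrid
    meioses_total: int

    def modelling_frame(self) -> pd.DataFrame:
        """Bins eligible for modelling: SNP-empty bins excluded."""
        return self.frame.loc[~self.frame["snp_empty"]].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_recomb_map(
    cos: COSet,
    grid: BinGrid,
    snp_positions: pd.DataFrame | None = None,
) -> RecombMap:
    """Assemble the per-bin map: fractional CO counts, rates, SNP normalization."""
    counts = assign_cos_to_bins(cos, grid)
    rate = recombination_rate(counts, cos.meioses_total, grid)
    frame = grid.frame.copy()
    frame["co_count"] = counts
    frame["rate"] = rate
    if snp_positions is not None:
        snps = count_snps(snp_positions, grid)
    else:
        snps = np.zeros(grid.n_bins, dtype=np.int64)
    frame["snp_count"] = snps
    empty = snps == 0
    frame["snp_empty"] = empty
    norm = np.full(grid.n_bins, np.nan)
    norm[~empty] = rate[~empty] / snps[~empty]
    frame["normalized_rate"] = norm
    frame["hotspot_label"] = "unlabelled"
    return RecombMap(frame=frame, grid=grid, meioses_total=cos.meioses_total)


def sample_hotspots(
    rmap: RecombMap,
    seed: int,
    top_quantile: float = 0.95,
    nonhotspot_below: float = 0.75,
    on: str = "rate",
) -> RecombMap:
    """Label hotspot bins and a balanced per-chromosome non-hotspot sample.

    Hotspots are the bins strictly above the genome-wide ``top_quantile``
    of ``on`` (SNP-empty bins excluded from both the percentile computation
    and labelling). For each chromosome, the same number of non-hotspot bins
    is drawn uniformly without replacement from that chromosome's eligible
    bins strictly below the genome-wide ``nonhotspot_below`` quantile. If a
    chromosome has too few eligible non-hotspot bins the sample is truncated
    with a warning.
    """
    frame = rmap.frame.copy()
    values = frame[on].to_numpy(dtype=float)
    eligible = ~frame["snp_empty"].to_numpy()
    thr_hot = np.quantile(values[eligible], top_quantile)
    thr_low = np.quantile(values[eligible], nonhotspot_below)
    is_hot = eligible & (values > thr_hot)
    labels = np.full(len(frame), "unlabelled", dtype=object)
    labels[is_hot] = "hotspot"
    rng = np.random.default_rng(seed)
    chrom_arr = frame["chrom"].to_numpy()
    for chrom in frame["chrom"].unique():
        on_chrom = chrom_arr == chrom
        n_hot = int((is_hot & on_chrom).sum())
        if n_hot == 0:
            continue
        pool = np.flatnonzero(on_chrom & eligible & (values < thr_low) & ~is_hot)
        if pool.size < n_hot:
            warnings.warn(
                f"{chrom}: only {pool.size} eligible non-hotspot bins for "
                f"{n_hot} hotspots; sample truncated",
                stacklevel=2,
            )
        take = rng.choice(pool, size=min(n_hot, pool.size), replace=False)
        labels[take] = "non_hotspot_sampled"
    frame["hotspot_label"] = labels
    return RecombMap(frame=frame, grid=rmap.grid, meioses_total=rmap.meioses_total)
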