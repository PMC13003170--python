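"""Synthetic genomes, multi-omic tracks, SNP maps and crossover sets.

The generator emulates the statistical structure the analysis assumes in an
allotetraploid A/C genome: a latent heterochromatin field rising toward the
centromere (sharply and further out in the C subgenome, giving the bimodal
A-vs-C feature distributions), methylation/TE tracks increasing and
gene/expression/accessibility tracks decreasing with that field, TE-body CHH
methylation coupled positively to gene content, SNP density coupled to gene
density, centromere-suppressed crossover intensity with subgenome-specific
positional profiles (subtelomeric peak in A, interior peak in C),
marker-resolution CO intervals, and a planted fraction of genotyping-artifact
individuals with inflated CO counts. The planted ground truth is returned
alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeLayout, build_bins, default_layout, telomere_distance
from .recmap import COSet

__all__ = ["SynthConfig", "SynthTruth", "SimResult", "generate_features",
           "generate_recombination", "simulate"]

FEATURE_ORDER = [
    "CpG", "CHG", "CHH", "CHH_TEs", "gene", "TE", "transposon", "retrotransposon",
    "accessibility", "expression", "GC", "AT", "telomere_distance", "C_subgenome",
]


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    layout: GenomeLayout = field(default_factory=default_layout)
    bin_width: int = 300_000
    n_individuals: tuple[int, ...] = (1243, 1323)
    mean_co_per_chromosome: float = 1.2
    #: log-intensity coefficients of (z-scored) features driving CO placement
    beta: dict[str, float] = field(
        default_factory=lambda: {"CpG": -1.5, "TE": -1.1, "gene": 1.3}
    )
    #: positional effect of telomere distance d on log CO intensity, per subgenome
    pos_amp: dict[str, float] = field(default_factory=lambda: {"A": 2.0, "C": 7.5})
    pos_peak: dict[str, float] = field(default_factory=lambda: {"A": 0.25, "C": 0.75})
    pos_width: dict[str, float] = field(default_factory=lambda: {"A": 0.25, "C": 0.22})
    #: arm fraction where the heterochromatin field rises, per subgenome
    het_midpoint: dict[str, float] = field(default_factory=lambda: {"A": 0.80, "C": 0.45})
    het_steepness: float = 0.08
    #: optional additive mean shifts applied to C-subgenome bins
    subgenome_offsets: dict[str, float] = field(default_factory=dict)
    latent_noise: float = 0.10
    noise_scale: float = 0.06
    smooth_window: int = 5
    snp_mean_per_bin: float = 4.0
    centromere_exclusion: float = 0.04  # fraction of chromosome length around centromere
    artifact_fraction: float = 0.01
    artifact_multiplier: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_co_per_chromosome <= 0:
            raise ValueError("mean_co_per_chromosome must be positive")
        if not (0 <= self.artifact_fraction < 1):
            raise ValueError("artifact_fraction must be in [0, 1)")
        if self.noise_scale < 0 or self.latent_noise < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class SynthTruth:
    """Planted ground truth for recovery tests."""

    beta: dict[str, float]
    pos_amp: dict[str, float]
    pos_peak: dict[str, float]
    pos_width: dict[str, float]
    chromatin: np.ndarray | None = None          # latent field per bin
    intensity: np.ndarray | None = None          # lambda per bin (0 in exclusion zones)
    excluded: np.ndarray | None = None           # centromere-exclusion mask per bin
    artifact_individuals: list[str] = field(default_factory=list)
    co_points: pd.DataFrame | None = None        # latent CO positions, one row per emitted CO


def _smoothed_noise(rng, n: int, scale: float, window: int) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise: spatially autocorrelated."""
    raw = rng.normal(0.0, scale, size=n + window - 1)
    kernel = np.ones(window) / window
    return np.convolve(raw, kernel, mode="valid") * np.sqrt(window)


def generate_features(
    layout: GenomeLayout,
    grid: BinGrid,
    config: SynthConfig,
    rng: np.random.Generator,
    truth: SynthTruth | None = None,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Per-bin multi-omic feature tracks with the planted correlation structure.

    A latent chromatin field c in [0, 1] (sigmoid of telomere distance plus
    smoothed noise, shifted upward in the C subgenome) drives every track:
    methylation contexts and TE coverage rise with c, gene coverage,
    expression and accessibility fall with it; GC tracks c weakly and the AT
    dinucleotide mirrors GC tightly (the nucleotide-composition cluster);
    TE-body CHH methylation is tied to gene coverage (positive association);
    SNP counts are Poisson with intensity increasing in gene coverage.
    """
    if grid.n_bins == 0:
        raise ValueError("empty bin grid")
    if truth is None:
        truth = SynthTruth(
            beta=dict(config.beta),
            pos_amp=dict(config.pos_amp),
            pos_peak=dict(config.pos_peak),
            pos_width=dict(config.pos_width),
        )
    chroms = grid.frame["chrom"].to_numpy()
    d = telomere_distance(grid.frame["mid"].to_numpy(), chroms, layout)
    sub = np.array([layout.subgenome_of(c) for c in chroms])
    is_c = (sub == "C").astype(float)

    mid = np.where(is_c == 1, config.het_midpoint["C"], config.het_midpoint["A"])
    base = 1.0 / (1.0 + np.exp(-(d - mid) / config.het_steepness))
    noise = np.empty(grid.n_bins)
    for chrom in pd.unique(chroms):
        sl = grid.chrom_slice(str(chrom))
        noise[sl] = _smoothed_noise(rng, sl.stop - sl.start, config.latent_noise,
                                    config.smooth_window)
    c_field = np.clip(base + noise, 0.0, 1.0)
    truth.chromatin = c_field

    ns = config.noise_scale

    def eps(scale=ns):
        return rng.normal(0.0, scale, size=grid.n_bins)

    # planted CO drivers (CpG, TE, gene) track the latent field tightly; the
    # remaining chromatin proxies carry extra independent noise so they are
    # correlated-but-distinguishable, as in real multi-omic panels
    gene = np.clip(0.65 - 0.52 * c_field + eps(), 0, 1)
    feats = pd.DataFrame(
        {
            "CpG": np.clip(0.12 + 0.70 * c_field + eps(), 0, 1),
            "CHG": np.clip(0.08 + 0.55 * c_field + eps(0.12), 0, 1),
            "CHH": np.clip(0.01 + 0.09 * c_field + eps(0.03), 0, 1),
            "CHH_TEs": np.clip(0.08 + 0.06 * gene + eps(0.015), 0, 1),
            "gene": gene,
            "TE": np.clip(0.15 + 0.65 * c_field + eps(), 0, 1),
            "transposon": np.clip(0.05 + 0.20 * c_field + eps(0.07), 0, 1),
            "retrotransposon": np.clip(0.08 + 0.50 * c_field + eps(0.12), 0, 1),
            "accessibility": np.clip(0.45 - 0.30 * c_field + eps(0.09), 0, 1),
            "expression": -1.0 + 2.0 * gene + eps(0.30),
            "GC": np.clip(0.36 + 0.05 * c_field + eps(0.03), 0, 1),
            "telomere_distance": d,
            "C_subgenome": is_c,
        }
    )
    for name, off in config.subgenome_offsets.items():
        shifted = feats[name] + off * is_c
        feats[name] = shifted if name == "expression" else np.clip(shifted, 0, 1)
    feats["AT"] = np.clip(0.88 - 1.1 * feats["GC"] + eps(0.005), 0, 1)
    w = 0.15 + gene / max(gene.mean(), 1e-9)
    lam_snp = config.snp_mean_per_bin * w / w.mean()
    # truncated terminal bins get proportionally fewer markers
    lam_snp = lam_snp * grid.lengths_bp() / grid.width
    feats["snp_count"] = rng.poisson(lam_snp)
    return feats[FEATURE_ORDER + ["snp_count"]], truth


def _positional_effect(d: np.ndarray, sub: np.ndarray, config: SynthConfig) -> np.ndarray:
    out = np.empty_like(d)
    for s in ("A", "C"):
        m = sub == s
        out[m] = config.pos_amp[s] * np.exp(
            -(((d[m] - config.pos_peak[s]) / config.pos_width[s]) ** 2)
        )
    return out


def generate_recombination(
    layout: GenomeLayout,
    grid: BinGrid,
    features: pd.DataFrame,
    truth: SynthTruth,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[COSet, pd.DataFrame]:
    """Simulate SNP maps and marker-resolution CO intervals per meiosis.

    Per-bin CO intensity is exp(beta . z-scored features + positional effect
    of telomere distance, subgenome-specific), clamped to zero within the
    centromere exclusion window. Each individual undergoes two informative
    meioses; CO counts per meiosis and chromosome are Poisson with the
    configured mean, crossover points are placed proportionally to intensity,
    and each CO is reported as the interval between its two flanking
    simulated markers (array-resolution emulation; points without flanking
    markers on both sides are unobservable and dropped). A configured
    fraction of individuals receives multiplied CO counts, emulating
    genotyping artifacts; their ids are recorded in the truth.
    """
    chroms = grid.frame["chrom"].to_numpy()
    d = features["telomere_distance"].to_numpy()
    sub = np.array([layout.subgenome_of(c) for c in chroms])

    log_lam = np.zeros(grid.n_bins)
    for name, b in config.beta.items():
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        if sd > 0:
            log_lam += b * (x - x.mean()) / sd
    log_lam += _positional_effect(d, sub, config)
    lam = np.exp(log_lam)

    mids = grid.frame["mid"].to_numpy()
    excluded = np.zeros(grid.n_bins, dtype=bool)
    for rec in layout.chromosomes:
        sl = grid.chrom_slice(rec.name)
        excluded[sl] = (
            np.abs(mids[sl] - rec.centromere) < config.centromere_exclusion * rec.length
        )
    lam = np.where(excluded, 0.0, lam)
    truth.intensity = lam
    truth.excluded = excluded

    # SNP marker positions: uniform within each bin given the planted counts
    snp_rows = []
    marker_arrays: dict[str, np.ndarray] = {}
    counts_per_bin = features["snp_count"].to_numpy()
    for rec in layout.chromosomes:
        sl = grid.chrom_slice(rec.name)
        starts = grid.frame["start"].to_numpy()[sl]
        ends = grid.frame["end"].to_numpy()[sl]
        ks = counts_per_bin[sl]
        pos = np.concatenate(
            [
                rng.uniform(s, e, size=int(k)).astype(np.int64)
                for s, e, k in zip(starts, ends, ks)
            ]
            or [np.array([], dtype=np.int64)]
        )
        pos = np.unique(pos)
        marker_arrays[rec.name] = pos
        snp_rows.append(pd.DataFrame({"chrom": rec.name, "pos": pos}))
    snp_map = pd.concat(snp_rows, ignore_index=True)

    # individuals, populations, artifact flags
    pops, individuals, artifact = [], [], []
    for p, n in enumerate(config.n_individuals, start=1):
        ids = [f"P{p}_{i:05d}" for i in range(n)]
        n_art = int(round(config.artifact_fraction * n))
        art_idx = rng.choice(n, size=n_art, replace=False) if n_art else np.array([], int)
        flags = np.zeros(n, dtype=bool)
        flags[art_idx] = True
        pops.extend([f"Pop{p}"] * n)
        individuals.extend(ids)
        artifact.extend(flags.tolist())
    individuals = np.array(individuals)
    pops = np.array(pops)
    artifact = np.array(artifact)
    truth.artifact_individuals = sorted(individuals[artifact].tolist())
    generations = rng.integers(2, 5, size=individuals.size)

    n_meioses = 2 * individuals.size
    mean_co = np.where(
        np.repeat(artifact, 2), config.mean_co_per_chromosome * config.artifact_multiplier,
        config.mean_co_per_chromosome,
    )

    records = []
    point_rows: list[pd.DataFrame] = []
    for rec in layout.chromosomes:
        sl = grid.chrom_slice(rec.name)
        weights = lam[sl] * (grid.lengths_bp()[sl] / grid.width)
        total_w = weights.sum()
        if total_w <= 0:
            raise ValueError(f"{rec.name}: all-zero CO intensity")
        p_bins = weights / total_w
        counts = rng.poisson(mean_co)  # one draw per meiosis for this chromosome
        total = int(counts.sum())
        if total == 0:
            continue
        bin_idx = rng.choice(p_bins.size, size=total, p=p_bins)
        starts = grid.frame["start"].to_numpy()[sl][bin_idx]
        ends = grid.frame["end"].to_numpy()[sl][bin_idx]
        points = rng.uniform(starts, ends)
        meiosis_of = np.repeat(np.arange(n_meioses), counts)
        markers = marker_arrays[rec.name]
        j = np.searchsorted(markers, points, side="left")
        ok = (j > 0) & (j < markers.size)
        j = j[ok]
        points = points[ok]
        meiosis_of = meiosis_of[ok]
        ind_idx = meiosis_of // 2
        point_rows.append(pd.DataFrame({"chrom": rec.name, "pos": points}))
        records.append(
            pd.DataFrame(
                {
                    "chrom": rec.name,
                    "start": markers[j - 1],
                    "end": markers[j],
                    "individual": individuals[ind_idx],
                    "population": pops[ind_idx],
                    "generation": generations[ind_idx],
                }
            )
        )
    frame = pd.concat(records, ignore_index=True)
    truth.co_points = pd.concat(point_rows, ignore_index=True)
    meioses = {
        f"Pop{p}": 2 * n for p, n in enumerate(config.n_individuals, start=1)
    }
    return COSet(frame=frame, meioses=meioses), snp_map


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    config: SynthConfig
    layout: GenomeLayout
    grid: BinGrid
    features: pd.DataFrame
    truth: SynthTruth
    cos: COSet
    snp_map: pd.DataFrame


def simulate(config: SynthConfig | None = None, seed: int | None = None) -> SimResult:
    """Run the full generator: layout -> bins -> feature tracks -> CO set.

    ``seed`` overrides ``config.seed``; with a fixed seed the output is
    bit-reproducible.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    grid = build_bins(config.layout, config.bin_width)
    features, truth = generate_features(config.layout, grid, config, rng)
    cos, snp_map = generate_recombination(config.layout, grid, features, truth, config, rng)
    return SimResult(
        config=config, layout=config.layout, grid=grid, features=features,
        truth=truth, cos=cos, snp_map=snp_map,
    )
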