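"""Genome coordinate model for an allopolyploid (A + C subgenome) genome.

Provides the chromosome layout (lengths, subgenome membership, single-point
centromeres, homoeolog groups), the fixed-width bin grid on which every
downstream track lives, the telomere-distance feature, and the
homoeolog-grouped fold assignments used for leakage-free cross-validation.

All internal coordinates are 0-based half-open; the I/O layer converts
1-based closed dialects at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChromRecord",
    "GenomeLayout",
    "BinGrid",
    "default_layout",
    "build_bins",
    "telomere_distance",
    "homoeolog_folds",
]


@dataclass(frozen=True)
class ChromRecord:
    """One chromosome: label, length (bp), subgenome (A/C), centromere point, homoeolog group."""

    name: str
    length: int
    subgenome: str
    centromere: int
    homoeolog_group: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (0 < self.centromere < self.length):
            raise ValueError(f"{self.name}: centromere must lie strictly inside the chromosome")
        if self.subgenome not in ("A", "C"):
            raise ValueError(f"{self.name}: subgenome must be 'A' or 'C'")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome layout of the genome."""

    chromosomes: tuple[ChromRecord, ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout must contain at least one chromosome")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> ChromRecord:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    def subgenome_of(self, name: str) -> str:
        return self[name].subgenome

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [c.length for c in self.chromosomes],
                "subgenome": [c.subgenome for c in self.chromosomes],
                "centromere": [c.centromere for c in self.chromosomes],
                "homoeolog_group": [c.homoeolog_group for c in self.chromosomes],
            }
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "length", "subgenome", "centromere", "homoeolog_group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"layout file missing columns: {sorted(missing)}")
        recs = tuple(
            ChromRecord(
                name=str(r.chrom),
                length=int(r.length),
                subgenome=str(r.subgenome),
                centromere=int(r.centromere),
                homoeolog_group=int(r.homoeolog_group),
            )
            for r in df.itertuples()
        )
        return cls(recs)

    def scaled(self, factor: float) -> "GenomeLayout":
        """Return a layout with all lengths/centromeres multiplied by ``factor``.

        Handy for running the full pipeline at reduced problem size.
        """
        recs = tuple(
            ChromRecord(
                name=c.name,
                length=max(1, int(round(c.length * factor))),
                subgenome=c.subgenome,
                centromere=max(1, int(round(c.centromere * factor))),
                homoeolog_group=c.homoeolog_group,
            )
            for c in self.chromosomes
        )
        return GenomeLayout(recs)


# Synthetic default: 19 chromosomes, 10 A + 9 C, with loosely realistic rapeseed
# proportions (C subgenome physically larger than A). Lengths are in bp;
# centromeres are single representative points at varied arm fractions.
_DEFAULT_SPEC: list[tuple[str, float, str, float, int]] = [
    # (name, length Mbp, subgenome, centromere fraction, homoeolog group)
    ("A01", 27.8, "A", 0.42, 1),
    ("A02", 31.2, "A", 0.55, 2),
    ("A03", 35.1, "A", 0.48, 3),
    ("A04", 23.5, "A", 0.38, 4),
    ("A05", 26.9, "A", 0.52, 5),
    ("A06", 28.4, "A", 0.45, 6),
    ("A07", 29.3, "A", 0.58, 7),
    ("A08", 21.9, "A", 0.41, 8),
    ("A09", 45.4, "A", 0.50, 9),
    ("A10", 24.8, "A", 0.36, 9),
    ("C01", 44.8, "C", 0.46, 1),
    ("C02", 51.2, "C", 0.54, 2),
    ("C03", 65.0, "C", 0.50, 3),
    ("C04", 55.1, "C", 0.44, 4),
    ("C05", 45.3, "C", 0.57, 5),
    ("C06", 41.4, "C", 0.40, 6),
    ("C07", 48.4, "C", 0.49, 7),
    ("C08", 42.5, "C", 0.53, 8),
    ("C09", 52.9, "C", 0.47, 9),
]


def default_layout(scale: float = 1.0) -> GenomeLayout:
    """The packaged synthetic 19-chromosome rapeseed-like layout.

    10 A chromosomes (A01-A10) and 9 C chromosomes (C01-C09); homoeolog
    groups pair A0k with C0k for k=1..8, and A09/A10/C09 form the ninth
    group (A10 has no C counterpart). ``scale`` shrinks chromosome lengths
    proportionally for fast runs.
    """
    recs = tuple(
        ChromRecord(
            name=name,
            length=int(round(mbp * 1e6 * scale)),
            subgenome=sub,
            centromere=int(round(mbp * 1e6 * scale * cen_frac)),
            homoeolog_group=grp,
        )
        for name, mbp, sub, cen_frac, grp in _DEFAULT_SPEC
    )
    return GenomeLayout(recs)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width, non-overlapping bin grid covering every chromosome.

    ``frame`` has one row per bin with columns chrom, start, end, mid; bins
    are contiguous and sorted within a chromosome, all of length ``width``
    except possibly a truncated terminal bin.
    """

    frame: pd.DataFrame = field(repr=False)
    width: int

    @property
    def n_bins(self) -> int:
        return len(self.frame)

    def lengths_bp(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.frame["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bins_per_chromosome(self) -> dict[str, int]:
        return self.frame.groupby("chrom", sort=False).size().to_dict()


def build_bins(layout: GenomeLayout, width: int = 300_000) -> BinGrid:
    """Partition each chromosome into half-open bins of ``width`` bp.

    The number of bins per chromosome is ceil(length / width); the final bin
    is truncated at the chromosome end and keeps its true length.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    for c in layout.chromosomes:
        starts = np.arange(0, c.length, width, dtype=np.int64)
        ends = np.minimum(starts + width, c.length)
        rows.append(
            pd.DataFrame(
                {"chrom": c.name, "start": starts, "end": ends, "mid": (starts + ends) // 2}
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    return BinGrid(frame=frame, width=width)


def telomere_distance(
    midpoints, chroms, layout: GenomeLayout, orientation: str = "telomere"
) -> np.ndarray:
    """Relative position along the chromosome arm for each bin midpoint.

    With the default ``orientation="telomere"`` the value is 0 at either
    telomere and 1 at the centromere (the orientation used for the
    "distance from telomere" feature axis); ``orientation="centromere"``
    returns the reflected ratio (0 at the centromere).
    """
    if orientation not in ("telomere", "centromere"):
        raise ValueError("orientation must be 'telomere' or 'centromere'")
    midpoints = np.asarray(midpoints, dtype=np.float64)
    chroms = np.asarray(chroms)
    out = np.empty(midpoints.shape, dtype=np.float64)
    for name in np.unique(chroms):
        rec = layout[str(name)]
        m = chroms == name
        mid = midpoints[m]
        left = mid <= rec.centromere
        d = np.empty(mid.shape)
        d[left] = mid[left] / rec.centromere
        d[~left] = (rec.length - mid[~left]) / (rec.length - rec.centromere)
        out[m] = np.clip(d, 0.0, 1.0)
    if orientation == "centromere":
        out = 1.0 - out
    return out


def homoeolog_folds(
    layout: GenomeLayout, subgenome_filter: str | None = None
) -> list[list[str]]:
    """Cross-validation fold assignments over chromosomes.

    Genome-wide: one fold per homoeolog group (9 on the default layout).
    Restricted to a single subgenome, homoeolog grouping is moot and each
    chromosome forms its own fold.
    """
    if subgenome_filter is None:
        groups: dict[int, list[str]] = {}
        for c in layout.chromosomes:
            groups.setdefault(c.homoeolog_group, []).append(c.name)
        return [groups[g] for g in sorted(groups)]
    if subgenome_filter not in ("A", "C"):
        raise ValueError("subgenome_filter must be 'A', 'C', or None")
    return [[c.name] for c in layout.chromosomes if c.subgenome == subgenome_filter]
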