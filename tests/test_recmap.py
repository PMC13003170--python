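"""CO filtering, proportional bin assignment, rates, SNP normalization, hotspots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from recombml.genome import ChromRecord, GenomeLayout, build_bins
from recombml.recmap import (
    COSet,
    assign_cos_to_bins,
    build_recomb_map,
    count_snps,
    filter_individuals,
    filter_intervals,
    recombination_rate,
    sample_hotspots,
)

from conftest import make_coset


class TestFilterIndividuals:
    def test_boundary_at_threshold(self):
        # ind_a: exactly 100 COs (retained); ind_b: 101 COs (removed)
        recs = [("A01", i * 10, i * 10 + 5, "ind_a") for i in range(100)]
        recs += [("A01", i * 10, i * 10 + 5, "ind_b") for i in range(101)]
        cos = make_coset(recs)
        out = filter_individuals(cos, max_total=100)
        assert set(out.frame["individual"]) == {"ind_a"}
        assert len(out) == 100

    def test_meioses_reduced_by_two_per_removed_individual(self):
        recs = [("A01", i, i + 1, "bad") for i in range(150)]
        recs += [("A01", 0, 5, "good1"), ("A01", 10, 15, "good2")]
        cos = make_coset(recs)
        assert cos.meioses == {"Pop1": 6}
        out = filter_individuals(cos)
        assert out.meioses == {"Pop1": 4}

    def test_empty_set_passthrough(self):
        cos = COSet(
            frame=pd.DataFrame(
                columns=["chrom", "start", "end", "individual", "population", "generation"]
            ),
            meioses={"Pop1": 10},
        )
        assert len(filter_individuals(cos)) == 0

    def test_commutes_with_interval_filter_on_raw_thresholds(self):
        rng = np.random.default_rng(7)
        recs = []
        for ind in range(30):
            n = rng.integers(1, 160)
            for _ in range(n):
                start = int(rng.integers(0, 2_000_000))
                recs.append(("A01", start, start + int(rng.integers(1, 3_000_000)), f"i{ind}"))
        cos = make_coset(recs)
        a = filter_intervals(filter_individuals(cos))
        b = filter_individuals(filter_intervals(cos), max_total=100)
        # commutation holds when the individual threshold is evaluated on the
        # raw set; order used by the pipeline is individuals-first
        raw_bad = cos.frame.groupby("individual").size()
        bad = set(raw_bad.index[raw_bad > 100])
        b_frame = b.frame[~b.frame["individual"].isin(bad)]
        assert set(a.frame["individual"]) <= set(cos.frame["individual"]) - bad
        assert len(a) <= len(b_frame) or len(a) == len(b.frame)


class TestFilterIntervals:
    def test_strict_longer_than_boundary(self):
        cos = make_coset(
            [
                ("A01", 0, 2_000_000, "a"),  # exactly 2 Mbp: retained
                ("A01", 0, 2_000_001, "b"),  # longer: removed
            ]
        )
        out = filter_intervals(cos)
        assert list(out.frame["individual"]) == ["a"]

    def test_all_short_is_identity(self):
        cos = make_coset([("A01", 0, 10, "a"), ("A01", 50, 80, "b")])
        out = filter_intervals(cos)
        pd.testing.assert_frame_equal(out.frame, cos.frame)


class TestAssignment:
    def test_fully_contained_co(self, toy_grid):
        cos = make_coset([("A01", 10_000, 20_000, "a")])
        counts = assign_cos_to_bins(cos, toy_grid)
        assert counts[0] == pytest.approx(1.0)
        assert counts.sum() == pytest.approx(1.0)

    def test_proportional_split_across_bins(self, toy_grid):
        cos = make_coset([("A01", 250_000, 550_000, "a")])
        counts = assign_cos_to_bins(cos, toy_grid)
        assert counts[0] == pytest.approx(1 / 6)
        assert counts[1] == pytest.approx(5 / 6)

    def test_vectorized_equals_per_co_loop(self, toy_layout, toy_grid, rng):
        chroms = rng.choice(toy_layout.names, size=1000)
        lengths = {c.name: c.length for c in toy_layout.chromosomes}
        starts = np.array([rng.integers(0, lengths[c] - 10) for c in chroms])
        ends = np.array(
            [min(s + rng.integers(1, 900_000), lengths[c]) for s, c in zip(starts, chroms)]
        )
        cos = make_coset(list(zip(chroms, starts, ends, [f"i{k}" for k in range(1000)])))
        counts = assign_cos_to_bins(cos, toy_grid)
        oracle = np.zeros(toy_grid.n_bins)
        gf = toy_grid.frame
        for c, s, e in zip(chroms, starts, ends):
            for b in range(toy_grid.n_bins):
                if gf["chrom"].iloc[b] != c:
                    continue
                ov = max(0, min(e, gf["end"].iloc[b]) - max(s, gf["start"].iloc[b]))
                oracle[b] += ov / (e - s)
        assert np.allclose(counts, oracle, atol=1e-9)
        # mass conservation
        assert counts.sum() == pytest.approx(1000.0, abs=1e-9)

    def test_unknown_chromosome_raises(self, toy_grid):
        cos = make_coset([("Z01", 0, 10, "a")])
        with pytest.raises(KeyError):
            assign_cos_to_bins(cos, toy_grid)


class TestRate:
    def test_worked_example(self):
        """3 CO-equivalents over 1,000 meioses in a 0.3-Mbp bin is 1 cM/Mbp."""
        lay = GenomeLayout((ChromRecord("A01", 300_000, "A", 100_000, 1),))
        grid = build_bins(lay, 300_000)
        rate = recombination_rate(np.array([3.0]), 1000, grid)
        assert rate[0] == pytest.approx(1.0)

    def test_zero_cos_zero_rate(self, toy_grid):
        rate = recombination_rate(np.zeros(toy_grid.n_bins), 500, toy_grid)
        assert (rate == 0).all()

    def test_genome_wide_identity(self, toy_grid, toy_layout, rng):
        """Sum of rate_i x len_i equals 100 x N_CO / meioses."""
        lengths = {c.name: c.length for c in toy_layout.chromosomes}
        chroms = rng.choice(toy_layout.names, size=500)
        starts = np.array([rng.integers(0, lengths[c] - 10) for c in chroms])
        ends = np.array(
            [min(s + rng.integers(1, 500_000), lengths[c]) for s, c in zip(starts, chroms)]
        )
        cos = make_coset(list(zip(chroms, starts, ends, [f"i{k}" for k in range(500)])))
        counts = assign_cos_to_bins(cos, toy_grid)
        rate = recombination_rate(counts, cos.meioses_total, toy_grid)
        total = (rate * toy_grid.lengths_bp() / 1e6).sum()
        assert total == pytest.approx(100 * 500 / cos.meioses_total, abs=1e-9)

    def test_zero_meioses_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            recombination_rate(np.zeros(toy_grid.n_bins), 0, toy_grid)


class TestNormalization:
    def test_normalized_rate_and_empty_flag(self, toy_grid):
        cos = make_coset([("A01", 0, 100, "a")])
        snps = pd.DataFrame({"chrom": ["A01"] * 4, "pos": [10, 20, 30, 400_000]})
        rmap = build_recomb_map(cos, toy_grid, snps)
        fr = rmap.frame
        assert fr["snp_count"].iloc[0] == 3
        assert fr["normalized_rate"].iloc[0] == pytest.approx(fr["rate"].iloc[0] / 3)
        assert fr["snp_empty"].iloc[2]
        assert np.isnan(fr["normalized_rate"].iloc[2])
        assert (fr["snp_empty"] == (fr["snp_count"] == 0)).all()

    def test_uniform_snp_density_preserves_ranks(self, toy_grid, toy_layout, rng):
        lengths = {c.name: c.length for c in toy_layout.chromosomes}
        chroms = rng.choice(toy_layout.names, size=300)
        starts = np.array([rng.integers(0, lengths[c] - 10) for c in chroms])
        cos = make_coset(
            list(zip(chroms, starts, starts + 5_000, [f"i{k}" for k in range(300)]))
        )
        # exactly 2 SNPs in every bin
        gf = toy_grid.frame
        snps = pd.DataFrame(
            {
                "chrom": np.repeat(gf["chrom"].to_numpy(), 2),
                "pos": np.concatenate(
                    [[s + 1, s + 2] for s in gf["start"]]
                ),
            }
        )
        rmap = build_recomb_map(cos, toy_grid, snps)
        rho = sps.spearmanr(rmap.frame["rate"], rmap.frame["normalized_rate"])[0]
        assert rho == pytest.approx(1.0)

    def test_count_snps(self, toy_grid):
        snps = pd.DataFrame({"chrom": ["A01", "A01", "C01"], "pos": [0, 299_999, 5]})
        counts = count_snps(snps, toy_grid)
        assert counts[toy_grid.chrom_slice("A01")][0] == 2
        assert counts[toy_grid.chrom_slice("C01")][0] == 1


class TestHotspots:
    def _map_with_rates(self, rates, chroms=None, snp_per_bin=1):
        n = len(rates)
        chroms = chroms or ["A01"] * n
        width = 1000
        frame = pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.tile(np.arange(0, 10**9, width), 5)[:n],
                "end": np.tile(np.arange(width, 10**9 + width, width), 5)[:n],
            }
        )
        # rebuild per-chromosome coordinates
        parts = []
        for c in pd.unique(np.asarray(chroms)):
            k = sum(np.asarray(chroms) == c)
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": np.arange(k) * width,
                        "end": (np.arange(k) + 1) * width,
                    }
                )
            )
        frame = pd.concat(parts, ignore_index=True)
        frame["mid"] = (frame["start"] + frame["end"]) // 2
        frame["co_count"] = 0.0
        frame["rate"] = rates
        frame["snp_count"] = snp_per_bin
        frame["snp_empty"] = frame["snp_count"] == 0
        frame["normalized_rate"] = frame["rate"] / np.maximum(frame["snp_count"], 1)
        frame["hotspot_label"] = "unlabelled"
        from recombml.genome import BinGrid
        from recombml.recmap import RecombMap

        grid = BinGrid(frame=frame[["chrom", "start", "end", "mid"]].copy(), width=width)
        return RecombMap(frame=frame, grid=grid, meioses_total=100)

    def test_five_percent_of_100_distinct_bins(self):
        rmap = self._map_with_rates(list(np.arange(100.0)))
        out = sample_hotspots(rmap, seed=0)
        labels = out.frame["hotspot_label"]
        assert (labels == "hotspot").sum() == 5
        assert (labels == "non_hotspot_sampled").sum() == 5
        hot = set(out.frame.index[labels == "hotspot"])
        non = set(out.frame.index[labels == "non_hotspot_sampled"])
        assert hot.isdisjoint(non)
        # hotspots are the top five rates
        assert sorted(out.frame.loc[sorted(hot), "rate"]) == [95, 96, 97, 98, 99]

    def test_chromosome_without_hotspots_contributes_nothing(self):
        rates = list(np.arange(100.0)) + [1.0] * 50  # chr2 all cold
        chroms = ["A01"] * 100 + ["A02"] * 50
        rmap = self._map_with_rates(rates, chroms)
        out = sample_hotspots(rmap, seed=0)
        chr2 = out.frame[out.frame["chrom"] == "A02"]
        assert (chr2["hotspot_label"] == "unlabelled").all()

    def test_snp_empty_bins_excluded_everywhere(self):
        rates = list(np.arange(100.0))
        rmap = self._map_with_rates(rates)
        rmap.frame.loc[99, "snp_count"] = 0
        rmap.frame.loc[99, "snp_empty"] = True
        out = sample_hotspots(rmap, seed=0)
        assert out.frame.loc[99, "hotspot_label"] == "unlabelled"

    def test_seed_determinism(self):
        rmap = self._map_with_rates(list(np.arange(200.0)))
        a = sample_hotspots(rmap, seed=5).frame["hotspot_label"]
        b = sample_hotspots(rmap, seed=5).frame["hotspot_label"]
        c = sample_hotspots(rmap, seed=6).frame["hotspot_label"]
        assert (a == b).all()
        assert set(np.flatnonzero(a == "hotspot")) == set(np.flatnonzero(c == "hotspot"))

    def test_per_chromosome_balance(self):
        rng = np.random.default_rng(0)
        rates = rng.uniform(0, 10, 300)
        chroms = ["A01"] * 150 + ["C01"] * 150
        out = sample_hotspots(self._map_with_rates(list(rates), chroms), seed=1)
        fr = out.frame
        for c in ("A01", "C01"):
            sub = fr[fr["chrom"] == c]
            assert (sub["hotspot_label"] == "hotspot").sum() == (
                sub["hotspot_label"] == "non_hotspot_sampled"
            ).sum()
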