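"""Multi-omic feature computation: coverage, methylation, sequence, smoothing."""

import numpy as np
import pandas as pd
import pytest

from recombml.features import (
    accessibility_score,
    assemble_table,
    coverage_fraction,
    dinucleotide_fraction,
    expression_score,
    gc_content,
    methylation_rate,
    ses_smooth,
    te_body_chh,
    weighted_methylation,
)
from recombml.genome import ChromRecord, GenomeLayout, build_bins


@pytest.fixture(scope="module")
def small_grid():
    lay = GenomeLayout((ChromRecord("A01", 10_000, "A", 5_000, 1),))
    return build_bins(lay, 1_000)  # 10 bins of 1 kb


def ivs(*triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"])


class TestCoverage:
    def test_duplicates_counted_once(self, small_grid):
        out = coverage_fraction(ivs(("A01", 0, 500), ("A01", 0, 500)), small_grid)
        assert out[0] == pytest.approx(0.5)

    def test_boundary_spanning_interval(self, small_grid):
        out = coverage_fraction(ivs(("A01", 800, 1_300)), small_grid)
        assert out[0] == pytest.approx(0.2)
        assert out[1] == pytest.approx(0.3)

    def test_trimming_removes_higher_priority_overlap(self, small_grid):
        te = ivs(("A01", 0, 1_000))
        genes = ivs(("A01", 0, 400))
        out = coverage_fraction(te, small_grid, trim_against=[genes])
        assert out[0] == pytest.approx(0.6)

    def test_against_per_base_mask_oracle(self, small_grid, rng):
        n = 60
        starts = rng.integers(0, 9_900, size=n)
        ends = np.minimum(starts + rng.integers(1, 700, size=n), 10_000)
        frame = pd.DataFrame({"chrom": "A01", "start": starts, "end": ends})
        out = coverage_fraction(frame, small_grid)
        mask = np.zeros(10_000, dtype=bool)
        for s, e in zip(starts, ends):
            mask[s:e] = True
        oracle = mask.reshape(10, 1_000).mean(axis=1)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_out_of_bounds_clipped_with_warning(self, small_grid):
        with pytest.warns(UserWarning):
            out = coverage_fraction(ivs(("A01", 9_500, 11_000)), small_grid)
        assert out[-1] == pytest.approx(0.5)


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "context", "tissue", "replicate", "meth", "total"]
    )


class TestMethylation:
    def test_averaging_cascade_single_cytosine(self, small_grid):
        calls = calls_frame(
            [
                ("A01", 100, "CpG", "leaf", "r1", 2, 4),
                ("A01", 100, "CpG", "leaf", "r2", 1, 1),
            ]
        )
        out = methylation_rate(calls, small_grid, "CpG")
        assert out[0] == pytest.approx((0.5 + 1.0) / 2)

    def test_cytosine_missing_in_a_replicate_excluded(self, small_grid):
        calls = calls_frame(
            [
                ("A01", 100, "CpG", "leaf", "r1", 2, 4),
                ("A01", 200, "CpG", "leaf", "r1", 4, 4),
                ("A01", 200, "CpG", "leaf", "r2", 0, 4),
            ]
        )
        out = methylation_rate(calls, small_grid, "CpG")
        # position 100 seen in only one of leaf's two replicates: dropped
        assert out[0] == pytest.approx(0.5)

    def test_all_methylated_gives_one(self, small_grid):
        calls = calls_frame(
            [("A01", p, "CpG", "leaf", "r1", 5, 5) for p in (10, 20, 30)]
        )
        assert methylation_rate(calls, small_grid, "CpG")[0] == pytest.approx(1.0)

    def test_tissue_then_replicate_averaging(self, small_grid):
        calls = calls_frame(
            [
                ("A01", 100, "CpG", "leaf", "r1", 1, 2),  # 0.5
                ("A01", 100, "CpG", "root", "r1", 0, 4),  # 0.0
            ]
        )
        assert methylation_rate(calls, small_grid, "CpG")[0] == pytest.approx(0.25)

    def test_weighted_pools_counts(self, small_grid):
        calls = calls_frame(
            [
                ("A01", 100, "CpG", "leaf", "r1", 2, 4),
                ("A01", 200, "CpG", "leaf", "r1", 1, 1),
            ]
        )
        out = weighted_methylation(calls, small_grid, "CpG")
        assert out[0] == pytest.approx(3 / 5)
        # single-base mean differs under uneven coverage
        sb = methylation_rate(calls, small_grid, "CpG")
        assert sb[0] == pytest.approx(0.75)

    def test_weighted_equals_single_base_under_uniform_coverage(self, small_grid, rng):
        rows = []
        for p in range(10, 900, 37):
            meth = int(rng.integers(0, 5))
            rows.append(("A01", p, "CpG", "leaf", "r1", meth, 4))
        calls = calls_frame(rows)
        assert weighted_methylation(calls, small_grid, "CpG")[0] == pytest.approx(
            methylation_rate(calls, small_grid, "CpG")[0]
        )

    def test_empty_bins_are_nan(self, small_grid):
        calls = calls_frame([("A01", 100, "CpG", "leaf", "r1", 1, 2)])
        out = methylation_rate(calls, small_grid, "CpG")
        assert np.isnan(out[5])


class TestTeBodyChh:
    def test_restriction_to_te_positions(self, small_grid):
        calls = calls_frame(
            [
                ("A01", 100, "CHH", "leaf", "r1", 1, 1),  # inside TE
                ("A01", 500, "CHH", "leaf", "r1", 0, 1),  # outside
            ]
        )
        te = ivs(("A01", 50, 200))
        out = te_body_chh(calls, te, small_grid)
        assert out[0] == pytest.approx(1.0)

    def test_te_covering_everything_equals_plain_chh(self, small_grid, rng):
        rows = [
            ("A01", int(p), "CHH", "leaf", "r1", int(rng.integers(0, 3)), 3)
            for p in rng.integers(1, 10_000, size=80)
        ]
        calls = calls_frame(rows)
        te = ivs(("A01", 0, 10_000))
        out = te_body_chh(calls, te, small_grid)
        plain = methylation_rate(calls, small_grid, "CHH")
        assert np.allclose(out, plain, equal_nan=True)

    def test_matches_membership_loop_oracle(self, small_grid, rng):
        positions = rng.integers(1, 10_000, size=120)
        rows = [
            ("A01", int(p), "CHH", "leaf", "r1", int(rng.integers(0, 4)), 4)
            for p in positions
        ]
        calls = calls_frame(rows).drop_duplicates(subset=["pos"])
        te = ivs(("A01", 1_000, 2_500), ("A01", 4_000, 4_100), ("A01", 9_000, 10_000))
        out = te_body_chh(calls, te, small_grid)
        inside = calls[
            calls["pos"].apply(
                lambda p: any(s < p <= e for _, s, e in te.itertuples(index=False))
            )
        ]
        oracle = np.full(10, np.nan)
        for b in range(10):
            sub = inside[((inside["pos"] - 1) // 1_000) == b]
            if len(sub):
                oracle[b] = (sub["meth"] / sub["total"]).mean()
        assert np.allclose(out, oracle, equal_nan=True)


class TestSequenceFeatures:
    def grid_for(self, seq):
        lay = GenomeLayout((ChromRecord("A01", len(seq), "A", len(seq) // 2, 1),))
        return build_bins(lay, len(seq))

    def test_gc_simple(self):
        grid = self.grid_for("ATGC")
        assert gc_content({"A01": "ATGC"}, grid)[0] == pytest.approx(0.5)

    def test_gc_case_and_ambiguity(self):
        grid = self.grid_for("atgcNN")
        assert gc_content({"A01": "atgcNN"}, grid)[0] == pytest.approx(2 / 6)

    def test_gc_length_mismatch(self):
        grid = self.grid_for("ATGC")
        with pytest.raises(ValueError):
            gc_content({"A01": "ATGCA"}, grid)

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATAT", 1.0),  # matches at offsets 0 and 2 cover everything
            ("AATT", 0.5),  # single central match covers 2 of 4 bases
            ("GGGG", 0.0),
        ],
    )
    def test_at_dinucleotide_union_coverage(self, seq, expected):
        grid = self.grid_for(seq)
        assert dinucleotide_fraction({"A01": seq}, grid, "AT")[0] == pytest.approx(expected)


class TestAccessibility:
    def test_zero_accessible_is_zero(self, small_grid):
        out = accessibility_score({"leaf": ivs(("A01", 5_000, 5_001))}, small_grid)
        assert out[0] == pytest.approx(0.0)

    def test_one_base_short_of_full_is_one(self, small_grid):
        # log10(999 + 1) / log10(1000) = 1 exactly
        out = accessibility_score({"leaf": ivs(("A01", 0, 999))}, small_grid)
        assert out[0] == pytest.approx(1.0)

    def test_full_bin_capped_at_one(self, small_grid):
        out = accessibility_score({"leaf": ivs(("A01", 0, 1_000))}, small_grid)
        assert out[0] == pytest.approx(1.0)

    def test_mean_over_tissues(self, small_grid):
        out = accessibility_score(
            {"leaf": ivs(("A01", 0, 999)), "root": ivs(("A01", 5_000, 5_001))},
            small_grid,
        )
        assert out[0] == pytest.approx(0.5)


class TestExpression:
    def tpm(self, rows):
        return pd.DataFrame(rows, columns=["gene", "tissue", "replicate", "tpm"])

    def genes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])

    def test_transform_floor_and_unity(self, small_grid):
        tpm = self.tpm([("g1", "leaf", "r1", 0.9), ("g2", "leaf", "r1", 0.0)])
        genes = self.genes([("g1", "A01", 0, 100), ("g2", "A01", 1_100, 1_200)])
        out = expression_score(tpm, genes, small_grid)
        assert out[0] == pytest.approx(0.0)  # log10(0.9 + 0.1)
        assert out[1] == pytest.approx(-1.0)  # log10(0 + 0.1)

    def test_bin_mean_of_two_genes(self, small_grid):
        # transformed values -1 and +1 average to 0
        tpm = self.tpm([("g1", "leaf", "r1", 0.0), ("g2", "leaf", "r1", 9.9)])
        genes = self.genes([("g1", "A01", 0, 100), ("g2", "A01", 200, 300)])
        out = expression_score(tpm, genes, small_grid)
        assert out[0] == pytest.approx(0.0)

    def test_geneless_bins_at_floor_and_missing_gene_warns(self, small_grid):
        tpm = self.tpm([("g1", "leaf", "r1", 1.0)])
        genes = self.genes([("g1", "A01", 0, 100), ("orphan", "A01", 3_000, 3_100)])
        with pytest.warns(UserWarning):
            out = expression_score(tpm, genes, small_grid)
        assert out[5] == pytest.approx(-1.0)
        assert out[3] == pytest.approx(-1.0)  # orphan treated as TPM 0

    def test_replicate_then_tissue_averaging(self, small_grid):
        tpm = self.tpm(
            [
                ("g1", "leaf", "r1", 0.6),
                ("g1", "leaf", "r2", 1.2),  # leaf mean 0.9 -> log10(1.0) = 0
                ("g1", "root", "r1", 99.9),  # log10(100) = 2
            ]
        )
        genes = self.genes([("g1", "A01", 0, 100)])
        assert expression_score(tpm, genes, small_grid)[0] == pytest.approx(1.0)


class TestSmoothing:
    def test_constant_series_fixed_point(self):
        x = np.full(20, 3.7)
        assert np.allclose(ses_smooth(x, 0.1), x)

    def test_hand_recursion(self):
        assert np.allclose(ses_smooth([0.0, 10.0], 0.1), [0.0, 1.0])

    def test_alpha_one_identity(self, rng):
        x = rng.normal(size=50)
        assert np.allclose(ses_smooth(x, 1.0), x)

    def test_linear_and_shift_equivariant(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        a, b = 2.5, -1.0
        assert np.allclose(
            ses_smooth(a * x + b * y, 0.3),
            a * ses_smooth(x, 0.3) + b * ses_smooth(y, 0.3),
        )
        assert np.allclose(ses_smooth(x + 7.0, 0.3), ses_smooth(x, 0.3) + 7.0)

    def test_output_within_input_range(self, rng):
        x = rng.uniform(-5, 5, size=100)
        s = ses_smooth(x, 0.1)
        assert s.min() >= x.min() - 1e-12 and s.max() <= x.max() + 1e-12

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ses_smooth([], 0.1)


class TestAssembly:
    @pytest.fixture()
    def labelled_map(self, toy_layout, toy_grid, rng):
        from conftest import make_coset
        from recombml.recmap import build_recomb_map, sample_hotspots

        lengths = {c.name: c.length for c in toy_layout.chromosomes}
        chroms = rng.choice(toy_layout.names, size=400)
        starts = np.array([rng.integers(0, lengths[c] - 10_000) for c in chroms])
        cos = make_coset(
            list(zip(chroms, starts, starts + 9_000, [f"i{k}" for k in range(400)]))
        )
        gf = toy_grid.frame
        snp_rows = []
        for i, (c, s) in enumerate(zip(gf["chrom"], gf["start"])):
            if i % 7 != 3:  # every 7th bin is SNP-empty
                snp_rows.append((c, s + 100))
                snp_rows.append((c, s + 200))
        snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
        return sample_hotspots(build_recomb_map(cos, toy_grid, snps), seed=0)

    def tracks_for(self, grid, rng):
        return pd.DataFrame(
            {
                "feat_a": rng.uniform(0, 1, grid.n_bins),
                "feat_b": rng.uniform(0, 1, grid.n_bins),
                "telomere_distance": rng.uniform(0, 1, grid.n_bins),
                "C_subgenome": (grid.frame["chrom"].str.startswith("C")).astype(float),
            }
        )

    def test_classification_rows_balanced(self, labelled_map, toy_grid, rng):
        table = assemble_table(labelled_map, self.tracks_for(toy_grid, rng), "classification")
        n_hot = (labelled_map.frame["hotspot_label"] == "hotspot").sum()
        n_non = (labelled_map.frame["hotspot_label"] == "non_hotspot_sampled").sum()
        assert len(table.frame) == n_hot + n_non
        assert table.y.sum() == n_hot

    def test_regression_excludes_snp_empty(self, labelled_map, toy_grid, rng):
        table = assemble_table(labelled_map, self.tracks_for(toy_grid, rng), "regression")
        n_empty = labelled_map.frame["snp_empty"].sum()
        assert len(table.frame) == toy_grid.n_bins - n_empty
        assert not table.frame["normalized_rate"].isna().any()

    def test_unsmoothed_columns_preserved(self, labelled_map, toy_grid, rng):
        tracks = self.tracks_for(toy_grid, rng)
        table = assemble_table(labelled_map, tracks, "regression", smooth_alpha=0.1)
        keep = ~labelled_map.frame["snp_empty"].to_numpy()
        assert np.allclose(
            table.frame["telomere_distance"], tracks["telomere_distance"][keep]
        )
        smoothed = table.frame["feat_a"].to_numpy()
        assert not np.allclose(smoothed, tracks["feat_a"][keep])
        assert not table.smoothable["telomere_distance"]
        assert table.smoothable["feat_a"]

    def test_imputation_logged(self, labelled_map, toy_grid, rng):
        tracks = self.tracks_for(toy_grid, rng)
        tracks.loc[3, "feat_a"] = np.nan
        table = assemble_table(labelled_map, tracks, "regression")
        assert table.imputation_log["feat_a"] == 1
        assert not table.frame["feat_a"].isna().any()

    def test_round_trip_tsv(self, labelled_map, toy_grid, rng, tmp_path):
        table = assemble_table(labelled_map, self.tracks_for(toy_grid, rng), "regression")
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, table.frame)
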