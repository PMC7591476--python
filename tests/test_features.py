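"""Feature extraction against hand values and quadratic oracles."""

import numpy as np
import pandas as pd
import pytest

from cancerfeat import (
    DEFAULT_REGISTRY,
    ValidationError,
    assemble_feature_matrix,
    compute_expression_features,
    compute_ld_features,
    compute_structure_features,
    count_tf_sites,
)


def make_genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    df["terminator"] = np.where(df["strand"] == "+", df["end"], df["start"])
    return df


class TestStructure:
    def setup_method(self):
        self.genes = make_genes([("g1", "chr1", 1_000, 2_000, "+")])
        self.tx = pd.DataFrame(
            {"transcript_id": ["t1", "t2"], "gene_id": ["g1", "g1"],
             "utr3_len": [300.0, np.nan], "utr5_len": [np.nan, np.nan]}
        )
        self.ex = pd.DataFrame(
            {"transcript_id": ["t1", "t1", "t2"], "gene_id": ["g1"] * 3,
             "start": [1_000, 1_200, 1_500], "end": [1_099, 1_399, 1_799]}
        )

    def test_inclusive_length_and_exon_stats(self):
        out = compute_structure_features(self.genes, self.tx, self.ex)
        row = out.loc["g1"]
        assert row["gene_length"] == 1_001  # end - start + 1
        assert row["n_isoforms"] == 2
        assert row["n_exons"] == 3
        # exon lengths {100, 200} and {300} pooled over isoforms
        assert row["mean_exon_length"] == 200

    def test_utr_mean_over_possessing_isoforms_and_missing(self):
        out = compute_structure_features(self.genes, self.tx, self.ex)
        assert out.loc["g1", "mean_utr3_length"] == 300.0
        assert np.isnan(out.loc["g1", "mean_utr5_length"])

    def test_gene_without_isoforms_is_an_error(self):
        genes = make_genes([("g1", "chr1", 1_000, 2_000, "+"),
                            ("g2", "chr1", 5_000, 6_000, "+")])
        with pytest.raises(ValidationError, match="g2"):
            compute_structure_features(genes, self.tx, self.ex)

    def test_exon_outside_gene_body_is_an_error(self):
        ex = self.ex.copy()
        ex.loc[0, "end"] = 3_000
        with pytest.raises(ValidationError, match="g1"):
            compute_structure_features(self.genes, self.tx, ex)


class TestLdFeatures:
    def test_mean_and_sample_sd(self):
        genes = make_genes([("g1", "chr1", 100, 200, "+")])
        var = pd.DataFrame({"variant_id": list("abc"), "chrom": ["chr1"] * 3,
                            "pos": [110, 150, 190], "ld_score": [2.0, 4.0, 6.0]})
        out = compute_ld_features(genes, var)
        assert out.loc["g1", "ld_score_mean"] == pytest.approx(4.0)
        assert out.loc["g1", "ld_score_sd"] == pytest.approx(2.0)  # n-1 denominator

    def test_no_variants_both_missing_one_variant_sd_missing(self):
        genes = make_genes([("g1", "chr1", 100, 200, "+"),
                            ("g2", "chr1", 300, 400, "+")])
        var = pd.DataFrame({"variant_id": ["a"], "chrom": ["chr1"],
                            "pos": [350], "ld_score": [5.0]})
        out = compute_ld_features(genes, var)
        assert np.isnan(out.loc["g1", "ld_score_mean"])
        assert np.isnan(out.loc["g1", "ld_score_sd"])
        assert out.loc["g2", "ld_score_mean"] == 5.0
        assert np.isnan(out.loc["g2", "ld_score_sd"])

    def test_negative_ld_score_rejected(self):
        genes = make_genes([("g1", "chr1", 100, 200, "+")])
        var = pd.DataFrame({"variant_id": ["a"], "chrom": ["chr1"],
                            "pos": [150], "ld_score": [-1.0]})
        with pytest.raises(ValidationError):
            compute_ld_features(genes, var)

    def test_random_instance_matches_per_gene_scan_oracle(self):
        rng = np.random.default_rng(42)
        genes = make_genes(
            [(f"g{i}", f"chr{rng.integers(1, 4)}",
              int(s := rng.integers(1, 90_000)), int(s + rng.integers(10, 5_000)), "+")
             for i in range(200)]
        )
        var = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(3_000)],
            "chrom": [f"chr{c}" for c in rng.integers(1, 4, 3_000)],
            "pos": rng.integers(1, 100_000, 3_000),
            "ld_score": rng.gamma(2, 2, 3_000),
        })
        out = compute_ld_features(genes, var)
        for _, g in genes.iterrows():
            inside = var[(var["chrom"] == g["chrom"])
                         & (var["pos"] >= g["start"]) & (var["pos"] <= g["end"])]
            s = inside["ld_score"].to_numpy()
            if len(s) == 0:
                assert np.isnan(out.loc[g["gene_id"], "ld_score_mean"])
            else:
                assert out.loc[g["gene_id"], "ld_score_mean"] == pytest.approx(s.mean())
                if len(s) > 1:
                    assert out.loc[g["gene_id"], "ld_score_sd"] == pytest.approx(
                        s.std(ddof=1))
                else:
                    assert np.isnan(out.loc[g["gene_id"], "ld_score_sd"])


class TestExpression:
    def test_breadth_counts_strictly_above_threshold(self):
        genes = make_genes([("g1", "chr1", 1, 10, "+"), ("g2", "chr1", 20, 30, "+"),
                            ("g3", "chr1", 40, 50, "+")])
        tpm = pd.DataFrame(
            [[0.5, 2.0, 3.0], [0.0, 1.0, 4.0], [5.0, 5.0, 5.0]],
            index=["g1", "g2", "g3"], columns=["t1", "t2", "t3"],
        )
        out = compute_expression_features(genes, tpm)
        assert out.loc["g1", "n_tissues_expressed"] == 2
        assert out.loc["g2", "n_tissues_expressed"] == 1  # exactly 1 TPM not counted
        assert out.loc["g3", "tpm_sd"] == 0.0

    def test_gene_absent_from_matrix_is_missing_not_error(self):
        genes = make_genes([("g1", "chr1", 1, 10, "+"), ("gX", "chr1", 20, 30, "+")])
        tpm = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["t1", "t2"])
        out = compute_expression_features(genes, tpm)
        assert np.isnan(out.loc["gX", "tpm_mean"])
        assert np.isnan(out.loc["gX", "n_tissues_expressed"])


class TestTfSites:
    def peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_class"])

    def test_window_definitions_on_spec_example(self):
        genes = make_genes([("g1", "chr1", 1_000, 2_000, "+")])  # tss 1000
        pk = self.peaks([("chr1", 500, 500, "a"), ("chr1", 1_500, 1_500, "a"),
                         ("chr1", 150_000, 150_000, "a")])
        out = count_tf_sites(genes, pk)
        assert out.loc["g1", "tf_sites_promoter"] == 2  # [1, 2000] after clipping
        assert out.loc["g1", "tf_sites_body_per_bp"] == pytest.approx(1 / 1_001)
        # distal flanks [1,999] and [2001,102000]: peak at 500 only
        assert out.loc["g1", "tf_sites_distal_per_bp"] == pytest.approx(1 / 1_001)

    def test_peak_exactly_at_window_edge_counts(self):
        genes = make_genes([("g1", "chr1", 10_000, 12_000, "+")])  # tss 10000
        pk = self.peaks([("chr1", 9_000, 9_000, "a")])  # at tss - 1000
        out = count_tf_sites(genes, pk)
        assert out.loc["g1", "tf_sites_promoter"] == 1

    def test_promoter_invariant_under_strand_flip(self):
        plus = make_genes([("g1", "chr1", 50_000, 60_000, "+")])
        minus = plus.copy()
        minus["strand"] = "-"
        # keep the TSS fixed while flipping strand
        minus["tss"], minus["terminator"] = plus["tss"], plus["terminator"]
        rng = np.random.default_rng(0)
        pos = rng.integers(40_000, 70_000, 500)
        pk = pd.DataFrame({"chrom": "chr1", "start": pos, "end": pos + 100,
                           "tf_class": "a"})
        out_p = count_tf_sites(plus, pk)
        out_m = count_tf_sites(minus, pk)
        assert out_p.loc["g1", "tf_sites_promoter"] == out_m.loc["g1", "tf_sites_promoter"]

    def test_other_chromosome_never_counts(self):
        genes = make_genes([("g1", "chr1", 1_000, 2_000, "+")])
        pk = self.peaks([("chr2", 1_500, 1_500, "a")])
        out = count_tf_sites(genes, pk)
        assert out.loc["g1", "tf_sites_promoter"] == 0
        assert out.loc["g1", "tf_sites_body_per_bp"] == 0

    def test_invalid_peak_rejected(self):
        genes = make_genes([("g1", "chr1", 1_000, 2_000, "+")])
        with pytest.raises(ValidationError):
            count_tf_sites(genes, self.peaks([("chr1", 100, 50, "a")]))

    def test_random_instance_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        genes = make_genes(
            [(f"g{i}", f"chr{rng.integers(1, 3)}",
              int(s := rng.integers(1, 500_000)),
              int(s + rng.integers(500, 20_000)),
              rng.choice(["+", "-"])) for i in range(100)]
        )
        ps = rng.integers(1, 600_000, 2_000)
        pk = pd.DataFrame({"chrom": [f"chr{c}" for c in rng.integers(1, 3, 2_000)],
                           "start": ps, "end": ps + rng.integers(1, 400, 2_000),
                           "tf_class": rng.choice(list("ab"), 2_000)})
        out = count_tf_sites(genes, pk)

        def overlaps(lo, hi, s, e):
            return lo <= hi and s <= hi and e >= lo

        for _, g in genes.iterrows():
            sub = pk[pk["chrom"] == g["chrom"]]
            tss, gs, ge = g["tss"], g["start"], g["end"]
            length = ge - gs + 1
            prom = sum(overlaps(max(tss - 1_000, 1), tss + 1_000, s, e)
                       for s, e in zip(sub["start"], sub["end"]))
            body = sum(overlaps(gs, ge, s, e) for s, e in zip(sub["start"], sub["end"]))
            dist = sum(
                overlaps(max(gs - 100_000, 1), gs - 1, s, e)
                + overlaps(ge + 1, ge + 100_000, s, e)
                for s, e in zip(sub["start"], sub["end"])
            )
            gid = g["gene_id"]
            assert out.loc[gid, "tf_sites_promoter"] == prom
            assert out.loc[gid, "tf_sites_body_per_bp"] == pytest.approx(body / length)
            assert out.loc[gid, "tf_sites_distal_per_bp"] == pytest.approx(dist / length)


class TestAssembly:
    def test_registry_order_and_shape(self, small_dataset):
        from cancerfeat.synth import realized_feature_matrix

        ds = small_dataset
        raw = {"transcripts": ds.transcripts, "exons": ds.exons,
               "expression": ds.expression, "tf_peaks": ds.tf_peaks,
               "variants": ds.variants, "counts": ds.counts}
        fm = realized_feature_matrix(ds.genes, raw)
        assert fm.values.shape == (len(ds.genes), len(DEFAULT_REGISTRY))
        assert fm.feature_names == list(DEFAULT_REGISTRY)
        assert not fm.scaled

    def test_missing_registry_feature_is_an_error(self):
        block = pd.DataFrame({"gene_length": [1.0]}, index=["g1"])
        with pytest.raises(ValidationError, match="gc_content"):
            assemble_feature_matrix([block], registry=("gene_length", "gc_content"))

    def test_duplicate_gene_ids_rejected(self):
        block = pd.DataFrame({"f": [1.0, 2.0]}, index=["g1", "g1"])
        with pytest.raises(ValidationError, match="g1"):
            assemble_feature_matrix([block], registry=("f",))
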