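"""Locus boundaries, merging, gene assignment and pleiotropy."""

import numpy as np
import pandas as pd
import pytest

from cancerfeat import (
    Locus,
    ValidationError,
    assign_genes,
    build_loci,
    classify_pleiotropy,
    locus_boundaries,
    merge_loci,
)


def proxies(rows):
    return pd.DataFrame(rows, columns=["proxy_id", "index_id", "chrom", "pos",
                                       "d_prime"])


INDEX = pd.Series({"variant_id": "i1", "chrom": "chr1", "pos": 100,
                   "tissue_cluster": "breast", "p_value": 1e-9})


class TestBoundaries:
    def test_threshold_keeps_moderate_ld_proxies(self):
        px = proxies([("p1", "i1", "chr1", 50, 0.9), ("p2", "i1", "chr1", 200, 0.6),
                      ("p3", "i1", "chr1", 300, 0.3)])
        assert locus_boundaries(INDEX, px) == (50, 200)

    def test_no_proxies_degenerate_locus(self):
        assert locus_boundaries(INDEX, proxies([])) == (100, 100)

    def test_all_proxies_below_threshold_degenerate(self):
        px = proxies([("p1", "i1", "chr1", 50, 0.2), ("p2", "i1", "chr1", 900, 0.49)])
        assert locus_boundaries(INDEX, px) == (100, 100)

    def test_literal_lt_reading_selectable(self):
        px = proxies([("p1", "i1", "chr1", 50, 0.9), ("p2", "i1", "chr1", 300, 0.3)])
        assert locus_boundaries(INDEX, px, extend_through="lt") == (100, 300)

    def test_cross_chromosome_proxy_rejected(self):
        px = proxies([("p1", "i1", "chr2", 50, 0.9)])
        with pytest.raises(ValidationError):
            locus_boundaries(INDEX, px)

    def test_raising_threshold_never_widens(self):
        rng = np.random.default_rng(3)
        px = proxies([(f"p{i}", "i1", "chr1", int(rng.integers(1, 1_000)),
                       float(rng.random())) for i in range(30)])
        widths = []
        for thr in (0.2, 0.5, 0.8):
            lo, hi = locus_boundaries(INDEX, px, d_prime_threshold=thr)
            widths.append(hi - lo)
        assert widths[0] >= widths[1] >= widths[2]


def mk(chrom, lo, hi, ids=(), clusters=("breast",)):
    return Locus(locus_id="x", chrom=chrom, lo=lo, hi=hi,
                 index_ids=set(ids), tissue_clusters=set(clusters))


class TestMerging:
    def test_overlapping_merged(self):
        out = merge_loci([mk("chr1", 50, 200, ["a"]), mk("chr1", 150, 400, ["b"])])
        assert len(out) == 1
        assert (out[0].lo, out[0].hi) == (50, 400)
        assert out[0].index_ids == {"a", "b"}

    def test_disjoint_untouched(self):
        out = merge_loci([mk("chr1", 1, 10), mk("chr1", 20, 30)])
        assert [(l.lo, l.hi) for l in out] == [(1, 10), (20, 30)]

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        loci = [mk("chr1", int(lo := rng.integers(1, 5_000)),
                   int(lo + rng.integers(1, 500))) for _ in range(100)]
        once = merge_loci(loci)
        twice = merge_loci(once)
        assert [(l.lo, l.hi) for l in once] == [(l.lo, l.hi) for l in twice]

    def test_matches_fixed_point_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        intervals = [(int(lo := rng.integers(1, 20_000)),
                      int(lo + rng.integers(1, 1_000))) for _ in range(1_000)]

        def oracle(iv):
            iv = [list(t) for t in iv]
            changed = True
            while changed:
                changed = False
                for i in range(len(iv)):
                    if iv[i] is None:
                        continue
                    for j in range(i + 1, len(iv)):
                        if iv[j] is None:
                            continue
                        a, b = iv[i], iv[j]
                        if a[0] <= b[1] and b[0] <= a[1]:
                            a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                            iv[j] = None
                            changed = True
            return sorted((t[0], t[1]) for t in iv if t)

        expected = oracle(intervals)
        got = [(l.lo, l.hi) for l in merge_loci([mk("chr1", lo, hi)
                                                 for lo, hi in intervals])]
        assert got == expected


class TestGeneAssignment:
    def test_endpoint_rule(self, tiny_genes):
        # gA: chr1 [1000,2000] tss 1000; gB: chr1 [10000,15000] tss 15000
        loci = [mk("chr1", 900, 1_100)]
        assign_genes(loci, tiny_genes)
        assert loci[0].member_genes == {"gA"}

    def test_spanning_gene_with_endpoints_outside_not_member(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr1"],
                              "start": [50], "end": [500], "strand": ["+"],
                              "tss": [50], "terminator": [500]})
        loci = [mk("chr1", 100, 200)]
        assign_genes(loci, genes)
        assert loci[0].member_genes == set()

    def test_matches_endpoint_containment_oracle(self):
        rng = np.random.default_rng(8)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(300)],
            "chrom": [f"chr{c}" for c in rng.integers(1, 4, 300)],
        })
        start = rng.integers(1, 100_000, 300)
        genes["start"] = start
        genes["end"] = start + rng.integers(100, 10_000, 300)
        strand = rng.choice(["+", "-"], 300)
        genes["tss"] = np.where(strand == "+", genes["start"], genes["end"])
        genes["terminator"] = np.where(strand == "+", genes["end"], genes["start"])
        loci = [mk(f"chr{rng.integers(1, 4)}", int(lo := rng.integers(1, 100_000)),
                   int(lo + rng.integers(100, 20_000))) for _ in range(40)]
        assign_genes(loci, genes)
        for loc in loci:
            expected = {
                g["gene_id"] for _, g in genes.iterrows()
                if g["chrom"] == loc.chrom
                and (loc.lo <= g["tss"] <= loc.hi
                     or loc.lo <= g["terminator"] <= loc.hi)
            }
            assert loc.member_genes == expected


class TestPleiotropy:
    def test_single_cluster_not_pleiotropic(self):
        loci, single, pleio = classify_pleiotropy([mk("chr1", 1, 10, clusters=("breast",))])
        assert not loci[0].pleiotropic

    def test_two_clusters_pleiotropic(self):
        loci, _, _ = classify_pleiotropy(
            [mk("chr1", 1, 10, clusters=("breast", "ovarian"))])
        assert loci[0].pleiotropic

    def test_gene_in_both_kinds_is_pleiotropic(self):
        a = mk("chr1", 1, 10, clusters=("breast",))
        a.member_genes = {"g1", "g2"}
        b = mk("chr1", 100, 200, clusters=("breast", "lung"))
        b.member_genes = {"g2", "g3"}
        _, single, pleio = classify_pleiotropy([a, b])
        assert pleio == {"g2", "g3"}
        assert single == {"g1"}

    def test_empty_cluster_set_rejected(self):
        with pytest.raises(ValidationError):
            classify_pleiotropy([mk("chr1", 1, 10, clusters=())])


class TestBuildLoci:
    def test_forced_overlap_reduces_locus_count(self, small_dataset):
        loci, _, _ = build_loci(small_dataset.gwas_index,
                                small_dataset.gwas_proxies,
                                small_dataset.genes)
        assert len(loci) < len(small_dataset.gwas_index)

    def test_zero_proxies_degenerate_loci(self, small_dataset):
        empty = small_dataset.gwas_proxies.iloc[0:0]
        loci, _, _ = build_loci(small_dataset.gwas_index, empty,
                                small_dataset.genes)
        merged_pos_span = [l.hi - l.lo for l in loci if len(l.index_ids) == 1]
        assert all(s == 0 for s in merged_pos_span)

    def test_non_significant_index_dropped(self, small_dataset):
        idx = small_dataset.gwas_index.copy()
        idx.loc[idx.index[2:], "p_value"] = 1e-5  # keep only two indices
        loci, _, _ = build_loci(idx, small_dataset.gwas_proxies,
                                small_dataset.genes)
        assert sum(len(l.index_ids) for l in loci) == 2

    def test_member_endpoints_inside_locus(self, pipeline_result):
        genes = pipeline_result.genes.set_index("gene_id")
        for loc in pipeline_result.loci:
            for gid in loc.member_genes:
                g = genes.loc[gid]
                assert (loc.lo <= g["tss"] <= loc.hi
                        or loc.lo <= g["terminator"] <= loc.hi)
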