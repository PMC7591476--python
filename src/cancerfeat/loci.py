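"""GWAS locus construction, merging, gene assignment and pleiotropy.

A locus starts from a genome-wide significant index variant (p <= 5e-8)
and extends to its most distant LD proxies still in moderate linkage
disequilibrium with it. By default a proxy qualifies when D' >= 0.5 (the
locus extends through correlated variants, the conventional reading); the
threshold and its direction are exposed so the literal "D' < 0.5" reading
can be selected. Overlapping loci are merged transitively; a gene belongs
to a locus iff its TSS or its terminator lies within the locus boundaries
(a gene whose body spans the locus with both endpoints outside is not a
member — a documented consequence of the endpoint rule). A locus is
pleiotropic iff its index variants carry two or more distinct tissue
clusters; a gene in any pleiotropic locus is pleiotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import ValidationError

__all__ = [
    "GENOME_WIDE_SIGNIFICANCE",
    "Locus",
    "locus_boundaries",
    "merge_loci",
    "assign_genes",
    "classify_pleiotropy",
    "build_loci",
    "locus_gene_table",
]

GENOME_WIDE_SIGNIFICANCE = 5.00e-8


@dataclass
class Locus:
    locus_id: str
    chrom: str
    lo: int
    hi: int
    index_ids: set[str] = field(default_factory=set)
    tissue_clusters: set[str] = field(default_factory=set)
    pleiotropic: bool = False
    member_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValidationError(f"locus {self.locus_id}: lo > hi")


def locus_boundaries(
    index: pd.Series | dict,
    proxies: pd.DataFrame,
    d_prime_threshold: float = 0.5,
    extend_through: str = "ge",
) -> tuple[int, int]:
    """Boundaries [lo, hi] of the locus around one index variant.

    ``extend_through='ge'`` (default) keeps proxies with D' >= threshold;
    ``'lt'`` selects the literal complementary reading (D' < threshold).
    With no qualifying proxy the locus degenerates to [pos, pos].
    """
    pos = int(index["pos"])
    chrom = index["chrom"]
    if len(proxies):
        if (proxies["chrom"] != chrom).any():
            bad = proxies.loc[proxies["chrom"] != chrom].iloc[0]
            raise ValidationError(
                f"proxy {bad.get('proxy_id', '?')} on {bad['chrom']} but its "
                f"index variant is on {chrom}"
            )
        if extend_through == "ge":
            keep = proxies["d_prime"] >= d_prime_threshold
        elif extend_through == "lt":
            keep = proxies["d_prime"] < d_prime_threshold
        else:
            raise ValueError("extend_through must be 'ge' or 'lt'")
        positions = [pos, *proxies.loc[keep, "pos"].astype(int)]
    else:
        positions = [pos]
    return min(positions), max(positions)


def merge_loci(loci: list[Locus]) -> list[Locus]:
    """Transitively merge overlapping loci (closed intervals, >= 1 bp shared).

    Index ids and tissue clusters are unioned; output is sorted by
    (chrom, lo) and pairwise disjoint per chromosome. Idempotent.
    """
    merged: list[Locus] = []
    by_chrom: dict[str, list[Locus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom in sorted(by_chrom):
        current: Locus | None = None
        for loc in sorted(by_chrom[chrom], key=lambda l: (l.lo, l.hi)):
            if current is not None and loc.lo <= current.hi:
                current.hi = max(current.hi, loc.hi)
                current.index_ids |= loc.index_ids
                current.tissue_clusters |= loc.tissue_clusters
            else:
                if current is not None:
                    merged.append(current)
                current = Locus(
                    locus_id="", chrom=chrom, lo=loc.lo, hi=loc.hi,
                    index_ids=set(loc.index_ids),
                    tissue_clusters=set(loc.tissue_clusters),
                )
        if current is not None:
            merged.append(current)
    for i, loc in enumerate(merged):
        loc.locus_id = f"locus_{i + 1:04d}"
    return merged


def assign_genes(loci: list[Locus], genes: pd.DataFrame) -> list[Locus]:
    """Assign member genes: TSS or terminator within the locus boundaries."""
    for loc in loci:
        sub = genes[genes["chrom"] == loc.chrom]
        tss_in = sub["tss"].between(loc.lo, loc.hi)
        term_in = sub["terminator"].between(loc.lo, loc.hi)
        loc.member_genes = set(sub.loc[tss_in | term_in, "gene_id"])
    return loci


def classify_pleiotropy(loci: list[Locus]) -> tuple[list[Locus], set[str], set[str]]:
    """Flag pleiotropic loci and split member genes.

    Returns (loci, single_tissue_genes, pleiotropic_genes); a gene in both
    a pleiotropic and a single-tissue locus is pleiotropic.
    """
    pleio_genes: set[str] = set()
    single_genes: set[str] = set()
    for loc in loci:
        if not loc.tissue_clusters:
            raise ValidationError(f"locus {loc.locus_id} has an empty tissue cluster set")
        loc.pleiotropic = len(loc.tissue_clusters) >= 2
        (pleio_genes if loc.pleiotropic else single_genes).update(loc.member_genes)
    single_genes -= pleio_genes
    return loci, single_genes, pleio_genes


def build_loci(
    index_variants: pd.DataFrame,
    proxies: pd.DataFrame,
    genes: pd.DataFrame,
    d_prime_threshold: float = 0.5,
    extend_through: str = "ge",
    significance: float = GENOME_WIDE_SIGNIFICANCE,
) -> tuple[list[Locus], set[str], set[str]]:
    """Full locus pipeline: filter, bound, merge, assign, classify.

    Index variants with p above genome-wide significance are dropped at
    ingest (equality included). Returns the merged loci plus the
    single-tissue and pleiotropic GWAS gene sets.
    """
    if "p_value" in index_variants.columns:
        index_variants = index_variants[index_variants["p_value"] <= significance]
    raw: list[Locus] = []
    grouped = proxies.groupby("index_id") if len(proxies) else None
    for _, row in index_variants.iterrows():
        sub = (
            grouped.get_group(row["variant_id"])
            if grouped is not None and row["variant_id"] in grouped.groups
            else proxies.iloc[0:0]
        )
        lo, hi = locus_boundaries(row, sub, d_prime_threshold, extend_through)
        raw.append(
            Locus(locus_id="", chrom=row["chrom"], lo=lo, hi=hi,
                  index_ids={row["variant_id"]},
                  tissue_clusters={row["tissue_cluster"]})
        )
    merged = merge_loci(raw)
    assign_genes(merged, genes)
    merged, single, pleio = classify_pleiotropy(merged)
    return merged, single, pleio


def locus_gene_table(loci: list[Locus]) -> pd.DataFrame:
    """Long-format (locus_id, gene_id, pleiotropic) membership table."""
    rows = [
        (loc.locus_id, gid, loc.pleiotropic)
        for loc in loci
        for gid in sorted(loc.member_genes)
    ]
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "pleiotropic"])
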