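"""Gene-level omic feature extraction.

Aggregates raw genomic inputs (gene models, variant tables with LD scores,
expression matrices, transcription-factor binding peaks, and pre-computed
per-gene counts) into a genes x features matrix. Coordinates are 1-based
inclusive throughout; BED input is converted on read (see :mod:`cancerfeat.io`).

Window conventions
------------------
promoter : ``[tss - 1000, tss + 1000]`` — symmetric around the TSS, so
    promoter counts are strand-independent.
body : ``[start, end]`` (the longest-transcript span).
distal : ``[start - 100_000, end + 100_000]`` minus the body, i.e. the two
    flanks ``[start - 100_000, start - 1]`` and ``[end + 1, end + 100_000]``.
    Body and distal are disjoint so a site is never double counted between
    them. All windows are clipped at position 1. A peak counts toward a
    window if it overlaps it by at least 1 bp (closed intervals).

Body and distal counts are divided by the gene length in bp; promoter counts
are raw. Sample standard deviations use the n-1 denominator everywhere, and
a single observation yields a missing SD, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_REGISTRY",
    "PASSTHROUGH_FEATURES",
    "GeneRecord",
    "FeatureMatrix",
    "ValidationError",
    "compute_structure_features",
    "compute_ld_features",
    "compute_expression_features",
    "count_tf_sites",
    "assemble_feature_matrix",
]

PROMOTER_HALF_WIDTH = 1_000
DISTAL_EXTENT = 100_000

#: Default feature registry, in report order. 22 features are fixed by the
#: aggregation rules in this module; the last slot is configurable and
#: defaults to the number of distinct PTM types observed on the protein.
DEFAULT_REGISTRY: tuple[str, ...] = (
    "gene_length",
    "gc_content",
    "n_isoforms",
    "n_exons",
    "mean_exon_length",
    "mean_utr3_length",
    "mean_utr5_length",
    "n_orthologues_hominidae",
    "n_paralogues",
    "ld_score_mean",
    "ld_score_sd",
    "z_synonymous",
    "z_missense",
    "z_lof",
    "tpm_mean",
    "tpm_sd",
    "n_tissues_expressed",
    "n_eqtl",
    "tf_sites_promoter",
    "tf_sites_body_per_bp",
    "tf_sites_distal_per_bp",
    "n_ptm_total",
    "n_ptm_types",
)

#: Features taken as pre-computed per-gene columns (from counts.tsv) rather
#: than derived from interval/matrix inputs by this module.
PASSTHROUGH_FEATURES: tuple[str, ...] = (
    "gc_content",
    "n_orthologues_hominidae",
    "n_paralogues",
    "z_synonymous",
    "z_missense",
    "z_lof",
    "n_eqtl",
    "n_ptm_total",
    "n_ptm_types",
)


class ValidationError(ValueError):
    """Raised when an input table violates a structural precondition."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated protein-coding gene (longest-transcript span).

    ``tss`` is ``start`` on the plus strand and ``end`` on the minus strand;
    the terminator is the opposite end. Coordinates are 1-based inclusive.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    terminator: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        expect_tss = self.start if self.strand == "+" else self.end
        if self.tss != expect_tss or self.terminator != (
            self.end if self.strand == "+" else self.start
        ):
            raise ValidationError(
                f"gene {self.gene_id}: TSS/terminator inconsistent with strand"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureMatrix:
    """Genes x features value matrix with NaN-encoded missingness.

    ``values`` is indexed by gene_id with one column per registry feature,
    in registry order. ``scaled=True`` asserts each non-constant column has
    mean 0 and sample SD 1 over its non-missing entries.
    """

    values: pd.DataFrame
    scaled: bool = False
    constant_features: tuple[str, ...] = field(default_factory=tuple)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()

    def copy(self) -> "FeatureMatrix":
        return replace(self, values=self.values.copy())


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table lacks columns {missing}")


# ---------------------------------------------------------------------------
# gene structure


def compute_structure_features(
    genes: pd.DataFrame, transcripts: pd.DataFrame, exons: pd.DataFrame
) -> pd.DataFrame:
    """Gene length, isoform/exon counts, mean exon and UTR lengths.

    Parameters
    ----------
    genes : DataFrame with gene_id, chrom, start, end (1-based inclusive).
    transcripts : DataFrame with transcript_id, gene_id, utr3_len, utr5_len
        (UTR lengths NaN when the isoform has no annotated UTR).
    exons : DataFrame with transcript_id, gene_id, start, end.

    Gene length is the longest-transcript span, ``end - start + 1``. Exon
    statistics pool all exons of all isoforms. UTR means average over the
    isoforms possessing that UTR; a gene with no annotated UTR of a kind is
    missing for that feature. A gene present in ``genes`` but absent from
    the transcript table is a validation error (zero isoforms).
    """
    _require_columns(genes, ["gene_id", "start", "end"], "genes")
    _require_columns(
        transcripts, ["transcript_id", "gene_id", "utr3_len", "utr5_len"], "transcripts"
    )
    _require_columns(exons, ["transcript_id", "gene_id", "start", "end"], "exons")

    g = genes.set_index("gene_id")
    with_tx = set(transcripts["gene_id"])
    orphans = [gid for gid in g.index if gid not in with_tx]
    if orphans:
        raise ValidationError(f"gene {orphans[0]} has zero isoforms in transcript table")

    ex = exons.merge(g[["start", "end"]], left_on="gene_id", right_index=True,
                     suffixes=("", "_gene"))
    bad = ex[(ex["start"] < ex["start_gene"]) | (ex["end"] > ex["end_gene"])]
    if len(bad):
        raise ValidationError(
            f"exon outside gene body for gene {bad.iloc[0]['gene_id']}"
        )

    out = pd.DataFrame(index=g.index)
    out["gene_length"] = (g["end"] - g["start"] + 1).astype(float)
    out["n_isoforms"] = transcripts.groupby("gene_id").size().reindex(g.index).astype(float)
    exon_len = (exons["end"] - exons["start"] + 1).astype(float)
    by_gene = exon_len.groupby(exons["gene_id"].values)
    out["n_exons"] = by_gene.size().reindex(g.index).astype(float)
    out["mean_exon_length"] = by_gene.mean().reindex(g.index)
    out["mean_utr3_length"] = transcripts.groupby("gene_id")["utr3_len"].mean().reindex(g.index)
    out["mean_utr5_length"] = transcripts.groupby("gene_id")["utr5_len"].mean().reindex(g.index)
    return out


# ---------------------------------------------------------------------------
# LD score aggregation


def compute_ld_features(genes: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of LD scores of variants inside each gene body.

    A gene with no variant in its body is missing for both statistics; with
    exactly one variant the mean is defined and the SD is missing.
    """
    _require_columns(genes, ["gene_id", "chrom", "start", "end"], "genes")
    _require_columns(variants, ["chrom", "pos", "ld_score"], "variants")
    if (variants["ld_score"] < 0).any():
        raise ValidationError("negative ld_score in variant table")

    means = pd.Series(np.nan, index=genes["gene_id"], dtype=float)
    sds = pd.Series(np.nan, index=genes["gene_id"], dtype=float)
    for chrom, vsub in variants.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        pos = np.sort(vsub["pos"].to_numpy())
        order = np.argsort(vsub["pos"].to_numpy(), kind="stable")
        score = vsub["ld_score"].to_numpy()[order]
        cs = np.concatenate([[0.0], np.cumsum(score)])
        cs2 = np.concatenate([[0.0], np.cumsum(score**2)])
        lo = np.searchsorted(pos, gsub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, gsub["end"].to_numpy(), side="right")
        n = (hi - lo).astype(float)
        s1 = cs[hi] - cs[lo]
        s2 = cs2[hi] - cs2[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
            var = np.where(n > 1, (s2 - s1**2 / np.maximum(n, 1)) / np.maximum(n - 1, 1), np.nan)
        means.loc[gsub["gene_id"]] = mean
        sds.loc[gsub["gene_id"]] = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame({"ld_score_mean": means, "ld_score_sd": sds})


# ---------------------------------------------------------------------------
# expression summaries


def compute_expression_features(
    genes: pd.DataFrame, tpm: pd.DataFrame, expressed_threshold: float = 1.0
) -> pd.DataFrame:
    """TPM mean/SD across tissues and expression breadth.

    ``n_tissues_expressed`` counts tissues with TPM strictly greater than
    the threshold (default 1): a tissue at exactly 1 TPM is *not* counted.
    Genes absent from the expression matrix are missing (not an error).
    """
    if tpm.shape[1] < 1:
        raise ValidationError("expression matrix has no tissue columns")
    if (tpm.to_numpy() < 0).any():
        raise ValidationError("negative TPM in expression matrix")
    idx = pd.Index(genes["gene_id"])
    sub = tpm.reindex(idx)
    out = pd.DataFrame(index=idx)
    out["tpm_mean"] = sub.mean(axis=1)
    out["tpm_sd"] = sub.std(axis=1, ddof=1)
    breadth = (sub > expressed_threshold).sum(axis=1).astype(float)
    breadth[sub.isna().all(axis=1)] = np.nan
    out["n_tissues_expressed"] = breadth
    return out


# ---------------------------------------------------------------------------
# TF binding site windows


def _count_in_window(
    starts: np.ndarray, ends_sorted: np.ndarray, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Count intervals overlapping closed windows [lo, hi] per window.

    ``starts`` sorted ascending; ``ends_sorted`` the interval ends sorted
    independently. overlap <=> start <= hi and end >= lo, so the count is
    #(start <= hi) - #(end < lo). Empty windows (lo > hi) count zero.
    """
    n_le_hi = np.searchsorted(starts, hi, side="right")
    n_end_lt_lo = np.searchsorted(ends_sorted, lo, side="left")
    counts = n_le_hi - n_end_lt_lo
    return np.where(lo > hi, 0, np.maximum(counts, 0))


def count_tf_sites(
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    promoter_half_width: int = PROMOTER_HALF_WIDTH,
    distal_extent: int = DISTAL_EXTENT,
) -> pd.DataFrame:
    """TF binding site counts in promoter, body and distal windows.

    Returns ``tf_sites_promoter`` (raw count), ``tf_sites_body_per_bp`` and
    ``tf_sites_distal_per_bp`` (counts divided by gene length), plus one
    auxiliary ``tf_promoter_<class>`` column per TF class present in the
    peak table.
    """
    _require_columns(genes, ["gene_id", "chrom", "start", "end", "tss"], "genes")
    _require_columns(peaks, ["chrom", "start", "end"], "tf_peaks")
    if (peaks["end"] < peaks["start"]).any():
        raise ValidationError("TF peak with end < start")

    idx = pd.Index(genes["gene_id"])
    prom = pd.Series(0.0, index=idx)
    body = pd.Series(0.0, index=idx)
    distal = pd.Series(0.0, index=idx)
    tf_classes = (
        sorted(peaks["tf_class"].unique()) if "tf_class" in peaks.columns else []
    )
    per_class = {c: pd.Series(0.0, index=idx) for c in tf_classes}

    for chrom, psub in peaks.groupby("chrom", sort=False):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        starts = np.sort(psub["start"].to_numpy())
        ends_sorted = np.sort(psub["end"].to_numpy())
        gid = gsub["gene_id"]
        tss = gsub["tss"].to_numpy()
        gs, ge = gsub["start"].to_numpy(), gsub["end"].to_numpy()

        p_lo = np.maximum(tss - promoter_half_width, 1)
        p_hi = tss + promoter_half_width
        prom.loc[gid] = _count_in_window(starts, ends_sorted, p_lo, p_hi)
        body.loc[gid] = _count_in_window(starts, ends_sorted, gs, ge)
        # distal = the two flanks, disjoint from the body
        left = _count_in_window(starts, ends_sorted, np.maximum(gs - distal_extent, 1), gs - 1)
        right = _count_in_window(starts, ends_sorted, ge + 1, ge + distal_extent)
        distal.loc[gid] = left + right

        if tf_classes:
            for cls, csub in psub.groupby("tf_class", sort=False):
                c_starts = np.sort(csub["start"].to_numpy())
                c_ends = np.sort(csub["end"].to_numpy())
                per_class[cls].loc[gid] = _count_in_window(c_starts, c_ends, p_lo, p_hi)

    length = (
        (genes.set_index("gene_id")["end"] - genes.set_index("gene_id")["start"] + 1)
        .reindex(idx)
        .astype(float)
    )
    out = pd.DataFrame(
        {
            "tf_sites_promoter": prom,
            "tf_sites_body_per_bp": body / length,
            "tf_sites_distal_per_bp": distal / length,
        }
    )
    for cls in tf_classes:
        out[f"tf_promoter_{cls}"] = per_class[cls]
    return out


# ---------------------------------------------------------------------------
# assembly


def assemble_feature_matrix(
    columns: list[pd.DataFrame],
    registry: tuple[str, ...] | list[str] = DEFAULT_REGISTRY,
    gene_ids: pd.Index | None = None,
) -> FeatureMatrix:
    """Join per-source column blocks into one raw FeatureMatrix.

    ``columns`` are gene-indexed frames; every registry feature must appear
    in exactly one of them. ``gene_ids``, when given, restricts and orders
    the rows (the filtered gene universe). Auxiliary columns (e.g. per-TF-
    class promoter counts) are dropped from the matrix; select them from the
    source frames directly if needed.
    """
    registry = tuple(registry)
    if len(set(registry)) != len(registry):
        raise ValidationError("duplicate feature names in registry")
    merged = pd.concat(columns, axis=1)
    if merged.index.has_duplicates:
        dup = merged.index[merged.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in feature columns")
    absent = [f for f in registry if f not in merged.columns]
    if absent:
        raise ValidationError(f"registry features not computed: {absent}")
    values = merged[list(registry)].astype(float)
    if gene_ids is not None:
        values = values.reindex(gene_ids)
    return FeatureMatrix(values=values, scaled=False)
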