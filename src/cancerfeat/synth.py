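"""Synthetic genome, omic-feature inputs, class labels and pathways.

Everything downstream of this module (feature extraction, class
construction, association, scoring, locus prioritization, enrichment) is
exercisable on the output of :func:`generate_dataset` with no external data.

Generative model
----------------
1. A latent Gaussian matrix Z (genes x features) is drawn, with optional
   correlation blocks induced by shared factors: within a block with
   coefficient r, each latent is ``sqrt(r)*u_block + sqrt(1-r)*eps``.
2. Raw inputs (gene models, transcripts/exons, TPM matrix, variant LD
   scores, TF peaks, per-gene counts) are constructed so each feature's
   realized value is a monotone function of its latent.
3. The realized feature matrix is computed with the same aggregation rules
   the extraction module applies, standardized, and class labels are drawn
   from a per-class logistic model on those standardized values with the
   planted log-odds coefficients. Membership probabilities therefore match
   what a downstream logistic fit estimates; with correlation blocks active,
   univariate fits estimate *marginal*, not conditional, effects.
4. GWAS index variants are placed preferentially near genes with a high
   "gwas" linear predictor (membership in GWAS classes is positional, via
   locus construction); LD proxies with D' in [0, 1] define locus spans,
   and some index pairs are co-located to force locus merging and
   multi-tissue (pleiotropic) loci.
5. Pathways: "signal" pathways over-sample genes from the top decile of the
   true gwas score; "null" pathways sample uniformly.

Randomness: one root seed; each component uses ``default_rng([component_id,
seed])`` (NumPy PCG64) so streams are independent and adding a component
never perturbs the others. A fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .features import (
    DEFAULT_REGISTRY,
    PASSTHROUGH_FEATURES,
    assemble_feature_matrix,
    compute_expression_features,
    compute_ld_features,
    compute_structure_features,
    count_tf_sites,
)

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "ConfigError",
    "CapacityError",
    "TISSUE_CLUSTERS",
    "generate_genome",
    "generate_feature_inputs",
    "generate_gwas_architecture",
    "generate_pathways",
    "generate_dataset",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CapacityError(ValueError):
    """Requested genes do not fit on the simulated chromosomes."""


#: The 20-tissue vocabulary for GWAS association signals.
TISSUE_CLUSTERS: tuple[str, ...] = (
    "breast", "skin", "colorectal", "ovarian", "uterus", "testicular",
    "thyroid", "oesophageal", "lung", "renal", "prostate", "pancreas",
    "oral", "bladder", "cervix", "haematological", "cns", "meningioma",
    "sarcoma", "uveal_melanoma",
)

TF_CLASS_VOCAB = (
    "bZIP", "bHLH", "C2H2_ZF", "Homeodomain",
    "Nuclear_receptor", "Forkhead", "HMG", "ETS",
)

# fixed component ids for stream splitting
_STREAMS = {
    "latent": 1, "genome": 2, "transcripts": 3, "expression": 4,
    "variants": 5, "tf_peaks": 6, "counts": 7, "labels": 8,
    "survival": 9, "gwas": 10, "pathways": 11, "missing": 12,
}

#: Default planted per-feature log-odds effects, echoing the qualitative
#: profile of cancer genes: longer, lower GC, more isoforms, broadly
#: expressed, more promoter TF sites, more mutation-intolerant.
DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "germline": {"gene_length": 0.4, "n_tissues_expressed": 0.35,
                 "tpm_sd": -0.3, "tf_sites_promoter": 0.3},
    "somatic": {"gene_length": 0.5, "gc_content": -0.3, "z_lof": 0.4,
                "n_paralogues": -0.3, "n_eqtl": -0.2},
    "driver": {"gene_length": 0.5, "z_missense": 0.4, "n_isoforms": 0.3},
    "survival": {"tpm_mean": 0.35, "n_tissues_expressed": 0.25,
                 "n_ptm_total": 0.2},
    "gwas": {"gene_length": 0.4, "gc_content": 0.25, "tf_sites_promoter": 0.35,
             "n_tissues_expressed": 0.25},
}

DEFAULT_BLOCKS: list[tuple[tuple[str, ...], float]] = [
    (("gene_length", "n_isoforms", "n_exons", "n_eqtl",
      "tpm_mean", "n_tissues_expressed"), 0.5),
    (("gc_content", "mean_exon_length", "mean_utr3_length",
      "mean_utr5_length", "n_paralogues", "tpm_sd"), 0.4),
    (("z_synonymous", "z_missense", "z_lof"), 0.6),
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults are chosen as a plausible desk-scale genome: 3,000 genes on 22
    chromosomes, 44 expression tissues, modest planted effects and 2%
    missingness on the maskable features.
    """

    n_genes: int = 3000
    n_chromosomes: int = 22
    n_tissues: int = 44
    chromosome_length: int = 100_000_000
    feature_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_EFFECTS.items()}
    )
    feature_correlation_blocks: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: [(tuple(b), r) for b, r in DEFAULT_BLOCKS]
    )
    class_prevalences: dict[str, float] = field(
        default_factory=lambda: {"germline": 0.01, "somatic": 0.04,
                                 "driver": 0.02, "survival": 0.08}
    )
    missing_rate: float = 0.02
    n_index_variants: int | None = None
    proxies_per_index: int = 20
    n_pathways: int = 50
    planted_pathway_fraction: float = 0.8
    n_survival_datasets: int = 3
    registry: tuple[str, ...] = DEFAULT_REGISTRY
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_tissues < 1:
            raise ConfigError("n_genes, n_chromosomes and n_tissues must be >= 1")
        for name, frac in [("missing_rate", self.missing_rate),
                           ("planted_pathway_fraction", self.planted_pathway_fraction)]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {frac}")
        for cls, prev in self.class_prevalences.items():
            if not 0.0 <= prev <= 1.0:
                raise ConfigError(f"prevalence of {cls} must be in [0, 1]")
        if sum(self.class_prevalences.values()) > 1.0 + 1e-12:
            raise ConfigError("class prevalences sum to more than 1")
        if self.proxies_per_index < 0:
            raise ConfigError("proxies_per_index must be >= 0")
        if self.n_pathways < 0:
            raise ConfigError("n_pathways must be >= 0")
        known = set(self.registry)
        for cls, effects in self.feature_effects.items():
            for feat in effects:
                if feat not in known:
                    raise ConfigError(
                        f"unknown feature {feat!r} in feature_effects[{cls!r}]"
                    )
        seen: set[str] = set()
        for block, r in self.feature_correlation_blocks:
            if not 0.0 <= r < 1.0:
                raise ConfigError(f"block correlation {r} outside [0, 1)")
            for feat in block:
                if feat not in known:
                    raise ConfigError(f"unknown feature {feat!r} in correlation block")
                if feat in seen:
                    raise ConfigError(f"feature {feat!r} in more than one block")
                seen.add(feat)

    def rng(self, component: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[component], self.seed])

    @property
    def resolved_n_index(self) -> int:
        if self.n_index_variants is not None:
            return self.n_index_variants
        return max(10, self.n_genes // 50)


@dataclass
class SyntheticDataset:
    """All raw inputs plus the generating truth, as in-memory tables."""

    config: SynthConfig
    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame
    expression: pd.DataFrame
    tf_peaks: pd.DataFrame
    variants: pd.DataFrame
    counts: pd.DataFrame
    gwas_index: pd.DataFrame
    gwas_proxies: pd.DataFrame
    survival_evidence: pd.DataFrame
    pathways: dict[str, set[str]]
    pathway_sources: dict[str, str]
    truth: dict

    def write(self, out_dir: str | Path) -> None:
        """Write every table in its on-disk format (deterministic)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfio.write_tsv(self.genes, out / "genes.tsv")
        cfio.write_tsv(self.transcripts, out / "transcripts.tsv")
        cfio.write_tsv(self.exons, out / "exons.tsv")
        self.expression.to_csv(out / "expression.tsv", sep="\t",
                               float_format=cfio.FLOAT_FORMAT)
        cfio.write_bed_peaks(self.tf_peaks, out / "tf_peaks.bed")
        cfio.write_tsv(self.variants, out / "variants.tsv")
        cfio.write_tsv(self.counts, out / "counts.tsv")
        cfio.write_tsv(self.gwas_index, out / "gwas_index.tsv")
        cfio.write_tsv(self.gwas_proxies, out / "gwas_proxies.tsv")
        cfio.write_tsv(self.survival_evidence, out / "survival_evidence.tsv")
        cfio.write_gmt(self.pathways, out / "pathways.gmt",
                       {n: self.pathway_sources.get(n, "na") for n in self.pathways})
        for cls, members in sorted(self.truth["class_members"].items()):
            cfio.write_gene_list(members, out / f"{cls}.txt")
        cfio.write_json(self.truth, out / "truth.json")


# ---------------------------------------------------------------------------
# latents


def _latent_matrix(config: SynthConfig) -> pd.DataFrame:
    rng = config.rng("latent")
    n, feats = config.n_genes, list(config.registry)
    eps = rng.standard_normal((n, len(feats)))
    Z = pd.DataFrame(eps, columns=feats)
    for block, r in config.feature_correlation_blocks:
        u = rng.standard_normal(n)
        for feat in block:
            Z[feat] = math.sqrt(r) * u + math.sqrt(1.0 - r) * Z[feat].to_numpy()
    return Z


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SynthConfig, lengths: np.ndarray | None = None) -> pd.DataFrame:
    """Place non-overlapping genes on fixed-length chromosomes.

    Lengths are lognormal (long-tailed) unless supplied; intergenic gaps are
    exponential with mean 30 kb. Genes are assigned to chromosomes
    round-robin and packed left to right; exceeding the chromosome length
    raises :class:`CapacityError`.
    """
    rng = config.rng("genome")
    n = config.n_genes
    if lengths is None:
        z = rng.standard_normal(n)
        lengths = np.clip(np.round(np.exp(math.log(20_000) + 0.5 * z)), 2_000, 2_000_000)
    lengths = np.asarray(lengths, dtype=np.int64)
    gaps = np.round(rng.exponential(30_000, n)).astype(np.int64) + 1
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    chrom_idx = np.arange(n) % config.n_chromosomes
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    for c in range(config.n_chromosomes):
        sel = np.flatnonzero(chrom_idx == c)
        if sel.size == 0:
            continue
        # start_i = 1 + sum(gaps+lengths)_{<i} + gap_i
        span = gaps[sel] + lengths[sel]
        offset = 1 + np.concatenate([[0], np.cumsum(span[:-1])])
        starts[sel] = offset + gaps[sel]
        ends[sel] = starts[sel] + lengths[sel] - 1
        if ends[sel][-1] > config.chromosome_length:
            raise CapacityError(
                f"{sel.size} genes do not fit on chromosome chr{c + 1} "
                f"(length {config.chromosome_length} bp); reduce n_genes or "
                f"increase chromosome_length"
            )
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n)],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "start": starts,
            "end": ends,
            "strand": strands,
            "biotype": "protein_coding",
        }
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])
    genes["terminator"] = np.where(genes["strand"] == "+", genes["end"], genes["start"])
    return genes


# ---------------------------------------------------------------------------
# raw feature inputs


def _poisson_counts(rng, rate: np.ndarray) -> np.ndarray:
    return rng.poisson(np.clip(rate, 0, 1e6))


def generate_feature_inputs(
    genes: pd.DataFrame, config: SynthConfig, Z: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Construct every raw input table from the latent matrix.

    Returns a dict with keys ``transcripts, exons, expression, tf_peaks,
    variants, counts``. Each realized feature is monotone in its latent;
    distributional forms (lognormal sizes, Poisson counts, gamma LD scores,
    lognormal TPM) are artifact choices, documented in the methods note.
    """
    if genes.empty:
        raise ConfigError("genes table is empty")
    if Z is None:
        Z = _latent_matrix(config)
    n = len(genes)
    gid = genes["gene_id"].to_numpy()
    length = (genes["end"] - genes["start"] + 1).to_numpy()

    # --- transcripts & exons ------------------------------------------------
    rng = config.rng("transcripts")
    n_iso = np.clip(np.round(np.exp(0.9 + 0.45 * Z["n_isoforms"].to_numpy())), 1, 30).astype(int)
    n_ex = np.clip(np.round(np.exp(1.8 + 0.5 * Z["n_exons"].to_numpy())), n_iso, 200).astype(int)
    mean_ex = np.clip(
        np.round(np.exp(5.0 + 0.4 * Z["mean_exon_length"].to_numpy())), 30, np.minimum(1_500, length)
    ).astype(int)
    utr3 = np.round(np.exp(5.5 + 0.6 * Z["mean_utr3_length"].to_numpy())).astype(float)
    utr5 = np.round(np.exp(4.5 + 0.6 * Z["mean_utr5_length"].to_numpy())).astype(float)

    tx_gene = np.repeat(np.arange(n), n_iso)
    tx_rank = np.concatenate([np.arange(k) for k in n_iso])
    transcripts = pd.DataFrame(
        {
            "transcript_id": [f"{gid[g]}.t{j}" for g, j in zip(tx_gene, tx_rank)],
            "gene_id": gid[tx_gene],
            "utr3_len": utr3[tx_gene],
            "utr5_len": utr5[tx_gene],
        }
    )
    # spread the gene's exon total over its isoforms (each >= 1)
    ex_per_tx = np.ones(len(tx_gene), dtype=int)
    extra = n_ex - n_iso
    first_tx_of_gene = np.concatenate([[0], np.cumsum(n_iso)[:-1]])
    ex_per_tx[first_tx_of_gene] += extra
    ex_tx = np.repeat(np.arange(len(tx_gene)), ex_per_tx)
    ex_gene = tx_gene[ex_tx]
    max_start = genes["end"].to_numpy()[ex_gene] - mean_ex[ex_gene] + 1
    lo = genes["start"].to_numpy()[ex_gene]
    ex_start = rng.integers(lo, np.maximum(max_start, lo) + 1)
    exons = pd.DataFrame(
        {
            "transcript_id": transcripts["transcript_id"].to_numpy()[ex_tx],
            "gene_id": gid[ex_gene],
            "start": ex_start,
            "end": ex_start + mean_ex[ex_gene] - 1,
        }
    )

    # --- expression ---------------------------------------------------------
    rng = config.rng("expression")
    beta = np.clip(0.5 + 0.3 * Z["tpm_sd"].to_numpy(), 0.1, 1.5)
    alpha = 0.3 + 0.8 * Z["tpm_mean"].to_numpy() - beta**2 / 2.0
    eps = rng.standard_normal((n, config.n_tissues))
    tpm = np.exp(alpha[:, None] + beta[:, None] * eps)
    expression = pd.DataFrame(
        tpm, index=pd.Index(gid, name="gene_id"),
        columns=[f"tissue_{t + 1}" for t in range(config.n_tissues)],
    )

    # --- variants with LD scores -------------------------------------------
    rng = config.rng("variants")
    n_var = rng.poisson(5.0, n)
    mu = np.exp(1.5 + 0.6 * Z["ld_score_mean"].to_numpy())
    sd = np.exp(0.5 + 0.5 * Z["ld_score_sd"].to_numpy())
    v_gene = np.repeat(np.arange(n), n_var)
    shape = (mu / sd) ** 2
    scale = sd**2 / mu
    scores = rng.gamma(shape[v_gene], scale[v_gene])
    vpos = rng.integers(genes["start"].to_numpy()[v_gene], genes["end"].to_numpy()[v_gene] + 1)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(v_gene))],
            "chrom": genes["chrom"].to_numpy()[v_gene],
            "pos": vpos,
            "ld_score": scores,
        }
    )

    # --- TF peaks -----------------------------------------------------------
    rng = config.rng("tf_peaks")
    tss = genes["tss"].to_numpy()
    peak_w = 150
    parts = []
    n_prom = rng.poisson(np.exp(1.3 + 0.5 * Z["tf_sites_promoter"].to_numpy()))
    p_gene = np.repeat(np.arange(n), n_prom)
    p_start = rng.integers(
        np.maximum(tss[p_gene] - 1_000, 1), tss[p_gene] + 1_000 - peak_w + 2
    )
    parts.append((p_gene, p_start))
    n_body = rng.poisson(length * np.exp(-7.3 + 0.5 * Z["tf_sites_body_per_bp"].to_numpy()))
    b_gene = np.repeat(np.arange(n), n_body)
    b_start = rng.integers(
        genes["start"].to_numpy()[b_gene],
        np.maximum(genes["end"].to_numpy()[b_gene] - peak_w + 1,
                   genes["start"].to_numpy()[b_gene]) + 1,
    )
    parts.append((b_gene, b_start))
    n_dist = rng.poisson(2e5 * np.exp(-8.0 + 0.5 * Z["tf_sites_distal_per_bp"].to_numpy()))
    d_gene = np.repeat(np.arange(n), n_dist)
    side = rng.random(len(d_gene)) < 0.5
    gs, ge = genes["start"].to_numpy()[d_gene], genes["end"].to_numpy()[d_gene]
    d_start = np.where(
        side,
        rng.integers(np.maximum(gs - 100_000, 1), np.maximum(gs - peak_w, 1) + 1),
        rng.integers(ge + 1, ge + 100_000 - peak_w + 2),
    )
    parts.append((d_gene, d_start))
    all_gene = np.concatenate([p[0] for p in parts])
    all_start = np.concatenate([p[1] for p in parts]).astype(np.int64)
    tf_peaks = pd.DataFrame(
        {
            "chrom": genes["chrom"].to_numpy()[all_gene],
            "start": all_start,
            "end": all_start + peak_w - 1,
            "tf_class": rng.choice(TF_CLASS_VOCAB, len(all_gene)),
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    # --- pass-through counts ------------------------------------------------
    rng = config.rng("counts")
    counts = pd.DataFrame({"gene_id": gid})
    counts["gc_content"] = np.clip(0.45 + 0.06 * Z["gc_content"].to_numpy(), 0.25, 0.75)
    counts["n_orthologues_hominidae"] = np.clip(
        np.round(3 + 1.2 * Z["n_orthologues_hominidae"].to_numpy()), 0, 8
    )
    counts["n_paralogues"] = np.round(np.exp(1.0 + 0.6 * Z["n_paralogues"].to_numpy()))
    for zc in ("z_synonymous", "z_missense", "z_lof"):
        counts[zc] = 1.5 * Z[zc].to_numpy()
    counts["n_eqtl"] = rng.poisson(np.exp(1.6 + 0.5 * Z["n_eqtl"].to_numpy())).astype(float)
    counts["n_ptm_total"] = rng.poisson(np.exp(2.0 + 0.5 * Z["n_ptm_total"].to_numpy())).astype(float)
    counts["n_ptm_types"] = np.clip(np.round(3 + 1.5 * Z["n_ptm_types"].to_numpy()), 0, 12)
    # genotyping probe count: confounded with gene length by construction
    counts["probe_n"] = np.round(length / 1_500.0 * np.exp(0.3 * rng.standard_normal(n))) + 1

    # --- missingness (MCAR on maskable features) ----------------------------
    rng = config.rng("missing")
    if config.missing_rate > 0:
        maskable = [f for f in PASSTHROUGH_FEATURES if f in counts.columns]
        for feat in maskable:
            hit = rng.random(n) < config.missing_rate
            counts.loc[hit, feat] = np.nan
        for col, feat in (("utr3_len", "mean_utr3_length"), ("utr5_len", "mean_utr5_length")):
            hit = rng.random(n) < config.missing_rate
            hit_ids = set(gid[hit])
            transcripts.loc[transcripts["gene_id"].isin(hit_ids), col] = np.nan
    else:
        # consume the streams identically so missing_rate=0 differs only in masking
        pass

    return {
        "transcripts": transcripts,
        "exons": exons,
        "expression": expression,
        "tf_peaks": tf_peaks,
        "variants": variants,
        "counts": counts,
    }


# ---------------------------------------------------------------------------
# realized features and labels


def realized_feature_matrix(genes: pd.DataFrame, raw: dict[str, pd.DataFrame],
                            registry=DEFAULT_REGISTRY):
    """Compute the raw FeatureMatrix from generated inputs (same rules as
    the extraction module — it *is* the extraction module)."""
    blocks = [
        compute_structure_features(genes, raw["transcripts"], raw["exons"]),
        compute_ld_features(genes, raw["variants"]),
        compute_expression_features(genes, raw["expression"]),
        count_tf_sites(genes, raw["tf_peaks"]),
        raw["counts"].set_index("gene_id"),
    ]
    return assemble_feature_matrix(blocks, registry, gene_ids=pd.Index(genes["gene_id"]))


def _standardized(values: pd.DataFrame) -> pd.DataFrame:
    """Mean-0 / SD-1 per column over non-missing entries; missing -> 0."""
    mu = values.mean()
    sd = values.std(ddof=1).replace(0.0, 1.0)
    return ((values - mu) / sd).fillna(0.0)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _class_linear_predictors(x_std: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    lps = pd.DataFrame(0.0, index=x_std.index, columns=list(config.feature_effects))
    for cls, effects in config.feature_effects.items():
        for feat, beta in effects.items():
            lps[cls] += beta * x_std[feat]
    return lps


def generate_labels(x_std: pd.DataFrame, config: SynthConfig) -> dict[str, set[str]]:
    """Bernoulli class membership from per-class logistic models."""
    rng = config.rng("labels")
    lps = _class_linear_predictors(x_std, config)
    members: dict[str, set[str]] = {}
    for cls, prev in config.class_prevalences.items():
        if prev <= 0.0:
            members[cls] = set()
            continue
        lp = lps[cls] if cls in lps.columns else 0.0
        p = 1.0 / (1.0 + np.exp(-(_logit(prev) + lp)))
        draw = rng.random(len(x_std)) < p
        members[cls] = set(x_std.index[draw])
    return members


def generate_survival_evidence(genes: pd.DataFrame, survival_members: set[str],
                               config: SynthConfig) -> pd.DataFrame:
    """Per-dataset survival p-values: planted genes get strong p-values in
    at least two datasets with a consistent hazard direction; the rest get
    uniform p-values."""
    rng = config.rng("survival")
    n_ds = config.n_survival_datasets
    gid = genes["gene_id"].to_numpy()
    is_member = np.isin(gid, sorted(survival_members))
    direction = np.where(rng.random(len(gid)) < 0.5, 1, -1)
    rows = []
    n_sig = rng.integers(2, n_ds + 1, len(gid))  # datasets with signal, if member
    for d in range(n_ds):
        p = rng.random(len(gid))
        strong = is_member & (d < n_sig)
        p[strong] = 10.0 ** (-rng.uniform(4, 8, int(strong.sum())))
        p = np.clip(p, 1e-300, 1.0)
        rows.append(pd.DataFrame({
            "gene_id": gid, "dataset_id": f"ds{d + 1}",
            "p_value": p, "hazard_direction": direction,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# GWAS architecture


def generate_gwas_architecture(
    genes: pd.DataFrame, config: SynthConfig, gwas_lp: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index variants (with tissue clusters) and their LD proxies.

    Indices are sampled near gene TSSs, preferentially at genes with a high
    "gwas" linear predictor when one is supplied. The first quarter of the
    indices are arranged in co-located pairs carrying different tissue
    clusters, so the merged loci include forced-overlap, pleiotropic cases.
    """
    if config.proxies_per_index < 0:
        raise ConfigError("proxies_per_index must be >= 0")
    rng = config.rng("gwas")
    n_index = min(config.resolved_n_index, len(genes))
    if gwas_lp is not None:
        w = np.exp(1.5 * (gwas_lp - gwas_lp.mean()) / max(gwas_lp.std(ddof=0), 1e-9))
        w = (w / w.sum()).to_numpy()
    else:
        w = None
    chosen = rng.choice(len(genes), size=n_index, replace=False, p=w)
    tss = genes["tss"].to_numpy()[chosen]
    chrom = genes["chrom"].to_numpy()[chosen]
    pos = np.maximum(tss + rng.integers(-20_000, 20_001, n_index), 1)
    clusters = rng.choice(TISSUE_CLUSTERS, n_index)

    # co-locate pairs to force merging with distinct clusters
    n_pairs = n_index // 8
    for j in range(n_pairs):
        a, b = 2 * j, 2 * j + 1
        chrom[b] = chrom[a]
        pos[b] = pos[a] + rng.integers(500, 1_500)
        if clusters[b] == clusters[a]:
            alt = [c for c in TISSUE_CLUSTERS if c != clusters[a]]
            clusters[b] = alt[rng.integers(len(alt))]

    index_df = pd.DataFrame(
        {
            "variant_id": [f"idx{i}" for i in range(n_index)],
            "chrom": chrom,
            "pos": pos,
            "tissue_cluster": clusters,
            "p_value": 10.0 ** (-rng.uniform(7.35, 30, n_index)),
        }
    )

    k = config.proxies_per_index
    if k == 0:
        proxies = pd.DataFrame(
            columns=["proxy_id", "index_id", "chrom", "pos", "d_prime"]
        ).astype({"pos": np.int64, "d_prime": float})
    else:
        span = rng.uniform(50_000, 250_000, n_index)
        p_index = np.repeat(np.arange(n_index), k)
        offset = rng.uniform(-1.0, 1.0, n_index * k) * span[p_index]
        ppos = np.maximum(pos[p_index] + np.round(offset).astype(np.int64), 1)
        proxies = pd.DataFrame(
            {
                "proxy_id": [f"px{i}" for i in range(n_index * k)],
                "index_id": index_df["variant_id"].to_numpy()[p_index],
                "chrom": chrom[p_index],
                "pos": ppos,
                "d_prime": rng.random(n_index * k),
            }
        )
    return index_df, proxies


# ---------------------------------------------------------------------------
# pathways


def generate_pathways(
    genes: pd.DataFrame, true_score: pd.Series, config: SynthConfig
) -> tuple[dict[str, set[str]], dict[str, str], list[str]]:
    """GMT pathways with planted signal.

    ~10% of pathways are "signal": a ``planted_pathway_fraction`` share of
    their members is drawn from the top decile of ``true_score`` (the
    planted gwas linear predictor), the rest uniformly. Null pathways sample
    uniformly. When the universe is large enough, one undersized (<20) and
    one oversized (>1000) null pathway are included to exercise the term
    size filters downstream.
    """
    rng = config.rng("pathways")
    universe = genes["gene_id"].to_numpy()
    n = len(universe)
    if config.n_pathways == 0:
        return {}, {}, []
    order = np.argsort(-true_score.reindex(universe).fillna(0.0).to_numpy(), kind="stable")
    top = universe[order[: max(1, n // 10)]]
    rest = universe[order[max(1, n // 10):]]

    pathways: dict[str, set[str]] = {}
    sources: dict[str, str] = {}
    source_cycle = ("GO:BP", "GO:MF", "KEGG", "REAC", "WP", "HALLMARK")
    n_signal = max(1, round(0.1 * config.n_pathways)) if config.n_pathways else 0
    n_signal = min(n_signal, config.n_pathways)

    for i in range(n_signal):
        size = int(rng.integers(50, 201))
        size = min(size, n)
        n_top = min(int(round(size * config.planted_pathway_fraction)), len(top))
        members = set(rng.choice(top, n_top, replace=False))
        pool = rest if len(rest) >= size - n_top else universe
        fill = rng.choice(pool, size - n_top, replace=False)
        members |= set(fill)
        name = f"SIGNAL_{i + 1:02d}"
        pathways[name] = members
        sources[name] = source_cycle[i % len(source_cycle)]

    n_null = config.n_pathways - n_signal
    special_sizes = []
    if n_null >= 4 and n > 1_300:
        special_sizes = [8, min(1_100, n - 1)]  # exercise <20 and >1000 filters
    for i in range(n_null):
        if i < len(special_sizes):
            size = special_sizes[i]
        else:
            size = int(rng.integers(20, 401))
        size = min(size, n)
        name = f"NULL_{i + 1:02d}"
        pathways[name] = set(rng.choice(universe, size, replace=False))
        sources[name] = source_cycle[(n_signal + i) % len(source_cycle)]
    return pathways, sources, [f"SIGNAL_{i + 1:02d}" for i in range(n_signal)]


# ---------------------------------------------------------------------------
# orchestration


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Run the whole generative model and return the dataset plus truth."""
    Z = _latent_matrix(config)
    genes = generate_genome(
        config,
        lengths=np.clip(
            np.round(np.exp(math.log(20_000) + 0.5 * Z["gene_length"].to_numpy())),
            2_000, 2_000_000,
        ),
    )
    raw = generate_feature_inputs(genes, config, Z)
    fm = realized_feature_matrix(genes, raw, config.registry)
    x_std = _standardized(fm.values)
    members = generate_labels(x_std, config)
    survival_evidence = generate_survival_evidence(
        genes, members.get("survival", set()), config
    )
    lps = _class_linear_predictors(x_std, config)
    gwas_lp = lps["gwas"] if "gwas" in lps.columns else pd.Series(0.0, index=x_std.index)
    gwas_index, gwas_proxies = generate_gwas_architecture(genes, config, gwas_lp)
    pathways, sources, signal_names = generate_pathways(genes, gwas_lp, config)

    truth = {
        "class_members": {c: sorted(m) for c, m in members.items()},
        "planted_effects": config.feature_effects,
        "signal_pathways": signal_names,
        "gwas_true_score": {g: float(v) for g, v in gwas_lp.items()},
        "seed": config.seed,
    }
    return SyntheticDataset(
        config=config,
        genes=genes,
        transcripts=raw["transcripts"],
        exons=raw["exons"],
        expression=raw["expression"],
        tf_peaks=raw["tf_peaks"],
        variants=raw["variants"],
        counts=raw["counts"],
        gwas_index=gwas_index,
        gwas_proxies=gwas_proxies,
        survival_evidence=survival_evidence,
        pathways=pathways,
        pathway_sources=sources,
        truth=truth,
    )
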