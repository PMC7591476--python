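"""End-to-end pipeline: simulate -> features -> classes -> loci ->
associate -> score -> prioritize -> enrichment.

The stages are the library functions of the sibling modules; this module
only wires them together, carries the intermediate tables in a result
object, and optionally writes every table in its on-disk format. With a
fixed config seed, repeated runs produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cfio
from .assoc import condition_number, fit_association_matrix, scale_features
from .classes import apply_region_exclusion, call_survival_genes, disjoint_classes
from .enrich import gsea, ora
from .features import FeatureMatrix
from .loci import Locus, build_loci, locus_gene_table
from .prioritize import rank_within_loci, select_sets
from .score import (
    compare_weighting_schemes,
    compute_scores,
    impute_median,
    nagelkerke_r2,
    score_correlations,
)
from .synth import SynthConfig, generate_dataset, realized_feature_matrix

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    dataset: object
    genes: pd.DataFrame
    feature_matrix: FeatureMatrix
    scaled: FeatureMatrix
    complete: FeatureMatrix
    class_assignment: pd.DataFrame
    loci: list[Locus]
    locus_genes: pd.DataFrame
    associations: pd.DataFrame
    scores: pd.DataFrame
    evaluations: pd.DataFrame
    score_corr: pd.DataFrame
    ranking: pd.DataFrame
    high_set: set[str] = field(default_factory=set)
    low_set: set[str] = field(default_factory=set)
    ora_high: pd.DataFrame | None = None
    ora_low: pd.DataFrame | None = None
    gsea_result: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)


def run_pipeline(
    config: SynthConfig,
    out_dir: str | Path | None = None,
    exclusion_region: tuple[str, int, int] | None = None,
    rank_class: str = "gwas_single",
    top_k: int = 2,
    run_gsea: bool = False,
    compare_weights: bool = False,
    n_perm: int = 500,
) -> PipelineResult:
    """Run every stage on a freshly generated synthetic dataset.

    ``exclusion_region`` defaults to None because the synthetic genome has
    no MHC; pass :data:`cancerfeat.classes.MHC_REGION`-style tuples to
    exercise the filter. ``rank_class`` chooses the score used for locus
    ranking (the single-tissue GWAS score by default).
    """
    ds = generate_dataset(config)
    genes = apply_region_exclusion(ds.genes, exclusion_region)

    raw = {
        "transcripts": ds.transcripts, "exons": ds.exons,
        "expression": ds.expression, "tf_peaks": ds.tf_peaks,
        "variants": ds.variants, "counts": ds.counts,
    }
    fm = realized_feature_matrix(genes, raw, config.registry)

    loci, gwas_single, gwas_pleio = build_loci(ds.gwas_index, ds.gwas_proxies, genes)
    survival_called = set(call_survival_genes(ds.survival_evidence)["gene_id"])
    members = ds.truth["class_members"]
    class_df = disjoint_classes(
        germline=set(members.get("germline", [])),
        somatic=set(members.get("somatic", [])),
        driver=set(members.get("driver", [])),
        survival=survival_called,
        gwas_single=gwas_single,
        gwas_pleiotropic=gwas_pleio,
        universe=set(genes["gene_id"]),
    )

    scaled = scale_features(fm)
    probe = ds.counts.set_index("gene_id")["probe_n"]
    associations = fit_association_matrix(scaled, class_df, probe_counts=probe)

    complete = impute_median(scaled)
    scores = compute_scores(complete, associations)

    by_class = class_df.groupby("class")["gene_id"].apply(set).to_dict()
    background = by_class.get("background", set())
    evals = []
    for cls in scores.columns:
        ids = sorted(by_class.get(cls, set())) + sorted(background)
        y = np.concatenate(
            [np.ones(len(by_class.get(cls, set()))),
             np.zeros(len(background))]
        )
        ev = nagelkerke_r2(y, scores.loc[ids, cls], cls)
        evals.append({"class": cls, "nagelkerke_r2": ev.nagelkerke_r2,
                      "loglik_null": ev.loglik_null,
                      "loglik_model": ev.loglik_model, "n": ev.n})
    evaluations = pd.DataFrame(evals)
    score_corr = score_correlations(scores) if scores.shape[1] >= 2 else pd.DataFrame()

    locus_genes = locus_gene_table(loci)
    if rank_class not in scores.columns and len(scores.columns):
        logger.warning("no %r score column; ranking by %r", rank_class, scores.columns[0])
        rank_class = scores.columns[0]
    ranking = rank_within_loci(locus_genes, scores[rank_class])
    high, low = select_sets(ranking, mode="top_k", k=top_k) if len(ranking) else (set(), set())

    universe = set(genes["gene_id"])
    ora_high = ora(high, ds.pathways, universe, sources=ds.pathway_sources) if high else None
    ora_low = ora(low, ds.pathways, universe, sources=ds.pathway_sources) if low else None

    gsea_result = None
    if run_gsea and len(ranking):
        full = ranking.drop_duplicates("gene_id").sort_values(
            ["score", "gene_id"], ascending=[False, True], kind="stable"
        )[["gene_id", "score"]]
        gsea_result = gsea(full, ds.pathways, n_perm=n_perm,
                           seed=config.seed, sources=ds.pathway_sources)

    diagnostics: dict = {
        "condition_number": condition_number(complete.values),
        "n_genes": len(genes),
        "n_loci": len(loci),
        "class_sizes": {c: len(s) for c, s in sorted(by_class.items())},
    }
    if compare_weights and rank_class in by_class:
        try:
            diagnostics["weighting"] = compare_weighting_schemes(
                scaled, class_df, rank_class, probe_counts=probe
            )
        except Exception as exc:  # degenerate small-class fits
            logger.warning("weighting comparison failed: %s", exc)

    result = PipelineResult(
        dataset=ds, genes=genes, feature_matrix=fm, scaled=scaled,
        complete=complete, class_assignment=class_df, loci=loci,
        locus_genes=locus_genes, associations=associations, scores=scores,
        evaluations=evaluations, score_corr=score_corr, ranking=ranking,
        high_set=high, low_set=low, ora_high=ora_high, ora_low=ora_low,
        gsea_result=gsea_result, diagnostics=diagnostics,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    res.dataset.write(out / "inputs")
    cfio.write_tsv(res.feature_matrix.values, out / "features_raw.tsv", index=True)
    cfio.write_tsv(res.class_assignment, out / "classes.tsv")
    cfio.write_tsv(res.associations, out / "associations.tsv")
    loci_df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "chrom": l.chrom, "lo": l.lo, "hi": l.hi,
                "n_index": len(l.index_ids),
                "clusters": ",".join(sorted(l.tissue_clusters)),
                "pleiotropic": l.pleiotropic,
            }
            for l in res.loci
        ]
    )
    cfio.write_tsv(loci_df, out / "loci.tsv")
    cfio.write_tsv(res.locus_genes, out / "locus_genes.tsv")
    cfio.write_tsv(res.scores, out / "scores.tsv", index=True)
    cfio.write_tsv(res.evaluations, out / "score_eval.tsv")
    cfio.write_tsv(res.score_corr, out / "score_corr.tsv", index=True)
    cfio.write_tsv(res.ranking, out / "ranking.tsv")
    cfio.write_gene_list(res.high_set, out / "high_set.txt")
    cfio.write_gene_list(res.low_set, out / "low_set.txt")
    if res.ora_high is not None:
        cfio.write_tsv(res.ora_high, out / "enrichment_high.tsv")
    if res.ora_low is not None:
        cfio.write_tsv(res.ora_low, out / "enrichment_low.tsv")
    if res.gsea_result is not None:
        cfio.write_tsv(res.gsea_result, out / "enrichment_gsea.tsv")
    cfio.write_json(res.diagnostics, out / "diagnostics.json")
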