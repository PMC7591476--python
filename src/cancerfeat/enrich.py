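"""Pathway enrichment: over-representation and rank-based GSEA.

ORA tests each pathway for overlap with a query gene set by the
hypergeometric upper tail within a gene universe, after restricting
pathways to the universe. Pathways larger than ``max_term`` genes (counted
within the universe) are excluded, as are pathways covering less than
``min_precision`` of the query (precision = overlap / query size, default
2.5%, applied before testing). Benjamini-Hochberg q-values are computed
both across all tested pathways and within each annotation source.

GSEA walks the score-ranked gene list with the weighted Kolmogorov-Smirnov
running sum (weight exponent 1 on |score|); the null is by gene-label
permutation with a fixed seed. NES divides the observed ES by the mean
|null ES| of the same sign; the permutation p-value uses the same-sign null
tail with the +1 correction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .features import ValidationError

__all__ = ["ora", "gsea", "hypergeom_tail"]

logger = logging.getLogger(__name__)


def hypergeom_tail(overlap: int, universe: int, term: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, term, query)."""
    return float(hypergeom.sf(overlap - 1, universe, term, query))


def ora(
    query: set[str],
    pathways: dict[str, set[str]],
    universe: set[str],
    max_term: int = 1000,
    min_precision: float = 0.025,
    sources: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Over-representation analysis of a query set against GMT pathways.

    Returns one row per tested pathway: term_size (within universe),
    overlap, precision, hypergeometric p, BH q overall (``q``) and within
    the pathway's source (``q_source``). Pathways failing the term-size or
    precision filter are not tested (and absorb no multiple-testing
    burden).
    """
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query set")
    if not query <= universe:
        raise ValidationError("query is not a subset of the universe")

    n_universe, n_query = len(universe), len(query)
    rows = []
    for name in sorted(pathways):
        members = pathways[name] & universe
        term_size = len(members)
        if term_size == 0 or term_size > max_term:
            continue
        overlap = len(members & query)
        precision = overlap / n_query
        if precision < min_precision:
            continue
        rows.append(
            {
                "pathway": name,
                "source": (sources or {}).get(name, "synthetic"),
                "term_size": term_size,
                "overlap": overlap,
                "precision": precision,
                "p": hypergeom_tail(overlap, n_universe, term_size, n_query),
            }
        )
    out = pd.DataFrame(rows, columns=["pathway", "source", "term_size",
                                      "overlap", "precision", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["q_source"] = np.nan
        for _, idx in out.groupby("source").groups.items():
            out.loc[idx, "q_source"] = multipletests(out.loc[idx, "p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
        out["q_source"] = pd.Series(dtype=float)
    return out


# ---------------------------------------------------------------------------
# GSEA


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Enrichment score given sorted member positions in the ranked list.

    ``weights`` are the member weights in position order; misses decrement
    by 1/(n - k). The running sum's extremes occur right after a hit (for
    the maximum) or right before one / at the end (for the minimum).
    """
    k = len(pos)
    wsum = weights.sum()
    if wsum == 0:
        weights = np.ones(k)
        wsum = float(k)
    hit_cum = np.cumsum(weights) / wsum
    miss_step = 1.0 / (n - k)
    miss_before = (pos - np.arange(k)) * miss_step  # misses seen before each hit
    after_hit = hit_cum - miss_before
    before_hit = np.concatenate([[0.0], hit_cum[:-1]]) - miss_before
    hi = after_hit.max()
    lo = min(before_hit.min(), hit_cum[-1] - 1.0)  # end of list
    return float(hi if hi >= -lo else lo)


def gsea(
    ranking: pd.DataFrame,
    pathways: dict[str, set[str]],
    min_term: int = 20,
    max_term: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    sources: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank-based gene set enrichment of a score-ordered gene list.

    ``ranking`` has columns gene_id and score, strictly ordered by
    descending score (break ties upstream). Term sizes are measured within
    the ranked universe and restricted to [min_term, max_term]; pathways
    with no ranked member are skipped. Returns ES, NES, permutation p and
    BH q per tested pathway.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is low; permutation p-values will be coarse", n_perm)
    genes = ranking["gene_id"].to_numpy()
    scores = ranking["score"].to_numpy(dtype=float)
    if len(genes) != len(set(genes)):
        raise ValidationError("duplicate gene ids in ranking")
    n = len(genes)
    w_all = np.abs(scores) ** weight_exponent
    pos_of = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            es = np.empty(n_perm)
            for b in range(n_perm):
                perm_pos = np.sort(rng.choice(n, k, replace=False))
                es[b] = _es_from_positions(perm_pos, w_all[perm_pos], n)
            null_cache[k] = es
        return null_cache[k]

    rows = []
    for name in sorted(pathways):
        members = pathways[name] & set(genes)
        k = len(members)
        if k == 0:
            logger.info("pathway %s has no ranked member; skipped", name)
            continue
        if not (min_term <= k <= max_term):
            continue
        if k == n:
            continue  # ES undefined: no misses
        pos = np.sort(np.fromiter((pos_of[g] for g in members), dtype=int, count=k))
        es = _es_from_positions(pos, w_all[pos], n)
        null = null_es(k)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same):
            mean_abs = np.abs(same).mean()
            nes = es / mean_abs if mean_abs > 0 else 0.0
            p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
        else:
            nes, p = 0.0, 1.0 / (1.0 + n_perm)
        rows.append(
            {
                "pathway": name,
                "source": (sources or {}).get(name, "synthetic"),
                "term_size": k,
                "es": es,
                "nes": float(nes),
                "direction": "up" if es >= 0 else "down",
                "perm_p": float(p),
            }
        )
    out = pd.DataFrame(rows, columns=["pathway", "source", "term_size",
                                      "es", "nes", "direction", "perm_p"])
    if len(out):
        out["q"] = multipletests(out["perm_p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out
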