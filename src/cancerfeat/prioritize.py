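"""Per-locus gene ranking and high/low candidate set selection.

Genes within each GWAS locus are ranked by descending class score (ties
broken by ascending gene id, deterministically). The high set takes the top
k genes per locus (default k=2) or the top p% (ceiling, at least one gene);
everything else falls into the low set. A gene appearing in several loci is
high if it is high in any of them; the final sets are disjoint.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from .features import ValidationError

__all__ = ["rank_within_loci", "select_sets"]

logger = logging.getLogger(__name__)


def rank_within_loci(
    locus_genes: pd.DataFrame, scores: pd.Series
) -> pd.DataFrame:
    """Rank locus member genes by descending score.

    ``locus_genes`` is the long-format (locus_id, gene_id) table;
    ``scores`` the chosen class score indexed by gene_id — every locus gene
    must have one. Returns (locus_id, gene_id, score, rank) with rank 1 the
    best per locus.
    """
    missing = set(locus_genes["gene_id"]) - set(scores.index)
    if missing:
        raise ValidationError(f"locus genes without a score: {sorted(missing)[:5]}")
    if locus_genes.empty:
        logger.warning("empty locus gene table; nothing to rank")
        return pd.DataFrame(columns=["locus_id", "gene_id", "score", "rank"])
    df = locus_genes[["locus_id", "gene_id"]].copy()
    df["score"] = scores.reindex(df["gene_id"]).to_numpy()
    df = df.sort_values(["locus_id", "score", "gene_id"],
                        ascending=[True, False, True], kind="stable")
    df["rank"] = df.groupby("locus_id").cumcount() + 1
    return df.reset_index(drop=True)


def select_sets(
    rankings: pd.DataFrame, mode: str = "top_k", k: int = 2, percent: float = 10.0
) -> tuple[set[str], set[str]]:
    """Split ranked locus genes into high- and low-score sets.

    ``top_k`` keeps up to k genes per locus; ``top_percent`` keeps
    ceil(percent% of the locus size), at least 1. Genes high in any locus
    are removed from the low set (high-anywhere precedence).
    """
    if mode == "top_k":
        if k <= 0:
            raise ValidationError("k must be positive")
        cut = rankings["rank"] <= k
    elif mode == "top_percent":
        if not 0 < percent <= 100:
            raise ValidationError("percent must be in (0, 100]")
        sizes = rankings.groupby("locus_id")["gene_id"].transform("size")
        cut = rankings["rank"] <= sizes.map(
            lambda n: max(1, math.ceil(n * percent / 100.0))
        )
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")
    high = set(rankings.loc[cut, "gene_id"])
    low = set(rankings["gene_id"]) - high
    return high, low
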