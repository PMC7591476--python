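"""Cancer gene class construction.

Builds six mutually exclusive cancer gene classes — germline, somatic,
driver, survival, single-tissue GWAS and pleiotropic GWAS — plus the
background set, from raw membership lists, per-dataset survival evidence
and GWAS locus gene sets. The gene universe is restricted to protein-coding
genes outside a configurable exclusion region (default: the highly
pleiotropic MHC region, chr6:25,477,797-33,448,354).

Exclusion rules (applied to the *original* input sets):

* germline ∩ somatic removed from both;
* driver genes that are germline or somatic removed from driver, and
  somatic ∩ driver removed from somatic (symmetric treatment);
* survival minus (germline ∪ somatic ∪ driver ∪ GWAS);
* GWAS minus (germline ∪ somatic ∪ driver ∪ survival).

The resulting classes are pairwise disjoint; genes dropped by these rules
fall into the background set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import ValidationError

__all__ = [
    "MHC_REGION",
    "CLASS_NAMES",
    "call_survival_genes",
    "disjoint_classes",
    "apply_region_exclusion",
]

logger = logging.getLogger(__name__)

#: chrom, lo, hi (1-based inclusive, hg19 convention of the default).
MHC_REGION: tuple[str, int, int] = ("chr6", 25_477_797, 33_448_354)

CLASS_NAMES = ("germline", "somatic", "driver", "survival",
               "gwas_single", "gwas_pleiotropic")


def call_survival_genes(
    evidence: pd.DataFrame,
    fdr_threshold: float = 0.01,
    min_datasets: int = 2,
) -> pd.DataFrame:
    """Call survival genes from per-dataset association evidence.

    Within each dataset, p-values are Benjamini-Hochberg adjusted; a gene
    is called if its adjusted p falls below ``fdr_threshold`` in at least
    ``min_datasets`` datasets. The hazard direction is recorded as
    ``positive``/``negative`` when all significant datasets agree, else
    left empty.

    Returns a DataFrame (gene_id, n_significant, direction) of called genes.
    """
    p = evidence["p_value"]
    if ((p <= 0) | (p > 1)).any() or p.isna().any():
        raise ValidationError("survival evidence p_value outside (0, 1]")

    ev = evidence.copy()
    ev["q"] = np.nan
    for _, idx in ev.groupby("dataset_id").groups.items():
        ev.loc[idx, "q"] = multipletests(ev.loc[idx, "p_value"], method="fdr_bh")[1]
    sig = ev[ev["q"] < fdr_threshold]
    counts = sig.groupby("gene_id").size()
    called = counts[counts >= min_datasets]

    directions = []
    for gid in called.index:
        signs = set(np.sign(sig.loc[sig["gene_id"] == gid, "hazard_direction"]))
        if signs == {1}:
            directions.append("positive")
        elif signs == {-1}:
            directions.append("negative")
        else:
            directions.append("")
    return pd.DataFrame(
        {"gene_id": called.index, "n_significant": called.to_numpy(),
         "direction": directions}
    ).reset_index(drop=True)


def disjoint_classes(
    germline: set[str],
    somatic: set[str],
    driver: set[str],
    survival: set[str],
    gwas_single: set[str],
    gwas_pleiotropic: set[str],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the mutual-exclusion rules and assign one class per gene.

    ``universe``, when given, drops unknown gene ids (with a logged
    warning) and adds a ``background`` row for every universe gene left in
    no cancer class. Idempotent: feeding the output classes back in leaves
    them unchanged.
    """
    g0, s0, d0 = set(germline), set(somatic), set(driver)
    sv0 = set(survival)
    w0 = set(gwas_single) | set(gwas_pleiotropic)

    g = g0 - s0
    s = s0 - g0 - d0
    d = d0 - g0 - s0
    sv = sv0 - g0 - s0 - d0 - w0
    w_single = set(gwas_single) - g0 - s0 - d0 - sv0
    w_pleio = set(gwas_pleiotropic) - g0 - s0 - d0 - sv0
    w_single -= w_pleio  # pleiotropic wins for genes seen in both GWAS sets

    assignment = {}
    for cls, members in (("germline", g), ("somatic", s), ("driver", d),
                         ("survival", sv), ("gwas_single", w_single),
                         ("gwas_pleiotropic", w_pleio)):
        for gid in members:
            assignment[gid] = cls

    if universe is not None:
        unknown = set(assignment) - set(universe)
        if unknown:
            logger.warning("dropping %d gene ids outside the universe", len(unknown))
            for gid in unknown:
                del assignment[gid]
        for gid in set(universe) - set(assignment):
            assignment[gid] = "background"

    out = pd.DataFrame(
        sorted(assignment.items()), columns=["gene_id", "class"]
    )
    return out


def apply_region_exclusion(
    genes: pd.DataFrame, region: tuple[str, int, int] | None = MHC_REGION
) -> pd.DataFrame:
    """Drop genes whose body overlaps the exclusion region by >= 1 bp.

    A gene straddling the region boundary is not "outside" it and is
    removed. ``region=None`` disables the filter.
    """
    if region is None:
        return genes
    chrom, lo, hi = region
    overlap = (
        (genes["chrom"] == chrom)
        & (genes["start"] <= hi)
        & (genes["end"] >= lo)
    )
    return genes[~overlap].reset_index(drop=True)
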