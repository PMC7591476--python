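"""Tabular I/O for the pipeline's on-disk formats.

All genomic tables are tab-separated with a header row. Genes and variants
use 1-based inclusive coordinates (biomaRt convention); TF peaks are read
from BED (0-based half-open) and converted to 1-based inclusive on load.
Writers are deterministic: fixed column order, fixed float formatting, sorted
gene sets — so a fixed-seed pipeline run is byte-identical across repeats.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_genes(path: str | Path) -> pd.DataFrame:
    """genes.tsv: gene_id, chrom, start, end, strand, tss, terminator."""
    df = read_tsv(path, dtype={"chrom": str})
    for col in ("start", "end", "tss", "terminator"):
        df[col] = df[col].astype(int)
    return df


def read_bed_peaks(path: str | Path) -> pd.DataFrame:
    """BED3(+1) TF peaks -> 1-based inclusive (chrom, start, end, tf_class)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "tf_class"],
        dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1  # 0-based half-open -> 1-based incl.
    df["end"] = df["end"].astype(int)
    return df


def write_bed_peaks(df: pd.DataFrame, path: str | Path) -> None:
    """Write internal 1-based inclusive peaks back to BED."""
    out = df.copy()
    out["start"] = out["start"].astype(int) - 1
    cols = ["chrom", "start", "end"] + (["tf_class"] if "tf_class" in out.columns else [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """expression.tsv: genes x tissues TPM, gene_id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT: name <tab> description <tab> gene ids. Returns name -> set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(pathways: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if hasattr(o, "item"):  # numpy scalar
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
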