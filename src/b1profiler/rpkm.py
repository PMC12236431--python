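"""RPKM normalization and depth-resolved gene/transcript profiles.

Counts are per open reading frame (ORF) per sample; RPKM divides each count
by ORF length in kilobases and by library size in millions of mapped reads,
making gene abundances comparable across ORFs and sequencing depths:

    rpkm(o, s) = count(o, s) / ( (length_bp(o)/1000) * (library_size(s)/1e6) )

The library size is the externally known total of mapped reads when supplied,
else the column sum of the count table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

ORF_META_COLUMNS = ("length_bp", "genome_id", "gene_symbol", "taxon_class", "domain")


def check_orf_meta(orf_meta: pd.DataFrame, counts: pd.DataFrame) -> None:
    missing = sorted(set(counts.index) - set(orf_meta.index))
    if missing:
        raise ConsistencyError(f"ORF metadata missing lengths for: {missing[:10]}")
    lengths = orf_meta.loc[counts.index, "length_bp"]
    if (lengths <= 0).any():
        bad = sorted(lengths.index[lengths <= 0])
        raise ConsistencyError(f"non-positive ORF lengths for: {bad[:10]}")


def compute_rpkm(
    counts: pd.DataFrame,
    orf_meta: pd.DataFrame,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize an ORF x sample count table to RPKM.

    Parameters
    ----------
    counts:
        Non-negative integer counts, ORFs as rows, samples as columns.
    orf_meta:
        Indexed by orf_id with at least a positive ``length_bp`` column.
    library_sizes:
        sample_id -> total mapped reads; defaults to per-sample column sums.
    """
    check_orf_meta(orf_meta, counts)
    if (counts.to_numpy() < 0).any():
        raise ConsistencyError("negative counts")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series({s: float(library_sizes[s]) for s in counts.columns})
    if (lib <= 0).any():
        bad = sorted(lib.index[lib <= 0])
        raise ConfigurationError(f"non-positive library sizes for samples: {bad}")
    kb = orf_meta.loc[counts.index, "length_bp"].astype(float) / 1000.0
    per_million = lib / 1e6
    return counts.astype(float).div(kb, axis=0).div(per_million, axis=1)


def gene_depth_profile(
    rpkm: pd.DataFrame,
    orf_meta: pd.DataFrame,
    gene_symbols: Sequence[str],
    group_by: str = "domain",
) -> pd.DataFrame:
    """Sum RPKM over ORFs per requested gene symbol within each group.

    Returns a long table (sample, group, gene_symbol, rpkm). Unknown symbols
    simply yield no rows.
    """
    if group_by not in {"domain", "taxon_class", "genome"}:
        raise ConfigurationError(f"unknown group_by {group_by!r}")
    if not gene_symbols:
        raise ConfigurationError("gene_symbols must be non-empty")
    col = {"domain": "domain", "taxon_class": "taxon_class", "genome": "genome_id"}[group_by]
    meta = orf_meta.loc[rpkm.index]
    mask = meta["gene_symbol"].isin(set(gene_symbols))
    sub = rpkm.loc[mask]
    if sub.empty:
        return pd.DataFrame(columns=["sample", "group", "gene_symbol", "rpkm"])
    grouped = (
        sub.groupby([meta.loc[mask, col].rename("group"),
                     meta.loc[mask, "gene_symbol"]])
        .sum()
    )
    long = grouped.stack().rename("rpkm").reset_index()
    long.columns = ["group", "gene_symbol", "sample", "rpkm"]
    return long[["sample", "group", "gene_symbol", "rpkm"]].sort_values(
        ["sample", "gene_symbol", "group"]
    ).reset_index(drop=True)


def domain_ratios(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-sample archaea:bacteria RPKM ratio per gene symbol.

    Takes the output of :func:`gene_depth_profile` with ``group_by="domain"``.
    Samples where both domains are zero yield a missing ratio (NaN), never 0.
    """
    wide = profile.pivot_table(
        index=["sample", "gene_symbol"], columns="group", values="rpkm",
        aggfunc="sum", fill_value=0.0,
    )
    arc = wide.get("archaea", pd.Series(0.0, index=wide.index))
    bac = wide.get("bacteria", pd.Series(0.0, index=wide.index))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (arc == 0) & (bac == 0), np.nan,
            np.where(bac == 0, np.inf, arc / bac),
        )
    out = wide.reset_index()[["sample", "gene_symbol"]]
    out["archaea_bacteria_ratio"] = ratio
    return out


def transcript_shares(
    rpkm: pd.DataFrame,
    orf_meta: pd.DataFrame,
    gene_symbols: Sequence[str],
    group_by: str = "taxon_class",
) -> pd.DataFrame:
    """Within-sample share of summed thiamine-gene RPKM per group.

    Shares sum to 1 over groups within each sample; groups with zero RPKM get
    share 0. Samples where no requested gene has any RPKM get missing shares
    (NaN), not zeros.
    """
    profile = gene_depth_profile(rpkm, orf_meta, gene_symbols, group_by=group_by)
    if profile.empty:
        return pd.DataFrame(columns=["sample", "group", "share"])
    per_group = profile.groupby(["sample", "group"])["rpkm"].sum().reset_index()
    totals = per_group.groupby("sample")["rpkm"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        per_group["share"] = np.where(totals > 0, per_group["rpkm"] / totals, np.nan)
    return per_group[["sample", "group", "share"]]
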