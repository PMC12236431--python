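"""Thiamine (B1) physiology genotyping of genomes and MAGs.

A genome's de novo thiamine biosynthesis capacity is read from three pathway
branches: the pyrimidine branch (*thiC*), the thiazole branch (*thiG* or the
*thi4*-type synthase), and the condensation step (*thiE*, or the archaeal
*thiDN* fusion). Genomes encoding all three are tentative prototrophs; a
missing pyrimidine branch implies HMP auxotrophy, a missing thiazole branch
HET auxotrophy, and condensation alone a dual-precursor auxotroph. Genomes
with no condensation step but salvage or transport genes are salvage-only.

Because assembled genomes are incomplete, every call that rests on gene
*absence* carries ``p_chance = (1 - completeness)^k``: the probability that
the k required genes are all unobserved purely because the assembly is
incomplete, under independent uniform gene recovery. When that probability
reaches the tolerance ``alpha`` the call is downgraded to INDETERMINATE — a
definite absence call requires ``p_chance < alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import GENE_SYMBOLS, TRANSPORTER_SYMBOLS
from .errors import ConfigurationError, ConsistencyError, ParseError

CATEGORIES = (
    "PROTOTROPH", "AUX_HMP", "AUX_HET", "AUX_DUAL",
    "SALVAGE_ONLY", "NO_PATHWAY", "INDETERMINATE",
)

SALVAGE_GENES = ("thiL", "thiM", "tenA", "thiD")

CHEMOAUTOTROPHY_FLAGS = {
    "ammonia_oxidation": ("amoA",),
    "nitrite_oxidation": ("nxr",),
    "sulfur_oxidation": ("aprA", "aprB", "dsrA"),
    "cbb_fixation": ("rbcL",),
}

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GenomeMeta:
    """Per-genome metadata: taxonomy and assembly quality estimates."""

    genome_id: str
    domain: str  # "bacteria" | "archaea"
    taxonomy: str  # semicolon-delimited ranks, domain first
    completeness: float  # fraction in [0, 1]
    contamination: float  # fraction, >= 0

    def __post_init__(self):
        if self.domain not in {"bacteria", "archaea"}:
            raise ConsistencyError(f"{self.genome_id}: unknown domain {self.domain!r}")
        if not 0.0 <= self.completeness <= 1.0:
            raise ConsistencyError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 1]"
            )
        if self.contamination < 0:
            raise ConsistencyError(f"{self.genome_id}: negative contamination")


@dataclass(frozen=True)
class PhenotypeCall:
    """One genome's B1 physiology call with incompleteness-aware confidence."""

    genome_id: str
    category: str
    tentative_category: str  # gene-pattern category before the confidence gate
    absent_required: frozenset[str]
    p_chance: float
    salvage_flags: frozenset[str]
    chemoautotrophy_flags: frozenset[str]
    quality_tier: str


def absence_confidence(completeness: float, k_absent: int) -> float:
    """Probability that ``k_absent`` encoded genes are all missing by chance.

    Under independent, uniformly recoverable genes this is
    ``(1 - completeness) ** k_absent``; by convention 1 when nothing is absent.
    """
    if not 0.0 <= completeness <= 1.0:
        raise ConfigurationError(f"completeness {completeness} outside [0, 1]")
    if k_absent < 0:
        raise ConfigurationError("k_absent must be non-negative")
    return (1.0 - completeness) ** k_absent


def _check_row(row: Mapping[str, int]) -> None:
    unknown = sorted(set(row) - GENE_SYMBOLS)
    if unknown:
        raise ConsistencyError(f"unknown gene symbols in presence row: {unknown}")


def quality_tier(completeness: float, contamination: float) -> str:
    """MAG quality tier: two printed gates, >=50%/<5% (high) and >=50%/<=10% (medium)."""
    if completeness >= 0.5 and contamination < 0.05:
        return "high"
    if completeness >= 0.5 and contamination <= 0.10:
        return "medium"
    return "below_threshold"


def classify_b1_genotype(
    row: Mapping[str, int],
    meta: GenomeMeta,
    alpha: float = DEFAULT_ALPHA,
    thidn_archaea_only: bool = True,
) -> PhenotypeCall:
    """Classify one genome's gene-presence row into a B1 genotype.

    Parameters
    ----------
    row:
        Gene symbol -> copy count, restricted to the catalog vocabulary.
    meta:
        Genome metadata; ``completeness`` feeds the absence-confidence gate
        and the domain selects which thiazole/condensation genes apply.
    alpha:
        Tolerance on ``p_chance``; absence-based calls with
        ``p_chance >= alpha`` are downgraded to INDETERMINATE.
    thidn_archaea_only:
        Accept the *thiDN* fusion as the condensation step only in archaea.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha {alpha} outside (0, 1)")
    _check_row(row)

    def has(sym: str) -> bool:
        return row.get(sym, 0) > 0

    archaeal = meta.domain == "archaea"
    pyr = has("thiC")
    thz = has("thiG") or has("thi4")
    cnd = has("thiE") or (has("thiDN") and (archaeal or not thidn_archaea_only))

    # Branch representatives used to count independently missing genes.
    thz_rep = "thi4" if archaeal else "thiG"
    cnd_rep = "thiDN" if archaeal else "thiE"

    salvage = frozenset(
        [g for g in SALVAGE_GENES if has(g)]
        + (["transporter"] if any(has(t) for t in TRANSPORTER_SYMBOLS) else [])
    )

    if cnd:
        if pyr and thz:
            cat, absent = "PROTOTROPH", frozenset()
        elif not pyr and thz:
            cat, absent = "AUX_HMP", frozenset({"thiC"})
        elif pyr and not thz:
            cat, absent = "AUX_HET", frozenset({thz_rep})
        else:
            cat, absent = "AUX_DUAL", frozenset({"thiC", thz_rep})
    elif salvage:
        cat, absent = "SALVAGE_ONLY", frozenset({cnd_rep})
    else:
        cat, absent = "NO_PATHWAY", frozenset({cnd_rep})

    p_chance = 0.0 if cat == "PROTOTROPH" else absence_confidence(
        meta.completeness, len(absent)
    )
    category = cat
    if cat != "PROTOTROPH" and p_chance >= alpha:
        category = "INDETERMINATE"

    return PhenotypeCall(
        genome_id=meta.genome_id,
        category=category,
        tentative_category=cat,
        absent_required=absent,
        p_chance=p_chance,
        salvage_flags=salvage,
        chemoautotrophy_flags=annotate_chemoautotrophy(row),
        quality_tier=quality_tier(meta.completeness, meta.contamination),
    )


def annotate_chemoautotrophy(row: Mapping[str, int]) -> frozenset[str]:
    """Chemoautotrophy marker flags from nitrification/sulfur/CBB marker genes."""
    _check_row(row)
    return frozenset(
        flag for flag, genes in CHEMOAUTOTROPHY_FLAGS.items()
        if any(row.get(g, 0) > 0 for g in genes)
    )


def classify_genomes(
    presence: pd.DataFrame,
    meta: Sequence[GenomeMeta] | Mapping[str, GenomeMeta],
    alpha: float = DEFAULT_ALPHA,
    thidn_archaea_only: bool = True,
) -> list[PhenotypeCall]:
    """Classify every row of a presence matrix. Metadata must cover all genomes."""
    if not isinstance(meta, Mapping):
        meta = {m.genome_id: m for m in meta}
    missing = sorted(set(presence.index) - set(meta))
    if missing:
        raise ConsistencyError(f"metadata missing for genomes: {missing}")
    return [
        classify_b1_genotype(
            presence.loc[g].to_dict(), meta[g], alpha=alpha,
            thidn_archaea_only=thidn_archaea_only,
        )
        for g in presence.index
    ]


def calls_to_frame(calls: Iterable[PhenotypeCall]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": c.genome_id,
            "category": c.category,
            "tentative_category": c.tentative_category,
            "absent_required": ",".join(sorted(c.absent_required)),
            "p_chance": c.p_chance,
            "salvage_flags": ",".join(sorted(c.salvage_flags)),
            "chemoautotrophy_flags": ",".join(sorted(c.chemoautotrophy_flags)),
            "quality_tier": c.quality_tier,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "category", "tentative_category", "absent_required",
            "p_chance", "salvage_flags", "chemoautotrophy_flags", "quality_tier",
        ],
    )


def _taxon_at_rank(taxonomy: str, rank: str) -> str:
    idx = RANKS.index(rank)
    parts = [p.strip() for p in taxonomy.split(";")]
    if idx >= len(parts):
        raise ConsistencyError(
            f"taxonomy {taxonomy!r} has no rank {rank!r} (only {len(parts)} levels)"
        )
    return parts[idx]


def genotype_summary(
    calls: Sequence[PhenotypeCall],
    meta: Sequence[GenomeMeta] | Mapping[str, GenomeMeta],
    rank: str | None = None,
    min_quality: str = "below_threshold",
) -> pd.DataFrame:
    """Category counts/fractions per domain (and per taxon at ``rank``).

    ``min_quality`` gates which genomes enter the summary:
    ``"high"`` keeps only high-tier, ``"medium"`` keeps high+medium,
    ``"below_threshold"`` (default) keeps everything. Fractions sum to 1
    within each (domain, taxon) group.
    """
    if rank is not None and rank not in RANKS:
        raise ConfigurationError(f"unknown rank {rank!r}; choose from {RANKS}")
    allowed = {
        "high": {"high"},
        "medium": {"high", "medium"},
        "below_threshold": {"high", "medium", "below_threshold"},
    }[min_quality]
    if not isinstance(meta, Mapping):
        meta = {m.genome_id: m for m in meta}

    rows = []
    for c in calls:
        if c.quality_tier not in allowed:
            continue
        m = meta[c.genome_id]
        taxon = _taxon_at_rank(m.taxonomy, rank) if rank else "all"
        rows.append((m.domain, taxon, c.category))
    cols = ["domain", "taxon", "category", "count", "fraction"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["domain", "taxon", "category"])
    counts = df.groupby(["domain", "taxon", "category"]).size().rename("count").reset_index()
    totals = counts.groupby(["domain", "taxon"])["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts[cols].sort_values(["domain", "taxon", "category"]).reset_index(drop=True)


def read_genome_meta(path: str | Path) -> list[GenomeMeta]:
    """Read genome metadata TSV; completeness/contamination may be percent or
    fraction — values are auto-scaled when a column exceeds 1."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome_id", "domain", "taxonomy", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"genome metadata missing columns {sorted(missing)}", path=str(path))
    for col in ("completeness", "contamination"):
        if (df[col] > 1.0).any():
            df[col] = df[col] / 100.0
    return [
        GenomeMeta(
            genome_id=str(r.genome_id), domain=str(r.domain),
            taxonomy=str(r.taxonomy),
            completeness=float(r.completeness), contamination=float(r.contamination),
        )
        for r in df.itertuples(index=False)
    ]
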