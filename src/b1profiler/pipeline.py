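"""End-to-end orchestration: config → annotate → genotype → profiles →
ecology → TRC → combined report.

The run is fully deterministic for a fixed config + inputs: the report
records the package version, a hash of the canonical config, and every seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import GeneFamilyCatalog, default_catalog
from .ecology import (
    bray_curtis_matrix, average_linkage, drop_chloroplasts, grouped_rank_test,
    indval, prototroph_share, relative_abundance, shannon_index,
)
from .errors import ConfigurationError, ProfilerError
from .genotype import (
    calls_to_frame, classify_genomes, genotype_summary, read_genome_meta,
)
from .hits import build_presence_matrix, filter_hits, parse_hit_table
from .rpkm import compute_rpkm, domain_ratios, gene_depth_profile, transcript_shares
from .trc import (
    assign_oxygen_layers, find_local_maxima, fold_change, read_ctd_table,
    read_trc_table, replicate_stats, COMPOUNDS,
)

log = logging.getLogger("b1profiler")

PROFILE_GENES = ("thiC", "thiG", "thi4", "thiE", "thiDN")


class StageError(ProfilerError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All inputs, thresholds and seeds of a pipeline run."""

    output_dir: str = "profiler_out"
    # inputs (paths; a stage is skipped when its inputs are absent)
    hits: str | None = None
    hits_format: str = "domtbl"
    catalog: str | None = None
    genome_meta: str | None = None
    asv_counts: str | None = None
    asv_taxonomy: str | None = None
    sample_meta: str | None = None
    orf_counts: str | None = None
    orf_meta: str | None = None
    tx_counts: str | None = None
    tx_meta: str | None = None
    trc: str | None = None
    ctd: str | None = None
    # thresholds
    general_evalue: float = 1e-10
    strict_evalue: float = 1e-15
    alpha: float = 0.05
    omz_do_max: float = 30.0
    omz_core_do_max: float = 10.0
    indval_permutations: int = 999
    seed: int = 7

    def validate(self) -> None:
        if self.strict_evalue <= 0 or self.general_evalue <= 0:
            raise ConfigurationError("e-value thresholds must be positive")
        if self.general_evalue < self.strict_evalue:
            raise ConfigurationError(
                "general e-value tier must be >= (looser than) the strict tier"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.indval_permutations < 99:
            raise ConfigurationError("indval_permutations must be >= 99")
        if self.omz_core_do_max > self.omz_do_max:
            raise ConfigurationError("OMZ core threshold must be <= OMZ threshold")
        for name in ("hits", "catalog", "genome_meta", "asv_counts", "asv_taxonomy",
                     "sample_meta", "orf_counts", "orf_meta", "tx_counts",
                     "tx_meta", "trc", "ctd"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input {name!r} does not exist: {p}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**data)


def config_template() -> str:
    """A fully commented config template."""
    lines = [
        "# b1profiler pipeline configuration",
        "output_dir: profiler_out",
        "# --- inputs (leave a block out to skip its stage) ---",
        "hits: null           # HMMER domtblout or 6-column TSV of homology hits",
        "hits_format: domtbl  # domtbl | tsv",
        "catalog: null        # gene-family catalog TSV; null = packaged default",
        "genome_meta: null    # genome_id, domain, taxonomy, completeness, contamination",
        "asv_counts: null     # ASV x sample count TSV",
        "asv_taxonomy: null   # taxon -> taxonomy TSV",
        "sample_meta: null    # sample_id, station, campaign, depth_m, dissolved_oxygen",
        "orf_counts: null     # metagenomic ORF x sample counts",
        "orf_meta: null       # orf_id, length_bp, genome_id, gene_symbol, taxon_class, domain",
        "tx_counts: null      # metatranscriptomic ORF x sample counts",
        "tx_meta: null",
        "trc: null            # long-format TRC replicate concentrations",
        "ctd: null            # depth context with dissolved_oxygen",
        "# --- thresholds ---",
        "general_evalue: 1.0e-10  # broad annotation tier (inclusive)",
        "strict_evalue: 1.0e-15   # verified tier for pathway families (inclusive)",
        "alpha: 0.05              # incompleteness tolerance for absence calls",
        "omz_do_max: 30.0         # OMZ: dissolved oxygen <= this (umol/kg)",
        "omz_core_do_max: 10.0    # OMZ core threshold",
        "indval_permutations: 999",
        "seed: 7",
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns the summary dict.

    Writes per-stage TSVs, ``summary.json``, and ``run.log`` under
    ``config.output_dir``. A failing stage leaves a ``FAILED`` marker naming
    it and re-raises as :class:`StageError`.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    log.info("b1profiler %s, config hash %s, seed %d",
             __version__, summary["config_hash"], config.seed)

    current_stage = "setup"
    try:
        catalog = (GeneFamilyCatalog.from_tsv(config.catalog)
                   if config.catalog else default_catalog())
        meta = read_genome_meta(config.genome_meta) if config.genome_meta else None
        genotype_map: dict[str, str] = {}
        calls = None

        if config.hits and meta is not None:
            current_stage = "annotate"
            hits = parse_hit_table(config.hits, format=config.hits_format)
            kept = filter_hits(hits, catalog, config.general_evalue, config.strict_evalue)
            presence = build_presence_matrix(kept, catalog, [m.genome_id for m in meta])
            presence.to_csv(outdir / "presence_matrix.tsv", sep="\t")
            log.info("annotate: %d hits -> %d after filtering, %d genomes",
                     len(hits), len(kept), presence.shape[0])

            current_stage = "genotype"
            calls = classify_genomes(presence, meta, alpha=config.alpha)
            calls_to_frame(calls).to_csv(outdir / "genotype_calls.tsv", sep="\t",
                                         index=False)
            genotype_summary(calls, meta).to_csv(outdir / "genotype_summary.tsv",
                                                 sep="\t", index=False)
            summary["genotype_counts"] = (
                calls_to_frame(calls)["category"].value_counts().to_dict()
            )
            by_tax: dict[str, list[str]] = {}
            for c, m in zip(calls, meta):
                by_tax.setdefault(m.taxonomy, []).append(c.category)
            genotype_map = {
                tax: max(set(cats), key=cats.count) for tax, cats in by_tax.items()
            }

        if config.orf_counts and config.orf_meta:
            current_stage = "rpkm"
            counts = pd.read_csv(config.orf_counts, sep="\t", index_col=0)
            orf_meta = pd.read_csv(config.orf_meta, sep="\t", index_col=0)
            rpkm = compute_rpkm(counts, orf_meta)
            rpkm.to_csv(outdir / "orf_rpkm.tsv", sep="\t")
            profile = gene_depth_profile(rpkm, orf_meta, PROFILE_GENES, group_by="domain")
            profile.to_csv(outdir / "gene_profile_domain.tsv", sep="\t", index=False)
            ratios = domain_ratios(profile)
            ratios.to_csv(outdir / "gene_domain_ratios.tsv", sep="\t", index=False)
            summary["mean_domain_ratio"] = {
                sym: float(sub["archaea_bacteria_ratio"].replace([np.inf], np.nan).mean())
                for sym, sub in ratios.groupby("gene_symbol")
            }

        if config.tx_counts and config.tx_meta:
            current_stage = "transcripts"
            tx = pd.read_csv(config.tx_counts, sep="\t", index_col=0)
            tx_meta = pd.read_csv(config.tx_meta, sep="\t", index_col=0)
            tx_rpkm = compute_rpkm(tx, tx_meta)
            shares = transcript_shares(tx_rpkm, tx_meta, PROFILE_GENES,
                                       group_by="taxon_class")
            shares.to_csv(outdir / "transcript_shares.tsv", sep="\t", index=False)
            summary["mean_transcript_share"] = (
                shares.groupby("group")["share"].mean().round(6).to_dict()
            )

        if config.asv_counts and config.sample_meta:
            current_stage = "ecology"
            asv = pd.read_csv(config.asv_counts, sep="\t", index_col=0)
            smeta = pd.read_csv(config.sample_meta, sep="\t", index_col=0)
            taxonomy = None
            if config.asv_taxonomy:
                taxonomy = pd.read_csv(config.asv_taxonomy, sep="\t",
                                       index_col=0)["taxonomy"]
                asv = drop_chloroplasts(asv, taxonomy)
            rel = relative_abundance(asv)
            rel.to_csv(outdir / "relative_abundance.tsv", sep="\t")
            shannon = rel.apply(shannon_index, axis=0).rename("shannon")
            shannon.to_csv(outdir / "shannon.tsv", sep="\t")
            bc = bray_curtis_matrix(rel)
            bc.to_csv(outdir / "bray_curtis.tsv", sep="\t")
            (outdir / "dendrogram.nwk").write_text(average_linkage(bc).to_newick() + "\n")
            layers = smeta.loc[rel.columns, "layer"]
            if layers.nunique() >= 2 and layers.value_counts().min() >= 2:
                stat, p = grouped_rank_test(shannon.to_numpy(), layers.to_numpy(),
                                            test="kruskal_wallis")
                summary["shannon_kruskal"] = {"statistic": stat, "p_value": p}
            iv = indval(asv, layers, n_permutations=config.indval_permutations,
                        seed=config.seed)
            iv.to_csv(outdir / "indval.tsv", sep="\t", index=False)
            if genotype_map and taxonomy is not None:
                taxon_cat = {
                    t: genotype_map[tax] for t, tax in taxonomy.items()
                    if tax in genotype_map
                }
                share = prototroph_share(rel, taxon_cat)
                share.to_csv(outdir / "prototroph_share.tsv", sep="\t")
                summary["prototroph_share_by_layer"] = (
                    share.groupby(layers).mean().round(6).to_dict()
                )

        if config.trc and config.ctd:
            current_stage = "trc"
            trc_tbl = read_trc_table(config.trc)
            ctd = read_ctd_table(config.ctd)
            profile = replicate_stats(trc_tbl)
            profile = assign_oxygen_layers(profile, ctd)
            profile.to_csv(outdir / "trc_profile.tsv", sep="\t", index=False)
            folds, maxima = {}, {}
            for cmp_name in COMPOUNDS:
                if cmp_name not in set(profile["compound"]):
                    continue
                fc_mean = fold_change(profile, cmp_name, rule="mean")
                fc_max = fold_change(profile, cmp_name, rule="max")
                folds[cmp_name] = {"mean": fc_mean.value, "max": fc_max.value}
                maxima[cmp_name] = find_local_maxima(profile, cmp_name)
            summary["trc_fold_changes"] = folds
            summary["trc_local_maxima_depths"] = maxima

        current_stage = "report"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        log.info("pipeline complete")
        return summary
    except ConfigurationError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{current_stage}: {exc}\n")
        log.error("stage %s failed: %s", current_stage, exc)
        raise StageError(current_stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
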