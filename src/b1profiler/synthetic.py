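"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the study system: a cohort of genomes drawn from
named genotype archetypes (ammonia-oxidizing archaea, *Nitrospina*,
Thioglobaceae/SUP05, SAR11, SAR202, Rhodobacterales, salvaging
Flavobacteria), degraded to MAG-like incompleteness by Bernoulli gene
dropout; depth-stratified amplicon communities with a mesopelagic-OMZ
enrichment of chemoautotrophic prototrophs; overdispersed ORF/transcript
count tables with planted domain ratios and class shares; and replicated
dissolved-TRC depth profiles with a planted multiplicative OMZ peak.

Every generator is deterministic given (config, seed) and returns its truth
alongside the tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneFamilyCatalog, default_catalog
from .errors import ConfigurationError, ConsistencyError
from .genotype import GenomeMeta, annotate_chemoautotrophy, classify_b1_genotype
from .hits import GeneHit
from .trc import OMZ_DO_MAX, OMZ_CORE_DO_MAX
from .ecology import assign_depth_layer


# ---------------------------------------------------------------------------
# Genotype archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeArchetype:
    """A named genome blueprint with known B1 genotype."""

    name: str
    domain: str
    taxonomy: str
    taxon_class: str
    genes: Mapping[str, int]            # gene symbol -> copy count
    expected_category: str
    expected_chemoautotrophy: frozenset[str] = frozenset()


def _arch(name, domain, taxonomy, taxon_class, genes, category, chemo=()):
    return GenotypeArchetype(
        name=name, domain=domain, taxonomy=taxonomy, taxon_class=taxon_class,
        genes=dict(genes), expected_category=category,
        expected_chemoautotrophy=frozenset(chemo),
    )


#: Default archetype library: the study's named guilds with their gene content.
ARCHETYPES: dict[str, GenotypeArchetype] = {a.name: a for a in [
    _arch(
        "AOA_prototroph", "archaea",
        "archaea;Thermoproteota;Nitrososphaeria;Nitrosopumilales;Nitrosopumilaceae;Nitrosopumilus",
        "Nitrososphaeria",
        {"thiC": 1, "thi4": 1, "thiDN": 1, "thiL": 1, "amoA": 1},
        "PROTOTROPH", {"ammonia_oxidation"},
    ),
    _arch(
        "Nitrospina_prototroph", "bacteria",
        "bacteria;Nitrospinota;Nitrospinia;Nitrospinales;Nitrospinaceae;Nitrospina",
        "Nitrospinia",
        {"thiC": 1, "thiG": 1, "thiE": 1, "thiD": 1, "tenA": 1, "thiL": 1, "nxr": 1},
        "PROTOTROPH", {"nitrite_oxidation"},
    ),
    _arch(
        "SUP05_prototroph", "bacteria",
        "bacteria;Pseudomonadota;Gammaproteobacteria;Thiomicrospirales;Thioglobaceae;SUP05",
        "Gammaproteobacteria",
        {"thiC": 1, "thiG": 2, "thiE": 2, "thiL": 1,
         "aprA": 1, "aprB": 1, "dsrA": 1, "rbcL": 1},
        "PROTOTROPH", {"sulfur_oxidation", "cbb_fixation"},
    ),
    _arch(
        "SAR11_HMP_aux", "bacteria",
        "bacteria;Pseudomonadota;Alphaproteobacteria;Pelagibacterales;Pelagibacteraceae;Pelagibacter",
        "Alphaproteobacteria",
        {"thiG": 1, "thiE": 1, "thiD": 1, "thiM": 1, "thiB": 1, "thiP": 1, "thiQ": 1},
        "AUX_HMP",
    ),
    _arch(
        "SAR202_HMP_aux", "bacteria",
        "bacteria;Chloroflexota;Dehalococcoidia;UBA3495;UBA3495_fam;UBA3495_gen",
        "Dehalococcoidia",
        {"thiG": 1, "thiE": 1, "tenA": 1, "thiL": 1, "ykoC": 1, "ykoD": 1},
        "AUX_HMP",
    ),
    _arch(
        "Rhodobacterales_dual_aux", "bacteria",
        "bacteria;Pseudomonadota;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Roseobacter",
        "Alphaproteobacteria",
        {"thiE": 1, "thiL": 1, "thiB": 1, "thiP": 1, "thiQ": 1},
        "AUX_DUAL",
    ),
    _arch(
        "Flavobacteria_salvage", "bacteria",
        "bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Flavobacteriaceae;Flavobacterium",
        "Bacteroidia",
        {"thiL": 1, "omr1": 1},
        "SALVAGE_ONLY",
    ),
]}


def check_archetype_consistency(
    archetypes: Mapping[str, GenotypeArchetype] | None = None,
) -> None:
    """Verify each archetype's gene set classifies to its declared category
    at completeness 1 (build-time self-consistency)."""
    for a in (archetypes or ARCHETYPES).values():
        meta = GenomeMeta(
            genome_id="check", domain=a.domain, taxonomy=a.taxonomy,
            completeness=1.0, contamination=0.0,
        )
        call = classify_b1_genotype(a.genes, meta)
        if call.category != a.expected_category:
            raise ConsistencyError(
                f"archetype {a.name}: classifies as {call.category}, "
                f"declared {a.expected_category}"
            )
        flags = annotate_chemoautotrophy(a.genes)
        if flags != a.expected_chemoautotrophy:
            raise ConsistencyError(
                f"archetype {a.name}: chemoautotrophy flags {set(flags)} != "
                f"declared {set(a.expected_chemoautotrophy)}"
            )


# ---------------------------------------------------------------------------
# Genome-set generation and MAG degradation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSet:
    hits: list[GeneHit]
    meta: list[GenomeMeta]
    truth: pd.DataFrame  # genome_id, archetype, true_category, completeness, contamination


def _symbol_to_family(catalog: GeneFamilyCatalog) -> dict[str, str]:
    return {sym: catalog.families_for(sym)[0] for sym in catalog.symbols()}


def generate_genome_set(
    archetype_mix: Mapping[str, int],
    seed: int,
    decoy_rate: float = 0.0,
    catalog: GeneFamilyCatalog | None = None,
) -> GenomeSet:
    """Emit synthetic per-genome hit tables for a mix of archetypes.

    True genes get full-sequence e-values log-uniform in [1e-40, 1e-16]
    (inside the strict tier); ``decoy_rate`` adds, per true gene, that many
    expected spurious hits with e-values in [1e-9, 1e-3] — above both
    filtering tiers, so a correct filter removes them all. Genomes are
    complete (completeness 1.0, contamination 0.0).
    """
    catalog = catalog or default_catalog()
    check_archetype_consistency()
    unknown = sorted(set(archetype_mix) - set(ARCHETYPES))
    if unknown:
        raise ConfigurationError(f"unknown archetypes: {unknown}")
    if any(c < 1 for c in archetype_mix.values()):
        raise ConfigurationError("archetype counts must be >= 1")

    rng = np.random.default_rng(seed)
    fam_of = _symbol_to_family(catalog)
    all_families = sorted(f for f in fam_of.values())
    hits: list[GeneHit] = []
    meta: list[GenomeMeta] = []
    truth_rows = []
    g = 0
    for name in sorted(archetype_mix):
        arch = ARCHETYPES[name]
        for _ in range(archetype_mix[name]):
            g += 1
            genome_id = f"G{g:05d}"
            p = 0
            n_true = 0
            for sym in sorted(arch.genes):
                for _copy in range(arch.genes[sym]):
                    p += 1
                    n_true += 1
                    evalue = 10.0 ** rng.uniform(-40, -16)
                    score = float(rng.uniform(80, 500))
                    start = int(rng.integers(1, 50))
                    length = int(rng.integers(150, 450))
                    hits.append(GeneHit(
                        protein_id=f"{genome_id}_{p:05d}",
                        genome_id=genome_id,
                        family_id=fam_of[sym],
                        full_seq_evalue=evalue,
                        bit_score=score,
                        alignment_coords=(start, start + length),
                    ))
            n_decoys = int(rng.poisson(decoy_rate * max(n_true, 1)))
            for _ in range(n_decoys):
                p += 1
                evalue = 10.0 ** rng.uniform(-9, -3)
                hits.append(GeneHit(
                    protein_id=f"{genome_id}_{p:05d}",
                    genome_id=genome_id,
                    family_id=str(rng.choice(all_families)),
                    full_seq_evalue=float(evalue),
                    bit_score=float(rng.uniform(10, 40)),
                    alignment_coords=(1, 100),
                ))
            meta.append(GenomeMeta(
                genome_id=genome_id, domain=arch.domain, taxonomy=arch.taxonomy,
                completeness=1.0, contamination=0.0,
            ))
            truth_rows.append({
                "genome_id": genome_id, "archetype": name,
                "true_category": arch.expected_category,
                "completeness": 1.0, "contamination": 0.0, "seed": seed,
            })
    return GenomeSet(hits=hits, meta=meta, truth=pd.DataFrame(truth_rows))


def degrade_to_mag(
    genome_set: GenomeSet,
    completeness: float,
    contamination: float = 0.0,
    seed: int = 0,
) -> GenomeSet:
    """Degrade complete genomes to MAG-like bins.

    Each true gene (symbol) of a genome survives independently with
    probability ``completeness`` (all its copies together, mimicking loss of
    the encoding locus). Contamination adds genes sampled from another
    genome in the set at a rate calibrated so the added-gene fraction of the
    bin is ~``contamination``. Metadata records the applied values.
    """
    if not 0.0 < completeness <= 1.0:
        raise ConfigurationError(f"completeness {completeness} outside (0, 1]")
    if not 0.0 <= contamination < 1.0:
        raise ConfigurationError(f"contamination {contamination} outside [0, 1)")
    rng = np.random.default_rng(seed)

    by_genome: dict[str, list[GeneHit]] = {}
    for h in genome_set.hits:
        by_genome.setdefault(h.genome_id, []).append(h)
    genome_ids = [m.genome_id for m in genome_set.meta]

    fam_by_protein = {}
    new_hits: list[GeneHit] = []
    for gid in genome_ids:
        own = by_genome.get(gid, [])
        families = sorted({h.family_id for h in own})
        kept_fams = {f for f in families if rng.random() < completeness}
        kept = [h for h in own if h.family_id in kept_fams]
        p = max((int(h.protein_id.rsplit("_", 1)[1]) for h in own), default=0)
        n_kept = len(kept)
        if contamination > 0 and len(genome_ids) > 1 and n_kept > 0:
            n_add = int(rng.binomial(n_kept, contamination / (1.0 - contamination)))
            donors = [x for x in genome_ids if x != gid]
            for _ in range(n_add):
                donor = str(rng.choice(donors))
                pool = by_genome.get(donor, [])
                if not pool:
                    continue
                src = pool[int(rng.integers(len(pool)))]
                p += 1
                kept.append(GeneHit(
                    protein_id=f"{gid}_{p:05d}", genome_id=gid,
                    family_id=src.family_id,
                    full_seq_evalue=src.full_seq_evalue,
                    bit_score=src.bit_score,
                    alignment_coords=src.alignment_coords,
                ))
        new_hits.extend(kept)

    new_meta = [
        GenomeMeta(
            genome_id=m.genome_id, domain=m.domain, taxonomy=m.taxonomy,
            completeness=completeness, contamination=contamination,
        )
        for m in genome_set.meta
    ]
    truth = genome_set.truth.copy()
    truth["completeness"] = completeness
    truth["contamination"] = contamination
    truth["seed"] = seed
    return GenomeSet(hits=new_hits, meta=new_meta, truth=truth)


# ---------------------------------------------------------------------------
# Depth-stratified community + count tables
# ---------------------------------------------------------------------------

#: Default vertical design: (depth m, dissolved oxygen µmol kg⁻¹). The DO
#: profile places the OMZ (<=30) at 500–1250 m with a core (<=10) at 700 m.
DEFAULT_DEPTH_DESIGN: tuple[tuple[float, float], ...] = (
    (2, 250.0), (60, 180.0), (100, 120.0), (200, 60.0), (300, 45.0),
    (500, 25.0), (700, 9.4), (900, 20.0), (1250, 30.0), (2000, 60.0),
    (2500, 95.0),
)

_BACKGROUND_TAXONOMY = {
    "Marinimicrobia_SAR324": "bacteria;Marinimicrobia;Marinimicrobia_cl;Marinimicrobia_ord",
    "Cyanobacteria": "bacteria;Cyanobacteria;Cyanobacteriia;Synechococcales",
    "Gammaproteobacteria_other": "bacteria;Pseudomonadota;Gammaproteobacteria;SAR86",
    "MGII_Euryarchaeota": "archaea;Thermoplasmatota;Poseidoniia;Poseidoniales",
    "Other": "bacteria;unclassified",
}

#: Per-regime community composition (fractions sum to 1). The mesopelagic-OMZ
#: regime plants 24% ammonia-oxidizing archaea and a 31% total prototroph share.
DEFAULT_COMPOSITION_RULES: dict[str, dict[str, float]] = {
    "epipelagic": {
        "SAR11_HMP_aux": 0.28, "Gammaproteobacteria_other": 0.14,
        "Flavobacteria_salvage": 0.11, "Cyanobacteria": 0.10,
        "AOA_prototroph": 0.05, "MGII_Euryarchaeota": 0.05,
        "Nitrospina_prototroph": 0.01, "SUP05_prototroph": 0.01,
        "SAR202_HMP_aux": 0.02, "Rhodobacterales_dual_aux": 0.05,
        "Marinimicrobia_SAR324": 0.08, "Other": 0.10,
    },
    "omz_mesopelagic": {
        "AOA_prototroph": 0.24, "SUP05_prototroph": 0.04,
        "Nitrospina_prototroph": 0.03, "Marinimicrobia_SAR324": 0.17,
        "MGII_Euryarchaeota": 0.09, "SAR202_HMP_aux": 0.10,
        "SAR11_HMP_aux": 0.08, "Flavobacteria_salvage": 0.04,
        "Rhodobacterales_dual_aux": 0.02, "Gammaproteobacteria_other": 0.06,
        "Other": 0.13,
    },
    "deep": {
        "AOA_prototroph": 0.14, "SAR202_HMP_aux": 0.14,
        "Marinimicrobia_SAR324": 0.14, "MGII_Euryarchaeota": 0.05,
        "SAR11_HMP_aux": 0.06, "Nitrospina_prototroph": 0.02,
        "SUP05_prototroph": 0.02, "Flavobacteria_salvage": 0.05,
        "Rhodobacterales_dual_aux": 0.03, "Gammaproteobacteria_other": 0.10,
        "Other": 0.25,
    },
}

#: Planted metatranscriptome class shares of thiamine-related transcripts.
DEFAULT_TRANSCRIPT_SHARES: dict[str, float] = {
    "Gammaproteobacteria": 0.40, "Nitrososphaeria": 0.22,
    "Verrucomicrobiae": 0.08, "Dehalococcoidia": 0.06, "Bacteroidia": 0.05,
    "Alphaproteobacteria": 0.10, "Nitrospinia": 0.05, "Other": 0.04,
}

_TRANSCRIPT_CLASS_DOMAIN = {
    "Gammaproteobacteria": "bacteria", "Nitrososphaeria": "archaea",
    "Verrucomicrobiae": "bacteria", "Dehalococcoidia": "bacteria",
    "Bacteroidia": "bacteria", "Alphaproteobacteria": "bacteria",
    "Nitrospinia": "bacteria", "Other": "bacteria",
}

#: Planted metagenomic RPKM of key synthesis genes per (domain, gene, regime).
#: Archaeal thi4 is 3x bacterial in the meso- and bathypelagic; archaeal thiC
#: is 4x bacterial in the bathypelagic.
_GENE_RPKM_PLAN: dict[tuple[str, str], dict[str, float]] = {
    ("archaea", "thi4"): {"epipelagic": 5.0, "mesopelagic": 30.0, "bathypelagic": 30.0},
    ("bacteria", "thi4"): {"epipelagic": 10.0, "mesopelagic": 10.0, "bathypelagic": 10.0},
    ("archaea", "thiC"): {"epipelagic": 5.0, "mesopelagic": 20.0, "bathypelagic": 40.0},
    ("bacteria", "thiC"): {"epipelagic": 15.0, "mesopelagic": 15.0, "bathypelagic": 10.0},
    ("bacteria", "thiG"): {"epipelagic": 10.0, "mesopelagic": 15.0, "bathypelagic": 20.0},
    ("bacteria", "thiE"): {"epipelagic": 12.0, "mesopelagic": 18.0, "bathypelagic": 20.0},
    ("archaea", "thiDN"): {"epipelagic": 4.0, "mesopelagic": 12.0, "bathypelagic": 15.0},
}


@dataclass
class CommunitySim:
    asv_counts: pd.DataFrame        # taxa x samples
    taxonomy: pd.Series             # taxon -> semicolon taxonomy
    sample_meta: pd.DataFrame       # sample_id, station, campaign, depth_m, layer, dissolved_oxygen
    orf_counts: pd.DataFrame        # orf x samples (metagenomic)
    orf_meta: pd.DataFrame          # orf_id -> length_bp, genome_id, gene_symbol, taxon_class, domain
    tx_counts: pd.DataFrame         # orf x samples (metatranscriptomic)
    tx_meta: pd.DataFrame
    truth: dict


def _regime(depth: float, do: float) -> str:
    layer = assign_depth_layer(depth)
    if layer == "epipelagic":
        return "epipelagic"
    if layer == "mesopelagic" and do <= OMZ_DO_MAX:
        return "omz_mesopelagic"
    return "deep"


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + dispersion * mu^2 (gamma–Poisson
    mixture); dispersion -> 0 recovers Poisson."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_community_profile(
    depth_design: Sequence[tuple[float, float]] | None = None,
    composition_rules: Mapping[str, Mapping[str, float]] | None = None,
    n_reads: int = 100_000,
    n_mapped_reads: int = 10_000_000,
    orfs_per_feature: int = 10,
    dispersion: float = 0.1,
    seed: int = 0,
    station: str = "67-70",
    campaign: str = "autumn2018",
) -> CommunitySim:
    """Simulate amplicon, ORF, and transcript count tables over a depth profile.

    ASV counts are multinomial draws of ``n_reads`` amplicons from the regime
    composition at each depth; ORF and transcript counts are
    negative-binomial around RPKM-consistent expectations for a shotgun
    library of ``n_mapped_reads`` mapped reads per sample (shotgun libraries
    run orders of magnitude deeper than amplicon ones). Truth records every
    planted share.
    """
    design = list(depth_design or DEFAULT_DEPTH_DESIGN)
    rules = {k: dict(v) for k, v in (composition_rules or DEFAULT_COMPOSITION_RULES).items()}
    if n_reads < 1_000:
        raise ConfigurationError("n_reads must be >= 1000 per sample")
    for regime, comp in rules.items():
        if abs(sum(comp.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"composition for {regime!r} sums to {sum(comp.values())}, not 1"
            )
    rng = np.random.default_rng(seed)

    taxa = sorted({t for comp in rules.values() for t in comp})
    taxonomy = pd.Series({
        t: (ARCHETYPES[t].taxonomy if t in ARCHETYPES else _BACKGROUND_TAXONOMY[t])
        for t in taxa
    })
    genotype_map = {t: ARCHETYPES[t].expected_category for t in taxa if t in ARCHETYPES}

    samples, meta_rows, comp_truth = [], [], {}
    asv_cols = {}
    for depth, do in design:
        sid = f"{station}_{campaign}_{int(depth)}m"
        samples.append(sid)
        regime = _regime(depth, do)
        comp = rules[regime]
        p = np.array([comp.get(t, 0.0) for t in taxa])
        asv_cols[sid] = rng.multinomial(n_reads, p)
        meta_rows.append({
            "sample_id": sid, "station": station, "campaign": campaign,
            "depth_m": depth, "layer": assign_depth_layer(depth),
            "dissolved_oxygen": do, "regime": regime,
        })
        comp_truth[sid] = {t: comp.get(t, 0.0) for t in taxa}
    asv_counts = pd.DataFrame(asv_cols, index=taxa)
    asv_counts.index.name = "taxon"
    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # --- metagenomic ORF counts with planted per-regime RPKM ---------------
    # Each (domain, gene) pool is spread over several ORFs, as many genomes
    # carry these genes; the planted RPKM is the pool total.
    orf_rows, mu_rows = [], []
    for (domain, gene), per_layer in sorted(_GENE_RPKM_PLAN.items()):
        for k in range(orfs_per_feature):
            orf_id = f"orf_{domain}_{gene}_{k:02d}"
            length = int(rng.integers(900, 1500))
            orf_rows.append({
                "orf_id": orf_id, "length_bp": length,
                "genome_id": f"{domain}_pool_{k:02d}", "gene_symbol": gene,
                "taxon_class": ("Nitrososphaeria" if domain == "archaea"
                                else "mixed_bacteria"),
                "domain": domain,
            })
            mu_rows.append([
                per_layer[assign_depth_layer(depth)] / orfs_per_feature
                * (length / 1000.0) * (n_mapped_reads / 1e6)
                for depth, _do in design
            ])
    orf_meta = pd.DataFrame(orf_rows).set_index("orf_id")
    mu = np.array(mu_rows)
    orf_counts = pd.DataFrame(
        _nb_draw(rng, mu, dispersion), index=orf_meta.index, columns=samples
    )

    # --- metatranscriptomic counts with planted class shares ---------------
    tx_rows, tx_mu = [], []
    shares = DEFAULT_TRANSCRIPT_SHARES
    for cls in sorted(shares):
        for k in range(orfs_per_feature):
            orf_id = f"tx_{cls}_thi_{k:02d}"
            length = int(rng.integers(900, 1500))
            tx_rows.append({
                "orf_id": orf_id, "length_bp": length,
                "genome_id": f"{cls}_bin_{k:02d}", "gene_symbol": "thiC",
                "taxon_class": cls, "domain": _TRANSCRIPT_CLASS_DOMAIN[cls],
            })
            # expected count proportional to share x length so RPKM shares
            # match; planted class RPKM pool = 1000 x share
            tx_mu.append([
                shares[cls] * 1000.0 / orfs_per_feature
                * (length / 1000.0) * (n_mapped_reads / 1e6)
                for _ in design
            ])
    tx_meta = pd.DataFrame(tx_rows).set_index("orf_id")
    tx_counts = pd.DataFrame(
        _nb_draw(rng, np.array(tx_mu), dispersion), index=tx_meta.index, columns=samples
    )

    proto_taxa = [t for t, c in genotype_map.items() if c == "PROTOTROPH"]
    truth = {
        "composition": comp_truth,
        "genotype_map": genotype_map,
        "prototroph_share": {
            s: sum(comp_truth[s][t] for t in proto_taxa) for s in samples
        },
        "aoa_share": {s: comp_truth[s].get("AOA_prototroph", 0.0) for s in samples},
        "transcript_class_shares": dict(shares),
        "thi4_domain_ratio_mesopelagic": (
            _GENE_RPKM_PLAN[("archaea", "thi4")]["mesopelagic"]
            / _GENE_RPKM_PLAN[("bacteria", "thi4")]["mesopelagic"]
        ),
        "thiC_domain_ratio_bathypelagic": (
            _GENE_RPKM_PLAN[("archaea", "thiC")]["bathypelagic"]
            / _GENE_RPKM_PLAN[("bacteria", "thiC")]["bathypelagic"]
        ),
        "n_reads": n_reads, "n_mapped_reads": n_mapped_reads,
        "dispersion": dispersion, "seed": seed,
    }
    return CommunitySim(
        asv_counts=asv_counts, taxonomy=taxonomy, sample_meta=sample_meta,
        orf_counts=orf_counts, orf_meta=orf_meta,
        tx_counts=tx_counts, tx_meta=tx_meta, truth=truth,
    )


# ---------------------------------------------------------------------------
# TRC dataset
# ---------------------------------------------------------------------------

#: Near-surface baseline concentrations (pM) per compound.
DEFAULT_TRC_BASELINE_PM = {"B1": 30.0, "AmMP": 6.0, "HMP": 1.2, "HET": 4.0, "cHET": 10.0}

#: Default OMZ fold increases per compound (the planted B1 fold is 3.5; all
#: defaults sit in the 1.1–4.5 band typical of OMZ enrichment).
DEFAULT_TRC_FOLDS = {"B1": 3.5, "AmMP": 2.9, "HMP": 2.4, "HET": 4.5, "cHET": 1.9}

_PEAK_CONTRAST = 0.25  # peak/shoulder contrast within the OMZ window


@dataclass
class TrcSim:
    measurements: pd.DataFrame  # long format, one row per replicate
    ctd: pd.DataFrame
    truth: dict


def simulate_trc_dataset(
    depth_design: Sequence[tuple[float, float]] | None = None,
    peak_spec: tuple[str, float, float] = ("B1", 700.0, 3.5),
    replicate_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    station: str = "67-70",
    campaign: str = "autumn2018",
) -> TrcSim:
    """Simulate a replicated dissolved-TRC depth profile with a planted OMZ peak.

    Each compound has a flat near-surface baseline; depths inside the
    mesopelagic OMZ are raised so their mean is exactly ``fold`` x baseline,
    with the peak depth strictly highest. Replicates are log-normal with the
    stated CV around the planted means (CV 0 reproduces them exactly).

    ``peak_spec`` is (compound, peak depth m, fold); other compounds use
    their default folds at the same peak depth.
    """
    compound, peak_depth, fold = peak_spec
    if compound not in DEFAULT_TRC_BASELINE_PM:
        raise ConfigurationError(f"unknown compound {compound!r}")
    if fold <= 0:
        raise ConfigurationError("fold must be positive")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if replicate_cv < 0:
        raise ConfigurationError("replicate_cv must be >= 0")
    design = list(depth_design or DEFAULT_DEPTH_DESIGN)
    rng = np.random.default_rng(seed)

    depths = [d for d, _ in design]
    do = {d: o for d, o in design}
    omz_meso = [d for d in depths
                if do[d] <= OMZ_DO_MAX and assign_depth_layer(d) == "mesopelagic"]
    if peak_depth not in omz_meso:
        raise ConfigurationError(
            f"peak depth {peak_depth} is not an OMZ mesopelagic depth of the design"
        )
    if do[peak_depth] > OMZ_CORE_DO_MAX:
        raise ConfigurationError(
            f"peak depth {peak_depth} has DO {do[peak_depth]} > core threshold"
        )

    folds = dict(DEFAULT_TRC_FOLDS)
    folds[compound] = fold
    n_omz = len(omz_meso)
    planted: dict[tuple[str, float], float] = {}
    rows = []
    for cmp_name in sorted(DEFAULT_TRC_BASELINE_PM):
        base = DEFAULT_TRC_BASELINE_PM[cmp_name]
        f = folds[cmp_name]
        for d in depths:
            if d in omz_meso:
                if d == peak_depth:
                    value = f * base * (1.0 + _PEAK_CONTRAST * (n_omz - 1))
                else:
                    value = f * base * (1.0 - _PEAK_CONTRAST)
            else:
                value = base
            planted[(cmp_name, d)] = value
            if replicate_cv > 0:
                sigma2 = np.log1p(replicate_cv ** 2)
                mu_log = np.log(value) - sigma2 / 2.0
                reps = rng.lognormal(mu_log, np.sqrt(sigma2), size=n_replicates)
            else:
                reps = np.full(n_replicates, value)
            for r, conc in enumerate(reps, start=1):
                rows.append({
                    "station": station, "campaign": campaign, "depth_m": d,
                    "compound": cmp_name, "replicate_id": r,
                    "concentration": float(conc), "units": "pM",
                })
    measurements = pd.DataFrame(rows)

    ctd = pd.DataFrame([
        {
            "station": station, "campaign": campaign, "depth_m": d,
            "dissolved_oxygen": do[d],
            "nitrite": 0.3 if do[d] <= OMZ_DO_MAX else 0.05,
            "nitrate": 5.0 + 0.012 * d,
            "temperature": max(1.5, 16.0 - 0.009 * d),
        }
        for d in depths
    ])

    truth = {
        "planted_means_pm": {f"{c}@{d}": v for (c, d), v in planted.items()},
        "folds": folds, "peak_depth_m": peak_depth, "peak_compound": compound,
        "omz_mesopelagic_depths": omz_meso,
        "replicate_cv": replicate_cv, "n_replicates": n_replicates, "seed": seed,
    }
    return TrcSim(measurements=measurements, ctd=ctd, truth=truth)


# ---------------------------------------------------------------------------
# File writers (the exact dialects the ingest modules read)
# ---------------------------------------------------------------------------

def write_domtbl(hits: Sequence[GeneHit], path: str | Path) -> None:
    """Write hits as HMMER3 ``--domtblout`` rows (hmmsearch orientation:
    target = protein, query = HMM family)."""
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  acc\n")
        fh.write("#" + "-" * 120 + "\n")
        for h in hits:
            start, end = h.alignment_coords
            tlen = end + 10
            fh.write(
                f"{h.protein_id} - {tlen} {h.family_id}_model {h.family_id} {end - start + 1} "
                f"{h.full_seq_evalue:.2g} {h.bit_score:.1f} 0.0 1 1 "
                f"{h.full_seq_evalue:.2g} {h.full_seq_evalue:.2g} {h.bit_score:.1f} 0.0 "
                f"1 {end - start + 1} {start} {end} {start} {end} 0.95\n"
            )


def write_genome_inputs(genome_set: GenomeSet, outdir: str | Path) -> dict[str, Path]:
    """Write a genome set as domtbl + metadata TSV + truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hits": outdir / "hits.domtbl",
        "genome_meta": outdir / "genome_meta.tsv",
        "truth": outdir / "genome_truth.tsv",
    }
    write_domtbl(genome_set.hits, paths["hits"])
    pd.DataFrame([
        {
            "genome_id": m.genome_id, "domain": m.domain, "taxonomy": m.taxonomy,
            "completeness": m.completeness, "contamination": m.contamination,
        }
        for m in genome_set.meta
    ]).to_csv(paths["genome_meta"], sep="\t", index=False)
    genome_set.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_community_inputs(sim: CommunitySim, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "asv_counts": outdir / "asv_counts.tsv",
        "asv_taxonomy": outdir / "asv_taxonomy.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "orf_counts": outdir / "orf_counts.tsv",
        "orf_meta": outdir / "orf_meta.tsv",
        "tx_counts": outdir / "tx_counts.tsv",
        "tx_meta": outdir / "tx_meta.tsv",
    }
    sim.asv_counts.to_csv(paths["asv_counts"], sep="\t")
    sim.taxonomy.rename("taxonomy").rename_axis("taxon").to_csv(
        paths["asv_taxonomy"], sep="\t")
    sim.sample_meta.to_csv(paths["sample_meta"], sep="\t")
    sim.orf_counts.rename_axis("orf_id").to_csv(paths["orf_counts"], sep="\t")
    sim.orf_meta.to_csv(paths["orf_meta"], sep="\t")
    sim.tx_counts.rename_axis("orf_id").to_csv(paths["tx_counts"], sep="\t")
    sim.tx_meta.to_csv(paths["tx_meta"], sep="\t")
    return paths


def write_trc_inputs(sim: TrcSim, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"trc": outdir / "trc_measurements.tsv", "ctd": outdir / "ctd.tsv"}
    sim.measurements.to_csv(paths["trc"], sep="\t", index=False)
    sim.ctd.to_csv(paths["ctd"], sep="\t", index=False)
    return paths
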