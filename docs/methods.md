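# Methods

This note documents the models, rules, and numerical choices behind
`b1profiler`, and what the synthetic testbed does and does not establish.

## Annotation ingestion and filtering

Hit tables are HMMER3 per-domain tabular output (`--domtblout`, hmmsearch
orientation: target = protein, query = HMM) or a six-column TSV. Genome ids
are derived from the protein-id prefix up to the last occurrence of a
configurable delimiter (default `_`), since domtbl files carry protein ids
only.

Filtering is two-tiered and **inclusive** (`≤`): families flagged
`strict_tier` in the gene-family catalog (all B1 pathway, salvage, and
transporter families, plus the nitrification and carbon-fixation marker KOs)
require full-sequence e-value ≤ 1e-15; all other catalogued families require
≤ 1e-10. Sulfur-oxidation markers (aprA/aprB/dsrA) sit in the general tier,
as they are neither nitrification nor carbon-fixation functions. Full-sequence
rather than per-domain e-values are used by default (configurable in the
parser): the tiers describe whole-protein homology confidence.

When one protein hits several families, the best surviving hit wins: highest
bit score, ties broken by lower e-value, then lexicographically smallest
family id. Bit score is the primary key because it is stable across database
sizes. The presence matrix counts distinct proteins per (genome, symbol), so
multi-copy genes (common for *thiG* and *thiE*) stay visible as counts.

## Genotype model

The three de novo branches are: pyrimidine (*thiC*), thiazole (*thiG*, or the
*thi4*-type synthase accepted in both domains), and condensation (*thiE*; the
fused *thiDN* counts only for archaea by default, configurable). The category
lattice (see README) is total: every possible presence row maps to exactly
one of six categories, which is exhaustively enumerated in the tests.

**Incompleteness model.** A MAG with completeness *c* is modelled as
retaining each encoded gene independently with probability *c* (uniform
recovery). The probability that the *k* genes a negative call rests on are
all absent despite being encoded is then `p_chance = (1 − c)^k`. *k* counts
missing *branches*, one representative gene per branch (e.g. a dual auxotroph
call rests on {thiC, thiG}, k = 2): the branches are alternative routes, so
one unobserved gene per branch suffices to explain the pattern.

A definite absence-based call requires `p_chance < α` (default 0.05);
otherwise the call is INDETERMINATE (abstention), with the tentative
gene-pattern category still recorded. The threshold comparison is strict on
the definite side deliberately: an absence pattern exactly as probable as the
tolerance is not treated as evidence. A consequence worth noting when reading
recovery numbers: at completeness 0.95 a single dropped gene produces
`p_chance = 0.05 = α`, so such genomes abstain rather than being called
wrongly, and the rate of definite wrong calls among true prototrophs stays
below α. Recovery at degraded completeness is therefore reported as the
fraction of genomes either correctly classified or abstained; a genome that
physically lost its *thiC* locus in binning cannot be recovered by any
classifier, only abstained on.

Contamination does not enter the probability model (no principled
false-positive rate is available); it only sets the quality tier: high
(completeness ≥ 50%, contamination < 5%), medium (≥ 50%, ≤ 10%), else
below_threshold. Calls are still computed for below-threshold bins, flagged.

## Abundance profiles

RPKM uses externally supplied total mapped reads when given, else column sums
of the count table; per-sample (not per-bin) library sizes are the default,
with the caller free to pass per-bin totals. Domain ratios (archaea:bacteria
per gene symbol per sample) report NaN for 0/0 and +inf when only archaea are
non-zero. Transcript shares are within-sample proportions of summed
thiamine-gene RPKM per taxon class; samples with zero thiamine RPKM get
missing shares, never zeros.

## Community ecology

Shannon diversity uses the natural log (configurable base). Bray–Curtis is
delegated to `scipy.spatial.distance.braycurtis` and validated against the
`1 − 2Σmin/(Σx+Σy)` closed form in tests. Average-linkage (UPGMA) clustering
is implemented directly — the required deterministic tie-break
(lexicographically smallest combined member labels) is not available in
library implementations — and is cross-checked against
`scipy.cluster.hierarchy.linkage(..., "average")` on random tie-free
matrices. The dendrogram exports ultrametric Newick with node heights at half
the merge dissimilarity. Rank tests are `scipy.stats.kruskal` and
`scipy.stats.mannwhitneyu` (two-sided asymptotic, mid-rank tie correction);
the degenerate all-identical-values input returns (0, 1).

IndVal is the original single-group Dufrêne–Legendre form:
`A_ij = μ_ij / Σ_j μ_ij` (specificity from group mean abundances),
`B_ij` = occurrence fraction, statistic `max_j A·B`, with
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)` under seeded relabelling with fixed
group sizes (n_perm ≥ 99 enforced, so p has usable resolution). Same seed ⇒
bit-identical output.

Depth layers: epipelagic ≤ 200 m, mesopelagic (200, 1000] m, bathypelagic
below; boundary depths belong to the shallower layer. Observed richness, when
needed, is the raw per-sample ASV count. ASVs whose taxonomy contains
"chloroplast" (case-insensitive) can be removed by a pre-filter.

## TRC profiles

Replicate summaries are arithmetic mean and n−1 standard deviation (sd = 0
for singletons). Each profile row is matched to the nearest CTD depth for the
same station/campaign within ±5 m (configurable); OMZ flags are DO ≤ 30 and
core ≤ 10 µmol kg⁻¹, inclusive. Concentrations are normalized to pM on
ingest (fM and nM accepted via a units column).

The fold change has no single canonical definition, so the rule is explicit
and recorded in the result: reference = mean of per-depth means over the
upper 100 m; target = OMZ-flagged mesopelagic depths summarized by mean
(default) or max. Local maxima require strict inequality over both sampled
neighbours (endpoints over their single neighbour) and are returned largest
first; at least three depths are required.

## Synthetic testbed

The generator encodes the study conditions as defaults and records all truth:

- **Archetypes** (gene sets): AOA prototroph (*thiC thi4 thiDN thiL amoA*),
  *Nitrospina* prototroph (*thiCGE* + *tenA–thiD* salvage + *nxr*),
  Thioglobaceae/SUP05 prototroph (*thiC*, 2×*thiG*, 2×*thiE*, *apr/dsr/rbcL*),
  SAR11 pyrimidine auxotroph (*thiGE* + *thiBPQ* transport), SAR202
  pyrimidine auxotroph, Rhodobacterales dual auxotroph (*thiE* only), and
  salvaging Flavobacteria (*thiL* + *omr1*). Each archetype is
  self-consistency-checked against the classifier at completeness 1.
- **Degradation**: per-gene Bernoulli dropout at the target completeness
  (uniform and independent — the simplest model consistent with the
  completeness metric); contamination adds genes from a random donor genome
  at a rate calibrated so the added fraction ≈ the target contamination.
- **Community**: eleven depths from 2 to 2500 m with a DO profile placing the
  OMZ at 500–1250 m and its core (DO 9.4) at 700 m. Planted compositions:
  epipelagic dominated by SAR11 (28%), other Gammaproteobacteria (14%),
  Flavobacteria (11%), Cyanobacteria (10%); the mesopelagic OMZ enriched in
  AOA (24%) with total chemoautotroph prototroph share 31%. ASV counts are
  multinomial at 10⁵ amplicons per sample.
- **ORF/transcript counts**: negative-binomial (gamma–Poisson,
  var = μ + d·μ², default d = 0.1, d → 0 giving Poisson) around
  RPKM-consistent expectations for 10⁷ mapped reads per sample — shotgun
  libraries run far deeper than amplicon ones. Planted signals: archaeal
  *thi4* RPKM 3× bacterial in meso/bathypelagic, archaeal *thiC* 4× in the
  bathypelagic, and transcript class shares of 40% Gammaproteobacteria / 22%
  Nitrososphaeria / 10% Alphaproteobacteria / 8% Verrucomicrobiae / 6%
  Dehalococcoidia / 5% each Bacteroidia and Nitrospinia / 4% other. Each
  (domain, gene) or class pool is spread over 10 ORFs, as many genomes carry
  these genes.
- **TRC**: flat per-compound baselines (B1 30 pM, AmMP 6, HMP 1.2, HET 4,
  cHET 10) with a multiplicative OMZ enhancement whose within-OMZ mean is
  exactly fold × baseline and whose peak depth (700 m) is strictly highest;
  default folds B1 3.5, HET 4.5, AmMP 2.9, HMP 2.4, cHET 1.9. Replicates
  (n = 3) are log-normal with 10% CV around planted means — concentrations
  are positive and LC-MS error is multiplicative; this is a testbed
  assumption, not an empirical claim.

All generators are bit-reproducible given (config, seed).

**What passing tests show — and don't.** The testbed establishes internal
correctness: filtering, classification, normalization, the ecology statistics
and the TRC summaries recover planted truth at the stated noise levels. It
does not emulate annotation transfer error, chimeric bins, compositional
coupling between taxa across depths, primer bias, or LC-MS matrix effects, so
recovery rates here are upper bounds on real-data performance.

## Problem sizes

Default test and acceptance runs use 500 genomes per archetype (3500 total)
for recovery/calibration, 100 random 5×5 matrices for the clustering oracle,
200 null taxa × 999 permutations for IndVal calibration, and 10⁵-amplicon /
10⁷-read samples over 11 depths — sizes at which multinomial and binomial
sampling error is far smaller than the planted effects being recovered.

## Known limitations

- The uniform-dropout completeness model ignores contig-level (block) gene
  loss; clustered pathway genes are lost together in real bins, which makes
  `p_chance` optimistic for syntenic operons.
- Contamination is not modelled as false gene presence.
- AUX_HET is included for lattice completeness; thiazole-only auxotrophy is
  rarely resolvable in practice and the class is flagged as artifact-defined.
- The per-taxon genotype map used for prototroph amplicon shares links ASVs
  to genomes by exact taxonomy-string match; real studies need curated
  cross-referencing between 16S taxa and MAGs.
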