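# Methods

`usprok` implements the bespoke computations used to characterize
ultra-small prokaryote communities — Patescibacteria (CPR), Dependentiae
and DPANN archaea — across groundwater metagenome and metatranscriptome
samples, together with a synthetic-data generator that plants the
statistical structure the analysis assumes, so every stage can be scored
against known truth.

## Genome quality and size (`genome_metrics`)

Ultra-small lineages lack many universal marker genes, so bin quality is
assessed against lineage-specific single-copy gene (SCG) sets: 51
bacterial markers for Dependentiae, 43 for Patescibacteria, 38 archaeal
markers for DPANN. Completeness is the fraction of the set present at
least once. The SCG convention only defines *presence*; we define
contamination as the fraction of markers present in two or more copies
(duplication, paralleling the CheckM convention), which guarantees
contamination ≤ completeness.

Estimated genome size corrects bin size for both effects:

    estimated_size = (bin_size − bin_size · contamination) / completeness

Quality tiers carry mixed inequality semantics as conventionally printed:
completeness strictly above 50%/70% (with contamination strictly below
5%), at-or-above 80%/90%. Redox classes from dissolved oxygen (g/m³):
oxic strictly above 3 (fixed by field convention); the lower boundaries
(anoxic < 0.1, suboxic 0.1–0.3, dysoxic 0.3–3) are configurable defaults
applied as half-open intervals, so DO = 3.0 is dysoxic, DO = 0.3 dysoxic,
DO = 0.1 suboxic.

## Abundance (`abundance`)

Counts are made comparable across samples by scaling every sample's
counts so each column total equals the highest per-sample total
("normalization based on the highest read count between samples"; we read
this as up-scaling, which preserves within-sample proportions exactly —
a down-scaling-to-minimum mode is available behind `mode="min"`).
Relative abundance divides each sample by its total.

The enrichment factor of a taxon between sample groups A and B is

    EF = mean(relative abundance over A) / mean(over B)

Classes: enriched-A (EF above the neutral band), enriched-B, exclusive-A
(B mean zero, EF = +∞), exclusive-B (EF = 0), absent. A taxon whose EF
falls within [1/1.05, 1.05] is called neutral rather than risking a
knife-edge call; the band width is a parameter. Presence means a strictly
positive value (a configurable floor is provided, default 0).

Also here: prevalence at a sample-fraction threshold (ceiling rule),
Venn-style fraction sharing with per-partition abundance shares,
seeded rarefaction (a multivariate-hypergeometric draw; reported richness
is a single draw, matching common practice), Shannon diversity in nats,
Bray–Curtis dissimilarity (bounded, symmetric; *not* asserted to be a
metric), and min–max scaling of physicochemistry.

## Transcription (`transcription`)

Reads per gene are normalized by the modified-TPM formula

    modified_tpm = reads · (1000 / gene_length) · (10⁶ / library_size)

"Library size" is taken as the total quality-trimmed reads of the sample
(the generator defines it so mapped reads are 80% of it); a mapped-only
mode is a matter of passing different column totals. Per-MAG expression
sums modified-TPM over the MAG's genes, optionally divided by estimated
genome size in Mbp so gene-rich large genomes do not dominate. Condition
summaries (COG-category proportions, fold changes) average per-sample
totals within condition first, then compare conditions. Condition-
exclusive features are those detected (> 0 by default) in one condition
and never in the other. Cold-shock genes *cspA/B/C* are reported but
flagged as a sample-preservation artifact, never dropped.

### Compositional baseline in recovery tests

Because modified-TPM (and relative abundance) are normalized within each
sample, every observed oxic:dysoxic ratio carries one common
community-composition factor: boosting some MAGs in oxic samples deflates
everything else's share there. Planted-effect recovery therefore divides
the observed ratio by a baseline that estimates this factor — the median
ratio over categories planted at 1.0 (category recovery), or over
neutral-labelled MAGs (per-MAG fold-change and enrichment-factor
recovery). This is the package's own design choice for scoring recovery
and is reported alongside the raw ratios.

## AAI novelty (`aai`)

AAI between two genomes is the unweighted mean percent identity over
retained best-hit protein pairs. Hits are kept at ≥ 30% identity over
≥ 70% coverage; "70% of alignment length" is self-referential if read
literally, so coverage is computed against the shorter protein of the
pair (the common AAI convention) with the literal mode available
(`coverage_mode="none"`). Pairing defaults to reciprocal best hits
(bitscore, ties by identity then subject id; the pair identity is the
mean of the two directions, making AAI symmetric by construction);
one-way mode and length weighting are options. The 45–65% band is used
as the AAI range spanned by genomes of the same family; only this
family-band call is made — rank assignment beyond it requires
phylogenomic placement and is out of scope.

## Correlation screens (`correlation`)

Spearman's ρ (average ranks for ties, product-moment on ranks) and
Pearson's r, each with the two-sided t-approximation p-value on n − 2
degrees of freedom — adequate at the study's n = 16 — plus a seeded
Monte-Carlo permutation p for Spearman used in validation. Screens
correlate every matrix row against every environmental parameter,
pairwise-complete over missing chemistry with the effective n recorded.
No multiplicity correction is applied by default, mirroring raw
p < 0.05 / p < 0.001 reporting; Benjamini–Hochberg is available behind a
flag.

## Co-occurrence and cohorts (`cooccurrence`)

The network links MAG pairs with Spearman ρ > 0.8 and p < 0.001
(positive correlations only); all MAGs remain as nodes, so isolated
organisms are visible. Constant-profile MAGs cannot be ranked and are
excluded from pairing with a log message.

Cohorts are detected by Ward minimum-variance hierarchical clustering of
per-MAG profiles, standardized per MAG (z-scores across samples) so
profile *shape* rather than magnitude drives the dendrogram (raw mode
available). The cut rule operationalizes "confirmed by rank
correlation": starting from the root, any cluster whose members' median
pairwise Spearman ρ falls below 0.8 is split into its two children,
recursively; the cohorts returned are the maximal confirmed clusters,
and singletons stay unassigned. Rows are sorted lexicographically before
linkage so merge-order ties resolve deterministically. A cohort is
preference-uniform for a grouping (aquifer fraction, or DO) when all
members fall on the same enrichment side, exclusive counting as enriched.

## Synthetic data (`synthetic`)

The generator emulates the study design: 4 sites × 2 wells ×
{groundwater, sediment-enriched} = 16 metagenome samples; 6
metatranscriptomes (2 oxic, 4 dysoxic); 200 ultra-small MAGs (group
frequencies weighted as in diverse groundwater communities, heavily
Patescibacteria) plus 100 larger background MAGs. Chemistry is drawn
per site, uniformly within DO 0.37–7.5, DOC 0–26, nitrate-N
0.45–12.6 g/m³ (plus pH, sulfate, ORP, temperature, DRP, conductivity at
realistic groundwater ranges); the first site is forced oxic and the
last dysoxic so both regimes always exist.

Key planted structure and the reasoning behind the defaults:

* **True genome sizes** ~ N(1.0, 0.4) Mbp truncated at 0.4 Mbp for
  ultra-small MAGs (2–6 Mbp uniform for background); bin size =
  true · completeness · (1 + contamination) with completeness ~
  U(0.5, 1) and contamination ~ U(0, 0.05). SCG presence is a Bernoulli
  realization of the drawn completeness.
* **Cohorts**: up to 20 cohorts of 2–20 members. Each draws a log-normal
  (σ = 1) base profile across samples, boosted 10-fold at one dominant
  site (round-robin over sites) — mirroring the observed site-exclusivity
  of co-occurrence clusters; members multiply the base by log-normal
  noise with CV 0.2. The within-cohort CV is a free parameter of this
  package (no field value exists for it), chosen so cohorts are tight
  but not degenerate.
* **Enrichment**: each cohort (and each cohort-free MAG) draws one label
  from {oxic, dysoxic, fraction-planktonic, fraction-attached, neutral};
  labelled MAGs are multiplied 4-fold in their preferred samples.
* **Counts**: multinomial reads per sample at a depth uniform over a
  5× range (1–5 M), so per-sample totals differ and depth normalization
  is consequential.
* **Transcripts**: ~600–1200 genes per MAG, lengths log-normal around
  900 bp, negative-binomial counts with dispersion 0.3 (the standard
  overdispersed count model). Ultra-small MAGs have 80% of genes without
  a functional category (40% for others), matching the observation that
  most ultra-small expression cannot be assigned a function. Planted
  per-category oxic:dysoxic ratios default to E 88:12, T 86:14, I 81:19,
  B 7:93, N 34:66; oxygen-labelled MAGs additionally get a 4-fold
  per-MAG condition effect. 5% of genes are forced condition-exclusive.
* **Protein hits**: one-to-one orthologue pairs in both directions with
  identities ~ N(true AAI, 3), plus decoys violating the identity and
  coverage filters.

All stages draw from per-stage child generators of one seed; identical
configs give byte-identical outputs.

What the generator does **not** emulate: sequences or assembly artifacts
(no reads, no FASTA), chimeric binning errors, phylogenetic correlation
between MAGs, zero-inflation beyond what the multinomial induces,
temporal structure, or host–symbiont pairing. Passing recovery tests
therefore show the estimators are correct and well-calibrated under the
assumed generative model, not that real groundwater data meet those
assumptions.

### Isolation experiments

Two recovery experiments deliberately switch off a confounder:

* **Enrichment accuracy** (effect 4.0, CV 0.3) runs with the cohort site
  effect at 1.0. Redox class is a site-level property, so with site
  structure on, a cohort's dominant site masquerades as an oxygen
  preference and no classifier could separate the two from these data.
  Accuracy is scored over directionally labelled MAGs; the knife-edge
  neutral band is not recoverable from finite noisy data and neutral
  MAGs are not scored.
* **Category-ratio recovery** runs with the per-MAG condition effect at
  1.0 (it multiplies every category's observed ratio by one common
  label-mixture factor); conversely per-MAG fold-change recovery runs
  with category effects off.

## Numerical choices

* Column totals of zero: left zero with a warning (normalization,
  relative abundance); Bray–Curtis between two all-zero samples is 0
  with a warning; constant vectors give NaN correlations, all-zero
  z-scores, and min–max maps to the lower bound — each logged.
* Ties: best hits break by bitscore, identity, then lexicographic id;
  top-gene rankings break by gene id; Ward merge order by lexicographic
  MAG id.
* Perfect monotone profiles (|ρ| = 1) get p = 0 rather than the t
  singularity.
* Floating-point TSV output uses `%.10g` so repeated runs are
  byte-identical.

## Problem sizes

Validation experiments are sized for quick iteration while keeping
estimator variance low: 1000 null rows for type-I calibration at n = 16,
500 profiles (~125k pairs) for the network false-edge rate, 10k draws
for the rarefaction oracle, 200 protein pairs per AAI estimate, 8
planted cohorts at the full 200-MAG default for cohort recovery, and
60 + 20 MAGs (~72k genes) for the transcription recovery experiments.
The full default pipeline (300 MAGs, ~270k genes, 16 + 6 samples) runs
in well under a minute on one CPU.

## Known limitations

* The up-scaling reading of depth normalization is an interpretation;
  results are invariant to the alternative down-scaling mode at the
  relative-abundance stage, but raw normalized counts differ by a
  constant factor.
* Contamination from SCG duplication underestimates contamination from
  closely related strains that share single-copy markers.
* The confirmation-cut cohort rule can admit a small number of
  stragglers whose profiles happen to track a cohort; with the default
  thresholds this was rare in validation runs (purity ≥ 0.95).
* AAI is computed from provided alignment tables; alignment quality,
  and hence AAI, is only as good as its input.
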