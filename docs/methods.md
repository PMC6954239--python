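# Methods

This note records the model behind `dualinit`, the default parameters and
why they hold their values, what the synthetic generator does and does not
emulate, and the judgment calls made where a rule admits more than one
reading.

## 1. CTSS model and normalization

A CTSS table is `(chrom, pos, strand, count)` with `pos` the 1-based
coordinate of the +1 (first transcribed) base. Duplicate positions are
summed on read; malformed lines fail with their line number.

Two normalizations are available per library:

- **TPM** (default): `count / total * 1e6`.
- **Power-law**: CAGE tag counts follow an approximate power law; the
  reverse-cumulative distribution is fitted in log-log space over the count
  range [10, 1000], and counts are mapped through
  `c ↦ c^(alpha_fit / alpha_ref)` with reference slope `alpha_ref = 1.22`,
  rescaled to 10⁶ total. This aligns libraries of different depth and tail
  shape while preserving ranks. If fewer than 3 distinct count values fall
  in the fit range, the library falls back to TPM with a warning rather
  than extrapolating from an unconstrained fit.

## 2. Initiator classification

The −1/+1 dinucleotide is read on the transcript strand (reverse
complemented for −-strand CTSSs):

- `YR` = {CA, CG, TA, TG} (4 of 16 dinucleotides),
- `YC` = {CC, TC} (2 of 16; the TCT/5′-TOP context),
- `OTHER` = the remaining 10 (GG included).

Contig-edge positions lacking a −1 base classify as `OTHER` (their
dinucleotide carries an `N`).

## 3. Filtering and tag clustering

A CTSS qualifies if it reaches ≥ 1 TPM in at least one stage; in a
qualifying CTSS, per-stage values below 0.5 TPM are zeroed (the rescue rule:
sub-threshold expression in other stages is kept only once one stage passes
the primary threshold). The rescue rule is applied per CTSS position, not
per cluster — clustering happens after filtering.

Tag clusters are maximal runs of same-class, same-strand, same-chromosome
CTSSs with inter-position gaps ≤ 20 nt (single linkage, so a cluster can be
wider than 20 nt). The dominant TSS of a cluster is its highest-expressed
member; ties break to the 5′-most position in transcript orientation.

## 4. Promoter calls

The promoter window of a gene is [TSS − 500, TSS + 300] in transcript
orientation, inclusive. A cluster belongs to a gene when its dominant TSS
falls in the window on the matching strand; with several candidate genes the
nearest TSS wins (ties break deterministically to the lexicographically
smallest gene id, and are logged).

**DI status.** A component (YR or YC) is *robust* when it reaches ≥ 3 TPM in
at least 2 stages; the 3-TPM reading is per stage (two stages each ≥ 3 TPM),
not a sum. A gene with both components robust is `DUAL`; with one, `YR_ONLY`
or `YC_ONLY`; with neither, `NONE`.

**Dominance.** Per stage, the component with > 50 % of the gene's promoter
expression dominates; exact ties count as YR-dominant (YR is the canonical
default). Stages where both components are zero have undefined dominance.

**Offset.** `yc_offset = (dominant_yc_pos − dominant_yr_pos) × strand_sign`,
so −1 means the YC site sits immediately upstream of the YR site. Offsets 0
and +1 are impossible by construction: the YC +1 base is a C while the YR +1
base is a purine, and the YR −1 base is a pyrimidine.

**Sequence features.** The 5′ UTR length is the exonic distance from the
dominant TSS to the base before the CDS start, including any unspliced
leader upstream of the annotated first exon (a dominant TSS upstream of the
annotation extends the UTR; a CDS upstream of the dominant TSS makes the UTR
undefined). Pyrimidine-run length is the maximal contiguous pyrimidine
stretch (transcript strand) containing the +1 base.

## 5. Temporal dynamics

Per-gene YR and YC stage profiles of `DUAL` genes are min–max scaled to
[0, 1] (constant vectors map to 0.5 and are flagged). The scaled YR‖YC
concatenations feed a batch self-organizing map: Gaussian neighborhood,
linearly decaying radius, prototypes seeded from data rows, batch updates
(order-invariant given the seed). The default 4×4 grid is a deliberate
compromise — large enough to separate maternal/zygotic archetypes, small
enough that nodes stay populated at a few hundred genes. A k-means run on
the same matrix is used in the tests as an independent oracle, not in the
pipeline itself.

Divergence is additionally ranked directly: the Pearson correlation between
the raw YR and YC vectors, with r ≤ −0.5 (inclusive) flagged anticorrelated.

## 6. snoRNA coupling

Host-gene intronic snoRNAs are filtered before use: fewer than 5 supporting
reads, mature length < 51 nt, or overlap with annotated exons or repeats
drops a candidate (each dropped record carries its reason).

Coupling of snoRNA output to the host's components is measured on pooled
stage-transition log2 fold changes (pseudocount 0.5) across all host genes:
`r_yc` correlates snoRNA LFCs with YC-component LFCs, `r_yr` with YR. The
pooled (gene × transition) correlation is used rather than per-gene
averaging because single hosts contribute few transitions; a per-gene mode
exists for inspection. A dominance-matched comparison (Mann–Whitney on
snoRNA expression between YC- and YR-dominant hosts matched within 0.25
log10 units of host expression) controls for host level.

## 7. Perturbation statistics

For a treated-vs-control contrast, each gene's 2×2 table
(YC/YR × treated/control, TPM values rounded to counts) gets a two-sided
Fisher exact test; p-values are Benjamini–Hochberg adjusted across the
tested universe (genes with all four cells positive). Component log2 fold
changes use pseudocount 0.5. The lfc_yc and lfc_yr distributions are
compared with a two-sample Kolmogorov–Smirnov test, and a direction summary
reports the YC-up / YR-down quadrant fractions. Tables with a zero margin
are reported as p = 1 with undefined odds ratio.

## 8. Synthetic data generator

The generator is the package's validation instrument: it plants promoters
with known architecture and returns the ground truth alongside the genome.

Layout: genes occupy alternating strands in non-overlapping 2,000-nt slots
on one chromosome with 1,000-nt margins; the dominant YR site anchors at
slot + 1,000. Gene models carry two exons and a CDS start 310–500 nt into
the transcript, so UTR and window logic is exercised on both strands.

Per gene:

- class `DUAL` (default fraction 0.20), `YC_ONLY` (0.05), else `YR_ONLY`;
- the YC component carries a planted fraction of the gene's expression
  (its dominant site offset −1 with probability 0.18, otherwise uniform
  over admissible offsets in [−30, +30] — the core-promoter scale —
  excluding the impossible {0, +1} and the planted YR minor-site
  footprint);
- each component has 2 minor sites at ±3 nt spacing whose expression decays
  geometrically (factor 0.35) from the dominant site;
- YC sites sit inside a planted pyrimidine run of 4–12 nt with purine
  guards at both ends, so run lengths are exactly recoverable; YR sites get
  a pyrimidine at −1 and purine at +1;
- base expression is log-normal (median 400, log-sd 1.0); temporal profiles
  are `MATERNAL`, `ZYGOTIC` (switching at stage index 7 of 12, silent phase
  at 5 % floor) or `CONSTANT`; 25 % of dual genes get opposing YR/YC
  profiles.

Sampling: per stage, each gene's expected weight is multiplied by a gamma
factor (dispersion 0.1) and tags are drawn multinomially at the requested
depth — overdispersed totals with exact within-gene proportions. The
noise-free expected TPM per gene × component × stage is available as an
oracle (`expected_component_tpm`), which is how recovery tests define truth
labels without re-deriving thresholds.

snoRNA counts are gamma-Poisson with mean
`scale × (c · YC + (1 − c) · YR)` for coupling `c`; dispersion 0 returns
exact means so limit identities hold. Perturbations draw Poisson counts
around the baseline with component-specific multiplicative effects.

**Not emulated:** mapping artifacts and multi-mapping, sequencing errors,
chromatin or TATA/GC context beyond the initiator and pyrimidine run,
inter-gene correlation, splicing isoforms beyond one model per gene, and
genome-scale intergenic background (an optional intergenic tag fraction
exists but defaults to 0).

## 9. Numerical and testing choices

- Thresholds are inclusive where a boundary case exists (≥ 3 TPM,
  r ≤ −0.5, gap ≤ 20); the anticorrelation flag tolerates 1e-12 of float
  noise at the boundary.
- All stochastic code takes explicit seeds; identical seeds give
  byte-identical FASTA and tables.
- Standard statistics use scipy/statsmodels (Fisher, BH, KS, Pearson,
  Mann–Whitney); the test suite re-derives each against hand-written
  oracles (hypergeometric enumeration, step-up BH, ECDF scan) and checks
  clustering against a union-find transitive closure.
- Problem sizes in `tests/` and `scripts/acceptance.py` (10³ genes,
  10⁶ tags/stage, 12 stages) are chosen so every recovery statistic is
  estimated from hundreds of events while a full run stays in the
  minutes range on one CPU.
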