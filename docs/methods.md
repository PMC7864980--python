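# Methods

## Problem setting

16S rRNA amplicon sequencing of low-biomass specimens (lung tissue here) is
dominated by two facts: the bacterial signal is small, and DNA-extraction
kits and laboratory plastics carry their own bacterial DNA. The workflow
implemented in this package assumes the study design that makes those
contaminants trackable: for every patient, a cancerous tissue sample, an
adjacent healthy tissue sample and a *single* negative control (an empty
tube handled identically through homogenization, extraction and
sequencing), all processed with the same DNA-extraction kit. The pipeline
starts at the clustered OTU table (mothur `.shared` + `.cons.taxonomy`);
sequence cleaning, clustering and classification are upstream and out of
scope.

## The ratio removal rule

For an OTU with relative read counts `c` (cancerous), `h` (healthy) and
`k > 0` (control), the OTU is kept iff `c > R·k` and `h > R·k`, with
`R = ratio_threshold = 1000`. Choices worth stating:

- **Strict inequality.** The rule is "strictly greater than R times"; the
  documented consequence is that on a 20,000-read control a single-OTU
  tissue (relative abundance 1.0) is removed at exactly 20 control reads
  and tolerates 1–19.
- **Joint removal.** A failing OTU is zeroed in both tissues at once, never
  in only one — otherwise the filter itself would create intra-patient
  differences. Because both tissues must pass, an OTU absent from one
  tissue (relative abundance 0) can never be kept; the rule is
  asymmetric-proof by construction.
- **Zeroing, not deletion.** Removal zeroes counts so every downstream
  stage sees a stable OTU universe; all-zero columns can be dropped at
  export time.
- **The control row is never filtered.** Controls are the reference, not a
  subject of cleaning.
- **Control-present OTUs absent from both tissues** are recorded in the
  removed set (no observable effect) so that removed ∪ kept always
  partitions the control-present OTUs.
- Relative abundances are computed per sample independently, before any
  removal; zero-total samples are an error, not a NaN.

Diagnostics reproduce the two published summaries: percent remaining
OTUs (`100 · observed-after / observed-before`, counting per-tissue nonzero
OTUs only) and the Pearson correlation between each tissue and its control
over the full OTU universe, computed *before* removal (enforced by pipeline
order). Pearson is computed on relative counts by default with a raw-count
flag; Shapiro–Wilk p-values accompany it as diagnostics only, since these
zero-inflated profiles are essentially never normal.

## Core contaminants

Per kit, an OTU is *core* when its relative abundance reaches
`core_abundance_cutoff = 1e-5` (0.001%, inclusive `≥`) in at least
`ceil(core_frequency_cutoff · n_controls)` of the kit's controls
(`0.40` → 2 of 5). Singletons (total count 1 over the pooled control
table) are removed before any per-kit subsetting; the order matters because
it changes totals and is therefore fixed. Mean relative abundance is
averaged over **all** of a kit's controls, zeros included. The union of the
per-kit core sets is partitioned by exact kit membership (the 7 nonempty
Venn regions for 3 kits), each region annotated with per-kit summed mean
abundances — sums are per-kit and deliberately do not total 100%. The
non-core statistic counts OTUs that pass the abundance cutoff in ≥ 1
control but fail the frequency cutoff. Region abundances are emitted
per kit for every region; any cross-kit aggregation is left to the report
consumer.

## Spike-in scoring

The packaged reference panel is the 20-strain even mock community (5% per
strain, whole-cell or genomic variants), shipped as an editable TSV. Since
the panel holds two *Staphylococcus* and two *Streptococcus* strains, it
collapses to 18 distinct genera; the detection percentage uses that
denominator (the 20-strain denominator is reported alongside, because the
per-strain protocol wording suggests 20 while the arithmetic of the
replicate averages — 49/54 = 90.7%, 48/54 = 88.9% — requires 18).
A genus is detected in a replicate when its genus-agglomerated count
reaches `min_reads = 1` (no stated detection threshold). When an unspiked
background table is supplied, genera present in the background are not
credited to the spike, except the genera known to occur naturally in the
tissue (*Acinetobacter*, *Staphylococcus*), which stay credited unless the
strict flag is set. Expected spike loads: 2.5×10³ cells/g of tissue
(whole-cell) and 1.25×10³ genomes per sample (genomic).

## Diversity statistics

- **Shannon** uses the natural logarithm (the vegan default; the index name
  alone does not fix a base).
- **Bray–Curtis** weighted is computed on per-sample relative abundances
  (raw-count variant behind a flag) — this removes sequencing-depth
  artifacts; unweighted uses presence/absence indicators.
- **PCoA** is classical scaling (double-center −D²/2, eigendecompose).
  Axes with positive eigenvalues are kept, proportions explained are over
  the positive-eigenvalue sum, and negative eigenvalues are reported
  unchanged — no Lingoes/Cailliez correction, the simplest faithful choice.
- **PERMANOVA (ADONIS)**, one-way: SST = Σ_{i<j} d²_ij / n, SSW analogous
  within groups, F = (SSB/(g−1)) / (SSW/(n−g)), R² = SSB/SST. The p-value
  uses `(exceedances+1)/(B+1)` with a `≥` comparison (so p ≥ 1/(B+1)),
  seeded for bit-reproducibility; 5000 permutations by default. A
  degenerate SSW = 0 yields F = +∞ with exceedance counting still valid.
  For tiny n an exhaustive mode enumerates all n! relabelings and returns
  the exact exceedance fraction. PCoA and the PERMANOVA statistic are
  authored here (the R² and exhaustive mode are not available from the
  library routine) and are cross-checked against scikit-bio in the tests.
- **Paired tests**: the signed-rank test uses the exact distribution for
  n ≤ 25 with zero differences dropped (Wilcoxon's convention) — required
  to reach the small-n landmark p-values (n = 5, all same sign → 2/2⁵ =
  0.0625); p-values are always two-sided. Zero-variance differences are an
  error for the t test, all-zero differences for the signed-rank test.
- **DNA yield**: concentration (ng/µL) × eluate volume (µL) / tissue mass
  (g).

## Synthetic study generator

The generator emulates the study design so that every stage is testable
with no download:

- **Design**: `n_patients = 5`, all three kits, one
  cancerous/healthy/control triplet per patient and kit (45 samples, 15
  controls), sequencing depth 20,000 reads per sample — the scale of the
  worked control example.
- **Taxa**: 40 endogenous taxa, 10 core contaminants shared by every kit
  (the size of the shared core observed across kits), ~30 kit-specific
  contaminants per kit (the observed kit-exclusive pools were 25–34).
- **Profiles**: each kit draws one contaminant profile over core ∪
  kit-specific taxa from a Dirichlet (core taxa get a larger concentration
  parameter, 2.0 vs 0.5, so the shared pool reliably appears in every
  kit's controls). Each patient draws an endogenous profile from a
  Dirichlet(0.5) and log-normal perturbations (σ = 0.5) derive the
  cancerous vs healthy variants.
- **Counts**: controls ~ Multinomial(depth, kit profile); tissues ~
  Multinomial(depth, (1−f)·endogenous + f·kit profile) with
  `contaminant_fraction_in_tissue f = 0.05` — a modest planted
  contaminant share appropriate for low-biomass tissue.
- **Ground truth** labels every taxon (endogenous / core contaminant /
  kit contaminant) and retains the per-sample mixture weights, making
  sensitivity/specificity of the removal rule exactly evaluable. Controls
  are pure contaminant draws by default (the empty-tube design); a
  `leakage` parameter (default 0) admits endogenous bleed-through for
  stress tests.

What the generator does **not** model: PCR/primer bias, chimeras,
taxonomic mis-assignment, depth variation between samples, overdispersion
beyond the Dirichlet draw, or physical association between host tissue and
bacteria. Passing tests therefore demonstrate the pipeline's correctness
and its behaviour under the assumed mixture structure — not recovery rates
on real sequencing runs.

Because endogenous taxa never enter controls, specificity of the removal
rule is analytically 1.0 under the default generator; the Monte-Carlo
checks confirm it, and sensitivity is exercised by the planted contaminant
fraction. As `f → 0` supports become disjoint and nothing observable is
removed (percent remaining 100%); as `f` rises the seed-averaged percent
remaining falls monotonically.

## Numerical and interface choices

- Counts are integers throughout; relative abundances are derived views.
- Sample identity (not file order) joins counts to metadata.
- Taxonomy is fixed at six ranks (domain…genus); deeper strings are
  truncated, shallower ones padded with the mothur `_unclassified`
  convention — genus-level reporting needs a stable genus slot.
- Readers reject malformed input (ragged rows, numOtus mismatches,
  duplicate groups, unknown enum values) rather than coercing; writers emit
  UTF-8/tab/LF with 6-significant-digit floats, and every writer's output
  is accepted by its paired reader (round-trip property).
- Only single-label `.shared` files load implicitly; multi-label files
  need an explicit label. Taxonomy bootstrap values are parsed and
  discarded (no downstream use).
- Test and acceptance runs use scaled-down problem sizes chosen for desk
  reproducibility: triplet tables of ≤ 20 OTUs for oracle-equivalence
  sweeps, 1–5 patients at depth 2,000–20,000 for generator checks,
  99–199 permutations where only reproducibility (not the p-value itself)
  is under test, and 20 seeds for trend assertions.

## Known limitations

- The ratio rule needs exactly one control per patient/kit; multi-control
  designs (pooling or per-step controls) are unsupported.
- Prevalence- or frequency-based contaminant models (e.g. the decontam
  package's) and qPCR-informed scaling are intentionally out of scope; the
  removal step is modular and can be swapped.
- PCoA reports but does not correct negative eigenvalues; strongly
  non-Euclidean distance matrices shift explained-variance fractions.
- The spike-in scorer is qualitative (presence at the genus rank); it does
  not attempt quantitative recovery or per-Gram-stain extraction-efficiency
  modelling.
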