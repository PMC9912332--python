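# Methods

## The screen and its quantities

A pooled LNP delivery screen formulates each candidate nanoparticle chemistry
with a reporter mRNA and a unique DNA barcode, pools the particles, injects
the pool, sorts reporter-positive cells by tissue and cell type, and
sequences barcode amplicons from each sorted population plus an aliquot of
the injected pool. The analysis reduces to: (1) enumerate the chemical
design space and its barcodes, (2) count barcodes per sample, (3) convert
counts to a per-LNP delivery score, (4) relate scores to chemistry, and
(5) for single-cell follow-up of lead particles, quantify reporter capture
and transcriptional response per cell population.

## Library enumeration and barcodes

`library.enumerate_library` crosses a helper-lipid panel with molar-ratio
arms and PEG-lipid arms; the default configuration is an 18-lipid panel
(3 cationic, 8 neutral, 7 anionic) × 4 molar ratios × 2 PEG-lipids =
144 designs, of which 137 are pooled by default. Three of the four default
ratio arms place the helper lipid at 12%, 27.5% and 44.5% of moles; the
fourth (20%) is a placeholder completing the factorial and, like everything
else in the table, is user-configurable. The default panel's named lipids
are representative commercial phospholipids and quaternary amines spanning
the three charge classes, with nominal headgroup masses; the panel is an
input table, not a measurement. Which designs fail pre-pooling quality
criteria (particle size / polydispersity) is likewise an experimental input:
the default marks 7 of 144 as unpooled, and the choice of which is arbitrary.

Barcodes are rejection-sampled random oligos constrained to pairwise Hamming
distance ≥ 3 (defaults: length 8), which allows correction of any single
substitution; one extra barcode is reserved for the unencapsulated control.
Assignment is deterministic given a seed and fails loudly when the requested
code cannot be placed.

`dose_per_lnp` reports total dose / pool size to two significant figures
(1.0 mg/kg over 23 particles → 0.043 mg/kg per LNP).

## Normalized delivery

For a sorted sample, each barcode's proportion is divided by its proportion
in the input pool — removing unequal pool representation — and the resulting
ratios over retained LNPs are rescaled to sum to 100. This
ratio-then-renormalize construction is our explicit reconstruction of the
"normalized delivery" score displayed on a 0–100 scale in such screens; it
is the minimal procedure consistent with that definition. Two consequences
are used as invariants everywhere: retained scores sum to 100 per sample
(to 1e-6), and scores are invariant to rescaling a raw counts column.

The naked control is deliberately **excluded from the renormalization
denominator** and reported separately as `100 · r_control / Σ r_LNP`, i.e. on
the same scale as LNP scores. Including it would inflate every LNP's score
by a sample-dependent amount; excluding it preserves its role as a
delivery floor.

QC is inclusive-boundary and deterministic: samples need ≥ 10⁴ assigned
reads (default), and barcodes must reach at least half the uniform
expectation of input-pool proportion (default). Normalization is per-sample,
then mice are aggregated as mean ± SEM (sd/√n, ddof = 1; SEM reported absent
for n = 1). Aggregating after normalization keeps each mouse's compositional
constraint intact; the alternative order (merge counts, then normalize)
would weight mice by depth.

## Decile enrichment

Scores for a cell type are ranked; the top and bottom `ceil(fraction · N)`
designs (default fraction 0.1) form the comparison sets. Enrichment of a
property value is its frequency in a set divided by its library frequency
*f*, so 1 is chance, the range is [0, 1/f], and for any partition of the
library into property values the weighted sum Σ f_v·e_v equals 1 exactly —
an identity the tests exploit. Fold enrichment is top minus bottom
enrichment, in [−1/f, 1/f]. A frequency-difference variant (chance level 0)
is available via `method="difference"`. Ties are broken by stable design
order, with the bottom set drawn from the tail of the same ordering so the
two sets are always disjoint; the ceiling and tie rules are our documented
defaults, as is computing enrichment on mouse-averaged scores (per-tissue
summaries average per-cell-type folds with equal weight).

Significance is by label permutation: LNP property labels are shuffled
against the fixed scores, and the two-sided p-value is
`(1 + #{|fold_perm| ≥ |fold_obs|}) / (1 + n_perm)`. Because the fold
statistic of a label subset of size m in fixed sets of size k lives on an
integer lattice, its permutation p-values are discrete; calibration checks
against a continuous uniform are therefore run at large synthetic label
counts (N = 20 000), where the lattice is fine relative to the resolution of
a Kolmogorov–Smirnov test. At library-sized N the p-values remain valid
(super-uniform) but visibly discrete; the small-N correctness of the
procedure is checked against exhaustive enumeration of label placements
instead.

## Barcode extraction

Reads carry the barcode at a fixed offset between constant anchors
(defaults: 8-nt anchors either side, 2 anchor mismatches tolerated). The
barcode window is matched exactly first, then to the unique library barcode
within `max_mismatch` substitutions (default 1); equidistant ambiguity and
anchor failure yield "unassigned", never a wrong assignment. The constraint
`max_mismatch < min_pairwise_hamming / 2` is enforced, which guarantees a
unique nearest barcode. Reads are used as-is — the screen counts presence,
so quality trimming is left to upstream tooling; reverse-complement handling
is flag-enabled. Assigned + unassigned always equals reads processed.

At a 1% per-base substitution rate with 8-nt barcodes, one-mismatch
correction recovers ≈ 99.7% of barcode windows; the dominant residual loss
is ≥ 2 errors in a window or anchor, giving per-barcode count recovery
within 2% at depths of 10⁵ (verified by round trip against truth).

## Screen simulator

Potency of LNP *i* for cell type *t* is
`baseline · effect(charge_i, tissue_t) · ε_i` with `ε_i` lognormal
(σ = 0.3) shared across cell types, and the naked control's potency is
`baseline · 0.02`. Default tropism multipliers encode the qualitative
biology — cationic×lung 50, cationic×heart/kidney 3, neutral/anionic×liver
10, modest spleen effects — and are synthetic working values, not estimates.
The input pool is near-uniform (Dirichlet, concentration 400). A sorted
sample's expected proportions are input-weighted potencies normalized to the
simplex; observed proportions add Dirichlet overdispersion (concentration
200 by default) to model replicate-mouse variability, and counts are
multinomial at the configured depth (default 10⁵ per sorted sample,
2×10⁵ for the pool), so column sums equal depth exactly. With
overdispersion → ∞ and depth 10⁶, empirical proportions match expectation
to < 0.01 and normalized delivery recovers `100 · potency / Σ potency` to
well under one point — the pipeline's recovery benchmark.

Two emergent behaviours matter for interpretation. First, the naked
control's score is at the floor (≤ every LNP's score) in ≈ 95% of sorted
samples; the exceptions arise when overdispersion drives a weak LNP to zero
reads while the control draws one or two, a tie-at-zero artefact of finite
depth rather than efficient control delivery. Second, because the default
tropism acts at the charge-class level, every cationic lipid — including the
DDAB-like panel member — shows maximal positive lung fold enrichment in a
pooled all-charges screen.

The FASTQ generator expands any count column into anchored reads with i.i.d.
substitution errors and writes truth counts alongside, enabling lossless
(error 0) and noisy round-trip tests of the demultiplexer.

## Single-cell simulator and readouts

Cells are drawn per (cluster, group) stratum — defaults: 8 lung-like
clusters (3 endothelial, fibroblast, 3 immune, epithelial) × 4 treatment
groups (Cat-LNP, Neu-LNP, An-LNP, PBS) × 150 cells — with per-gene negative
binomial counts (baseline means lognormal-spread over ~0.05–10, dispersion
0.5). A planted block of genes (default 15 at log2FC = 2 in Cat-LNP)
provides DE truth. The delivery reporter is an aVHH pseudogene appended to
the gene list, drawn as Bernoulli(capture) × (1 + Poisson(1)); default
capture is 0.6 in endothelial clusters under Cat-LNP, 0.05 in other clusters,
0.02 under the other LNPs, 0 under PBS. The simulator deliberately omits
marker-gene cluster structure, batch effects and ambient RNA — cluster labels
are an analysis input here, so tests validate the delivery/DE/ORA readouts,
not clustering.

`percent_positive` reports the share of cells at ≥ 1 reporter count
(threshold configurable) per cluster × group; empty strata are absent, not
0%. Differential expression scales counts to 10⁴ per cell, applies log1p,
and tests each gene by two-sided Wilcoxon rank-sum (asymptotic,
tie-corrected) — the most common scRNA-seq default — with BH q-values over
tested genes; genes expressed in < 5% of selected cells are excluded but
reported. Both raw p and q are emitted because volcano-style gene lists
conventionally filter at raw p < 0.05. log2FC compares normalized group
means with a pseudocount of 1. Note that planted group-specific effects
induce a small compositional shift in all other genes after per-cell
normalization; type-I calibration is therefore assessed between groups
simulated from identical parameters, where the rejection rate at p < 0.05
is 0.05 ± 0.02.

Overrepresentation is the upper-tail hypergeometric test of a query list
against GMT gene sets intersected with an explicit background, flagged at
p < 0.001 by default. No pathway database is bundled — set content and the
size of the pathway universe are user inputs, since database versions are
outside reproducibility control.

## Problem sizes and determinism

Every generator is a pure function of (config, seed). The validation suite
uses a 137-LNP library with 19 cell types × 4 mice (76 sorted samples),
sequencing depths of 10⁵–10⁶, 10⁵-read FASTQ round trips, and single-cell
matrices of ~4 800 cells × 1 201 genes — sizes chosen so the full suite and
the reproduction script each complete in well under a minute of compute
while leaving estimation error far from the tolerances being tested.

## Known limitations

- The normalized-delivery formula and QC ordering are reconstructions of
  common practice, documented above, not a reimplementation of any specific
  lab's scripts.
- The simulators encode qualitative tropism and capture structure with
  synthetic magnitudes; passing recovery tests demonstrates the estimators'
  correctness under the stated generative model, not performance on real
  sequencing artefacts (index hopping, PCR chimeras, ambient RNA).
- Barcode extraction handles substitutions only; indels shift the fixed
  window and are counted as unassigned.
- Rank-sum DE on pseudoreplicated cells (no per-mouse random effect) is the
  field's default but anticonservative for between-animal inference; the
  simulator has no animal level, so the package makes no claim there.
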