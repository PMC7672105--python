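# Methods

`sscatac` implements the downstream analysis of a multi-cell-type skin
ATAC-seq study: eight sorted cell populations (CD4⁺ and CD8⁺ T cells,
dendritic cells, Langerhans cells, endothelial cells, macrophages,
fibroblasts, keratinocytes) sampled from healthy skin and from the
clinically unaffected and affected skin of systemic sclerosis (SSc)
patients. All stages operate on a peak-by-sample read-count matrix and on
small auxiliary tables; no sequence-level data are touched.

## Count model and normalization

The backbone is an N×M matrix D of raw Tn5 read counts over N merged
peaks and M samples. Columns are quantile-normalized with the classic
rank-mean algorithm: the reference distribution is the per-rank mean of
the sorted columns, and a value tied across ranks r..r+c−1 receives the
mean of the reference over that block. Consequences worth knowing:

- tie-free columns end up with bitwise-identical sorted value vectors;
- tied values receive rank-block means, so columns with ties deviate
  from the shared reference exactly at the tied entries;
- the grand sum per column equals the mean of the original column sums
  when no ties are present.

Peak intensity is log2(normalized + 1). The pseudocount is a design
choice: normalized counts of zero occur (silent peaks), and log2 of zero
is not usable downstream; the +1 floor maps zero to zero and is standard
for count data on a log scale. All genomic coordinates are BED-style
0-based half-open internally; 1-based inputs (the SNP catalog) are
converted on read.

## Differential accessibility and cell-type-specific peaks

Group comparisons use a two-sided Welch t-test on intensities — a robust
default at the 2–4 replicates per group this design carries — with
Benjamini–Hochberg correction (statsmodels). The effect size is the
difference of mean log2 intensities ("log2 fold change of mean peak
intensity"; the alternative reading, log2 of the ratio of mean counts,
is not used). When both groups are constant the p-value degenerates to 1
(equal means) or 0 (unequal), a documented limit convention. Groups with
a single replicate fall back to a fold-change-only mode.

Cell-type-specific peaks are called one-vs-rest per cell type at
p < 0.005 and log2FC > 2 (focal higher), with two coefficient-of-
variation filters on the normalized (linear-scale) counts: inCov < 0.5
within the focal cell type and outCov < 0.5 across all remaining
samples. CVs are computed on the linear scale because the CV of log
values depends on an arbitrary origin. A zero mean sets the CV to +inf
(the filter fails, with a warning). Calls are mutually exclusive in
practice; at exact boundaries the larger fold change wins.

## Six-state classification

For one cell type, peaks differential between any pair of clinical
states (p < 0.01, |log2FC| > 2; the candidate set is the union over the
three comparisons) are assigned to one of six enrichment patterns over
{normal, unaffected, affected}: the singletons C1 (normal), C3
(unaffected), C5 (affected) and the pairs C2 (normal+unaffected), C4
(unaffected+affected), C6 (normal+affected). A candidate takes pattern S
iff every in-S group mean exceeds every out-of-S group mean by more than
0.8 intensity units and every group's within-group range stays below
1.5; otherwise it is unassigned. If several patterns qualify (possible
only at exact boundaries) the smallest subset wins, then C1 < … < C6.
Reported ratios are per-cluster counts over all candidates.

With only two replicates per state (the default study design) the n=2
Welch test at p < 0.01 is conservative and roughly half of genuinely
state-patterned peaks reach candidacy; labelling among candidates is
~97–100% accurate. The dedicated recovery analysis therefore uses three
replicates per state, where ≥95% of planted peaks are recovered.

## SNP deviation scores

Trait-associated SNPs (a GRASP-like catalog) are filtered at association
thresholds 0.05, 1e-3, 1e-5, 1e-6 and 1e-8; traits retaining fewer than
20 SNPs are discarded as statistically unstable. SNP-in-peak overlap
(half-open) yields a binary trait-by-peak membership matrix. For trait t
and sample j the raw deviation is

    y_tj = (O_tj − E_tj) / E_tj,   O = Σ_i m_ti D_ij,   E = f_t T_j,

where f_t is the member peaks' share of the total mean accessibility
(x̄_i averaged across samples) and T_j the sample's total counts. The
whole-universe membership vector gives y ≡ 0 by construction. A
background z-score standardizes y against random peak sets drawn to
match the member set's profile over mean-accessibility deciles (50 sets
by default; seeded). GC-content matching, part of the original deviation
recipe for sequence-based data, is deliberately omitted: the synthetic
peaks carry no sequence, and mean accessibility is the only bias axis
the generator creates. Both raw and z-scored deviations are emitted;
cell-type enrichment is the arithmetic mean over the cell type's
samples.

## Signature scores and clinical severity

Signature genes per cell type are the deduplicated nearest genes
(minimal |peak center − TSS|, lexicographic tie-break, no distance cap)
of that cell type's specific peaks. Treatment-response genes —
differential between treated and baseline arrays at |log2FC| > 2,
p < 0.005 — are removed from every signature before scoring, including
the paired analysis, so a drug effect cannot masquerade as a cell-type
trend. A signature score is the mean normalized expression of the
remaining measured genes. Association with the modified Rodnan skin
score (mRSS) uses Pearson R with the two-tailed t transform
t = R·sqrt((n−2)/(1−R²)). The paired analysis selects, per patient, the
arrays at the lowest and highest mRSS (ties → earliest timepoint),
keeps patients with range > 5, and applies a paired two-tailed t-test.
The module accepts an already-normalized expression matrix; microarray
preprocessing is out of scope.

## TF footprinting

Mapped reads are reduced to Tn5 cleavage positions: plus-strand reads at
start+4, minus-strand reads at their 5′ base (end−1) shifted −5. The
shift is not idempotent; a provenance flag on the read table refuses a
second application. Groups are depth-equalized by seeded sampling
without replacement, defaulting to the smallest group's depth. The
aggregate profile counts insertions at offsets −w..+w around each motif
site center (w = 50, covering the "100 bp region centered on the site";
minus-strand sites are mirrored) and averages over sites. Point
insertions are aggregated by default; an extended-coverage variant
(reads widened around the cleavage position) is not implemented because
the point profile is what the dip statistics below consume.

## Motif enrichment (module map)

Motif hits become a binary peak-by-motif occupancy matrix (half-open
overlap). Enrichment of a motif in a peak set against the universe is a
hypergeometric test in both directions; the smaller tail fixes the
direction, BH runs across all (motif, set) pairs, and the reported score
is sign × −log10(adjusted p) (positive = enriched). This is a
reimplementation of the module-map idea with the standard hypergeometric
core, not an emulation of any specific tool's internals.

## Receptor-ligand interaction alteration

Gene-level accessibility is the sum of intensities of the peaks imputed
to a gene. Per cell type, a gene's Alteration Score is

    AS = log2((mean_affected + 1) / (mean_normal + 1)),

with per-cell-type means over replicate samples taken before the ratio.
The log scale is a deliberate reading of "fold change": the symmetric
retention threshold (±7) and the |AS| < 1 null zone are only coherent on
a signed log scale. For an ordered (sender, receiver) pair and a
ligand-receptor pair,

    SIA = 0                         if |AS_receptor| < 1 or |AS_ligand| < 1
        = AS_receptor + AS_ligand   otherwise,

with an additional sign-concordance requirement by default (an
interaction is called only coherently up or down; a flag restores the
literal two-branch form). Interactions with |SIA| > 7 (strict) are
retained; summaries count each retained interaction once per distinct
participating cell type, split by direction.

## Synthetic study generator

Every pipeline input is generated from a single seeded configuration on
a synthetic single-chromosome coordinate space (peaks tiled every 2 kb,
width 500 bp; 1,000 genes on a regular TSS grid). Counts are
gamma-Poisson (negative binomial, dispersion 0.01) around per-peak
baseline means drawn log-uniform over 2^5..2^10, with planted effects as
log2 offsets and multiplicative log-normal noise (sd 0.2 by default):

- 100 specific peaks per cell type at +4 intensity units in the focal
  type — the recovery design for one-vs-rest calling;
- 100 peaks per six-state pattern at a 3-unit gap in the fibroblast
  compartment (sd 0.1 in the dedicated recovery design);
- planted ligand-receptor switches: each planted gene owns six dedicated
  peaks next to its TSS, silent (mean 2^−6) except in the designated
  cell type's affected (up) or normal (down) samples where they rise to
  2^12; neighborhoods of these genes carry no other peaks, so both
  sides of a planted pair clear |AS| ≥ 1 and the pair clears |SIA| > 7.
  A block of 100 constitutively silent padding peaks anchors the bottom
  of the count distribution so that the quantile reference at low ranks
  stays near zero for every sample — without it, tie-averaging of the
  zero block leaks moderate reference values into silent peaks and
  produces spurious alteration scores;
- the trait-SNP catalog places the planted trait's SNPs inside the
  target cell type's specific peaks at odds 20:1 over a uniform draw;
  association P-values are log-uniform over 1e-12..0.05 so each
  threshold of the sweep retains a different subset;
- the expression cohort has 30 patients and 105 arrays (3–4 timepoints
  each), mRSS trajectories as a positive random walk, and the target
  cell type's exclusive signature genes sharing a latent component
  correlated with mRSS at rho (0.4 by default). Coupling only
  target-exclusive genes keeps the planted association from leaking
  into other signatures through shared nearest genes. Twenty
  treatment-response genes gain +5 on treated arrays; an optional
  paired delta shifts target genes at each patient's highest-mRSS
  array (used by the paired-test recovery design, where coupling is
  switched off);
- insertion tracks are per-bp Poisson draws around motif sites, rate
  0.2 with flank factor 1.5 and a protection factor inside the motif
  (0.2 emulates a bound factor's footprint; 1.0 gives a flat track).

What the generator does not emulate: GC/sequence composition,
fragment-length structure, chromosomal heterogeneity, LD between SNPs,
batch effects, and microarray normalization artifacts. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under its stated assumptions, not robustness to those real-data
phenomena.

## Numerical and scale choices

Peak center is floor((start+end)/2). Nearest-gene ties break to the
lexicographically smallest gene id. The acceptance analyses use
problem sizes chosen to be decisive yet desk-scale: 5,000-peak × 24- or
48-sample matrices, 100 catalog replicates for the deviation argmax
rate, 500 replicates for the null-uniformity check, 500 motif sites for
footprint profiles. Statistical acceptance bands (±3 SE, the Fisher-z
interval) are evaluated at fixed seeds; the per-offset 3-SE band on a
101-offset flat profile is an aggressive simultaneous criterion and can
fail by chance for an unlucky draw (~1 − 0.9973^101), which is why the
acceptance script reports the max deviation in SE units rather than a
boolean.

## Known limitations

- The t-test-based stages assume approximately normal intensities;
  strongly dispersed counts at low depth violate this and are only
  partially covered by the generator's dispersion knob.
- Deviation z-scores depend on the background bin count and set count;
  defaults (10 bins, 50 sets) trade stability for speed.
- `altered_interactions` scans ordered cell-type pairs; a symmetric
  collapse is left to consumers of the output table.
- With duplicate peak coordinates the auto-generated BED peak ids
  collide and reading fails by design (ids must be unique).
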