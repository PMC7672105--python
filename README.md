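# sscatac

Downstream analysis of multi-cell-type skin ATAC-seq for systemic
sclerosis (SSc) chromatin studies: from a peak-by-sample Tn5 read-count
matrix to cell-type-specific regulatory elements, disease-state chromatin
dynamics, GWAS-variant enrichment, transcription-factor footprints and
altered receptor-ligand communication between skin cell types.

The package is aimed at epigenomics analysts who already have peak calls
and count matrices (eight sorted skin populations — CD4, CD8, DC, LC, EC,
Mac, Fib, KC — across normal, clinically unaffected and affected skin)
and want the downstream statistics as tested, seeded, reusable code. A
first-class synthetic-data generator emulates the whole study design with
machine-readable ground truth, so every stage is testable without any
sequencing data.

## What it computes

Let D be the N×M matrix of raw read counts over N merged peaks and M
samples. After quantile normalization (rank-mean, tie-averaging) and the
intensity transform I = log2(D_norm + 1):

- **Cell-type-specific peaks** — one-vs-rest Welch t-test on intensities
  with BH correction; a peak is specific at p < 0.005, log2FC > 2,
  inCov < 0.5 and outCov < 0.5 (coefficients of variation within the
  focal cell type and across the rest).
- **Six-state classification** — peaks differential between clinical
  states are assigned to patterns C1–C6 over {normal, unaffected,
  affected} when every in-pattern group mean exceeds every out-of-pattern
  mean by > 0.8 and within-group ranges stay < 1.5.
- **SNP deviation scores** — for a trait's SNP-bearing peaks,
  y = (O − E)/E per sample with E from the peak set's share of total
  mean accessibility, plus a z-score against accessibility-matched
  random peak sets; swept over association thresholds 0.05…1e-8.
- **Signature scores vs mRSS** — nearest-gene signatures of specific
  peaks, treatment-response genes removed, scored as mean expression and
  related to the modified Rodnan skin score by Pearson R (two-tailed t
  P-value) and by a paired Low/High-mRSS test.
- **TF footprints** — Tn5 cleavage positions (+4/−5 strand shift),
  seeded depth equalization, and per-offset mean insertion profiles
  around motif sites.
- **Motif module map** — hypergeometric enrichment/depletion of each
  motif in each peak set vs the universe, BH-corrected, as signed
  −log10(adjusted p).
- **Interaction alteration (SIA)** — per gene and cell type,
  AS = log2 fold change of summed peak intensity in affected vs normal;
  for a receptor/ligand pair across an ordered cell-type pair,

      SIA = 0                          if |AS_receptor| < 1 or |AS_ligand| < 1
          = AS_receptor + AS_ligand    otherwise,

  retaining |SIA| > 7 as up-/down-regulated communication.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic design (5,090 peaks × 48 samples, seed 20260928) and write
their tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_normalize_and_cluster.py
python analysis/03_specific_peaks.py
python analysis/09_communication.py
```

prints, among other things:

```
simulated 5090 peaks x 48 samples (8 cell types, 3 clinical states) ...
hierarchical clustering leaf order forms 8 cell-type blocks (8 would be a perfect grouping)
796 cell-type-specific peaks called ({'Mac': 100, 'CD8': 100, 'EC': 100, ...})
recovery vs planted truth: sensitivity 0.995, precision 1.000
5 interactions retained at |SIA| > 7 (3 up, 2 down)
planted switches recovered: 5/5
```

Reading: the 48 samples cluster perfectly by cell type on distal-peak
correlations; 796 of the 800 planted cell-type-specific peaks are
recovered with no false calls; and all five planted receptor-ligand
switches (three up-regulated in affected skin, two down-regulated) are
retained at the |SIA| > 7 threshold, with dendritic cells carrying the
most up-regulated interactions, as planted.

The same stages are exposed as a CLI (`sscatac normalize`,
`specific-peaks`, `six-state`, `snp-enrich`, `signature`, `footprint`,
`motif-enrich`, `communicate`, `simulate`) for use on your own files.

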