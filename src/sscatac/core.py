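"""Core data model for peak-by-sample accessibility analysis.

The backbone object is the :class:`AccessibilityMatrix`: an N x M matrix of
raw Tn5 read counts over N merged peaks and M samples, which is quantile
normalized across samples and then log2-transformed into "peak intensities".
All genomic coordinates are BED-style 0-based half-open internally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

logger = logging.getLogger(__name__)

STATES = ("normal", "unaffected", "affected")
DEFAULT_CELL_TYPES = ("CD4", "CD8", "DC", "LC", "EC", "Mac", "Fib", "KC")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need end > start >= 0"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    peak_id: str


class PeakSet:
    """Ordered collection of peaks with unique ids."""

    def __init__(self, peaks: list[Peak]):
        ids = [p.peak_id for p in peaks]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValueError(f"duplicate peak id: {dup}")
        self.peaks = list(peaks)
        self._index = {p.peak_id: p for p in self.peaks}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, peak_id: str) -> Peak:
        return self._index[peak_id]

    @property
    def ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.interval.chrom for p in self.peaks],
                "start": [p.interval.start for p in self.peaks],
                "end": [p.interval.end for p in self.peaks],
            },
            index=pd.Index(self.ids, name="peak_id"),
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


class AccessibilityMatrix:
    """Peak-by-sample count matrix with optional normalized/intensity layers.

    ``raw`` holds non-negative integer read counts; ``normalized`` is filled
    by :func:`quantile_normalize` and ``intensity`` (log2(normalized + 1))
    by :func:`intensity`.
    """

    def __init__(self, raw: pd.DataFrame, peaks: PeakSet | None = None):
        arr = raw.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("raw counts must be numeric")
        if np.any(arr < 0):
            raise ValueError("raw counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("raw counts must be integers")
        if raw.index.duplicated().any():
            dup = raw.index[raw.index.duplicated()][0]
            raise ValueError(f"duplicate peak id in matrix: {dup}")
        if raw.columns.duplicated().any():
            raise ValueError("duplicate sample id in matrix")
        if peaks is not None and list(raw.index) != peaks.ids:
            raise ValueError("matrix row ids do not match peak set")
        self.raw = raw.astype(np.int64)
        self.peaks = peaks
        self.normalized: pd.DataFrame | None = None
        self.intensity: pd.DataFrame | None = None

    @property
    def peak_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape


# ---------------------------------------------------------------------------
# I/O


def read_peaks_bed(path) -> PeakSet:
    """Read a BED3+/BED6 peak file; names default to ``chrom:start-end``."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") \
                else f"{chrom}:{start}-{end}"
            peaks.append(Peak(iv, name))
    logger.info("read %d peaks from %s", len(peaks), path)
    return PeakSet(peaks)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t{p.peak_id}\n")


def read_count_matrix(path, peaks: PeakSet | None = None) -> AccessibilityMatrix:
    """Read a TSV count matrix (first column peak ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = AccessibilityMatrix(df, peaks=peaks)
    logger.info("read count matrix %d peaks x %d samples from %s", *m.shape, path)
    return m


def write_matrix(matrix: AccessibilityMatrix, path, layer: str = "raw") -> None:
    df = getattr(matrix, layer)
    if df is None:
        raise ValueError(f"layer {layer!r} not computed")
    df.to_csv(path, sep="\t", index_label="peak_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV; requires sample_id, cell_type, state, donor_id."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_type", "state", "donor_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad = set(meta["state"]) - set(STATES)
    if bad:
        raise ValueError(f"unknown clinical state(s): {sorted(bad)}; allowed {STATES}")
    return meta.set_index("sample_id", drop=False)


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss"}
    if not required <= set(df.columns):
        raise ValueError(f"gene models need columns {sorted(required)}")
    strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        GeneModel(str(g), str(c), int(t), str(s))
        for g, c, t, s in zip(df["gene_id"], df["chrom"], df["tss"], strands)
    ]


def write_gene_models(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalization and transforms


def quantile_normalize(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    """Quantile-normalize columns (classic rank-mean algorithm).

    After the transform every sample shares the same sorted value vector: the
    per-rank mean of the sorted raw columns. Ties within a column receive the
    average of the tied ranks' reference values.
    """
    X = matrix.raw.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    # a value tied over ranks r..r+c-1 receives mean(reference[r..r+c-1])
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(X)
    for j in range(m):
        _, inv, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        block_mean = (ref_cum[starts + counts] - ref_cum[starts]) / counts
        out[:, j] = block_mean[inv]
    matrix.normalized = pd.DataFrame(out, index=matrix.raw.index, columns=matrix.raw.columns)
    return matrix


def intensity(matrix: AccessibilityMatrix) -> AccessibilityMatrix:
    """Fill the intensity layer: log2(normalized + 1)."""
    if matrix.normalized is None:
        raise ValueError("normalize before computing intensities")
    arr = matrix.normalized.to_numpy()
    if np.any(arr < 0):
        raise ValueError("normalized counts must be non-negative")
    matrix.intensity = pd.DataFrame(
        np.log2(arr + 1.0), index=matrix.normalized.index, columns=matrix.normalized.columns
    )
    return matrix


# ---------------------------------------------------------------------------
# Peak-gene annotation


def annotate_nearest_gene(peaks: PeakSet, gene_models: list[GeneModel]) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Distance is signed: peak center minus TSS. Ties break to the
    lexicographically smallest gene_id. Peaks on chromosomes without any
    gene get gene_id "NA" and NaN distance.

    Returns a frame indexed by peak_id with columns gene_id, distance.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in gene_models}:
        genes = [g for g in gene_models if g.chrom == chrom]
        # sort by (tss, gene_id) so equidistant ties resolve lexicographically
        genes.sort(key=lambda g: (g.tss, g.gene_id))
        by_chrom[chrom] = (
            np.array([g.tss for g in genes]),
            np.array([g.gene_id for g in genes], dtype=object),
        )
    gene_ids, distances = [], []
    for p in peaks:
        entry = by_chrom.get(p.interval.chrom)
        if entry is None:
            gene_ids.append("NA")
            distances.append(np.nan)
            continue
        tss, ids = entry
        c = p.interval.center
        j = np.searchsorted(tss, c)
        cand = [k for k in (j - 1, j) if 0 <= k < len(tss)]
        best = min(abs(c - tss[k]) for k in cand)
        # gather every gene at distance `best` (TSS may be duplicated)
        winners: list[int] = []
        for t in {c - best, c + best}:
            lo, hi = np.searchsorted(tss, t, "left"), np.searchsorted(tss, t, "right")
            winners.extend(range(lo, hi))
        k = min(winners, key=lambda k: ids[k])
        gene_ids.append(ids[k])
        distances.append(c - tss[k])
    return pd.DataFrame(
        {"gene_id": gene_ids, "distance": distances},
        index=pd.Index(peaks.ids, name="peak_id"),
    )


def classify_distal(
    peaks: PeakSet, gene_models: list[GeneModel], min_dist: int = 1000
) -> pd.Series:
    """Label each peak distal (|distance to nearest TSS| > min_dist) or proximal."""
    ann = annotate_nearest_gene(peaks, gene_models)
    labels = np.where(ann["distance"].abs() > min_dist, "distal", "proximal")
    labels = np.where(ann["distance"].isna(), "distal", labels)  # no gene: treat as distal
    return pd.Series(labels, index=ann.index, name="class")


def gene_accessibility(matrix: AccessibilityMatrix, annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene-level accessibility: per sample, sum of intensities of the peaks
    imputed to each gene. Genes with no assigned peak are absent."""
    if matrix.intensity is None:
        raise ValueError("intensity layer required")
    ann = annotation.loc[matrix.intensity.index]
    keep = ann["gene_id"] != "NA"
    return matrix.intensity.loc[keep].groupby(ann.loc[keep, "gene_id"]).sum()


# ---------------------------------------------------------------------------
# Sample correlation / clustering


def sample_correlation(
    matrix: AccessibilityMatrix, peak_subset: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between samples over a peak subset, plus the leaf
    order of average-linkage hierarchical clustering on 1 - r distance."""
    if matrix.intensity is None:
        raise ValueError("intensity layer required")
    sub = matrix.intensity if peak_subset is None else matrix.intensity.loc[peak_subset]
    if len(sub) < 2:
        raise ValueError("need >= 2 peaks for sample correlation")
    X = sub.to_numpy()
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance sample(s); correlations set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X.T)
    corr_df = pd.DataFrame(corr, index=sub.columns, columns=sub.columns)
    dist = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    order = [sub.columns[i] for i in sch.leaves_list(Z)]
    return corr_df, order
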