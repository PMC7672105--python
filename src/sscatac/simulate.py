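"""Seeded synthetic-data generators for every pipeline input.

The generators emulate a multi-cell-type skin ATAC-seq study on a synthetic
single-chromosome coordinate space: a peak-by-sample count matrix with
planted cell-type-specific and clinical-state-specific peaks, a trait-SNP
catalog with a planted cell-type enrichment, an expression/mRSS cohort with
a planted signature-score correlation and treatment-response genes, Tn5
insertion tracks with planted footprint protection, and a ligand-receptor
table whose planted pairs are engineered to exceed the interaction-
alteration threshold. Every generator is a pure function of its
configuration (seed included) and records machine-readable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CELL_TYPES,
    STATES,
    AccessibilityMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
)
from .footprint import InsertionSet

CHROM = "chrS"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-scale defaults.

    The default design is 8 cell types x 3 clinical states x 2 replicates
    (48 samples) over ~5,000 peaks, 100 planted specific peaks per cell
    type at +4 log2 intensity units, and 100 planted peaks per six-state
    cluster pattern at a 3-unit gap in the fibroblast compartment.
    """

    seed: int = 0
    # accessibility matrix
    n_peaks: int = 5000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    replicates: dict[str, int] = field(
        default_factory=lambda: {"normal": 2, "unaffected": 2, "affected": 2}
    )
    n_specific_per_type: int = 100
    specific_effect: float = 4.0
    noise_sd: float = 0.2
    dispersion: float = 0.01
    base_log2_mean_range: tuple[float, float] = (5.0, 10.0)
    peak_width: int = 500
    peak_spacing: int = 2000
    n_genes: int = 1000
    # six-state planted peaks
    state_peaks_per_cluster: int = 100
    state_gap: float = 3.0
    state_target_cell_type: str = "Fib"
    # trait-SNP catalog
    n_traits: int = 5
    snps_per_trait: int = 300
    trait_target: str = "planted_trait"
    trait_target_cell_type: str = "CD4"
    enrichment_odds: float = 20.0
    assoc_log10p_range: tuple[float, float] = (-12.0, np.log10(0.05))
    # ligand-receptor communication
    lr_pairs_total: int = 30
    lr_planted_up: tuple[tuple[str, str], ...] = (("DC", "CD4"), ("DC", "Fib"), ("DC", "CD8"))
    lr_planted_down: tuple[tuple[str, str], ...] = (("Fib", "KC"), ("EC", "Mac"))
    lr_peaks_per_gene: int = 6
    lr_low_log2: float = -6.0
    lr_high_log2: float = 12.0
    # constitutively silent peaks anchoring the bottom of the count
    # distribution, so the quantile reference at low ranks stays near zero
    # regardless of how many planted LR peaks are silent in a given sample
    n_padding_peaks: int = 100
    # expression / clinical cohort
    n_patients: int = 30
    n_arrays: int = 105
    mrss_rho: float = 0.4
    expr_target_cell_type: str = "Fib"
    n_response_genes: int = 20
    response_shift: float = 5.0
    expr_noise_sd: float = 0.5
    signature_gene_noise_sd: float = 0.1
    paired_delta: float = 0.0
    # footprinting
    fp_n_sites: int = 200
    fp_motif_len: int = 20
    fp_rate: float = 0.2
    fp_flank_factor: float = 1.5
    fp_halfwidth: int = 50

    def __post_init__(self) -> None:
        if not -1 < self.mrss_rho < 1:
            raise ValueError("mrss_rho must lie in (-1, 1)")
        planted = (
            self.n_specific_per_type * len(self.cell_types)
            + self.state_peaks_per_cluster * 6
        )
        if planted > self.n_peaks:
            raise ValueError(
                f"{planted} planted peaks exceed n_peaks={self.n_peaks}"
            )

    @property
    def genome_length(self) -> int:
        return self.n_peaks * self.peak_spacing

    @property
    def gene_spacing(self) -> int:
        return self.genome_length // self.n_genes


@dataclass
class GroundTruth:
    """Planted structure of a simulation, sufficient for recovery metrics."""

    specific_peaks: dict[str, str] = field(default_factory=dict)   # peak_id -> cell type
    state_peaks: dict[str, str] = field(default_factory=dict)      # peak_id -> cluster
    trait_target: str = ""
    trait_target_cell_type: str = ""
    lr_interactions: list[dict] = field(default_factory=list)
    lr_genes: dict[str, str] = field(default_factory=dict)         # gene -> cell type
    response_genes: list[str] = field(default_factory=list)
    expr_target_cell_type: str = ""
    signature_genes: dict[str, list[str]] = field(default_factory=dict)
    protected_groups: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


SIX_STATE_PATTERNS = {
    "C1": ("normal",),
    "C2": ("normal", "unaffected"),
    "C3": ("unaffected",),
    "C4": ("unaffected", "affected"),
    "C5": ("affected",),
    "C6": ("normal", "affected"),
}


@dataclass
class SimulatedStudy:
    peaks: PeakSet
    counts: pd.DataFrame            # raw counts, peaks x samples
    meta: pd.DataFrame              # indexed by sample_id
    genes: list[GeneModel]
    truth: GroundTruth

    @property
    def matrix(self) -> AccessibilityMatrix:
        return AccessibilityMatrix(self.counts, peaks=self.peaks)


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for ct in config.cell_types:
        for state, n_rep in config.replicates.items():
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            for r in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{ct}_{state}_{r}",
                        "cell_type": ct,
                        "state": state,
                        "donor_id": f"{state}_donor_{r}",
                    }
                )
    meta = pd.DataFrame(rows)
    return meta.set_index("sample_id", drop=False)


def simulate_accessibility(config: SimulationConfig) -> SimulatedStudy:
    """Simulate the peak universe, raw count matrix and sample metadata.

    Counts follow a gamma-Poisson (negative binomial) around per-peak
    baseline means, with planted effects applied as log2 offsets: specific
    peaks gain ``specific_effect`` in the focal cell type, six-state peaks
    gain ``state_gap`` in the in-pattern states of the target cell type,
    and ligand/receptor peaks of planted communication pairs are switched
    between near-zero and high accessibility in the designated cell type's
    affected (up) or normal (down) samples.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    samples = list(meta.index)

    # gene models on a regular TSS grid
    genes = [
        GeneModel(f"G{j:04d}", CHROM, j * config.gene_spacing, "+")
        for j in range(config.n_genes)
    ]

    # reserve genes for planted ligand/receptor partners (drawn from the
    # tail of the grid, spaced apart); their neighborhoods get no regular
    # peaks so their accessibility is fully controlled
    lr_specs = [(s, r, "up") for s, r in config.lr_planted_up] + [
        (s, r, "down") for s, r in config.lr_planted_down
    ]
    n_lr_genes = 2 * len(lr_specs)
    lr_gene_idx = [config.n_genes - 2 * (k + 1) for k in range(n_lr_genes)]
    lr_gene_ids = [genes[j].gene_id for j in lr_gene_idx]
    # the half-spacing boundary ties to the reserved gene under the
    # lexicographic rule, so pad the exclusion zone by one peak spacing
    pad = config.gene_spacing // 2 + config.peak_spacing
    forbidden = [(genes[j].tss - pad, genes[j].tss + pad) for j in lr_gene_idx]

    # regular peak tiling, skipping planted-gene neighborhoods
    half_w = config.peak_width // 2
    centers, ids = [], []
    for i in range(config.n_peaks):
        c = i * config.peak_spacing + config.peak_spacing // 2
        if any(lo <= c < hi for lo, hi in forbidden):
            continue
        centers.append(c)
        ids.append(f"peak_{i:05d}")
    peaks_list = [
        Peak(GenomicInterval(CHROM, c - half_w, c + half_w), pid)
        for c, pid in zip(centers, ids)
    ]

    # dedicated peaks for planted LR genes, clustered at the gene TSS
    lr_peak_rows: dict[str, list[int]] = {}
    offsets = np.arange(config.lr_peaks_per_gene) * (config.peak_width + 50)
    for gid, j in zip(lr_gene_ids, lr_gene_idx):
        tss = genes[j].tss
        rows = []
        for k, off in enumerate(offsets):
            start = tss + 100 + int(off)
            rows.append(len(peaks_list))
            peaks_list.append(
                Peak(
                    GenomicInterval(CHROM, start, start + config.peak_width),
                    f"lrpeak_{gid}_{k}",
                )
            )
        lr_peak_rows[gid] = rows
    # silent padding peaks in otherwise unused tiling slots
    pad_rows = []
    for i in range(config.n_padding_peaks):
            start = i * config.peak_spacing + config.peak_spacing - config.peak_width
            pad_rows.append(len(peaks_list))
            peaks_list.append(
                Peak(GenomicInterval(CHROM, start, start + config.peak_width), f"padpeak_{i:03d}")
            )
    peaks = PeakSet(peaks_list)
    n_total = len(peaks)

    # baseline means (log2) and planted log2 offsets
    base_log2 = rng.uniform(*config.base_log2_mean_range, size=n_total)
    lr_rows_all = [r for rows in lr_peak_rows.values() for r in rows] + pad_rows
    base_log2[lr_rows_all] = config.lr_low_log2  # near-silent unless switched on
    delta = np.zeros((n_total, len(samples)))
    truth = GroundTruth(
        trait_target=config.trait_target,
        trait_target_cell_type=config.trait_target_cell_type,
        expr_target_cell_type=config.expr_target_cell_type,
    )

    lr_rows_set = set(lr_rows_all)
    regular_rows = [i for i in range(n_total) if i not in lr_rows_set]
    perm = rng.permutation(len(regular_rows))
    cursor = 0

    col_of = {s: k for k, s in enumerate(samples)}
    # planted cell-type-specific peaks
    for ct in config.cell_types:
        take = [regular_rows[perm[cursor + k]] for k in range(config.n_specific_per_type)]
        cursor += config.n_specific_per_type
        cols = [col_of[s] for s in meta.index[meta["cell_type"] == ct]]
        for r in take:
            delta[r, cols] += config.specific_effect
            truth.specific_peaks[peaks.peaks[r].peak_id] = ct

    # planted six-state cluster peaks in the target cell type
    tgt = config.state_target_cell_type
    for cluster, states in SIX_STATE_PATTERNS.items():
        take = [
            regular_rows[perm[cursor + k]] for k in range(config.state_peaks_per_cluster)
        ]
        cursor += config.state_peaks_per_cluster
        cols = [
            col_of[s]
            for s in meta.index[
                (meta["cell_type"] == tgt) & meta["state"].isin(states)
            ]
        ]
        for r in take:
            delta[r, cols] += config.state_gap
            truth.state_peaks[peaks.peaks[r].peak_id] = cluster

    # planted ligand/receptor switches
    gene_iter = iter(lr_gene_ids)
    for sender, receiver, direction in lr_specs:
        ligand, receptor = next(gene_iter), next(gene_iter)
        for gid, ct in ((ligand, sender), (receptor, receiver)):
            state = "affected" if direction == "up" else "normal"
            cols = [
                col_of[s]
                for s in meta.index[
                    (meta["cell_type"] == ct) & (meta["state"] == state)
                ]
            ]
            for r in lr_peak_rows[gid]:
                delta[r, cols] += config.lr_high_log2 - config.lr_low_log2
            truth.lr_genes[gid] = ct
        truth.lr_interactions.append(
            {
                "sender": sender,
                "receiver": receiver,
                "ligand": ligand,
                "receptor": receptor,
                "direction": direction,
            }
        )

    # gamma-Poisson counts around mean * 2^(delta + noise)
    noise = rng.normal(0.0, config.noise_sd, size=delta.shape)
    lam = 2 ** (base_log2[:, None] + delta + noise)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(peaks.ids, name="peak_id"), columns=samples)
    return SimulatedStudy(peaks, counts_df, meta, genes, truth)


# ---------------------------------------------------------------------------
# trait-SNP catalog


def simulate_snp_catalog(study: SimulatedStudy, config: SimulationConfig) -> pd.DataFrame:
    """Simulate a GRASP-like trait-SNP catalog (1-based positions).

    Background traits place SNPs uniformly on the genome; the planted
    trait's SNPs fall inside the target cell type's specific peaks with
    odds ``enrichment_odds`` relative to a uniform draw.
    """
    rng = np.random.default_rng(config.seed + 1)
    target_peaks = [
        study.peaks[pid].interval
        for pid, ct in study.truth.specific_peaks.items()
        if ct == config.trait_target_cell_type
    ]
    if not target_peaks:
        raise ValueError("no specific peaks for the trait's target cell type")
    L = config.genome_length
    covered = sum(iv.end - iv.start for iv in target_peaks)
    q = covered / L
    p_in = config.enrichment_odds * q / (config.enrichment_odds * q + (1 - q))

    traits = [config.trait_target] + [
        f"background_trait_{k}" for k in range(1, config.n_traits)
    ]
    rows = []
    lo, hi = config.assoc_log10p_range
    for trait in traits:
        for _ in range(config.snps_per_trait):
            if trait == config.trait_target and rng.random() < p_in:
                iv = target_peaks[rng.integers(len(target_peaks))]
                pos0 = int(rng.integers(iv.start, iv.end))
            else:
                pos0 = int(rng.integers(0, L))
            rows.append(
                {
                    "trait": trait,
                    "chrom": CHROM,
                    "pos": pos0 + 1,
                    "p": float(10 ** rng.uniform(lo, hi)),
                }
            )
    df = pd.DataFrame(rows)
    df["pos0"] = df["pos"] - 1
    return df


# ---------------------------------------------------------------------------
# expression / clinical cohort


def simulate_expression_clinical(
    gene_sets: dict[str, set[str]],
    config: SimulationConfig,
    all_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a treated-cohort expression matrix and clinical table.

    The target cell type's signature genes share a latent component
    correlated with mRSS at ``mrss_rho``; planted treatment-response genes
    are shifted on treated arrays; with ``paired_delta`` > 0 the target
    genes additionally gain a shift on each patient's highest-mRSS array.
    Returns (expression, clinical, response_genes).
    """
    rng = np.random.default_rng(config.seed + 2)
    if all_genes is None:
        all_genes = sorted({g for s in gene_sets.values() for g in s})
    # arrays: first patients get an extra timepoint until n_arrays is reached
    base_tp = 3
    extra = config.n_arrays - config.n_patients * base_tp
    if extra < 0 or extra > config.n_patients:
        raise ValueError("n_arrays must lie in [3, 4] timepoints per patient")
    rows = []
    for p in range(config.n_patients):
        n_tp = base_tp + (1 if p < extra else 0)
        mrss = max(0.0, rng.uniform(5, 35))
        for t in range(n_tp):
            rows.append(
                {
                    "array_id": f"A{p:02d}_{t}",
                    "patient_id": f"P{p:02d}",
                    "timepoint": f"T{t}",
                    "mrss": round(max(0.0, mrss), 1),
                    "phase": "baseline" if t == 0 else "treated",
                }
            )
            mrss += rng.normal(0, 4)
    clinical = pd.DataFrame(rows).set_index("array_id", drop=False)
    n_arr = len(clinical)

    mrss_v = clinical["mrss"].to_numpy(dtype=float)
    z = (mrss_v - mrss_v.mean()) / mrss_v.std()
    shared = config.mrss_rho * z + np.sqrt(1 - config.mrss_rho**2) * rng.normal(size=n_arr)

    # couple only genes exclusive to the target signature, so the planted
    # association cannot leak into other cell types via shared nearest genes
    target_set = set(gene_sets.get(config.expr_target_cell_type, set()))
    for ct, genes in gene_sets.items():
        if ct != config.expr_target_cell_type:
            target_set -= set(genes)
    expr = pd.DataFrame(
        5.0 + rng.normal(0, config.expr_noise_sd, size=(len(all_genes), n_arr)),
        index=pd.Index(all_genes, name="gene_id"),
        columns=clinical.index,
    )
    tgt_genes = [g for g in all_genes if g in target_set]
    if tgt_genes:
        expr.loc[tgt_genes] = (
            5.0
            + shared[None, :]
            + rng.normal(0, config.signature_gene_noise_sd, size=(len(tgt_genes), n_arr))
        )
    if config.paired_delta > 0 and tgt_genes:
        for _, grp in clinical.groupby("patient_id"):
            grp = grp.sort_values("timepoint", kind="stable")
            hi_array = grp.iloc[int(np.argmax(grp["mrss"].to_numpy()))]["array_id"]
            expr.loc[tgt_genes, hi_array] += config.paired_delta

    # treatment-response genes, drawn outside the target signature
    candidates = [g for g in all_genes if g not in target_set]
    response = sorted(
        rng.choice(candidates, size=min(config.n_response_genes, len(candidates)), replace=False)
    )
    treated = clinical.index[clinical["phase"] == "treated"]
    expr.loc[response, treated] += config.response_shift
    return expr, clinical, list(response)


# ---------------------------------------------------------------------------
# footprinting


def simulate_motif_sites(config: SimulationConfig, motif_id: str = "MOTIF1") -> pd.DataFrame:
    """Equal-length motif sites on a regular grid with alternating strand."""
    rng = np.random.default_rng(config.seed + 3)
    spacing = 4 * config.fp_halfwidth
    starts = np.arange(config.fp_n_sites) * spacing + 1000
    strands = np.where(rng.random(config.fp_n_sites) < 0.5, "+", "-")
    return pd.DataFrame(
        {
            "chrom": CHROM,
            "start": starts,
            "end": starts + config.fp_motif_len,
            "motif_id": motif_id,
            "score": 0,
            "strand": strands,
        }
    )


def simulate_insertions(
    motif_sites: pd.DataFrame,
    protection_by_group: dict[str, float],
    config: SimulationConfig,
) -> dict[str, InsertionSet]:
    """Poisson Tn5 insertions around motif sites per sample group.

    Insertion rate is ``fp_rate * fp_flank_factor`` per bp in the flanks
    and ``fp_rate * protection`` inside the motif; protection 1.0 with
    flank factor 1.0 yields a flat profile.
    """
    rng = np.random.default_rng(config.seed + 4)
    w = config.fp_halfwidth
    out = {}
    for group, protection in protection_by_group.items():
        chroms, positions = [], []
        for _, site in motif_sites.iterrows():
            center = (int(site["start"]) + int(site["end"])) // 2
            for pos in range(center - w, center + w + 1):
                inside = site["start"] <= pos < site["end"]
                factor = protection if inside else (
                    config.fp_flank_factor if protection != 1.0 else 1.0
                )
                k = rng.poisson(config.fp_rate * factor)
                if k:
                    chroms.extend([CHROM] * k)
                    positions.extend([pos] * k)
        out[group] = InsertionSet(
            np.array(chroms, dtype=object), np.array(positions, dtype=np.int64), group=group
        )
    return out


# ---------------------------------------------------------------------------
# ligand-receptor table and motif hits


def simulate_lr_pairs(study: SimulatedStudy, config: SimulationConfig) -> pd.DataFrame:
    """LR table: the planted pairs plus background pairs of unperturbed genes."""
    rng = np.random.default_rng(config.seed + 5)
    rows = [
        {"ligand": rec["ligand"], "receptor": rec["receptor"], "source": "planted"}
        for rec in study.truth.lr_interactions
    ]
    planted_genes = {r["ligand"] for r in rows} | {r["receptor"] for r in rows}
    pool = [g.gene_id for g in study.genes if g.gene_id not in planted_genes]
    seen = {(r["ligand"], r["receptor"]) for r in rows}
    while len(rows) < config.lr_pairs_total:
        lig, rec = rng.choice(pool, size=2, replace=False)
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        rows.append({"ligand": lig, "receptor": rec, "source": "background"})
    return pd.DataFrame(rows)


def simulate_motif_hits(
    study: SimulatedStudy,
    config: SimulationConfig,
    planted_motif: str = "MOTIF_X",
    planted_cell_type: str = "CD4",
    n_background_motifs: int = 4,
    hit_fraction: float = 0.1,
    planted_fraction: float = 0.8,
) -> pd.DataFrame:
    """Motif hit locations: background motifs hit peaks uniformly, the
    planted motif concentrates in one cell type's specific peaks."""
    rng = np.random.default_rng(config.seed + 6)
    rows = []
    peak_list = study.peaks.peaks
    specific = [
        study.peaks[pid] for pid, ct in study.truth.specific_peaks.items()
        if ct == planted_cell_type
    ]
    for m in range(n_background_motifs):
        take = rng.random(len(peak_list)) < hit_fraction
        for p, t in zip(peak_list, take):
            if t:
                c = p.interval.center
                rows.append((p.interval.chrom, c - 5, c + 5, f"MOTIF_BG{m}"))
    for p in specific:
        if rng.random() < planted_fraction:
            c = p.interval.center
            rows.append((p.interval.chrom, c - 5, c + 5, planted_motif))
    # sprinkle the planted motif thinly outside its home set
    others = [p for p in peak_list if p.peak_id not in study.truth.specific_peaks]
    for p in others:
        if rng.random() < hit_fraction / 2:
            c = p.interval.center
            rows.append((p.interval.chrom, c - 5, c + 5, planted_motif))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "motif_id"])
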