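"""Quantile-normalize the count matrix and cluster samples.

Fills the normalized and intensity layers, classifies peaks as distal or
proximal to their nearest TSS, and checks that unsupervised clustering of
sample-sample Pearson correlations over distal peaks groups samples by
cell type.
"""

from pathlib import Path

import pandas as pd

from sscatac import core

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    peaks = core.read_peaks_bed(BASE / "sim" / "peaks.bed")
    matrix = core.read_count_matrix(BASE / "sim" / "counts.tsv", peaks=peaks)
    meta = core.read_metadata(BASE / "sim" / "metadata.tsv")
    genes = core.read_gene_models(BASE / "sim" / "genes.tsv")

    core.intensity(core.quantile_normalize(matrix))
    core.write_matrix(matrix, BASE / "intensity.tsv", layer="intensity")

    distal = core.classify_distal(peaks, genes, min_dist=1000)
    distal.to_frame().to_csv(BASE / "distal_class.tsv", sep="\t")
    distal_ids = list(distal.index[distal == "distal"])

    corr, order = core.sample_correlation(matrix, distal_ids)
    corr.to_csv(BASE / "sample_correlation.tsv", sep="\t")
    pd.Series(order, name="sample_id").to_csv(BASE / "cluster_leaf_order.tsv",
                                              sep="\t", index=False)

    # how well does the leaf order group samples of the same cell type?
    cts = [meta.loc[s, "cell_type"] for s in order]
    blocks = sum(1 for a, b in zip(cts, cts[1:]) if a != b) + 1
    print(f"{len(distal_ids)} distal peaks (> 1 kb from the nearest TSS) "
          f"of {len(peaks)} total")
    print(f"hierarchical clustering leaf order forms {blocks} cell-type blocks "
          f"({meta['cell_type'].nunique()} would be a perfect grouping)")


if __name__ == "__main__":
    main()
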