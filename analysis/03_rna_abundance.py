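#!/usr/bin/env python
"""Estimate immune-cell abundances from the bulk RNA-seq counts.

log2(CPM+1)-normalizes the gene x sample count matrix and averages each
immune feature's marker genes (CD8 -> CD8A/CD8B, TLS -> the
CCL19/CCL21/CXCL13 chemokine signature, ...).
"""

from pathlib import Path

from timehom import io as tio
from timehom import default_gene_sets, gene_set_abundance, normalize_counts

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    counts = tio.read_expression(ROOT / "cohort" / "expression.tsv")
    normalized = normalize_counts(counts, method="log2cpm")
    ab = gene_set_abundance(normalized, default_gene_sets(), normalization="log2cpm")
    tio.write_abundance(ab.data, ROOT / "abundance.tsv")
    print(f"abundance matrix: {len(ab.features)} features x {len(ab.samples)} samples")
    tumor = ab.data[[c for c in ab.data.columns if not c.endswith("_P")]]
    order = tumor.mean(axis=1).sort_values(ascending=False)
    print("mean abundance ranking (tumor samples):")
    for feat, val in order.items():
        print(f"  {feat:6s} {val:6.2f}")


if __name__ == "__main__":
    main()
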