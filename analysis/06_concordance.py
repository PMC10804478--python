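#!/usr/bin/env python
"""Concordance between the IHC and RNA-seq views of the TIME.

Per-marker Spearman correlation across the T1/T3/T5 samples present in
both modalities, and tumor-level agreement of the homogeneity
classifications.
"""

import json
from pathlib import Path

from timehom import io as tio
from timehom import (
    DEFAULT_PANEL,
    analyze_cohort,
    assemble_features,
    modality_concordance,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = tio.read_regional_samples(ROOT / "regional_samples.tsv")
    ab = tio.read_abundance(ROOT / "abundance.tsv")
    X_ihc = assemble_features(samples, DEFAULT_PANEL, source="ihc")
    X_rna = assemble_features(ab, DEFAULT_PANEL, source="rna")
    res_ihc = analyze_cohort(X_ihc, lomo=False)
    res_rna = analyze_cohort(X_rna, lomo=False)
    rep = modality_concordance(X_ihc, X_rna, res_ihc, res_rna)
    with open(ROOT / "concordance.json", "w") as fh:
        json.dump(rep, fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"matched samples: {rep['n_matched_samples']}")
    print(f"median per-marker Spearman rho (IHC vs RNA): {rep['median_rho']:.2f}")
    for feat, v in sorted(rep["per_feature"].items(), key=lambda kv: -kv[1]["rho"]):
        print(f"  {feat:6s} rho={v['rho']:5.2f} p={v['p_value']:.3g}")
    agree = rep["classification_agreement"]
    print(f"classification agreement: {agree['agreement_fraction']:.0%} "
          f"of {agree['n_tumors']} tumors; table {agree['table']}")


if __name__ == "__main__":
    main()
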