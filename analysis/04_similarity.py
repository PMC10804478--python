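#!/usr/bin/env python
"""Mahalanobis-distance similarity of the TIME across tumor regions.

For each tumor, squared Mahalanobis distances of its regions to the tumor
centroid (pooled, jackknifed within-tumor covariance; distances
F-calibrated to the chi-square scale) are compared to the critical value
22 = rounded chi2_{0.99}(9).  Heterogeneous tumors get leave-one-marker-
out driver attribution.  Run on the IHC densities and, separately, on the
RNA-seq abundances.
"""

import json
from pathlib import Path

from timehom import io as tio
from timehom import DEFAULT_PANEL, analyze_cohort, assemble_features, cohort_summary

ROOT = Path(__file__).resolve().parents[1] / "results"


def report(source: str, results) -> None:
    summ = cohort_summary(results)
    print(f"[{source}] {summ['n_homogeneous']}/{summ['n_tumors']} tumors homogeneous "
          f"({100 * summ['frac_homogeneous']:.0f}%), "
          f"{summ['n_range_narrow']} narrow-range")
    for r in results:
        if not r.homogeneous:
            tag = "no single-marker fix" if r.irreducible else f"drivers {r.driver_markers}"
            print(f"  {r.tumor_id}: max d2 {r.max_distance:.1f} > 22; {tag}")


def main() -> None:
    samples = tio.read_regional_samples(ROOT / "regional_samples.tsv")
    ab = tio.read_abundance(ROOT / "abundance.tsv")
    out = {}
    for source, data in (("ihc", samples), ("rna", ab)):
        X = assemble_features(data, DEFAULT_PANEL, source=source)
        results = analyze_cohort(X)
        out[source] = [r.to_dict() for r in results]
        report(source, results)
    with open(ROOT / "similarity.json", "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"wrote {ROOT / 'similarity.json'}")


if __name__ == "__main__":
    main()
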