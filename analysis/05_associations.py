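#!/usr/bin/env python
"""Immune features vs clinicopathology; TLS and PD-L1 stratification.

Rank-sum comparisons across sex, multiplicity, diagnosis, pathological
type and an age median split, Spearman correlations against diameter and
age, and section-level comparisons of marker densities between TLS+/TLS-
and PD-L1+/PD-L1- sections.
"""

from pathlib import Path

import pandas as pd

from timehom import io as tio
from timehom import DEFAULT_PANEL, association_screen, tls_stratified_compare

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = tio.read_regional_samples(ROOT / "regional_samples.tsv")
    clin = tio.read_clinicopath(ROOT / "cohort" / "clinicopath.csv")
    feats = samples[["tumor_id"]].copy()
    for m in DEFAULT_PANEL.markers:
        feats[m] = samples[f"{m}_density"]
    feats["TLS"] = samples["tls_count"]
    screen = association_screen(feats, clin)
    screen.to_csv(ROOT / "associations.tsv", sep="\t", index=False)
    sig = screen.query("computable and p_value < 0.05")
    print(f"{len(sig)}/{len(screen)} associations with raw p < 0.05:")
    for _, row in sig.sort_values("p_value").head(10).iterrows():
        print(f"  {row['feature']:6s} vs {row['covariate']:12s} "
              f"{row['kind']:9s} stat={row['statistic']:8.3f} p={row['p_value']:.4f}")

    frames = []
    for strat in ("tls", "pdl1"):
        cmp = tls_stratified_compare(samples, DEFAULT_PANEL.markers, stratify_by=strat)
        frames.append(cmp.assign(stratification=strat))
        up = cmp.query("computable and p_value < 0.05")
        print(f"{strat.upper()} stratification: {len(up)} markers differ at p<0.05 "
              f"({', '.join(up['feature']) or 'none'})")
    pd.concat(frames).to_csv(ROOT / "stratified_comparisons.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
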