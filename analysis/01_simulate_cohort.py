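#!/usr/bin/env python
"""Generate the synthetic multiregion study cohort.

Emulates the study design: 10 tumors sampled at T1 (centre) .. T5
(periphery), 8 IHC markers counted in 10 high-power fields per section,
TLS counts, RNA-seq at T1/T3/T5 plus one paratumor sample per tumor, and
a clinicopathological table.  Writes the fixture under results/cohort/
and prints the planted ground truth.
"""

from pathlib import Path

from timehom import SimConfig, simulate_cohort, write_fixture

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    bundle = simulate_cohort(cfg)
    paths = write_fixture(bundle, OUT)
    het = [t for t, h in bundle.truth.heterogeneous.items() if h]
    print(f"cohort: {cfg.n_tumors} tumors x {len(cfg.regions)} regions (seed {SEED})")
    print(f"planted heterogeneous tumors: {het or 'none'}")
    for t in het:
        print(f"  {t}: drivers {bundle.truth.driver_markers[t]}")
    print(f"TLS structures in cohort: {int(bundle.tls['tls_count'].sum())}")
    for name, p in paths.items():
        print(f"wrote {name}: {p}")


if __name__ == "__main__":
    main()
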