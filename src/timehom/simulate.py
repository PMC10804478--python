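"""Synthetic multiregion cohort generator with known ground truth.

Emulates the study design the pipeline was built for: N tumors, each
sampled at five sites (T1 centre ... T5 periphery) along the long axis,
with eight IHC markers counted in 10 high-power fields per section, TLS
counts per section, coupled bulk RNA-seq marker expression at T1/T3/T5
(plus one paratumor sample per tumor), and a clinicopathological table.

Model
-----
* Tumor-level log density per marker: baseline + between-tumor normal
  effect + clinicopathological covariate effects (diameter, multiplicity,
  sex, age) on the log scale.
* Region-level biological variation: log-normal with coefficient of
  variation ``within_tumor_cv`` around the tumor level.
* Heterogeneous tumors (fraction ``prop_heterogeneous``) receive, for
  ``n_driver_markers`` randomly chosen driver markers, a mean-centred
  linear log-density ramp across the T1..T5 axis whose extremes sit at
  -/+ ``driver_effect`` pooled within-tumor SDs from the tumor mean
  (centre-to-periphery growth geometry).  The SD unit is the total
  within-tumor log SD including the Poisson counting-noise contribution,
  so the planted effect is calibrated against the noise the downstream
  Mahalanobis analysis sees.
* IHC: field-level positive counts are Poisson(density x field area),
  capped at the number of assessed cells.
* TLS: Poisson per section, rate tls_rate scaled by exp(tls_coupling x
  mean standardized CD4/CD8/CD68 log-density deviation) so TLS co-varies
  with the cellular infiltrate.
* RNA-seq: marker-gene counts negative-binomial around
  exp(intercept + slope x log density + noise) times a log-normal library
  factor; filler genes i.i.d.; paratumor samples at a shifted baseline.

Identical configuration (including seed) reproduces byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MarkerPanel, DEFAULT_PANEL
from .rna import default_gene_sets

DEFAULT_REGIONS = ("T1", "T2", "T3", "T4", "T5")
DEFAULT_RNA_REGIONS = ("T1", "T3", "T5")

#: Baseline log densities (log positive cells/mm^2), ordered from the most
#: to the least abundant population seen in dedifferentiated liposarcoma:
#: CD4 T cells most common, then CD68 macrophages and PD-1+ cells; Foxp3
#: Tregs rarest, then CD8 T cells and PD-L1+ cells.
DEFAULT_BASELINE_LOG_DENSITY = {
    "CD4": np.log(120.0),
    "CD8": np.log(15.0),
    "Foxp3": np.log(5.0),
    "CD20": np.log(30.0),
    "CD68": np.log(80.0),
    "LAMP3": np.log(20.0),
    "PD-1": np.log(60.0),
    "PD-L1": np.log(8.0),
}


@dataclass(frozen=True)
class RnaCoupling:
    """Link from log IHC density to marker-gene log expression."""

    slope: float = 1.0
    intercept: float = 3.0
    noise_sd: float = 0.25
    dispersion: float = 0.1


@dataclass(frozen=True)
class CovariateEffects:
    """Signed log-scale effects of clinical covariates on densities."""

    diameter: float = -0.03  # per cm
    multiple: float = -0.35  # multiple vs single tumors
    female: float = 0.35  # female vs male
    age: float = 0.015  # per year, centred at 58


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    n_tumors: int = 10
    regions: tuple[str, ...] = DEFAULT_REGIONS
    panel: MarkerPanel = DEFAULT_PANEL
    prop_heterogeneous: float = 0.2
    n_driver_markers: int = 2
    driver_effect: float = 3.0
    baseline_log_density_mean: dict[str, float] | None = None
    between_tumor_sd: float = 0.5
    within_tumor_cv: float = 0.15
    fields_per_section: int = 10
    cells_per_field: int = 100
    field_area: float = 0.0788
    tls_rate: float = 1.1
    tls_coupling: float = 0.8
    rna_regions: tuple[str, ...] = DEFAULT_RNA_REGIONS
    rnaseq_coupling: RnaCoupling = RnaCoupling()
    covariate_effects: CovariateEffects = CovariateEffects()
    n_filler_genes: int = 400
    library_sd: float = 0.2
    paratumor_shift: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        if len(self.regions) < 2:
            raise ValueError("need at least two regions")
        if not 0.0 <= self.prop_heterogeneous <= 1.0:
            raise ValueError("prop_heterogeneous must lie in [0, 1]")
        if self.n_driver_markers < 1:
            raise ValueError("n_driver_markers must be >= 1")
        if self.within_tumor_cv < 0:
            raise ValueError("within_tumor_cv must be non-negative")
        if self.field_area <= 0 or self.fields_per_section <= 0 or self.cells_per_field <= 0:
            raise ValueError("field geometry must be positive")
        if self.between_tumor_sd <= 0:
            raise ValueError("between_tumor_sd must be positive")
        unknown = [r for r in self.rna_regions if r not in self.regions]
        if unknown:
            raise ValueError(f"rna_regions not in regions: {unknown}")

    @property
    def baselines(self) -> dict[str, float]:
        base = self.baseline_log_density_mean or DEFAULT_BASELINE_LOG_DENSITY
        missing = [m for m in self.panel.markers if m not in base]
        if missing:
            raise ValueError(f"no baseline log density for marker(s): {missing}")
        return {m: float(base[m]) for m in self.panel.markers}

    def pooled_log_sd(self, marker: str) -> float:
        """Total within-tumor log-density SD: biological CV plus the
        delta-method Poisson counting contribution at the baseline."""
        bio = np.log1p(self.within_tumor_cv**2)
        expected_total_count = (
            self.fields_per_section * np.exp(self.baselines[marker]) * self.field_area
        )
        return float(np.sqrt(bio + 1.0 / expected_total_count))


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    heterogeneous: dict[str, bool]
    driver_markers: dict[str, list[str]]
    true_density: pd.DataFrame  # (tumor_id, region) x marker, cells/mm^2

    def to_json_dict(self) -> dict:
        dens = {
            f"{t}|{r}": {m: float(v) for m, v in row.items()}
            for (t, r), row in self.true_density.iterrows()
        }
        return {
            "heterogeneous": self.heterogeneous,
            "driver_markers": self.driver_markers,
            "true_density": dens,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        recs = {tuple(k.split("|")): v for k, v in d["true_density"].items()}
        dens = pd.DataFrame.from_dict(recs, orient="index")
        dens.index = pd.MultiIndex.from_tuples(dens.index, names=["tumor_id", "region"])
        return cls(
            heterogeneous={k: bool(v) for k, v in d["heterogeneous"].items()},
            driver_markers={k: list(v) for k, v in d["driver_markers"].items()},
            true_density=dens,
        )


@dataclass
class CohortBundle:
    """All synthetic inputs for one cohort plus the ground truth."""

    ihc_fields: pd.DataFrame
    tls: pd.DataFrame
    expression: pd.DataFrame
    clinicopath: pd.DataFrame
    truth: SyntheticTruth
    config: SimConfig


def _simulate_clinicopath(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"case{i + 1:02d}" for i in range(cfg.n_tumors)]
    age = np.clip(np.round(rng.normal(58.0, 5.0, cfg.n_tumors)), 40, 75).astype(int)
    sex = np.where(rng.random(cfg.n_tumors) < 0.3, "F", "M")
    diameter = np.round(rng.uniform(10.0, 30.0, cfg.n_tumors), 1)
    ptype = np.where(rng.random(cfg.n_tumors) < 0.7, "CD", "PD")
    diagnosis = np.where(rng.random(cfg.n_tumors) < 0.3, "primary", "recurrent")
    multiplicity = np.where(rng.random(cfg.n_tumors) < 0.4, "single", "multiple")
    return pd.DataFrame(
        {
            "case_id": ids,
            "age": age,
            "sex": sex,
            "max_diameter": diameter,
            "pathological_type": ptype,
            "diagnosis": diagnosis,
            "multiplicity": multiplicity,
        }
    )


def simulate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate one multiregion cohort (IHC sheet, TLS counts, expression
    matrix, clinicopathological table) plus its :class:`SyntheticTruth`."""
    rng = np.random.default_rng(cfg.seed)
    markers = list(cfg.panel.markers)
    baselines = cfg.baselines
    eff = cfg.covariate_effects
    clin = _simulate_clinicopath(cfg, rng)
    m_regions = len(cfg.regions)
    sigma_bio = float(np.sqrt(np.log1p(cfg.within_tumor_cv**2)))

    # --- ground truth densities -------------------------------------------
    het_flags: dict[str, bool] = {}
    drivers: dict[str, list[str]] = {}
    rows = []
    tls_log_factor: dict[tuple[str, str], float] = {}
    for i, tid in enumerate(clin["case_id"]):
        het = bool(rng.random() < cfg.prop_heterogeneous)
        het_flags[tid] = het
        n_drv = min(cfg.n_driver_markers, len(markers))
        drv = sorted(rng.choice(markers, size=n_drv, replace=False).tolist(),
                     key=markers.index) if het else []
        drivers[tid] = drv
        cov_shift = (
            eff.diameter * (clin["max_diameter"][i] - 20.0)
            + (eff.multiple if clin["multiplicity"][i] == "multiple" else 0.0)
            + (eff.female if clin["sex"][i] == "F" else 0.0)
            + eff.age * (clin["age"][i] - 58.0)
        )
        tumor_level = {
            m: baselines[m] + cov_shift + rng.normal(0.0, cfg.between_tumor_sd)
            for m in markers
        }
        # mean-centred linear ramp, extremes at -/+ driver_effect pooled SD
        ramp = np.linspace(-1.0, 1.0, m_regions)
        for j, region in enumerate(cfg.regions):
            rec = {"tumor_id": tid, "region": region}
            std_dev_sum = 0.0
            for m in markers:
                logd = tumor_level[m] + rng.normal(0.0, sigma_bio)
                if m in drv:
                    logd += cfg.driver_effect * cfg.pooled_log_sd(m) * ramp[j]
                rec[m] = float(np.exp(logd))
                if m in ("CD4", "CD8", "CD68"):
                    std_dev_sum += (logd - baselines[m]) / cfg.between_tumor_sd
            tls_log_factor[(tid, region)] = std_dev_sum / 3.0
            rows.append(rec)
    true_density = pd.DataFrame(rows).set_index(["tumor_id", "region"])
    truth = SyntheticTruth(het_flags, drivers, true_density)

    # --- IHC field counts --------------------------------------------------
    ihc_rows = []
    for (tid, region), dens in true_density.iterrows():
        for m in markers:
            lam = dens[m] * cfg.field_area
            counts = np.minimum(
                rng.poisson(lam, cfg.fields_per_section), cfg.cells_per_field
            )
            for k, c in enumerate(counts):
                ihc_rows.append(
                    {
                        "tumor_id": tid,
                        "region": region,
                        "marker": m,
                        "field_index": k + 1,
                        "positive_count": int(c),
                        "cells_assessed": cfg.cells_per_field,
                    }
                )
    ihc_fields = pd.DataFrame(ihc_rows)

    # --- TLS counts ---------------------------------------------------------
    tls_rows = []
    tls_rate_by_sample: dict[tuple[str, str], float] = {}
    for (tid, region) in true_density.index:
        rate = cfg.tls_rate * float(np.exp(cfg.tls_coupling * tls_log_factor[(tid, region)]))
        tls_rate_by_sample[(tid, region)] = rate
        tls_rows.append(
            {"tumor_id": tid, "region": region, "tls_count": int(rng.poisson(rate))}
        )
    tls = pd.DataFrame(tls_rows)

    # --- RNA-seq counts -----------------------------------------------------
    gene_sets = default_gene_sets()
    cpl = cfg.rnaseq_coupling
    sample_ids = [
        f"{tid}_{r}" for tid in clin["case_id"] for r in cfg.rna_regions
    ] + [f"{tid}_P" for tid in clin["case_id"]]
    lib = np.exp(rng.normal(0.0, cfg.library_sd, len(sample_ids)))
    filler_names = [f"GENE{i + 1:04d}" for i in range(cfg.n_filler_genes)]
    filler_base = np.exp(rng.normal(3.5, 1.0, cfg.n_filler_genes))

    def nb(mu: np.ndarray) -> np.ndarray:
        shape = 1.0 / cpl.dispersion
        return rng.poisson(rng.gamma(shape, mu * cpl.dispersion / 1.0, size=mu.shape))

    expr: dict[str, np.ndarray] = {}
    marker_genes: list[str] = []
    for feat, genes in gene_sets.items():
        for g in genes:
            mus = []
            for s in sample_ids:
                tid, region = s.rsplit("_", 1)
                if region == "P":
                    if feat == "TLS":
                        level = np.log(cfg.tls_rate + 0.5) + cfg.paratumor_shift
                    else:
                        level = baselines.get(feat, 3.0) + cfg.paratumor_shift
                    level += rng.normal(0.0, sigma_bio)
                elif feat == "TLS":
                    level = np.log(tls_rate_by_sample[(tid, region)] + 0.5)
                else:
                    level = np.log(true_density.loc[(tid, region), feat])
                mus.append(np.exp(cpl.intercept + cpl.slope * level + rng.normal(0.0, cpl.noise_sd)))
            expr[g] = nb(np.asarray(mus) * lib)
            marker_genes.append(g)
    for name, base in zip(filler_names, filler_base):
        expr[name] = nb(base * lib)
    expression = pd.DataFrame(expr, index=sample_ids).T.astype(int)
    expression.index.name = "gene_id"
    expression.columns = sample_ids

    return CohortBundle(ihc_fields, tls, expression, clin, truth, cfg)


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the cohort bundle as the plain-text pipeline inputs.

    Produces ``ihc_fields.csv``, ``tls.csv``, ``expression.tsv``
    (featureCounts-style gene x sample), ``clinicopath.csv`` and
    ``truth.json``; the CSV/TSV files round-trip losslessly through the
    pipeline readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ihc_fields": directory / "ihc_fields.csv",
        "tls": directory / "tls.csv",
        "expression": directory / "expression.tsv",
        "clinicopath": directory / "clinicopath.csv",
        "truth": directory / "truth.json",
    }
    bundle.ihc_fields.to_csv(paths["ihc_fields"], index=False)
    bundle.tls.to_csv(paths["tls"], index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.clinicopath.to_csv(paths["clinicopath"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
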