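"""End-to-end orchestration: simulate -> quantify -> abundance ->
similarity -> associations -> concordance -> report.

Every stage's output is written as plain TSV/JSON into the run directory;
``report.json`` aggregates the cohort summaries, associations,
concordance and provenance (config hash, seed, package version).  The
same configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .panel import DEFAULT_PANEL
from . import io as tio
from .ihc import quantify_cohort
from .rna import default_gene_sets, load_gene_sets, normalize_counts, gene_set_abundance
from .similarity import (
    DEFAULT_CRITICAL_VALUE,
    analyze_cohort,
    assemble_features,
    cohort_summary,
)
from .simulate import SimConfig, simulate_cohort, write_fixture
from .stats import association_screen, modality_concordance, tls_stratified_compare

log = logging.getLogger("timehom")

KNOWN_REGIONS = ("T1", "T2", "T3", "T4", "T5", "P")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    input_dir: str | None = None  # None -> simulate a synthetic cohort
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    gene_sets_path: str | None = None
    normalization: str = "log2cpm"
    critical_value: float = DEFAULT_CRITICAL_VALUE
    range_threshold: float | None = None
    shrinkage: str | float = "auto"
    age_cut: float | None = None
    adjust: str = "fdr_bh"
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_canonical_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def analytic_fingerprint(self) -> str:
        """Hash of the parameters that determine the numbers in the
        report (output location and verbosity excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("quiet", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()


def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Schema and cross-reference checks; reports, never raises.

    ``paths`` maps the logical names ``ihc_fields``, ``tls``,
    ``expression``, ``clinicopath`` to files.  Each entry of the report
    carries ``ok`` plus a list of human-readable issues.
    """
    report: dict[str, dict] = {}

    def entry(name: str) -> dict:
        report[name] = {"ok": True, "issues": []}
        return report[name]

    frames: dict[str, pd.DataFrame] = {}
    readers = {
        "ihc_fields": tio.read_ihc_fields,
        "tls": tio.read_tls,
        "expression": tio.read_expression,
        "clinicopath": tio.read_clinicopath,
    }
    for name, reader in readers.items():
        if name not in paths:
            continue
        e = entry(name)
        try:
            frames[name] = reader(paths[name])
        except Exception as exc:  # noqa: BLE001 - validation must not throw
            e["ok"] = False
            e["issues"].append(str(exc))
    if "ihc_fields" in frames:
        e = report["ihc_fields"]
        bad_regions = sorted(set(frames["ihc_fields"]["region"]) - set(KNOWN_REGIONS))
        if bad_regions:
            e["ok"] = False
            e["issues"].append(f"unknown region label(s): {bad_regions}")
        neg = frames["ihc_fields"].query("positive_count < 0 or cells_assessed <= 0")
        if len(neg):
            e["ok"] = False
            e["issues"].append(f"{len(neg)} rows with invalid counts")
    if "clinicopath" in frames:
        known_tumors = set(frames["clinicopath"]["case_id"])
        for name, col in (("ihc_fields", "tumor_id"), ("tls", "tumor_id")):
            if name in frames:
                orphans = sorted(set(frames[name][col]) - known_tumors)
                if orphans:
                    report[name]["ok"] = False
                    report[name]["issues"].append(
                        f"tumor id(s) absent from clinicopath table: {orphans}"
                    )
        if "expression" in frames:
            e = report["expression"]
            orphan_samples = sorted(
                s
                for s in frames["expression"].columns
                if s.rsplit("_", 1)[0] not in known_tumors
            )
            if orphan_samples:
                e["ok"] = False
                e["issues"].append(
                    f"expression sample(s) without a cohort tumor: {orphan_samples}"
                )
    report["all_ok"] = {"ok": all(v["ok"] for k, v in report.items() if k != "all_ok"),
                       "issues": []}
    return report


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run the full chain; returns the run directory.

    A stage failure raises with the stage name prefixed; outputs produced
    before the failure are retained in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    (out / "run_config.json").write_text(config.to_canonical_json() + "\n")

    stage = "inputs"
    try:
        if config.input_dir is None:
            stage = "simulate"
            log.info("[simulate] generating synthetic cohort (seed=%d)", config.seed)
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", config.seed)
            bundle = simulate_cohort(SimConfig(**sim_kwargs))
            paths = write_fixture(bundle, out / "inputs")
        else:
            indir = Path(config.input_dir)
            paths = {
                "ihc_fields": indir / "ihc_fields.csv",
                "tls": indir / "tls.csv",
                "expression": indir / "expression.tsv",
                "clinicopath": indir / "clinicopath.csv",
            }
            for name, p in paths.items():
                if not p.exists():
                    raise FileNotFoundError(f"missing input file for {name!r}: {p}")

        stage = "validate"
        validation = validate_inputs(paths)
        _write_json(validation, out / "validation.json")

        stage = "quantify"
        fields = tio.read_ihc_fields(paths["ihc_fields"])
        tls = tio.read_tls(paths["tls"])
        panel = DEFAULT_PANEL
        samples = quantify_cohort(fields, tls, panel=panel)
        tio.write_regional_samples(samples, out / "regional_samples.tsv")
        log.info("[quantify] %d sections quantified", len(samples))

        stage = "abundance"
        counts = tio.read_expression(paths["expression"])
        gene_sets = (
            load_gene_sets(config.gene_sets_path)
            if config.gene_sets_path
            else default_gene_sets()
        )
        normalized = normalize_counts(counts, method=config.normalization)
        abundance = gene_set_abundance(
            normalized, gene_sets, normalization=config.normalization
        )
        tio.write_abundance(abundance.data, out / "abundance.tsv")

        stage = "similarity"
        X_ihc = assemble_features(samples, panel, source="ihc")
        X_rna = assemble_features(abundance.data, panel, source="rna")
        res_ihc = analyze_cohort(
            X_ihc,
            critical_value=config.critical_value,
            range_threshold=config.range_threshold,
            shrinkage=config.shrinkage,
        )
        res_rna = analyze_cohort(
            X_rna,
            critical_value=config.critical_value,
            range_threshold=config.range_threshold,
            shrinkage=config.shrinkage,
        )
        similarity_out = {
            "ihc": [r.to_dict() for r in res_ihc],
            "rna": [r.to_dict() for r in res_rna],
        }
        _write_json(similarity_out, out / "similarity.json")
        flat = []
        for src, results in (("ihc", res_ihc), ("rna", res_rna)):
            for r in results:
                for region, d in r.distances.items():
                    flat.append(
                        {
                            "source": src,
                            "tumor_id": r.tumor_id,
                            "region": region,
                            "mahalanobis_sq": d,
                            "homogeneous": r.homogeneous,
                            "range_narrow": r.range_narrow,
                        }
                    )
        pd.DataFrame(flat).to_csv(out / "similarity.tsv", sep="\t", index=False)
        log.info(
            "[similarity] IHC: %d/%d homogeneous; RNA: %d/%d homogeneous",
            sum(r.homogeneous for r in res_ihc), len(res_ihc),
            sum(r.homogeneous for r in res_rna), len(res_rna),
        )

        stage = "associations"
        clin = tio.read_clinicopath(paths["clinicopath"])
        feat_table = samples[["tumor_id"]].copy()
        for m in panel.markers:
            feat_table[m] = samples[f"{m}_density"]
        feat_table["TLS"] = samples["tls_count"]
        assoc = association_screen(
            feat_table, clin, age_cut=config.age_cut, adjust=config.adjust
        )
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        tls_cmp = tls_stratified_compare(samples, panel.markers, stratify_by="tls")
        pdl1_cmp = tls_stratified_compare(samples, panel.markers, stratify_by="pdl1")
        tls_cmp.assign(stratification="TLS").pipe(
            lambda d: pd.concat([d, pdl1_cmp.assign(stratification="PD-L1")])
        ).to_csv(out / "stratified_comparisons.tsv", sep="\t", index=False)

        stage = "concordance"
        concordance = modality_concordance(X_ihc, X_rna, res_ihc, res_rna)
        _write_json(concordance, out / "concordance.json")

        stage = "report"
        report = {
            "provenance": {
                "package_version": __version__,
                "seed": config.seed,
                "config_sha256": config.analytic_fingerprint(),
            },
            "validation_ok": validation["all_ok"]["ok"],
            "n_tumors": int(samples["tumor_id"].nunique()),
            "n_sections": int(len(samples)),
            "cohort_summary": {
                "ihc": cohort_summary(res_ihc),
                "rna": cohort_summary(res_rna),
            },
            "n_associations": int(len(assoc)),
            "n_significant_raw": int((assoc["p_value"] < 0.05).sum()),
            "concordance": concordance,
        }
        _write_json(report, out / "report.json")
        log.info("[report] written to %s", out / "report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
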