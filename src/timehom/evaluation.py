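"""Self-validation experiments: calibration, recovery, type-I error.

These run the pipeline against its own synthetic ground truth and are
shared by the test suite and the reproduction script.  Problem sizes are
kept at desk scale (a few cohorts of 100 tumors, 10^4 calibration
regions, ~10^3 null tests); each function takes an explicit seed and is
fully deterministic given it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ihc import quantify_cohort
from .panel import DEFAULT_PANEL
from .similarity import (
    CovarianceModel,
    FeatureMatrix,
    analyze_cohort,
    assemble_features,
    mahalanobis_distances,
    pooled_covariance,
)
from .simulate import SimConfig, simulate_cohort
from .stats import rank_sum_test, spearman_corr


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def calibration_exceedance(
    n_regions: int = 10_000,
    n_features: int = 9,
    alpha: float = 0.01,
    seed: int = 0,
    oracle: bool = True,
    regions_per_tumor: int = 5,
    centroid_correction: bool = True,
) -> dict:
    """Fraction of homogeneous multivariate-normal regions whose squared
    Mahalanobis distance exceeds the upper-``alpha`` chi-square point.

    ``oracle=True`` plugs in the true mean and covariance per tumor, where
    the exceedance must equal ``alpha`` up to Monte-Carlo error.  With
    ``oracle=False`` centroids and covariance are estimated from
    ``regions_per_tumor`` regions per tumor, optionally with the
    n/(n-1) centroid correction.
    """
    rng = np.random.default_rng(seed)
    # a correlated, heteroscedastic covariance so the test is not trivial
    A = rng.normal(size=(n_features, n_features)) / np.sqrt(n_features)
    sigma = A @ A.T + np.eye(n_features)
    scale = np.diag(rng.uniform(0.5, 2.0, n_features))
    sigma = scale @ sigma @ scale
    mu = rng.normal(0.0, 5.0, n_features)
    n_tumors = int(np.ceil(n_regions / regions_per_tumor))
    L = np.linalg.cholesky(sigma)
    X_arr = mu + rng.normal(size=(n_tumors * regions_per_tumor, n_features)) @ L.T
    idx = pd.MultiIndex.from_arrays(
        [
            np.repeat([f"t{i:05d}" for i in range(n_tumors)], regions_per_tumor),
            np.tile([f"T{j + 1}" for j in range(regions_per_tumor)], n_tumors),
        ],
        names=["tumor_id", "region"],
    )
    feats = [f"f{k}" for k in range(n_features)]
    X = FeatureMatrix(pd.DataFrame(X_arr, index=idx, columns=feats))
    crit = stats.chi2.ppf(1.0 - alpha, n_features)
    if oracle:
        cov = CovarianceModel(sigma, tuple(feats), shrinkage=0.0, df=n_regions)
        centroids = {t: mu for t in X.tumor_ids}
        d2 = mahalanobis_distances(X, cov, centroids=centroids)
    else:
        cov = pooled_covariance(X)
        d2 = mahalanobis_distances(X, cov, centroid_correction=centroid_correction)
    d2 = d2.iloc[:n_regions]
    exceed = float(np.mean(d2.to_numpy() > crit))
    return {
        "exceedance": exceed,
        "nominal": alpha,
        "n_regions": int(len(d2)),
        "mc_3se": 3.0 * float(np.sqrt(alpha * (1 - alpha) / len(d2))),
    }


def recovery_experiment(
    n_cohorts: int = 3,
    n_tumors: int = 100,
    prop_heterogeneous: float = 0.2,
    driver_effect: float = 3.0,
    seed: int = 0,
    critical_value: float = 22.0,
) -> dict:
    """Heterogeneity-classification recovery against synthetic truth.

    Simulates ``n_cohorts`` cohorts of ``n_tumors`` tumors, runs the IHC
    quantification + similarity classification with defaults, and pools
    recall, specificity, and top-1 driver identification accuracy (the
    top-ranked attributed marker is one of the planted drivers) over the
    cohorts.
    """
    seeds = _spawn_seeds(seed, n_cohorts)
    tp = fn = fp = tn = 0
    top1_hits = 0
    detected_het = 0
    for s in seeds:
        cfg = SimConfig(
            n_tumors=n_tumors,
            prop_heterogeneous=prop_heterogeneous,
            driver_effect=driver_effect,
            seed=s,
        )
        bundle = simulate_cohort(cfg)
        samples = quantify_cohort(bundle.ihc_fields, bundle.tls)
        X = assemble_features(samples, DEFAULT_PANEL, source="ihc")
        results = analyze_cohort(X, critical_value=critical_value)
        for r in results:
            truth_het = bundle.truth.heterogeneous[r.tumor_id]
            pred_het = not r.homogeneous
            if truth_het and pred_het:
                tp += 1
                detected_het += 1
                if r.top_driver in bundle.truth.driver_markers[r.tumor_id]:
                    top1_hits += 1
            elif truth_het:
                fn += 1
            elif pred_het:
                fp += 1
            else:
                tn += 1
    return {
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "top1_driver_accuracy": top1_hits / detected_het if detected_het else float("nan"),
        "n_heterogeneous_true": tp + fn,
        "n_homogeneous_true": tn + fp,
        "n_cohorts": n_cohorts,
        "n_tumors_per_cohort": n_tumors,
    }


def type1_experiment(
    n_tests: int = 1000,
    group_size: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the rank-sum and Spearman tests under the null.

    Half the tests are two-group rank-sum comparisons of i.i.d. normal
    samples (``group_size`` per arm); half are Spearman correlations of
    independent normal pairs (n = 2 * group_size).
    """
    rng = np.random.default_rng(seed)
    n_each = n_tests // 2
    rejections = 0
    total = 0
    for _ in range(n_each):
        a = rng.normal(size=group_size)
        b = rng.normal(size=group_size)
        rejections += rank_sum_test(a, b).p_value < alpha
        total += 1
    for _ in range(n_tests - n_each):
        x = rng.normal(size=2 * group_size)
        y = rng.normal(size=2 * group_size)
        rejections += spearman_corr(x, y).p_value < alpha
        total += 1
    return {"rejection_rate": rejections / total, "n_tests": total, "alpha": alpha}


def default_cohort_summary(seed: int = 0) -> dict:
    """Run the default 10-tumor study design end to end and summarize the
    fraction of tumors classified homogeneous per source (IHC and RNA)."""
    from .rna import default_gene_sets, gene_set_abundance, normalize_counts
    from .similarity import cohort_summary

    bundle = simulate_cohort(SimConfig(seed=seed))
    samples = quantify_cohort(bundle.ihc_fields, bundle.tls)
    X_ihc = assemble_features(samples, DEFAULT_PANEL, source="ihc")
    res_ihc = analyze_cohort(X_ihc, lomo=False)
    norm = normalize_counts(bundle.expression)
    ab = gene_set_abundance(norm, default_gene_sets())
    X_rna = assemble_features(ab.data, DEFAULT_PANEL, source="rna")
    res_rna = analyze_cohort(X_rna, lomo=False)
    return {
        "ihc": cohort_summary(res_ihc),
        "rna": cohort_summary(res_rna),
        "n_ihc_sections": int(len(X_ihc.data)),
        "n_rna_samples": int(len(X_rna.data)),
    }
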