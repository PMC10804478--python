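"""Association and concordance statistics for the multiregion cohort.

Nonparametric two-group comparisons (Mann-Whitney U), rank correlations
(Spearman), the clinicopathological association screen, TLS / PD-L1
stratified comparisons, and IHC vs RNA-seq concordance.

Exact p-values are used where enumeration is cheap: the rank-sum test is
exact for n1 + n2 <= 12 without ties, and the Spearman permutation null is
enumerated for n <= 8; both fall back to the usual large-sample
approximations (normal with tie and continuity correction; t with n-2 df).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_RANKSUM_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8


@dataclass
class AssociationResult:
    """One test: a feature against a grouping or covariate."""

    feature: str
    covariate: str
    kind: str  # "rank_sum" | "spearman"
    statistic: float
    p_value: float
    n1: int
    n2: int | None = None
    direction: str | None = None
    method: str | None = None
    computable: bool = True
    q_value: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    feature: str = "",
    covariate: str = "",
    method: str = "auto",
) -> AssociationResult:
    """Two-sided Mann-Whitney U test of ``a`` vs ``b``.

    ``method="auto"`` uses the exact null when n1 + n2 <= 12 and there are
    no ties, otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    if method == "auto":
        if a.size + b.size <= EXACT_RANKSUM_MAX_N and not _has_ties(np.concatenate([a, b])):
            method = "exact"
        else:
            method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    direction = "a>b" if np.median(a) > np.median(b) else ("a<b" if np.median(a) < np.median(b) else "a=b")
    return AssociationResult(
        feature=feature,
        covariate=covariate,
        kind="rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(a.size),
        n2=int(b.size),
        direction=direction,
        method=method,
    )


def _midrank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_corr(
    x: Sequence[float],
    y: Sequence[float],
    feature: str = "",
    covariate: str = "",
    method: str = "auto",
) -> AssociationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of midranks.  ``method="auto"``
    enumerates the permutation null exactly for n <= 8, otherwise uses the
    t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman_corr requires n >= 3 pairs")
    rho = _midrank_rho(x, y)
    if method == "auto":
        method = "exact" if n <= EXACT_SPEARMAN_MAX_N else "t"
    if method == "exact":
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return AssociationResult(
        feature=feature,
        covariate=covariate,
        kind="spearman",
        statistic=rho,
        p_value=p,
        n1=int(n),
        direction="positive" if rho > 0 else ("negative" if rho < 0 else "zero"),
        method=method,
    )


# ---------------------------------------------------------------------------
# screens


_GROUPINGS = {
    "sex": ("F", "M"),
    "multiplicity": ("single", "multiple"),
    "diagnosis": ("primary", "recurrent"),
    "pathological_type": ("CD", "PD"),
}


def association_screen(
    features: pd.DataFrame,
    clinicopath: pd.DataFrame,
    age_cut: float | None = None,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Screen every immune feature against the clinicopathological table.

    ``features`` holds one row per section with a ``tumor_id`` column and
    numeric feature columns; each section inherits its tumor's covariates.
    Per feature: rank-sum tests across sex, multiplicity, diagnosis,
    pathological type and an age median-split (``age_cut`` overrides the
    cohort-median cutoff), plus Spearman correlations against maximum
    diameter and age.  Raw p-values are reported unchanged; BH-adjusted
    q-values are added alongside.
    """
    if "tumor_id" not in features.columns:
        raise ValueError("features table needs a 'tumor_id' column")
    feat_cols = [c for c in features.columns if c != "tumor_id"]
    clin = clinicopath.set_index("case_id")
    unmatched = sorted(set(features["tumor_id"]) - set(clin.index))
    if unmatched:
        raise ValueError(f"tumor id(s) missing from the clinicopathological table: {unmatched}")
    merged = features.join(clin, on="tumor_id")
    if age_cut is None:
        age_cut = float(clin["age"].median())
    merged["age_group"] = np.where(merged["age"] > age_cut, "older", "younger")
    results: list[AssociationResult] = []
    for feat in feat_cols:
        vals = merged[feat].to_numpy(dtype=float)
        for cov_name, (lvl_a, lvl_b) in {**_GROUPINGS, "age_group": ("older", "younger")}.items():
            ga = vals[merged[cov_name] == lvl_a]
            gb = vals[merged[cov_name] == lvl_b]
            if ga.size == 0 or gb.size == 0:
                results.append(
                    AssociationResult(feat, cov_name, "rank_sum", np.nan, np.nan,
                                      int(ga.size), int(gb.size), computable=False)
                )
                continue
            results.append(rank_sum_test(ga, gb, feature=feat, covariate=cov_name))
        for cov_name in ("max_diameter", "age"):
            results.append(
                spearman_corr(merged[cov_name].to_numpy(float), vals,
                              feature=feat, covariate=cov_name, method="t")
            )
    out = pd.DataFrame([r.to_dict() for r in results])
    if len(out):
        ok = out["computable"] & out["p_value"].notna()
        out["q_value"] = np.nan
        if ok.any():
            out.loc[ok, "q_value"] = multipletests(out.loc[ok, "p_value"], method=adjust)[1]
    return out


def tls_stratified_compare(
    samples: pd.DataFrame,
    markers: Sequence[str],
    stratify_by: str = "tls",
    pdl1_marker: str = "PD-L1",
    level: str = "section",
) -> pd.DataFrame:
    """Compare marker densities between strata of sections.

    ``stratify_by="tls"`` splits sections into TLS-present (count > 0) vs
    TLS-absent; ``stratify_by="pdl1"`` splits into PD-L1 positive (score
    >= 1, i.e. positive index >= 1%) vs negative.  With
    ``level="tumor"`` sections are first aggregated to tumor means and a
    tumor is stratum-positive if any of its sections is.  An empty stratum
    yields a flagged, non-computable row rather than an error.
    """
    df = samples.copy()
    if stratify_by == "tls":
        flag = df["tls_count"] > 0
        label = "TLS"
    elif stratify_by == "pdl1":
        flag = df[f"{pdl1_marker}_score"] >= 1
        label = "PD-L1"
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")
    df["_stratum"] = flag
    if level == "tumor":
        agg = {f"{m}_density": "mean" for m in markers}
        agg["_stratum"] = "any"
        df = df.groupby("tumor_id", as_index=False).agg(agg)
    elif level != "section":
        raise ValueError("level must be 'section' or 'tumor'")
    rows = []
    for m in markers:
        if stratify_by == "pdl1" and m == pdl1_marker:
            continue
        pos = df.loc[df["_stratum"], f"{m}_density"].to_numpy(float)
        neg = df.loc[~df["_stratum"], f"{m}_density"].to_numpy(float)
        if pos.size == 0 or neg.size == 0:
            rows.append(
                AssociationResult(m, f"{label}+ vs {label}-", "rank_sum", np.nan,
                                  np.nan, int(pos.size), int(neg.size),
                                  computable=False).to_dict()
            )
            continue
        res = rank_sum_test(pos, neg, feature=m, covariate=f"{label}+ vs {label}-")
        rec = res.to_dict()
        rec["median_positive"] = float(np.median(pos))
        rec["median_negative"] = float(np.median(neg))
        rows.append(rec)
    return pd.DataFrame(rows)


def modality_concordance(
    ihc_X,
    rna_X,
    ihc_results=None,
    rna_results=None,
    min_matched: int = 3,
) -> dict:
    """Agreement between the IHC and RNA-seq views of the cohort.

    Per-feature Spearman correlation across the (tumor, region) samples
    present in both feature matrices (features with fewer than
    ``min_matched`` matched samples are skipped with a warning), plus the
    tumor-level homogeneity-classification agreement between the two
    sources when similarity results are provided.
    """
    a = ihc_X.data
    b = rna_X.data
    common_samples = a.index.intersection(b.index)
    common_feats = [f for f in a.columns if f in set(b.columns)]
    if len(common_samples) < min_matched:
        raise ValueError(
            f"need >= {min_matched} matched samples, found {len(common_samples)}"
        )
    per_feature = {}
    for f in common_feats:
        x = a.loc[common_samples, f].to_numpy(float)
        y = b.loc[common_samples, f].to_numpy(float)
        if len(x) < min_matched:
            warnings.warn(f"feature {f!r}: fewer than {min_matched} matched samples; skipped")
            continue
        try:
            res = spearman_corr(x, y, feature=f, covariate="ihc_vs_rna", method="t")
        except ValueError:
            warnings.warn(f"feature {f!r}: correlation undefined (constant values); skipped")
            continue
        per_feature[f] = {"rho": res.statistic, "p_value": res.p_value, "n": res.n1}
    report: dict = {
        "n_matched_samples": int(len(common_samples)),
        "per_feature": per_feature,
        "median_rho": float(np.median([v["rho"] for v in per_feature.values()]))
        if per_feature
        else None,
    }
    if ihc_results is not None and rna_results is not None:
        ihc_map = {r.tumor_id: r.homogeneous for r in ihc_results}
        rna_map = {r.tumor_id: r.homogeneous for r in rna_results}
        shared = sorted(set(ihc_map) & set(rna_map))
        table = {"both_homogeneous": 0, "ihc_only": 0, "rna_only": 0, "neither": 0}
        agree = 0
        for t in shared:
            hi, hr = ihc_map[t], rna_map[t]
            agree += hi == hr
            if hi and hr:
                table["both_homogeneous"] += 1
            elif hi:
                table["ihc_only"] += 1
            elif hr:
                table["rna_only"] += 1
            else:
                table["neither"] += 1
        report["classification_agreement"] = {
            "n_tumors": len(shared),
            "agreement_fraction": agree / len(shared) if shared else None,
            "table": table,
        }
    return report
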