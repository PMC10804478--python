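"""Regional similarity of the tumor immune microenvironment.

Each tumor is sampled in several regions along its long axis; every region
carries a positional feature vector (eight immune-marker densities plus
the TLS count, or the matching RNA-seq abundances).  The squared
Mahalanobis distance of each region to its own tumor's centroid,

    d^2(x) = (x - mu_t)' Sigma^{-1} (x - mu_t),

measures how far that region sits from the rest of the tumor once feature
scales and correlations are accounted for.  A tumor is called homogeneous
when all its regional distances stay at or below a critical value; under
multivariate normality the squared distance is approximately chi-square
with df = number of features, and the default critical value 22 is the
rounded upper-1% chi-square point for nine features (21.67).

Because a single tumor has fewer regions than features, its own covariance
is singular; the covariance is therefore estimated by pooling
region-minus-centroid deviations over all tumors and shrinking toward the
diagonal, Sigma_lambda = (1-lambda) S + lambda diag(S), with lambda chosen
(automatically) as the smallest value keeping the condition number under a
bound.

Four safeguards keep the statistic on its chi-square reference:

* Deviations from an *estimated* centroid of n_t regions have covariance
  (1 - 1/n_t) Sigma, so squared distances are rescaled by n_t/(n_t - 1)
  (skipped when true centroids are supplied in oracle mode).
* Classification uses jackknifed pooling: a tumor's distances are judged
  against a covariance pooled from the *other* tumors, so a heterogeneous
  tumor's own regional trend cannot inflate the covariance it is tested
  with.
* Jackknifed deviations are independent of the Wishart covariance
  estimate, so d^2 (nu-p+1)/(nu p) ~ F(p, nu-p+1) under homogeneity;
  distances are mapped through this exact null onto the chi-square(p)
  scale (see :func:`f_calibrate_distances`), keeping the critical value
  correctly calibrated at small cohort sizes.
* Classification iterates a standard reweighting: after each pass the
  covariance is re-pooled from the tumors currently classified
  homogeneous, until a fixed point (cf. reweighted robust covariance
  estimation).

IHC densities enter the feature matrix on the square-root scale
(Anscombe-type variance stabilization: densities are scaled Poisson
counts, and sqrt makes the counting noise approximately homoscedastic
across markers of very different abundance without the zero-saturation a
log transform would impose on sparse markers).

Leave-one-marker-out (LOMO) attribution recomputes pooled covariance and
distances after dropping each feature in turn; markers whose removal flips
a heterogeneous tumor to homogeneous (or narrows a wide distance range)
are its heterogeneity drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .panel import MarkerPanel, DEFAULT_PANEL, TLS_FEATURE

DEFAULT_CRITICAL_VALUE = 22.0
DEFAULT_CONDITION_BOUND = 1e6


def chi2_critical(df: int, alpha: float = 0.01) -> float:
    """Rounded upper-``alpha`` chi-square quantile (df = feature count)."""
    return float(round(stats.chi2.ppf(1.0 - alpha, df)))


def f_calibrate_distances(d2: np.ndarray | pd.Series, cov_df: int, n_features: int):
    """Map squared distances onto the chi-square scale through their exact
    finite-sample null.

    With the covariance estimated on ``cov_df`` within-tumor degrees of
    freedom (Wishart) and a deviation independent of it (guaranteed by
    leave-one-tumor-out pooling), d^2 * (nu - p + 1)/(nu p) follows
    F(p, nu - p + 1) under homogeneity.  The monotone map
    chi2_isf(F_sf(.)) makes the returned values directly comparable to a
    chi-square(p) critical value regardless of cohort size; it converges
    to the identity as cov_df grows.  Returned unchanged when
    cov_df <= n_features (calibration undefined).
    """
    nu, p = cov_df, n_features
    if nu - p + 1 <= 0:
        return d2
    scale = (nu - p + 1) / (nu * p)
    vals = np.asarray(d2, dtype=float)
    tail = stats.f.sf(vals * scale, p, nu - p + 1)
    out = stats.chi2.isf(np.clip(tail, 1e-300, 1.0), p)
    if isinstance(d2, pd.Series):
        return pd.Series(out, index=d2.index, name=d2.name)
    return out


@dataclass
class FeatureMatrix:
    """Region x feature matrix with tumor membership.

    ``data`` is indexed by (tumor_id, region) and has one column per
    feature in panel order; ``source`` tags the modality ("ihc" or "rna").
    """

    data: pd.DataFrame
    source: str = "ihc"

    def __post_init__(self) -> None:
        if self.data.isna().to_numpy().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValueError(f"feature matrix has missing values at {bad}")
        counts = self.data.groupby(level=0).size()
        few = counts[counts < 2]
        if len(few):
            raise ValueError(
                f"every tumor needs >=2 regions; offending tumor(s): {list(few.index)}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def tumor_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values(0)))

    def drop_feature(self, feature: str) -> "FeatureMatrix":
        if feature not in self.data.columns:
            raise ValueError(f"unknown feature {feature!r}")
        if self.data.shape[1] < 2:
            raise ValueError("cannot drop the only feature")
        return FeatureMatrix(self.data.drop(columns=[feature]), source=self.source)


@dataclass
class CovarianceModel:
    """Pooled within-tumor covariance after diagonal shrinkage."""

    matrix: np.ndarray
    features: tuple[str, ...]
    shrinkage: float
    df: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(m)
        if eigvals.min() <= 0:
            raise ValueError(
                "covariance is not positive definite; increase shrinkage "
                f"(min eigenvalue {eigvals.min():.3g})"
            )


@dataclass
class TumorSimilarityResult:
    """Similarity verdict for one tumor."""

    tumor_id: str
    distances: dict[str, float]
    critical_value: float
    range_threshold: float
    homogeneous: bool
    range_narrow: bool
    driver_markers: list[str] = field(default_factory=list)
    driver_scores: dict[str, float] = field(default_factory=dict)
    driver_set: list[str] = field(default_factory=list)
    irreducible: bool = False

    @property
    def max_distance(self) -> float:
        return max(self.distances.values())

    @property
    def top_driver(self) -> str | None:
        """Best single-marker attribution: first flipping driver, else the
        marker whose removal reduces the max distance the most."""
        if self.driver_markers:
            return self.driver_markers[0]
        if self.driver_scores:
            return max(self.driver_scores, key=lambda f: self.driver_scores[f])
        return None

    def to_dict(self) -> dict:
        return {
            "tumor_id": self.tumor_id,
            "distances": {r: float(d) for r, d in self.distances.items()},
            "critical_value": self.critical_value,
            "range_threshold": self.range_threshold,
            "homogeneous": self.homogeneous,
            "range_narrow": self.range_narrow,
            "driver_markers": list(self.driver_markers),
            "driver_scores": {f: float(s) for f, s in self.driver_scores.items()},
            "driver_set": list(self.driver_set),
            "irreducible": self.irreducible,
        }


# ---------------------------------------------------------------------------
# assembly


def assemble_features(
    source_data: pd.DataFrame,
    panel: MarkerPanel = DEFAULT_PANEL,
    source: str = "ihc",
    transform: str | None = "default",
) -> FeatureMatrix:
    """Build the region x feature matrix for the similarity analysis.

    For ``source="ihc"`` expects the regional-samples table (rows per
    tumor x region, ``<marker>_density`` columns plus ``tls_count``).  For
    ``source="rna"`` expects an abundance feature x sample table whose
    sample ids are ``<tumor>_<region>``; paratumor samples (region ``P``)
    are excluded.

    ``transform`` is applied elementwise after assembly: ``"sqrt"``
    variance-stabilizes count-derived values, ``None`` leaves them raw.
    ``"default"`` resolves to sqrt for IHC densities and raw for RNA
    abundances (already log-normalized upstream).
    """
    if transform == "default":
        transform = "sqrt" if source == "ihc" else None
    feats = list(panel.features)
    if source == "ihc":
        cols = {f"{m}_density": m for m in panel.markers}
        missing = [c for c in cols if c not in source_data.columns]
        if missing:
            raise ValueError(f"regional-sample table missing columns: {missing}")
        df = source_data.set_index(["tumor_id", "region"])[list(cols)].rename(columns=cols)
        if panel.include_tls:
            if "tls_count" not in source_data.columns:
                raise ValueError("regional-sample table missing 'tls_count'")
            df[TLS_FEATURE] = source_data.set_index(["tumor_id", "region"])["tls_count"]
        df = df[feats]
    elif source == "rna":
        missing = [f for f in feats if f not in source_data.index]
        if missing:
            raise ValueError(f"abundance matrix missing feature(s): {missing}")
        wide = source_data.loc[feats].T
        ids = [str(s).rsplit("_", 1) for s in wide.index]
        bad = [s for s, parts in zip(wide.index, ids) if len(parts) != 2]
        if bad:
            raise ValueError(f"sample ids not of the form <tumor>_<region>: {bad}")
        tumors = [p[0] for p in ids]
        regions = [p[1] for p in ids]
        wide.index = pd.MultiIndex.from_arrays([tumors, regions], names=["tumor_id", "region"])
        df = wide[~wide.index.get_level_values("region").isin(["P"])]
    else:
        raise ValueError(f"unknown source {source!r} (expected 'ihc' or 'rna')")
    df = df.sort_index()
    df.index.names = ["tumor_id", "region"]
    df = df.astype(float)
    if transform == "sqrt":
        if (df < 0).to_numpy().any():
            raise ValueError("sqrt transform requires non-negative values")
        df = np.sqrt(df)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    return FeatureMatrix(df, source=source)


# ---------------------------------------------------------------------------
# covariance


def _within_tumor_deviations(X: FeatureMatrix) -> tuple[np.ndarray, int]:
    centered = X.data - X.data.groupby(level=0).transform("mean")
    n_tumors = len(X.tumor_ids)
    df = len(X.data) - n_tumors
    return centered.to_numpy(dtype=float), df


def pooled_covariance(
    X: FeatureMatrix,
    shrinkage: float | str = "auto",
    condition_bound: float = DEFAULT_CONDITION_BOUND,
    tumors: Iterable[str] | None = None,
) -> CovarianceModel:
    """Pooled within-tumor covariance with diagonal shrinkage.

    Deviations of each region from its tumor centroid are pooled over all
    tumors (df = n_regions_total - n_tumors) and shrunk toward the
    diagonal.  ``shrinkage="auto"`` picks the smallest lambda in [0, 1]
    whose shrunk matrix has condition number <= ``condition_bound``; a
    float fixes lambda.  ``tumors`` restricts pooling to a subset of
    tumors (used by the reweighted classification).
    """
    if tumors is not None:
        tumors = set(tumors)
        sub = X.data.loc[X.data.index.get_level_values(0).isin(tumors)]
        X = FeatureMatrix(sub, source=X.source)
    dev, df = _within_tumor_deviations(X)
    if not np.all(np.isfinite(dev)):
        raise ValueError("non-finite values in feature matrix")
    if df < 2:
        raise ValueError(
            f"need >= 2 within-tumor degrees of freedom, got {df}; add regions or tumors"
        )
    S = dev.T @ dev / df
    if np.any(np.diag(S) <= 0):
        zero = [X.features[i] for i in np.flatnonzero(np.diag(S) <= 0)]
        raise ValueError(f"feature(s) with zero within-tumor variance: {zero}")

    matrix, lam = _shrink_toward_diagonal(S, shrinkage, condition_bound)
    return CovarianceModel(matrix=matrix, features=tuple(X.features), shrinkage=lam, df=df)


def _shrink_toward_diagonal(
    S: np.ndarray, shrinkage: float | str, condition_bound: float
) -> tuple[np.ndarray, float]:
    target = np.diag(np.diag(S))

    def shrunk(lam: float) -> np.ndarray:
        return (1.0 - lam) * S + lam * target

    def cond(m: np.ndarray) -> float:
        ev = np.linalg.eigvalsh(m)
        return np.inf if ev.min() <= 0 else ev.max() / ev.min()

    if shrinkage == "auto":
        if cond(S) <= condition_bound:
            lam = 0.0
        else:
            lo, hi = 0.0, 1.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if cond(shrunk(mid)) <= condition_bound:
                    hi = mid
                else:
                    lo = mid
            lam = hi
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage intensity must be in [0, 1]")
    matrix = shrunk(lam)
    if np.linalg.eigvalsh(matrix).min() <= 0:
        raise ValueError(
            "pooled covariance is singular at the requested shrinkage; "
            "use shrinkage='auto' or a larger lambda"
        )
    return matrix, lam


def mahalanobis_distances(
    X: FeatureMatrix,
    cov: CovarianceModel,
    centroids: Mapping[str, np.ndarray] | None = None,
    centroid_correction: bool = True,
) -> pd.Series:
    """Squared Mahalanobis distance of each region to its tumor centroid.

    ``centroids`` optionally supplies known per-tumor mean vectors (oracle
    mode, e.g. for calibration studies); by default the empirical tumor
    centroids are used.  Solved via Cholesky factorization.

    With empirical centroids and ``centroid_correction`` (default), each
    squared distance is rescaled by n_t/(n_t - 1): a deviation from the
    mean of n_t regions has covariance (1 - 1/n_t) Sigma, and the
    correction restores the chi-square(df = n_features) reference that
    the critical value presumes.  No correction applies in oracle mode.
    """
    if tuple(X.features) != tuple(cov.features):
        raise ValueError(
            f"feature mismatch between matrix {X.features} and covariance {list(cov.features)}"
        )
    try:
        cho = linalg.cho_factor(cov.matrix, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded by CovarianceModel
        raise ValueError("singular covariance; increase shrinkage") from exc
    if centroids is None:
        centered = (X.data - X.data.groupby(level=0).transform("mean")).to_numpy(dtype=float)
    else:
        mu = np.vstack(
            [np.asarray(centroids[t], dtype=float) for t in X.data.index.get_level_values(0)]
        )
        centered = X.data.to_numpy(dtype=float) - mu
    z = linalg.cho_solve(cho, centered.T)
    d2 = np.einsum("ij,ji->i", centered, z)
    if centroids is None and centroid_correction:
        n_t = X.data.groupby(level=0).size()
        factor = (n_t / (n_t - 1.0)).reindex(X.data.index.get_level_values(0)).to_numpy()
        d2 = d2 * factor
    return pd.Series(d2, index=X.data.index, name="mahalanobis_sq")


# ---------------------------------------------------------------------------
# classification and attribution


def classify_tumor(
    distances: Mapping[str, float] | pd.Series,
    tumor_id: str = "",
    critical_value: float = DEFAULT_CRITICAL_VALUE,
    range_threshold: float | None = None,
) -> TumorSimilarityResult:
    """Homogeneity verdict from one tumor's regional squared distances.

    Homogeneous iff the maximum distance is <= ``critical_value``; the
    distance range (max - min) is "narrow" iff <= ``range_threshold``
    (default: half the critical value — a package convention, the source
    analyses never define "narrow" numerically).
    """
    if isinstance(distances, pd.Series):
        distances = {str(k): float(v) for k, v in distances.items()}
    if len(distances) < 2:
        raise ValueError("classification needs >= 2 regional distances")
    if range_threshold is None:
        range_threshold = critical_value / 2.0
    vals = np.array(list(distances.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("squared distances must be non-negative")
    return TumorSimilarityResult(
        tumor_id=tumor_id,
        distances={k: float(v) for k, v in distances.items()},
        critical_value=float(critical_value),
        range_threshold=float(range_threshold),
        homogeneous=bool(vals.max() <= critical_value),
        range_narrow=bool(vals.max() - vals.min() <= range_threshold),
    )


def _tumor_distances(
    X: FeatureMatrix,
    cov: CovarianceModel,
    tumor_id: str,
    centroid_correction: bool = True,
) -> dict[str, float]:
    d2 = mahalanobis_distances(X, cov, centroid_correction=centroid_correction)
    sub = f_calibrate_distances(d2.xs(tumor_id, level=0), cov.df, len(X.features))
    return {str(r): float(v) for r, v in sub.items()}


def leave_one_marker_out(
    X: FeatureMatrix,
    tumor_id: str,
    critical_value: float = DEFAULT_CRITICAL_VALUE,
    range_threshold: float | None = None,
    shrinkage: float | str = "auto",
    condition_bound: float = DEFAULT_CONDITION_BOUND,
    pair_search: bool = True,
    covariance_tumors: Iterable[str] | None = None,
    centroid_correction: bool = True,
) -> dict:
    """Attribute one tumor's regional heterogeneity to individual markers.

    For each feature, the pooled covariance and the tumor's distances are
    recomputed on the remaining features.  The attribution score of a
    feature is the reduction in the tumor's maximum squared distance; the
    drivers are the features whose removal flips the tumor to homogeneous
    (and, for a homogeneous-but-wide tumor, the features whose removal
    narrows the range).  When no single removal flips a heterogeneous
    tumor, a greedy forward search of depth 2 looks for a flipping pair.
    """
    if len(X.features) < 2:
        raise ValueError("leave-one-marker-out needs >= 2 features")
    if range_threshold is None:
        range_threshold = critical_value / 2.0
    cov_full = pooled_covariance(
        X, shrinkage=shrinkage, condition_bound=condition_bound, tumors=covariance_tumors
    )
    base = classify_tumor(
        _tumor_distances(X, cov_full, tumor_id, centroid_correction),
        tumor_id,
        critical_value,
        range_threshold,
    )
    scores: dict[str, float] = {}
    flips: list[str] = []
    narrows: list[str] = []
    for f in X.features:
        Xr = X.drop_feature(f)
        cov_r = pooled_covariance(
            Xr, shrinkage=shrinkage, condition_bound=condition_bound, tumors=covariance_tumors
        )
        d = _tumor_distances(Xr, cov_r, tumor_id, centroid_correction)
        dmax = max(d.values())
        scores[f] = base.max_distance - dmax
        if not base.homogeneous and dmax <= critical_value:
            flips.append(f)
        if not base.range_narrow and (dmax - min(d.values())) <= range_threshold:
            narrows.append(f)
    order = X.features
    if not base.homogeneous:
        drivers = sorted(
            flips, key=lambda f: (-scores[f], order.index(f))
        )
    elif not base.range_narrow:
        drivers = sorted(narrows, key=lambda f: (-scores[f], order.index(f)))
    else:
        drivers = []
    irreducible = (not base.homogeneous) and not flips
    driver_set: list[str] = []
    if irreducible and pair_search and len(X.features) > 2:
        best = max(scores, key=lambda f: (scores[f], -order.index(f)))
        X1 = X.drop_feature(best)
        for g in X1.features:
            if len(X1.features) < 2:
                break
            Xr = X1.drop_feature(g)
            cov_r = pooled_covariance(
                Xr, shrinkage=shrinkage, condition_bound=condition_bound, tumors=covariance_tumors
            )
            d = _tumor_distances(Xr, cov_r, tumor_id, centroid_correction)
            if max(d.values()) <= critical_value:
                driver_set = sorted([best, g], key=order.index)
                break
    return {
        "scores": scores,
        "drivers": drivers,
        "driver_set": driver_set,
        "irreducible": irreducible,
        "base": base,
    }


def analyze_cohort(
    X: FeatureMatrix,
    critical_value: float = DEFAULT_CRITICAL_VALUE,
    range_threshold: float | None = None,
    shrinkage: float | str = "auto",
    condition_bound: float = DEFAULT_CONDITION_BOUND,
    lomo: bool = True,
    max_refine: int = 5,
    centroid_correction: bool = True,
    jackknife: bool = True,
) -> list[TumorSimilarityResult]:
    """Classify every tumor; run LOMO attribution on the non-similar ones.

    Two safeguards keep a heterogeneous tumor's own regional trend from
    inflating the covariance it is judged against:

    * ``jackknife`` (default): each tumor's distances use a covariance
      pooled from the *other* tumors (leave-one-tumor-out), so a tumor
      never masks itself.
    * a reweighting loop (at most ``max_refine`` passes, stopping at a
      fixed point): after each pass the pooling is further restricted to
      tumors currently classified homogeneous, cf. reweighted robust
      covariance estimation.

    Either restriction is skipped whenever it would leave fewer
    within-tumor degrees of freedom than features.  ``max_refine=1,
    jackknife=False`` reproduces plain pooling over all tumors.
    """
    if range_threshold is None:
        range_threshold = critical_value / 2.0
    all_ids = X.tumor_ids
    keep: set[str] = set(all_ids)
    n_feat = len(X.features)
    if not np.all(np.isfinite(X.data.to_numpy())):
        raise ValueError("non-finite values in feature matrix")

    # cache per-tumor centred deviations and scatter matrices: the pooled
    # covariance for any tumor subset is an O(1) combination of these
    centered = X.data - X.data.groupby(level=0).transform("mean")
    dev_by_tumor = {tid: centered.xs(tid, level=0).to_numpy(float) for tid in all_ids}
    ss_by_tumor = {tid: d.T @ d for tid, d in dev_by_tumor.items()}
    df_by_tumor = {tid: len(d) - 1 for tid, d in dev_by_tumor.items()}
    corr_by_tumor = {
        tid: len(d) / (len(d) - 1.0) if centroid_correction else 1.0
        for tid, d in dev_by_tumor.items()
    }

    def pool_df(tumors: set[str]) -> int:
        return sum(df_by_tumor[t] for t in tumors)

    def distances_for(tid: str, pool: set[str]) -> pd.Series:
        subset = pool - {tid} if jackknife else pool
        if pool_df(subset) <= n_feat:
            subset = set(all_ids) - {tid} if jackknife else set(all_ids)
        if pool_df(subset) <= n_feat:
            subset = set(all_ids)
        df = pool_df(subset)
        S = sum(ss_by_tumor[t] for t in subset) / df
        if np.any(np.diag(S) <= 0):
            zero = [X.features[i] for i in np.flatnonzero(np.diag(S) <= 0)]
            raise ValueError(f"feature(s) with zero within-tumor variance: {zero}")
        matrix, _ = _shrink_toward_diagonal(S, shrinkage, condition_bound)
        cho = linalg.cho_factor(matrix, lower=True)
        dev = dev_by_tumor[tid]
        d2 = np.einsum("ij,ji->i", dev, linalg.cho_solve(cho, dev.T))
        d2 = d2 * corr_by_tumor[tid]
        series = pd.Series(d2, index=centered.xs(tid, level=0).index)
        return f_calibrate_distances(series, df, n_feat)

    d2_by_tumor: dict[str, pd.Series] = {}
    for _ in range(max(1, max_refine)):
        d2_by_tumor = {tid: distances_for(tid, keep) for tid in all_ids}
        new_keep = {
            tid for tid in all_ids if d2_by_tumor[tid].max() <= critical_value
        }
        if not new_keep:
            new_keep = set(all_ids)
        if new_keep == keep:
            break
        keep = new_keep
    d2 = pd.concat(d2_by_tumor, names=["tumor_id", "region"])
    results = []
    for tid in all_ids:
        sub = d2.xs(tid, level=0)
        res = classify_tumor(
            {str(r): float(v) for r, v in sub.items()},
            tid,
            critical_value,
            range_threshold,
        )
        if lomo and (not res.homogeneous or not res.range_narrow):
            pool = keep - {tid} if jackknife else set(keep)
            if pool_df(pool) <= n_feat:
                pool = set(all_ids) - {tid} if jackknife else set(all_ids)
            if pool_df(pool) <= n_feat:
                pool = set(all_ids)
            cov_tumors = pool if pool != set(all_ids) else None
            att = leave_one_marker_out(
                X,
                tid,
                critical_value=critical_value,
                range_threshold=range_threshold,
                shrinkage=shrinkage,
                condition_bound=condition_bound,
                covariance_tumors=cov_tumors,
                centroid_correction=centroid_correction,
            )
            res.driver_markers = att["drivers"]
            res.driver_scores = att["scores"]
            res.driver_set = att["driver_set"]
            res.irreducible = att["irreducible"]
        results.append(res)
    return results


def cohort_summary(results: Sequence[TumorSimilarityResult]) -> dict:
    """Fractions of tumors classified homogeneous / narrow-range."""
    if len(results) == 0:
        raise ValueError("cohort_summary needs at least one tumor result")
    n = len(results)
    n_hom = sum(r.homogeneous for r in results)
    n_narrow = sum(r.range_narrow for r in results)
    return {
        "n_tumors": n,
        "n_homogeneous": n_hom,
        "frac_homogeneous": n_hom / n,
        "n_range_narrow": n_narrow,
        "frac_range_narrow": n_narrow / n,
        "heterogeneous_tumors": [r.tumor_id for r in results if not r.homogeneous],
        "wide_range_tumors": [r.tumor_id for r in results if not r.range_narrow],
    }
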