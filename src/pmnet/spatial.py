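"""Pairwise spatial-variability statistics and community group tests.

The spatial analysis asks how uniform PM2.5 is across a monitoring
domain.  Two pairwise statistics are used on aligned site series:

* the squared Pearson correlation (R2), sensitive to shared temporal
  structure but blind to scale offsets; and
* the coefficient of divergence

      COD_jk = sqrt( (1/p) * sum_i ((x_ij - x_ik) / (x_ij + x_ik))^2 ),

  which is 0 for identical series, 1 for completely divergent ones, and
  by convention >= 0.2 flags a heterogeneous pair.

Supporting pieces: great-circle distances, a distance-decay regression
(closer pairs should correlate more / diverge less), global Moran's I with
a permutation test for spatial clustering of per-site means, and
EJ-versus-non-EJ community comparisons (Welch t on pooled values, pairwise
rank-sum across site pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import InsufficientDataError, ValidationError, align_pairwise

logger = logging.getLogger("pmnet")

COD_HETEROGENEITY_THRESHOLD = 0.2
EARTH_RADIUS_KM = 6371.0

# default minimum overlap for a pairwise entry
MIN_OVERLAP = {"hourly": 72, "daily": 14}


@dataclass(frozen=True)
class PairwiseStatMatrix:
    stat: str  # cod | r2
    resolution: str  # hourly | daily
    values: pd.DataFrame  # symmetric, unit diag (r2) / zero diag (cod)
    n_overlap: pd.DataFrame


@dataclass(frozen=True)
class GroupComparison:
    test: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    statistic: float
    p_value: float
    mean_difference: float


def cod_pair(x, y, min_pairs: int = 1) -> float:
    """Coefficient of divergence of two aligned nonnegative series.

    Pairs whose sum is zero contribute no information to the relative
    difference and are skipped (with a QC log line), reducing p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("COD inputs must be aligned to equal length")
    keep = (x + y) != 0
    n_skipped = int(x.size - keep.sum())
    if n_skipped:
        logger.info("QC: COD skipped %d zero-sum pairs", n_skipped)
    x, y = x[keep], y[keep]
    if x.size < min_pairs or x.size == 0:
        raise InsufficientDataError("too few usable pairs for COD")
    return float(np.sqrt(np.mean(((x - y) / (x + y)) ** 2)))


def r2_pair(x, y) -> float:
    """Squared Pearson correlation of two aligned series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("R2 needs two varying series")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def pairwise_matrix(
    series_by_site: dict[str, pd.Series] | pd.DataFrame,
    stat: str = "cod",
    resolution: str = "hourly",
    min_overlap: int | None = None,
) -> PairwiseStatMatrix:
    """Site x site matrix of COD or R2 on pairwise-aligned series.

    Each pair is aligned on timestamps where both sites report; pairs
    below ``min_overlap`` (default 72 hours / 14 days) are left missing
    and logged.
    """
    if stat not in ("cod", "r2"):
        raise ValidationError("stat must be 'cod' or 'r2'")
    if isinstance(series_by_site, pd.DataFrame):
        series_by_site = {c: series_by_site[c] for c in series_by_site.columns}
    sites = list(series_by_site)
    if len(sites) < 2:
        raise ValidationError("pairwise statistics need at least two sites")
    if min_overlap is None:
        min_overlap = MIN_OVERLAP.get(resolution, 1)
    diag = 1.0 if stat == "r2" else 0.0
    values = pd.DataFrame(np.eye(len(sites)) * diag, index=sites, columns=sites)
    n_overlap = pd.DataFrame(0, index=sites, columns=sites)
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            pairs = align_pairwise(series_by_site[a], series_by_site[b])
            n = len(pairs)
            n_overlap.loc[a, b] = n_overlap.loc[b, a] = n
            if n < min_overlap:
                logger.warning("QC: pair (%s, %s) below minimum overlap (%d < %d)", a, b, n, min_overlap)
                values.loc[a, b] = values.loc[b, a] = np.nan
                continue
            try:
                v = cod_pair(pairs["a"], pairs["b"]) if stat == "cod" else r2_pair(pairs["a"], pairs["b"])
            except InsufficientDataError:
                v = np.nan
            values.loc[a, b] = values.loc[b, a] = v
    return PairwiseStatMatrix(stat=stat, resolution=resolution, values=values, n_overlap=n_overlap)


def summarize_matrix(matrix: PairwiseStatMatrix | pd.DataFrame) -> dict:
    """Mean/min/max over the off-diagonal entries of one triangle."""
    df = matrix.values if isinstance(matrix, PairwiseStatMatrix) else matrix
    arr = df.to_numpy()
    tri = arr[np.tril_indices_from(arr, k=-1)]
    tri = tri[np.isfinite(tri)]
    if tri.size == 0:
        raise InsufficientDataError("no finite pairwise entries")
    return {"mean": float(tri.mean()), "min": float(tri.min()), "max": float(tri.max()), "n_pairs": int(tri.size)}


def classify_homogeneity(
    matrix: PairwiseStatMatrix, threshold: float = COD_HETEROGENEITY_THRESHOLD
) -> tuple[pd.DataFrame, float]:
    """Label site pairs homogeneous (< threshold) or heterogeneous (>=).

    Only meaningful for COD matrices; returns the per-pair long table and
    the fraction of pairs labelled heterogeneous.
    """
    if matrix.stat != "cod":
        raise ValidationError("homogeneity classification applies to COD matrices")
    sites = list(matrix.values.index)
    rows = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            v = matrix.values.loc[a, b]
            if not np.isfinite(v):
                continue
            rows.append(
                {"site_a": a, "site_b": b, "cod": float(v), "label": "heterogeneous" if v >= threshold else "homogeneous"}
            )
    table = pd.DataFrame(rows)
    frac = float((table["label"] == "heterogeneous").mean()) if len(table) else np.nan
    return table, frac


def haversine_km(a, b) -> float:
    """Great-circle distance between (lat, lon) points, Earth radius 6371 km."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValidationError("coordinates outside valid lat/lon ranges")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def distance_matrix(sites: pd.DataFrame) -> pd.DataFrame:
    """Symmetric site x site great-circle distances from a site table."""
    ids = sites["site_id"].tolist()
    coords = sites[["lat", "lon"]].to_numpy()
    n = len(ids)
    km = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            km[i, j] = km[j, i] = haversine_km(coords[i], coords[j])
    return pd.DataFrame(km, index=ids, columns=ids)


def distance_decay(stat_matrix: PairwiseStatMatrix | pd.DataFrame, dist_km: pd.DataFrame) -> dict:
    """OLS of the pairwise statistic on pairwise distance.

    COD is expected to rise with distance and R2 to fall; the slope sign
    is reported, not enforced.
    """
    values = stat_matrix.values if isinstance(stat_matrix, PairwiseStatMatrix) else stat_matrix
    if list(values.index) != list(dist_km.index):
        # allow the same sites in a different order
        if set(values.index) != set(dist_km.index):
            raise ValidationError("statistic and distance matrices cover different sites")
        dist_km = dist_km.loc[values.index, values.columns]
    arr_s = values.to_numpy()
    arr_d = dist_km.to_numpy()
    idx = np.tril_indices_from(arr_s, k=-1)
    s, d = arr_s[idx], arr_d[idx]
    keep = np.isfinite(s) & np.isfinite(d)
    s, d = s[keep], d[keep]
    if s.size < 3:
        raise InsufficientDataError("too few pairs for distance-decay regression")
    if np.allclose(s, s[0]):
        return {"slope": 0.0, "intercept": float(s[0]), "r2": 0.0, "p_value": 1.0, "n_pairs": int(s.size)}
    res = stats.linregress(d, s)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n_pairs": int(s.size),
    }


# ---------------------------------------------------------------------------
# spatial autocorrelation


def _row_standardize(w: np.ndarray) -> np.ndarray:
    rowsum = w.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValidationError("weight matrix has an isolated site (zero row sum)")
    return w / rowsum


def spatial_weights(sites: pd.DataFrame, scheme: str = "inverse_distance", k: int = 4) -> pd.DataFrame:
    """Row-standardized spatial weights from site coordinates."""
    km = distance_matrix(sites).to_numpy()
    n = km.shape[0]
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / km
        np.fill_diagonal(w, 0.0)
    elif scheme == "k_nearest":
        w = np.zeros_like(km)
        for i in range(n):
            order = np.argsort(km[i])
            neighbors = [j for j in order if j != i][:k]
            w[i, neighbors] = 1.0
    else:
        raise ValidationError("weights scheme must be 'inverse_distance' or 'k_nearest'")
    ids = sites["site_id"].tolist()
    return pd.DataFrame(_row_standardize(w), index=ids, columns=ids)


def morans_i(
    values,
    weights: pd.DataFrame | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    row_standardize: bool = True,
) -> dict:
    """Global Moran's I with a permutation p-value.

    ``values`` are per-site scalars (e.g. study-period mean PM2.5) in the
    same order as the weight matrix rows.  The p-value is two-sided around
    the permutation-null expectation E[I] = -1/(n-1), computed with the
    (1 + k) / (n_perm + 1) estimator.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValidationError("Moran's I needs at least 4 sites")
    if np.allclose(x, x[0]):
        raise InsufficientDataError("Moran's I undefined for constant values")
    w = weights.to_numpy(dtype=float) if isinstance(weights, pd.DataFrame) else np.asarray(weights, dtype=float)
    if w.shape != (n, n):
        raise ValidationError("weight matrix shape does not match values")
    if row_standardize:
        w = _row_standardize(w.copy())

    def _moran(z):
        zc = z - z.mean()
        return float(n / w.sum() * (zc @ w @ zc) / (zc @ zc))

    i_obs = _moran(x)
    expected = -1.0 / (n - 1)
    p = np.nan
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        dev_obs = abs(i_obs - expected)
        hits = 0
        for _ in range(n_permutations):
            if abs(_moran(rng.permutation(x)) - expected) >= dev_obs - 1e-15:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
    return {"I": i_obs, "expected": expected, "p_value": float(p), "n_sites": n}


# ---------------------------------------------------------------------------
# community group comparisons


def _pool(series_by_site: dict[str, pd.Series], sites: list[str]) -> np.ndarray:
    vals = np.concatenate([np.asarray(series_by_site[s].dropna(), dtype=float) for s in sites])
    if vals.size < 2:
        raise ValidationError("group needs at least two values")
    return vals


def welch_group_test(
    series_by_site: dict[str, pd.Series], group_a: list[str], group_b: list[str]
) -> GroupComparison:
    """Unequal-variance t-test of pooled values, group A minus group B."""
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    a, b = _pool(series_by_site, group_a), _pool(series_by_site, group_b)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        test="welch_t",
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
    )


def rank_sum_pairwise(
    series_by_site: dict[str, pd.Series],
    group_a: list[str],
    group_b: list[str],
    holm: bool = False,
) -> pd.DataFrame:
    """Two-sided rank-sum test for every (group A site, group B site) pair.

    Uses the exact null distribution when sample sizes permit (scipy's
    exact Mann-Whitney path; no ties, n small) and the normal
    approximation otherwise.  P-values are reported raw; ``holm=True``
    adds a step-down-adjusted column.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    rows = []
    for a in group_a:
        for b in group_b:
            x = np.asarray(series_by_site[a].dropna(), dtype=float)
            y = np.asarray(series_by_site[b].dropna(), dtype=float)
            if x.size < 2 or y.size < 2:
                raise ValidationError(f"pair ({a}, {b}) has a group with < 2 values")
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            rows.append(
                {
                    "site_a": a,
                    "site_b": b,
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "mean_difference": float(x.mean() - y.mean()),
                }
            )
    table = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        table["p_holm"] = multipletests(table["p_value"], method="holm")[1]
    return table


def group_test(
    series_by_site: dict[str, pd.Series],
    group_a: list[str],
    group_b: list[str],
    test: str = "welch_t",
    holm: bool = False,
):
    """Dispatch to the Welch pooled test or the pairwise rank-sum table."""
    if test == "welch_t":
        return welch_group_test(series_by_site, group_a, group_b)
    if test == "wilcoxon_rank":
        return rank_sum_pairwise(series_by_site, group_a, group_b, holm=holm)
    raise ValidationError("test must be 'welch_t' or 'wilcoxon_rank'")
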