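"""Inferential layer: fixed-effects ANOVA, Storey q-values, interaction
clustering, Tukey post hoc contrasts and log2 fold-change correlations.

The one- and two-way ANOVAs are the classical balanced sum-of-squares
decompositions, vectorized so thousands of proteins are tested in one call.
The degenerate all-constant case (zero between- and within-group variance)
is defined as F = 0, p = 1.  Storey's q-value uses the cubic-smoother pi0
estimate on a lambda grid, which reduces exactly to Benjamini–Hochberg
adjusted p-values when pi0 is forced to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import StatsPreconditionError

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)

__all__ = [
    "one_way_anova",
    "one_way_anova_matrix",
    "two_way_anova",
    "two_way_anova_matrix",
    "storey_pi0",
    "storey_qvalues",
    "tukey_hsd",
    "cluster_interaction_profiles",
    "correlate_log2fc",
    "CorrelationResult",
]


def _f_pvalue(F, dfn, dfd):
    with np.errstate(invalid="ignore"):
        return sps.f.sf(F, dfn, dfd)


def one_way_anova_matrix(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise one-way fixed-effects ANOVA.

    ``groups`` is a list of 2-D arrays, one per group, each shaped
    (n_items, n_replicates); returns per-item F and p arrays.
    """
    if len(groups) < 2:
        raise StatsPreconditionError("need at least 2 groups")
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if any(g.shape[1] < 2 for g in groups):
        raise StatsPreconditionError("every group needs at least 2 values")
    n_items = groups[0].shape[0]
    if any(g.shape[0] != n_items for g in groups):
        raise ValueError("groups must agree on the number of rows")
    sizes = np.array([g.shape[1] for g in groups], dtype=float)
    total_n = sizes.sum()
    k = len(groups)
    means = np.stack([g.mean(axis=1) for g in groups], axis=1)
    grand = (means * sizes).sum(axis=1) / total_n
    ss_between = (sizes * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means.T))
    dfb = k - 1
    dfw = total_n - k
    if dfw < 1:
        raise StatsPreconditionError("error degrees of freedom must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / dfb) / (ss_within / dfw)
    p = _f_pvalue(F, dfb, dfw)
    # Degenerate cases: no variance anywhere -> F=0, p=1; perfect separation
    # with zero within-group variance -> p=0.
    all_flat = (ss_within == 0) & (ss_between == 0)
    F = np.where(all_flat, 0.0, F)
    p = np.where(all_flat, 1.0, p)
    sep = (ss_within == 0) & (ss_between > 0)
    F = np.where(sep, np.inf, F)
    p = np.where(sep, 0.0, p)
    return F, p


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over ≥2 groups of ≥2 replicate values.

    For two groups F equals the square of the pooled-variance t statistic.
    """
    F, p = one_way_anova_matrix([np.asarray(g, dtype=float)[None, :] for g in groups])
    return float(F[0]), float(p[0])


@dataclass(frozen=True)
class TwoWayAnovaResult:
    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_ab: float
    p_ab: float


def two_way_anova_matrix(values: np.ndarray) -> dict[str, np.ndarray]:
    """Balanced fixed-effects two-way ANOVA with interaction, vectorized.

    ``values`` has shape (n_items, a, b, r): a levels of the first factor
    (condition), b of the second (time), r replicates per cell.  NaNs are
    rejected — the design must be balanced and complete.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 3:
        x = x[None, ...]
    if x.ndim != 4:
        raise ValueError("expected array of shape (n_items, a, b, r)")
    if np.isnan(x).any():
        raise StatsPreconditionError("unbalanced design: missing cell values")
    _, a, b, r = x.shape
    if a < 2 or b < 2 or r < 2:
        raise StatsPreconditionError("need >=2 levels per factor and >=2 replicates")
    grand = x.mean(axis=(1, 2, 3), keepdims=True)
    am = x.mean(axis=(2, 3), keepdims=True)
    bm = x.mean(axis=(1, 3), keepdims=True)
    cm = x.mean(axis=3, keepdims=True)
    ss_a = (b * r) * ((am - grand) ** 2).sum(axis=(1, 2, 3))
    ss_b = (a * r) * ((bm - grand) ** 2).sum(axis=(1, 2, 3))
    ss_ab = r * ((cm - am - bm + grand) ** 2).sum(axis=(1, 2, 3))
    ss_e = ((x - cm) ** 2).sum(axis=(1, 2, 3))
    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    out = {}
    mse = ss_e / df_e
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss / df) / mse
        p = _f_pvalue(F, df, df_e)
        flat = (ss_e == 0) & (ss == 0)
        F = np.where(flat, 0.0, F)
        p = np.where(flat, 1.0, p)
        sep = (ss_e == 0) & (ss > 0)
        F = np.where(sep, np.inf, F)
        p = np.where(sep, 0.0, p)
        out[f"f_{name}"] = F
        out[f"p_{name}"] = p
    return out


def two_way_anova(values: np.ndarray) -> TwoWayAnovaResult:
    """Scalar convenience wrapper around :func:`two_way_anova_matrix`."""
    res = two_way_anova_matrix(np.asarray(values, dtype=float)[None, ...])
    return TwoWayAnovaResult(
        f_a=float(res["f_a"][0]),
        p_a=float(res["p_a"][0]),
        f_b=float(res["f_b"][0]),
        p_b=float(res["p_b"][0]),
        f_ab=float(res["f_ab"][0]),
        p_ab=float(res["p_ab"][0]),
    )


def _validate_pvalues(p: np.ndarray) -> None:
    if p.size == 0:
        raise StatsPreconditionError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise StatsPreconditionError("p-values must lie in (0, 1]")


def storey_pi0(p, lambdas=DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 with the cubic-smoother method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    and a cubic smoother extrapolates to lambda = 1; the estimate is clipped
    to (0, 1].  Fewer than 10 p-values fall back to pi0 = 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    _validate_pvalues(p)
    m = p.size
    if m < 10:
        return 1.0
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, 1.0))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(p, pi0: float | None = None, lambdas=DEFAULT_LAMBDA_GRID) -> np.ndarray:
    """Storey q-values for a collection of p-values.

    ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j)``; with
    ``pi0=1`` this is exactly Benjamini–Hochberg.  Output order matches the
    input, q is monotone in sorted p, and q <= 1.
    """
    p = np.asarray(p, dtype=float).ravel()
    _validate_pvalues(p)
    if pi0 is None:
        pi0 = storey_pi0(p, lambdas=lambdas)
    if not (0 < pi0 <= 1):
        raise StatsPreconditionError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for every pair of groups.

    Built on the studentized-range distribution (scipy); for two groups the
    adjusted p coincides with the pooled two-sample t-test p-value.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatsPreconditionError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise StatsPreconditionError("every group needs at least 2 values")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(groups))]
    means = [g.mean() for g in groups]
    ss_within = sum(((g - mu) ** 2).sum() for g, mu in zip(groups, means))
    rows = []
    if ss_within == 0:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                diff = means[i] - means[j]
                rows.append((labels[i], labels[j], diff, 1.0 if diff == 0 else 0.0))
    else:
        res = sps.tukey_hsd(*groups)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                rows.append(
                    (labels[i], labels[j], means[i] - means[j], float(res.pvalue[i, j]))
                )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])


def cluster_interaction_profiles(profiles: pd.DataFrame, k: int) -> pd.DataFrame:
    """Hierarchical (Ward, Euclidean) clustering of z-scored profiles.

    Rows are proteins, columns condition×time mean-abundance cells.  The
    frame is sorted by accession before clustering so the partition is
    independent of input row order; cluster ids 1..k are assigned in
    descending cluster size (ties broken by smallest member accession).
    Returns a frame with the cluster id and the standardized profile.
    """
    if k < 2:
        raise StatsPreconditionError("k must be >= 2")
    if k > len(profiles):
        raise StatsPreconditionError(
            f"k={k} exceeds the number of profiles ({len(profiles)})"
        )
    prof = profiles.sort_index()
    x = prof.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    raw = fcluster(linkage(z, method="ward"), t=k, criterion="maxclust")
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), prof.index[raw == c].min()),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    out = pd.DataFrame(
        z, index=prof.index, columns=[f"z_{c}" for c in prof.columns]
    )
    out.insert(0, "cluster_id", [relabel[c] for c in raw])
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    n_dropped: int


def correlate_log2fc(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson correlation of two per-protein log2 fold-change vectors.

    Pairs are matched on the shared index; non-finite pairs are dropped and
    counted.  Needs n >= 3 finite pairs and nonzero variance in both.
    """
    common = x.index.intersection(y.index)
    xv = x.reindex(common).to_numpy(dtype=float)
    yv = y.reindex(common).to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    n_dropped = int((~ok).sum())
    xv, yv = xv[ok], yv[ok]
    if xv.size < 3:
        raise StatsPreconditionError("need at least 3 finite pairs")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise StatsPreconditionError("zero variance in correlation input")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(
        r=float(r), r_squared=float(r) ** 2, p_value=float(p), n=int(xv.size),
        n_dropped=n_dropped,
    )
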