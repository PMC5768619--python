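"""Adaptive correlation testing and the group × time ANOVA screen.

The decision procedure implemented by :func:`adaptive_correlation`:

1. Both series are screened for normality (Shapiro–Wilk).  If either fails,
   Spearman's test is used on the full data — rank correlation is the
   appropriate test for non-normal marginals.
2. If both pass and neither series contains an outlier (any value outside
   mean ± 2·SD of its series), Pearson's test is used on the full data.
3. If an outlier is present, Pearson is run with and without the flagged
   donor(s).  If the outcome — significance at ``alpha`` and the sign of r —
   is unchanged, the outlier is included back and the full-data Pearson
   result is reported.  Otherwise the outlier drove the result and the
   robust Spearman test on the full data is preferred.

This guards the small cohorts typical of donor studies (n = 6–9) against
single extreme measurements manufacturing or masking a correlation.

Spearman p-values are exact for n <= 8 (full enumeration of rank
permutations, ties handled through average ranks); the t approximation is
used for larger n.  Significance is accepted at p < 0.01 by default
throughout the package.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnovaRow,
    CorrelationResult,
    InsufficientDataError,
    Method,
    NormalityResult,
    Timepoint,
    ZeroVarianceError,
)

EXACT_SPEARMAN_MAX_N = 8


def _as_clean_array(values: Sequence[float], name: str = "values") -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return x


def shapiro_wilk(values: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk normality test (W statistic and approximate p)."""
    x = _as_clean_array(values)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"Shapiro–Wilk requires n >= 3, got {n}")
    if n > 5000:
        raise ValueError("Shapiro–Wilk p approximation unreliable for n > 5000")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("zero variance: all values equal")
    res = stats.shapiro(x)
    return NormalityResult(W=float(res.statistic), p=float(res.pvalue), n=n)


def detect_outliers(values: Sequence[float]) -> list[int]:
    """Indices of values outside mean ± 2·SD of the full series.

    The sample (n−1) standard deviation is used, computed on the complete
    series including the candidate outliers.  A constant series has no
    outliers.
    """
    x = _as_clean_array(values)
    if x.size < 3:
        raise InsufficientDataError(f"outlier detection requires n >= 3, got {x.size}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return []
    mean = float(np.mean(x))
    return [int(i) for i in np.nonzero(np.abs(x - mean) > 2.0 * sd)[0]]


def _check_pair(x: np.ndarray, y: np.ndarray) -> int:
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"correlation requires n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVarianceError("undefined correlation: constant input")
    return n


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Product-moment correlation with two-sided p from t with n−2 df."""
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    n = _check_pair(xa, ya)
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    p = _pearson_pvalue(r, n)
    return r, p, n


def _pearson_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    """All n! permutations as an (n!, n) index array (n <= 8)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman rank correlation; exact permutation p for n <= 8.

    rho is Pearson's r on average ranks (ties receive the mean rank).  The
    exact two-sided p is the proportion of the n! equally likely rank
    assignments with |rho| at least as extreme as observed; for n > 8 the
    t approximation with n−2 df is used.
    """
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    n = _check_pair(xa, ya)
    xr = stats.rankdata(xa)
    yr = stats.rankdata(ya)
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ZeroVarianceError("undefined correlation: constant ranks")
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    rho = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = _rank_permutations(n)
        # correlation of xr with every permutation of yr, vectorized
        yp = yc[perms]  # (n!, n), already centered
        rhos = yp @ xc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = _pearson_pvalue(rho, n)
    return rho, p, n


def _align_pair(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if labels is None:
        labels = [str(i) for i in range(xa.size)]
    if len(labels) != xa.size:
        raise ValueError("labels must match data length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep], [labels[i] for i in np.nonzero(keep)[0]]


def adaptive_correlation(
    x: Sequence[float],
    y: Sequence[float],
    *,
    labels: Sequence[str] | None = None,
    alpha: float = 0.01,
    normality_alpha: float = 0.05,
    var_a: str = "x",
    var_b: str = "y",
    timepoint: Timepoint | None = None,
    _norm_p: tuple[float, float] | None = None,
    _outlier_idx: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
) -> CorrelationResult:
    """Run the adaptive Pearson/Spearman decision procedure on one pair.

    ``labels`` identifies observations (donor ids); pairs with a missing
    value in either series are dropped first (pairwise-complete).  The
    private ``_norm_p`` / ``_outlier_idx`` arguments let bulk scans pass in
    per-series screening results precomputed on complete series; results are
    identical to recomputation.
    """
    xa, ya, labs = _align_pair(x, y, labels)
    n = _check_pair(xa, ya)
    trace: list[str] = []

    if _norm_p is None:
        px = shapiro_wilk(xa).p
        py = shapiro_wilk(ya).p
    else:
        px, py = _norm_p
    normal = px >= normality_alpha and py >= normality_alpha
    if not normal:
        which = [v for v, p_ in ((var_a, px), (var_b, py)) if p_ < normality_alpha]
        trace.append(f"shapiro_fail:{','.join(which)}")
        trace.append("spearman")
        r, p, n_used = spearman(xa, ya)
        return CorrelationResult(
            var_a, var_b, timepoint, Method.SPEARMAN, r, p, n_used,
            decision_trace=tuple(trace),
        )
    trace.append("normality_ok")

    if _outlier_idx is None:
        out_idx = sorted(set(detect_outliers(xa)) | set(detect_outliers(ya)))
    else:
        out_idx = sorted(set(_outlier_idx[0]) | set(_outlier_idx[1]))
    if not out_idx:
        trace.append("no_outliers")
        trace.append("pearson")
        r, p, n_used = pearson(xa, ya)
        return CorrelationResult(
            var_a, var_b, timepoint, Method.PEARSON, r, p, n_used,
            decision_trace=tuple(trace),
        )

    flagged = tuple(labs[i] for i in out_idx)
    trace.append(f"outliers:{','.join(flagged)}")
    r_full, p_full, _ = pearson(xa, ya)
    keep = np.ones(n, dtype=bool)
    keep[out_idx] = False
    if keep.sum() < 3 or np.ptp(xa[keep]) == 0 or np.ptp(ya[keep]) == 0:
        trace.append("retest_infeasible")
        trace.append("spearman")
        r, p, n_used = spearman(xa, ya)
        return CorrelationResult(
            var_a, var_b, timepoint, Method.SPEARMAN, r, p, n_used,
            outliers_excluded=flagged, decision_trace=tuple(trace),
        )
    r_sub, p_sub, _ = pearson(xa[keep], ya[keep])
    same_outcome = ((p_full < alpha) == (p_sub < alpha)) and (
        np.sign(r_full) == np.sign(r_sub)
    )
    if same_outcome:
        trace.append("outlier_retest_consistent")
        trace.append("pearson")
        return CorrelationResult(
            var_a, var_b, timepoint, Method.PEARSON, r_full, p_full, n,
            outliers_excluded=flagged, decision_trace=tuple(trace),
        )
    trace.append("outlier_retest_changed")
    trace.append("spearman")
    r, p, n_used = spearman(xa, ya)
    return CorrelationResult(
        var_a, var_b, timepoint, Method.SPEARMAN, r, p, n_used,
        outliers_excluded=flagged, decision_trace=tuple(trace),
    )


# -- two-way ANOVA --------------------------------------------------------


def two_way_anova(
    data: pd.DataFrame,
    variable: str = "",
    alpha: float = 0.01,
) -> AnovaRow:
    """Fixed-effects two-way (group × time) ANOVA with interaction.

    ``data`` is a tidy frame with columns ``group``, ``timepoint`` and
    ``value``.  Balanced designs use the exact Type I sums-of-squares
    decomposition (SS_total = SS_group + SS_time + SS_interaction +
    SS_error); unbalanced cells are handled by the unweighted (cell-mean)
    analysis with the harmonic mean cell size, in which case the components
    no longer add to SS_total.  Raises on any empty cell, naming it.
    """
    for c in ("group", "timepoint", "value"):
        if c not in data.columns:
            raise ValueError(f"two_way_anova: missing column {c!r}")
    d = data.dropna(subset=["value"])
    groups = sorted(d["group"].unique())
    times = sorted(d["timepoint"].unique(),
                   key=lambda t: Timepoint(t).day if t in Timepoint._value2member_map_ else str(t))
    if len(groups) < 2 or len(times) < 2:
        raise ValueError("two_way_anova: need >= 2 levels per factor")
    a, b = len(groups), len(times)
    cells = {}
    for g in groups:
        for t in times:
            vals = d.loc[(d["group"] == g) & (d["timepoint"] == t), "value"].to_numpy()
            if vals.size == 0:
                raise ValueError(f"two_way_anova: empty cell (group={g}, timepoint={t})")
            cells[(g, t)] = vals
    sizes = {k: v.size for k, v in cells.items()}
    N = sum(sizes.values())
    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_e = N - a * b
    if df_e <= 0:
        raise ValueError("two_way_anova: no residual degrees of freedom")
    ss_e = sum(float(((v - v.mean()) ** 2).sum()) for v in cells.values())
    balanced = len(set(sizes.values())) == 1

    if balanced:
        y = d["value"].to_numpy()
        grand = y.mean()
        mean_g = {g: np.concatenate([cells[(g, t)] for t in times]).mean() for g in groups}
        mean_t = {t: np.concatenate([cells[(g, t)] for g in groups]).mean() for t in times}
        n_cell = next(iter(sizes.values()))
        ss_a = n_cell * b * sum((mean_g[g] - grand) ** 2 for g in groups)
        ss_b = n_cell * a * sum((mean_t[t] - grand) ** 2 for t in times)
        ss_ab = n_cell * sum(
            (cells[(g, t)].mean() - mean_g[g] - mean_t[t] + grand) ** 2
            for g in groups
            for t in times
        )
    else:
        m = {k: v.mean() for k, v in cells.items()}
        n_h = (a * b) / sum(1.0 / s for s in sizes.values())
        row = {g: np.mean([m[(g, t)] for t in times]) for g in groups}
        col = {t: np.mean([m[(g, t)] for g in groups]) for t in times}
        grand_m = np.mean(list(m.values()))
        ss_a = n_h * b * sum((row[g] - grand_m) ** 2 for g in groups)
        ss_b = n_h * a * sum((col[t] - grand_m) ** 2 for t in times)
        ss_ab = n_h * sum(
            (m[(g, t)] - row[g] - col[t] + grand_m) ** 2
            for g in groups
            for t in times
        )

    mse = ss_e / df_e
    if mse == 0:
        raise ZeroVarianceError("two_way_anova: zero within-cell variance")
    F_a = (ss_a / df_a) / mse
    F_b = (ss_b / df_b) / mse
    F_ab = (ss_ab / df_ab) / mse
    p_a = float(stats.f.sf(F_a, df_a, df_e))
    p_b = float(stats.f.sf(F_b, df_b, df_e))
    p_ab = float(stats.f.sf(F_ab, df_ab, df_e))
    ss_total = float(((d["value"] - d["value"].mean()) ** 2).sum())
    return AnovaRow(
        variable=variable,
        F_group=float(F_a), F_time=float(F_b), F_interaction=float(F_ab),
        p_group=p_a, p_time=p_b, p_interaction=p_ab,
        sig_group=p_a < alpha, sig_time=p_b < alpha, sig_interaction=p_ab < alpha,
        ss_group=float(ss_a), ss_time=float(ss_b), ss_interaction=float(ss_ab),
        ss_error=float(ss_e), ss_total=ss_total, balanced=balanced,
    )


def anova_screen(dataset, variables: Sequence[str] | None = None,
                 alpha: float = 0.01) -> pd.DataFrame:
    """Group × storage-time ANOVA for every ex-vivo variable in a dataset.

    Returns one row per variable with F and p per factor; variables whose
    design has an empty cell are skipped (reported in the ``error`` column).
    """
    from .datatypes import Compartment  # local to avoid cycle at import time

    if variables is None:
        variables = dataset.variables_in(Compartment.EX_VIVO)
    rows = []
    for var in variables:
        frames = []
        for tp in dataset.storage_timepoints():
            for g in ("deficient", "sufficient"):
                s = dataset.series(var, tp, group=g)
                if len(s):
                    frames.append(pd.DataFrame(
                        {"group": g, "timepoint": tp.value, "value": s.to_numpy()}
                    ))
        tidy = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["group", "timepoint", "value"]
        )
        try:
            row = two_way_anova(tidy, variable=var, alpha=alpha)
            rows.append({**row.__dict__, "error": ""})
        except (ValueError, ZeroVarianceError) as exc:
            rows.append({"variable": var, "error": str(exc)})
    return pd.DataFrame(rows)
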