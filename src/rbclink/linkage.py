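"""Metabolic linkage matrices, between-group rewiring, intra-parameter scans.

Metabolites connected by shared enzymatic constraints correlate with each
other; a between-group change in such a correlation ("rewiring") is scored
as the absolute difference in correlation magnitude, Δ = ||r_A| − |r_B||,
with pairs exceeding a 0.30 threshold flagged.  Linkage correlations pool
every (donor, storage-timepoint) observation of a group — a deliberate
fidelity-over-purity choice (repeated measures per donor are
pseudo-replicates; a per-timepoint-average alternative is provided).

The intra-parameter scan asks whether a variable measured in both
compartments tracks its own baseline throughout storage (the
"donor-signature" effect): baseline vs stored levels, day by day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corrstats import adaptive_correlation
from .datatypes import (
    Compartment,
    CorrelationResult,
    Group,
    InsufficientDataError,
    LinkageDelta,
    Timepoint,
    ZeroVarianceError,
)
from .dataset import LongitudinalDataset

logger = logging.getLogger(__name__)

DELTA_MODES = ("abs_magnitude", "signed")
REWIRED_THRESHOLD = 0.30


@dataclass
class LinkageMatrices:
    """Symmetric correlation (r) and p matrices over one group's variables."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    group: str
    insufficient_pairs: list[tuple[str, str]] = field(default_factory=list)


def linkage_matrix(
    dataset: LongitudinalDataset,
    group: Group | str,
    variables: Sequence[str] | None = None,
    *,
    alpha: float = 0.01,
    include_baseline: bool = False,
    collapse: str = "pooled",
) -> LinkageMatrices:
    """All-vs-all correlations within one group, pooled over storage days.

    ``collapse='pooled'`` uses every (donor, storage-timepoint) observation
    as one point (the default; baseline samples excluded unless asked for);
    ``collapse='timepoint_mean'`` first averages each donor over timepoints.
    Method selection per pair follows :func:`adaptive_correlation` on the
    pooled series.  Pairs with fewer than 3 pooled observations get a
    missing (NaN) cell and are listed in ``insufficient_pairs``.
    """
    if collapse not in ("pooled", "timepoint_mean"):
        raise ValueError("collapse must be 'pooled' or 'timepoint_mean'")
    g = Group(group)
    if variables is None:
        variables = dataset.variables_in(Compartment.EX_VIVO)
    variables = list(variables)
    series: dict[str, pd.Series] = {}
    for v in variables:
        s = dataset.pooled_series(v, group=g, include_baseline=include_baseline)
        if collapse == "timepoint_mean":
            donors = [lab.split(":", 1)[0] for lab in s.index]
            s = s.groupby(donors).mean()
        series[v] = s
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables)
    insufficient: list[tuple[str, str]] = []
    for i, a in enumerate(variables):
        n.iloc[i, i] = len(series[a])
        for j in range(i + 1, k):
            b = variables[j]
            sa, sb = series[a].align(series[b], join="inner")
            try:
                res = adaptive_correlation(
                    sa.to_numpy(), sb.to_numpy(), labels=list(sa.index),
                    alpha=alpha, var_a=a, var_b=b,
                )
            except (InsufficientDataError, ZeroVarianceError):
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                insufficient.append((a, b))
                continue
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p
            n.loc[a, b] = n.loc[b, a] = res.n_used
    return LinkageMatrices(r=r, p=p, n=n, group=g.value,
                           insufficient_pairs=insufficient)


def differential_linkage(
    matrix_a: LinkageMatrices | pd.DataFrame,
    matrix_b: LinkageMatrices | pd.DataFrame,
    threshold: float = REWIRED_THRESHOLD,
    mode: str = "abs_magnitude",
) -> list[LinkageDelta]:
    """Pairwise correlation deltas between two groups, sorted descending.

    ``abs_magnitude`` (default): delta = ||r_A| − |r_B||, the change in
    linkage strength regardless of direction.  ``signed``: delta =
    |r_A − r_B|, which also scores sign flips.  Pairs whose correlation
    changes sign with both |r| >= 0.2 carry ``sign_flip=True`` in either
    mode.  Symmetric in its two arguments.  Pairs with a missing r in
    either matrix are skipped.
    """
    if mode not in DELTA_MODES:
        raise ValueError(f"mode must be one of {DELTA_MODES}")
    ra = matrix_a.r if isinstance(matrix_a, LinkageMatrices) else matrix_a
    rb = matrix_b.r if isinstance(matrix_b, LinkageMatrices) else matrix_b
    set_a, set_b = set(ra.index), set(rb.index)
    if set_a != set_b:
        diff = sorted(set_a.symmetric_difference(set_b))
        raise ValueError(f"variable sets differ between groups: {diff}")
    variables = list(ra.index)
    rb = rb.loc[variables, variables]
    out: list[LinkageDelta] = []
    for i, a in enumerate(variables):
        for j in range(i + 1, len(variables)):
            b = variables[j]
            r1 = float(ra.loc[a, b])
            r2 = float(rb.loc[a, b])
            if np.isnan(r1) or np.isnan(r2):
                continue
            if mode == "abs_magnitude":
                delta = abs(abs(r1) - abs(r2))
            else:
                delta = abs(r1 - r2)
            flip = (np.sign(r1) != np.sign(r2)) and min(abs(r1), abs(r2)) >= 0.2
            out.append(
                LinkageDelta(
                    var_a=a, var_b=b, r_group1=r1, r_group2=r2,
                    delta=delta, sign_flip=bool(flip),
                    rewired=delta > threshold,
                )
            )
    out.sort(key=lambda d: (-d.delta, d.var_a, d.var_b))
    return out


def deltas_to_frame(deltas: Sequence[LinkageDelta]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in deltas])


@dataclass
class IntraParameterResult:
    """Baseline→storage self-correlation of one both-compartment variable."""

    variable: str
    per_timepoint: list[CorrelationResult]
    all_timepoints_significant: bool
    partial: bool


def intra_parameter_scan(
    dataset: LongitudinalDataset,
    alpha: float = 0.01,
    *,
    group: Group | str | None = Group.DEFICIENT,
    normality_alpha: float = 0.05,
) -> list[IntraParameterResult]:
    """Correlate each both-compartment variable's baseline with its stored
    levels at every storage day; flag variables significant at every day.

    Variables with no baseline measurements are skipped with a log entry.
    Days without stored measurements are skipped and the result marked
    ``partial`` (the flag then refers to the tested days only).
    """
    results: list[IntraParameterResult] = []
    tps = dataset.storage_timepoints()
    both_vars = [
        str(n) for n, c in dataset.variables["compartment"].items()
        if c == Compartment.BOTH.value
    ]
    for var in both_vars:
        base = dataset.series(var, Timepoint.NS, group=group)
        if len(base) == 0:
            logger.info("intra_parameter_scan: %s has no baseline values; skipped", var)
            continue
        per_tp: list[CorrelationResult] = []
        partial = False
        ok = True
        for tp in tps:
            stored = dataset.series(var, tp, group=group)
            if len(stored) == 0:
                partial = True
                continue
            sa, sb = base.align(stored, join="inner")
            if len(sa) < 3:
                ok = False
                continue
            try:
                res = adaptive_correlation(
                    sa.to_numpy(), sb.to_numpy(), labels=list(sa.index),
                    alpha=alpha, normality_alpha=normality_alpha,
                    var_a=var, var_b=var, timepoint=tp,
                )
            except (ZeroVarianceError, InsufficientDataError):
                ok = False
                continue
            per_tp.append(res)
            if res.p >= alpha:
                ok = False
        if not per_tp:
            logger.info("intra_parameter_scan: %s untestable; skipped", var)
            continue
        results.append(
            IntraParameterResult(
                variable=var,
                per_timepoint=per_tp,
                all_timepoints_significant=ok,
                partial=partial,
            )
        )
    return results


def intra_to_frame(results: Sequence[IntraParameterResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for c in res.per_timepoint:
            rows.append(
                {
                    "variable": res.variable,
                    "timepoint": c.timepoint.value if c.timepoint else "",
                    "r": c.r,
                    "p": c.p,
                    "method": c.method.value,
                    "n_used": c.n_used,
                    "all_timepoints_significant": res.all_timepoints_significant,
                    "partial": res.partial,
                }
            )
    return pd.DataFrame(rows)
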