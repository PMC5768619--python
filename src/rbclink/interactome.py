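"""Repeated-correlation screening and interactome construction.

An edge of the interactome is an in-vivo ↔ ex-vivo variable pair whose
correlation is significant (p < alpha, default 0.01) at *every* storage
timepoint with a consistent sign — repetition across weeks is the screen
against the false discoveries a small cohort invites.  Surviving edges can
be further thinned by a Bonferroni-style family-wise correction, assembled
into an undirected bipartite graph, and exported for Cytoscape (SIF or
GraphML) with edge length drawn inversely proportional to |r|.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .corrstats import adaptive_correlation, detect_outliers, shapiro_wilk
from .datatypes import (
    Compartment,
    CorrelationResult,
    Group,
    InsufficientDataError,
    RepeatedEdge,
    Sign,
    Timepoint,
    ZeroVarianceError,
)
from .dataset import LongitudinalDataset

CORRECTION_METHODS = ("max-p", "per-tp", "fisher")


def _series_stats(values: np.ndarray) -> tuple[float | None, tuple[int, ...]]:
    """Shapiro p and outlier indices for one complete series (or None)."""
    try:
        p = shapiro_wilk(values).p
    except (ZeroVarianceError, InsufficientDataError, ValueError):
        p = None
    try:
        out = tuple(detect_outliers(values))
    except InsufficientDataError:
        out = ()
    return p, out


def repeated_scan(
    dataset: LongitudinalDataset,
    alpha: float = 0.01,
    *,
    group: Group | str | None = Group.DEFICIENT,
    normality_alpha: float = 0.05,
    require_sign_consistency: bool = True,
    fail_fast: bool = True,
) -> list[RepeatedEdge]:
    """Test every in-vivo × ex-vivo pair at every storage timepoint.

    Baseline (NS) values of the in-vivo variable are paired donor-by-donor
    with the stored-unit values of the ex-vivo variable at each storage day
    and submitted to :func:`adaptive_correlation`.  An edge ``passes_raw``
    iff p < alpha at every tested day with a constant sign of r.  Days where
    the ex-vivo variable was not measured at all are skipped and the edge is
    annotated ``partial``; a day with 1–2 paired donors fails the edge with
    reason ``insufficient n``.  With ``fail_fast`` (default) testing of a
    pair stops at its first failing day; the emitted edge then carries the
    results up to and including that day and the first failing day in
    ``fail_reason``.

    Scans one donor group at a time (default: deficient), matching a design
    where networks are built per genotype.
    """
    tps = dataset.storage_timepoints()
    if not tps:
        raise ValueError("repeated_scan: dataset has no storage timepoints")
    invivo = dataset.variables_in(Compartment.IN_VIVO)
    exvivo = dataset.variables_in(Compartment.EX_VIVO)
    if not invivo or not exvivo:
        raise ValueError("repeated_scan: need >= 1 in-vivo and >= 1 ex-vivo variable")

    # per-series cache: donor tuple, values, shapiro p, outlier indices
    cache: dict[tuple[str, Timepoint], tuple[tuple[str, ...], np.ndarray,
                                             float | None, tuple[int, ...]]] = {}

    def get_series(var: str, tp: Timepoint):
        key = (var, tp)
        if key not in cache:
            s = dataset.series(var, tp, group=group)
            vals = s.to_numpy()
            norm_p, out_idx = _series_stats(vals) if vals.size >= 3 else (None, ())
            cache[key] = (tuple(s.index), vals, norm_p, out_idx)
        return cache[key]

    edges: list[RepeatedEdge] = []
    for iv in invivo:
        b_donors, b_vals, b_norm, b_out = get_series(iv, Timepoint.NS)
        for ev in exvivo:
            per_tp: list[CorrelationResult] = []
            fail_reason: str | None = None
            partial = False
            signs: set[float] = set()
            for tp in tps:
                s_donors, s_vals, s_norm, s_out = get_series(ev, tp)
                if len(s_donors) == 0 or len(b_donors) == 0:
                    partial = True
                    continue
                if s_donors == b_donors:
                    x, y = b_vals, s_vals
                    labels = list(b_donors)
                    norm_p = (b_norm, s_norm) if (b_norm is not None and s_norm is not None) else None
                    out_idx = (b_out, s_out) if norm_p is not None else None
                else:
                    common = [d for d in b_donors if d in set(s_donors)]
                    bmap = {d: v for d, v in zip(b_donors, b_vals)}
                    smap = {d: v for d, v in zip(s_donors, s_vals)}
                    x = np.array([bmap[d] for d in common])
                    y = np.array([smap[d] for d in common])
                    labels = common
                    norm_p = None
                    out_idx = None
                if len(labels) < 3:
                    fail_reason = f"insufficient n at {tp.value}"
                    break
                try:
                    res = adaptive_correlation(
                        x, y, labels=labels, alpha=alpha,
                        normality_alpha=normality_alpha,
                        var_a=iv, var_b=ev, timepoint=tp,
                        _norm_p=norm_p, _outlier_idx=out_idx,
                    )
                except ZeroVarianceError:
                    fail_reason = f"zero variance at {tp.value}"
                    break
                per_tp.append(res)
                if res.p >= alpha:
                    if fail_reason is None:
                        fail_reason = f"not significant at {tp.value}"
                    if fail_fast:
                        break
                    continue
                sgn = 1.0 if res.r >= 0 else -1.0
                if require_sign_consistency:
                    signs.add(sgn)
                    if len(signs) > 1 and fail_reason is None:
                        fail_reason = f"sign inconsistent at {tp.value}"
                        if fail_fast:
                            break
            passes = fail_reason is None and len(per_tp) >= 1
            rep_r = per_tp[-1].r if per_tp else math.nan
            edges.append(
                RepeatedEdge(
                    invivo_var=iv,
                    exvivo_var=ev,
                    per_timepoint=per_tp,
                    sign=Sign.of(rep_r if not math.isnan(rep_r) else 0.0),
                    representative_r=rep_r,
                    passes_raw=passes,
                    passes_corrected=False,
                    partial=partial,
                    fail_reason=fail_reason,
                )
            )
    return edges


def bonferroni_correct(
    edges: Iterable[RepeatedEdge],
    m: int,
    family_alpha: float = 0.05,
    method: str = "max-p",
) -> list[RepeatedEdge]:
    """Apply a Bonferroni-style family-wise correction to repeated edges.

    ``m`` is the family size — the number of candidate pairs actually
    scanned (callers supply it; it is at least the number of edges given).
    Variants: ``max-p`` (default, most conservative: the worst per-timepoint
    p must clear family_alpha / m), ``per-tp`` (every per-timepoint p must
    clear family_alpha / (m · T), counting each timepoint as a test) and
    ``fisher`` (Fisher-combined p across timepoints cleared at
    family_alpha / m).  The corrected set is always a subset of the raw set.
    """
    edges = list(edges)
    if not isinstance(m, (int, np.integer)) or m <= 0:
        raise ValueError(f"family size m must be a positive integer, got {m!r}")
    if m < len(edges):
        raise ValueError(
            f"family size m={m} smaller than the {len(edges)} candidate edges"
        )
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}; "
                         f"choose from {CORRECTION_METHODS}")
    out = []
    for e in edges:
        ok = False
        if e.passes_raw and e.per_timepoint:
            ps = [c.p for c in e.per_timepoint]
            if method == "max-p":
                ok = max(ps) <= family_alpha / m
            elif method == "per-tp":
                ok = all(p <= family_alpha / (m * len(ps)) for p in ps)
            else:  # fisher
                combined = float(stats.combine_pvalues(
                    [max(p, 1e-300) for p in ps], method="fisher").pvalue)
                ok = combined <= family_alpha / m
        out.append(dataclasses.replace(e, passes_corrected=ok))
    return out


# -- network assembly -----------------------------------------------------


class Interactome:
    """Undirected bipartite graph of repeated in-vivo ↔ ex-vivo correlations.

    Thin wrapper over a :class:`networkx.Graph`; node attributes carry the
    variable name, compartment and class, edge attributes the sign,
    representative (latest-day) r, layout length 1/|r| and per-timepoint
    r/p values.
    """

    def __init__(self, graph: nx.Graph | None = None,
                 metadata: dict | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.metadata = metadata or {}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_classes(self) -> set[str]:
        return {d.get("var_class", "unclassified")
                for _, d in self.graph.nodes(data=True)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Interactome({self.n_nodes} nodes, {self.n_edges} edges)"


def _node_id(var: str, side: Compartment, var_compartment: str) -> str:
    if var_compartment == Compartment.BOTH.value:
        return f"{var} ({'in vivo' if side is Compartment.IN_VIVO else 'ex vivo'})"
    return var


def build_network(
    edges: Iterable[RepeatedEdge],
    variables: pd.DataFrame | None = None,
    corrected_only: bool = False,
    metadata: dict | None = None,
) -> Interactome:
    """Assemble passing edges into an interactome.

    ``variables`` is the dataset's variable-metadata frame (index name,
    columns ``compartment``/``var_class``) used to attach node attributes;
    only variables incident to a surviving edge become nodes.  Edge length
    is 1 / |representative r| — stronger correlations draw shorter.
    """
    g = nx.Graph()
    for e in edges:
        if corrected_only and not e.passes_corrected:
            continue
        if not e.passes_raw:
            continue
        vc_a = vc_b = ""
        cls_a = cls_b = "unclassified"
        if variables is not None:
            if e.invivo_var in variables.index:
                vc_a = variables.loc[e.invivo_var, "compartment"]
                cls_a = variables.loc[e.invivo_var, "var_class"]
            if e.exvivo_var in variables.index:
                vc_b = variables.loc[e.exvivo_var, "compartment"]
                cls_b = variables.loc[e.exvivo_var, "var_class"]
        a = _node_id(e.invivo_var, Compartment.IN_VIVO, vc_a)
        b = _node_id(e.exvivo_var, Compartment.EX_VIVO, vc_b)
        g.add_node(a, variable=e.invivo_var,
                   compartment=Compartment.IN_VIVO.value, var_class=cls_a)
        g.add_node(b, variable=e.exvivo_var,
                   compartment=Compartment.EX_VIVO.value, var_class=cls_b)
        attrs: dict[str, object] = {
            "sign": e.sign.value,
            "representative_r": float(e.representative_r),
            "length": float(1.0 / abs(e.representative_r))
            if e.representative_r else math.inf,
            "passes_corrected": bool(e.passes_corrected),
            "partial": bool(e.partial),
        }
        for c in e.per_timepoint:
            attrs[f"r_{c.timepoint.value}"] = float(c.r)
            attrs[f"p_{c.timepoint.value}"] = float(c.p)
        g.add_edge(a, b, **attrs)
    meta = dict(metadata or {})
    meta.setdefault("corrected_only", corrected_only)
    return Interactome(g, meta)


def extract_subnetwork(
    network: Interactome,
    seeds: Sequence[str],
    mode: str = "incident",
) -> Interactome:
    """Sub-network around seed nodes (``incident``) or class tags (``class``).

    Incident mode keeps every edge touching any seed node plus the edge
    endpoints (an isolated seed yields an edgeless subgraph containing it);
    class mode keeps every edge touching any node whose class tag is listed.
    """
    g = network.graph
    if mode == "incident":
        unknown = [s for s in seeds if s not in g]
        if unknown:
            raise KeyError(
                f"unknown node(s) {unknown}; valid nodes: {sorted(g.nodes)}"
            )
        anchor = set(seeds)
    elif mode == "class":
        valid = network.node_classes()
        unknown = [s for s in seeds if s not in valid]
        if unknown:
            raise KeyError(
                f"unknown class tag(s) {unknown}; valid classes: {sorted(valid)}"
            )
        anchor = {n for n, d in g.nodes(data=True)
                  if d.get("var_class") in set(seeds)}
    else:
        raise ValueError("mode must be 'incident' or 'class'")
    keep = set(anchor)
    sub = nx.Graph()
    for n in anchor:
        sub.add_node(n, **g.nodes[n])
    for u, v, d in g.edges(data=True):
        if u in anchor or v in anchor:
            keep.update((u, v))
            sub.add_node(u, **g.nodes[u])
            sub.add_node(v, **g.nodes[v])
            sub.add_edge(u, v, **d)
    return Interactome(sub, dict(network.metadata, subnetwork=list(seeds), mode=mode))


def hub_ranking(
    network: Interactome, top_k: int | None = None
) -> list[tuple[str, int]]:
    """Nodes by degree, descending; ties broken lexicographically by name."""
    ranked = sorted(network.graph.degree, key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ranked = ranked[: max(top_k, 0)]
    return [(str(n), int(d)) for n, d in ranked]


def export_network(network: Interactome, path, format: str = "sif") -> None:
    """Write the network as Cytoscape-readable SIF or GraphML.

    SIF: one line per edge, ``nodeA <pos|neg> nodeB`` (tab-separated).
    GraphML keeps all node and edge attributes.
    """
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, d in network.graph.edges(data=True):
                rel = "pos" if d.get("sign") == Sign.POSITIVE.value else "neg"
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif fmt == "graphml":
        g = network.graph.copy()
        for _, _, d in g.edges(data=True):
            if math.isinf(d.get("length", 0.0)):
                d["length"] = float(1e300)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r} (sif or graphml)")
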