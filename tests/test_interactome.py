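"""Repeated-correlation scan, correction, network assembly and export."""

import math

import networkx as nx
import numpy as np
import pytest

from rbclink import (
    CorrelationResult,
    Interactome,
    Method,
    RepeatedEdge,
    Sign,
    Timepoint,
    bonferroni_correct,
    build_network,
    export_network,
    extract_subnetwork,
    hub_ranking,
    repeated_scan,
)
from rbclink.corrstats import adaptive_correlation
from rbclink.dataset import LongitudinalDataset
from rbclink.datatypes import Compartment, Group, SampleKey, VariableMeta
from rbclink.simulate import SimConfig, generate_cohort


def _drop_timepoints(ds, keep):
    keep_vals = {t.value for t in keep} | {Timepoint.NS.value}
    cols = [c for c in ds.values.columns if c[2] in keep_vals]
    return LongitudinalDataset(ds.values[cols], ds.variables.copy())


def _self_tracking_dataset(n_donors=8, n_tp=3):
    """A 'both' variable whose stored level equals its baseline plus drift."""
    rng = np.random.default_rng(0)
    base = rng.standard_normal(n_donors)
    tps = [Timepoint.D7, Timepoint.D14, Timepoint.D21][:n_tp]
    samples, cols = [], []
    donors = [f"d{i}" for i in range(n_donors)]
    for i, d in enumerate(donors):
        samples.append(SampleKey(d, Group.DEFICIENT, Timepoint.NS,
                                 Compartment.IN_VIVO))
        cols.append([base[i], np.nan])
    for k, tp in enumerate(tps):
        for i, d in enumerate(donors):
            samples.append(SampleKey(d, Group.DEFICIENT, tp,
                                     Compartment.EX_VIVO))
            cols.append([base[i] + 0.5 * (k + 1), rng.standard_normal()])
    variables = [
        VariableMeta("X", Compartment.BOTH, "physiological"),
        VariableMeta("noise_ev", Compartment.EX_VIVO, "redox"),
    ]
    return LongitudinalDataset.from_parts(np.array(cols).T, samples, variables)


class TestRepeatedScan:
    def test_study_design_yields_36_observations_per_edge(self, study_design_cohort):
        """6 deficient donors x 6 weekly tests back each candidate edge."""
        ds, _ = study_design_cohort
        edges = repeated_scan(ds, group="deficient", fail_fast=False)
        assert edges
        for e in edges:
            assert sum(c.n_used for c in e.per_timepoint) == 36

    def test_planted_edge_recovered(self, study_design_cohort):
        ds, truth = study_design_cohort
        edges = repeated_scan(ds, group="deficient")
        passing = {(e.invivo_var, e.exvivo_var) for e in edges if e.passes_raw}
        assert ("IV001", "EV001") in passing

    def test_identical_variable_in_both_compartments_gives_unit_r(self):
        ds = _self_tracking_dataset()
        edges = repeated_scan(ds, group="deficient")
        self_edge = next(e for e in edges
                         if e.invivo_var == "X" and e.exvivo_var == "X")
        assert self_edge.passes_raw
        for c in self_edge.per_timepoint:
            assert c.r == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_donors_fail_with_reason(self):
        ds = _self_tracking_dataset(n_donors=8)
        # blank out all but 2 donors of noise_ev at D14
        vals = ds.values.copy()
        cols = [c for c in vals.columns if c[2] == "D14" and c[0] not in ("d0", "d1")]
        vals.loc["noise_ev", cols] = np.nan
        ds2 = LongitudinalDataset(vals, ds.variables.copy())
        edges = repeated_scan(ds2, group="deficient", fail_fast=False)
        bad = next(e for e in edges if e.exvivo_var == "noise_ev")
        assert not bad.passes_raw
        assert "insufficient n" in bad.fail_reason

    def test_no_storage_timepoints_rejected(self):
        ds = _self_tracking_dataset()
        baseline_only = _drop_timepoints(ds, [])
        with pytest.raises(ValueError, match="storage"):
            repeated_scan(baseline_only)

    def test_adding_timepoints_never_grows_raw_edge_set(self, demo_cohort):
        """The repeated filter is an intersection over days: monotone."""
        ds, _ = demo_cohort
        tps = ds.storage_timepoints()
        previous = None
        for k in (2, 4, 6):
            sub = _drop_timepoints(ds, tps[:k])
            edges = repeated_scan(sub, group="deficient")
            raw = {(e.invivo_var, e.exvivo_var) for e in edges if e.passes_raw}
            if previous is not None:
                assert raw.issubset(previous)
            previous = raw

    def test_matches_straight_loop_oracle(self, demo_cohort):
        """Independent pair x timepoint loop (no caching, no early exit)."""
        ds, _ = demo_cohort
        alpha = 0.01
        oracle_raw = set()
        invivo = ds.variables_in(Compartment.IN_VIVO)
        exvivo = ds.variables_in(Compartment.EX_VIVO)
        for iv in invivo:
            base = ds.series(iv, Timepoint.NS, group="deficient")
            for ev in exvivo:
                ok, signs = True, set()
                for tp in ds.storage_timepoints():
                    stored = ds.series(ev, tp, group="deficient")
                    a, b = base.align(stored, join="inner")
                    res = adaptive_correlation(
                        a.to_numpy(), b.to_numpy(), labels=list(a.index),
                        alpha=alpha, var_a=iv, var_b=ev, timepoint=tp,
                    )
                    ok = ok and res.p < alpha
                    signs.add(res.r >= 0)
                if ok and len(signs) == 1:
                    oracle_raw.add((iv, ev))
        edges = repeated_scan(ds, alpha=alpha, group="deficient")
        raw = {(e.invivo_var, e.exvivo_var) for e in edges if e.passes_raw}
        assert raw == oracle_raw


def _fake_edge(ps, r=0.9, passes_raw=True):
    tps = list(Timepoint)[1 : len(ps) + 1]
    per = [
        CorrelationResult("A", "B", tp, Method.PEARSON, r, p, 6)
        for tp, p in zip(tps, ps)
    ]
    return RepeatedEdge("A", "B", per, Sign.of(r), r, passes_raw, False)


class TestBonferroni:
    def test_m_one_is_plain_family_alpha_threshold(self):
        edges = [_fake_edge([0.04, 0.01]), _fake_edge([0.2, 0.06], passes_raw=False)]
        # m must cover candidates; use the passing edge alone
        out = bonferroni_correct(edges, m=2, family_alpha=0.05)
        assert not out[0].passes_corrected  # max p 0.04 > 0.05/2
        out = bonferroni_correct([edges[0]], m=1, family_alpha=0.05)
        assert out[0].passes_corrected  # max p 0.04 <= 0.05

    def test_threshold_arithmetic(self):
        e = _fake_edge([4e-4, 6e-4])
        assert not bonferroni_correct([e], m=100)[0].passes_corrected  # 6e-4 > 5e-4
        e2 = _fake_edge([4e-4, 5e-4])
        assert bonferroni_correct([e2], m=100)[0].passes_corrected

    def test_corrected_subset_of_raw(self, demo_cohort):
        ds, _ = demo_cohort
        edges = repeated_scan(ds, group="deficient")
        for method in ("max-p", "per-tp", "fisher"):
            out = bonferroni_correct(edges, m=len(edges), method=method)
            for e in out:
                assert not e.passes_corrected or e.passes_raw

    @pytest.mark.parametrize("bad_m", [0, -5])
    def test_invalid_family_size_rejected(self, bad_m):
        with pytest.raises(ValueError, match="positive"):
            bonferroni_correct([_fake_edge([0.01])], m=bad_m)

    def test_family_smaller_than_candidates_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            bonferroni_correct([_fake_edge([0.01])] * 3, m=2)


class TestNetwork:
    def test_empty_edge_list_gives_empty_graph(self):
        net = build_network([])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_length_inversely_proportional_to_r(self):
        e1 = _fake_edge([1e-5], r=0.95)
        e2 = RepeatedEdge("C", "D", _fake_edge([1e-5], r=0.92).per_timepoint,
                          Sign.POSITIVE, 0.92, True, False)
        net = build_network([e1, e2])
        lens = {frozenset((u, v)): d["length"]
                for u, v, d in net.graph.edges(data=True)}
        assert lens[frozenset(("A", "B"))] == pytest.approx(1 / 0.95)
        assert lens[frozenset(("A", "B"))] < lens[frozenset(("C", "D"))]

    def test_nodes_are_exactly_incident_variables(self, demo_cohort):
        ds, truth = demo_cohort
        edges = repeated_scan(ds, group="deficient")
        net = build_network(edges, variables=ds.variables)
        incident = set()
        for e in edges:
            if e.passes_raw:
                incident.add(e.invivo_var)
                incident.add(e.exvivo_var)
        assert {d["variable"] for _, d in net.graph.nodes(data=True)} == incident

    def test_edges_connect_invivo_to_exvivo_only(self, demo_cohort):
        ds, _ = demo_cohort
        net = build_network(repeated_scan(ds, group="deficient"),
                            variables=ds.variables)
        for u, v in net.graph.edges:
            comps = {net.graph.nodes[u]["compartment"],
                     net.graph.nodes[v]["compartment"]}
            assert comps == {"in_vivo", "ex_vivo"}


def _star_network():
    edges = []
    for i in range(5):
        per = [CorrelationResult("hub", f"leaf{i}", Timepoint.D42,
                                 Method.PEARSON, 0.9, 1e-6, 6)]
        edges.append(RepeatedEdge("hub", f"leaf{i}", per, Sign.POSITIVE,
                                  0.9, True, True))
    return build_network(edges)


class TestSubnetworkAndHubs:
    def test_isolated_seed_gives_edgeless_subgraph(self):
        net = _star_network()
        net.graph.add_node("lonely", variable="lonely", compartment="in_vivo",
                           var_class="redox")
        sub = extract_subnetwork(net, ["lonely"], mode="incident")
        assert sub.n_nodes == 1 and sub.n_edges == 0

    def test_hub_seed_returns_its_degree_edges(self):
        sub = extract_subnetwork(_star_network(), ["hub"], mode="incident")
        assert sub.n_edges == 5

    def test_class_covering_all_nodes_is_identity(self, demo_cohort):
        ds, _ = demo_cohort
        net = build_network(repeated_scan(ds, group="deficient"),
                            variables=ds.variables)
        sub = extract_subnetwork(net, sorted(net.node_classes()), mode="class")
        assert set(sub.graph.nodes) == set(net.graph.nodes)
        assert sub.n_edges == net.n_edges

    def test_unknown_seed_lists_valid_names(self):
        with pytest.raises(KeyError, match="valid nodes"):
            extract_subnetwork(_star_network(), ["nope"], mode="incident")

    def test_star_ranking(self):
        ranking = hub_ranking(_star_network())
        assert ranking[0] == ("hub", 5)
        # ties among leaves broken lexicographically
        assert [n for n, _ in ranking[1:]] == sorted(f"leaf{i}" for i in range(5))

    def test_top_k_beyond_node_count_returns_all(self):
        assert len(hub_ranking(_star_network(), top_k=100)) == 6


class TestExport:
    def test_sif_line_format(self, tmp_path):
        net = build_network([_fake_edge([1e-6], r=0.9)])
        path = tmp_path / "net.sif"
        export_network(net, path, format="sif")
        assert path.read_text() == "A\tpos\tB\n"

    def test_negative_edge_relation(self, tmp_path):
        net = build_network([_fake_edge([1e-6], r=-0.9)])
        export_network(net, tmp_path / "n.sif", format="sif")
        assert (tmp_path / "n.sif").read_text() == "A\tneg\tB\n"

    def test_graphml_round_trip_preserves_attributes(self, tmp_path, demo_cohort):
        ds, _ = demo_cohort
        net = build_network(repeated_scan(ds, group="deficient"),
                            variables=ds.variables)
        path = tmp_path / "net.graphml"
        export_network(net, path, format="graphml")
        back = nx.read_graphml(path)
        assert back.number_of_edges() == net.n_edges
        assert back.number_of_nodes() == net.n_nodes
        for u, v, d in net.graph.edges(data=True):
            d2 = back.edges[u, v]
            assert d2["sign"] == d["sign"]
            assert float(d2["representative_r"]) == pytest.approx(
                d["representative_r"])
            assert float(d2["length"]) == pytest.approx(d["length"])

    def test_empty_network_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_network(Interactome(), path, format="graphml")
        assert nx.read_graphml(path).number_of_nodes() == 0
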