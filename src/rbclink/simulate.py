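"""Synthetic donor cohorts with planted, machine-readable ground truth.

The generator emulates the design of a two-group donor storage study: a few
donors per group, each measured once at donation (baseline, in vivo) and
weekly during refrigerated storage of the packed unit (ex vivo, days 7–42).

The dependence model is a Gaussian copula.  Every variable owns a latent
standard-normal donor score; a target correlation matrix ``C`` over all
latent scores encodes the planted structure (persistent in-vivo↔ex-vivo
edges, within-baseline correlations, group-specific "rewired" ex-vivo
pairs, and baseline→storage donor signatures for both-compartment
variables).  Baseline observations are the baseline-block latents ``X``;
the storage-block observation at week ``t`` is

    V_t = M X + sqrt(1-k) P + sqrt(k) W_t,        M = C_sb C_bb^{-1},

with ``P`` (persistent) and ``W_t`` (weekly refresh) i.i.d. draws from the
conditional covariance ``C_ss − C_sb C_bb^{-1} C_bs``.  This makes every
per-timepoint cross-sectional correlation exactly equal to the target in
``C`` while still letting sample correlations fluctuate from week to week;
``k = noise_sd**2`` is the refreshed share of the residual variance.
Storage means additionally drift over weeks (the storage lesion) without
affecting cross-donor correlations at a fixed timepoint.  Non-normal
marginals are produced by exponentiating the Gaussian value — a strictly
monotone map that preserves Spearman but not Pearson correlation.  Outlier
cells receive an additive shift of several stratum SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    STORAGE_TIMEPOINTS,
    Compartment,
    Group,
    InfeasibleCorrelationError,
    SampleKey,
    Timepoint,
    VariableMeta,
)
from .dataset import LongitudinalDataset

_INVIVO_CLASSES = (
    "hematological", "physiological", "redox", "lipid",
    "amino_acid", "glycolysis", "purine", "bile_acid",
)
_EXVIVO_CLASSES = (
    "glycolysis", "ppp", "purine", "redox", "lipid",
    "amino_acid", "hemolysis", "one_carbon",
)


@dataclass
class SimConfig:
    """Study-design and ground-truth configuration for one synthetic cohort.

    Defaults mirror the emulated study: 6 deficient + 3 sufficient donors,
    45 baseline (in-vivo) parameters, 293 stored-unit (ex-vivo) metabolites,
    weekly sampling from day 7 to day 42.
    """

    seed: int
    n_deficient: int = 6
    n_sufficient: int = 3
    n_variables_invivo: int = 45
    n_variables_exvivo: int = 293
    timepoints: tuple[Timepoint, ...] = STORAGE_TIMEPOINTS
    #: (invivo_var, exvivo_var, true_r) — persistent cross-compartment edges
    planted_edges: tuple[tuple[str, str, float], ...] = ()
    #: (var_a, var_b, r_deficient, r_sufficient) — ex-vivo pairs that rewire
    planted_rewired_pairs: tuple[tuple[str, str, float, float], ...] = ()
    #: (var_a, var_b, r) — correlations among baseline variables (e.g. hubs)
    planted_invivo_correlations: tuple[tuple[str, str, float], ...] = ()
    #: (var_name, true_r) — both-compartment donor-signature variables
    planted_signatures: tuple[tuple[str, float], ...] = ()
    #: (var_name, offset_in_sd) — group main effect on a storage variable
    planted_group_effects: tuple[tuple[str, float], ...] = ()
    outlier_rate: float = 0.01
    outlier_magnitude: float = 5.0
    nonnormal_fraction: float = 0.25
    #: weekly refreshed share of residual SD, in (0, 1]
    noise_sd: float = 0.5
    drift_per_week: float = 0.15
    drift_shape: str = "linear"  # or "u"

    def __post_init__(self) -> None:
        if self.n_deficient < 1 or self.n_sufficient < 0:
            raise ValueError("need at least one deficient donor")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")
        if not (0 <= self.nonnormal_fraction <= 1):
            raise ValueError("nonnormal_fraction must be in [0, 1]")
        if not (0 < self.noise_sd <= 1):
            raise ValueError("noise_sd must be in (0, 1]")
        if self.drift_shape not in ("linear", "u"):
            raise ValueError("drift_shape must be 'linear' or 'u'")
        if len(self.timepoints) < 1:
            raise ValueError("need at least one storage timepoint")
        self.timepoints = tuple(Timepoint(t) for t in self.timepoints)
        for spec_list in (self.planted_edges, self.planted_rewired_pairs,
                          self.planted_invivo_correlations):
            for entry in spec_list:
                for r in entry[2:]:
                    if not abs(float(r)) < 1:
                        raise ValueError(f"planted |r| must be < 1: {entry}")
        for _, r in self.planted_signatures:
            if not abs(float(r)) < 1:
                raise ValueError("planted signature |r| must be < 1")

    # variable name rosters -------------------------------------------------

    @property
    def invivo_names(self) -> list[str]:
        return [f"IV{i + 1:03d}" for i in range(self.n_variables_invivo)]

    @property
    def exvivo_names(self) -> list[str]:
        return [f"EV{i + 1:03d}" for i in range(self.n_variables_exvivo)]

    @property
    def signature_names(self) -> list[str]:
        return [name for name, _ in self.planted_signatures]


@dataclass
class TruthTable:
    """Planted structure written alongside every simulated dataset."""

    planted_edges: list[tuple[str, str, float]] = field(default_factory=list)
    rewired_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    signatures: list[tuple[str, float]] = field(default_factory=list)
    group_effects: list[tuple[str, float]] = field(default_factory=list)
    outlier_cells: list[tuple[str, str, str]] = field(default_factory=list)
    nonnormal_variables: list[str] = field(default_factory=list)

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        pd.DataFrame(self.planted_edges,
                     columns=["invivo_var", "exvivo_var", "true_r"]).to_csv(
            os.path.join(directory, "truth_edges.csv"), index=False)
        pd.DataFrame(self.rewired_pairs,
                     columns=["var_a", "var_b", "r_deficient", "r_sufficient"]
                     ).to_csv(os.path.join(directory, "truth_rewired.csv"), index=False)
        pd.DataFrame(self.signatures, columns=["variable", "true_r"]).to_csv(
            os.path.join(directory, "truth_signatures.csv"), index=False)
        pd.DataFrame(self.outlier_cells,
                     columns=["variable", "donor", "timepoint"]).to_csv(
            os.path.join(directory, "truth_outliers.csv"), index=False)
        pd.DataFrame({"variable": self.nonnormal_variables}).to_csv(
            os.path.join(directory, "truth_nonnormal.csv"), index=False)


def critical_r(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| reaching two-sided significance at ``alpha`` for sample n."""
    if n < 3:
        return 1.0
    t = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t * t + n - 2))


def _build_target_matrix(cfg: SimConfig, group: Group) -> tuple[np.ndarray, list[str], list[str]]:
    """Target latent correlation matrix and the base/storage latent rosters."""
    base = cfg.invivo_names + cfg.signature_names
    store = cfg.exvivo_names + cfg.signature_names
    idx_b = {name: i for i, name in enumerate(base)}
    idx_s = {name: len(base) + i for i, name in enumerate(store)}
    dim = len(base) + len(store)
    C = np.eye(dim)

    def set_entry(i: int, j: int, r: float, what: str) -> None:
        if i == j:
            raise InfeasibleCorrelationError(f"self-correlation planted: {what}")
        if C[i, j] not in (0.0, r):
            raise InfeasibleCorrelationError(f"conflicting plant for pair: {what}")
        C[i, j] = C[j, i] = r

    for a, b, r in cfg.planted_invivo_correlations:
        _require(a in idx_b and b in idx_b, f"unknown baseline variable in {(a, b)}")
        set_entry(idx_b[a], idx_b[b], float(r), f"invivo {(a, b)}")
    for u, v, r in cfg.planted_edges:
        _require(u in idx_b, f"unknown in-vivo variable {u!r} in planted edge")
        _require(v in idx_s, f"unknown ex-vivo variable {v!r} in planted edge")
        set_entry(idx_b[u], idx_s[v], float(r), f"edge {(u, v)}")
    for name, r in cfg.planted_signatures:
        set_entry(idx_b[name], idx_s[name], float(r), f"signature {name}")
    for a, b, r_def, r_suf in cfg.planted_rewired_pairs:
        _require(a in idx_s and b in idx_s, f"unknown ex-vivo variable in {(a, b)}")
        r = float(r_def if group is Group.DEFICIENT else r_suf)
        set_entry(idx_s[a], idx_s[b], r, f"rewired {(a, b)}")
    return C, base, store


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _safe_cholesky(mat: np.ndarray, what: str, pairs_hint: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat + 1e-12 * np.eye(mat.shape[0]))
    except np.linalg.LinAlgError:
        raise InfeasibleCorrelationError(
            f"target correlation structure is not positive semidefinite "
            f"({what}); offending planted pairs: {pairs_hint}"
        ) from None


def generate_cohort(cfg: SimConfig) -> tuple[LongitudinalDataset, TruthTable]:
    """Simulate one cohort; fully determined by ``cfg`` (including seed)."""
    rng = np.random.default_rng(cfg.seed)
    rc = critical_r(cfg.n_deficient)
    weak = [e for e in cfg.planted_edges if abs(e[2]) < rc]
    if weak and cfg.n_deficient < 10:
        warnings.warn(
            f"planted edges below the detectability limit |r| >= {rc:.3f} "
            f"at n = {cfg.n_deficient}, alpha = 0.01: {weak}",
            stacklevel=2,
        )

    pairs_hint = ", ".join(
        str((e[0], e[1])) for e in
        list(cfg.planted_edges) + list(cfg.planted_rewired_pairs)
        + list(cfg.planted_invivo_correlations)
    ) or "(none)"
    k = cfg.noise_sd ** 2
    tps = list(cfg.timepoints)
    weeks = np.array([t.day / 7.0 for t in tps])

    # variable metadata ----------------------------------------------------
    variables: list[VariableMeta] = []
    for i, name in enumerate(cfg.invivo_names):
        variables.append(VariableMeta(name, Compartment.IN_VIVO,
                                      _INVIVO_CLASSES[i % len(_INVIVO_CLASSES)]))
    for i, name in enumerate(cfg.exvivo_names):
        variables.append(VariableMeta(name, Compartment.EX_VIVO,
                                      _EXVIVO_CLASSES[i % len(_EXVIVO_CLASSES)]))
    for name in cfg.signature_names:
        variables.append(VariableMeta(name, Compartment.BOTH, "physiological"))
    all_names = [v.name for v in variables]
    _require(len(set(all_names)) == len(all_names), "variable names collide")

    # drift directions (shared across groups; rewired pairs stay drift-free
    # so pooled between-group correlation deltas are not confounded)
    rewired_vars = {v for pr in cfg.planted_rewired_pairs for v in pr[:2]}
    store_names_all = cfg.exvivo_names + cfg.signature_names
    drift_dir = {
        name: (0.0 if name in rewired_vars else float(rng.choice([-1.0, 1.0])))
        for name in store_names_all
    }
    if cfg.drift_shape == "linear":
        drift_profile = weeks
    else:  # U-shape echoing the three metabolic phases
        drift_profile = (weeks - weeks.mean()) ** 2 - np.mean(
            (weeks - weeks.mean()) ** 2
        )

    # non-normal marginals --------------------------------------------------
    n_nonnormal = int(round(cfg.nonnormal_fraction * len(all_names)))
    nonnormal = set(
        rng.choice(all_names, size=n_nonnormal, replace=False)
    ) if n_nonnormal else set()

    group_sizes = {Group.DEFICIENT: cfg.n_deficient, Group.SUFFICIENT: cfg.n_sufficient}
    donor_names = {
        Group.DEFICIENT: [f"def{i + 1:02d}" for i in range(cfg.n_deficient)],
        Group.SUFFICIENT: [f"suf{i + 1:02d}" for i in range(cfg.n_sufficient)],
    }
    offsets = dict((name, off) for name, off in cfg.planted_group_effects)

    samples: list[SampleKey] = []
    columns: list[np.ndarray] = []
    name_pos = {n: i for i, n in enumerate(all_names)}

    for group in (Group.DEFICIENT, Group.SUFFICIENT):
        n_don = group_sizes[group]
        if n_don == 0:
            continue
        C, base, store = _build_target_matrix(cfg, group)
        nb, ns = len(base), len(store)
        C_bb = C[:nb, :nb]
        C_sb = C[nb:, :nb]
        C_ss = C[nb:, nb:]
        L_bb = _safe_cholesky(C_bb, f"baseline block, group {group.value}", pairs_hint)
        # M = C_sb C_bb^{-1}; Sigma_cond = C_ss - M C_bs
        M = np.linalg.solve(C_bb, C_sb.T).T
        Sigma_cond = C_ss - M @ C_sb.T
        L_cond = _safe_cholesky(
            Sigma_cond, f"storage conditional block, group {group.value}", pairs_hint
        )

        X = rng.standard_normal((n_don, nb)) @ L_bb.T
        P = rng.standard_normal((n_don, ns)) @ L_cond.T
        signal = X @ M.T
        V = {}
        for ti, tp in enumerate(tps):
            W = rng.standard_normal((n_don, ns)) @ L_cond.T
            V[tp] = signal + np.sqrt(1 - k) * P + np.sqrt(k) * W
            for si, name in enumerate(store):
                V[tp][:, si] += drift_dir[name] * cfg.drift_per_week * drift_profile[ti]
                if group is Group.DEFICIENT and name in offsets:
                    V[tp][:, si] += offsets[name]

        base_pos = {n: i for i, n in enumerate(base)}
        store_pos = {n: i for i, n in enumerate(store)}
        for di, donor in enumerate(donor_names[group]):
            col = np.full(len(all_names), np.nan)
            for name in base:
                val = X[di, base_pos[name]]
                col[name_pos[name]] = np.exp(val) if name in nonnormal else val
            samples.append(SampleKey(donor, group, Timepoint.NS, Compartment.IN_VIVO))
            columns.append(col)
        for tp in tps:
            for di, donor in enumerate(donor_names[group]):
                col = np.full(len(all_names), np.nan)
                for name in store:
                    val = V[tp][di, store_pos[name]]
                    col[name_pos[name]] = np.exp(val) if name in nonnormal else val
                samples.append(SampleKey(donor, group, tp, Compartment.EX_VIVO))
                columns.append(col)

    values = np.column_stack(columns)
    ds = LongitudinalDataset.from_parts(values, samples, variables)

    truth = TruthTable(
        planted_edges=[(u, v, float(r)) for u, v, r in cfg.planted_edges],
        rewired_pairs=[(a, b, float(rd), float(rs))
                       for a, b, rd, rs in cfg.planted_rewired_pairs],
        signatures=[(s, float(r)) for s, r in cfg.planted_signatures],
        group_effects=[(s, float(o)) for s, o in cfg.planted_group_effects],
        nonnormal_variables=sorted(nonnormal),
    )
    if cfg.outlier_rate > 0:
        ds, cells = _inject(ds, cfg.outlier_rate, cfg.outlier_magnitude, rng)
        truth.outlier_cells = cells
    return ds, truth


def inject_outliers(
    dataset: LongitudinalDataset,
    rate: float,
    magnitude: float = 5.0,
    seed: int | None = None,
) -> tuple[LongitudinalDataset, list[tuple[str, str, str]]]:
    """Shift randomly chosen observed cells by ``magnitude`` stratum SDs.

    The stratum is (variable, group, timepoint) — the series an outlier
    check would scan.  Returns the modified copy and the list of cells
    (variable, donor, timepoint).
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    return _inject(dataset, rate, magnitude, rng)


def _inject(
    dataset: LongitudinalDataset,
    rate: float,
    magnitude: float,
    rng: np.random.Generator,
) -> tuple[LongitudinalDataset, list[tuple[str, str, str]]]:
    values = dataset.values.copy()
    cells: list[tuple[str, str, str]] = []
    if rate == 0:
        return LongitudinalDataset(values, dataset.variables.copy()), cells
    cols = values.columns
    groups = cols.get_level_values("group")
    tps = cols.get_level_values("timepoint")
    arr = values.to_numpy()
    strata: dict[tuple[str, str], np.ndarray] = {}
    for key in {(g, t) for g, t in zip(groups, tps)}:
        strata[key] = np.asarray((groups == key[0]) & (tps == key[1]))
    for vi, var in enumerate(values.index):
        row = arr[vi]
        observed = np.nonzero(~np.isnan(row))[0]
        if observed.size == 0:
            continue
        hits = observed[rng.random(observed.size) < rate]
        for ci in hits:
            g, t = groups[ci], tps[ci]
            stratum = row[strata[(g, t)]]
            stratum = stratum[~np.isnan(stratum)]
            sd = float(np.std(stratum, ddof=1)) if stratum.size > 1 else 1.0
            if sd == 0:
                sd = 1.0
            arr[vi, ci] = row[ci] + magnitude * sd * float(rng.choice([-1.0, 1.0]))
            cells.append((str(var), cols[ci][0], str(t)))
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return LongitudinalDataset(out, dataset.variables.copy()), cells


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["timepoints"] = [t.value for t in cfg.timepoints]
    return d
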