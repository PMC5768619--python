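"""Readers and writers for the tabular formats the pipeline consumes/emits.

Long CSV is the canonical on-disk form (columns: variable, donor, group,
timepoint, compartment, value, plus optional var_class / var_compartment);
a wide layout (variables in rows, ``donor|group|timepoint`` sample columns)
is supported as a convenience.  Missing cells are empty strings or ``NA``.
Edge tables are TSV with one row per repeated edge and per-timepoint r/p/n
columns.
"""

from __future__ import annotations

import math
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    STORAGE_TIMEPOINTS,
    Compartment,
    CorrelationResult,
    DatasetFormatError,
    Group,
    Method,
    RepeatedEdge,
    Sign,
    Timepoint,
    parse_timepoint,
)
from .dataset import COLUMN_LEVELS, LongitudinalDataset

LONG_REQUIRED = ("variable", "donor", "group", "timepoint", "compartment", "value")


def _parse_group(label: str, context: str) -> Group:
    try:
        return Group(str(label).strip().lower())
    except ValueError:
        raise DatasetFormatError(f"unknown group label {label!r} ({context})") from None


def dataset_from_long(df: pd.DataFrame) -> LongitudinalDataset:
    """Build a validated dataset from a canonical long table."""
    missing = [c for c in LONG_REQUIRED if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"long table missing required columns: {missing}")
    df = df.copy()
    tps = []
    for i, raw in df["timepoint"].items():
        try:
            tps.append(parse_timepoint(raw).value)
        except DatasetFormatError:
            raise DatasetFormatError(
                f"unknown timepoint label {raw!r} at row {i}"
            ) from None
    df["timepoint"] = tps
    df["group"] = [ _parse_group(g, f"row {i}").value
                    for i, g in df["group"].items() ]
    df["donor"] = df["donor"].astype(str)
    df["variable"] = df["variable"].astype(str)
    # sample compartment is determined by the timepoint; validate declarations
    declared = df["compartment"].astype(str)
    expected = np.where(df["timepoint"] == Timepoint.NS.value,
                        Compartment.IN_VIVO.value, Compartment.EX_VIVO.value)
    bad = df.index[(declared != expected) & (declared != "") & (declared != "NA")]
    if len(bad):
        i = bad[0]
        raise DatasetFormatError(
            f"row {i}: sample at timepoint {df.loc[i, 'timepoint']} declared "
            f"{declared[i]!r}, expected {expected[list(df.index).index(i)]!r}"
        )
    df["compartment"] = expected

    dup = df.duplicated(subset=["variable", "donor", "timepoint", "compartment"])
    if dup.any():
        first = df.loc[dup, ["variable", "donor", "timepoint"]].iloc[0].tolist()
        raise DatasetFormatError(
            f"duplicate (variable, sample) cell: {tuple(first)}"
        )

    # duplicates were rejected above; pivot keeps observed sample columns only
    wide = df.pivot_table(
        index="variable",
        columns=["donor", "group", "timepoint", "compartment"],
        values="value",
        aggfunc="first",
    )
    wide.columns = wide.columns.set_names(COLUMN_LEVELS)
    # order columns donor, then timepoint chronologically
    order = sorted(
        wide.columns,
        key=lambda c: (c[0], Timepoint(c[2]).day),
    )
    wide = wide[order]

    # variable metadata: explicit columns when present, else inferred
    if "var_compartment" in df.columns:
        vcomp = df.groupby("variable")["var_compartment"].first()
    else:
        seen = df.groupby("variable")["compartment"].agg(lambda s: set(s))
        vcomp = seen.map(
            lambda s: Compartment.BOTH.value if len(s) > 1 else next(iter(s))
        )
    if "var_class" in df.columns:
        vclass = df.groupby("variable")["var_class"].first().fillna("unclassified")
    else:
        vclass = pd.Series("unclassified", index=vcomp.index)
    variables = pd.DataFrame(
        {"compartment": vcomp, "var_class": vclass}
    ).loc[wide.index]
    variables.index.name = "variable"
    return LongitudinalDataset(wide, variables)


def read_dataset(path: str | os.PathLike, format: str = "long") -> LongitudinalDataset:
    """Read a dataset from CSV. ``format`` is ``long`` (canonical) or ``wide``."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "long":
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
        return dataset_from_long(df)
    if format == "wide":
        return _read_wide(path)
    raise ValueError(f"unknown format: {format!r}")


def write_dataset(
    ds: LongitudinalDataset, path: str | os.PathLike, format: str = "long"
) -> None:
    if format == "long":
        ds.to_long().to_csv(path, index=False)
    elif format == "wide":
        _write_wide(ds, path)
    else:
        raise ValueError(f"unknown format: {format!r}")


def _write_wide(ds: LongitudinalDataset, path: str | os.PathLike) -> None:
    out = ds.values.copy()
    out.columns = [f"{d}|{g}|{t}" for d, g, t, _ in out.columns]
    out.insert(0, "var_class", ds.variables["var_class"])
    out.insert(0, "var_compartment", ds.variables["compartment"])
    out.to_csv(path, index_label="variable")


def _read_wide(path: str | os.PathLike) -> LongitudinalDataset:
    df = pd.read_csv(path, na_values=["NA"], index_col="variable")
    meta_cols = ["var_compartment", "var_class"]
    for c in meta_cols:
        if c not in df.columns:
            raise DatasetFormatError(f"wide table missing column {c!r}")
    records = []
    for col in df.columns:
        if col in meta_cols:
            continue
        parts = str(col).split("|")
        if len(parts) != 3:
            raise DatasetFormatError(
                f"wide sample column {col!r} must be 'donor|group|timepoint'"
            )
        donor, group, tp_raw = parts
        tp = parse_timepoint(tp_raw)
        comp = Compartment.IN_VIVO if tp is Timepoint.NS else Compartment.EX_VIVO
        for var, val in df[col].items():
            if pd.isna(val):
                continue
            records.append(
                {
                    "variable": var,
                    "donor": donor,
                    "group": _parse_group(group, f"column {col!r}").value,
                    "timepoint": tp.value,
                    "compartment": comp.value,
                    "value": float(val),
                    "var_class": df.loc[var, "var_class"],
                    "var_compartment": df.loc[var, "var_compartment"],
                }
            )
    return dataset_from_long(pd.DataFrame.from_records(records))


# -- edge tables ----------------------------------------------------------

EDGE_FIXED_COLUMNS = [
    "invivo_var",
    "exvivo_var",
    "sign",
    "representative_r",
    "passes_raw",
    "passes_corrected",
    "partial",
    "fail_reason",
    "outliers_excluded",
]


def write_edges(
    edges: Iterable[RepeatedEdge],
    path: str | os.PathLike,
    timepoints: list[Timepoint] | None = None,
) -> None:
    """Write a TSV edge table, one row per edge with per-timepoint r/p/n/method."""
    edges = list(edges)
    if timepoints is None:
        seen: set[Timepoint] = set()
        for e in edges:
            seen.update(e.tested_timepoints)
        timepoints = sorted(seen, key=lambda t: t.day) or list(STORAGE_TIMEPOINTS)
    rows = []
    for e in edges:
        per_tp = {c.timepoint: c for c in e.per_timepoint}
        row: dict[str, object] = {
            "invivo_var": e.invivo_var,
            "exvivo_var": e.exvivo_var,
            "sign": e.sign.value,
            "representative_r": e.representative_r,
            "passes_raw": e.passes_raw,
            "passes_corrected": e.passes_corrected,
            "partial": e.partial,
            "fail_reason": e.fail_reason if e.fail_reason else "",
            "outliers_excluded": ";".join(
                f"{c.timepoint.value}:{donor}"
                for c in e.per_timepoint
                for donor in c.outliers_excluded
            ),
        }
        for tp in timepoints:
            c = per_tp.get(tp)
            row[f"r_{tp.value}"] = c.r if c else math.nan
            row[f"p_{tp.value}"] = c.p if c else math.nan
            row[f"n_{tp.value}"] = c.n_used if c else ""
            row[f"method_{tp.value}"] = c.method.value if c else ""
        rows.append(row)
    cols = list(EDGE_FIXED_COLUMNS)
    for tp in timepoints:
        cols += [f"r_{tp.value}", f"p_{tp.value}", f"n_{tp.value}", f"method_{tp.value}"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_edges(path: str | os.PathLike) -> list[RepeatedEdge]:
    """Read back an edge table written by :func:`write_edges`.

    Per-timepoint decision traces are not serialized (they live in debug
    logs); everything else round-trips to full float precision.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    tp_cols = [c for c in df.columns if c.startswith("r_")]
    tps = [Timepoint(c[2:]) for c in tp_cols]
    edges = []
    for _, row in df.iterrows():
        flagged: dict[str, list[str]] = {}
        raw = row["outliers_excluded"]
        if isinstance(raw, str) and raw:
            for item in raw.split(";"):
                tp_lab, donor = item.split(":", 1)
                flagged.setdefault(tp_lab, []).append(donor)
        per_tp = []
        for tp in tps:
            r = row[f"r_{tp.value}"]
            if pd.isna(r):
                continue
            per_tp.append(
                CorrelationResult(
                    var_a=row["invivo_var"],
                    var_b=row["exvivo_var"],
                    timepoint=tp,
                    method=Method(row[f"method_{tp.value}"]),
                    r=float(r),
                    p=float(row[f"p_{tp.value}"]),
                    n_used=int(row[f"n_{tp.value}"]),
                    outliers_excluded=tuple(flagged.get(tp.value, ())),
                )
            )
        fail = row["fail_reason"]
        edges.append(
            RepeatedEdge(
                invivo_var=row["invivo_var"],
                exvivo_var=row["exvivo_var"],
                per_timepoint=per_tp,
                sign=Sign(row["sign"]),
                representative_r=float(row["representative_r"]),
                passes_raw=bool(row["passes_raw"]),
                passes_corrected=bool(row["passes_corrected"]),
                partial=bool(row["partial"]),
                fail_reason=str(fail) if isinstance(fail, str) and fail else None,
            )
        )
    return edges
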