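"""The universal input container: a variables × samples measurement matrix.

Columns carry a four-level MultiIndex (donor, group, timepoint, compartment);
rows are variables.  Missing cells are NaN and are never imputed — every
downstream test uses pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    Compartment,
    DatasetFormatError,
    Group,
    SampleKey,
    Timepoint,
    VariableMeta,
)

COLUMN_LEVELS = ("donor", "group", "timepoint", "compartment")


def _timepoint_sort_key(tp: str) -> int:
    return Timepoint(tp).day


@dataclass
class LongitudinalDataset:
    """Variables × samples matrix with sample and variable metadata.

    Parameters
    ----------
    values
        DataFrame indexed by variable name; columns are a MultiIndex with
        levels ``(donor, group, timepoint, compartment)`` holding string
        enum values.
    variables
        DataFrame indexed by variable name with columns ``compartment``
        and ``var_class``.
    """

    values: pd.DataFrame
    variables: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_parts(
        cls,
        values: np.ndarray | pd.DataFrame,
        samples: list[SampleKey],
        variables: list[VariableMeta],
    ) -> "LongitudinalDataset":
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(variables), len(samples)):
            raise DatasetFormatError(
                f"values shape {arr.shape} != "
                f"({len(variables)} variables, {len(samples)} samples)"
            )
        cols = pd.MultiIndex.from_tuples(
            [
                (s.donor_id, s.group.value, s.timepoint.value, s.compartment.value)
                for s in samples
            ],
            names=COLUMN_LEVELS,
        )
        vdf = pd.DataFrame(
            {
                "compartment": [v.compartment.value for v in variables],
                "var_class": [v.var_class for v in variables],
            },
            index=pd.Index([v.name for v in variables], name="variable"),
        )
        df = pd.DataFrame(arr, index=vdf.index, columns=cols)
        return cls(df, vdf)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        cols = self.values.columns
        if list(cols.names) != list(COLUMN_LEVELS):
            raise DatasetFormatError(
                f"sample columns must have levels {COLUMN_LEVELS}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DatasetFormatError(f"duplicate variable names: {dups}")
        if not self.values.index.equals(self.variables.index):
            raise DatasetFormatError(
                "values rows and variable metadata must list the same names"
            )
        key = cols.droplevel("group")
        if key.has_duplicates:
            dups = key[key.duplicated()].tolist()
            raise DatasetFormatError(
                f"duplicate sample (donor, timepoint, compartment): {dups}"
            )
        for donor, group, tp, comp in cols:
            Group(group)
            t = Timepoint(tp)
            expected = Compartment.IN_VIVO if t is Timepoint.NS else Compartment.EX_VIVO
            if Compartment(comp) is not expected:
                raise DatasetFormatError(
                    f"sample ({donor}, {tp}) must be {expected.value}, got {comp}"
                )
        groups_per_donor = (
            pd.DataFrame({"donor": cols.get_level_values("donor"),
                          "group": cols.get_level_values("group")})
            .groupby("donor")["group"].nunique()
        )
        bad = groups_per_donor[groups_per_donor > 1]
        if len(bad):
            raise DatasetFormatError(
                f"donors assigned to more than one group: {bad.index.tolist()}"
            )
        for name, meta in self.variables.iterrows():
            Compartment(meta["compartment"])
            if not meta["var_class"]:
                raise DatasetFormatError(
                    f"variable {name!r}: class tag must be non-empty"
                )

    # -- accessors --------------------------------------------------------

    @property
    def samples(self) -> list[SampleKey]:
        return [
            SampleKey(d, Group(g), Timepoint(t), Compartment(c))
            for d, g, t, c in self.values.columns
        ]

    @property
    def variable_meta(self) -> list[VariableMeta]:
        return [
            VariableMeta(str(name), Compartment(row["compartment"]), row["var_class"])
            for name, row in self.variables.iterrows()
        ]

    def donors(self, group: Group | str | None = None) -> list[str]:
        cols = self.values.columns
        if group is not None:
            g = Group(group).value
            mask = cols.get_level_values("group") == g
            cols = cols[mask]
        return sorted(set(cols.get_level_values("donor")))

    def storage_timepoints(self) -> list[Timepoint]:
        tps = {
            Timepoint(t)
            for t in self.values.columns.get_level_values("timepoint")
            if Timepoint(t).is_storage
        }
        return sorted(tps, key=lambda t: t.day)

    def variables_in(self, compartment: Compartment) -> list[str]:
        """Variables observable on the given side (``both`` counts for each)."""
        want = {compartment.value, Compartment.BOTH.value}
        return [
            str(n)
            for n, c in self.variables["compartment"].items()
            if c in want
        ]

    def series(
        self,
        variable: str,
        timepoint: Timepoint | str,
        group: Group | str | None = None,
    ) -> pd.Series:
        """Donor-indexed values of one variable at one timepoint (NaN dropped)."""
        tp = Timepoint(timepoint) if not isinstance(timepoint, Timepoint) else timepoint
        if variable not in self.values.index:
            raise KeyError(f"unknown variable: {variable!r}")
        row = self.values.loc[variable]
        mask = row.index.get_level_values("timepoint") == tp.value
        if group is not None:
            g = Group(group).value
            mask &= row.index.get_level_values("group") == g
        sub = row[mask]
        sub.index = sub.index.get_level_values("donor")
        return sub.dropna().sort_index()

    def pooled_series(
        self,
        variable: str,
        group: Group | str | None = None,
        include_baseline: bool = False,
    ) -> pd.Series:
        """One variable's observations pooled over (donor, storage timepoint).

        The index is ``donor:timepoint`` so that pooled observations from
        different timepoints of the same donor stay distinguishable.
        """
        parts = []
        tps: list[Timepoint] = list(self.storage_timepoints())
        if include_baseline:
            tps = [Timepoint.NS] + tps
        for tp in tps:
            s = self.series(variable, tp, group=group)
            s.index = [f"{d}:{tp.value}" for d in s.index]
            parts.append(s)
        if not parts:
            return pd.Series(dtype=float)
        return pd.concat(parts)

    # -- conversion -------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Canonical long table (one row per non-missing cell)."""
        stacked = (
            self.values.stack(COLUMN_LEVELS, future_stack=True)
            .rename("value")
            .reset_index()
        )
        stacked = stacked.dropna(subset=["value"])
        meta = self.variables.reset_index()
        out = stacked.merge(meta, on="variable", how="left")
        out = out.rename(columns={"compartment_x": "compartment",
                                  "compartment_y": "var_compartment"})
        cols = [
            "variable", "donor", "group", "timepoint", "compartment",
            "value", "var_class", "var_compartment",
        ]
        return out[cols].sort_values(
            ["variable", "donor", "timepoint"],
            key=lambda s: s.map(_timepoint_sort_key) if s.name == "timepoint" else s,
            kind="stable",
        ).reset_index(drop=True)

    def n_samples(self) -> int:
        return self.values.shape[1]

    def n_variables(self) -> int:
        return self.values.shape[0]
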