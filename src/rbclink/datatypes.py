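"""Domain types for longitudinal donor/storage correlation studies.

The study design these types describe: blood is drawn from each donor once at
donation ("in vivo" baseline, timepoint NS = non-stored) and the packed
red-cell unit prepared from it is sampled weekly during refrigerated storage
("ex vivo", days 7, 14, 21, 28, 35, 42).  Donors belong to one of two groups
(e.g. G6PD-deficient vs sufficient).  Variables are metabolites or
hematological/physiological parameters measured in one compartment or both.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Group(str, enum.Enum):
    DEFICIENT = "deficient"
    SUFFICIENT = "sufficient"


class Timepoint(str, enum.Enum):
    """Sampling timepoints: NS = fresh (non-stored) blood, D7..D42 weekly."""

    NS = "NS"
    D7 = "D7"
    D14 = "D14"
    D21 = "D21"
    D28 = "D28"
    D35 = "D35"
    D42 = "D42"

    @property
    def day(self) -> int:
        return 0 if self is Timepoint.NS else int(self.value[1:])

    @property
    def is_storage(self) -> bool:
        return self is not Timepoint.NS


#: Storage timepoints in chronological order.
STORAGE_TIMEPOINTS: tuple[Timepoint, ...] = tuple(
    t for t in Timepoint if t.is_storage
)

_TIMEPOINT_ALIASES = {
    "fresh": Timepoint.NS,
    "ns": Timepoint.NS,
    "d0": Timepoint.NS,
    "day0": Timepoint.NS,
}


def parse_timepoint(label: str) -> Timepoint:
    """Parse a timepoint label (``NS``, ``D7`` .. ``D42``; ``fresh`` = NS)."""
    s = str(label).strip()
    key = s.lower().replace(" ", "")
    if key in _TIMEPOINT_ALIASES:
        return _TIMEPOINT_ALIASES[key]
    key = key.replace("day", "d")
    try:
        return Timepoint(key.upper().replace("DAY", "D"))
    except ValueError:
        raise DatasetFormatError(f"unknown timepoint label: {label!r}") from None


class Compartment(str, enum.Enum):
    IN_VIVO = "in_vivo"
    EX_VIVO = "ex_vivo"
    #: variable-level only: measured both at baseline and in the stored unit
    BOTH = "both"


class DatasetFormatError(ValueError):
    """Malformed tabular input or violated dataset invariant."""


class ZeroVarianceError(ValueError):
    """A statistic that requires variation was given a constant series."""


class InsufficientDataError(ValueError):
    """Fewer paired observations than the minimum (3) for a defined test."""


class InfeasibleCorrelationError(ValueError):
    """Requested correlation structure is not positive semidefinite."""


@dataclass(frozen=True)
class SampleKey:
    """One measurement context: donor, group, timepoint, compartment.

    Baseline (NS) samples are in-vivo by definition; stored-unit samples
    (D7..D42) are ex-vivo.
    """

    donor_id: str
    group: Group
    timepoint: Timepoint
    compartment: Compartment

    def __post_init__(self) -> None:
        expected = (
            Compartment.IN_VIVO
            if self.timepoint is Timepoint.NS
            else Compartment.EX_VIVO
        )
        if self.compartment is not expected:
            raise DatasetFormatError(
                f"sample ({self.donor_id}, {self.timepoint.value}) must be "
                f"{expected.value}, got {self.compartment.value}"
            )


@dataclass(frozen=True)
class VariableMeta:
    """Variable-level metadata: compartment and a free-text class tag.

    The class tag (e.g. ``glycolysis``, ``redox``, ``hemolysis``) groups
    nodes into pathway/phenotype areas for sub-network extraction.
    """

    name: str
    compartment: Compartment
    var_class: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.name:
            raise DatasetFormatError("variable name must be non-empty")
        if not self.var_class:
            raise DatasetFormatError(
                f"variable {self.name!r}: class tag must be non-empty"
            )


class Method(str, enum.Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


@dataclass(frozen=True)
class CorrelationResult:
    """One pairwise correlation test with its decision audit trail.

    ``outliers_excluded`` lists donors flagged by the mean ± 2·SD rule and
    excluded during the Pearson re-test; when the re-test outcome was
    unchanged they are included back (``n_used`` is then the full n) but the
    flagged donors remain recorded here, and ``decision_trace`` records the
    re-test step.
    """

    var_a: str
    var_b: str
    timepoint: Timepoint | None
    method: Method
    r: float
    p: float
    n_used: int
    outliers_excluded: tuple[str, ...] = ()
    decision_trace: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: r={self.r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: p={self.p}")
        if self.n_used < 3:
            raise ValueError("n_used must be >= 3")


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def of(cls, r: float) -> "Sign":
        return cls.POSITIVE if r >= 0 else cls.NEGATIVE


@dataclass
class RepeatedEdge:
    """An in-vivo ↔ ex-vivo pair tested at every storage timepoint.

    ``passes_raw`` means the correlation was significant (p < alpha) at every
    tested storage day with a consistent sign — a "repeated correlation".
    ``representative_r`` is the r at the latest tested day (end of storage).
    ``partial`` marks variables measured at only a subset of storage days
    (e.g. end-of-storage-only assays); the repeated filter then applies to
    the days where data exist.
    """

    invivo_var: str
    exvivo_var: str
    per_timepoint: list[CorrelationResult] = field(default_factory=list)
    sign: Sign = Sign.POSITIVE
    representative_r: float = math.nan
    passes_raw: bool = False
    passes_corrected: bool = False
    partial: bool = False
    fail_reason: str | None = None

    @property
    def tested_timepoints(self) -> list[Timepoint]:
        return [c.timepoint for c in self.per_timepoint if c.timepoint]

    @property
    def max_p(self) -> float:
        if not self.per_timepoint:
            return math.nan
        return max(c.p for c in self.per_timepoint)


@dataclass(frozen=True)
class LinkageDelta:
    """Between-group change in the correlation of one variable pair.

    Under the default (absolute-magnitude) definition,
    ``delta = | |r_group1| - |r_group2| |`` and the pair is called rewired
    when delta exceeds the threshold (default 0.30).  ``sign_flip`` marks
    pairs whose correlation changes sign between groups with both |r| >= 0.2.
    """

    var_a: str
    var_b: str
    r_group1: float
    r_group2: float
    delta: float
    sign_flip: bool
    rewired: bool


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro–Wilk test outcome for one series."""

    W: float
    p: float
    n: int


@dataclass(frozen=True)
class AnovaRow:
    """Fixed-effects group × time ANOVA decomposition for one variable.

    For balanced designs the sums of squares decompose exactly:
    ss_total = ss_group + ss_time + ss_interaction + ss_error.  Under the
    unweighted-means analysis used for unbalanced cells the factor SS are
    on the cell-mean scale and the identity no longer holds.
    """

    variable: str
    F_group: float
    F_time: float
    F_interaction: float
    p_group: float
    p_time: float
    p_interaction: float
    sig_group: bool
    sig_time: bool
    sig_interaction: bool
    ss_group: float = math.nan
    ss_time: float = math.nan
    ss_interaction: float = math.nan
    ss_error: float = math.nan
    ss_total: float = math.nan
    balanced: bool = True
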