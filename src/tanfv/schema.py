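"""Variable schemas, discretization and cohort file I/O.

A cohort is a table of integer-coded discrete clinical variables, one row
per patient.  Each column is described by a :class:`VariableSpec`: an
ordered list of state labels (codes are consecutive integers starting at
0) and, for variables measured on a continuous scale (age in years, serum
AFP in ng/mL, tumor size in cm, survival time in months, ...), the
intervals that map a raw measurement onto a state code.

The default schema describes the 16-variable hepatocellular-carcinoma
hepatectomy cohort this package was built around: 15 clinical attributes
plus a binary survival-time class (short, ``<=10`` months, coded 0 versus
long, ``>10`` months, coded 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "Interval",
    "VariableSpec",
    "CohortTable",
    "SchemaError",
    "ValidationError",
    "default_schema",
    "discretize",
    "load_cohort",
    "write_cohort",
    "class_counts",
    "schema_to_yaml",
    "schema_from_yaml",
]


class SchemaError(ValueError):
    """A file or table does not match the declared variable schema."""


class ValidationError(ValueError):
    """A cell holds a value that is not a valid state code."""


@dataclass(frozen=True)
class Interval:
    """A real interval with explicit boundary closure on each side."""

    low: float
    high: float
    low_closed: bool = True
    high_closed: bool = False

    def __contains__(self, value: float) -> bool:
        if value < self.low or value > self.high:
            return False
        if value == self.low and not self.low_closed:
            return False
        if value == self.high and not self.high_closed:
            return False
        return True


def _cut(edges: Sequence[float]) -> tuple[Interval, ...]:
    """Left-closed/right-open intervals from edges; the last one is closed."""
    ivs = []
    for i in range(len(edges) - 1):
        last = i == len(edges) - 2
        ivs.append(Interval(edges[i], edges[i + 1], True, last))
    return tuple(ivs)


@dataclass(frozen=True)
class VariableSpec:
    """One column of a cohort: name, role, states and optional bins.

    Parameters
    ----------
    name : str
        Column identifier.
    states : tuple of str
        Ordered state labels; the state code of ``states[j]`` is ``j``.
    role : {"attribute", "class"}
        Whether the variable is a predictor or the class to be predicted.
    bins : tuple of Interval, optional
        For continuous sources, ``bins[j]`` is the interval mapped to
        state ``j``.  Intervals must be ordered and non-overlapping.
    units : str, optional
        Units of the raw (pre-discretization) measurement.
    """

    name: str
    states: tuple[str, ...]
    role: str = "attribute"
    bins: tuple[Interval, ...] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemaError(f"variable {self.name!r} needs >=2 states")
        if self.role not in ("attribute", "class"):
            raise SchemaError(f"variable {self.name!r}: bad role {self.role!r}")
        if self.bins is not None:
            if len(self.bins) != len(self.states):
                raise SchemaError(
                    f"variable {self.name!r}: {len(self.bins)} bins for "
                    f"{len(self.states)} states"
                )
            for a, b in zip(self.bins, self.bins[1:]):
                if b.low < a.high or (b.low == a.high and a.high_closed and b.low_closed):
                    raise SchemaError(f"variable {self.name!r}: bins overlap or decrease")

    @property
    def n_states(self) -> int:
        return len(self.states)


def discretize(raw_value: float, spec: VariableSpec) -> int:
    """Map a raw measurement onto the state code of its containing bin.

    Raises
    ------
    ValueError
        If the spec has no bins or the value falls outside every bin.
    """
    if spec.bins is None:
        raise ValueError(f"variable {spec.name!r} has no bins; it is already discrete")
    if not math.isfinite(raw_value):
        raise ValueError(f"variable {spec.name!r}: non-finite value {raw_value!r}")
    for j, iv in enumerate(spec.bins):
        if raw_value in iv:
            return j
    raise ValueError(
        f"variable {spec.name!r}: value {raw_value} outside all bins "
        f"[{spec.bins[0].low}, {spec.bins[-1].high}]"
    )


_INF = math.inf

# Age interval edges.  The primary convention is 16-45 / 46-59 / 60-84
# (value 46 already belongs to the middle bin, hence the edge at 46);
# an alternative convention with cuts at 45 and 60 is also in clinical
# use and selectable via ``age_bins="cut45"``.
_AGE_BINS = {
    "table1": _cut([16.0, 46.0, 60.0, 84.0]),
    "table4": _cut([16.0, 45.0, 60.0, 84.0]),
}

# Serum AFP: 0-8 ng/mL is the conventional normal range (closed at 8);
# the middle bin is the open interval (8, 400) so that values quoted at
# two-decimal resolution ("8.01 ... 399.99") land there; >=400 is high.
_AFP_BINS = (
    Interval(0.0, 8.0, True, True),
    Interval(8.0, 400.0, False, False),
    Interval(400.0, 121_000.0, True, True),
)

# Tumor size: any measurable tumor below 2 cm is "small" (the smallest
# recorded lesion is 0.8 cm, but no positive size is rejected).
_SIZE_BINS = (
    Interval(0.0, 2.0, False, False),
    Interval(2.0, 5.0, True, False),
    Interval(5.0, 10.0, True, False),
    Interval(10.0, _INF, True, False),
)

# Survival class: short means <=10 months (10 itself is short).
_SURVIVAL_BINS = (
    Interval(0.0, 10.0, False, True),
    Interval(10.0, _INF, False, False),
)

_BLOOD_BINS = (Interval(0.0, 400.0, True, True), Interval(400.0, _INF, False, False))
_TCPH_BINS = (Interval(0.0, 15.0, True, True), Interval(15.0, _INF, False, False))


def default_schema(age_bins: str = "table1") -> list[VariableSpec]:
    """The 16-variable hepatectomy-cohort schema.

    15 attributes (sex, age, hepatitis B/C history, preoperative AFP,
    Child-Pugh liver-function grade, tumor size and number, portal vein
    tumor thrombosis, operative method, metastasis, porta-hepatis
    clamping time, intraoperative blood loss, postoperative complication,
    postoperative TACE) plus the binary survival-time class.

    Parameters
    ----------
    age_bins : {"table1", "table4"}
        Which age-interval convention to use: cuts at 46/60 ("table1",
        the default) or at 45/60 ("table4").
    """
    if age_bins not in _AGE_BINS:
        raise SchemaError(f"age_bins must be 'table1' or 'table4', got {age_bins!r}")
    V = VariableSpec
    return [
        V("sex", ("female", "male")),
        V("age", ("16-45", "46-59", "60-84"), bins=_AGE_BINS[age_bins], units="years"),
        V("hbv", ("no", "yes")),
        V("hcv", ("no", "yes")),
        V("afp", ("0-8", "8-400", "400-121000"), bins=_AFP_BINS, units="ng/mL"),
        V("liver_function", ("child_a", "child_b")),
        V("tumor_size", ("<2", "2-4.9", "5-9.9", ">=10"), bins=_SIZE_BINS, units="cm"),
        V("tumor_number", ("single", "multi")),
        V("pvtt", ("no", "yes")),
        V("operative_method", ("pah", "anh")),
        V("metastasis", ("no", "yes")),
        V("tcph", ("<=15", ">15"), bins=_TCPH_BINS, units="min"),
        V("blood_loss", ("<=400", ">400"), bins=_BLOOD_BINS, units="mL"),
        V("complication", ("no", "yes")),
        V("tace", ("no", "yes")),
        V("survival", ("<=10", ">10"), role="class", bins=_SURVIVAL_BINS, units="months"),
    ]


@dataclass
class CohortTable:
    """A validated cohort: a schema plus integer-coded patient records."""

    schema: list[VariableSpec]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        names = [v.name for v in self.schema]
        if list(self.data.columns) != names:
            raise SchemaError(
                f"columns {list(self.data.columns)} do not match schema {names}"
            )
        self.data = self.data.astype(int)
        for v in self.schema:
            col = self.data[v.name]
            bad = col[(col < 0) | (col >= v.n_states)]
            if len(bad):
                row = int(bad.index[0])
                raise ValidationError(
                    f"row {row}, column {v.name!r}: code {int(bad.iloc[0])} "
                    f"outside 0..{v.n_states - 1}"
                )

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def class_var(self) -> VariableSpec:
        cls = [v for v in self.schema if v.role == "class"]
        if len(cls) != 1:
            raise SchemaError(f"schema has {len(cls)} class variables, need exactly 1")
        return cls[0]

    @property
    def attributes(self) -> list[VariableSpec]:
        return [v for v in self.schema if v.role == "attribute"]

    def spec(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise SchemaError(f"no variable named {name!r}")


def load_cohort(path: str | Path, schema: Sequence[VariableSpec]) -> CohortTable:
    """Read a coded-cohort CSV and validate it against *schema*.

    The file must have a header row whose names match the schema exactly
    (same order); every cell must be an integer state code in range.
    """
    path = Path(path)
    df = pd.read_csv(path)
    names = [v.name for v in schema]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in names]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")
    if df.isna().any().any():
        r, c = next(
            (i, c) for c in df.columns for i in df.index[df[c].isna()]
        )
        raise ValidationError(f"{path}: missing cell at row {r}, column {c!r}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")
    for c in names:
        if not (df[c] == df[c].astype(int)).all():
            bad = df.index[df[c] != df[c].astype(int)][0]
            raise ValidationError(f"{path}: non-integer cell at row {bad}, column {c!r}")
    return CohortTable(list(schema), df[names].astype(int).reset_index(drop=True))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as a coded CSV (header row, integer codes)."""
    table.data.to_csv(path, index=False)


def class_counts(table: CohortTable) -> dict[str, int]:
    """Number of records per class state, keyed by state label."""
    cls = table.class_var
    counts = table.data[cls.name].value_counts()
    return {cls.states[j]: int(counts.get(j, 0)) for j in range(cls.n_states)}


# ---------------------------------------------------------------------------
# YAML round-trip for schemas, so bin definitions can live in config files.

def _interval_to_dict(iv: Interval) -> dict:
    return {
        "low": None if iv.low == -_INF else iv.low,
        "high": None if iv.high == _INF else iv.high,
        "low_closed": iv.low_closed,
        "high_closed": iv.high_closed,
    }


def _interval_from_dict(d: dict) -> Interval:
    low = -_INF if d["low"] is None else float(d["low"])
    high = _INF if d["high"] is None else float(d["high"])
    return Interval(low, high, bool(d["low_closed"]), bool(d["high_closed"]))


def schema_to_yaml(schema: Iterable[VariableSpec]) -> str:
    out = []
    for v in schema:
        d: dict = {"name": v.name, "role": v.role, "states": list(v.states)}
        if v.units:
            d["units"] = v.units
        if v.bins is not None:
            d["bins"] = [_interval_to_dict(iv) for iv in v.bins]
        out.append(d)
    return yaml.safe_dump(out, sort_keys=False)


def schema_from_yaml(text: str) -> list[VariableSpec]:
    raw = yaml.safe_load(text)
    schema = []
    for d in raw:
        bins = None
        if "bins" in d:
            bins = tuple(_interval_from_dict(b) for b in d["bins"])
        schema.append(
            VariableSpec(
                name=d["name"],
                states=tuple(d["states"]),
                role=d.get("role", "attribute"),
                bins=bins,
                units=d.get("units"),
            )
        )
    return schema
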