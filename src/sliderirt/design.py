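"""Response data handling and study design.

Long-format response tables (one row per person x item x occasion), the
multitrait-multimethod design layout (random person-specific split of
each scale's items into single-slider and dual-range-slider halves, held
fixed across occasions), reverse coding, and the preprocessing exclusion
rules with their bookkeeping report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "ResponseRecord",
    "ResponseTable",
    "DesignSpec",
    "ExclusionConfig",
    "ExclusionReport",
    "read_responses",
    "write_responses",
    "make_design",
    "reverse_code",
    "apply_reverse_coding",
    "apply_exclusions",
]

COLUMNS = [
    "person_id",
    "item_id",
    "trait",
    "occasion",
    "format",
    "value_low",
    "value_high",
    "reverse_coded",
    "block_order",
    "response_time_s",
    "serious",
]

VAS = "VAS"
DRS = "DRS"
BLOCK_ORDERS = ("VAS_first", "DRS_first")

# MAD -> SD consistency factor for normal data
_MAD_SCALE = 1.4826


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names the row."""


@dataclass(frozen=True)
class ResponseRecord:
    """One observed slider response.

    For VAS responses ``value_low == value_high`` (the single slider
    position); for DRS responses they are the interval bounds.
    """

    person_id: str
    item_id: str
    trait: str
    occasion: int
    format: str
    value_low: float
    value_high: float
    reverse_coded: bool = False
    block_order: str = "VAS_first"
    response_time_s: float | None = None
    serious: bool | None = None

    def __post_init__(self) -> None:
        if self.format not in (VAS, DRS):
            raise ValidationError(f"unknown format {self.format!r}")
        if self.value_low > self.value_high:
            raise ValidationError(
                f"value_low {self.value_low} > value_high {self.value_high}"
            )
        if self.format == VAS and self.value_low != self.value_high:
            raise ValidationError("VAS record requires value_low == value_high")
        if self.occasion < 1:
            raise ValidationError(f"occasion must be >= 1, got {self.occasion}")
        if self.block_order not in BLOCK_ORDERS:
            raise ValidationError(f"unknown block_order {self.block_order!r}")


class ResponseTable:
    """A validated long-format collection of response records.

    Backed by a :class:`pandas.DataFrame` with the canonical column
    order.  Record-level invariants (value ordering, bounds, VAS
    degeneracy) and format consistency across occasions are enforced at
    construction; duplicate (person, item, occasion) rows are permitted
    so that raw exports can be loaded and cleaned by
    :func:`apply_exclusions`.
    """

    def __init__(self, df: pd.DataFrame, scale_max: float = 100.0):
        if scale_max <= 0:
            raise ValueError("scale_max must be positive")
        self.scale_max = float(scale_max)
        self.df = _coerce_frame(df, self.scale_max)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: list[ResponseRecord], scale_max: float = 100.0
    ) -> "ResponseTable":
        df = pd.DataFrame(
            [
                {
                    "person_id": r.person_id,
                    "item_id": r.item_id,
                    "trait": r.trait,
                    "occasion": r.occasion,
                    "format": r.format,
                    "value_low": r.value_low,
                    "value_high": r.value_high,
                    "reverse_coded": r.reverse_coded,
                    "block_order": r.block_order,
                    "response_time_s": r.response_time_s,
                    "serious": r.serious,
                }
                for r in records
            ],
            columns=COLUMNS,
        )
        return cls(df, scale_max=scale_max)

    def records(self) -> Iterator[ResponseRecord]:
        for row in self.df.itertuples(index=False):
            yield ResponseRecord(
                person_id=row.person_id,
                item_id=row.item_id,
                trait=row.trait,
                occasion=int(row.occasion),
                format=row.format,
                value_low=float(row.value_low),
                value_high=float(row.value_high),
                reverse_coded=bool(row.reverse_coded),
                block_order=row.block_order,
                response_time_s=None
                if pd.isna(row.response_time_s)
                else float(row.response_time_s),
                serious=None if pd.isna(row.serious) else bool(row.serious),
            )

    # -- properties --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseTable):
            return NotImplemented
        if self.scale_max != other.scale_max:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    @property
    def persons(self) -> list[str]:
        return list(pd.unique(self.df["person_id"]))

    @property
    def occasions(self) -> list[int]:
        return sorted(int(o) for o in self.df["occasion"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def has_duplicates(self) -> bool:
        return bool(
            self.df.duplicated(subset=["person_id", "item_id", "occasion"]).any()
        )

    def subset(self, mask) -> "ResponseTable":
        return ResponseTable(self.df[mask].reset_index(drop=True), self.scale_max)


def _coerce_frame(df: pd.DataFrame, scale_max: float) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy().reset_index(drop=True)
    df["person_id"] = df["person_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)
    df["trait"] = df["trait"].astype(str)
    df["occasion"] = df["occasion"].astype(int)
    df["format"] = df["format"].astype(str)
    for col in ("value_low", "value_high", "response_time_s"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["reverse_coded"] = df["reverse_coded"].astype(bool)
    df["serious"] = df["serious"].astype("boolean")

    bad_format = ~df["format"].isin([VAS, DRS])
    if bad_format.any():
        raise ValidationError(f"unknown format in row(s) {_rows(bad_format)}")
    bad_nan = df["value_low"].isna() | df["value_high"].isna()
    if bad_nan.any():
        raise ValidationError(f"missing response value in row(s) {_rows(bad_nan)}")
    bad_range = (
        (df["value_low"] < 0)
        | (df["value_high"] > scale_max)
        | (df["value_low"] > df["value_high"])
    )
    if bad_range.any():
        raise ValidationError(
            f"value outside [0, {scale_max}] or value_low > value_high "
            f"in row(s) {_rows(bad_range)}"
        )
    bad_vas = (df["format"] == VAS) & (df["value_low"] != df["value_high"])
    if bad_vas.any():
        raise ValidationError(
            f"VAS rows require value_low == value_high: row(s) {_rows(bad_vas)}"
        )
    bad_occ = df["occasion"] < 1
    if bad_occ.any():
        raise ValidationError(f"occasion < 1 in row(s) {_rows(bad_occ)}")
    bad_order = ~df["block_order"].isin(BLOCK_ORDERS)
    if bad_order.any():
        raise ValidationError(f"unknown block_order in row(s) {_rows(bad_order)}")

    # same (person, item) pair must keep its format at every occasion
    fmts = df.groupby(["person_id", "item_id"])["format"].nunique()
    inconsistent = fmts[fmts > 1]
    if len(inconsistent):
        pair = inconsistent.index[0]
        raise ValidationError(
            f"(person, item) pair {pair} appears with more than one format"
        )
    return df


def _rows(mask: pd.Series) -> str:
    idx = list(mask[mask].index[:5])
    return ", ".join(str(i) for i in idx) + (", ..." if mask.sum() > 5 else "")


# ---------------------------------------------------------------------------
# I/O


def read_responses(
    path, dialect: Mapping[str, str] | None = None, scale_max: float = 100.0
) -> ResponseTable:
    """Read a long-format response CSV.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    dialect : mapping, optional
        Maps canonical column names to the names used in the file,
        e.g. ``{"person_id": "subject"}``.
    """
    df = pd.read_csv(path)
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        df = df.rename(columns=rename)
    return ResponseTable(df, scale_max=scale_max)


def write_responses(table: ResponseTable, path) -> None:
    """Write a response table as CSV (stable column order, full precision)."""
    table.df.to_csv(path, index=False, columns=COLUMNS)


# ---------------------------------------------------------------------------
# Design


@dataclass(frozen=True)
class DesignSpec:
    """The multitrait-multimethod layout.

    ``format_assignment`` maps ``(person_id, item_id)`` to a response
    format; the assignment is shared by all occasions.  For every person
    and trait exactly half of the trait's items are VAS and half DRS.
    """

    n_persons: int
    traits: tuple[str, ...]
    items_per_trait: int
    n_occasions: int
    format_assignment: Mapping[tuple[str, str], str]
    block_order: Mapping[tuple[str, int], str]
    reverse_coded_items: frozenset = field(default_factory=frozenset)
    seed: int = 0

    @property
    def person_ids(self) -> list[str]:
        return [f"P{i + 1:03d}" for i in range(self.n_persons)]

    def item_ids(self, trait: str) -> list[str]:
        return [f"{trait}{j + 1:02d}" for j in range(self.items_per_trait)]

    @property
    def all_item_ids(self) -> list[str]:
        return [i for t in self.traits for i in self.item_ids(t)]

    @property
    def n_slots(self) -> int:
        """Total response slots: persons x items x occasions."""
        return self.n_persons * len(self.traits) * self.items_per_trait * self.n_occasions

    def trait_of(self, item_id: str) -> str:
        for t in self.traits:
            if item_id.startswith(t):
                return t
        raise KeyError(item_id)


def make_design(
    n_persons: int,
    items_per_trait: int,
    n_occasions: int = 2,
    traits: tuple[str, ...] = ("E", "C"),
    seed: int = 0,
    reverse_coded_items: frozenset = frozenset(),
) -> DesignSpec:
    """Randomly split each trait's items into VAS/DRS halves per person.

    The split is drawn independently per person and trait, then held
    fixed across occasions.  Block order is drawn uniformly per
    person-occasion.  Deterministic given ``seed``.
    """
    if items_per_trait % 2 != 0:
        raise ValueError("items_per_trait must be even to split into format halves")
    if n_persons < 1:
        raise ValueError("need at least one person")
    rng = np.random.default_rng(seed)
    persons = [f"P{i + 1:03d}" for i in range(n_persons)]
    assignment: dict[tuple[str, str], str] = {}
    for pid in persons:
        for trait in traits:
            items = [f"{trait}{j + 1:02d}" for j in range(items_per_trait)]
            half = items_per_trait // 2
            vas_items = rng.choice(items, size=half, replace=False)
            vas_set = set(vas_items.tolist())
            for item in items:
                assignment[(pid, item)] = VAS if item in vas_set else DRS
    block = {
        (pid, occ): BLOCK_ORDERS[rng.integers(2)]
        for pid in persons
        for occ in range(1, n_occasions + 1)
    }
    return DesignSpec(
        n_persons=n_persons,
        traits=tuple(traits),
        items_per_trait=items_per_trait,
        n_occasions=n_occasions,
        format_assignment=assignment,
        block_order=block,
        reverse_coded_items=frozenset(reverse_coded_items),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Reverse coding


def reverse_code(record: ResponseRecord, scale_max: float = 100.0) -> ResponseRecord:
    """Reflect a reverse-coded response about the scale midpoint.

    VAS: ``value -> scale_max - value``.  DRS: ``(low, high) ->
    (scale_max - high, scale_max - low)``, which preserves the interval
    width.  The ``reverse_coded`` flag is cleared on the result.
    """
    if not record.reverse_coded:
        return record
    return replace(
        record,
        value_low=scale_max - record.value_high,
        value_high=scale_max - record.value_low,
        reverse_coded=False,
    )


def apply_reverse_coding(table: ResponseTable) -> ResponseTable:
    """Reflect all flagged records in a table and clear their flags."""
    df = table.df.copy()
    m = df["reverse_coded"].to_numpy(dtype=bool)
    lo = df.loc[m, "value_low"].to_numpy()
    hi = df.loc[m, "value_high"].to_numpy()
    df.loc[m, "value_low"] = table.scale_max - hi
    df.loc[m, "value_high"] = table.scale_max - lo
    df["reverse_coded"] = False
    return ResponseTable(df, table.scale_max)


# ---------------------------------------------------------------------------
# Exclusions


@dataclass(frozen=True)
class ExclusionConfig:
    """Preprocessing exclusion rules, applied in a fixed order.

    1. duplicate (person, item, occasion) rows — keep the first in file
       order;
    2. persons flagged non-serious at any occasion;
    3. persons with a per-occasion completion time below/above the
       configured quantiles of the completion-time distribution
       (thresholds computed once, from the table as it stands when the
       rule runs);
    4. persons whose response mean or SD is a robust outlier
       (|median/MAD z| > ``outlier_z``).

    ``require_both_occasions`` additionally drops persons missing any
    occasion; the retained/attrition tallies are always reported.
    """

    drop_duplicates: bool = True
    drop_non_serious: bool = True
    fast_quantile: float | None = 0.01
    slow_quantile: float | None = 0.99
    outlier_z: float | None = 3.5
    require_both_occasions: bool = True

    def __post_init__(self) -> None:
        for q in (self.fast_quantile, self.slow_quantile):
            if q is not None and not 0.0 < q < 1.0:
                raise ValueError(f"quantile {q} outside (0, 1)")
        if (
            self.fast_quantile is not None
            and self.slow_quantile is not None
            and not self.fast_quantile < self.slow_quantile
        ):
            raise ValueError("fast_quantile must be below slow_quantile")
        if self.outlier_z is not None and self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")


@dataclass
class ExclusionReport:
    """Tallies of the exclusion rules and retention across occasions.

    ``n_removed_by_rule`` maps rule name to
    ``{"respondents": ..., "entries": ...}`` where an entry is one
    person-occasion questionnaire.
    """

    n_removed_by_rule: dict = field(default_factory=dict)
    n_retained_both: int = 0
    n_retained_t1_only: int = 0

    @property
    def attrition_pct(self) -> float:
        """100 * t1_only / (t1_only + both)."""
        total = self.n_retained_t1_only + self.n_retained_both
        if total == 0:
            return 0.0
        return 100.0 * self.n_retained_t1_only / total

    def to_dict(self) -> dict:
        return {
            "n_removed_by_rule": self.n_removed_by_rule,
            "n_retained_both": self.n_retained_both,
            "n_retained_t1_only": self.n_retained_t1_only,
            "attrition_pct": self.attrition_pct,
        }


def _entry_count(df: pd.DataFrame) -> int:
    return len(df[["person_id", "occasion"]].drop_duplicates())


def apply_exclusions(
    table: ResponseTable, cfg: ExclusionConfig
) -> tuple[ResponseTable, ExclusionReport]:
    """Apply the exclusion rules in order and report the bookkeeping."""
    df = table.df
    report = ExclusionReport()

    if cfg.drop_duplicates:
        dup = df.duplicated(subset=["person_id", "item_id", "occasion"], keep="first")
        removed = df[dup]
        report.n_removed_by_rule["duplicates"] = {
            "respondents": removed["person_id"].nunique(),
            "entries": _entry_count(removed),
        }
        df = df[~dup]

    if cfg.drop_non_serious:
        flagged = df.loc[df["serious"] == False, "person_id"].unique()  # noqa: E712
        removed = df[df["person_id"].isin(flagged)]
        report.n_removed_by_rule["non_serious"] = {
            "respondents": len(flagged),
            "entries": _entry_count(removed),
        }
        df = df[~df["person_id"].isin(flagged)]

    if cfg.fast_quantile is not None or cfg.slow_quantile is not None:
        if df["response_time_s"].isna().all():
            raise ValueError(
                "completion-time rule enabled but response_time_s is missing everywhere"
            )
        entry_time = df.groupby(["person_id", "occasion"])["response_time_s"].sum(
            min_count=1
        )
        times = entry_time.dropna()
        fast_persons: set = set()
        slow_persons: set = set()
        if cfg.fast_quantile is not None:
            lo = float(np.quantile(times.to_numpy(), cfg.fast_quantile))
            fast_persons = set(times[times < lo].index.get_level_values(0))
        if cfg.slow_quantile is not None:
            hi = float(np.quantile(times.to_numpy(), cfg.slow_quantile))
            slow_persons = set(times[times > hi].index.get_level_values(0))
        slow_persons -= fast_persons
        for name, persons in (("fast", fast_persons), ("slow", slow_persons)):
            removed = df[df["person_id"].isin(persons)]
            report.n_removed_by_rule[name] = {
                "respondents": len(persons),
                "entries": _entry_count(removed),
            }
        df = df[~df["person_id"].isin(fast_persons | slow_persons)]

    if cfg.outlier_z is not None:
        value = np.where(
            df["format"] == DRS,
            (df["value_low"] + df["value_high"]) / 2.0,
            df["value_low"],
        )
        per_person = (
            pd.DataFrame({"person_id": df["person_id"].to_numpy(), "value": value})
            .groupby("person_id")["value"]
            .agg(["mean", "std"])
            .fillna(0.0)
        )
        outliers: set = set()
        for col in ("mean", "std"):
            x = per_person[col].to_numpy()
            med = np.median(x)
            mad = np.median(np.abs(x - med)) * _MAD_SCALE
            if mad > 0:
                z = np.abs(x - med) / mad
                outliers |= set(per_person.index[z > cfg.outlier_z])
        removed = df[df["person_id"].isin(outliers)]
        report.n_removed_by_rule["outlier"] = {
            "respondents": len(outliers),
            "entries": _entry_count(removed),
        }
        df = df[~df["person_id"].isin(outliers)]

    occasions = sorted(df["occasion"].unique())
    per_person_occ = df.groupby("person_id")["occasion"].nunique()
    if occasions:
        first_only = df.groupby("person_id")["occasion"].agg(
            lambda s: set(s) == {occasions[0]}
        )
        report.n_retained_t1_only = int(first_only.sum())
        report.n_retained_both = int((per_person_occ == len(occasions)).sum())
    if cfg.require_both_occasions and occasions:
        complete = per_person_occ[per_person_occ == len(occasions)].index
        df = df[df["person_id"].isin(complete)]

    return ResponseTable(df.reset_index(drop=True), table.scale_max), report
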