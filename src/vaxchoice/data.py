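"""Long-format choice data container and CSV round-tripping.

The canonical on-disk layout is one row per respondent x task x
alternative: columns ``resp_id, task, alt, chosen``, the nine vaccine
attribute columns (empty on opt-out rows), and one column per respondent
covariate (repeated across the respondent's rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .types import ChoiceTask, Respondent, VaccineProfile, respondent_field_names

ATTRIBUTE_CSV_COLUMNS = (
    "cost",
    "effectiveness",
    "incubation",
    "protection",
    "mild",
    "severe",
    "recommender",
    "origin",
    "introduced",
)

KEY_COLUMNS = ("resp_id", "task", "alt", "chosen")

_NUMERIC_ATTRS = tuple(c for c in ATTRIBUTE_CSV_COLUMNS if c not in ("recommender", "origin"))


class DataValidationError(ValueError):
    """Raised when long-format records violate the task structure."""


@dataclass
class ChoiceDataset:
    """Validated panel of choice tasks in long format.

    Wraps the long DataFrame; rows are sorted by (resp_id, task) with
    alternatives in the fixed order A, B, optout.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate_long(self.df)

    # -- basic shape --------------------------------------------------------

    @property
    def n_tasks(self) -> int:
        return len(self.df) // 3

    @property
    def n_respondents(self) -> int:
        return self.df["resp_id"].nunique()

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.df["resp_id"].unique()

    def respondents(self) -> pd.DataFrame:
        """One row per respondent with the covariate columns, indexed by id."""
        cov = [c for c in respondent_field_names() if c in self.df.columns]
        return self.df.groupby("resp_id", sort=False)[cov].first()

    def respondent(self, resp_id) -> Respondent:
        row = self.respondents().loc[resp_id]
        kwargs = {
            k: (float(v) if k in ("household_income", "age", "bmi") else int(v))
            for k, v in row.items()
        }
        return Respondent(id=resp_id, **kwargs)

    # -- object views -------------------------------------------------------

    def iter_tasks(self) -> Iterator[tuple[Respondent, ChoiceTask]]:
        """Yield (Respondent, ChoiceTask) pairs; convenient for small data."""
        resp_cache: dict = {}
        for (rid, t), grp in self.df.groupby(["resp_id", "task"], sort=False):
            if rid not in resp_cache:
                resp_cache[rid] = self.respondent(rid)
            rows = {r["alt"]: r for _, r in grp.iterrows()}
            task = ChoiceTask(
                respondent_id=rid,
                task_index=int(t),
                alternative_A=_profile_from_row(rows["A"]),
                alternative_B=_profile_from_row(rows["B"]),
                chosen=grp.loc[grp["chosen"] == 1, "alt"].iloc[0],
            )
            yield resp_cache[rid], task

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        # %.17g round-trips float64 exactly; pandas' default writer truncates
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ChoiceDataset":
        # the round_trip parser restores float64 values bit-exactly
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df)

    def __eq__(self, other) -> bool:  # bit-identical round trip check
        if not isinstance(other, ChoiceDataset):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True)
            )
        except AssertionError:
            return False
        return True


def _profile_from_row(row) -> VaccineProfile:
    return VaccineProfile(
        cost=float(row["cost"]),
        effectiveness=float(row["effectiveness"]),
        incubation_days=float(row["incubation"]),
        protection_months=float(row["protection"]),
        mild_per10=float(row["mild"]),
        severe_per1e6=float(row["severe"]),
        recommender=str(row["recommender"]),
        origin=str(row["origin"]),
        introduced_months=float(row["introduced"]),
    )


def _validate_long(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS + ATTRIBUTE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"missing required columns: {missing}")
    if df.empty:
        raise DataValidationError("dataset has no rows")
    df = df.copy()
    bad_alt = ~df["alt"].isin(["A", "B", "optout"])
    if bad_alt.any():
        rows = df.index[bad_alt].tolist()[:5]
        raise DataValidationError(f"invalid alt labels at rows {rows}")
    dup = df.duplicated(subset=["resp_id", "task", "alt"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise DataValidationError(
            f"duplicate (resp_id, task, alt) combinations at rows {rows}"
        )
    df["chosen"] = df["chosen"].astype(int)

    counts = df.groupby(["resp_id", "task"])["alt"].count()
    bad = counts[counts != 3]
    if len(bad):
        raise DataValidationError(
            f"tasks without exactly 3 alternatives: {bad.index.tolist()[:5]}"
        )
    chosen_counts = df.groupby(["resp_id", "task"])["chosen"].sum()
    bad = chosen_counts[chosen_counts != 1]
    if len(bad):
        raise DataValidationError(
            f"tasks with zero or multiple chosen rows: {bad.index.tolist()[:5]}"
        )

    # canonical ordering: A, B, optout within each (resp_id, task)
    alt_order = pd.Categorical(df["alt"], categories=["A", "B", "optout"], ordered=True)
    df = (
        df.assign(_alt_order=alt_order.codes)
        .sort_values(["resp_id", "task", "_alt_order"], kind="stable")
        .drop(columns="_alt_order")
        .reset_index(drop=True)
    )

    vac = df["alt"] != "optout"
    for col in _NUMERIC_ATTRS:
        vals = pd.to_numeric(df.loc[vac, col], errors="coerce")
        if vals.isna().any():
            rows = vals.index[vals.isna()].tolist()[:5]
            raise DataValidationError(f"non-numeric {col} on vaccine rows {rows}")
        df.loc[vac, col] = vals
    return df


def dataset_from_objects(
    respondents: list[Respondent], tasks: list[ChoiceTask]
) -> ChoiceDataset:
    """Assemble the long DataFrame from typed objects."""
    resp_map = {r.id: r for r in respondents}
    cov_names = respondent_field_names()
    records = []
    for task in tasks:
        r = resp_map[task.respondent_id]
        cov = {name: getattr(r, name) for name in cov_names}
        for alt, profile in (
            ("A", task.alternative_A),
            ("B", task.alternative_B),
            ("optout", None),
        ):
            rec = {
                "resp_id": task.respondent_id,
                "task": task.task_index,
                "alt": alt,
                "chosen": int(task.chosen == alt),
            }
            if profile is None:
                rec.update({c: np.nan for c in ATTRIBUTE_CSV_COLUMNS})
            else:
                rec.update(
                    cost=profile.cost,
                    effectiveness=profile.effectiveness,
                    incubation=profile.incubation_days,
                    protection=profile.protection_months,
                    mild=profile.mild_per10,
                    severe=profile.severe_per1e6,
                    recommender=profile.recommender,
                    origin=profile.origin,
                    introduced=profile.introduced_months,
                )
            rec.update(cov)
            records.append(rec)
    return ChoiceDataset(pd.DataFrame.from_records(records))
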