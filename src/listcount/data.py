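"""Respondent tables for double-list experiments.

Two layouts are used throughout:

* **wide** (:class:`SurveyDataset`): one row per respondent with the item
  counts for both lists, the randomisation group, and the direct-question
  answer;
* **long** (:class:`LongDataset`): one row per respondent x list carrying the
  count ``Y``, the treatment indicator ``T`` and a list-A flag — the unit of
  analysis for every regression estimator.

Group 1 is treated on list A and control on list B; group 2 the reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .designs import ListDesign, default_designs

logger = logging.getLogger(__name__)

#: columns every wide table must carry, in canonical order
WIDE_COLUMNS = ["respondent_id", "group", "y_listA", "y_listB", "treated_list", "direct_report"]

LONG_COLUMNS = ["respondent_id", "list", "Y", "T", "list_A_flag"]


class ValidationError(ValueError):
    """A survey table violates the design contract; offenders are listed."""


@dataclass
class SurveyDataset:
    """Validated wide respondent table plus the two list designs."""

    df: pd.DataFrame
    designs: tuple[ListDesign, ListDesign] = field(default_factory=default_designs)

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        validate_wide(self.df, self.designs)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in WIDE_COLUMNS]

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class LongDataset:
    """Stacked respondent x list observations."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"long table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    def restrict(self, list_id: str) -> "LongDataset":
        """Rows for a single list (the single-list analysis sample)."""
        sub = self.df[self.df["list"] == list_id]
        if sub.empty:
            raise ValidationError(f"no rows for list {list_id!r}")
        return LongDataset(sub.copy())

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in LONG_COLUMNS]


def validate_wide(df: pd.DataFrame, designs: tuple[ListDesign, ListDesign]) -> None:
    """Check the wide-table contract, raising with row numbers on failure."""
    missing = [c for c in WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    problems: list[str] = []

    dup = df["respondent_id"][df["respondent_id"].duplicated()]
    if not dup.empty:
        problems.append(f"duplicate respondent_id values: {sorted(dup.unique().tolist())[:10]}")

    for col in ("group", "y_listA", "y_listB", "direct_report"):
        bad = df.index[df[col].isna()].tolist()
        if bad:
            problems.append(f"missing values in {col!r} at rows {bad[:10]}")
    if problems:
        raise ValidationError("; ".join(problems))

    bad_group = df.index[~df["group"].isin([1, 2])].tolist()
    if bad_group:
        problems.append(f"group must be 1 or 2; offending rows {bad_group[:10]}")
    bad_direct = df.index[~df["direct_report"].isin([0, 1])].tolist()
    if bad_direct:
        problems.append(f"direct_report must be 0/1; offending rows {bad_direct[:10]}")

    design_by_id = {d.list_id: d for d in designs}
    for col, list_id in (("y_listA", "A"), ("y_listB", "B")):
        j = design_by_id[list_id].n_items
        treated = df["group"] == (1 if list_id == "A" else 2)
        upper = treated.map({True: j + 1, False: j})
        bad = df.index[(df[col] < 0) | (df[col] > upper)].tolist()
        if bad:
            problems.append(
                f"{col} outside [0, J] (control) or [0, J+1] (treated), J={j}; rows {bad[:10]}"
            )
    expected_treated = df["group"].map({1: "A", 2: "B"})
    bad_t = df.index[df["treated_list"] != expected_treated].tolist()
    if bad_t:
        problems.append(f"treated_list inconsistent with group at rows {bad_t[:10]}")

    if problems:
        raise ValidationError("; ".join(problems))


def read_survey(
    path: str | Path, designs: tuple[ListDesign, ListDesign] | None = None
) -> SurveyDataset:
    """Read and validate a wide respondent CSV (comma separated, header row)."""
    df = pd.read_csv(path)
    return SurveyDataset(df, designs or default_designs())


def to_long(data: SurveyDataset) -> LongDataset:
    """Stack the wide table into respondent x list rows.

    Each respondent contributes two rows; ``T`` is 1 on the treated list
    only, so the long table has exactly ``n`` treated rows.
    """
    df = data.df
    covs = ["direct_report", *data.covariates]  # carried along for paired analyses
    rows = []
    for list_id, ycol, treat_group in (("A", "y_listA", 1), ("B", "y_listB", 2)):
        part = pd.DataFrame(
            {
                "respondent_id": df["respondent_id"],
                "list": list_id,
                "Y": df[ycol],
                "T": (df["group"] == treat_group).astype(int),
                "list_A_flag": int(list_id == "A"),
            }
        )
        for c in covs:
            part[c] = df[c].to_numpy()
        rows.append(part)
    long_df = pd.concat(rows, ignore_index=True)
    return LongDataset(long_df)


def to_wide(
    data: LongDataset, designs: tuple[ListDesign, ListDesign] | None = None,
    direct_report: pd.Series | None = None,
) -> SurveyDataset:
    """Inverse of :func:`to_long` (direct reports supplied separately if the
    long table came without them)."""
    df = data.df
    covs = data.covariates
    has_direct = "direct_report" in covs
    piv = df.pivot(index="respondent_id", columns="list", values="Y")
    treated = df[df["T"] == 1].set_index("respondent_id")["list"]
    wide = pd.DataFrame(
        {
            "respondent_id": piv.index,
            "group": treated.reindex(piv.index).map({"A": 1, "B": 2}).to_numpy(),
            "y_listA": piv["A"].to_numpy(),
            "y_listB": piv["B"].to_numpy(),
            "treated_list": treated.reindex(piv.index).to_numpy(),
        }
    )
    first = df.drop_duplicates("respondent_id").set_index("respondent_id")
    if has_direct:
        wide["direct_report"] = first["direct_report"].reindex(piv.index).to_numpy()
    elif direct_report is not None:
        wide["direct_report"] = direct_report.reindex(piv.index).to_numpy()
    else:
        raise ValidationError("direct_report not present in long table nor supplied")
    for c in covs:
        if c != "direct_report":
            wide[c] = first[c].reindex(piv.index).to_numpy()
    wide = wide.sort_values("respondent_id").reset_index(drop=True)
    return SurveyDataset(wide, designs or default_designs())


def expand_categorical(df: pd.DataFrame, column: str) -> tuple[pd.DataFrame, list[str]]:
    """Expand a categorical covariate into 0/1 indicators.

    The reference level is the most frequent category and gets no column.
    """
    counts = df[column].value_counts()
    reference = counts.index[0]
    out = df.copy()
    new_cols = []
    for level in counts.index[1:]:
        name = f"{column}_{level}"
        out[name] = (df[column] == level).astype(int)
        new_cols.append(name)
    logger.info("expanded %r into %d indicators (reference %r)", column, len(new_cols), reference)
    return out.drop(columns=[column]), new_cols


def drop_missing_covariates(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Listwise deletion on the given covariates, logging the count dropped."""
    keep = df.dropna(subset=columns)
    dropped = len(df) - len(keep)
    if dropped:
        logger.warning("listwise deletion removed %d rows with missing covariates", dropped)
    return keep
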