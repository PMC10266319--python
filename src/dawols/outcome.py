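"""Outcome construction for days-alive-without-life-support (DAWOLS) type outcomes.

A DAWOLS-type outcome counts, per patient, the number of days within a fixed
follow-up window on which the patient was alive and free of life support
(mechanical ventilation, vasopressors/inotropes, renal replacement therapy).
Days alive and out of hospital (DAOH) is the same construction with a
narrower set of "free" states. Deceased patients are usually penalised with
the worst possible value: 0 days, or -1 when the outcome is treated as an
ordinal variable so that death sorts below every attainable day count.

Days are 1-based; the follow-up window is the closed set {1, ..., max_days}.
The day of death counts as a dead day (not a free day), and death is
absorbing: once a patient is dead they stay dead for the rest of follow-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

STATES = ("home", "hospital", "life_support", "dead")

#: states that count as "alive without life support" (DAWOLS). DAOH uses {"home"}.
DEFAULT_FREE_STATES = frozenset({"home", "hospital"})

DEATH_HANDLINGS = ("penalize_zero", "penalize_minus_one", "actual")
SCALES = ("days", "proportion", "ordinal")


class DataError(ValueError):
    """Structural problem in input data (missing days, non-absorbing death...)."""


class ConfigError(ValueError):
    """Invalid or incompatible outcome / model configuration."""


@dataclass(frozen=True)
class OutcomeSpec:
    """Follow-up length, death-handling rule and outcome scale.

    Parameters
    ----------
    max_days
        Follow-up truncation in days (e.g. 28). The outcome lives on
        {0..max_days} (days), {k/max_days} (proportion) or the observed
        ordered categories including -1 (ordinal).
    death_handling
        ``penalize_zero`` assigns non-survivors 0 days, ``penalize_minus_one``
        assigns -1 (ordinal scale only, a category worse than all real
        values), ``actual`` keeps the observed count without penalty.
    scale
        ``days``, ``proportion`` (days / max_days) or ``ordinal``.
    free_states
        Daily states counted as outcome days. The default counts any day
        alive and not on life support (DAWOLS); ``{"home"}`` yields DAOH.
    """

    max_days: int = 28
    death_handling: str = "penalize_zero"
    scale: str = "days"
    free_states: frozenset = field(default_factory=lambda: DEFAULT_FREE_STATES)

    def __post_init__(self):
        if not (isinstance(self.max_days, (int, np.integer)) and self.max_days > 0):
            raise ConfigError(f"max_days must be a positive integer, got {self.max_days!r}")
        if self.death_handling not in DEATH_HANDLINGS:
            raise ConfigError(f"unknown death_handling {self.death_handling!r}")
        if self.scale not in SCALES:
            raise ConfigError(f"unknown scale {self.scale!r}")
        if self.death_handling == "penalize_minus_one" and self.scale != "ordinal":
            raise ConfigError(
                "penalize_minus_one assigns a category below all day counts and "
                "is only valid with scale='ordinal'"
            )
        object.__setattr__(self, "free_states", frozenset(self.free_states))
        bad = self.free_states - set(STATES)
        if bad:
            raise ConfigError(f"unknown free_states {sorted(bad)}")
        if "dead" in self.free_states:
            raise ConfigError("'dead' can never be a free state")

    def with_(self, **kw) -> "OutcomeSpec":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeSpec":
        d = dict(d)
        if "free_states" in d:
            d["free_states"] = frozenset(d["free_states"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "OutcomeSpec":
        """Load a spec from a YAML or JSON config file."""
        text = open(path).read()
        d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# daily-state table validation and collapsing


def validate_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Validate a long daily-state table (patient_id, day, state).

    Enforces: known states; exactly one row per (patient, day); days contiguous
    from 1; death absorbing. Returns the table sorted by (patient_id, day).
    Raises :class:`DataError` naming the offending patient and day.
    """
    required = {"patient_id", "day", "state"}
    missing = required - set(daily.columns)
    if missing:
        raise DataError(f"daily table missing columns {sorted(missing)}")
    bad_states = set(daily["state"].unique()) - set(STATES)
    if bad_states:
        raise DataError(f"unknown states {sorted(map(str, bad_states))}")
    daily = daily.sort_values(["patient_id", "day"], kind="stable").reset_index(drop=True)
    for pid, grp in daily.groupby("patient_id", sort=False):
        days = grp["day"].to_numpy()
        expected = np.arange(1, len(days) + 1)
        if len(days) != len(np.unique(days)):
            dup = int(days[np.argmax(np.diff(days) == 0)])
            raise DataError(f"patient {pid!r}: duplicate row for day {dup}")
        if not np.array_equal(days, expected):
            gap = int(expected[np.argmax(days != expected)])
            raise DataError(f"patient {pid!r}: missing day {gap} (days must run 1..n)")
        dead = (grp["state"].to_numpy() == "dead")
        if dead.any():
            first = int(np.argmax(dead))
            if not dead[first:].all():
                bad_day = first + 1 + int(np.argmax(~dead[first:]))
                raise DataError(
                    f"patient {pid!r}: non-absorbing death (alive on day {bad_day} "
                    f"after dying on day {first + 1})"
                )
    return daily


def build_outcome_from_daily(daily: pd.DataFrame, spec: OutcomeSpec) -> pd.DataFrame:
    """Collapse a daily-state table into per-patient outcomes.

    The raw count is the number of days in 1..max_days whose state is in
    ``spec.free_states`` (post-discharge days and days between repeat
    life-support episodes all count); ``died`` is True if the patient is dead
    on any day of the window. Death handling is then applied per ``spec``.

    Returns a DataFrame with columns ``patient_id``, ``outcome``, ``died``,
    ``raw_count``.
    """
    daily = validate_daily(daily)
    max_obs = daily.groupby("patient_id")["day"].max().min()
    if spec.max_days > max_obs:
        raise DataError(
            f"max_days={spec.max_days} exceeds observed follow-up ({max_obs} days) "
            "for at least one patient"
        )
    window = daily[daily["day"] <= spec.max_days]
    free = window["state"].isin(spec.free_states)
    dead = window["state"] == "dead"
    agg = pd.DataFrame(
        {
            "raw_count": free.groupby(window["patient_id"], sort=False).sum(),
            "died": dead.groupby(window["patient_id"], sort=False).any(),
        }
    ).reset_index()
    agg["outcome"] = [
        apply_death_handling(rc, d, spec)
        for rc, d in zip(agg["raw_count"], agg["died"])
    ]
    return agg[["patient_id", "outcome", "died", "raw_count"]]


def apply_death_handling(raw_count: int, died: bool, spec: OutcomeSpec):
    """Apply the spec's death-handling rule to one raw day count.

    Survivors are unchanged under every rule; non-survivors get 0
    (``penalize_zero``), -1 (``penalize_minus_one``, ordinal only) or their
    actual count (``actual``).
    """
    raw_count = int(raw_count)
    if not 0 <= raw_count <= spec.max_days:
        raise DataError(f"raw_count {raw_count} outside [0, {spec.max_days}]")
    if not died or spec.death_handling == "actual":
        return raw_count
    if spec.death_handling == "penalize_zero":
        return 0
    return -1  # penalize_minus_one; spec validation guarantees ordinal scale


def to_proportion(outcome_days: int, max_days: int) -> float:
    """Rescale a day count to a proportion of the maximum number of days.

    Boundary membership (0 or 1) is decided on the integer inputs; the -1
    death code is rejected because the beta-family models live on [0, 1].
    """
    outcome_days = int(outcome_days)
    if outcome_days == -1:
        raise ConfigError(
            "outcome -1 (ordinal death code) cannot be rescaled to a proportion; "
            "use death_handling='penalize_zero' before beta modelling"
        )
    if not 0 <= outcome_days <= max_days:
        raise DataError(f"outcome_days {outcome_days} outside [0, {max_days}]")
    return outcome_days / max_days


def to_ordinal_categories(outcomes) -> tuple[np.ndarray, list[int]]:
    """Map outcomes to ordered category indices.

    Categories are the distinct observed values sorted ascending (-1, the
    death category, sorts first when present). Returns ``(codes, value_map)``
    where ``value_map[code] = original value``; the value map is what the
    estimand layer later multiplies category probabilities by.
    """
    values = np.asarray(outcomes)
    if not np.issubdtype(values.dtype, np.integer):
        as_int = values.astype(int)
        if not np.array_equal(as_int, values):
            raise DataError("ordinal outcomes must be integers")
        values = as_int
    value_map = sorted(np.unique(values).tolist())
    if len(value_map) < 3:
        raise ConfigError(
            f"only {len(value_map)} distinct outcome values; the ordinal model is "
            "degenerate — use logistic regression instead"
        )
    codes = np.searchsorted(value_map, values)
    return codes, [int(v) for v in value_map]


# ---------------------------------------------------------------------------
# per-patient trial table


def validate_trial_table(df: pd.DataFrame, spec: OutcomeSpec | None = None) -> pd.DataFrame:
    """Validate a per-patient analysis table (patient_id, arm, outcome, died).

    ``arm`` becomes an ordered categorical whose first level is the control
    arm (declared order respected if already categorical, else order of first
    appearance). At least two non-empty arms are required and arm/outcome may
    not contain missing values.
    """
    required = {"patient_id", "arm", "outcome", "died"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"trial table missing columns {sorted(missing)}")
    if df["arm"].isna().any() or df["outcome"].isna().any():
        raise DataError("missing values in arm/outcome are not supported")
    df = df.copy()
    if not isinstance(df["arm"].dtype, pd.CategoricalDtype):
        levels = list(pd.unique(df["arm"]))
        df["arm"] = pd.Categorical(df["arm"], categories=levels, ordered=True)
    counts = df["arm"].value_counts()
    if (counts > 0).sum() < 2:
        raise DataError("need at least 2 non-empty arms")
    out = df["outcome"].to_numpy()
    if spec is not None:
        if out.max() > spec.max_days:
            raise DataError(f"outcome exceeds max_days={spec.max_days}")
        if (out == -1).any():
            if spec.death_handling != "penalize_minus_one":
                raise DataError("outcome -1 present but death_handling is not penalize_minus_one")
            if not df.loc[out == -1, "died"].all():
                raise DataError("outcome -1 on a surviving patient")
        if out.min() < -1:
            raise DataError("outcomes below -1 are invalid")
    return df


def arms(df: pd.DataFrame) -> list[str]:
    """Arm levels in declared order; the first level is the control arm."""
    if "arm" not in df.columns:
        raise DataError("data has no 'arm' column")
    col = df["arm"]
    if not isinstance(col.dtype, pd.CategoricalDtype):
        col = pd.Categorical(col, categories=list(pd.unique(col)), ordered=True)
        return [a for a in col.categories if (col == a).any()]
    return [a for a in col.cat.categories if (col == a).any()]


def covariate_columns(df: pd.DataFrame) -> list[str]:
    reserved = {"patient_id", "arm", "outcome", "died", "raw_count"}
    return [c for c in df.columns if c not in reserved]


def read_daily_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["day"] = df["day"].astype(int)
    return validate_daily(df)


def read_trial_csv(path, spec: OutcomeSpec | None = None, arm_order=None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if arm_order is not None:
        df["arm"] = pd.Categorical(df["arm"], categories=list(arm_order), ordered=True)
    df["died"] = df["died"].astype(bool)
    return validate_trial_table(df, spec)
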