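"""Task data model and per-trial decision variables.

A trial presents two offers, one per juice (A and B). Each offer carries a
juice quantity and a binary action cost (low ``+`` = short saccade, high
``-`` = long saccade). Exactly one offer is low cost and the two offers, and
the two saccade targets, sit in opposite hemifields. The animal reveals its
choice with a saccade; the chosen juice, together with the spatial layout,
defines everything downstream analyses need.

The canonical in-memory container is a pandas ``DataFrame`` with one row per
trial (see :data:`TRIAL_COLUMNS`). :class:`Offer` and :class:`TrialRecord`
are light validated views used to build small sessions by hand.

Twenty-one candidate decision variables are defined per trial, each a
function of the offers, the choice, the spatial configuration, and the
session's behavioral fit (relative value ``rho`` and action cost ``xi``).
They span four reference frames: juice-based (offer value A/B, chosen
juice), cost-based (offer value -/+, chosen cost), visuospatial (offer value
L/R, offer locations) and action-based (target-value and target-location
variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"
LEFT, RIGHT = "L", "R"

#: Canonical trial-table columns (the trial CSV schema).
TRIAL_COLUMNS = [
    "session_id",
    "trial_index",
    "qA",
    "qB",
    "costA",
    "costB",
    "offerA_side",
    "targetA_side",
    "chosen_juice",
    "chosen_side",
    "target_angle_deg",
]

#: Decision variables in canonical order (index 1..21).
VARIABLES = {
    1: "offer_value_A",
    2: "offer_value_B",
    3: "chosen_juice",
    4: "offer_value_minus",
    5: "offer_value_plus",
    6: "chosen_cost",
    7: "offer_value_left",
    8: "offer_value_right",
    9: "offer_value_target_left",
    10: "offer_value_target_right",
    11: "cost_of_A",
    12: "offer_A_location",
    13: "target_A_location",
    14: "offer_plus_location",
    15: "target_plus_location",
    16: "spatial_congruence",
    17: "chosen_value",
    18: "value_ratio",
    19: "cost_benefit_conflict",
    20: "chosen_offer_loc_only",
    21: "chosen_target_loc_only",
}
VARIABLE_INDEX = {name: idx for idx, name in VARIABLES.items()}

#: Location-only variables, assessed with the group-only (horizontal) model.
LOCATION_ONLY = (20, 21)

#: ANCOVA covariates (1 = contralateral to the recorded hemisphere).
COVARIATES = ("chosen_offer_contra", "chosen_target_contra")

#: Variables collapsed for display (offer value pairs share a label).
COLLAPSED_GROUPS = {
    "offer_value_juice": (1, 2),
    "offer_value_cost": (4, 5),
    "offer_value_location": (7, 8),
    "offer_value_target": (9, 10),
}


@dataclass(frozen=True)
class Offer:
    """A single offer: juice identity, quantity (drops), and action cost."""

    juice_id: str
    quantity: int
    cost_level: str

    def __post_init__(self) -> None:
        if self.juice_id not in ("A", "B"):
            raise ValueError(f"juice_id must be 'A' or 'B', got {self.juice_id!r}")
        if self.quantity < 0:
            raise ValueError("offer quantity must be non-negative")
        if self.cost_level not in (LOW, HIGH):
            raise ValueError(f"cost_level must be 'low' or 'high', got {self.cost_level!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One completed choice trial.

    Previous-trial fields feed the hysteresis terms of the choice model and
    default to ``None`` on the first trial of a session.
    """

    session_id: str
    trial_index: int
    offer_a: Offer
    offer_b: Offer
    offer_a_side: str
    target_a_side: str
    chosen_juice: str
    prev_chosen_juice: str | None = None
    prev_chosen_cost: str | None = None
    target_angle_deg: float = np.nan

    def __post_init__(self) -> None:
        if {self.offer_a.cost_level, self.offer_b.cost_level} != {LOW, HIGH}:
            raise ValueError("exactly one offer must be low cost and the other high cost")
        if self.offer_a_side not in (LEFT, RIGHT) or self.target_a_side not in (LEFT, RIGHT):
            raise ValueError("sides must be 'L' or 'R'")
        if self.chosen_juice not in ("A", "B"):
            raise ValueError("chosen_juice must be 'A' or 'B'")

    @property
    def offer_b_side(self) -> str:
        return RIGHT if self.offer_a_side == LEFT else LEFT

    @property
    def target_b_side(self) -> str:
        return RIGHT if self.target_a_side == LEFT else LEFT

    @property
    def chosen_offer(self) -> Offer:
        return self.offer_a if self.chosen_juice == "A" else self.offer_b

    @property
    def chosen_side(self) -> str:
        return self.offer_a_side if self.chosen_juice == "A" else self.offer_b_side

    @property
    def chosen_target_side(self) -> str:
        return self.target_a_side if self.chosen_juice == "A" else self.target_b_side


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    """Convert TrialRecord objects into the canonical trial table."""
    rows = []
    for t in trials:
        rows.append(
            {
                "session_id": t.session_id,
                "trial_index": t.trial_index,
                "qA": t.offer_a.quantity,
                "qB": t.offer_b.quantity,
                "costA": t.offer_a.cost_level,
                "costB": t.offer_b.cost_level,
                "offerA_side": t.offer_a_side,
                "targetA_side": t.target_a_side,
                "chosen_juice": t.chosen_juice,
                "chosen_side": t.chosen_side,
                "target_angle_deg": t.target_angle_deg,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def validate_trials(trials: pd.DataFrame) -> None:
    """Check structural invariants of a trial table; raise ``ValueError`` on failure."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns and c != "target_angle_deg"]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if len(trials) == 0:
        return
    if (trials["qA"] < 0).any() or (trials["qB"] < 0).any():
        raise ValueError("offer quantities must be non-negative")
    costs = set(map(tuple, trials[["costA", "costB"]].drop_duplicates().to_numpy()))
    if not costs <= {(LOW, HIGH), (HIGH, LOW)}:
        raise ValueError("exactly one offer per trial must be low cost")
    if not set(trials["chosen_juice"].unique()) <= {"A", "B"}:
        raise ValueError("chosen_juice must be 'A' or 'B'")
    for col in ("offerA_side", "targetA_side"):
        if not set(trials[col].unique()) <= {LEFT, RIGHT}:
            raise ValueError(f"{col} must be 'L' or 'R'")


def add_indicators(trials: pd.DataFrame) -> pd.DataFrame:
    """Append the signed indicator differences used by the logistic choice model.

    Adds ``d_cost`` (cost of B low minus cost of A low), ``d_hyst`` and
    ``d_costhyst`` (previous-trial juice / cost-level hysteresis), ``d_offer``
    and ``d_target`` (side-bias terms), plus the resolved ``chosen_side`` and
    ``chosen_target_side``. Hysteresis indicators are 0 on the first trial of
    each session; previous-trial state is taken from the preceding row in
    trial order within each session.
    """
    df = trials.sort_values(["session_id", "trial_index"]).copy()
    b_low = (df["costB"] == LOW).astype(int)
    a_low = (df["costA"] == LOW).astype(int)
    df["d_cost"] = b_low - a_low

    offer_b_side = np.where(df["offerA_side"] == LEFT, RIGHT, LEFT)
    target_b_side = np.where(df["targetA_side"] == LEFT, RIGHT, LEFT)
    df["chosen_side"] = np.where(df["chosen_juice"] == "A", df["offerA_side"], offer_b_side)
    df["chosen_target_side"] = np.where(
        df["chosen_juice"] == "A", df["targetA_side"], target_b_side
    )
    chosen_cost_level = np.where(df["chosen_juice"] == "A", df["costA"], df["costB"])

    grp = df.groupby("session_id", sort=False)
    prev_juice = grp["chosen_juice"].shift(1)
    prev_cost = pd.Series(chosen_cost_level, index=df.index).groupby(df["session_id"]).shift(1)
    df["d_hyst"] = np.where(prev_juice == "B", 1, 0) - np.where(prev_juice == "A", 1, 0)
    df["d_costhyst"] = np.where(df["costB"] == prev_cost, 1, 0) - np.where(
        df["costA"] == prev_cost, 1, 0
    )

    df["d_offer"] = np.where(df["offerA_side"] == LEFT, -1, 1)
    df["d_target"] = np.where(df["targetA_side"] == LEFT, -1, 1)
    return df


def enumerate_trial_types(trials: pd.DataFrame) -> pd.DataFrame:
    """Partition a single session's trials into trial types with counts.

    A trial type is the pair of offers together with the choice, e.g.
    ``[1A+:3B-, A]``. Returns one row per trial type with its count; counts
    sum to the number of trials.
    """
    if len(trials) == 0:
        return pd.DataFrame(
            columns=["qA", "costA", "qB", "costB", "chosen_juice", "trial_type", "count"]
        )
    if trials["session_id"].nunique() > 1:
        raise ValueError("trials must come from a single session")
    keys = ["qA", "costA", "qB", "costB", "chosen_juice"]
    counts = trials.groupby(keys, sort=True).size().reset_index(name="count")
    counts["trial_type"] = counts.apply(_trial_type_label, axis=1)
    return counts[keys + ["trial_type", "count"]]


def _trial_type_label(row: pd.Series) -> str:
    sa = "+" if row["costA"] == LOW else "-"
    sb = "+" if row["costB"] == LOW else "-"
    return f"[{int(row['qA'])}A{sa}:{int(row['qB'])}B{sb}, {row['chosen_juice']}]"


def trial_type_key(trials: pd.DataFrame) -> pd.Series:
    """A label per trial identifying its trial type (offers + choice)."""
    sa = np.where(trials["costA"] == LOW, "+", "-")
    sb = np.where(trials["costB"] == LOW, "+", "-")
    return (
        trials["qA"].astype(int).astype(str)
        + "A"
        + sa
        + ":"
        + trials["qB"].astype(int).astype(str)
        + "B"
        + sb
        + ","
        + trials["chosen_juice"]
    )


def contralateral_side(hemisphere: str) -> str:
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    return RIGHT if hemisphere == "left" else LEFT


def variable_table(
    trials: pd.DataFrame,
    rho: float,
    xi: float,
    hemisphere: str = "left",
) -> pd.DataFrame:
    """Compute the 21 decision variables and the two ANCOVA covariates per trial.

    ``rho`` (relative value of juice A in units of juice B) and ``xi`` (action
    cost, same units) come from the session's behavioral fit. Offer values are

    * offer value A = ``rho * qA + xi * [A low cost]``
    * offer value B = ``qB + xi * [B low cost]``

    so that the low-cost offer earns the value bonus ``xi``. Binary variables
    are coded 0/1; the covariates are 1 when the chosen offer (or chosen
    target) lies in the hemifield contralateral to the recorded hemisphere.
    ``value_ratio`` (other/chosen value) is NaN where the chosen value is 0;
    such trials are excluded pairwise from regressions on that variable.
    """
    df = trials if "d_cost" in trials.columns else add_indicators(trials)
    out = pd.DataFrame(index=df.index)

    a_low = (df["costA"] == LOW).to_numpy(int)
    b_low = (df["costB"] == LOW).to_numpy(int)
    ov_a = rho * df["qA"].to_numpy(float) + xi * a_low
    ov_b = df["qB"].to_numpy(float) + xi * b_low
    chose_b = (df["chosen_juice"] == "B").to_numpy(int)
    a_left = (df["offerA_side"] == LEFT).to_numpy(int)
    ta_left = (df["targetA_side"] == LEFT).to_numpy(int)

    out["offer_value_A"] = ov_a
    out["offer_value_B"] = ov_b
    out["chosen_juice"] = chose_b
    out["offer_value_minus"] = np.where(a_low == 0, ov_a, ov_b)
    out["offer_value_plus"] = np.where(a_low == 1, ov_a, ov_b)
    # 1 if the chosen offer is the low-cost one
    out["chosen_cost"] = np.where(chose_b == 1, b_low, a_low)
    out["offer_value_left"] = np.where(a_left == 1, ov_a, ov_b)
    out["offer_value_right"] = np.where(a_left == 0, ov_a, ov_b)
    out["offer_value_target_left"] = np.where(ta_left == 1, ov_a, ov_b)
    out["offer_value_target_right"] = np.where(ta_left == 0, ov_a, ov_b)
    out["cost_of_A"] = a_low
    out["offer_A_location"] = a_left
    out["target_A_location"] = ta_left
    out["offer_plus_location"] = np.where(a_low == 1, a_left, 1 - a_left)
    out["target_plus_location"] = np.where(a_low == 1, ta_left, 1 - ta_left)
    out["spatial_congruence"] = (a_left == ta_left).astype(int)

    chosen_value = np.where(chose_b == 1, ov_b, ov_a)
    other_value = np.where(chose_b == 1, ov_a, ov_b)
    out["chosen_value"] = chosen_value
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(chosen_value > 0, other_value / np.where(chosen_value > 0, chosen_value, 1.0), np.nan)
    out["value_ratio"] = ratio
    if np.isnan(ratio).any():
        warnings.warn(
            f"{int(np.isnan(ratio).sum())} trial(s) have chosen value 0; "
            "value_ratio set to NaN and excluded pairwise",
            stacklevel=2,
        )
    # conflict: the high-cost offer carries the higher offer value
    high_value = np.where(a_low == 0, ov_a, ov_b)
    low_value = np.where(a_low == 0, ov_b, ov_a)
    out["cost_benefit_conflict"] = (high_value > low_value).astype(int)

    chosen_left = np.where(chose_b == 1, 1 - a_left, a_left)
    chosen_target_left = np.where(chose_b == 1, 1 - ta_left, ta_left)
    out["chosen_offer_loc_only"] = chosen_left
    out["chosen_target_loc_only"] = chosen_target_left

    contra = contralateral_side(hemisphere)
    contra_is_left = 1 if contra == LEFT else 0
    out["chosen_offer_contra"] = np.where(chosen_left == contra_is_left, 1, 0)
    out["chosen_target_contra"] = np.where(chosen_target_left == contra_is_left, 1, 0)
    return out


def compute_variables(trial: TrialRecord, fit, hemisphere: str = "left") -> pd.Series:
    """The 21-variable vector (plus covariates) for a single trial.

    ``fit`` is anything exposing ``rho`` and ``xi`` attributes (typically a
    :class:`~costchoice.behavior.BehaviorFit`).
    """
    df = trials_to_frame([trial])
    if trial.prev_chosen_juice is not None:
        # splice the stated previous-trial state into the indicator columns
        df = add_indicators(df)
        df["d_hyst"] = (trial.prev_chosen_juice == "B") * 1 - (trial.prev_chosen_juice == "A") * 1
        if trial.prev_chosen_cost is not None:
            df["d_costhyst"] = int(trial.offer_b.cost_level == trial.prev_chosen_cost) - int(
                trial.offer_a.cost_level == trial.prev_chosen_cost
            )
    table = variable_table(df, rho=fit.rho, xi=fit.xi, hemisphere=hemisphere)
    return table.iloc[0]
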