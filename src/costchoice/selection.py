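"""Stepwise and best-subset selection of the encoded variable set.

Both procedures operate on the incidence table produced by the tuning
classification: for each task-related response, the set of variables that
explain it and the variable providing its best fit. The *explanatory power*
of a variable subset is the number of responses collectively explained —
responses whose explained set intersects the subset.

The stepwise procedure selects at each step the variable with the highest
number of best fits within any single time window, removes every response
that variable explains, and repeats on the residual data; it stops when the
marginal explanatory power of the best remaining variable falls below 2% of
the task-related responses. The best-subset procedure enumerates all
subsets of each size exhaustively (guaranteeing optimality) and stops at
the smallest size whose increment to the next size falls below the same 2%
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .task import VARIABLES

DEFAULT_STOP_FRACTION = 0.02
MAX_SUBSET_SIZE = 8


@dataclass
class SelectionResult:
    method: str  # "stepwise" or "best_subset"
    selected: list  # variable ids in selection order (stepwise) or the optimal set
    trace: pd.DataFrame  # per step/size: variable(s), marginal and cumulative power
    stop_reason: str
    n_responses: int


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize an incidence table: explained sets as Python sets."""
    df = table.copy()
    if df["explained"].dtype == object and len(df) and isinstance(df["explained"].iloc[0], str):
        df["explained"] = df["explained"].apply(
            lambda s: frozenset(int(v) for v in s.split(",")) if s else frozenset()
        )
    else:
        df["explained"] = df["explained"].apply(frozenset)
    return df


def explanatory_power(subset, table: pd.DataFrame) -> int:
    """Number of responses collectively explained by the variables in ``subset``."""
    subset = set(subset)
    df = _as_table(table)
    return int(df["explained"].apply(lambda s: bool(s & subset)).sum())


def _best_fit_score(df: pd.DataFrame, vid: int, window_rule: str) -> int:
    counts = df.loc[df["best_variable"] == vid].groupby("window_id").size()
    if counts.empty:
        return 0
    return int(counts.max() if window_rule == "max" else counts.sum())


def stepwise_select(
    table: pd.DataFrame,
    stop_fraction: float = DEFAULT_STOP_FRACTION,
    window_rule: str = "max",
) -> SelectionResult:
    """Greedy selection by per-window best-fit counts on residual data.

    ``window_rule`` controls how best-fit counts across windows score a
    candidate: ``"max"`` (highest count within any single window, the
    default) or ``"sum"`` (total across windows). Ties break by higher
    marginal explanatory power, then by variable index.
    """
    if len(table) == 0:
        raise ValueError("incidence table is empty")
    if window_rule not in ("max", "sum"):
        raise ValueError("window_rule must be 'max' or 'sum'")
    df = _as_table(table)
    n_total = len(df)
    threshold = stop_fraction * n_total
    residual = df
    selected, rows = [], []
    cumulative = 0
    stop_reason = "no variables left"
    while True:
        candidates = sorted(set().union(*residual["explained"]) - set(selected))
        if not candidates:
            break
        scored = []
        for vid in candidates:
            marginal = int(residual["explained"].apply(lambda s: vid in s).sum())
            scored.append((_best_fit_score(residual, vid, window_rule), marginal, -vid))
        best_score, marginal, neg_vid = max(scored)
        vid = -neg_vid
        if marginal < threshold:
            stop_reason = (
                f"marginal explanatory power {marginal} < "
                f"{stop_fraction:.0%} of {n_total} responses"
            )
            break
        selected.append(vid)
        cumulative += marginal
        rows.append(
            {
                "step": len(selected),
                "variable_id": vid,
                "variable": VARIABLES.get(vid, str(vid)),
                "best_fit_score": best_score,
                "marginal_power": marginal,
                "cumulative_power": cumulative,
            }
        )
        residual = residual[~residual["explained"].apply(lambda s: vid in s)]
        if residual.empty:
            stop_reason = "all responses explained"
            break
    trace = pd.DataFrame(
        rows,
        columns=[
            "step",
            "variable_id",
            "variable",
            "best_fit_score",
            "marginal_power",
            "cumulative_power",
        ],
    )
    return SelectionResult("stepwise", selected, trace, stop_reason, n_total)


def _bitmask_counts(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    masks = df["explained"].apply(lambda s: sum(1 << (v - 1) for v in s))
    counts = masks.value_counts()
    return counts.index.to_numpy(np.int64), counts.to_numpy(np.int64)


def best_subset_select(
    table: pd.DataFrame,
    max_size: int = MAX_SUBSET_SIZE,
    stop_fraction: float = DEFAULT_STOP_FRACTION,
    size: int | None = None,
) -> SelectionResult:
    """Exhaustively optimal subset of each size (optimality guaranteed).

    When ``size`` is given — the pipeline passes the stepwise selection
    size, so the two procedures are compared like for like — the optimal
    subset of exactly that size is returned. Otherwise the returned size is
    the smallest n whose marginal gain at n+1 falls below ``stop_fraction``
    of the responses.

    Decision variables come in collinear families (the offer-value
    variants), so distinct subsets often tie in explanatory power; ties
    break by the subset's total number of best fits, then lexicographically.
    """
    if len(table) == 0:
        raise ValueError("incidence table is empty")
    if max_size > MAX_SUBSET_SIZE or (size is not None and size > MAX_SUBSET_SIZE):
        raise ValueError(
            f"subset size exceeds the enumeration budget; "
            f"use sizes <= {MAX_SUBSET_SIZE} or the stepwise procedure"
        )
    df = _as_table(table)
    n_total = len(df)
    threshold = stop_fraction * n_total
    masks, counts = _bitmask_counts(df)
    universe = sorted(set().union(*df["explained"]))
    best_fit_counts = df["best_variable"].value_counts()

    def power_of(bits: int) -> int:
        return int(counts[(masks & bits) != 0].sum())

    best_by_size = {}
    rows = []
    prev_power = 0
    limit = min(max_size if size is None else size, len(universe))
    for n in range(1, limit + 1):
        best = (-1, -1, None)
        for combo in combinations(universe, n):
            bits = sum(1 << (v - 1) for v in combo)
            p = power_of(bits)
            if p > best[0]:
                best = (p, int(best_fit_counts.reindex(combo).fillna(0).sum()), combo)
            elif p == best[0]:
                bf = int(best_fit_counts.reindex(combo).fillna(0).sum())
                if bf > best[1]:
                    best = (p, bf, combo)
        best_by_size[n] = best
        rows.append(
            {
                "size": n,
                "variables": ",".join(str(v) for v in best[2]),
                "power": best[0],
                "marginal_power": best[0] - prev_power,
            }
        )
        prev_power = best[0]

    if size is not None:
        chosen_n = limit
        stop_reason = f"size fixed to {limit}"
    else:
        chosen_n = limit
        stop_reason = f"reached max size {limit}"
        for n in range(1, limit):
            gain = best_by_size[n + 1][0] - best_by_size[n][0]
            if gain < threshold:
                chosen_n = n
                stop_reason = (
                    f"gain from size {n} to {n + 1} is {gain} < "
                    f"{stop_fraction:.0%} of {n_total} responses"
                )
                break
    selected = list(best_by_size[chosen_n][2])
    trace = pd.DataFrame(rows, columns=["size", "variables", "power", "marginal_power"])
    return SelectionResult("best_subset", selected, trace, stop_reason, n_total)
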