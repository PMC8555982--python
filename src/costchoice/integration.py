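"""Dimensional integration: does chosen-value coding reflect the action cost?

Two variants of the chosen-value variable are compared on each
chosen-value-coding response: the *cost-affected* variant (offer values
include the action-cost term xi) and the *cost-independent* variant (xi
forced to 0, i.e. rho*qA or qB of the chosen juice). For a response where
both variants explain the activity (parallel-lines ANCOVA, p < 0.05), the
difference

    dR2 = R2_cost_affected - R2_cost_independent

measures which variant fits better. Responses are aggregated by trial
epoch — early (post-offer to pre-target, before action planning is
possible) vs late (post-target to post-juice) — and each epoch's dR2
distribution is tested against zero with a two-sided Wilcoxon signed-rank
test; the epochs are compared with a rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import ancova
from .task import LOW, trial_type_key
from .windows import COVARIATE_BY_WINDOW, EARLY_EPOCH_WINDOWS, LATE_EPOCH_WINDOWS


def chosen_value_variants(trials: pd.DataFrame, rho: float, xi: float) -> pd.DataFrame:
    """Per-trial cost-affected and cost-independent chosen values.

    The two variants coincide when xi = 0.
    """
    chose_b = (trials["chosen_juice"] == "B").to_numpy()
    a_low = (trials["costA"] == LOW).to_numpy(int)
    b_low = (trials["costB"] == LOW).to_numpy(int)
    qa = trials["qA"].to_numpy(float)
    qb = trials["qB"].to_numpy(float)
    affected = np.where(chose_b, qb + xi * b_low, rho * qa + xi * a_low)
    independent = np.where(chose_b, qb, rho * qa)
    return pd.DataFrame(
        {"cost_affected": affected, "cost_independent": independent}, index=trials.index
    )


def epoch_of(window_id: str) -> str | None:
    if window_id in EARLY_EPOCH_WINDOWS:
        return "early"
    if window_id in LATE_EPOCH_WINDOWS:
        return "late"
    return None


def delta_r2_table(
    rates: pd.DataFrame,
    trials: pd.DataFrame,
    variables: pd.DataFrame,
    rho: float,
    xi: float,
    responses: pd.DataFrame | None = None,
    level: str = "means",
    min_per_cell: int = 2,
) -> pd.DataFrame:
    """dR2 for every response where both chosen-value variants explain.

    Returns one row per qualifying response with the two R2 values, dR2,
    the assigned R2 (the larger of the two, used when classifying the
    response as chosen-value coding without biasing toward either variant),
    and the trial epoch. Responses in the pre-offer window are excluded
    from both epochs. Responses where only one variant explains are counted
    in the ``one_sided`` attribute of the result's ``attrs``.
    """
    trials_ix = trials.set_index("trial_index") if trials.index.name != "trial_index" else trials
    variants = chosen_value_variants(trials_ix, rho, xi)
    tt = trial_type_key(trials_ix)
    wanted = None
    if responses is not None:
        wanted = set(map(tuple, responses[["neuron_id", "window_id"]].to_numpy()))
    rows = []
    n_one_sided = 0
    for (nid, wid), sub in rates.groupby(["neuron_id", "window_id"], sort=False):
        if wanted is not None and (nid, wid) not in wanted:
            continue
        epoch = epoch_of(wid)
        if epoch is None:
            continue
        r = sub.set_index("trial_index")["rate"].reindex(trials_ix.index)
        group = variables.set_index(trials_ix.index)[COVARIATE_BY_WINDOW[wid]] if not variables.index.equals(trials_ix.index) else variables[COVARIATE_BY_WINDOW[wid]]
        fits = {}
        for name in ("cost_affected", "cost_independent"):
            y, x, g = ancova.aggregate_points(
                r, tt, group, variants[name], level=level, min_per_cell=min_per_cell
            )
            fits[name] = ancova.fit_parallel(y, x, g, neuron_id=nid, window_id=wid)
        ca, ci = fits["cost_affected"], fits["cost_independent"]
        if ca.explains != ci.explains:
            n_one_sided += 1
        if not (ca.explains and ci.explains):
            continue
        rows.append(
            {
                "neuron_id": nid,
                "window_id": wid,
                "epoch": epoch,
                "r2_cost_affected": ca.r2,
                "r2_cost_independent": ci.r2,
                "r2_assigned": max(ca.r2, ci.r2),
                "delta_r2": ca.r2 - ci.r2,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "window_id",
            "epoch",
            "r2_cost_affected",
            "r2_cost_independent",
            "r2_assigned",
            "delta_r2",
        ],
    )
    out.attrs["one_sided"] = n_one_sided
    return out


@dataclass
class IntegrationResult:
    """Population summary of the variant comparison, by epoch."""

    n_early: int
    n_late: int
    mean_early: float
    mean_late: float
    median_early: float
    median_late: float
    p_early: float  # signed-rank vs 0
    p_late: float
    p_between: float  # rank-sum early vs late

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _signed_rank_p(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    nonzero = values[values != 0]
    if len(nonzero) == 0:
        warnings.warn("all values are zero; signed-rank p undefined, reporting 1.0", stacklevel=2)
        return 1.0
    return float(stats.wilcoxon(values, alternative="two-sided").pvalue)


def epoch_summary(delta: pd.DataFrame) -> IntegrationResult:
    """Means, medians and tests of the dR2 distributions per epoch."""
    early = delta.loc[delta["epoch"] == "early", "delta_r2"].to_numpy(float)
    late = delta.loc[delta["epoch"] == "late", "delta_r2"].to_numpy(float)

    def _stats(v: np.ndarray) -> tuple[float, float, float]:
        if len(v) == 0:
            warnings.warn("empty epoch; statistics undefined", stacklevel=3)
            return np.nan, np.nan, np.nan
        return float(np.mean(v)), float(np.median(v)), _signed_rank_p(v)

    mean_e, med_e, p_e = _stats(early)
    mean_l, med_l, p_l = _stats(late)
    if len(early) and len(late):
        p_between = float(stats.ranksums(early, late).pvalue)
    else:
        p_between = np.nan
    return IntegrationResult(
        len(early), len(late), mean_e, mean_l, med_e, med_l, p_e, p_l, p_between
    )
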