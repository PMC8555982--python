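"""Session-level parameter tests and cross-area encoding comparisons.

Across sessions, each normalized behavioral parameter (action cost xi,
choice hysteresis eta, cost hysteresis phi, spatial biases delta and
epsilon) is summarized by its median and tested against zero with a
two-sided Wilcoxon signed-rank test (exact distribution up to n = 25,
normal approximation above). The relative value rho is reported without a
test — it is a quantity ratio with no natural null at zero.

Encoding percentages from two areas are compared per (window, variable)
cell with a Pearson chi-square test on the 2x2 table area x encodes/not
(df = 1, no continuity correction). Counts for the comparison area are
user-supplied; they are never recomputed here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import PARAM_NAMES

EXACT_WILCOXON_MAX_N = 25


def signed_rank_test(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a zero median."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if len(v) == 0 or np.all(v == 0):
        warnings.warn("degenerate sample; signed-rank p undefined", stacklevel=2)
        return np.nan
    method = "exact" if len(v) <= EXACT_WILCOXON_MAX_N else "approx"
    try:
        return float(stats.wilcoxon(v, alternative="two-sided", method=method).pvalue)
    except ValueError:
        # exact method rejects zeros/ties; fall back to the approximation
        return float(stats.wilcoxon(v, alternative="two-sided", method="approx").pvalue)


def session_param_tests(fits: pd.DataFrame, min_sessions: int = 6) -> pd.DataFrame:
    """Median and signed-rank test per normalized parameter across sessions.

    ``fits`` is a behavior-fit table with one row per session (columns
    ``rho, xi, eta, phi, delta, epsilon``).
    """
    if len(fits) < min_sessions:
        raise ValueError(f"need >= {min_sessions} sessions, got {len(fits)}")
    rows = []
    for name in PARAM_NAMES:
        v = fits[name].to_numpy(float)
        p = np.nan if name == "rho" else signed_rank_test(v)
        rows.append({"parameter": name, "median": float(np.median(v)), "n": len(v), "p": p})
    return pd.DataFrame(rows)


def area_comparison(
    n_encoding_1: int, n_total_1: int, n_encoding_2: int, n_total_2: int
) -> dict:
    """Chi-square comparison of encoding proportions between two areas.

    Returns the chi-square statistic (df = 1, no continuity correction), its
    p-value, and both percentages. When any expected cell count falls below
    1 a Fisher exact p-value is reported alongside with a warning; with a
    degenerate margin (no neuron encodes in either area, or all do) the
    statistic is 0 and p = 1.
    """
    if n_total_1 <= 0 or n_total_2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= n_encoding_1 <= n_total_1 and 0 <= n_encoding_2 <= n_total_2):
        raise ValueError("encoding counts must lie within totals")
    table = np.array(
        [
            [n_encoding_1, n_total_1 - n_encoding_1],
            [n_encoding_2, n_total_2 - n_encoding_2],
        ],
        float,
    )
    out = {
        "pct_1": 100.0 * n_encoding_1 / n_total_1,
        "pct_2": 100.0 * n_encoding_2 / n_total_2,
        "fisher_p": np.nan,
    }
    if (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate margin in 2x2 table; chi2 = 0", stacklevel=2)
        out.update({"chi2": 0.0, "p": 1.0})
        return out
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    out.update({"chi2": float(chi2), "p": float(p)})
    if (expected < 1).any():
        warnings.warn(
            "expected cell count < 1; reporting Fisher exact p alongside", stacklevel=2
        )
        out["fisher_p"] = float(stats.fisher_exact(table.astype(int))[1])
    return out


def area_comparison_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`area_comparison` over a counts table.

    ``counts`` has one row per (window, variable) with columns
    ``window_id, variable, n_encoding_1, n_total_1, n_encoding_2,
    n_total_2``.
    """
    rows = []
    for _, r in counts.iterrows():
        res = area_comparison(
            int(r["n_encoding_1"]), int(r["n_total_1"]), int(r["n_encoding_2"]), int(r["n_total_2"])
        )
        rows.append({"window_id": r["window_id"], "variable": r.get("variable", ""), **res})
    return pd.DataFrame(rows)
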